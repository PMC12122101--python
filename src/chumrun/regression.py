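"""Log-linear regression of cohort return rates on hypothesized stressors.

The response is ``log R_t`` (natural log of the release-year return rate, a
proportion).  Candidate covariates are grouped into thematic subset models
(hatchery carryovers, ocean conditions, predators/competitors).  Within each
allowed combination of groups the covariate pool is screened for
multicollinearity by sequential VIF removal, then every subset of the retained
covariates is fitted by OLS and ranked by small-sample-corrected AICc.
Combinations are compared by their minimum AICc; coefficients may be averaged
with Akaike weights over models within a Delta-AICc threshold of the best.
Effect sizes are reported multiplicatively, ``exp(beta)`` per practical unit.

Conventions
-----------
* The intercept is always included and never a selection candidate.
* AICc uses the Gaussian-likelihood parameter count ``k = p + 1`` (regression
  coefficients including the intercept, plus the residual variance), so
  ``AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1)``.
* RSS is floored at 1e-300 before taking the log, so a perfect fit yields a
  large negative (finite) AICc instead of ``-inf``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RSS_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# OLS fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """An OLS fit of log return rate on a set of covariate columns."""

    names: tuple[str, ...]          # covariate names, excluding the intercept
    beta: np.ndarray                # coefficients, intercept first
    se: np.ndarray                  # standard errors, intercept first
    sigma2: float                   # residual variance RSS/(n - p)
    n: int
    p: int                          # number of coefficients incl. intercept
    k: int                          # AICc parameter count = p + 1
    rss: float
    aicc: float
    r2: float
    adj_r2: float
    fitted: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    xtx_inv: np.ndarray             # (X'X)^{-1}, intercept first
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=("intercept",) + self.names)

    @property
    def stderr(self) -> pd.Series:
        return pd.Series(self.se, index=("intercept",) + self.names)

    def pvalues(self) -> pd.Series:
        t = self.beta / self.se
        p = 2.0 * stats.t.sf(np.abs(t), df=self.n - self.p)
        return pd.Series(p, index=("intercept",) + self.names)


def aicc(rss: float, n: int, p: int) -> float:
    """AICc for a Gaussian linear model with ``p`` coefficients.

    ``k = p + 1`` counts the residual variance.  Requires ``n - k - 1 > 0``.
    """
    k = p + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k}")
    rss = max(rss, RSS_FLOOR)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _design(Z: pd.DataFrame | np.ndarray, names=None):
    if isinstance(Z, pd.DataFrame):
        names = tuple(Z.columns)
        Zv = Z.to_numpy(dtype=float)
    else:
        Zv = np.asarray(Z, dtype=float)
        if Zv.ndim == 1:
            Zv = Zv[:, None]
        names = tuple(names) if names is not None else tuple(
            f"z{i}" for i in range(Zv.shape[1])
        )
    X = np.column_stack([np.ones(Zv.shape[0]), Zv])
    return X, names


def ols_fit(y, Z, names=None) -> FitResult:
    """Fit ``y = b0 + Z b + e`` by least squares.

    Parameters
    ----------
    y : array-like, response (log return rates).
    Z : DataFrame or 2-D array of covariate columns (may have zero columns).
    names : column names when ``Z`` is a bare array.

    Raises
    ------
    ValueError on rank deficiency, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(Z, names)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"n={n} too small for p={p} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    H_diag = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan
    return FitResult(
        names=names, beta=beta, se=se, sigma2=sigma2, n=n, p=p, k=p + 1,
        rss=rss, aicc=aicc(rss, n, p), r2=r2, adj_r2=adj_r2,
        fitted=fitted, residuals=resid, leverage=H_diag, xtx_inv=xtx_inv,
        X=X, y=y,
    )


def _collinear_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Columns of Z perfectly explained by the others (R^2 ~ 1)."""
    bad = []
    for j, name in enumerate(names):
        col = X[:, j + 1]
        others = np.delete(X, j + 1, axis=1)
        b, _, _, _ = np.linalg.lstsq(others, col, rcond=None)
        resid = col - others @ b
        denom = ((col - col.mean()) ** 2).sum()
        r2 = 1.0 - (resid @ resid) / denom if denom > 0 else 1.0
        if r2 > 1.0 - 1e-10:
            bad.append(name)
    return bad or list(names)


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------

def vif_values(Z: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) for every column of ``Z``.

    ``R^2_j`` is from regressing column j on the remaining columns plus an
    intercept.  Perfectly collinear columns get ``inf``.
    """
    cols = list(Z.columns)
    out = {}
    for j, name in enumerate(cols):
        yj = Z[name].to_numpy(dtype=float)
        others = Z.drop(columns=name).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(yj)), others])
        b, _, _, _ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ b
        tss = ((yj - yj.mean()) ** 2).sum()
        if tss <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - (resid @ resid) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_screen(Z: pd.DataFrame, threshold: float = 3.0):
    """Sequentially drop the max-VIF column until all VIFs are below threshold.

    Ties at the maximum break lexicographically by column name.  Returns the
    retained DataFrame and a removal log of ``(name, vif_at_removal)``.
    """
    if Z.shape[1] < 1:
        return Z, []
    kept = Z.copy()
    removed: list[tuple[str, float]] = []
    while kept.shape[1] >= 2:
        v = vif_values(kept)
        vmax = v.max()
        if vmax < threshold:
            break
        worst = sorted(v.index[v == vmax])[0]
        removed.append((worst, float(vmax)))
        logger.info("VIF screen: removing %s (VIF=%.3g)", worst, vmax)
        kept = kept.drop(columns=worst)
    return kept, removed


# ---------------------------------------------------------------------------
# All-subsets selection
# ---------------------------------------------------------------------------

@dataclass
class RankedModel:
    names: tuple[str, ...]
    aicc: float
    fit: FitResult


def all_subsets_select(y, Z: pd.DataFrame, max_s: int = 20) -> list[RankedModel]:
    """Fit every subset of the columns of ``Z`` (including the null model).

    Models are ranked by AICc; ties break toward fewer covariates, then
    lexicographic names.  Subsets too large for the sample size are skipped
    with a warning.
    """
    s = Z.shape[1]
    if s > max_s:
        raise ValueError(f"{s} covariates would require 2^{s} fits (max_s={max_s})")
    y = np.asarray(y, dtype=float)
    n = len(y)
    models: list[RankedModel] = []
    cols = list(Z.columns)
    for r in range(s + 1):
        for combo in itertools.combinations(cols, r):
            p = len(combo) + 1
            if n - (p + 1) - 1 <= 0:
                logger.warning("skipping subset %s: n=%d too small", combo, n)
                continue
            fit = ols_fit(y, Z[list(combo)] if combo else Z[[]])
            models.append(RankedModel(names=combo, aicc=fit.aicc, fit=fit))
    models.sort(key=lambda m: (m.aicc, len(m.names), m.names))
    return models


# ---------------------------------------------------------------------------
# Subset-model (group) combinations
# ---------------------------------------------------------------------------

@dataclass
class CombinationResult:
    groups: tuple[str, ...]
    pool: tuple[str, ...]             # covariates before VIF screening
    retained: tuple[str, ...]         # covariates after VIF screening
    vif_removed: list[tuple[str, float]]
    ranked: list[RankedModel]

    @property
    def best(self) -> RankedModel:
        return self.ranked[0]


@dataclass
class SelectionResult:
    combinations: list[CombinationResult]
    winner: CombinationResult
    best_model: RankedModel
    averaged: pd.DataFrame | None = None
    weights: pd.Series | None = None

    def aicc_table(self) -> pd.DataFrame:
        rows = []
        for c in self.combinations:
            rows.append({
                "groups": "+".join(c.groups),
                "n_groups": len(c.groups),
                "best_covariates": ", ".join(c.best.names),
                "n_covariates": len(c.best.names),
                "min_aicc": c.best.aicc,
            })
        df = pd.DataFrame(rows)
        df["delta_aicc"] = df["min_aicc"] - df["min_aicc"].min()
        return df.sort_values("min_aicc").reset_index(drop=True)


def compare_subset_models(
    y,
    Z: pd.DataFrame,
    groups: dict[str, list[str]],
    combinations: list[tuple[str, ...]] | None = None,
    vif_threshold: float = 3.0,
    avg_delta: float = 2.0,
    conditional: bool = True,
) -> SelectionResult:
    """Run VIF screening + all-subsets AICc selection per group combination.

    ``groups`` maps a subset-model name (e.g. ``"ocean"``) to its covariate
    columns; groups must be disjoint.  By default every non-empty combination
    of groups (including the full model) is evaluated, each re-screened by VIF
    within its own pooled covariates.  The winner is the combination with the
    globally minimal min-AICc; ties resolve toward fewer groups, then fewer
    covariates in the best model.  Coefficients are model-averaged over the
    winner's ranked list within ``avg_delta`` of its best model.
    """
    all_cols = [c for cols in groups.values() for c in cols]
    if len(set(all_cols)) != len(all_cols):
        raise ValueError("subset-model groups must be disjoint")
    missing = set(all_cols) - set(Z.columns)
    if missing:
        raise ValueError(f"covariates not in table: {sorted(missing)}")
    if combinations is None:
        names = list(groups)
        combinations = [
            combo
            for r in range(1, len(names) + 1)
            for combo in itertools.combinations(names, r)
        ]
    if not combinations:
        raise ValueError("no group combinations to evaluate")

    results: list[CombinationResult] = []
    for combo in combinations:
        pool = [c for g in combo for c in groups[g]]
        retained, removed = vif_screen(Z[pool], threshold=vif_threshold)
        ranked = all_subsets_select(y, retained)
        results.append(CombinationResult(
            groups=tuple(combo), pool=tuple(pool),
            retained=tuple(retained.columns), vif_removed=removed,
            ranked=ranked,
        ))

    winner = min(
        results,
        key=lambda c: (c.best.aicc, len(c.groups), len(c.best.names), c.best.names),
    )
    averaged, weights = model_average(
        winner.ranked, delta=avg_delta, conditional=conditional
    )
    return SelectionResult(
        combinations=results, winner=winner, best_model=winner.best,
        averaged=averaged, weights=weights,
    )


# ---------------------------------------------------------------------------
# Model averaging
# ---------------------------------------------------------------------------

def akaike_weights(aiccs) -> np.ndarray:
    """Weights proportional to exp(-AICc/2), normalized to sum to 1."""
    a = np.asarray(aiccs, dtype=float)
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def model_average(
    ranked: list[RankedModel], delta: float = 2.0, conditional: bool = True
):
    """Average coefficients over models within ``delta`` AICc of the best.

    Weights are Akaike weights over the retained set.  With
    ``conditional=True`` each term is averaged only over the models that
    contain it (its summed weight is reported); with ``conditional=False``
    absent terms contribute zero (full averaging).

    Returns ``(table, weights)`` where ``table`` has one row per term with
    columns ``estimate`` and ``weight``, and ``weights`` is the per-model
    Akaike weight Series indexed by a ``+``-joined covariate label.
    """
    if not ranked:
        raise ValueError("empty model list")
    best = ranked[0].aicc
    kept = [m for m in ranked if m.aicc - best < delta]
    w = akaike_weights([m.aicc for m in kept])
    labels = ["+".join(m.names) if m.names else "(null)" for m in kept]
    weights = pd.Series(w, index=labels, name="akaike_weight")

    terms = ["intercept"] + sorted({t for m in kept for t in m.names})
    rows = []
    for term in terms:
        num = 0.0
        wsum = 0.0
        for m, wm in zip(kept, w):
            contains = term == "intercept" or term in m.names
            if contains:
                num += wm * m.fit.coef[term]
                wsum += wm
            elif not conditional:
                wsum += wm  # zero contribution
        est = num / wsum if conditional and wsum > 0 else num
        rows.append({"term": term, "estimate": est, "weight": wsum})
    table = pd.DataFrame(rows).set_index("term")
    return table, weights


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def effect_sizes(
    estimates: pd.Series | dict,
    std_errors: pd.Series | dict,
    units: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Multiplicative effect sizes per practical unit of each covariate.

    For each coefficient ``b`` with standard error ``se`` (both on the scale
    of the covariate's practical unit): effect size ``exp(b)``, 95% CI
    ``exp(b +/- 1.96 se)``, and practical percent change ``(exp(b)-1)*100``.
    """
    est = pd.Series(estimates, dtype=float)
    se = pd.Series(std_errors, dtype=float).reindex(est.index)
    units = units or {}
    out = pd.DataFrame({
        "estimate": est,
        "se": se,
        "effect_size": np.exp(est),
        "ci_lower": np.exp(est - 1.96 * se),
        "ci_upper": np.exp(est + 1.96 * se),
        "practical_pct": (np.exp(est) - 1.0) * 100.0,
    })
    out["unit"] = [units.get(name, "") for name in out.index]
    return out


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_with_intervals(fit: FitResult, Znew: pd.DataFrame, alpha: float = 0.05):
    """Point predictions and prediction intervals on the rate scale.

    Predictions are made on the log scale and back-transformed with
    ``exp``; the 95% prediction interval uses the t quantile with the
    leverage term ``1 + x0'(X'X)^{-1}x0``.  New rows further than 3 SD from
    the training mean of any covariate trigger a logged extrapolation
    warning (never an error).
    """
    Znew = Znew[list(fit.names)] if fit.names else Znew.iloc[:, :0]
    Xn = np.column_stack([np.ones(len(Znew)), Znew.to_numpy(dtype=float)]) \
        if fit.names else np.ones((len(Znew), 1))
    if fit.names:
        Ztr = fit.X[:, 1:]
        mu, sd = Ztr.mean(axis=0), Ztr.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            zdist = np.abs((Znew.to_numpy(dtype=float) - mu) / sd)
        if np.any(zdist > 3):
            logger.warning(
                "prediction rows extrapolate beyond 3 SD of training covariates"
            )
    pred_log = Xn @ fit.beta
    lev = np.einsum("ij,jk,ik->i", Xn, fit.xtx_inv, Xn)
    se_pred = np.sqrt(fit.sigma2 * (1.0 + lev))
    tq = stats.t.ppf(1.0 - alpha / 2.0, df=fit.n - fit.p)
    return pd.DataFrame({
        "pred_log": pred_log,
        "pred_rate": np.exp(pred_log),
        "pi_lower": np.exp(pred_log - tq * se_pred),
        "pi_upper": np.exp(pred_log + tq * se_pred),
    }, index=Znew.index)


def prediction_correlation(observed, predicted):
    """Pearson r between observed and predicted, with its t statistic."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    r, p = stats.pearsonr(obs, pred)
    n = len(obs)
    t = r * math.sqrt((n - 2) / (1.0 - r * r)) if abs(r) < 1 else np.inf
    return {"r": float(r), "t": float(t), "p": float(p), "n": n}


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsResult:
    skipped: bool
    studentized: np.ndarray | None = None
    theoretical_q: np.ndarray | None = None
    envelope_lower: np.ndarray | None = None
    envelope_upper: np.ndarray | None = None
    fraction_inside: float | None = None
    notice: str = ""


def studentized_residuals(fit: FitResult) -> np.ndarray:
    """Externally studentized residuals (leave-one-out residual variance)."""
    e = fit.residuals
    h = fit.leverage
    n, p = fit.n, fit.p
    s2_loo = (fit.rss - e**2 / (1.0 - h)) / (n - p - 1)
    return e / np.sqrt(s2_loo * (1.0 - h))


def qq_envelope(n: int, n_sim: int = 1000, rng=None):
    """Pointwise 95% envelope of sorted standard-normal samples of size n."""
    rng = np.random.default_rng(rng)
    sims = np.sort(rng.standard_normal((n_sim, n)), axis=1)
    lower = np.percentile(sims, 2.5, axis=0)
    upper = np.percentile(sims, 97.5, axis=0)
    return lower, upper


def residual_diagnostics(
    fit: FitResult, n_sim: int = 1000, rng=None
) -> DiagnosticsResult:
    """QQ check of externally studentized residuals against a normal envelope.

    The envelope is the pointwise 95% band of order statistics from ``n_sim``
    simulated standard-normal samples of the same n.  A perfect fit (zero
    residual variance) skips the diagnostics with a notice.
    """
    if fit.n <= fit.k + 2:
        raise ValueError(f"diagnostics need n > k+2 (n={fit.n}, k={fit.k})")
    if fit.sigma2 <= 1e-16 * (1.0 + float(np.mean(fit.y**2))):
        return DiagnosticsResult(skipped=True, notice="perfect fit: zero residual variance")
    r = np.sort(studentized_residuals(fit))
    lower, upper = qq_envelope(fit.n, n_sim=n_sim, rng=rng)
    theo = stats.norm.ppf((np.arange(1, fit.n + 1) - 0.5) / fit.n)
    inside = (r >= lower) & (r <= upper)
    return DiagnosticsResult(
        skipped=False, studentized=r, theoretical_q=theo,
        envelope_lower=lower, envelope_upper=upper,
        fraction_inside=float(inside.mean()),
    )
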