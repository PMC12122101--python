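"""Screen a species x year commercial-catch matrix for range-shifting predators.

Stage one reduces the catch matrix by PCA (years as observations, species as
variables) to identify the component associated with catch level.  Stage two
operationalizes the visual trend check as a breakpoint rule: a species is a
candidate predator if it loads positively on the level component *and* its
post-breakpoint mean catch exceeds the pre-breakpoint mean by a configurable
ratio with a positive post-breakpoint linear trend.  (Applied to the real
Japanese catch statistics this procedure singled out yellowtail.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    loadings: pd.DataFrame        # species x component
    scores: pd.DataFrame          # year x component
    variance_explained: pd.Series  # percent per component, sums to 100
    scaled: bool


def _validate_catch(m: pd.DataFrame) -> None:
    if m.shape[0] < 3:
        raise ValueError("catch matrix needs >= 3 species")
    if m.shape[1] < 10:
        raise ValueError("catch matrix needs >= 10 years")
    if (m.to_numpy() < 0).any():
        raise ValueError("catch values must be nonnegative")


def pca_catch(m: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of a catch matrix (species rows x year columns).

    Years are the observations and species the variables: columns of the
    transposed matrix are centered (and scaled to unit variance when
    ``scale=True``, the default, since catches span orders of magnitude).
    The decomposition is by SVD with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).  Zero-variance
    species are removed with a logged warning.
    """
    _validate_catch(m)
    X = m.T.astype(float)            # years x species
    sd = X.std(ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        logger.warning("excluding zero-variance species from PCA: %s", dead)
        X = X.drop(columns=dead)
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant species")
    Xc = X - X.mean()
    if scale:
        Xc = Xc / X.std(ddof=1)
    U, s, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    # sign convention: largest |loading| positive per component
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    n = Xc.shape[0]
    var = s**2 / (n - 1)
    pct = 100.0 * var / var.sum()
    comps = [f"PC{i+1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=Xc.columns, columns=comps),
        scores=pd.DataFrame(U * s, index=Xc.index, columns=comps),
        variance_explained=pd.Series(pct, index=comps),
        scaled=scale,
    )


def screen_candidates(
    pca: PCAResult,
    m: pd.DataFrame,
    breakpoint_year: int = 1998,
    ratio_threshold: float = 1.5,
    component: str = "auto",
) -> pd.DataFrame:
    """Rank candidate range-shifting predators.

    A species is flagged when (a) its loading on the temporal-change
    component is positive and (b) its post-breakpoint mean catch exceeds its
    pre-breakpoint mean by ``ratio_threshold`` with a positive
    post-breakpoint linear trend.  Candidates are ranked by the post/pre
    ratio.  The breakpoint must leave at least 3 years on either side.

    With ``component="auto"`` the screen picks the component whose year
    scores correlate most strongly with time and orients it so the
    correlation is positive, so that species driving the recent increase
    load positively; pass e.g. ``"PC1"`` to fix the component instead (the
    loading sign is then taken as-is).
    """
    years = np.array([int(y) for y in m.columns])
    sign = 1.0
    if component == "auto":
        yr_scores = pca.scores.to_numpy()
        yrs = np.array([float(y) for y in pca.scores.index])
        with np.errstate(invalid="ignore"):
            corrs = np.array([
                np.corrcoef(yrs, yr_scores[:, j])[0, 1]
                for j in range(yr_scores.shape[1])
            ])
        corrs = np.nan_to_num(corrs)
        j = int(np.argmax(np.abs(corrs)))
        component = pca.loadings.columns[j]
        sign = float(np.sign(corrs[j]) or 1.0)
    pre = years < breakpoint_year
    post = ~pre
    if pre.sum() < 3 or post.sum() < 3:
        raise ValueError(
            f"breakpoint {breakpoint_year} leaves fewer than 3 years on one side"
        )
    rows = []
    for sp in m.index:
        if sp not in pca.loadings.index:
            continue  # zero-variance species dropped from PCA
        loading = sign * float(pca.loadings.loc[sp, component])
        v = m.loc[sp].to_numpy(dtype=float)
        pre_mean = v[pre].mean()
        post_mean = v[post].mean()
        ratio = post_mean / pre_mean if pre_mean > 0 else np.inf
        slope = np.polyfit(years[post], v[post], 1)[0]
        flagged = loading > 0 and ratio >= ratio_threshold and slope > 0
        rows.append({
            "species": sp, "loading": loading, "pre_mean": pre_mean,
            "post_mean": post_mean, "ratio": ratio, "post_slope": slope,
            "candidate": flagged,
        })
    out = pd.DataFrame(rows).set_index("species")
    return out.sort_values("ratio", ascending=False)
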