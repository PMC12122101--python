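"""Cohort reconstruction of release-year return rates.

Hatchery fry released in year ``t`` return as adults at ages 2-5, so an age-a
fish caught in return year ``t + a - 1`` belongs to the release-year cohort
``t``.  Return-year catch totals are split across contributing cohorts with
survey-weighted age proportions:

    Yhat_t = sum_{a=Amin..Amax} y_{t+a-1} * phat_{a, t+a-1}

and the cohort return rate (the marine-survival index) is
``Rhat_t = Yhat_t / X_t`` with ``X_t`` the number of fry released.

Tables are long-form pandas DataFrames with the column conventions of the
CSV schemas in :mod:`chumrun.io`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_MIN_DEFAULT = 2
AGE_MAX_DEFAULT = 5


def weighted_age_composition(surveys: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Survey-sample-size-weighted mean age proportions per (region, return_year).

    ``surveys`` columns: region, return_year, survey_id, age, proportion,
    sample_n.  For each (region, return_year):
    ``phat_a = sum_h p_ah n_h / sum_h n_h``.  Surveys whose proportions do not
    sum to 1 within ``tol`` are rejected with a logged warning.

    Returns columns: region, return_year, age, p_hat, imputed (False).
    """
    required = {"region", "return_year", "survey_id", "age", "proportion", "sample_n"}
    missing = required - set(surveys.columns)
    if missing:
        raise ValueError(f"age-survey table missing columns: {sorted(missing)}")
    if (surveys["sample_n"] < 1).any():
        raise ValueError("survey sample_n must be >= 1")

    sums = surveys.groupby(["region", "return_year", "survey_id"])["proportion"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        logger.warning(
            "rejecting %d survey(s) whose age proportions do not sum to 1: %s",
            len(bad), list(bad.index),
        )
        bad_keys = set(bad.index)
        keys = list(zip(surveys["region"], surveys["return_year"], surveys["survey_id"]))
        surveys = surveys.loc[[k not in bad_keys for k in keys]]
    if surveys.empty:
        raise ValueError("no valid surveys remain")

    df = surveys.assign(w=surveys["proportion"] * surveys["sample_n"])
    # one sample_n per survey: take it once per survey, then sum per year
    n_per_survey = df.groupby(
        ["region", "return_year", "survey_id"], as_index=False
    )["sample_n"].first()
    n_tot = n_per_survey.groupby(["region", "return_year"])["sample_n"].sum()
    num = df.groupby(["region", "return_year", "age"])["w"].sum()
    p_hat = (num / n_tot).rename("p_hat").reset_index()
    p_hat["imputed"] = False
    return p_hat.sort_values(["region", "return_year", "age"]).reset_index(drop=True)


def impute_age_composition(
    p_hat: pd.DataFrame, target_years: dict[str, list[int]] | list[int]
) -> pd.DataFrame:
    """Fill missing return years with a 3-year moving average of proportions.

    Each missing year's composition is the arithmetic mean of the previous
    three years' compositions (already-imputed years feed later ones), then
    renormalized to sum to 1.  Imputed rows carry ``imputed=True``.

    ``target_years`` is either a list applied to every region or a mapping
    region -> years.  Imputation of a year with fewer than three immediately
    preceding available years is an error naming the region and year.
    """
    out = [p_hat]
    regions = p_hat["region"].unique()
    for region in regions:
        years = (
            target_years.get(region, []) if isinstance(target_years, dict)
            else list(target_years)
        )
        sub = p_hat[p_hat["region"] == region]
        have = {
            y: g.set_index("age")["p_hat"]
            for y, g in sub.groupby("return_year")
        }
        for year in sorted(years):
            if year in have:
                continue
            prev = [year - 3, year - 2, year - 1]
            if not all(y in have for y in prev):
                missing = [y for y in prev if y not in have]
                raise ValueError(
                    f"cannot impute {region} {year}: missing prior years {missing}"
                )
            mean = pd.concat([have[y] for y in prev], axis=1).fillna(0.0).mean(axis=1)
            mean = mean / mean.sum()
            have[year] = mean
            out.append(pd.DataFrame({
                "region": region, "return_year": year,
                "age": mean.index, "p_hat": mean.values, "imputed": True,
            }))
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["region", "return_year", "age"]).reset_index(drop=True)


def allocate_returns(
    returns: pd.DataFrame,
    p_hat: pd.DataFrame,
    age_min: int = AGE_MIN_DEFAULT,
    age_max: int = AGE_MAX_DEFAULT,
    release_years: list[int] | None = None,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Allocate return-year totals to release-year cohorts by age proportions.

    ``Yhat_{a,t} = y_{t+a-1} * phat_{a, t+a-1}`` for ``a`` in
    ``[age_min, age_max]``.  By default proportions are *not* renormalized to
    the age window (mass at older ages is dropped, since such returns are
    rare); ``renormalize=True`` enables the sensitivity variant.

    Returns long-form columns: region, release_year, age, returns_allocated,
    plus per-cohort totals accessible via :func:`cohort_totals`.
    """
    ages = range(age_min, age_max + 1)
    ret = returns.set_index(["region", "return_year"])["returns_total"]
    ptab = p_hat.set_index(["region", "return_year", "age"])["p_hat"]
    if renormalize:
        window = p_hat[(p_hat["age"] >= age_min) & (p_hat["age"] <= age_max)]
        norm = window.groupby(["region", "return_year"])["p_hat"].sum()
        ptab = ptab / norm
    regions = returns["region"].unique()
    if release_years is None:
        rows_per_region = {
            r: sorted(returns.loc[returns["region"] == r, "return_year"])
            for r in regions
        }
    missing: list[tuple] = []
    rows = []
    for region in regions:
        if release_years is None:
            ret_years = rows_per_region[region]
            t_lo, t_hi = min(ret_years) - age_min + 1, max(ret_years) - age_max + 1
            t_range = range(t_lo, t_hi + 1)
        else:
            t_range = release_years
        for t in t_range:
            for a in ages:
                ry = t + a - 1
                if (region, ry) not in ret.index:
                    missing.append((region, ry))
                    continue
                if (region, ry, a) not in ptab.index:
                    missing.append((region, ry, a))
                    continue
                rows.append({
                    "region": region, "release_year": t, "age": a,
                    "returns_allocated": float(ret[(region, ry)]) * float(ptab[(region, ry, a)]),
                })
    if missing:
        raise ValueError(
            "missing returns or age proportions for: "
            f"{sorted(set(missing))[:10]}{'...' if len(set(missing)) > 10 else ''}"
        )
    return pd.DataFrame(rows)


def cohort_totals(cohorts: pd.DataFrame) -> pd.DataFrame:
    """Sum allocated returns over ages: one row per (region, release_year)."""
    tot = cohorts.groupby(["region", "release_year"], as_index=False)[
        "returns_allocated"
    ].sum()
    return tot.rename(columns={"returns_allocated": "cohort_returns"})


def compute_return_rates(cohorts: pd.DataFrame, releases: pd.DataFrame) -> pd.DataFrame:
    """Cohort return rates ``Rhat_t = Yhat_t / X_t`` and age-specific rates.

    Returns long-form columns: region, release_year, age, rate plus rows with
    ``age = 0`` are *not* used; the total is in :func:`total_return_rates`.
    """
    rel = releases.set_index(["region", "release_year"])["fry_released"]
    if (rel <= 0).any():
        bad = rel[rel <= 0].index.tolist()
        raise ValueError(f"non-positive fry_released for: {bad}")
    keys = list(zip(cohorts["region"], cohorts["release_year"]))
    missing = sorted({k for k in keys if k not in rel.index})
    if missing:
        raise ValueError(f"no release counts for: {missing[:10]}")
    x = np.array([rel[k] for k in keys], dtype=float)
    out = cohorts.copy()
    out["rate"] = out["returns_allocated"].to_numpy(dtype=float) / x
    return out


def total_return_rates(age_rates: pd.DataFrame) -> pd.DataFrame:
    """Total rate per cohort (sum of age-specific rates; additive by construction)."""
    tot = age_rates.groupby(["region", "release_year"], as_index=False)["rate"].sum()
    return tot.rename(columns={"rate": "return_rate"})


def merge_regions(
    mapping: dict[str, str],
    releases: pd.DataFrame | None = None,
    returns: pd.DataFrame | None = None,
    cohorts: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Merge management regions into analysis regions by summing counts.

    ``mapping`` assigns every source region to a target region; an unmapped
    region in any table is an error.  Counts (fry released, returns, allocated
    cohort returns) are summed, so a merged return rate is the pooled
    ``sum(Yhat)/sum(X)``, never a mean of rates.
    """
    def _apply(df: pd.DataFrame, value_col: str, keys: list[str]) -> pd.DataFrame:
        unmapped = set(df["region"]) - set(mapping)
        if unmapped:
            raise ValueError(f"regions missing from merge mapping: {sorted(unmapped)}")
        out = df.copy()
        out["region"] = out["region"].map(mapping)
        return out.groupby(keys, as_index=False)[value_col].sum()

    result: dict[str, pd.DataFrame] = {}
    if releases is not None:
        result["releases"] = _apply(releases, "fry_released", ["region", "release_year"])
    if returns is not None:
        result["returns"] = _apply(returns, "returns_total", ["region", "return_year"])
    if cohorts is not None:
        result["cohorts"] = _apply(
            cohorts, "returns_allocated", ["region", "release_year", "age"]
        )
    return result


# Seven management regions -> four analysis regions used in the regression.
DEFAULT_REGION_MERGE = {
    "Hokkaido Okhotsk": "Hokkaido Okhotsk",
    "Hokkaido Nemuro": "Hokkaido and Honshu Pacific",
    "Hokkaido Pacific East": "Hokkaido and Honshu Pacific",
    "Hokkaido Pacific West": "Hokkaido and Honshu Pacific",
    "Honshu Pacific": "Hokkaido and Honshu Pacific",
    "Hokkaido Sea of Japan": "Hokkaido Sea of Japan",
    "Honshu Sea of Japan": "Honshu Sea of Japan",
}


def rate_summary(rates: pd.DataFrame, lo: float = 5.0, hi: float = 95.0) -> pd.DataFrame:
    """Mean return rate with 5th/95th percentile range, per region (as %)."""
    def _f(g):
        v = g["return_rate"].to_numpy(dtype=float) * 100.0
        return pd.Series({
            "mean_pct": v.mean(),
            f"p{lo:g}_pct": np.percentile(v, lo),
            f"p{hi:g}_pct": np.percentile(v, hi),
            "n_years": len(v),
        })
    return rates.groupby("region").apply(_f, include_groups=False).reset_index()


def trait_summaries(
    release_events: pd.DataFrame, adult_traits: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Weighted mean fry size-at-release and adult reproductive-trait means.

    Fry size: ``BWbar = sum_k BW_k n_k / sum_k n_k`` per (region, year) over
    release events k.  Adult traits: relative fecundity per fish is
    ``fecundity / FL^3 * 10^3`` (eggs cm^-3 x 10^3); per-(region, year, age)
    means of fork length, fecundity, egg size, and relative fecundity, kept
    separately for age-4 and age-5 fish.  Rows with FL <= 0 are rejected.
    """
    ev = release_events
    w = ev["mean_bw_g"] * ev["n_released"]
    num = w.groupby([ev["region"], ev["year"]]).sum()
    den = ev.groupby(["region", "year"])["n_released"].sum()
    fry = (num / den).rename("mean_bw_g").reset_index()

    tr = adult_traits.copy()
    bad = tr["fl_cm"] <= 0
    if bad.any():
        logger.warning("rejecting %d adult trait rows with FL <= 0", int(bad.sum()))
        tr = tr[~bad]
    tr["relative_fecundity"] = tr["fecundity_eggs"] / tr["fl_cm"] ** 3 * 1e3
    adults = tr.groupby(["region", "year", "age"], as_index=False)[
        ["fl_cm", "fecundity_eggs", "egg_weight", "relative_fecundity"]
    ].mean()
    return {"fry_size": fry, "adult_traits": adults}
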