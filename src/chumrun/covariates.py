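"""Explanatory-variable construction: SST box means, release-window coastal
SSTs, lag alignment to release year, and standardization.

High-seas SST covariates are cosine-latitude-weighted means of gridded monthly
SST over named lat/lon boxes along the inferred migration route (southern Sea
of Okhotsk, western North Pacific, central Bering Sea, central Gulf of
Alaska), averaged over a month window.  Coastal covariates average monthly
mean SST over a region's member coastal areas during its fry-release window.
Every covariate is aligned to the release year ``t`` via a declared lag
(e.g. a ``t + 2`` competitor index for release year 1998 reads the year-2000
value), and can be standardized to mean 0, SD 1 over the analyzed years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoxDefinition:
    """A named lat/lon rectangle with a month window (inclusive bounds)."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float          # degrees E, 0-360 convention
    lon_max: float
    months: tuple[int, ...]  # contiguous month window

    def __post_init__(self):
        if not (-90 <= self.lat_min <= self.lat_max <= 90):
            raise ValueError(f"{self.name}: invalid latitude range")
        if not all(1 <= m <= 12 for m in self.months):
            raise ValueError(f"{self.name}: months must be in 1..12")


# The four high-seas distribution areas and their SST month windows.
HIGH_SEAS_BOXES = {
    "okhotsk_jul_sst": BoxDefinition(
        "Southern Sea of Okhotsk", 45.2, 46.5, 142.5, 148.5, (7,)),
    "wnp_jan_apr_sst": BoxDefinition(
        "Western North Pacific", 42.0, 45.0, 158.0, 165.0, (1, 2, 3, 4)),
    "bering_aug_sep_sst": BoxDefinition(
        "Central Bering Sea", 53.0, 58.0, 175.0, 190.0, (8, 9)),
    "goa_jan_apr_sst": BoxDefinition(
        "Central Gulf of Alaska", 48.0, 56.0, 210.0, 220.0, (1, 2, 3, 4)),
}

# Fry release windows (months) for the seven coastal management regions.
RELEASE_WINDOWS = {
    "Hokkaido Okhotsk": (4, 5, 6),
    "Hokkaido Nemuro": (3, 4, 5, 6),
    "Hokkaido Pacific East": (3, 4, 5, 6),
    "Hokkaido Pacific West": (3, 4, 5),
    "Hokkaido Sea of Japan": (3, 4, 5),
    "Honshu Pacific": (2, 3, 4, 5),
    "Honshu Sea of Japan": (2, 3, 4),
}


def _to_0360(lon):
    return np.mod(lon, 360.0)


def box_mean_sst(
    grid: xr.DataArray, box: BoxDefinition, year: int, month: int,
    area_weighted: bool = True,
) -> float:
    """Area-weighted mean SST over a box for one year-month.

    ``grid`` has dims (year, month, lat, lon) with lon in either -180..180 or
    0..360 convention (normalized internally).  Cells whose centers fall
    inside the box (inclusive bounds) enter the mean with cosine-latitude
    weights; missing (NaN) cells are excluded from numerator and denominator.
    An all-missing box yields NaN with a logged warning.
    """
    field = grid.sel(year=year, month=month)
    lon = _to_0360(field["lon"].values)
    lat = field["lat"].values
    lon_mask = (lon >= _to_0360(box.lon_min)) & (lon <= _to_0360(box.lon_max))
    lat_mask = (lat >= box.lat_min) & (lat <= box.lat_max)
    if not lon_mask.any() or not lat_mask.any():
        raise ValueError(f"box {box.name} does not intersect the grid")
    sub = field.values[np.ix_(lat_mask, lon_mask)]
    w = np.cos(np.deg2rad(lat[lat_mask]))[:, None] * np.ones(lon_mask.sum())
    if not area_weighted:
        w = np.ones_like(w)
    valid = ~np.isnan(sub)
    if not valid.any():
        logger.warning("box %s %d-%02d: all cells missing", box.name, year, month)
        return float("nan")
    return float((sub[valid] * w[valid]).sum() / w[valid].sum())


def seasonal_box_series(
    grid: xr.DataArray, box: BoxDefinition, area_weighted: bool = True
) -> pd.Series:
    """Yearly series of the box mean averaged over the box's month window."""
    missing = [m for m in box.months if m not in grid["month"].values]
    if missing:
        raise ValueError(f"grid lacks months {missing} for box {box.name}")
    years = [int(y) for y in grid["year"].values]
    vals = []
    for y in years:
        monthly = [
            box_mean_sst(grid, box, y, m, area_weighted=area_weighted)
            for m in box.months
        ]
        vals.append(float(np.mean(monthly)))
    return pd.Series(vals, index=pd.Index(years, name="year"), name=box.name)


def release_window_sst(
    coastal: pd.DataFrame, members: list[str], months: tuple[int, ...]
) -> pd.Series:
    """Release-window coastal SST: mean over member areas, then over months.

    ``coastal`` columns: area, year, month, mean_sst.  Any missing
    (area, year, month) combination within the window is an error.
    """
    sub = coastal[coastal["area"].isin(members) & coastal["month"].isin(months)]
    years = sorted(coastal["year"].unique())
    expected = len(members) * len(months)
    counts = sub.groupby("year").size()
    short = [y for y in years if counts.get(y, 0) < expected]
    if short:
        raise ValueError(f"missing coastal SST area-months for years {short}")
    by_month = sub.groupby(["year", "month"])["mean_sst"].mean()
    out = by_month.groupby("year").mean()
    out.name = "release_window_sst"
    return out


def lag_align(
    raw: dict[str, pd.Series],
    lags: dict[str, int],
    release_years: list[int],
) -> pd.DataFrame:
    """Align raw yearly series to release years via per-covariate lags.

    The covariate value for release year ``t`` is the raw series at
    ``t + lag``.  Release years with any missing lagged value are dropped
    with a logged list.  A covariate without a declared lag is an error.
    """
    missing_spec = sorted(set(raw) - set(lags))
    if missing_spec:
        raise ValueError(f"no lag declared for covariates: {missing_spec}")
    data = {}
    for name, series in raw.items():
        lag = lags[name]
        data[name] = [
            series.get(t + lag, np.nan) for t in release_years
        ]
    out = pd.DataFrame(data, index=pd.Index(release_years, name="release_year"))
    incomplete = out.index[out.isna().any(axis=1)].tolist()
    if incomplete:
        logger.info("dropping release years with missing lagged values: %s", incomplete)
        out = out.dropna()
    return out


@dataclass
class Standardization:
    mean: pd.Series
    sd: pd.Series


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardization]:
    """Center and scale each column to mean 0, SD 1 (denominator n-1).

    Scaling constants are returned for back-transformation.  Constant columns
    are an error naming the column.
    """
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 rows")
    mu = table.mean()
    sd = table.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant columns cannot be standardized: {constant}")
    return (table - mu) / sd, Standardization(mean=mu, sd=sd)


# Lags (offset from release year t) for the Table-1 covariate set.
DEFAULT_LAGS = {
    "relative_fecundity": -1,
    "egg_size": -1,
    "fry_size": 0,
    "sst_at_release": 0,
    "okhotsk_jul_sst": 0,
    "wnp_jan_apr_sst": 1,
    "bering_aug_sep_sst": 1,
    "goa_jan_apr_sst": 2,
    "yellowtail_catch": 0,
    "russia_chum_t3": 3,
    "russia_pink_t1": 1,
    "russia_pink_t2": 2,
    "russia_pink_t3": 3,
    "na_chum_t3": 3,
    "na_pink_t1": 1,
    "na_pink_t2": 2,
    "na_pink_t3": 3,
}

# Thematic subset-model membership for the covariate groups.
DEFAULT_GROUPS = {
    "hatchery_carryovers": ["relative_fecundity", "egg_size", "fry_size"],
    "ocean_conditions": [
        "sst_at_release", "okhotsk_jul_sst", "wnp_jan_apr_sst",
        "bering_aug_sep_sst", "goa_jan_apr_sst",
    ],
    "predators_competitors": [
        "yellowtail_catch", "russia_chum_t3", "russia_pink_t1",
        "russia_pink_t2", "russia_pink_t3", "na_chum_t3", "na_pink_t1",
        "na_pink_t2", "na_pink_t3",
    ],
}

# Practical reporting units per covariate (effect sizes are per one unit).
PRACTICAL_UNITS = {
    "relative_fecundity": "100 eggs",
    "egg_size": "10 mg",
    "fry_size": "0.1 g",
    "sst_at_release": "1 degC",
    "okhotsk_jul_sst": "1 degC",
    "wnp_jan_apr_sst": "1 degC",
    "bering_aug_sep_sst": "1 degC",
    "goa_jan_apr_sst": "1 degC",
    "yellowtail_catch": "100 tons",
    "russia_chum_t3": "10 million fish",
    "russia_pink_t1": "100 million fish",
    "russia_pink_t2": "100 million fish",
    "russia_pink_t3": "100 million fish",
    "na_chum_t3": "10 million fish",
    "na_pink_t1": "100 million fish",
    "na_pink_t2": "100 million fish",
    "na_pink_t3": "100 million fish",
}
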