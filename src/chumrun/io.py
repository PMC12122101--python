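"""CSV schemas, dataset round-tripping, and run manifests.

All tables are UTF-8 comma-separated files with a header row; missing values
are empty fields; years and ages are integers.  The synthetic generator
writes the same schemas the pipeline reads, plus a ``truth.json`` sidecar
with the generating parameters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMAS = {
    "releases": ["region", "release_year", "fry_released"],
    "returns": ["region", "return_year", "returns_total"],
    "age_surveys": ["region", "return_year", "survey_id", "age", "proportion", "sample_n"],
    "release_events": ["region", "river", "year", "month", "n_released", "mean_bw_g", "mean_fl_mm"],
    "adult_traits": ["region", "year", "age", "fl_cm", "fecundity_eggs", "egg_weight"],
    "coastal_sst": ["area", "year", "month", "mean_sst"],
    "covariates": ["region", "release_year"],  # plus free-form covariate columns
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a CSV table and validate its required columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path)
    required = SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path} ({kind}): missing columns {missing}")
    return df


def read_catch_matrix(path: str | Path) -> pd.DataFrame:
    """Species x year catch matrix: species rows, year columns."""
    m = pd.read_csv(path, index_col=0)
    m.columns = [int(c) for c in m.columns]
    m.index.name = "species"
    return m


def read_sst_grid(path: str | Path):
    """Gridded SST from NetCDF (lat, lon, year, month dims) or long CSV."""
    import xarray as xr

    path = Path(path)
    if path.suffix in {".nc", ".nc4", ".cdf"}:
        da = xr.open_dataset(path)["sst"]
        return da
    long = pd.read_csv(path)
    required = {"lat", "lon", "year", "month", "sst"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"{path}: long SST table missing columns {sorted(missing)}")
    return (
        long.set_index(["year", "month", "lat", "lon"])["sst"]
        .to_xarray()
        .rename("sst")
    )


def write_sst_grid_csv(grid, path: str | Path) -> None:
    """Write a gridded SST DataArray as a long CSV (lat, lon, year, month, sst)."""
    long = grid.to_dataframe().reset_index().dropna(subset=["sst"])
    long.to_csv(path, index=False)


def write_dataset(dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a SyntheticDataset as the pipeline's input CSVs + truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("releases", "returns", "age_surveys", "covariates"):
        df = getattr(dataset, name)
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    if dataset.catch_matrix is not None:
        p = out / "catch_matrix.csv"
        dataset.catch_matrix.to_csv(p)
        paths["catch_matrix"] = p
    if dataset.sst_grid is not None:
        p = out / "sst_grid.csv"
        write_sst_grid_csv(dataset.sst_grid, p)
        paths["sst_grid"] = p
    p = out / "truth.json"
    with open(p, "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
    paths["truth"] = p
    return paths


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, inputs: dict, seed, outputs: list[Path]) -> Path:
    """Machine-readable run manifest: inputs, seed, and output checksums."""
    from chumrun import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {
            Path(p).name: file_checksum(p) for p in sorted(outputs, key=str)
        },
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def to_jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
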