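"""End-to-end orchestration: reconstruct -> cluster -> screen -> regress -> trends.

``run_pipeline`` reads the standard input CSVs from a directory (the same
schemas the synthetic generator writes), executes every stage in order, and
writes all stage outputs plus a machine-readable manifest into an output
directory.  Runs are deterministic for fixed inputs and seed; a stage failure
aborts with the stage name and leaves a ``FAILED`` marker beside any partial
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chumrun import clustering, cohort, covariates as cov, io, predator, regression, trend

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str | Path
    output_dir: str | Path
    age_min: int = 2
    age_max: int = 5
    renormalize_ages: bool = False
    merge_mapping: dict[str, str] | None = None
    groups: dict[str, list[str]] | None = None  # None: fixed-model fit
    vif_threshold: float = 3.0
    avg_delta: float = 2.0
    conditional_averaging: bool = True
    units: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        inp = Path(self.input_dir)
        for name in ("releases", "returns", "age_surveys", "covariates"):
            p = inp / f"{name}.csv"
            if not p.exists():
                raise FileNotFoundError(f"missing input table: {p}")
        if self.vif_threshold <= 0 or self.avg_delta <= 0:
            raise ValueError("thresholds must be positive")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of in-memory stage results."""
    config.validate()
    inp = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "load"
    try:
        releases = io.read_table(inp / "releases.csv", "releases")
        returns = io.read_table(inp / "returns.csv", "returns")
        surveys = io.read_table(inp / "age_surveys.csv", "age_surveys")
        covariate_table = io.read_table(inp / "covariates.csv", "covariates")
        catch_path = inp / "catch_matrix.csv"
        catch = io.read_catch_matrix(catch_path) if catch_path.exists() else None

        stage = "reconstruct"
        p_hat = cohort.weighted_age_composition(surveys)
        release_years = sorted(releases["release_year"].unique())
        needed = range(
            min(release_years) + config.age_min - 1,
            max(release_years) + config.age_max - 1 + 1,
        )
        p_hat = cohort.impute_age_composition(p_hat, list(needed))
        cohorts = cohort.allocate_returns(
            returns, p_hat, config.age_min, config.age_max,
            release_years=release_years, renormalize=config.renormalize_ages,
        )
        age_rates = cohort.compute_return_rates(cohorts, releases)
        rates = cohort.total_return_rates(age_rates)
        cohorts.to_csv(out / "cohort_table.csv", index=False)
        rates.to_csv(out / "return_rates.csv", index=False)
        outputs += [out / "cohort_table.csv", out / "return_rates.csv"]

        stage = "cluster"
        tree = None
        if rates["region"].nunique() >= 3:
            dmat = clustering.correlation_distance_matrix(rates)
            tree = clustering.neighbor_joining(dmat)
            dmat.to_csv(out / "distance_matrix.csv")
            (out / "tree.nwk").write_text(tree.newick() + "\n")
            outputs += [out / "distance_matrix.csv", out / "tree.nwk"]

        stage = "merge"
        if config.merge_mapping:
            merged = cohort.merge_regions(
                config.merge_mapping, releases=releases, cohorts=cohorts
            )
            age_rates = cohort.compute_return_rates(
                merged["cohorts"], merged["releases"]
            )
            rates = cohort.total_return_rates(age_rates)
            covariate_table = covariate_table.copy()
            covariate_table["region"] = covariate_table["region"].map(
                config.merge_mapping
            )
            covariate_table = covariate_table.groupby(
                ["region", "release_year"], as_index=False
            ).mean()

        stage = "screen"
        screen_table = None
        if catch is not None:
            pca = predator.pca_catch(catch)
            screen_table = predator.screen_candidates(pca, catch)
            screen_table.to_csv(out / "candidates.csv")
            outputs.append(out / "candidates.csv")

        stage = "regress"
        covariate_cols = [
            c for c in covariate_table.columns
            if c not in ("region", "release_year")
        ]
        selection_rows, effect_frames, pred_frames = [], [], []
        best_models, diagnostics, fits = {}, {}, {}
        rng = np.random.default_rng(config.seed)
        for region, g in rates.groupby("region"):
            joined = g.merge(covariate_table, on=["region", "release_year"])
            joined = joined[joined["return_rate"] > 0]
            y = np.log(joined["return_rate"].to_numpy(dtype=float))
            Z = joined[covariate_cols]
            if config.groups:
                groups = {
                    name: [c for c in cols if c in covariate_cols]
                    for name, cols in config.groups.items()
                }
                groups = {k: v for k, v in groups.items() if v}
                sel = regression.compare_subset_models(
                    y, Z, groups, vif_threshold=config.vif_threshold,
                    avg_delta=config.avg_delta,
                    conditional=config.conditional_averaging,
                )
                fit = sel.best_model.fit
                tab = sel.aicc_table()
                tab.insert(0, "region", region)
                selection_rows.append(tab)
                best_models[region] = {
                    "groups": list(sel.winner.groups),
                    "covariates": list(sel.best_model.names),
                    "aicc": sel.best_model.aicc,
                    "adj_r2": fit.adj_r2,
                    "coefficients": io.to_jsonable(fit.coef.to_dict()),
                    "averaged": io.to_jsonable(
                        sel.averaged["estimate"].to_dict()
                    ),
                }
            else:
                fit = regression.ols_fit(y, Z)
                best_models[region] = {
                    "covariates": list(fit.names),
                    "aicc": fit.aicc,
                    "adj_r2": fit.adj_r2,
                    "coefficients": io.to_jsonable(fit.coef.to_dict()),
                }
            fits[region] = fit
            eff = regression.effect_sizes(
                fit.coef.drop("intercept"), fit.stderr.drop("intercept"),
                units=config.units,
            )
            eff.insert(0, "region", region)
            effect_frames.append(eff)
            pred = regression.predict_with_intervals(
                fit, joined.set_index("release_year")[list(fit.names)]
            )
            pred.insert(0, "region", region)
            pred["observed_rate"] = joined.set_index("release_year")[
                "return_rate"
            ]
            pred_frames.append(pred)
            diag = regression.residual_diagnostics(fit, rng=rng)
            diagnostics[region] = {
                "skipped": diag.skipped,
                "fraction_inside": diag.fraction_inside,
                "notice": diag.notice,
                "prediction_correlation": regression.prediction_correlation(
                    pred["observed_rate"], pred["pred_rate"]
                ),
            }
        if selection_rows:
            pd.concat(selection_rows).to_csv(out / "selection_table.csv", index=False)
            outputs.append(out / "selection_table.csv")
        pd.concat(effect_frames).to_csv(out / "effect_sizes.csv")
        pd.concat(pred_frames).to_csv(out / "predictions.csv")
        with open(out / "best_models.json", "w") as fh:
            json.dump(io.to_jsonable(best_models), fh, indent=1)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(io.to_jsonable(diagnostics), fh, indent=1)
        outputs += [
            out / "effect_sizes.csv", out / "predictions.csv",
            out / "best_models.json", out / "diagnostics.json",
        ]

        stage = "trends"
        trend_rows = []
        for region, g in rates.groupby("region"):
            g = g[g["return_rate"] > 0].sort_values("release_year")
            if len(g) < 8:
                continue
            tfit = trend.fit_year_trend(
                g["release_year"], np.log(g["return_rate"])
            )
            sig = trend.trend_significance(tfit, rng=rng)
            trend_rows.append({
                "series": f"log_return_rate:{region}", "edf": tfit.edf,
                "p_value": sig["p_value"], "significant": sig["significant"],
                "method": sig["method"],
            })
        pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)
        outputs.append(out / "trends.csv")

        stage = "manifest"
        manifest = io.write_manifest(
            out, inputs={"input_dir": inp}, seed=config.seed, outputs=outputs
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "rates": rates,
        "age_rates": age_rates,
        "tree": tree,
        "screen": screen_table,
        "best_models": best_models,
        "fits": fits,
        "diagnostics": diagnostics,
        "manifest": manifest,
        "outputs": outputs,
    }
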