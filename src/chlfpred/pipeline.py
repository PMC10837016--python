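"""End-to-end orchestration: simulate or ingest, filter, model, predict, scan.

`run_pipeline` executes the full analysis from a single `RunConfig` and
writes every intermediate table under the output directory, so each number
in the final report is traceable to a file.  Stage order: data acquisition
(synthetic generation or file ingestion) -> spectral indices -> quality
filtering -> light-response modelling with a single Cook's-distance screen
and refit -> slope/heritability extraction -> spatially adjusted trait
means and slope-trait correlation -> kinship-structured prediction with
cross-validation -> association scan.  A stage failure raises
`PipelineError` naming the stage; files written before the failure are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as chlf_io
from . import response as resp
from . import prediction as pred
from .simulate import (
    SimulationConfig,
    generate_population,
    generate_true_effects,
    simulate_chlf_series,
    simulate_yield,
)
from .spectral import bands_to_indices

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    ``mode='synthetic'`` generates the study from ``simulation``;
    ``mode='files'`` ingests the tables named in ``files``:
    ``records`` (list of {path, dialect, trial?}), ``traits`` (CSV with
    line/env/row/col/value), optional ``snp`` (dosage CSV) and
    ``ppfr_log``.  The seed propagates to every stochastic stage.
    """

    mode: str = "synthetic"
    outdir: str = "runs/out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter_rules: chlf_io.FilterRules = field(default_factory=chlf_io.FilterRules)
    response_variant: str = "interaction"
    cooks_factor: float = 50.0
    prediction: pred.GibbsSpec = field(default_factory=pred.GibbsSpec)
    models: tuple = ("genotype", "gxe", "gxec")
    cv_scenarios: tuple = ("CV1", "CV2")
    cv_reps: int = 2
    cv_parts: int = 3
    run_prediction: bool = True
    run_scan: bool = True
    quantile_q: float = 0.2
    files: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (
            ("simulation", SimulationConfig),
            ("filter_rules", chlf_io.FilterRules),
            ("prediction", pred.GibbsSpec),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        for key in ("models", "cv_scenarios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = asdict(self.simulation)
        d["filter_rules"] = asdict(self.filter_rules)
        d["prediction"] = asdict(self.prediction)
        return d


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report (also written as report.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": []}

    # -- acquire ------------------------------------------------------------
    truth = None
    snp = None
    with _stage("acquire"):
        if config.mode == "synthetic":
            sim = config.simulation
            if config.seed and sim.seed == 0:
                sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
            snp = generate_population(sim)
            truth = generate_true_effects(snp, sim)
            records, planted = simulate_chlf_series(truth, sim)
            traits = simulate_yield(truth, sim)
            snp.to_csv(out / "population.csv")
            truth.slope_table().to_csv(out / "ground_truth.csv", index=False)
            planted.to_csv(out / "planted_violations.csv", index=False)
            for trial, sub in records.groupby("trial", sort=True):
                chlf_io.write_chlf_table(sub, out / f"chlf_{trial}.csv")
            traits.to_csv(out / "traits.csv", index=False)
            # round-trip through the canonical reader, as file inputs would
            records = pd.concat(
                [
                    chlf_io.read_chlf_table(out / f"chlf_{trial}.csv", dialect="canonical")
                    for trial in sorted(records["trial"].unique())
                ],
                ignore_index=True,
            )
        elif config.mode == "files":
            files = config.files or {}
            frames = []
            for entry in files.get("records", []):
                frames.append(
                    chlf_io.read_chlf_table(
                        entry["path"],
                        dialect=entry.get("dialect", "canonical"),
                        column_map=entry.get("column_map"),
                        trial=entry.get("trial"),
                    )
                )
            if not frames:
                raise ValueError("files mode requires at least one records entry")
            records = pd.concat(frames, ignore_index=True)
            if files.get("ppfr_log"):
                log = chlf_io.read_ppfr_log(files["ppfr_log"])
                records = chlf_io.associate_ppfr(records, log)
            traits = pd.read_csv(files["traits"]) if files.get("traits") else None
            snp = pred.SNPMatrix.from_csv(files["snp"]) if files.get("snp") else None
        else:
            raise ValueError(f"unknown mode '{config.mode}'")
        report["n_records_raw"] = int(len(records))
        report["stages"].append("acquire")

    # -- indices ------------------------------------------------------------
    with _stage("indices"):
        records = bands_to_indices(records)
        report["stages"].append("indices")

    # -- filter -------------------------------------------------------------
    with _stage("filter"):
        filtered, filter_report = chlf_io.filter_records(records, config.filter_rules)
        filter_report.to_json(out / "filter_report.json")
        chlf_io.write_chlf_table(filtered, out / "chlf_filtered.csv")
        report["filter"] = json.loads(filter_report.to_json())
        report["stages"].append("filter")

    # -- respond ------------------------------------------------------------
    with _stage("respond"):
        fitted = resp.fit_response_model(filtered, variant=config.response_variant)
        screened, n_cooks = resp.cooks_screen(filtered, fitted, config.cooks_factor)
        if n_cooks:
            fitted = resp.fit_response_model(screened, variant=config.response_variant)
        filter_report.removed_cooks = n_cooks
        filter_report.n_retained -= n_cooks
        filter_report.to_json(out / "filter_report.json")
        slopes = resp.extract_slopes(fitted)
        slopes.to_csv(out / "slopes.csv", index=False)
        partition = resp.variance_partition(fitted)
        partition.to_csv(out / "variance_partition.csv", index=False)
        trial_slopes = resp.per_trial_slopes(screened)
        trial_slopes.to_csv(out / "slopes_per_trial.csv", index=False)
        report["removed_cooks"] = n_cooks
        report["ppfr_explained_pct"] = float(
            partition.loc[partition["term"] == "ppfr", "explained_pct"].sum()
        )
        report["stages"].append("respond")

    # -- traits -------------------------------------------------------------
    herit: dict = {}
    trait_means = None
    with _stage("traits"):
        if traits is not None:
            adjusted = resp.spatial_adjust(traits)
            adjusted.to_csv(out / "trait_adjusted_means.csv", index=False)
            trait_means = adjusted.set_index("line")["adjusted_mean"]
            herit["trait"] = resp.heritability_from_trait(traits)
            if trial_slopes["env"].nunique() > 1:
                herit["response"] = resp.heritability_from_slopes(trial_slopes)
            with open(out / "heritability.json", "w") as fh:
                json.dump(herit, fh, indent=2, default=float)
            slope_series = slopes.set_index("line")["slope"]
            common = slope_series.index.intersection(trait_means.index)
            r = float(np.corrcoef(slope_series.loc[common], trait_means.loc[common])[0, 1])
            report["slope_trait_pearson_r"] = r
            try:
                groups = resp.quantile_group_compare(slope_series, trait_means, config.quantile_q)
                groups["tukey"].to_csv(out / "quantile_groups_tukey.csv", index=False)
                report["quantile_group_means"] = groups["group_means"]
            except resp.ResponseModelError as exc:
                report["quantile_group_means"] = f"skipped: {exc}"
            report["heritability"] = {
                k: {kk: float(vv) for kk, vv in v.items()} for k, v in herit.items()
            }
        report["stages"].append("traits")

    # -- predict ------------------------------------------------------------
    with _stage("predict"):
        if config.run_prediction and snp is not None and traits is not None:
            snp_f = pred.maf_filter(snp)
            K = pred.compute_kinship(snp_f)
            per_env = resp.spatial_adjust(traits, per_trial=True)
            y_cells = per_env.rename(columns={"adjusted_mean": "value"})[["line", "env", "value"]]
            covariate = trial_slopes.rename(columns={"slope": "value"})[["line", "env", "value"]]
            cv_rows = []
            for scenario in config.cv_scenarios:
                for model in config.models:
                    spec = pred.GibbsSpec(
                        **{**asdict(config.prediction), "model": model, "seed": config.seed}
                    )
                    cov_arg = covariate if model == "gxec" else None
                    if model == "gxec" and not _covers_grid(covariate, y_cells):
                        continue
                    res = pred.cross_validate(
                        y_cells, K, cov_arg, spec, scenario,
                        reps=config.cv_reps, parts=config.cv_parts, seed=config.seed,
                    )
                    cv_rows.append(
                        {"scenario": scenario, "model": model,
                         "mean_r": res.mean, "sd_r": res.sd, "n_folds": len(res.accuracies)}
                    )
            cv_df = pd.DataFrame(cv_rows)
            cv_df.to_csv(out / "cv_results.csv", index=False)
            report["cv"] = cv_rows
        report["stages"].append("predict")

    # -- scan ---------------------------------------------------------------
    with _stage("scan"):
        if config.run_scan and snp is not None:
            snp_f = pred.maf_filter(snp)
            trait_for_scan = slopes.set_index("line")["slope"]
            scan, threshold = pred.association_scan(trait_for_scan, snp_f)
            scan.to_csv(out / "association_scan.csv", index=False)
            top = scan.nsmallest(1, "p").iloc[0]
            report["scan"] = {
                "bonferroni_threshold": threshold,
                "top_marker": str(top["marker"]),
                "top_p": float(top["p"]),
                "n_significant": int((scan["p"] < threshold).sum()),
            }
        report["stages"].append("scan")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float, sort_keys=True)
    return report


def _covers_grid(covariate: pd.DataFrame, y_cells: pd.DataFrame) -> bool:
    need = set(zip(y_cells["line"], y_cells["env"]))
    have = set(zip(covariate["line"], covariate["env"]))
    return need <= have
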