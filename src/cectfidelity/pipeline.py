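"""End-to-end pipeline driver.

``run_pipeline`` executes phantom simulation (or feature-table ingest)
-> quantitative/categorical feature extraction -> GT-vs-imputed
concordance -> diagnostic-feature scoring -> hallucination index ->
SD-vs-agreement and rater reliability, writing tidy CSVs plus a JSON
run-metadata file.  Outputs are reproducible byte for byte from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concord, dx, halluc, io, reliability
from .characterize import ProxyConfig, assemble_features
from .core import PHASES, Phase
from .phantom import CohortConfig, simulate_cohort, simulate_rater_scores
from .quantify import image_sd

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "extract_cohort_features", "evaluate_pair_tables", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "phantom"  # {"phantom", "table"}
    n_studies: int = 37
    seed: int = 0
    output_dir: str = "results"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    proxy: ProxyConfig = field(default_factory=ProxyConfig)
    binomial_null_p: float = 0.5
    n_histogram_bins: int = 64
    kappa_weights: str = "linear"
    bootstrap_reps: int = 2000
    simulate_raters: bool = True
    n_raters: int = 3
    feature_table: str | None = None  # table mode input
    schema_map: dict = field(default_factory=dict)
    rater_table: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("phantom", {}).items()})
        proxy = ProxyConfig(**raw.pop("proxy", {}))
        return cls(cohort=cohort, proxy=proxy, **raw)

    def validate(self) -> None:
        if self.mode not in ("phantom", "table"):
            raise ValueError("mode must be 'phantom' or 'table'")
        if self.mode == "table" and not self.feature_table:
            raise ValueError("table mode needs feature_table")
        if not (0 < self.binomial_null_p < 1):
            raise ValueError("binomial_null_p must be in (0, 1)")
        self.cohort.validate()


def extract_cohort_features(pairs, proxy: ProxyConfig | None = None):
    """Per-image feature tables for a simulated paired cohort.

    For each study, ground-truth vectors come from the all-GT study;
    the surrogate vector for phase p comes from the study with phase p
    swapped for its surrogate (mirroring imputation of a held-out
    phase).  Returns ``(gt_df, imp_df, sd_df)`` where ``sd_df`` holds
    each surrogate image's tumor-ROI SD.
    """
    gt_rows, imp_rows, sd_rows = [], [], []
    for pair in pairs:
        study = pair["gt"]
        for phase in PHASES:
            gt_rows.append(assemble_features(study, phase, config=proxy).as_row())
        for phase, surrogate in pair["surrogates"].items():
            mixed = study.with_image(surrogate)
            imp_rows.append(
                assemble_features(mixed, phase, config=proxy, provenance="surrogate").as_row()
            )
            sd_rows.append(
                {
                    "study_id": pair["study_id"],
                    "phase": Phase(phase).value,
                    "sd": image_sd(surrogate, mixed.tumor_roi),
                }
            )
    return pd.DataFrame(gt_rows), pd.DataFrame(imp_rows), pd.DataFrame(sd_rows)


def evaluate_pair_tables(gt_df, imp_df, null_p: float = 0.5) -> dict:
    """Concordance analyses that need only the paired feature tables."""
    profiles = concord.intensity_profiles(gt_df, imp_df)
    return {
        "agreement": concord.categorical_agreement(gt_df, imp_df, null_p=null_p),
        "correlations": concord.correlation_table(gt_df, imp_df),
        "profiles": profiles,
        "profile_diffs": concord.profile_diff_summary(profiles),
        "heatmap": concord.agreement_heatmap_data(gt_df, imp_df),
    }


def _hallucination_table(pairs, n_bins: int) -> pd.DataFrame:
    edges = halluc.default_bin_edges(n_bins)
    rows = []
    for pair in pairs:
        study = pair["gt"]
        for phase, surrogate in pair["surrogates"].items():
            rows.append(
                {
                    "study_id": pair["study_id"],
                    "phase": Phase(phase).value,
                    "hallucination_index": halluc.hallucination_index(
                        study[phase], surrogate, study.tumor_roi, edges
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full evaluation; returns (and writes) the result bundle."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.mode == "phantom":
        pairs, truth = simulate_cohort(config.n_studies, config.cohort, seed=config.seed)
        gt_df, imp_df, sd_df = extract_cohort_features(pairs, config.proxy)
        results["truth"] = truth
        results["halluc_per_pair"] = _hallucination_table(pairs, config.n_histogram_bins)
        results["halluc_summary"] = halluc.cohort_hallucination(results["halluc_per_pair"])
        diagnoses = truth.set_index("study_id")["diagnosis"]
    else:
        table = io.read_feature_table(config.feature_table, config.schema_map, strict=False)
        gt_df, imp_df, sd_df = table.gt, table.imputed, None
        diagnoses = None

    results["features_gt"] = gt_df
    results["features_imp"] = imp_df
    results.update(evaluate_pair_tables(gt_df, imp_df, null_p=config.binomial_null_p))

    if diagnoses is not None:
        gt_half = dx.diagnostic_feature_fraction(gt_df, diagnoses)
        imp_half = dx.diagnostic_feature_fraction(imp_df, diagnoses)
        results["dx_fractions_gt"] = gt_half
        results["dx_fractions_imp"] = imp_half
        results["dx_tests"] = dx.compare_gt_imputed_dx(gt_half, imp_half)

    if sd_df is not None:
        results["sd_table"] = sd_df
        results["sd_vs_agreement"] = reliability.sd_vs_agreement(sd_df, results["heatmap"])

    rater_df = None
    if config.rater_table:
        rater_df = pd.read_csv(config.rater_table)
    elif config.mode == "phantom" and config.simulate_raters:
        hp = results["halluc_per_pair"]
        rater_df = simulate_rater_scores(
            list(zip(hp["study_id"], hp["phase"])),
            hp["hallucination_index"].to_numpy(),
            n_raters=config.n_raters,
            seed=config.seed + 101,
        )
    if rater_df is not None:
        results["rater_scores"] = rater_df
        results["rater_summary"] = reliability.rater_summary(rater_df)
        raters = sorted(rater_df["rater"].unique())
        wide = rater_df.pivot_table(index="image_id", columns="rater",
                                    values="score", aggfunc="first").dropna()
        rel = []
        for i in range(len(raters)):
            for j in range(i + 1, len(raters)):
                r = reliability.rater_pair_reliability(
                    wide[raters[i]].to_numpy(int), wide[raters[j]].to_numpy(int),
                    raters[i], raters[j],
                    weights=config.kappa_weights,
                    n_boot=config.bootstrap_reps,
                    seed=config.seed + 7,
                )
                rel.append(
                    {
                        "rater_a": r.rater_a, "rater_b": r.rater_b, "n": r.n,
                        "weighted_kappa": r.weighted_kappa.value,
                        "kappa_ci_low": r.weighted_kappa.ci_low,
                        "kappa_ci_high": r.weighted_kappa.ci_high,
                        "pabak": r.pabak.value,
                        "pabak_ci_low": r.pabak.ci_low,
                        "pabak_ci_high": r.pabak.ci_high,
                        "pct_agree_0": r.percent_agreement["0"],
                        "pct_agree_1": r.percent_agreement["1"],
                        "pct_agree_total": r.percent_agreement["total"],
                    }
                )
        results["rater_reliability"] = pd.DataFrame(rel)

    _write_bundle(results, config, outdir)
    return results


def _write_bundle(results: dict, config: RunConfig, outdir: Path) -> None:
    for name in ("features_gt", "features_imp", "agreement", "correlations",
                 "profiles", "profile_diffs", "truth", "halluc_per_pair",
                 "dx_fractions_gt", "dx_fractions_imp", "dx_tests",
                 "sd_table", "rater_scores", "rater_reliability"):
        obj = results.get(name)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.csv", index=False)
    hm = results.get("heatmap")
    if hm is not None:
        hm.to_csv(outdir / "heatmap.csv")
    meta = {
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
        "summaries": _jsonable(
            {k: results[k] for k in ("halluc_summary", "rater_summary") if k in results}
        ),
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
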