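"""End-to-end orchestration: filter -> harmonize -> score -> structure -> assoc.

``run_pipeline`` executes the enabled stages in a fixed order and writes
every results table as TSV plus a JSON manifest (sample accounting, seeds,
per-stage marker counts). Identical inputs and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, popstruct
from .data_io import (
    CohortTable, align_samples, read_cohort, read_dosages, read_weight_table,
    write_table,
)
from .errors import GrslensError
from .grs import cohort_composition, compute_grs, summarize_grs
from .qc import (
    QcThresholds, fill_missing_dosages, filter_markers, filter_samples,
    harmonize_to_weights,
)

log = logging.getLogger("grslens")

TRAITS = ("HDL", "LDL", "TC", "TG")


class StageError(GrslensError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    weights: str
    dosages: str
    cohort: str
    out_dir: str
    qc: QcThresholds = field(default_factory=QcThresholds)
    exclude_lipid_med: bool = True
    lipid_panel: bool = True
    clinical_panel: bool = True
    moderation: bool = True
    joint_tests: bool = True
    pca: bool = True
    correlation: bool = False
    n_components: int = 2
    n_boot: int = 1000
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "qc" in raw:
            raw["qc"] = QcThresholds(**raw["qc"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("weights", "dosages", "cohort"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise StageError("validate", "missing_input",
                                 f"{name} file not found: {p}")
        if self.n_boot and self.seed is None:
            raise StageError("validate", "missing_seed",
                             "seed required when bootstrap is enabled")


def _quantile_table(scores: pd.DataFrame, cohort: CohortTable) -> pd.DataFrame:
    """Per-population score quantiles (distributional summary of each GRS)."""
    merged = cohort.df.merge(scores.reset_index(names="sample_id"), on="sample_id")
    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    rows = []
    for pop, grp in merged.groupby("population", sort=True):
        for col in scores.columns:
            vals = np.quantile(grp[col].to_numpy(), qs)
            rows.append((pop, col[:-4], *vals))
    return pd.DataFrame(rows, columns=["population", "trait",
                                       *(f"q{int(q * 100)}" for q in qs)])


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns {name: DataFrame} and writes TSVs."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "qc": asdict(cfg.qc)}
    results: dict[str, pd.DataFrame] = {}

    def _stage(name, code, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GrslensError as exc:
            raise StageError(name, code, str(exc)) from exc

    weights = _stage("read", "weights", read_weight_table, cfg.weights)
    dosages = _stage("read", "dosages", read_dosages, cfg.dosages)
    cohort = _stage("read", "cohort", read_cohort, cfg.cohort)
    manifest["samples_in"] = len(cohort)
    manifest["markers_in"] = dosages.n_markers
    manifest["weights_per_trait"] = weights.counts()

    if cfg.exclude_lipid_med and "lipid_med" in cohort.df.columns:
        filtered = _stage("filter_samples", "medication", filter_samples,
                          cohort, True)
    else:
        filtered = cohort
    manifest["samples_excluded_med"] = len(cohort) - len(filtered)

    dosages, filtered = _stage("align", "samples", align_samples,
                               dosages, filtered)
    manifest["samples_unmatched"] = (
        manifest["samples_in"] - manifest["samples_excluded_med"] - len(filtered)
    )
    manifest["samples_analyzed"] = len(filtered)
    assert (manifest["samples_in"] == manifest["samples_excluded_med"]
            + manifest["samples_unmatched"] + manifest["samples_analyzed"])

    dosages, qc_report = _stage("qc", "markers", filter_markers, dosages, cfg.qc)
    results["qc_report"] = qc_report
    manifest["markers_after_qc"] = dosages.n_markers

    dosages, harm = _stage("harmonize", "alleles", harmonize_to_weights,
                           dosages, weights)
    results["harmonization"] = harm.to_frame()
    manifest["harmonization"] = {
        "matched": harm.n_matched, "flipped": harm.n_flipped,
        "dropped_absent": harm.n_dropped_absent,
        "dropped_mismatch": harm.n_dropped_mismatch,
    }
    dosages = _stage("fill", "missing", fill_missing_dosages, dosages)
    weights_used = weights.subset(dosages.marker_ids)

    grs = _stage("score", "grs", compute_grs, dosages, weights_used)
    results["grs"] = grs.scores.reset_index(names="sample_id")
    results["grs_summary"] = summarize_grs(grs, filtered)
    results["cohort_composition"] = cohort_composition(filtered)
    results["grs_quantiles"] = _quantile_table(grs.scores, filtered)

    results["allele_freqs"] = popstruct.allele_freq_by_population(
        dosages, filtered)
    results["dosage_anova"] = popstruct.dosage_anova_all(dosages, filtered)
    if cfg.pca:
        pca = _stage("popstruct", "pca", popstruct.genotype_pca,
                     dosages, cfg.n_components)
        results["pca_scores"] = pca.scores.reset_index(names="sample_id")
        manifest["pca_explained_variance"] = [
            float(v) for v in pca.explained_variance_ratio]
    if cfg.correlation:
        mat, _ = popstruct.pairwise_individual_correlation(dosages)
        results["individual_correlation"] = mat.reset_index(names="sample_id")

    data = grs.merge_with(filtered)
    traits = [t for t in TRAITS
              if f"{t}_GRS" in data.columns and t in data.columns]
    if cfg.lipid_panel:
        rows = []
        for i, trait in enumerate(traits):
            for j, (pop, grp) in enumerate(data.groupby("population", sort=True)):
                r = assoc.delta_r2(trait, f"{trait}_GRS", grp,
                                   n_boot=cfg.n_boot,
                                   seed=cfg.seed + 97 * i + j)
                rows.append((trait, pop, r.delta_r2, r.ci_lower, r.ci_upper,
                             r.p, r.n))
        results["delta_r2"] = pd.DataFrame(
            rows, columns=["trait", "population", "delta_r2", "ci_lower",
                           "ci_upper", "p", "n"])
    if cfg.moderation:
        rows = []
        for trait in traits:
            t = assoc.moderation_test(trait, f"{trait}_GRS", data)
            rows.append((trait, t.statistic, t.df1, t.df2, t.p))
        results["moderation"] = pd.DataFrame(
            rows, columns=["trait", "F", "df1", "df2", "p"])
    if cfg.joint_tests:
        jrows, crows = [], []
        for trait in traits:
            for pop, grp in data.groupby("population", sort=True):
                t, coefs = assoc.joint_noncorresponding_test(trait, grp)
                jrows.append((trait, pop, t.statistic, t.df1, t.df2, t.p))
                for _, c in coefs.iterrows():
                    crows.append((trait, pop, c["grs"], c["coef"], c["se"],
                                  c["p"]))
        results["joint_tests"] = pd.DataFrame(
            jrows, columns=["trait", "population", "F", "df1", "df2", "p"])
        results["joint_coefficients"] = pd.DataFrame(
            crows, columns=["outcome", "population", "grs", "coef", "se", "p"])
    if cfg.clinical_panel:
        outcomes = list(filtered.available_outcomes())
        if outcomes:
            results["outcome_panel"] = assoc.outcome_panel(data, outcomes)

    for name, df in results.items():
        write_table(df, out_dir / f"{name}.tsv")
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %d tables in %s", len(results), out_dir)
    return {"manifest": manifest, **results}
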