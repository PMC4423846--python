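"""Weighted genetic risk scores and cohort summaries.

The score for individual *i* and trait *t* is the raw weighted allele count

    GRS_it = sum_m w_mt * d_im

over the trait's markers, with d_im the effect-allele dosage in [0, 2] and
w_mt the published per-copy effect. No normalization by marker count or
centering is applied, so scores are in trait units (mg/dL; log-mg/dL for TG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CohortTable, DosageMatrix, WeightTable
from .errors import ValidationError

log = logging.getLogger("grslens")


@dataclass
class GRSTable:
    """Per-sample scores, one column per trait (``<trait>_GRS``)."""

    scores: pd.DataFrame  # index sample_id
    skipped_traits: tuple[str, ...] = ()

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(c[:-4] for c in self.scores.columns)

    def merge_with(self, cohort: CohortTable) -> pd.DataFrame:
        """Inner-join scores onto the cohort table by sample_id."""
        return cohort.df.merge(self.scores.reset_index(names="sample_id"),
                               on="sample_id", how="inner")


def compute_grs(d: DosageMatrix, w: WeightTable) -> GRSTable:
    """Compute weighted allele-count scores from a harmonized, filled matrix.

    Every weight marker must be present (run harmonization first and subset
    the weight table to the surviving markers); every cell must be observed
    (run :func:`~grslens.qc.fill_missing_dosages` first). A trait whose
    marker set is empty after subsetting yields no column and is flagged.
    """
    if np.isnan(d.dosages).any():
        raise ValidationError("dosage matrix contains missing cells; fill first")
    pos = {m: i for i, m in enumerate(d.marker_ids)}
    absent = [m for m in w.marker_ids if m not in pos]
    if absent:
        raise ValidationError(
            f"weight markers absent from dosage matrix (harmonize first): {absent[:5]}"
        )
    cols: dict[str, np.ndarray] = {}
    skipped = []
    for trait in w.traits:
        weights = w.for_trait(trait)
        if not weights:
            skipped.append(trait)
            continue
        idx = [pos[m] for m in weights]
        wv = np.array([weights[m] for m in weights])
        cols[f"{trait}_GRS"] = d.dosages[:, idx] @ wv
    if skipped:
        log.warning("traits with no surviving markers, no score computed: %s", skipped)
    if not cols:
        raise ValidationError("no trait has surviving markers")
    scores = pd.DataFrame(cols, index=pd.Index(list(d.sample_ids), name="sample_id"))
    if not np.isfinite(scores.to_numpy()).all():
        raise ValidationError("non-finite score produced")
    return GRSTable(scores, tuple(skipped))


def summarize_grs(g: GRSTable, cohort: CohortTable) -> pd.DataFrame:
    """Per-population per-trait mean and sample SD (n-1 denominator)."""
    merged = g.merge_with(cohort)
    if merged.empty:
        raise ValidationError("no overlapping samples between scores and cohort")
    rows = []
    for pop, grp in merged.groupby("population", sort=True):
        for col in g.scores.columns:
            vals = grp[col].to_numpy()
            sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
            if len(vals) < 2:
                log.warning("population %s has n<2; SD undefined", pop)
            rows.append((pop, col[:-4], float(np.mean(vals)), sd, len(vals)))
    return pd.DataFrame(rows, columns=["population", "trait", "mean", "sd", "n"])


def cohort_composition(cohort: CohortTable | pd.Series) -> pd.DataFrame:
    """Per-population counts and percentages (full precision; display rounds)."""
    if isinstance(cohort, CohortTable):
        counts = cohort.df["population"].value_counts().sort_index()
    else:
        counts = pd.Series(cohort).sort_index()
    total = int(counts.sum())
    return pd.DataFrame({
        "population": counts.index,
        "n": counts.to_numpy(),
        "percent": 100.0 * counts.to_numpy() / total,
    }).reset_index(drop=True)
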