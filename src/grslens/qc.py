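"""Marker/sample quality control and effect-allele harmonization.

Marker filters mirror standard pre-imputation genotype QC: missingness
> 0.05, exact Hardy-Weinberg equilibrium p < 0.0005 (genotyped markers
only), minor allele frequency < 0.005 — all strict inequalities.
Harmonization recodes each dosage column so it counts the weight table's
effect allele (d -> 2 - d when the file counts the opposite allele);
markers with an incompatible allele pair, or absent from the genotype data
altogether, are dropped and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import CohortTable, DosageMatrix, WeightTable
from .errors import ValidationError

log = logging.getLogger("grslens")


@dataclass(frozen=True)
class QcThresholds:
    """Marker-level QC thresholds (defaults as in standard array QC)."""

    max_missing: float = 0.05
    min_hwe_p: float = 0.0005
    min_maf: float = 0.005

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_hwe_p", "min_maf"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name}={v} outside (0, 1)")


@dataclass
class HarmonizationReport:
    """Accounting of what happened to each weight-table marker."""

    n_matched: int = 0
    n_flipped: int = 0
    n_dropped_absent: int = 0
    n_dropped_mismatch: int = 0
    dropped_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("matched", self.n_matched), ("flipped", self.n_flipped),
                ("dropped_absent", self.n_dropped_absent),
                ("dropped_mismatch", self.n_dropped_mismatch)]
        return pd.DataFrame(rows, columns=["category", "n"])


def filter_samples(cohort: CohortTable, exclude_lipid_med: bool = True) -> CohortTable:
    """Drop individuals on lipid-lowering medication (as in lipid GWAS practice)."""
    if not exclude_lipid_med:
        return cohort
    if "lipid_med" not in cohort.df.columns:
        raise ValidationError(
            "lipid_med column required to exclude medicated individuals"
        )
    mask = cohort.df["lipid_med"].astype(bool)
    n_excluded = int(mask.sum())
    remaining = cohort.df.loc[~mask]
    log.info("excluded %d individuals on lipid-lowering medication", n_excluded)
    if remaining.empty:
        raise ValidationError("no samples remain after medication exclusion")
    return CohortTable(remaining)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one, under

        P(n_Aa | n, n_A) = n! / (n_AA! n_Aa! n_aa!) * 2**n_Aa
                           * n_A! n_a! / (2n)!

    Monomorphic input (one allele absent) returns 1.0.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or v != int(v):
            raise ValidationError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValidationError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        log.info("monomorphic marker in HWE test; p = 1.0")
        return 1.0
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)  # feasible heterozygote counts
    homs_rare = (rare - hets) // 2
    homs_common = (max(n_A, n_a) - hets) // 2
    logp = (gammaln(n + 1)
            - gammaln(homs_rare + 1) - gammaln(hets + 1) - gammaln(homs_common + 1)
            + hets * np.log(2.0)
            + gammaln(n_A + 1) + gammaln(n_a + 1) - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_Aa]
    if obs.size == 0:  # parity mismatch cannot happen for valid counts
        raise ValidationError("inconsistent genotype counts")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def marker_qc_stats(d: DosageMatrix) -> pd.DataFrame:
    """Per-marker missingness, MAF (dosage-based, folded) and HWE p."""
    miss = np.isnan(d.dosages).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(d.dosages, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.ones(d.n_markers)
    for j in range(d.n_markers):
        if d.is_imputed[j]:
            continue  # HWE applies to called genotypes only
        col = d.dosages[:, j]
        g = np.rint(col[~np.isnan(col)]).astype(int)
        hwe_p[j] = hwe_exact_test(int((g == 2).sum()), int((g == 1).sum()),
                                  int((g == 0).sum()))
    return pd.DataFrame({
        "marker_id": d.marker_ids, "missingness": miss, "maf": maf,
        "hwe_p": hwe_p, "is_imputed": d.is_imputed,
    })


def filter_markers(d: DosageMatrix, thr: QcThresholds = QcThresholds()
                   ) -> tuple[DosageMatrix, pd.DataFrame]:
    """Remove markers failing missingness, MAF or (genotyped-only) HWE filters.

    Returns the filtered matrix and a per-marker report with the triggering
    rule(s) for each removed marker. Thresholds are strict inequalities.
    """
    stats = marker_qc_stats(d)
    fail_miss = stats["missingness"].to_numpy() > thr.max_missing
    fail_maf = stats["maf"].to_numpy() < thr.min_maf
    fail_hwe = (~d.is_imputed) & (stats["hwe_p"].to_numpy() < thr.min_hwe_p)
    removed = fail_miss | fail_maf | fail_hwe
    rules = [
        ";".join(r for r, f in (("missingness", fm), ("maf", fa), ("hwe", fh)) if f)
        for fm, fa, fh in zip(fail_miss, fail_maf, fail_hwe)
    ]
    report = stats.assign(removed=removed, rule=rules)
    keep = np.flatnonzero(~removed)
    if keep.size == 0:
        raise ValidationError("all markers removed by QC filters")
    if removed.any():
        log.info("marker QC removed %d of %d markers", int(removed.sum()), d.n_markers)
    return d.subset_markers(keep), report


def harmonize_to_weights(d: DosageMatrix, w: WeightTable
                         ) -> tuple[DosageMatrix, HarmonizationReport]:
    """Align dosage columns to each weight's effect allele.

    Restricts the matrix to weight-table markers found in the genotype data.
    A column already counting the effect allele is kept as-is; one counting
    the other allele of the same pair is recoded 2 - d (missing stays
    missing); an incompatible allele pair drops the marker. Strand-ambiguous
    (A/T, C/G) pairs are matched by the labels as given, with a warning.
    """
    report = HarmonizationReport()
    pos = {m: i for i, m in enumerate(d.marker_ids)}
    keep_cols: list[int] = []
    flip: list[bool] = []
    ambiguous: list[str] = []
    for marker in w.marker_ids:
        effect, other = w.allele_pair(marker)
        j = pos.get(marker)
        if j is None:
            report.n_dropped_absent += 1
            report.dropped_ids.append(marker)
            continue
        counted, alt = d.counted_allele[j], d.alt_allele[j]
        if {effect, other} in ({"A", "T"}, {"C", "G"}):
            ambiguous.append(marker)
        if counted == effect and alt == other:
            keep_cols.append(j)
            flip.append(False)
        elif counted == other and alt == effect:
            keep_cols.append(j)
            flip.append(True)
        else:
            report.n_dropped_mismatch += 1
            report.dropped_ids.append(marker)
    if ambiguous:
        log.info("%d strand-ambiguous (A/T, C/G) markers matched by allele "
                 "label only: %s%s", len(ambiguous), ", ".join(ambiguous[:5]),
                 ", ..." if len(ambiguous) > 5 else "")
    if not keep_cols:
        raise ValidationError("no weight-table markers survive harmonization")
    out = d.subset_markers(keep_cols)
    flip_idx = np.flatnonzero(flip)
    if flip_idx.size:
        out.dosages[:, flip_idx] = 2.0 - out.dosages[:, flip_idx]
        swapped = out.counted_allele[flip_idx].copy()
        out.counted_allele[flip_idx] = out.alt_allele[flip_idx]
        out.alt_allele[flip_idx] = swapped
    report.n_matched = len(keep_cols)
    report.n_flipped = int(flip_idx.size)
    log.info("harmonization: %d matched (%d flipped), %d absent, %d mismatched",
             report.n_matched, report.n_flipped,
             report.n_dropped_absent, report.n_dropped_mismatch)
    return out, report


def fill_missing_dosages(d: DosageMatrix) -> DosageMatrix:
    """Replace missing cells with the marker's mean observed dosage.

    The fill value is a per-marker expected allelic dosage computed over the
    whole cohort (no population conditioning), so every individual gets one
    score from a complete vector.
    """
    miss = np.isnan(d.dosages)
    if not miss.any():
        return d
    all_missing = miss.all(axis=0)
    if all_missing.any():
        raise ValidationError(
            f"marker {d.marker_ids[int(np.argmax(all_missing))]} has no observed "
            "dosages (should have been removed by QC)"
        )
    filled = d.dosages.copy()
    col_means = np.nanmean(d.dosages, axis=0)
    filled[miss] = np.broadcast_to(col_means, d.dosages.shape)[miss]
    return DosageMatrix(d.sample_ids.copy(), d.marker_ids.copy(), filled,
                        d.counted_allele.copy(), d.alt_allele.copy(),
                        d.is_imputed.copy())
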