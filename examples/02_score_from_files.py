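"""Score a cohort from files: read, QC-filter, harmonize, fill, score.

Writes a small fixture to a temporary directory, then walks the exact file
path a real analysis takes: marker QC (missingness > 0.05, HWE p < 0.0005
on genotyped markers, MAF < 0.005), effect-allele harmonization (d -> 2-d
flips), mean-imputation of missing dosages, and the weighted sum.
"""

import tempfile
from pathlib import Path

from grslens import (
    SynthConfig, compute_grs, fill_missing_dosages, filter_markers,
    harmonize_to_weights, read_cohort, read_dosages, read_weight_table,
)
from grslens.simulate import write_fixture

with tempfile.TemporaryDirectory() as tmp:
    cfg = SynthConfig(seed=11, populations=(("PopA", 400, 0.12),
                                            ("PopB", 500, 0.05)))
    paths = write_fixture(cfg, Path(tmp) / "fx")
    weights = read_weight_table(paths["weights"])
    dosages = read_dosages(paths["dosages"])
    cohort = read_cohort(paths["cohort"])

print(f"weights per trait: {weights.counts()}")
dosages, qc_report = filter_markers(dosages)
print(f"markers after QC: {dosages.n_markers} "
      f"({int(qc_report.removed.sum())} removed)")
dosages, harm = harmonize_to_weights(dosages, weights)
print(f"harmonized: {harm.n_matched} matched, {harm.n_flipped} flipped, "
      f"{harm.n_dropped_absent} absent from genotypes")
dosages = fill_missing_dosages(dosages)
grs = compute_grs(dosages, weights.subset(dosages.marker_ids))
print("\nfirst three individuals' scores (trait units, mg/dL):")
print(grs.scores.head(3).round(3).to_string())
print("\nEach score is the sum of effect-allele dosages times published")
print("per-allele effects; flips ensure every column counts the effect allele.")
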