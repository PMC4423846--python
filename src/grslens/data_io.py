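"""Reading, validating and writing the three input artifacts.

Three tabular inputs drive every analysis:

* a **weight table** — one row per (marker, trait) giving the effect ("A2")
  allele and the per-allele-copy effect in trait units (mg/dL per copy;
  log-mg/dL for triglycerides);
* a **dosage matrix** — individuals x markers expected effect-allele counts in
  [0, 2], fractional when imputed, possibly missing; read from a VCF (DS or GT
  FORMAT fields) or a plain TSV;
* a **cohort table** — per-individual population label, covariates and
  phenotypes.

All tabular outputs are plain TSV with a header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger("grslens")

TRAITS = ("HDL", "LDL", "TC", "TG")
NUCLEOTIDES = frozenset("ACGT")

#: header synonyms used to resolve weight-table columns
_WEIGHT_COLUMN_SYNONYMS = {
    "marker_id": ("marker_id", "marker", "snp", "rsid", "rs_id", "id"),
    "trait": ("trait", "phenotype", "lipid"),
    "effect_allele": ("effect_allele", "a2", "ea", "allele2"),
    "other_allele": ("other_allele", "a1", "oa", "allele1"),
    "weight": ("weight", "effect", "beta", "effect_size"),
}

REQUIRED_COHORT_COLUMNS = ("sample_id", "population", "age", "sex")
BINARY_OUTCOMES = ("hypertension", "metabolic_syndrome", "T2D")
CONTINUOUS_OUTCOMES = ("BMI", "NCEP_10yr_risk", "Framingham_risk")
DEFAULT_SEX_MAPPING = {
    "f": 0, "female": 0, "0": 0, "m": 1, "male": 1, "1": 1,
}


@dataclass(frozen=True)
class MarkerWeight:
    """Per-allele effect of one marker on one lipid trait."""

    marker_id: str
    trait: str
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValidationError(
                f"unknown trait {self.trait!r} for {self.marker_id} "
                f"(expected one of {', '.join(TRAITS)})"
            )
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a not in NUCLEOTIDES:
                raise ValidationError(
                    f"non-nucleotide {name} {a!r} for marker {self.marker_id}"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"marker {self.marker_id}: effect and other allele are both "
                f"{self.effect_allele!r}"
            )
        if not np.isfinite(self.weight):
            raise ValidationError(f"non-finite weight for marker {self.marker_id}")


@dataclass
class WeightTable:
    """Collection of marker weights, one lead SNP per gene per trait."""

    entries: list[MarkerWeight]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("empty weight table")
        seen: set[tuple[str, str]] = set()
        alleles: dict[str, tuple[str, str]] = {}
        for e in self.entries:
            key = (e.marker_id, e.trait)
            if key in seen:
                raise ValidationError(
                    f"duplicate weight entry for marker {e.marker_id} / {e.trait}"
                )
            seen.add(key)
            pair = (e.effect_allele, e.other_allele)
            prev = alleles.setdefault(e.marker_id, pair)
            if prev != pair and prev != pair[::-1]:
                raise ValidationError(
                    f"marker {e.marker_id} has inconsistent allele pairs across traits"
                )

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(t for t in TRAITS if any(e.trait == t for e in self.entries))

    @property
    def marker_ids(self) -> list[str]:
        """Distinct marker IDs, in first-appearance order."""
        return list(dict.fromkeys(e.marker_id for e in self.entries))

    def for_trait(self, trait: str) -> dict[str, float]:
        """Map marker_id -> weight for one trait."""
        return {e.marker_id: e.weight for e in self.entries if e.trait == trait}

    def allele_pair(self, marker_id: str) -> tuple[str, str]:
        """(effect_allele, other_allele) for a marker."""
        for e in self.entries:
            if e.marker_id == marker_id:
                return (e.effect_allele, e.other_allele)
        raise KeyError(marker_id)

    def counts(self) -> dict[str, int]:
        return {t: sum(e.trait == t for e in self.entries) for t in self.traits}

    def subset(self, marker_ids: Iterable[str]) -> "WeightTable":
        """Restrict to markers present in ``marker_ids`` (e.g. after harmonization)."""
        keep = set(marker_ids)
        kept = [e for e in self.entries if e.marker_id in keep]
        if not kept:
            raise ValidationError("no weight-table markers remain after subsetting")
        return WeightTable(kept, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.marker_id, e.trait, e.effect_allele, e.other_allele, e.weight)
             for e in self.entries],
            columns=["marker_id", "trait", "effect_allele", "other_allele", "weight"],
        )


@dataclass
class DosageMatrix:
    """Individuals x markers expected effect-allele counts.

    ``dosages`` is an (n_samples, n_markers) float array; missing cells are
    NaN, every other cell lies in [0, 2]. ``counted_allele[m]`` is the allele
    whose copies column ``m`` counts (the VCF ALT under the DS convention).
    """

    sample_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    counted_allele: np.ndarray
    alt_allele: np.ndarray
    is_imputed: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.counted_allele = np.asarray(self.counted_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.is_imputed = np.asarray(self.is_imputed, dtype=bool)
        n, m = self.dosages.shape
        if n == 0 or m == 0:
            raise ValidationError("dosage matrix has zero samples or zero markers")
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValidationError("dosage matrix dimensions do not match ID lists")
        for name, ids in (("sample", self.sample_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} IDs in dosage matrix")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < -1e-6 or vals.max() > 2 + 1e-6):
            bad = vals[(vals < -1e-6) | (vals > 2 + 1e-6)][0]
            raise ValidationError(f"dosage {bad} outside [0, 2]")
        np.clip(self.dosages, 0.0, 2.0, out=self.dosages)
        if np.any(self.counted_allele == self.alt_allele):
            i = int(np.argmax(self.counted_allele == self.alt_allele))
            raise ValidationError(
                f"marker {self.marker_ids[i]}: counted and alt allele identical"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(marker_id)
        return int(idx[0])

    def subset_samples(self, sample_ids: Sequence[str]) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in sample_ids]
        return DosageMatrix(
            np.asarray(list(sample_ids), dtype=object), self.marker_ids.copy(),
            self.dosages[rows, :].copy(), self.counted_allele.copy(),
            self.alt_allele.copy(), self.is_imputed.copy(),
        )

    def subset_markers(self, keep: Sequence[int]) -> "DosageMatrix":
        keep = list(keep)
        return DosageMatrix(
            self.sample_ids.copy(), self.marker_ids[keep].copy(),
            self.dosages[:, keep].copy(), self.counted_allele[keep].copy(),
            self.alt_allele[keep].copy(), self.is_imputed[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples x markers DataFrame of dosages."""
        return pd.DataFrame(self.dosages, index=list(self.sample_ids),
                            columns=list(self.marker_ids))


class CohortTable:
    """Validated per-individual phenotype/covariate table.

    Wraps a DataFrame with one row per sample. Required columns:
    sample_id, population, age, sex (0=female, 1=male). Lipids are in mg/dL
    (TG raw; the natural log is applied downstream). Binary and continuous
    clinical outcomes are optional.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing required columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in cohort table")
        bad_age = df["age"] <= 0
        if bad_age.any():
            raise ValidationError(
                f"age <= 0 for sample {df.loc[bad_age, 'sample_id'].iloc[0]!r}"
            )
        if not set(df["sex"].dropna().unique()) <= {0, 1}:
            raise ValidationError("sex must be coded 0 (female) / 1 (male)")
        for lipid in ("HDL", "LDL", "TC"):
            if lipid in df.columns and (df[lipid].dropna() < 0).any():
                raise ValidationError(f"negative {lipid} value in cohort table")
        if "TG" in df.columns:
            bad = df["TG"].notna() & (df["TG"] <= 0)
            if bad.any():
                raise ValidationError(
                    "TG <= 0 (log undefined) for sample "
                    f"{df.loc[bad, 'sample_id'].iloc[0]!r}"
                )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].astype(str).unique())

    def available_outcomes(self) -> dict[str, str]:
        """Map outcome column -> family ('logistic' for binary, else 'linear')."""
        out: dict[str, str] = {}
        for c in BINARY_OUTCOMES:
            if c in self.df.columns:
                out[c] = "logistic"
        for c in CONTINUOUS_OUTCOMES:
            if c in self.df.columns:
                out[c] = "linear"
        return out


# ---------------------------------------------------------------------------
# readers


def _resolve_columns(header: Sequence[str],
                     synonyms: Mapping[str, Sequence[str]]) -> dict[str, str]:
    lower = {h.lower().strip(): h for h in header}
    resolved = {}
    for canonical, names in synonyms.items():
        for n in names:
            if n in lower:
                resolved[canonical] = lower[n]
                break
        else:
            raise ValidationError(
                f"could not resolve a column for {canonical!r} in header {list(header)}"
            )
    return resolved


def read_weight_table(path: str | Path, dialect: str = "auto") -> WeightTable:
    """Read a marker-weight table from CSV/TSV.

    Columns are resolved by header synonyms (marker/rsid, trait, effect
    allele (A2), other allele (A1), weight/effect). Rows whose weight is
    missing are excluded from that trait's entries.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValidationError(f"empty weight table: {path}")
    cols = _resolve_columns(df.columns, _WEIGHT_COLUMN_SYNONYMS)
    entries = []
    n_skipped = 0
    for _, row in df.iterrows():
        w = row[cols["weight"]]
        if w is None or (isinstance(w, float) and np.isnan(w)) or str(w).strip() == "":
            n_skipped += 1
            continue
        entries.append(MarkerWeight(
            marker_id=str(row[cols["marker_id"]]).strip(),
            trait=str(row[cols["trait"]]).strip().upper(),
            effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
            other_allele=str(row[cols["other_allele"]]).strip().upper(),
            weight=float(w),
        ))
    table = WeightTable(entries, provenance=str(path))
    if n_skipped:
        log.info("weight table %s: %d rows without a weight excluded", path, n_skipped)
    log.info("weight table %s: per-trait marker counts %s", path, table.counts())
    return table


def _dosage_from_gt(gt_types_row: np.ndarray) -> np.ndarray:
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    d = np.where(gt_types_row == 0, 0.0,
                 np.where(gt_types_row == 1, 1.0,
                          np.where(gt_types_row == 3, 2.0, np.nan)))
    return d


def _read_vcf(path: Path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, counted, alt, imputed = [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        marker = rec.ID if rec.ID not in (None, ".") else \
            f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        ds = rec.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < -1) | (d > 3), np.nan, d)  # sentinel fill values
            has_ds = True
        else:
            d = _dosage_from_gt(np.asarray(rec.gt_types))
            has_ds = False
        rows.append(d)
        ids.append(marker)
        counted.append(rec.ALT[0])
        alt.append(rec.REF)  # the non-counted allele of the pair
        imputed.append(has_ds)
    if n_multi:
        log.warning("skipped %d multi-allelic VCF records in %s", n_multi, path)
    if not rows:
        raise ValidationError(f"no biallelic records parsed from {path}")
    dosages = np.vstack(rows).T  # samples x markers
    return DosageMatrix(np.asarray(samples, dtype=object),
                        np.asarray(ids, dtype=object), dosages,
                        np.asarray(counted, dtype=object),
                        np.asarray(alt, dtype=object),
                        np.asarray(imputed, dtype=bool))


_DOSAGE_META = ["marker_id", "counted_allele", "alt_allele", "is_imputed"]


def _read_dosage_tsv(path: Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise ValidationError(f"dosage TSV missing metadata columns {missing}")
    sample_cols = [c for c in df.columns if c not in _DOSAGE_META]
    if df.empty or not sample_cols:
        raise ValidationError(f"zero markers or zero samples in {path}")
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return DosageMatrix(
        np.asarray(sample_cols, dtype=object),
        df["marker_id"].to_numpy(dtype=object), dosages,
        df["counted_allele"].to_numpy(dtype=object),
        df["alt_allele"].to_numpy(dtype=object),
        df["is_imputed"].astype(bool).to_numpy(),
    )


def read_dosages(path: str | Path, format: str = "auto") -> DosageMatrix:
    """Read per-individual effect-allele dosages.

    ``format='vcf'`` parses a (plain or bgzipped) VCF: the DS FORMAT field is
    used when present (``is_imputed`` true), otherwise hard GT genotypes are
    converted to ALT-allele counts 0/1/2 with ``./.`` as missing. The counted
    allele is the ALT allele. Multi-allelic records are skipped with a
    warning. ``format='dosage_tsv'`` reads one marker per row with metadata
    columns (marker_id, counted_allele, alt_allele, is_imputed) followed by
    one column per sample.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown dosage format {format!r}")


def read_cohort(path: str | Path,
                sex_mapping: Mapping[str, int] | None = None) -> CohortTable:
    """Read and validate a phenotype/covariate table (TSV or CSV by suffix)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    mapping = dict(DEFAULT_SEX_MAPPING)
    if sex_mapping:
        mapping.update({str(k).lower(): v for k, v in sex_mapping.items()})
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = df["sex"].astype(str).str.lower().map(mapping)
        if df["sex"].isna().any():
            raise ValidationError("unmappable sex codes in cohort table")
    return CohortTable(df)


# ---------------------------------------------------------------------------
# writers


def write_dosages(d: DosageMatrix, path: str | Path) -> None:
    """Write a DosageMatrix in the dosage_tsv layout (round-trips exactly)."""
    df = pd.DataFrame({
        "marker_id": d.marker_ids,
        "counted_allele": d.counted_allele,
        "alt_allele": d.alt_allele,
        "is_imputed": d.is_imputed,
    })
    body = pd.DataFrame(d.dosages.T, columns=list(d.sample_ids))
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False,
                                         float_format="%.10g", na_rep="NA")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any results table as TSV with a header (deterministic format)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def align_samples(d: DosageMatrix, cohort: CohortTable
                  ) -> tuple[DosageMatrix, CohortTable]:
    """Restrict both artifacts to their sample_id intersection (dosage order)."""
    common = [s for s in d.sample_ids if s in set(cohort.sample_ids)]
    if not common:
        raise ValidationError("no overlapping samples between dosages and cohort")
    n_drop = (len(d.sample_ids) - len(common)) + (len(cohort) - len(common))
    if n_drop:
        log.info("dropped %d non-overlapping samples during alignment", n_drop)
    sub = cohort.df.set_index("sample_id").loc[common].reset_index()
    return d.subset_samples(common), CohortTable(sub)
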