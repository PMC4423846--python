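"""Allele-frequency differentiation and population-structure statistics.

Operates on harmonized dosage matrices: per-population effect-allele
frequencies, a one-way ANOVA F-test contrasting per-individual dosage across
populations at each marker, pairwise Pearson correlation between individuals'
dosage vectors, and PCA of the column-standardized genotype matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CohortTable, DosageMatrix
from .errors import ValidationError

log = logging.getLogger("grslens")


def _grouped(d: DosageMatrix, cohort: CohortTable) -> tuple[np.ndarray, list[str]]:
    """Population index per dosage-matrix row (rows must be in the cohort)."""
    pop = cohort.df.set_index("sample_id")["population"]
    missing = [s for s in d.sample_ids if s not in pop.index]
    if missing:
        raise ValidationError(f"samples without cohort rows: {missing[:5]}")
    labels = pop.loc[list(d.sample_ids)].astype(str).to_numpy()
    uniq = sorted(set(labels))
    codes = np.array([uniq.index(v) for v in labels])
    return codes, uniq


def allele_freq_by_population(d: DosageMatrix, cohort: CohortTable) -> pd.DataFrame:
    """Effect-allele frequency per (marker, population).

    freq = sum(non-missing dosages) / (2 * n_non-missing). A population with
    zero non-missing calls at a marker gets NaN and is flagged in the log.
    """
    codes, pops = _grouped(d, cohort)
    rows = []
    for k, pop in enumerate(pops):
        sub = d.dosages[codes == k, :]
        n_obs = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(sub, axis=0) / (2.0 * n_obs)
        freq = np.where(n_obs == 0, np.nan, freq)
        if (n_obs == 0).any():
            log.warning("population %s has markers with no observed calls", pop)
        for j in range(d.n_markers):
            rows.append((d.marker_ids[j], pop, freq[j], int(n_obs[j])))
    return pd.DataFrame(rows, columns=["marker_id", "population", "freq", "n"])


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


def _anova_1way(groups: list[np.ndarray]) -> AnovaResult:
    k = len(groups)
    if k < 2:
        raise ValidationError("ANOVA needs at least 2 populations")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each population needs >= 2 non-missing values")
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1, df2 = k - 1, int(ns.sum()) - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0)
        log.warning("zero within-group variance with between-group differences")
        return AnovaResult(np.inf, df1, df2, 0.0, degenerate=True)
    F = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(F, df1, df2, float(stats.f.sf(F, df1, df2)))


def dosage_anova_f(d: DosageMatrix, cohort: CohortTable, marker: str) -> AnovaResult:
    """One-way ANOVA of per-individual dosage grouped by population."""
    codes, pops = _grouped(d, cohort)
    col = d.dosages[:, d.marker_index(marker)]
    groups = []
    for k in range(len(pops)):
        g = col[codes == k]
        g = g[~np.isnan(g)]
        if len(g) >= 2:
            groups.append(g)
    return _anova_1way(groups)


def dosage_anova_all(d: DosageMatrix, cohort: CohortTable) -> pd.DataFrame:
    """Vectorized per-marker across-population dosage ANOVA (all markers)."""
    codes, pops = _grouped(d, cohort)
    K = len(pops)
    if K < 2:
        raise ValidationError("ANOVA needs at least 2 populations")
    X = d.dosages
    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)
    n_k = np.vstack([obs[codes == k].sum(axis=0) for k in range(K)])  # K x m
    s_k = np.vstack([Xz[codes == k].sum(axis=0) for k in range(K)])
    ss_k = np.vstack([(Xz[codes == k] ** 2).sum(axis=0) for k in range(K)])
    n = n_k.sum(axis=0).astype(float)
    grand = s_k.sum(axis=0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_k = s_k / n_k
        ss_between = np.nansum(n_k * (mean_k - grand) ** 2, axis=0)
        ss_total = ss_k.sum(axis=0) - n * grand ** 2
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    df1 = (n_k >= 2).sum(axis=0) - 1  # populations contributing
    df1 = np.maximum(df1, 1)
    df2 = n - K
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    degenerate = (ss_within == 0) & (ss_between > 0)
    F = np.where(ss_within == 0, np.where(degenerate, np.inf, 0.0), F)
    p = np.where(degenerate, 0.0,
                 np.where(np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0),
                                                     df1, df2), 0.0))
    p = np.where((ss_between == 0) & (ss_within == 0), 1.0, p)
    return pd.DataFrame({
        "marker_id": d.marker_ids, "F": F, "df1": df1, "df2": df2.astype(int),
        "p": p, "degenerate": degenerate,
    })


def pairwise_individual_correlation(d: DosageMatrix,
                                    subset: list[str] | None = None
                                    ) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between individuals' dosage vectors.

    Returns the n x n correlation matrix (diagonal 1) and the list of
    individuals with constant dosage vectors, whose rows/columns are NaN
    rather than silently zero.
    """
    if subset is not None:
        idx = [d.marker_index(m) for m in subset]
        if len(idx) < 2:
            raise ValidationError("need at least 2 markers for correlation")
        X = d.dosages[:, idx]
    else:
        if d.n_markers < 2:
            raise ValidationError("need at least 2 markers for correlation")
        X = d.dosages
    if np.isnan(X).any():
        raise ValidationError("fill missing dosages before correlation")
    sd = X.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    np.fill_diagonal(R, 1.0)
    flagged = [str(s) for s in d.sample_ids[constant]]
    if flagged:
        log.warning("individuals with constant dosage vectors: %s", flagged[:5])
    mat = pd.DataFrame(R, index=list(d.sample_ids), columns=list(d.sample_ids))
    return mat, flagged


@dataclass
class PcaResult:
    scores: pd.DataFrame                 # samples x components
    explained_variance_ratio: np.ndarray
    n_markers_used: int


def genotype_pca(d: DosageMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the column-standardized (zero-mean, unit-variance) dosage matrix.

    Zero-variance markers are excluded automatically. Component signs are
    fixed by forcing the largest-magnitude loading positive, so outputs are
    deterministic.
    """
    from sklearn.decomposition import PCA

    if np.isnan(d.dosages).any():
        raise ValidationError("fill missing dosages before PCA")
    sd = d.dosages.std(axis=0)
    usable = sd > 0
    if usable.sum() < 2:
        raise ValidationError("fewer than 2 markers with variance; PCA undefined")
    X = (d.dosages[:, usable] - d.dosages[:, usable].mean(axis=0)) / sd[usable]
    n_components = min(n_components, d.n_samples - 1, int(usable.sum()))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for c in range(n_components):  # deterministic sign
        j = int(np.argmax(np.abs(pca.components_[c])))
        if pca.components_[c, j] < 0:
            pca.components_[c] *= -1
            scores[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        pd.DataFrame(scores, index=list(d.sample_ids), columns=cols),
        pca.explained_variance_ratio_.copy(), int(usable.sum()),
    )


def weir_cockerham_fst(d: DosageMatrix, cohort: CohortTable) -> float:
    """Moment-style multi-marker Fst estimate across populations.

    Ratio-of-averages estimator from per-population allele frequencies,
    suitable for checking that simulated cohorts carry the configured
    differentiation.
    """
    codes, pops = _grouped(d, cohort)
    K = len(pops)
    num = den = 0.0
    for j in range(d.n_markers):
        col = d.dosages[:, j]
        p_k, n_k = [], []
        for k in range(K):
            g = col[codes == k]
            g = g[~np.isnan(g)]
            if len(g):
                p_k.append(g.sum() / (2 * len(g)))
                n_k.append(len(g))
        if len(p_k) < 2:
            continue
        p_k = np.asarray(p_k)
        n_k = np.asarray(n_k, dtype=float)
        pbar = float(p_k.mean())
        if pbar <= 0.0 or pbar >= 1.0:
            continue
        s2 = float(p_k.var(ddof=1))
        # subtract the expected within-population binomial sampling variance
        sampling = pbar * (1 - pbar) * float(np.mean(1.0 / (2 * n_k)))
        num += s2 - sampling
        den += pbar * (1 - pbar)
    if den == 0:
        raise ValidationError("no polymorphic markers for Fst estimation")
    return max(0.0, num / den)
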