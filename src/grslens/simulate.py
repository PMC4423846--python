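"""Synthetic multi-population cohorts with known truth.

Emulates the statistical structure the evaluation pipeline assumes:

* allele-frequency divergence between population groups follows the
  Balding-Nichols model — per-population frequencies are Beta draws around
  an ancestral frequency with variance Fst * p * (1 - p);
* genotypes are Binomial(2, p) effect-allele counts; markers flagged as
  imputed carry truncated fractional noise to mimic dosage uncertainty;
* lipid phenotypes follow the additive model y = b0 + b_age*age +
  b_age2*age^2 + b_sex*sex + slope_k * GRS + eps, with the noise variance
  solved analytically per population so the expected variance explained by
  the score over the covariate-only model (ΔR²) hits a configured target;
* triglycerides are generated on the natural-log scale and exponentiated;
  binary clinical outcomes come from a logistic model on the four scores.

Every draw flows from one integer seed, so fixtures and tests are exactly
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CohortTable, DosageMatrix, MarkerWeight, WeightTable, write_dosages,
)
from .errors import ValidationError
from .grs import compute_grs

log = logging.getLogger("grslens")

TRAITS = ("HDL", "LDL", "TC", "TG")

#: default per-population group: (label, analysis n, Fst to the ancestral pool)
DEFAULT_POPULATIONS = (
    ("AfricanAmerican", 1355, 0.14),
    ("AsianAmerican", 666, 0.11),
    ("Caucasian", 2063, 0.06),
    ("Hispanic", 1256, 0.08),
)

DEFAULT_N_MARKERS = {"HDL": 46, "LDL": 37, "TC": 52, "TG": 32}
#: distinct markers in the shared pool; trait sets are drawn from it and overlap
DEFAULT_POOL_SIZE = 101

DEFAULT_WEIGHT_SD = {"HDL": 0.075, "LDL": 0.082, "TC": 0.070, "TG": 0.078}
DEFAULT_GRS_SLOPE = {"HDL": 20.0, "LDL": 20.0, "TC": 20.0, "TG": 1.2}
DEFAULT_SLOPE_MULTIPLIER = {
    "AfricanAmerican": 0.45, "AsianAmerican": 0.90,
    "Caucasian": 1.0, "Hispanic": 1.0,
}
#: expected ΔR² of the trait's own score over covariates, per population
DEFAULT_TARGET_DELTA_R2 = {
    "AfricanAmerican": 0.010, "AsianAmerican": 0.035,
    "Caucasian": 0.050, "Hispanic": 0.040,
}
#: (intercept, b_age, b_age2, b_sex) in trait units (log units for TG)
DEFAULT_COVARIATE_EFFECTS = {
    "HDL": (70.0, 0.15, -0.0010, -10.0),
    "LDL": (120.0, 0.60, -0.0060, 2.0),
    "TC": (190.0, 0.90, -0.0080, -5.0),
    "TG": (4.20, 0.0080, -0.00006, 0.12),
}
DEFAULT_BASE_RESIDUAL_SD = {"HDL": 14.0, "LDL": 30.0, "TC": 33.0, "TG": 0.45}
DEFAULT_BINARY_OUTCOMES = {
    "hypertension": {"intercept": -0.2},
    "metabolic_syndrome": {"intercept": -0.9, "HDL": -1.0, "TG": 1.0},
    "T2D": {"intercept": -2.2, "TG": -0.87},
}
DEFAULT_CONTINUOUS_OUTCOMES = {
    "BMI": {"intercept": 26.0, "b_age": 0.02, "b_sex": 0.5,
            "LDL": 0.8, "TC": -0.8, "resid_sd": 4.5},
    "NCEP_10yr_risk": {"intercept": 2.0, "b_age": 0.15, "b_sex": 3.0,
                       "HDL": -3.0, "resid_sd": 6.0},
    "Framingham_risk": {"intercept": 4.0, "b_age": 0.20, "b_sex": 4.0,
                        "HDL": -3.0, "TC": 1.5, "resid_sd": 7.0},
}


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 20150507
    populations: tuple = DEFAULT_POPULATIONS
    n_markers: dict = field(default_factory=lambda: dict(DEFAULT_N_MARKERS))
    pool_size: int = DEFAULT_POOL_SIZE
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    weight_sd: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHT_SD))
    grs_slope: dict = field(default_factory=lambda: dict(DEFAULT_GRS_SLOPE))
    slope_multiplier: dict = field(
        default_factory=lambda: dict(DEFAULT_SLOPE_MULTIPLIER))
    target_delta_r2: dict = field(
        default_factory=lambda: dict(DEFAULT_TARGET_DELTA_R2))
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    base_residual_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_BASE_RESIDUAL_SD))
    binary_outcome_models: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_BINARY_OUTCOMES.items()})
    continuous_outcome_models: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_CONTINUOUS_OUTCOMES.items()})
    age_range: tuple[float, float] = (45.0, 84.0)
    male_fraction: float = 0.47
    imputed_fraction: float = 0.84
    imputed_noise_sd: float = 0.1
    missing_rate: float = 0.01
    lipid_med_rate: float = 0.0

    def __post_init__(self) -> None:
        for label, n, fst in self.populations:
            if n < 2:
                raise ValidationError(f"population {label}: n must be >= 2")
            if not (0.0 <= fst < 1.0):
                raise ValidationError(f"population {label}: Fst {fst} outside [0,1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("ancestral_freq_range must lie inside (0,1)")
        for v in self.target_delta_r2.values():
            t = v if isinstance(v, dict) else {"_": v}
            for x in t.values():
                if not (0.0 <= x <= 0.5):
                    raise ValidationError(f"target ΔR² {x} outside [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate outside [0,1)")

    def target_for(self, trait: str, pop: str) -> float:
        v = self.target_delta_r2.get(pop, self.target_delta_r2)
        if isinstance(v, dict):  # nested pop -> trait
            return float(v.get(trait, 0.0))
        return float(v)

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.populations]


@dataclass
class SimulatedCohort:
    """Complete fixture: inputs for every pipeline stage plus the truth."""

    weights: WeightTable
    dosages: DosageMatrix          # with missingness mask applied
    complete_dosages: DosageMatrix  # pre-masking, used to build phenotypes
    cohort: CohortTable
    population_frequencies: pd.DataFrame
    truth: dict


def simulate_population_frequencies(p_ancestral: float, fst: float,
                                    rng: np.random.Generator,
                                    size: int | None = None):
    """Balding-Nichols draw: Beta with mean p and variance Fst*p*(1-p)."""
    if not (0.0 < p_ancestral < 1.0):
        raise ValidationError("ancestral frequency must lie in (0,1)")
    if fst == 0.0:
        return p_ancestral if size is None else np.full(size, p_ancestral)
    a = p_ancestral * (1.0 - fst) / fst
    b = (1.0 - p_ancestral) * (1.0 - fst) / fst
    return rng.beta(a, b, size=size)


def generate_weight_table(cfg: SynthConfig, rng: np.random.Generator
                          ) -> tuple[WeightTable, np.ndarray]:
    """Marker pool with per-trait weight draws; returns ancestral frequencies.

    Trait marker sets are sampled from one shared pool so a marker can carry
    weights for several traits, as lead SNPs of pleiotropic lipid genes do.
    """
    alleles = np.array(list("ACGT"))
    pool = [f"rs{1000 + i}" for i in range(cfg.pool_size)]
    pair_idx = np.array([rng.choice(4, size=2, replace=False)
                         for _ in range(cfg.pool_size)])
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.pool_size)
    entries = []
    for trait in TRAITS:
        n_t = cfg.n_markers[trait]
        if n_t > cfg.pool_size:
            raise ValidationError(f"{trait}: n_markers exceeds marker pool")
        chosen = rng.choice(cfg.pool_size, size=n_t, replace=False)
        w = rng.normal(0.0, cfg.weight_sd[trait], size=n_t)
        for j, wj in zip(chosen, w):
            entries.append(MarkerWeight(pool[j], trait, alleles[pair_idx[j, 0]],
                                        alleles[pair_idx[j, 1]], float(wj)))
    table = WeightTable(entries, provenance="synthetic")
    used = {m: i for i, m in enumerate(pool)}
    p_used = np.array([p_anc[used[m]] for m in table.marker_ids])
    return table, p_used


def simulate_dosages(cfg: SynthConfig, weights: WeightTable | None = None,
                     p_ancestral: np.ndarray | None = None,
                     rng: np.random.Generator | None = None
                     ) -> tuple[DosageMatrix, pd.DataFrame]:
    """Complete (no-missing) dosage matrix plus the true per-population freqs.

    Columns count the weight table's effect allele. Imputed-flagged markers
    get truncated Gaussian jitter (sd ``imputed_noise_sd``) to emulate
    fractional dosages.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if weights is None:
        weights, p_anc = generate_weight_table(cfg, rng)
    else:
        p_anc = p_ancestral
        if p_anc is None:
            lo, hi = cfg.ancestral_freq_range
            p_anc = rng.uniform(lo, hi, size=len(weights.marker_ids))
    markers = weights.marker_ids
    m = len(markers)
    is_imputed = rng.random(m) < cfg.imputed_fraction
    freq_rows = []
    blocks, sample_ids, pop_labels = [], [], []
    for label, n, fst in cfg.populations:
        p_k = np.array([simulate_population_frequencies(p, fst, rng)
                        for p in p_anc])
        geno = rng.binomial(2, p_k, size=(n, m)).astype(float)
        jitter = rng.normal(0.0, cfg.imputed_noise_sd, size=(n, m))
        geno[:, is_imputed] = np.clip(geno[:, is_imputed] + jitter[:, is_imputed],
                                      0.0, 2.0)
        blocks.append(geno)
        sample_ids.extend(f"{label}_{i:05d}" for i in range(n))
        pop_labels.extend([label] * n)
        freq_rows.extend(zip(markers, [label] * m, p_k))
    effect = np.array([weights.allele_pair(mk)[0] for mk in markers], dtype=object)
    other = np.array([weights.allele_pair(mk)[1] for mk in markers], dtype=object)
    d = DosageMatrix(np.asarray(sample_ids, dtype=object),
                     np.asarray(markers, dtype=object), np.vstack(blocks),
                     effect, other, is_imputed)
    freqs = pd.DataFrame(freq_rows, columns=["marker_id", "population", "freq"])
    d._populations = np.asarray(pop_labels, dtype=object)  # carried for phenotypes
    return d, freqs


def _mask_missing(d: DosageMatrix, rate: float,
                  rng: np.random.Generator) -> DosageMatrix:
    if rate <= 0.0:
        return d
    masked = d.dosages.copy()
    masked[rng.random(masked.shape) < rate] = np.nan
    out = DosageMatrix(d.sample_ids.copy(), d.marker_ids.copy(), masked,
                       d.counted_allele.copy(), d.alt_allele.copy(),
                       d.is_imputed.copy())
    return out


def simulate_phenotypes(cfg: SynthConfig, d: DosageMatrix, w: WeightTable,
                        populations: np.ndarray | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[CohortTable, dict]:
    """Phenotypes from the additive model with ΔR²-calibrated noise.

    For each (trait, population): the residual variance is solved from

        target = var(slope*GRS) / (var(covariates) + var(slope*GRS) + var_eps)

    using the empirical within-population variances, so the expected ΔR² of
    the score over the covariate-only model equals the configured target. A
    target that cannot be reached (score variance too small relative to the
    covariates) raises an error. Returns the cohort and a truth dictionary.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    if populations is None:
        populations = getattr(d, "_populations", None)
    if populations is None:
        raise ValidationError("population labels required to simulate phenotypes")
    populations = np.asarray(populations, dtype=object)
    n = d.n_samples
    grs = compute_grs(d, w).scores
    age = rng.uniform(*cfg.age_range, size=n)
    sex = (rng.random(n) < cfg.male_fraction).astype(int)
    out = pd.DataFrame({
        "sample_id": list(d.sample_ids), "population": populations,
        "age": np.round(age, 1), "sex": sex,
        "lipid_med": (rng.random(n) < cfg.lipid_med_rate).astype(int),
    })
    truth: dict = {"residual_sd": {}, "slope": {}, "target_delta_r2": {}}
    for trait in TRAITS:
        col = f"{trait}_GRS"
        if col not in grs.columns:
            continue
        b0, b_age, b_age2, b_sex = cfg.covariate_effects[trait]
        age_v = out["age"].to_numpy()
        cov_part = b_age * age_v + b_age2 * age_v ** 2 + b_sex * sex
        y = np.full(n, np.nan)
        g = grs[col].to_numpy()
        for label in cfg.labels:
            k = populations == label
            slope = cfg.grs_slope[trait] * cfg.slope_multiplier.get(label, 1.0)
            target = cfg.target_for(trait, label)
            gk = slope * g[k]
            var_g = float(np.var(gk))
            var_c = float(np.var(cov_part[k]))
            if target > 0.0 and var_g > 0.0:
                var_eps = var_g / target - var_g - var_c
                if var_eps <= 0.0:
                    raise ValidationError(
                        f"target ΔR²={target} unattainable for {trait}/{label}: "
                        "score variance too small relative to covariates"
                    )
            else:
                var_eps = cfg.base_residual_sd[trait] ** 2
            eps = rng.normal(0.0, np.sqrt(var_eps), size=int(k.sum()))
            y[k] = b0 + cov_part[k] + gk + eps
            truth["residual_sd"][f"{trait}/{label}"] = float(np.sqrt(var_eps))
            truth["slope"][f"{trait}/{label}"] = slope
            truth["target_delta_r2"][f"{trait}/{label}"] = target
        # lipids live on a positive scale; the far Gaussian tail is floored
        out[trait] = np.exp(y) if trait == "TG" else np.maximum(y, 1.0)
    for name, model in cfg.binary_outcome_models.items():
        eta = np.full(n, float(model.get("intercept", 0.0)))
        for trait in TRAITS:
            beta = float(model.get(trait, 0.0))
            if beta and f"{trait}_GRS" in grs.columns:
                eta += beta * grs[f"{trait}_GRS"].to_numpy()
        out[name] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    for name, model in cfg.continuous_outcome_models.items():
        y = (float(model.get("intercept", 0.0))
             + float(model.get("b_age", 0.0)) * out["age"].to_numpy()
             + float(model.get("b_sex", 0.0)) * sex)
        for trait in TRAITS:
            beta = float(model.get(trait, 0.0))
            if beta and f"{trait}_GRS" in grs.columns:
                y = y + beta * grs[f"{trait}_GRS"].to_numpy()
        out[name] = y + rng.normal(0.0, float(model.get("resid_sd", 1.0)), size=n)
    return CohortTable(out), truth


def simulate_cohort(cfg: SynthConfig | None = None) -> SimulatedCohort:
    """One-call generator: weights, dosages (masked + complete), phenotypes."""
    cfg = SynthConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed)
    weights, p_anc = generate_weight_table(cfg, rng)
    complete, freqs = simulate_dosages(cfg, weights, p_anc, rng)
    populations = complete._populations
    cohort, truth = simulate_phenotypes(cfg, complete, weights, populations, rng)
    masked = _mask_missing(complete, cfg.missing_rate, rng)
    masked._populations = populations
    truth["seed"] = cfg.seed
    truth["populations"] = {p[0]: {"n": p[1], "fst": p[2]}
                            for p in cfg.populations}
    return SimulatedCohort(weights, masked, complete, cohort, freqs, truth)


def calibrate_frequencies(weights: WeightTable, trait: str,
                          targets: dict[str, tuple[float, float]],
                          cfg: SynthConfig | None = None,
                          seed: int | None = None) -> dict[str, np.ndarray]:
    """Per-population frequencies matching target score means and SDs.

    Starts from a Balding-Nichols draw and solves, per population, the
    nearest frequency vector (least-squares, bounded away from 0/1) such
    that the implied score mean  sum_m 2 p_m w_m  and variance
    sum_m 2 p_m (1-p_m) w_m^2  hit the requested (mean, sd). Used to emulate
    printed cohort-level score summaries.
    """
    from scipy.optimize import minimize

    cfg = SynthConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    wmap = weights.for_trait(trait)
    if not wmap:
        raise ValidationError(f"no weights for trait {trait}")
    w = np.array(list(wmap.values()))
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=len(w))
    fst = {label: f for label, _, f in cfg.populations}
    out = {}
    def moments(p):
        return (2.0 * p @ w, 2.0 * (p * (1 - p)) @ (w ** 2))

    for pop, (mu, sd) in targets.items():
        solved = None
        for _attempt in range(10):  # restart from a fresh draw if stuck
            p0 = np.array([
                simulate_population_frequencies(p, fst.get(pop, 0.1), rng)
                for p in p_anc])
            p0 = np.clip(p0, 0.02, 0.98)
            res = minimize(
                lambda p: float(((p - p0) ** 2).sum()), p0, method="SLSQP",
                bounds=[(0.02, 0.98)] * len(w),
                constraints=[
                    {"type": "eq",
                     "fun": lambda p, mu=mu: moments(p)[0] - mu},
                    {"type": "eq",
                     "fun": lambda p, sd=sd: 10.0 * (moments(p)[1] - sd ** 2)},
                ],
                options={"maxiter": 1000, "ftol": 1e-12},
            )
            m1, m2 = moments(res.x)
            if abs(m1 - mu) < 1e-6 and abs(m2 - sd ** 2) < 1e-6:
                solved = res.x
                break
        if solved is None:
            raise ValidationError(f"frequency calibration failed for {pop}")
        out[pop] = solved
    return out


def write_fixture(cfg: SynthConfig, out_dir: str | Path,
                  force: bool = False) -> dict[str, Path]:
    """Write a complete self-describing fixture (weights/dosages/cohort/truth)."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ValidationError(f"output directory {out_dir} is not empty "
                              "(pass force=True to overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(cfg)
    paths = {
        "weights": out_dir / "weights.csv",
        "dosages": out_dir / "dosages.tsv",
        "cohort": out_dir / "cohort.tsv",
        "truth": out_dir / "truth.json",
    }
    sim.weights.to_frame().to_csv(paths["weights"], index=False,
                                  float_format="%.10g")
    write_dosages(sim.dosages, paths["dosages"])
    sim.cohort.df.to_csv(paths["cohort"], sep="\t", index=False,
                         float_format="%.10g")
    paths["truth"].write_text(json.dumps(sim.truth, indent=1, sort_keys=True))
    log.info("fixture written to %s", out_dir)
    return paths
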