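import numpy as np
import pandas as pd
import pytest

from grslens.data_io import CohortTable, DosageMatrix, MarkerWeight, WeightTable
from grslens.simulate import SynthConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_weights() -> WeightTable:
    return WeightTable([
        MarkerWeight("rs1", "HDL", "A", "G", 0.5),
        MarkerWeight("rs2", "HDL", "C", "T", -0.25),
        MarkerWeight("rs3", "TG", "G", "T", 0.1),
    ])


@pytest.fixture
def tiny_dosages() -> DosageMatrix:
    return DosageMatrix(
        sample_ids=np.array(["s1", "s2", "s3"], dtype=object),
        marker_ids=np.array(["rs1", "rs2", "rs3"], dtype=object),
        dosages=np.array([[0.0, 1.0, 2.0],
                          [2.0, 2.0, 1.3],
                          [1.0, 0.0, 0.0]]),
        counted_allele=np.array(["A", "C", "G"], dtype=object),
        alt_allele=np.array(["G", "T", "T"], dtype=object),
        is_imputed=np.array([False, False, True]),
    )


@pytest.fixture
def tiny_cohort() -> CohortTable:
    return CohortTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "population": ["PopA", "PopA", "PopB"],
        "age": [50.0, 60.0, 70.0],
        "sex": [0, 1, 0],
        "lipid_med": [0, 0, 1],
        "HDL": [55.0, 48.0, 62.0],
        "TG": [110.0, 95.0, 140.0],
    }))


@pytest.fixture(scope="session")
def small_sim():
    """Two-population synthetic cohort reused across read-only tests."""
    cfg = SynthConfig(
        seed=7,
        populations=(("AfricanAmerican", 400, 0.14), ("Caucasian", 500, 0.06)),
        missing_rate=0.01,
    )
    return simulate_cohort(cfg)


def make_assoc_frame(n: int, delta: float, seed: int,
                     slope: float = 1.0) -> pd.DataFrame:
    """Single-population regression dataset with known ΔR² of the score.

    Noise variance is solved so that var(slope*g) / var(y) = delta.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(45, 84, n)
    sex = rng.integers(0, 2, n)
    g = rng.normal(0.6, 0.25, n)
    cov = 0.15 * age - 0.001 * age ** 2 - 10.0 * sex
    signal = slope * g
    var_g, var_c = signal.var(), cov.var()
    if delta > 0:
        var_eps = var_g / delta - var_g - var_c
        assert var_eps > 0, "requested delta unattainable"
    else:
        var_eps = 1.0 if slope == 0 else var_g * 4
    y = 60.0 + cov + signal + rng.normal(0, np.sqrt(var_eps), n)
    return pd.DataFrame({"age": age, "sex": sex, "HDL": y, "HDL_GRS": g})
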