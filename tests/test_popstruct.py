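import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grslens.data_io import CohortTable
from grslens.errors import ValidationError
from grslens.popstruct import (
    allele_freq_by_population, dosage_anova_all, dosage_anova_f, genotype_pca,
    pairwise_individual_correlation, weir_cockerham_fst,
)
from .oracles import anova_oneway, pearson_r
from .test_qc import make_matrix


def cohort_for(d, pops):
    return CohortTable(pd.DataFrame({
        "sample_id": list(d.sample_ids), "population": pops,
        "age": [50.0] * d.n_samples, "sex": [0] * d.n_samples}))


class TestAlleleFreq:
    @pytest.mark.parametrize("dosages,expected", [
        ([[0.0], [1.0], [2.0]], 0.5),
        ([[2.0], [2.0]], 1.0),
        ([[0.5], [1.5]], 0.5),
    ])
    def test_single_population(self, dosages, expected):
        d = make_matrix(dosages, ["A"], ["G"])
        c = cohort_for(d, ["P"] * d.n_samples)
        out = allele_freq_by_population(d, c)
        assert out["freq"].iloc[0] == pytest.approx(expected)

    def test_pooled_equals_overall(self, rng):
        d = make_matrix(rng.binomial(2, 0.3, size=(60, 4)).astype(float),
                        ["A"] * 4, ["G"] * 4)
        pops = ["P"] * 20 + ["Q"] * 25 + ["R"] * 15
        out = allele_freq_by_population(d, cohort_for(d, pops))
        for j, mk in enumerate(d.marker_ids):
            sub = out[out.marker_id == mk]
            pooled = (sub["freq"] * sub["n"]).sum() / sub["n"].sum()
            assert pooled == pytest.approx(d.dosages[:, j].mean() / 2, abs=1e-12)

    def test_empty_population_flagged_nan(self):
        d = make_matrix([[np.nan], [1.0]], ["A"], ["G"])
        out = allele_freq_by_population(d, cohort_for(d, ["P", "Q"]))
        assert np.isnan(out.set_index("population").loc["P", "freq"])


class TestDosageAnova:
    def test_identical_groups_f_zero(self):
        vals = [[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]]
        d = make_matrix(vals, ["A"], ["G"])
        r = dosage_anova_f(d, cohort_for(d, ["P"] * 3 + ["Q"] * 3), "rs0")
        assert r.F == 0.0 and r.p == 1.0

    def test_degenerate_within_variance(self):
        vals = [[0.0]] * 4 + [[2.0]] * 4
        d = make_matrix(vals, ["A"], ["G"])
        r = dosage_anova_f(d, cohort_for(d, ["P"] * 4 + ["Q"] * 4), "rs0")
        assert r.degenerate and r.p == 0.0

    def test_hand_computed_example(self):
        vals = [[v] for v in (0, 1, 1, 2, 1, 2, 2, 2)]
        d = make_matrix(vals, ["A"], ["G"])
        r = dosage_anova_f(d, cohort_for(d, ["P"] * 4 + ["Q"] * 4), "rs0")
        F, df1, df2 = anova_oneway([np.array([0, 1, 1, 2.0]),
                                    np.array([1, 2, 2, 2.0])])
        assert (r.F, r.df1, r.df2) == (pytest.approx(F), df1, df2)
        assert r.p == pytest.approx(stats.f.sf(F, df1, df2))

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.binomial(2, rng.uniform(0.2, 0.8),
                                   size=rng.integers(5, 15)).astype(float)
                      for _ in range(k)]
            if any(g.var() == 0 for g in groups):
                continue
            d = make_matrix(np.concatenate(groups)[:, None], ["A"], ["G"])
            pops = sum(([f"P{i}"] * len(g) for i, g in enumerate(groups)), [])
            r = dosage_anova_f(d, cohort_for(d, pops), "rs0")
            F, p = stats.f_oneway(*groups)
            assert r.F == pytest.approx(F, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)

    def test_single_group_errors(self):
        d = make_matrix([[0.0], [1.0]], ["A"], ["G"])
        with pytest.raises(ValidationError):
            dosage_anova_f(d, cohort_for(d, ["P", "P"]), "rs0")

    def test_vectorized_agrees_with_scalar(self, small_sim):
        d = small_sim.complete_dosages
        c = small_sim.cohort
        table = dosage_anova_all(d, c).set_index("marker_id")
        for mk in list(d.marker_ids)[:10]:
            r = dosage_anova_f(d, c, mk)
            assert table.loc[mk, "F"] == pytest.approx(r.F, rel=1e-9)
            assert table.loc[mk, "p"] == pytest.approx(r.p, rel=1e-6, abs=1e-12)

    def test_null_pvalues_uniform(self, rng):
        # one shared frequency per marker: across-population F should be null
        n_markers, n_per = 2000, 80
        p = rng.uniform(0.2, 0.8, n_markers)
        blocks = [rng.binomial(2, p, size=(n_per, n_markers)).astype(float)
                  for _ in range(3)]
        d = make_matrix(np.vstack(blocks), ["A"] * n_markers, ["G"] * n_markers)
        pops = ["P"] * n_per + ["Q"] * n_per + ["R"] * n_per
        out = dosage_anova_all(d, cohort_for(d, pops))
        ks = stats.kstest(out["p"], "uniform").statistic
        assert ks < 0.05


class TestCorrelation:
    def test_self_correlation_one(self):
        d = make_matrix([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]],
                        ["A"] * 3, ["G"] * 3)
        mat, _ = pairwise_individual_correlation(d)
        assert mat.iloc[0, 0] == 1.0

    def test_perfect_anticorrelation(self):
        d = make_matrix([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]],
                        ["A"] * 3, ["G"] * 3)
        mat, _ = pairwise_individual_correlation(d)
        assert mat.iloc[0, 1] == pytest.approx(-1.0)

    def test_textbook_formula(self):
        a, b = np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 2.0])
        d = make_matrix(np.vstack([a, b]), ["A"] * 3, ["G"] * 3)
        mat, _ = pairwise_individual_correlation(d)
        assert mat.iloc[0, 1] == pytest.approx(pearson_r(a, b), abs=1e-12)

    def test_constant_vector_flagged(self):
        d = make_matrix([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                        ["A"] * 3, ["G"] * 3)
        mat, flagged = pairwise_individual_correlation(d)
        assert flagged == ["s0"]
        assert np.isnan(mat.iloc[0, 1])


class TestPca:
    def _two_clusters(self, rng, n=60, m=100, fst=0.15):
        p = rng.uniform(0.2, 0.8, m)
        freqs = [np.clip(rng.normal(p, np.sqrt(fst * p * (1 - p))), 0.02, 0.98)
                 for _ in range(2)]
        blocks = [rng.binomial(2, f, size=(n, m)).astype(float) for f in freqs]
        d = make_matrix(np.vstack(blocks), ["A"] * m, ["G"] * m)
        labels = np.array([0] * n + [1] * n)
        return d, labels

    def test_pc1_separates_clusters(self, rng):
        d, labels = self._two_clusters(rng)
        res = genotype_pca(d, 2)
        r = np.corrcoef(res.scores["PC1"], labels)[0, 1]
        assert abs(r) > 0.9

    def test_variance_fractions_monotone_and_bounded(self, rng):
        d, _ = self._two_clusters(rng)
        res = genotype_pca(d, 5)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-12

    def test_degenerate_all_identical(self):
        d = make_matrix(np.ones((5, 4)), ["A"] * 4, ["G"] * 4)
        with pytest.raises(ValidationError):
            genotype_pca(d, 2)

    def test_sign_deterministic(self, rng):
        d, _ = self._two_clusters(rng, n=30, m=40)
        a = genotype_pca(d, 2).scores
        b = genotype_pca(d, 2).scores
        pd.testing.assert_frame_equal(a, b)


def test_fst_moment_recovery(rng):
    target = 0.10
    n_markers, n_per, k = 500, 200, 3
    p = rng.uniform(0.1, 0.9, n_markers)
    a = p * (1 - target) / target
    b = (1 - p) * (1 - target) / target
    blocks = []
    for _ in range(k):
        f = rng.beta(a, b)
        blocks.append(rng.binomial(2, f, size=(n_per, n_markers)).astype(float))
    d = make_matrix(np.vstack(blocks), ["A"] * n_markers, ["G"] * n_markers)
    pops = sum(([f"P{i}"] * n_per for i in range(k)), [])
    est = weir_cockerham_fst(d, cohort_for(d, pops))
    assert est == pytest.approx(target, rel=0.2)
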