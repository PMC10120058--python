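import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tsrsweep import (
    ContingencyTable2x2,
    chi2_uncorrected,
    chi2_yates,
    ne_from_theta,
    nucleotide_diversity,
    watterson_theta,
)
from tsrsweep.popstats import harmonic_number, segregating_sites


class TestWatterson:
    def test_zero_segregating(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_two_sequences_harmonic_one(self):
        assert watterson_theta(5, 2, 1) == 5.0

    def test_scaling_in_length(self):
        assert watterson_theta(10, 5, 100) == pytest.approx(watterson_theta(10, 5, 1) / 100)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 1, 10)

    def test_harmonic(self):
        assert harmonic_number(3) == pytest.approx(1 + 0.5 + 1 / 3)


class TestNeFromTheta:
    def test_zero(self):
        assert ne_from_theta(0.0, 3e-8) == 0.0

    def test_identity_scaling(self):
        mu = 3e-8
        assert ne_from_theta(4 * mu, mu) == pytest.approx(1.0)

    def test_field_estimate(self):
        # theta_W = 0.0047 with the maize-derived mu gives ~39,167 diploids
        assert ne_from_theta(0.0047, 3.0e-8) == pytest.approx(39_166.67, rel=1e-4)

    def test_linear_in_theta(self):
        assert ne_from_theta(0.02, 1e-8) == pytest.approx(2 * ne_from_theta(0.01, 1e-8))

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            ne_from_theta(0.01, 0.0)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        mat = np.zeros((4, 50), dtype=int)
        assert nucleotide_diversity(mat) == 0.0

    def test_single_pair_single_difference(self):
        mat = np.zeros((2, 100), dtype=int)
        mat[1, 0] = 1
        assert nucleotide_diversity(mat) == pytest.approx(0.01)

    def test_matches_pairwise_brute_force(self, rng):
        mat = rng.integers(0, 4, size=(6, 30))
        n = mat.shape[0]
        acc = 0
        for i in range(n):
            for j in range(i + 1, n):
                acc += np.sum(mat[i] != mat[j])
        expected = acc / (n * (n - 1) / 2) / mat.shape[1]
        assert nucleotide_diversity(mat) == pytest.approx(expected)
        assert segregating_sites(mat) == int(np.sum(np.any(mat != mat[0], axis=0)))


class TestChi2Yates:
    def test_shared_haplotype_comparison(self):
        # 20/62 shared resistant vs 55/188 shared wild-type clusters
        stat, p = chi2_yates(ContingencyTable2x2(20, 42, 55, 133))
        assert stat == pytest.approx(0.0827, abs=5e-4)
        assert p == pytest.approx(0.7736, abs=5e-4)

    def test_proportional_table_is_null(self):
        stat, p = chi2_yates(ContingencyTable2x2(10, 10, 20, 20))
        assert stat == 0.0
        assert p == 1.0

    def test_matches_scipy_continuity_corrected(self):
        for cells in [(20, 42, 55, 133), (5, 15, 30, 10), (100, 3, 42, 9), (1, 2, 3, 4)]:
            t = ContingencyTable2x2(*cells)
            stat, p = chi2_yates(t)
            ref = sps.chi2_contingency(t.as_array(), correction=True)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_uncorrected_differs_and_matches_scipy(self):
        t = ContingencyTable2x2(20, 42, 55, 133)
        stat_u, p_u = chi2_uncorrected(t)
        ref = sps.chi2_contingency(t.as_array(), correction=False)
        assert stat_u == pytest.approx(ref.statistic, abs=1e-10)
        assert p_u != pytest.approx(0.7736, abs=5e-4)  # correction is what reproduces it

    def test_against_resampling_null(self, rng):
        # condition on the margins: the null distribution of cell `a` is
        # hypergeometric; the corrected p should sit within the Monte Carlo
        # interval of the two-sided resampling p-value
        t = ContingencyTable2x2(20, 42, 55, 133)
        stat_obs, p_obs = chi2_yates(t)
        r1, _r2, c1, _c2 = t.marginals
        n = t.total
        draws = rng.hypergeometric(c1, n - c1, r1, size=200_000)
        stats_null = np.array([
            chi2_yates(ContingencyTable2x2(int(a), r1 - int(a), c1 - int(a),
                                           n - r1 - c1 + int(a)))[0]
            for a in np.unique(draws)
        ])
        weights = np.array([(draws == a).mean() for a in np.unique(draws)])
        p_mc = weights[stats_null >= stat_obs - 1e-12].sum()
        se = np.sqrt(p_mc * (1 - p_mc) / draws.size)
        # chi-squared asymptotics vs exact conditional null: generous band
        assert abs(p_obs - p_mc) < 0.05 + 3 * se

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_row_and_column_swaps(self, a, b, c, d):
        base = chi2_yates(ContingencyTable2x2(a, b, c, d))
        assert chi2_yates(ContingencyTable2x2(c, d, a, b)) == pytest.approx(base)
        assert chi2_yates(ContingencyTable2x2(b, a, d, c)) == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_yates(ContingencyTable2x2(0, 0, 5, 5))
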