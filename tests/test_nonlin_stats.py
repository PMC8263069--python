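import numpy as np
import pytest

from burstdyn.nonlin_stats import (adaptive_fdr, barnard_test, bddls,
                                   bddls_rank_test, binomial_tail_test,
                                   cluster_permutation_test, contrasts,
                                   paired_profile_tests, rank_tests)
from burstdyn.types import AmplitudePDF, SpectralDensity, ThresholdProfile


def make_profile(durations, percentiles=None):
    d = np.asarray(durations, dtype=float)
    if percentiles is None:
        percentiles = np.linspace(0.2, 0.8, len(d))
    return ThresholdProfile(percentiles, np.sort(np.abs(d)), d)


class TestBDDLS:
    def test_identical_profiles_zero(self):
        p = make_profile([0.3, 0.2, 0.1])
        assert bddls(p, p) == 0.0

    def test_hand_calculation(self):
        data = make_profile([0.3, 0.2, 0.1])
        surr = make_profile([0.2, 0.2, 0.2])
        # ssd = 0.01 + 0 + 0.01 = 0.02; scale = mean(0.2)^2 = 0.04
        assert bddls(data, surr) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.random(8) + 0.1
        s = rng.random(8) + 0.1
        base = bddls(make_profile(d), make_profile(s))
        for k in (0.1, 3.0, 250.0):
            assert bddls(make_profile(k * d), make_profile(k * s)) == \
                pytest.approx(base, rel=1e-12)

    def test_grid_mismatch_raises(self):
        a = make_profile([0.1, 0.2], percentiles=np.array([0.2, 0.4]))
        b = make_profile([0.1, 0.2], percentiles=np.array([0.3, 0.5]))
        with pytest.raises(ValueError, match="grid"):
            bddls(a, b)


class TestContrasts:
    @staticmethod
    def _spec(scale=1.0):
        f = np.linspace(0, 100, 101)
        p = scale * np.exp(-0.5 * ((f - 20) / 3) ** 2) + 1e-3
        return SpectralDensity(f, p)

    def test_equal_conditions_zero(self):
        prof = make_profile([0.3, 0.2, 0.1])
        spec = self._spec()
        rep = contrasts(prof, prof, prof, prof, spec, spec, band=(13, 35))
        assert rep.bddls_diff == rep.dur_diff == rep.psd_diff == 0.0

    def test_durdiff_hand_value(self):
        on = make_profile([0.1, 0.1, 0.1])
        off = make_profile([0.3, 0.2, 0.1])
        rep = contrasts(on, off, on, off, self._spec(), self._spec(), band=(13, 35))
        assert rep.dur_diff == pytest.approx(0.3)

    def test_psd_doubling(self):
        prof = make_profile([0.3, 0.2, 0.1])
        rep = contrasts(prof, prof, prof, prof, self._spec(1.0), self._spec(2.0),
                        band=(13, 35))
        # doubling the Gaussian bump nearly doubles band power
        assert rep.psd_diff == pytest.approx(1.0, abs=0.05)


def two_stage_stepup_oracle(p, q=0.05):
    """Step-by-step two-stage adaptive linear step-up (independent oracle)."""
    p = np.asarray(p, dtype=float)
    m = len(p)

    def stepup(pvals, alpha):
        order = np.argsort(pvals)
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = np.nonzero(np.sort(pvals) <= thresh)[0]
        k = passed.max() + 1 if len(passed) else 0
        reject = np.zeros(m, bool)
        reject[order[:k]] = True
        return reject

    q1 = q / (1.0 + q)
    r1 = stepup(p, q1).sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    m0 = m - r1
    return stepup(p, q1 * m / m0)


class TestAdaptiveFDR:
    def test_degenerate_inputs(self):
        assert adaptive_fdr([]).size == 0
        assert not adaptive_fdr(np.ones(6)).any()
        assert adaptive_fdr(np.zeros(6)).all()

    def test_matches_stepwise_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.3, 0.9])
        assert np.array_equal(adaptive_fdr(p, q=0.05),
                              two_stage_stepup_oracle(p, 0.05))

    def test_oracle_agreement_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = np.round(rng.random(rng.integers(3, 15)), 4)
            assert np.array_equal(adaptive_fdr(p), two_stage_stepup_oracle(p))

    def test_achieved_fdr_controlled(self):
        # 50% true nulls: empirical FDR stays below q + 1%
        rng = np.random.default_rng(23)
        q = 0.05
        fdps = []
        for _ in range(1000):
            p_null = rng.random(10)
            p_alt = rng.beta(0.1, 8.0, 10)
            p = np.concatenate([p_null, p_alt])
            rej = adaptive_fdr(p, q=q)
            n_rej = rej.sum()
            fdps.append(rej[:10].sum() / max(n_rej, 1))
        assert np.mean(fdps) <= q + 0.01


def _pdf_group(rng, n, shift=0.0):
    out = []
    edges = np.linspace(-4, 4, 21)
    for _ in range(n):
        x = rng.normal(shift, 1.0, 400)
        dens, _ = np.histogram(x, bins=edges, density=True)
        out.append(AmplitudePDF(edges, dens / np.sum(dens * np.diff(edges))))
    return out


class TestClusterPermutation:
    def test_identical_groups_no_clusters(self):
        rng = np.random.default_rng(0)
        g = _pdf_group(rng, 6)
        clusters, p_min = cluster_permutation_test(g, g, n_perm=1000)
        assert clusters == []
        assert p_min == 1.0

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = np.asarray([p.density for p in _pdf_group(rng, 6)])
            b = np.asarray([p.density for p in _pdf_group(rng, 6)])
            _, p_min = cluster_permutation_test(a, b, n_perm=1000)
            hits += p_min <= 0.05
        assert 0.005 <= hits / n_rep <= 0.12

    def test_power_under_shift(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            a = _pdf_group(rng, 6)
            b = _pdf_group(rng, 6, shift=1.0)
            _, p_min = cluster_permutation_test(a, b, n_perm=500)
            hits += p_min <= 0.05
        assert hits / n_rep >= 0.9

    def test_p_floor(self):
        rng = np.random.default_rng(3)
        a = _pdf_group(rng, 5)
        b = _pdf_group(rng, 5, shift=2.0)
        results, p_min = cluster_permutation_test(a, b, n_perm=10_000)
        assert p_min >= 1.0 / (2 ** 5 + 1)


class TestPairedProfileTests:
    @staticmethod
    def _segments(rng, base, n=5, noise=0.01):
        return [make_profile(base + noise * rng.standard_normal(len(base)))
                for _ in range(n)]

    def test_identical_segments_no_rejections(self):
        rng = np.random.default_rng(0)
        base = np.array([0.3, 0.25, 0.2, 0.15])
        on = self._segments(rng, base)
        off = self._segments(rng, base)
        _, reject = paired_profile_tests(on, off)
        assert not reject.any()

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        base = np.array([0.3, 0.25, 0.2, 0.15])
        on = self._segments(rng, base, noise=0.005)
        shifted = base.copy()
        shifted[2] += 0.2  # ~ 40 SD shift at one threshold
        off = self._segments(rng, shifted, noise=0.005)
        p, reject = paired_profile_tests(on, off)
        assert reject[2]

    def test_p_matches_textbook_t(self):
        from scipy import stats
        x = np.array([0.1, 0.12, 0.11, 0.13, 0.09])
        y = np.array([0.2, 0.22, 0.19, 0.21, 0.23])
        on = [make_profile([v]) for v in x]
        off = [make_profile([v]) for v in y]
        p, _ = paired_profile_tests(on, off)
        assert p[0] == pytest.approx(stats.ttest_ind(x, y).pvalue, rel=1e-12)


class TestRankTests:
    def test_spearman_monotone(self):
        res = rank_tests([1, 2, 3, 4, 5], [2, 4, 8, 16, 32], kind="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_spearman_hand_value(self):
        res = rank_tests([1, 2, 3, 4], [1, 2, 4, 3], kind="spearman")
        assert res.statistic == pytest.approx(0.8)

    def test_wilcoxon_all_positive_exact(self):
        rng = np.random.default_rng(0)
        y = rng.random(16)
        x = y + rng.random(16) + 0.01
        res = rank_tests(x, y)
        assert res.p_value == pytest.approx(1 / 2 ** 16, rel=1e-9)

    def test_wilcoxon_zero_differences(self):
        x = np.ones(8)
        assert rank_tests(x, x).p_value == 1.0


class TestBinomialTail:
    def test_printed_worked_example(self):
        res = binomial_tail_test(10, 16, 0.3438)
        assert round(res.p_value, 3) == 0.020

    def test_k_zero(self):
        assert binomial_tail_test(0, 16, 0.3438).p_value == 1.0

    def test_small_enumeration(self):
        assert binomial_tail_test(2, 2, 0.5).p_value == pytest.approx(0.25)


def barnard_brute_force(table, n_grid=2001):
    """Enumerate all outcome tables at fixed column sizes; maximize the
    one-sided pooled-Wald tail probability over a nuisance grid."""
    from scipy.stats import binom
    t = np.asarray(table)
    c1, c2 = t[:, 0].sum(), t[:, 1].sum()

    def wald(x1, x2):
        p1, p2 = x1 / c1, x2 / c2
        pooled = (x1 + x2) / (c1 + c2)
        denom = np.sqrt(pooled * (1 - pooled) * (1 / c1 + 1 / c2))
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (p1 - p2) / denom
        return np.where(denom == 0, 0.0, w)

    obs = wald(t[0, 0], t[0, 1])
    x1, x2 = np.meshgrid(np.arange(c1 + 1), np.arange(c2 + 1), indexing="ij")
    stats_all = wald(x1, x2)
    mask = stats_all >= obs - 1e-12
    best = 0.0
    for pi in np.linspace(1e-6, 1 - 1e-6, n_grid):
        prob = binom.pmf(x1, c1, pi) * binom.pmf(x2, c2, pi)
        best = max(best, prob[mask].sum())
    return best


class TestBarnard:
    def test_minimal_model_table_worked_example(self):
        # 10/16 linear minimal models in one condition vs 5/16 in the other
        res = barnard_test([[10, 5], [6, 11]])
        assert res.p_value == pytest.approx(0.0551, abs=5e-4)

    def test_identical_rows_p_one(self):
        assert barnard_test([[3, 3], [5, 5]]).p_value == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        table = [[2, 0], [0, 2]]
        res = barnard_test(table, n_grid=256)
        assert res.p_value == pytest.approx(barnard_brute_force(table), abs=1e-3)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            barnard_test([[0, 0], [0, 0]])


class TestBDDLSRank:
    def test_rank_p_floor_and_range(self):
        rng = np.random.default_rng(9)
        grid = np.linspace(0.2, 0.8, 8)
        surr = [make_profile(0.1 + 0.01 * rng.standard_normal(8), grid)
                for _ in range(19)]
        data = make_profile(0.1 + 0.01 * rng.standard_normal(8), grid)
        res = bddls_rank_test(data, surr)
        assert 0.05 <= res.p_value <= 1.0
        strong = make_profile(np.full(8, 0.5), grid)
        assert bddls_rank_test(strong, surr).p_value == pytest.approx(0.05)
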