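import math

import numpy as np
import pytest
from scipy import integrate, stats

from conflictdecode.inference import (TfceParams, _tfce_max_batch_1d,
                                      bf01_ttest, bf10_ttest, bf_timecourse,
                                      classify_bf, d_av_from_summary,
                                      effect_summary, montecarlo_cluster_stat,
                                      stelzer_null, tfce)


def brute_force_tfce_1d(m, params):
    """Independent threshold-sum loop with explicit run scanning."""
    out = np.zeros_like(m, dtype=float)
    h = params.dh
    while h <= m.max(initial=0.0) + 1e-12:
        supp = m >= h
        i = 0
        while i < len(m):
            if supp[i]:
                j = i
                while j < len(m) and supp[j]:
                    j += 1
                out[i:j] += (j - i) ** params.E * h ** params.H * params.dh
                i = j
            else:
                i += 1
        h += params.dh
    return out


def brute_force_tfce_2d(m, params):
    """Flood-fill component sizes per threshold, 4-connectivity."""
    out = np.zeros_like(m, dtype=float)
    h = params.dh
    while h <= m.max(initial=0.0) + 1e-12:
        supp = m >= h
        seen = np.zeros_like(supp)
        for start in zip(*np.nonzero(supp & ~seen)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < m.shape[0] and 0 <= cc < m.shape[1]
                            and supp[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            inc = len(comp) ** params.E * h ** params.H * params.dh
            for r, c in comp:
                out[r, c] += inc
        h += params.dh
    return out


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert np.all(tfce(np.zeros(10)) == 0)

    def test_monotone_in_height(self, rng):
        m = np.abs(rng.normal(size=15))
        params = TfceParams()
        e1, e2 = tfce(m, params), tfce(2.0 * m, params)
        assert np.all(e2[m > 0] > e1[m > 0])

    def test_spec_ramp_example_matches_brute_force(self):
        m = np.array([0.0, 1, 2, 3, 2, 1, 0])
        params = TfceParams(E=0.5, H=2.0, dh=0.1)
        np.testing.assert_allclose(tfce(m, params),
                                   brute_force_tfce_1d(m, params), atol=1e-9)

    def test_random_1d_and_2d_against_brute_force(self, rng):
        params = TfceParams()
        for _ in range(20):
            m1 = np.maximum(rng.normal(size=30), 0)
            np.testing.assert_allclose(tfce(m1, params),
                                       brute_force_tfce_1d(m1, params),
                                       atol=1e-9)
        for _ in range(5):
            m2 = np.maximum(rng.normal(size=(12, 12)), 0)
            np.testing.assert_allclose(tfce(m2, params),
                                       brute_force_tfce_2d(m2, params),
                                       atol=1e-9)

    def test_graph_neighborhood_matches_lattice(self, rng):
        # chain adjacency over flattened cells == 1-D lattice connectivity
        n = 25
        m = np.maximum(rng.normal(size=n), 0)
        adj = np.zeros((n, n), dtype=bool)
        idx = np.arange(n - 1)
        adj[idx, idx + 1] = adj[idx + 1, idx] = True
        np.testing.assert_allclose(tfce(m, adjacency=adj), tfce(m), atol=1e-12)

    def test_asymmetric_adjacency_rejected(self, rng):
        m = np.abs(rng.normal(size=4))
        adj = np.zeros((4, 4))
        adj[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            tfce(m, adjacency=adj)

    def test_two_tailed_is_signed(self):
        m = np.array([0.0, -2, -2, 0, 2, 2, 0])
        e = tfce(m, TfceParams(tails="two"))
        assert e[1] < 0 < e[4]
        assert e[1] == -e[4]

    def test_batch_1d_max_matches_generic(self, rng):
        params = TfceParams()
        maps = rng.normal(size=(30, 40))
        batch = _tfce_max_batch_1d(maps, params)
        ref = np.array([tfce(np.maximum(r, 0), params).max() for r in maps])
        np.testing.assert_allclose(batch, ref, atol=1e-9)


class TestStelzerNull:
    def test_observed_dominates_all_draws(self, rng):
        perms = rng.normal(0.5, 0.01, size=(10, 20))
        null = stelzer_null(0.9, perms, n_draws=500, seed=0)
        assert null.percentile == 100.0

    def test_all_ties_give_midrank_50(self):
        perms = np.full((5, 10), 0.52)
        null = stelzer_null(0.52, perms, n_draws=200, seed=0)
        assert null.percentile == 50.0

    def test_clt_oracle(self):
        # iid N(0.5, 0.01^2) perms, 30 subjects: the group draw is
        # N(0.5, 0.01^2/30); percentile matches the normal CDF
        rng = np.random.default_rng(99)
        perms = rng.normal(size=(30, 4000))
        # standardize to exact first/second moments so the CLT prediction
        # is clean (the resampled draw then has mean 0.5, var 0.01^2/30)
        perms = 0.5 + 0.01 * (perms - perms.mean()) / perms.std()
        for observed in (0.501, 0.52):
            null = stelzer_null(observed, perms, n_draws=1_000_000, seed=1)
            expected = 100 * stats.norm.cdf((observed - 0.5)
                                            / (0.01 / math.sqrt(30)))
            assert abs(null.percentile - expected) < 0.5


class TestMonteCarloClusterStat:
    def test_recovers_planted_cluster_window(self, rng):
        # strong group effect over cells 20..39 of a 60-cell axis
        maps = rng.normal(0.5, 0.02, size=(15, 60))
        maps[:, 20:40] += 0.15
        ci = montecarlo_cluster_stat(maps, TfceParams(n_iter=500, seed=0),
                                     axes=[np.arange(60.0)])
        assert len(ci.clusters) == 1
        c = ci.clusters[0]
        assert abs(c["axis0_index_start"] - 20) <= 2
        assert abs(c["axis0_index_end"] - 39) <= 2

    def test_degenerate_identical_positive_maps(self):
        maps = np.tile(np.full(12, 0.7), (6, 1))
        ci = montecarlo_cluster_stat(maps, TfceParams(n_iter=200, seed=1))
        assert ci.significant.all()

    def test_grid_mismatch_and_subject_count_errors(self, rng):
        with pytest.raises(ValueError, match="two subjects"):
            montecarlo_cluster_stat(rng.normal(size=(1, 10)))

    def test_2d_path_agrees_with_1d_batch_on_null(self, rng):
        # identical seeds, same maps viewed as 1-D vs (n, 1) 2-D grid
        maps = rng.normal(0.5, 0.05, size=(10, 30))
        p = TfceParams(n_iter=300, seed=5)
        ci1 = montecarlo_cluster_stat(maps, p)
        ci2 = montecarlo_cluster_stat(maps[:, :, None], p)
        np.testing.assert_allclose(ci1.p_corrected, ci2.p_corrected[:, 0],
                                   atol=1e-12)


class TestBayesFactors:
    def test_published_worked_examples(self):
        # paired-contrast values reproducible from printed t and n
        assert abs(bf10_ttest(t=-2.43, n=507) - 0.93) < 0.02
        assert abs(bf10_ttest(t=-6.14, n=507) / 3.71e6 - 1.0) < 0.06

    def test_reciprocal_identity(self):
        for t, n in ((0.5, 10), (3.0, 30), (-2.2, 100)):
            assert abs(bf10_ttest(t=t, n=n) * bf01_ttest(t=t, n=n) - 1) < 1e-12

    def test_monotone_in_abs_t_and_null_at_zero(self):
        n = 25
        ts = [0.0, 0.5, 1.0, 2.0, 4.0]
        bfs = [bf10_ttest(t=t, n=n) for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert bfs[0] < 1.0
        assert abs(bf10_ttest(t=-3.0, n=n) - bf10_ttest(t=3.0, n=n)) < 1e-10

    def test_against_independent_quadrature_oracle(self):
        # same marginal likelihood, independently parametrized through
        # g = exp(u) with dense fixed quadrature
        def oracle(t, n, r=math.sqrt(2) / 2):
            v = n - 1

            def f(u):
                g = np.exp(u)
                dens = (r / np.sqrt(2 * np.pi)) * g ** -1.5 \
                    * np.exp(-r * r / (2 * g))
                like = (1 + n * g) ** -0.5 \
                    * (1 + t * t / ((1 + n * g) * v)) ** (-(v + 1) / 2)
                return like * dens * g  # du substitution jacobian

            val, _ = integrate.quad(f, -40, 40, epsrel=1e-12, limit=1000)
            return val / (1 + t * t / v) ** (-(v + 1) / 2)

        for t, n in ((0.0, 10), (1.3, 20), (3.0, 30), (-2.43, 507), (5.0, 80)):
            ours = bf10_ttest(t=t, n=n)
            ref = oracle(t, n)
            assert abs(ours / ref - 1.0) < 1e-6

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in ((1.5, 25), (-6.14, 507), (2.43, 100)):
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True))
            # pingouin's own quadrature tolerance limits the agreement
            assert abs(bf10_ttest(t=t, n=n) / ref - 1.0) < 1e-3

    def test_data_vector_overload(self, rng):
        x = rng.normal(0.3, 1.0, size=40)
        t = x.mean() / (x.std(ddof=1) / math.sqrt(40))
        assert abs(bf10_ttest(data=x) - bf10_ttest(t=t, n=40)) < 1e-10
        with pytest.raises(ValueError, match="zero variance"):
            bf10_ttest(data=np.full(10, 0.5))

    def test_evidence_bands(self):
        assert classify_bf(2.9) == "inconclusive"
        assert classify_bf(3.1) == "substantial"
        assert classify_bf(0.2) == "null"
        assert classify_bf(25.0) == "strong"
        assert classify_bf(200.0) == "very strong"

    def test_bf_timecourse_chance_cells_favor_null(self, rng):
        maps = np.full((10, 5), 0.5)  # exactly at chance: t = 0 everywhere
        bf = bf_timecourse(maps)
        assert np.all(bf < 1.0)
        strong = np.full((10, 3), 0.7) + rng.normal(0, 0.01, size=(10, 3))
        assert np.all(bf_timecourse(strong) > 3.0)


class TestEffectSummary:
    def test_d_av_from_published_summary_statistics(self):
        # battery-scale worked examples: RT summaries to two decimals
        assert round(d_av_from_summary(534.40, 120.56, 488.50, 106.89), 2) == 0.40
        assert round(d_av_from_summary(1572.35, 263.76, 1518.18, 275.12), 2) == 0.20
        assert round(d_av_from_summary(1915.23, 461.48, 1564.18, 370.20), 2) == 0.84

    def test_summary_fields_consistent(self, rng):
        x = rng.normal(600, 50, 200)
        y = x - rng.normal(40, 20, 200)
        s = effect_summary(x, y)
        assert s.df == 199 and s.n == 200
        assert s.ci_low < s.mean_diff < s.ci_high
        assert s.p < 0.001 and s.bf10 > 100
        t_ref, p_ref = stats.ttest_rel(x, y)
        assert abs(s.t - t_ref) < 1e-10 and abs(s.p - p_ref) < 1e-12
        assert abs(s.bf01 * s.bf10 - 1.0) < 1e-12

    def test_identical_vectors_zero_variance_error(self):
        x = np.arange(10.0)
        assert d_av_from_summary(1.0, 2.0, 1.0, 3.0) == 0.0
        with pytest.raises(ValueError, match="variance"):
            effect_summary(x, x)
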