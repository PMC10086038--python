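"""Cluster permutation machinery, lateralization contrasts, proportion tests."""

import itertools

import numpy as np
import pytest
from scipy.special import betaln, gammaln
from scipy.stats import t as t_dist

from presacc.layout import make_layout
from presacc.stats import (AdjacencyGraph, cluster_onesample_test,
                           duration_mask, lateralization_timecourse,
                           paired_hemisphere_ttest, proportion_tests)


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain loops + BFS; no shared code paths)
# ---------------------------------------------------------------------------

def _oracle_tmap(data, signs):
    n = data.shape[0]
    flipped = data * np.asarray(signs)[:, None, None]
    m = flipped.mean(0)
    sd = flipped.std(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _oracle_clusters(tmap, thr, adj):
    """BFS over supra-threshold (site, time) points; signed masses."""
    n_sites, n_time = tmap.shape
    out = []
    for sign in (1, -1):
        mask = sign * tmap > thr
        seen = np.zeros_like(mask)
        for s0 in range(n_sites):
            for t0 in range(n_time):
                if not mask[s0, t0] or seen[s0, t0]:
                    continue
                stack, members = [(s0, t0)], []
                seen[s0, t0] = True
                while stack:
                    s, t = stack.pop()
                    members.append((s, t))
                    for t2 in (t - 1, t + 1):
                        if 0 <= t2 < n_time and mask[s, t2] and not seen[s, t2]:
                            seen[s, t2] = True
                            stack.append((s, t2))
                    for s2 in range(n_sites):
                        if adj[s, s2] and mask[s2, t] and not seen[s2, t]:
                            seen[s2, t] = True
                            stack.append((s2, t))
                out.append(sum(tmap[s, t] for s, t in members))
    return out


def _oracle_exact_pvalues(data, adj, alpha=0.05):
    n = data.shape[0]
    thr = t_dist.ppf(1 - alpha / 2, n - 1)
    obs = _oracle_clusters(_oracle_tmap(data, np.ones(n)), thr, adj)
    null = []
    for signs in itertools.product((1, -1), repeat=n):
        masses = _oracle_clusters(_oracle_tmap(data, signs), thr, adj)
        null.append(max((abs(m) for m in masses), default=0.0))
    null = np.asarray(null)
    return {round(m, 10): (null >= abs(m) - 1e-12).mean() for m in obs}


@pytest.fixture(scope="module")
def chain3():
    adj = np.zeros((3, 3), dtype=bool)
    adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
    return adj


class TestClusterTest:
    def test_exact_matches_enumeration_oracle(self, chain3):
        rng = np.random.default_rng(21)
        data = rng.normal(0.4, 1.0, size=(8, 3, 5))
        oracle = _oracle_exact_pvalues(data, chain3)
        cs = cluster_onesample_test(data, AdjacencyGraph(chain3), exact=True)
        assert len(cs.clusters) == len(oracle)
        for c in cs.clusters:
            assert c.p == pytest.approx(oracle[round(c.mass, 10)], abs=1e-12)

    def test_isolated_strong_effect(self):
        rng = np.random.default_rng(22)
        data = rng.normal(0, 1.0, size=(16, 4, 20))
        data[:, 2, 5:15] += 30.0  # huge effect at one site
        adj = np.zeros((4, 4), dtype=bool)
        cs = cluster_onesample_test(data, AdjacencyGraph(adj), n_perm=199, seed=0)
        sig = [c for c in cs.clusters if c.p <= 0.05]
        big = max(cs.clusters, key=lambda c: abs(c.mass))
        assert set(big.sites) == {2}
        assert big.p == pytest.approx(1.0 / 200.0)
        assert sig and all(set(c.sites) == {2} for c in sig)

    def test_two_tailed_symmetry(self, chain3):
        rng = np.random.default_rng(23)
        data = rng.normal(0.3, 1.0, size=(9, 3, 12))
        a = cluster_onesample_test(data, AdjacencyGraph(chain3), n_perm=150, seed=5)
        b = cluster_onesample_test(-data, AdjacencyGraph(chain3), n_perm=150, seed=5)
        ma = sorted(round(c.mass, 9) for c in a.clusters)
        mb = sorted(round(-c.mass, 9) for c in b.clusters)
        assert ma == mb
        pa = {round(c.mass, 9): c.p for c in a.clusters}
        pb = {round(-c.mass, 9): c.p for c in b.clusters}
        assert pa == pb

    def test_site_relabeling_invariance(self):
        rng = np.random.default_rng(24)
        n_sites = 5
        adj = rng.random((n_sites, n_sites)) < 0.4
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        data = rng.normal(0.35, 1.0, size=(8, n_sites, 10))
        perm = rng.permutation(n_sites)
        a = cluster_onesample_test(data, AdjacencyGraph(adj), exact=True)
        b = cluster_onesample_test(data[:, perm], AdjacencyGraph(adj[perm][:, perm]),
                                   exact=True)
        assert sorted(round(c.mass, 9) for c in a.clusters) == \
            sorted(round(c.mass, 9) for c in b.clusters)
        assert sorted(c.p for c in a.clusters) == sorted(c.p for c in b.clusters)

    def test_input_validation(self, chain3):
        g = AdjacencyGraph(chain3)
        with pytest.raises(ValueError):
            cluster_onesample_test(np.zeros((1, 3, 5)), g)
        with pytest.raises(ValueError):
            cluster_onesample_test(np.zeros((4, 2, 5)), g)
        with pytest.raises(ValueError):
            cluster_onesample_test(np.zeros((4, 3, 5)), g, n_perm=0)

    def test_cluster_masses_match_mne(self):
        """Observed spatiotemporal clusters and their masses agree with an
        independent implementation (MNE's one-sample cluster test) at the
        same threshold and adjacency."""
        import mne
        from scipy import sparse

        rng = np.random.default_rng(31)
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        adj[2, 3] = adj[3, 2] = True
        data = rng.normal(0.4, 1.0, size=(9, 4, 12))
        thr = t_dist.ppf(0.975, 8)
        mine = cluster_onesample_test(data, AdjacencyGraph(adj), n_perm=50,
                                      seed=0)
        X = np.transpose(data, (0, 2, 1))  # (n_obs, n_times, n_spaces)
        t_obs, clusters, _, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            X, threshold=thr, tail=0, adjacency=sparse.coo_matrix(adj),
            n_permutations=100, seed=0, out_type="indices", verbose="error")
        ref = sorted(round(float(t_obs[c[0], c[1]].sum()), 8) for c in clusters)
        got = sorted(round(c.mass, 8) for c in mine.clusters)
        assert got == ref

    def test_type_one_calibration_quick(self, chain3):
        """Null maps: probability of a family-wise positive stays near alpha."""
        rng = np.random.default_rng(25)
        hits = 0
        n_coh = 60
        for _ in range(n_coh):
            data = rng.normal(size=(8, 3, 30))
            cs = cluster_onesample_test(data, AdjacencyGraph(chain3),
                                        n_perm=99, seed=int(rng.integers(1 << 30)))
            if any(c.p <= 0.05 for c in cs.clusters):
                hits += 1
        assert hits / n_coh < 0.17  # loose 3-sigma guard for 60 cohorts


class TestDurationMask:
    def _stats_with_runs(self, runs, n_time=40, sfreq=500.0):
        from presacc.stats import ClusterStats
        mask = np.zeros((len(runs), n_time), dtype=bool)
        for s, (start, length) in enumerate(runs):
            mask[s, start:start + length] = True
        return ClusterStats(clusters=[], t_obs=np.zeros_like(mask, dtype=float),
                            sig_mask=mask, alpha=0.05, threshold=2.0,
                            n_perm=100, seed=0, sfreq=sfreq)

    def test_span_convention_at_500hz(self):
        """7 samples span 12 ms (excluded); 8 samples span 14 ms (included)."""
        cs = self._stats_with_runs([(5, 7), (5, 8)])
        out = duration_mask(cs, min_dur=0.0125)
        assert list(out) == [False, True]

    def test_count_convention(self):
        cs = self._stats_with_runs([(5, 7)])
        assert duration_mask(cs, min_dur=0.0125, convention="count")[0]

    def test_empty_mask(self):
        cs = self._stats_with_runs([(0, 0), (0, 0)])
        assert not duration_mask(cs, min_dur=0.0125).any()

    def test_subset_of_significant_sites(self):
        cs = self._stats_with_runs([(0, 3), (0, 20), (0, 0)])
        out = duration_mask(cs, min_dur=0.0125)
        assert (out <= cs.sig_mask.any(axis=1)).all()


class TestLateralization:
    def test_mirror_symmetric_zero(self, small_layout):
        rng = np.random.default_rng(26)
        n_sites = small_layout.n_sites
        res = rng.normal(size=(6, n_sites, 20))
        # copy left values onto mirrored right sites -> exact symmetry
        left = small_layout.hemisphere_sites("left")
        right = small_layout.hemisphere_sites("right")
        pos = small_layout.pos
        for li in left:
            mirror = right[np.argmin(np.abs(pos[right] - pos[li] * [-1, 1]).sum(1))]
            res[:, mirror] = res[:, li]
        diff, cs = lateralization_timecourse(res, small_layout, n_perm=99, seed=0)
        assert np.abs(diff).max() < 1e-12
        assert not any(c.p <= 0.05 for c in cs.clusters)

    def test_right_effect_detected(self, small_layout):
        rng = np.random.default_rng(27)
        detected = 0
        for rep in range(20):
            res = rng.normal(0, 1, size=(10, small_layout.n_sites, 30))
            res[:, small_layout.hemisphere_sites("right"), 10:25] += 1.5
            diff, cs = lateralization_timecourse(res, small_layout, n_perm=99,
                                                 seed=rep)
            neg = [c for c in cs.clusters if c.p <= 0.05 and c.mass < 0]
            detected += bool(neg)
        assert detected >= 18

    def test_subset_plumbing(self, small_layout):
        rng = np.random.default_rng(28)
        res = rng.normal(size=(5, small_layout.n_sites, 15))
        region = np.asarray(small_layout.region)
        idx = np.flatnonzero(region == region[0])
        if not ((small_layout.hemisphere[idx] == "left").any()
                and (small_layout.hemisphere[idx] == "right").any()):
            idx = np.arange(small_layout.n_sites)
        diff, cs = lateralization_timecourse(res, small_layout, site_subset=idx,
                                             n_perm=49, seed=1)
        assert diff.shape == (5, 15)

    def test_empty_hemisphere_error(self, small_layout):
        res = np.zeros((4, small_layout.n_sites, 10))
        left_only = small_layout.hemisphere_sites("left")
        with pytest.raises(ValueError):
            lateralization_timecourse(res, small_layout, site_subset=left_only)


class TestPairedTtest:
    def test_identical(self):
        t, df, p = paired_hemisphere_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(29)
        t, df, p = paired_hemisphere_ttest(rng.normal(size=28), rng.normal(size=28))
        assert df == 27

    def test_constant_difference_sentinel(self):
        t, df, p = paired_hemisphere_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy(self):
        from scipy.stats import ttest_rel
        rng = np.random.default_rng(30)
        a, b = rng.normal(size=(2, 15))
        t, df, p = paired_hemisphere_ttest(a, b)
        ref = ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_too_few(self):
        with pytest.raises(ValueError):
            paired_hemisphere_ttest([1.0], [2.0])


def _bf_oracle(k1, n1, k2, n2, a=1.0):
    """Closed-form beta-binomial marginal-likelihood ratio (independent oracle)."""
    def log_bb(k, n):
        return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                + betaln(k + a, n - k + a) - betaln(a, a))
    log_m1 = log_bb(k1, n1) + log_bb(k2, n2)
    log_m0 = (gammaln(n1 + 1) - gammaln(k1 + 1) - gammaln(n1 - k1 + 1)
              + gammaln(n2 + 1) - gammaln(k2 + 1) - gammaln(n2 - k2 + 1)
              + betaln(k1 + k2 + a, n1 + n2 - k1 - k2 + a) - betaln(a, a))
    return float(np.exp(log_m1 - log_m0))


class TestProportionTests:
    def test_equal_table(self):
        out = proportion_tests(10, 20, 10, 20)
        assert out["chi2"] == 0.0 and out["p"] == 1.0

    def test_equal_proportions_favor_null(self):
        out = proportion_tests(25, 51, 25, 51)
        assert out["bf10"] < 1.0
        assert out["bf10"] == pytest.approx(_bf_oracle(25, 51, 25, 51), rel=1e-6)

    def test_extreme_imbalance(self):
        out = proportion_tests(50, 51, 1, 51)
        assert out["chi2"] > 50
        assert out["bf10"] > 1e6
        assert out["bf10"] == pytest.approx(_bf_oracle(50, 51, 1, 51), rel=1e-6)

    def test_bonferroni_factor(self):
        out = proportion_tests(15, 30, 7, 30, n_windows=2)
        assert out["p_bonferroni"] == pytest.approx(min(1.0, 2 * out["p"]))

    def test_validation(self):
        with pytest.raises(ValueError):
            proportion_tests(5, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_tests(11, 10, 1, 10)

    def test_bf_oracle_grid(self):
        for k1, n1, k2, n2 in [(3, 10, 7, 12), (0, 8, 8, 8), (20, 40, 22, 41)]:
            out = proportion_tests(k1, n1, k2, n2)
            assert out["bf10"] == pytest.approx(_bf_oracle(k1, n1, k2, n2), rel=1e-6)


class TestAdjacencyGraph:
    def test_from_layout_matches_radius(self):
        lay = make_layout(12, seed=3)
        g = AdjacencyGraph.from_layout(lay)
        d = np.linalg.norm(lay.pos[:, None] - lay.pos[None, :], axis=-1)
        expect = (d < lay.neighbor_radius) & ~np.eye(12, dtype=bool)
        assert np.array_equal(g.matrix, expect)

    def test_asymmetric_rejected(self):
        m = np.zeros((3, 3), dtype=bool)
        m[0, 1] = True
        with pytest.raises(ValueError):
            AdjacencyGraph(m)
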