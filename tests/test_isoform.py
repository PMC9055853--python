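import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from scutr import isoform

from conftest import step_coverage


def nnls_oracle(r, p):
    """Independent NNLS via scipy on the explicit two-column design."""
    L = r.size
    A = np.column_stack([np.ones(L), (np.arange(1, L + 1) <= p).astype(float)])
    w, rnorm = scipy_nnls(A, r)
    return w[0], w[1], rnorm**2


class TestNnlsWeights:
    def test_exact_two_step_profile(self):
        r = np.array([2, 2, 2, 2, 1, 1, 1, 1, 1, 1], float)
        assert isoform.nnls_weights(r, 4) == pytest.approx((1.0, 1.0, 0.0))

    def test_single_isoform_profile(self):
        assert isoform.nnls_weights(3 * np.ones(10), 4) == pytest.approx((3.0, 0.0, 0.0))

    def test_all_zero(self):
        wl, ws, res = isoform.nnls_weights(np.zeros(10), 5)
        assert (wl, ws, res) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_noisy_profiles(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.normal(1.0, 1.0, 20)  # may go negative: exercises the projection
        for p in range(2, 19):
            mine = isoform.nnls_weights(r, p)
            ref = nnls_oracle(r, p)
            assert mine[2] == pytest.approx(ref[2], abs=1e-9)
            assert mine[0] == pytest.approx(ref[0], abs=1e-7)
            assert mine[1] == pytest.approx(ref[1], abs=1e-7)


def exhaustive_fit(coverages, flank=None):
    """Brute-force oracle: scipy NNLS at every candidate site."""
    L = next(iter(coverages.values())).size
    cand = isoform.candidate_sites(L, flank)
    totals = []
    for p in cand:
        totals.append(sum(nnls_oracle(r, p)[2] for r in coverages.values()))
    best = int(np.argmin(totals))
    return int(cand[best]), float(totals[best])


class TestFitTwoSite:
    def test_noiseless_two_clusters_recovers_site(self):
        covs = {"a": step_coverage(100, 60, 1, 2), "b": step_coverage(100, 60, 2, 3)}
        fit = isoform.fit_two_site(covs, "g", flank=5)
        assert fit.proximal_site == 60
        assert fit.w_long == pytest.approx({"a": 1, "b": 2})
        assert fit.w_short == pytest.approx({"a": 2, "b": 3})

    def test_zero_cluster_does_not_pull_the_site(self):
        covs = {"a": step_coverage(100, 60, 1, 2), "b": np.zeros(100)}
        fit = isoform.fit_two_site(covs, "g", flank=5)
        assert fit.proximal_site == 60
        assert not fit.two_site_clusters["b"]

    def test_flat_coverage_is_single_site(self):
        fit = isoform.fit_two_site({"a": 3 * np.ones(100)}, "g", flank=5)
        assert not fit.two_site

    def test_all_zero_gene_dropped(self):
        assert isoform.fit_two_site({"a": np.zeros(100)}, "g") is None

    def test_tie_broken_toward_smallest_site(self):
        # two genuinely tied candidates: symmetric double step
        r = np.concatenate([np.full(20, 3.0), np.full(60, 2.0), np.full(20, 1.0)])
        fit = isoform.fit_two_site({"a": r}, "g", flank=5)
        oracle_p, _ = exhaustive_fit({"a": r}, flank=5)
        assert fit.proximal_site == oracle_p

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        L = int(rng.integers(60, 200))
        covs = {}
        for k in range(int(rng.integers(1, 4))):
            p = int(rng.integers(10, L - 10))
            r = step_coverage(L, p, rng.uniform(0.5, 3), rng.uniform(0.5, 3))
            covs[f"c{k}"] = r + rng.normal(0, 0.2, L)
        fit = isoform.fit_two_site(covs, "g", flank=5)
        oracle_p, oracle_res = exhaustive_fit(covs, flank=5)
        assert fit.proximal_site == oracle_p
        assert sum(fit.residual.values()) == pytest.approx(oracle_res, abs=1e-9)


class TestIsoformCounts:
    def test_classification_and_conservation(self):
        c = isoform.assign_isoform_counts([890, 400], 600, 10**6, "g", "k")
        assert (c.long_count, c.short_count) == (1, 1)
        assert c.cpm_long == pytest.approx(1.0)

    def test_all_short(self):
        c = isoform.assign_isoform_counts([100, 200, 300], 600, 10**6)
        assert c.long_count == 0 and c.total == 3

    def test_count_pdui_converges_to_weight_pdui(self):
        """With many reads, read-level PDUI approaches the abundance PDUI."""
        rng = np.random.default_rng(0)
        L, P, target = 1000, 400, 0.7
        n = 20000
        is_long = rng.random(n) < target
        ends = np.where(is_long, L, P) - rng.integers(0, 10, n)
        c = isoform.assign_isoform_counts(ends, P, 10**6)
        assert c.long_count / c.total == pytest.approx(target, abs=3 * 0.5 / np.sqrt(n))


class TestInternalPriming:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAAAAAGC", True),   # 8 consecutive adenines
        ("AAAAGAAACC", True),   # 8-window with one mismatch
        ("ACGTACGTAC", False),
        ("AAAANAAAGG", True),   # N is a mismatch, 7 A in the window
        ("AANANAAAGG", False),  # two non-A in every window
        ("AAAAAAA", False),     # shorter than the 8-base window
    ])
    def test_window_rule(self, seq, expected):
        assert isoform.flag_internal_priming(seq) is expected


class TestMultiSite:
    def test_two_site_matches_change_point_fit(self):
        W = np.zeros((100, 2))
        W[39] = [2.0, 1.0]   # site at transcript position 40
        W[99] = [1.0, 3.0]   # distal end
        C = np.cumsum(W[::-1], axis=0)[::-1]
        ms = isoform.fit_multi_site(C, lam=1e-6)
        assert ms.active_sites == [40, 100]
        fit = isoform.fit_two_site({"a": C[:, 0], "b": C[:, 1]}, "g", flank=5)
        assert fit.proximal_site == 40

    def test_three_sites_recovered(self):
        W = np.zeros((100, 3))
        W[19] = [1, 0, 2]
        W[59] = [2, 1, 0]
        W[99] = [1, 1, 1]
        C = np.cumsum(W[::-1], axis=0)[::-1]
        assert isoform.fit_multi_site(C, lam=1e-6).active_sites == [20, 60, 100]

    def test_huge_penalty_zeroes_everything(self):
        C = np.ones((50, 2))
        ms = isoform.fit_multi_site(C, lam=1e9)
        assert ms.active_sites == [] and np.all(ms.weights == 0)

    def test_max_sites_budget_enforced(self):
        rng = np.random.default_rng(3)
        W = np.zeros((80, 2))
        for i in (9, 29, 49, 69, 79):
            W[i] = rng.uniform(0.5, 2, 2)
        C = np.cumsum(W[::-1], axis=0)[::-1] + rng.normal(0, 0.05, (80, 2))
        ms = isoform.fit_multi_site(C, lam=1e-4, max_sites=4)
        assert len(ms.active_sites) <= 4


class TestPdui:
    @pytest.mark.parametrize("wl,ws,expected", [(3, 1, 0.75), (0, 5, 0.0), (2, 2, 0.5)])
    def test_values(self, wl, ws, expected):
        assert isoform.pdui(wl, ws) == expected

    def test_undefined_when_both_zero(self):
        assert np.isnan(isoform.pdui(0.0, 0.0))
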