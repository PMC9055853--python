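import numpy as np
import pytest

from scutr import model
from scutr.isoform import IsoformCounts, IsoformFit


def counts(gene, cluster, long, short, depth=10**6):
    scale = 1e6 / depth
    return IsoformCounts(gene, cluster, long, short, long * scale, short * scale)


def fake_fit(gene, clusters, two_site=True):
    return IsoformFit(gene, 50, 100,
                      {k: 1.0 for k in clusters}, {k: 1.0 for k in clusters},
                      {k: 0.0 for k in clusters},
                      {k: two_site for k in clusters})


class TestFilterGenes:
    CL = ["k1", "k2", "k3", "k4", "k5"]

    def make(self, long_cpms, short_cpms, totals=None, n_two_site=5):
        totals = totals or [1000] * 5
        per = {}
        for k, lc, sc, t in zip(self.CL, long_cpms, short_cpms, totals):
            frac = lc / (lc + sc)
            per[k] = IsoformCounts("g", k, round(t * frac), t - round(t * frac), lc, sc)
        fit = fake_fit("g", self.CL)
        for k in self.CL[n_two_site:]:
            fit.two_site_clusters[k] = False
        return {"g": per}, {"g": fit}

    def test_mean_cpm_rule_retains(self):
        c, f = self.make([12, 8, 10, 15, 9], [11, 11, 11, 11, 11])
        assert "g" in model.filter_genes(c, f)  # means 10.8 and 11 > 10

    def test_mean_cpm_rule_drops(self):
        c, f = self.make([12, 8, 10, 9, 9], [11, 11, 11, 11, 11])
        assert model.filter_genes(c, f) == {}  # long mean 9.6 <= 10

    def test_low_count_cluster_excluded(self):
        c, f = self.make([20] * 5, [20] * 5, totals=[1000, 19, 1000, 1000, 1000])
        retained = model.filter_genes(c, f)
        assert retained["g"] == ["k1", "k3", "k4", "k5"]

    def test_two_site_in_too_few_clusters_drops_gene(self):
        c, f = self.make([20] * 5, [20] * 5, n_two_site=2)
        assert model.filter_genes(c, f) == {}


class TestLogisticFit:
    def test_single_cluster_intercept_is_logit(self):
        obs = [model.Observation("k", 30, 70)]
        design = model.DesignSpec.from_observations(obs)
        fit = model.fit_logistic(obs, design)
        assert fit.params["intercept"] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_two_balanced_clusters(self):
        obs = [model.Observation("c1", 80, 20), model.Observation("c2", 20, 80)]
        betas, ses, fit = model.fit_logistic_all_clusters(obs)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert betas["c1"] == pytest.approx(np.log(4), abs=1e-8)
        assert betas["c2"] == pytest.approx(-np.log(4), abs=1e-8)

    def test_identical_proportions_give_null_betas(self):
        obs = [model.Observation(k, 40, 60) for k in "abc"]
        betas, _, _ = model.fit_logistic_all_clusters(obs)
        assert all(abs(b) < 1e-8 for b in betas.values())

    @pytest.mark.parametrize("seed", range(4))
    def test_weighted_effect_identities(self, seed):
        """sum(n_i beta_i) = 0 and intercept = read-weighted mean cluster logit."""
        rng = np.random.default_rng(seed)
        obs = [
            model.Observation(f"c{i}", int(rng.integers(20, 500)), int(rng.integers(20, 500)))
            for i in range(5)
        ]
        betas, _, fit = model.fit_logistic_all_clusters(obs)
        n = {o.cluster: o.total for o in obs}
        assert sum(n[c] * b for c, b in betas.items()) == pytest.approx(0.0, abs=1e-5)
        logits = {o.cluster: np.log(o.long / o.short) for o in obs}
        wmean = sum(n[c] * logits[c] for c in n) / sum(n.values())
        assert fit.params["intercept"] == pytest.approx(wmean, abs=1e-6)

    def test_two_reference_fits_agree_on_shared_clusters(self):
        rng = np.random.default_rng(5)
        obs = [model.Observation(f"c{i}", int(rng.integers(30, 300)),
                                 int(rng.integers(30, 300))) for i in range(4)]
        ref_a = model.DesignSpec.from_observations(obs, "c3")
        ref_b = model.DesignSpec.from_observations(obs, "c0")
        fa = model.fit_logistic(obs, ref_a)
        fb = model.fit_logistic(obs, ref_b)
        for c in ("c1", "c2"):
            assert fa.params[f"cluster[{c}]"] == pytest.approx(
                fb.params[f"cluster[{c}]"], abs=1e-6)

    def test_scaling_one_cluster_moves_intercept_with_its_weight(self):
        base = [model.Observation("a", 80, 20), model.Observation("b", 20, 80)]
        scaled = [model.Observation("a", 800, 200), model.Observation("b", 20, 80)]
        _, _, fit = model.fit_logistic_all_clusters(scaled)
        n = {"a": 1000, "b": 100}
        logits = {"a": np.log(4), "b": -np.log(4)}
        wmean = sum(n[c] * logits[c] for c in n) / 1100
        assert fit.params["intercept"] == pytest.approx(wmean, abs=1e-6)


class TestLrt:
    def test_g_statistic_on_crossed_table(self):
        obs = [model.Observation("c1", 80, 20), model.Observation("c2", 20, 80)]
        res = model.test_gene(obs, "g")
        # hand-computed G = 2 sum O ln(O/E) with all E = 50
        g = 2 * (2 * 80 * np.log(80 / 50) + 2 * 20 * np.log(20 / 50))
        assert res.lrt_stat == pytest.approx(g, rel=1e-6)
        assert res.lrt_stat == pytest.approx(77.10, abs=0.01)

    def test_equal_proportions_null(self):
        obs = [model.Observation(k, 50, 50) for k in "ab"]
        res = model.test_gene(obs, "g")
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.lrt_p == pytest.approx(1.0, abs=1e-6)

    def test_non_nested_errors(self):
        with pytest.raises(ValueError, match="nested"):
            model.lrt_across_cell_types(-10.0, -12.0, 0)


class TestBhAdjust:
    def test_worked_example(self):
        q = model.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        assert model.bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert model.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_qvalues_bounded_and_ge_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = model.bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)


class TestEffectGateAndDirections:
    def test_gate_examples(self):
        assert model.effect_size_gate({"a": np.log(4)})            # |log2 OR| = 2
        assert not model.effect_size_gate({"a": 0.0, "b": 0.0})
        assert not model.effect_size_gate({k: 0.10 * np.log(2) for k in "abc"})

    @pytest.mark.parametrize("odds,q,expected", [
        (4.0, 1e-6, "lengthening"),
        (0.4, 1e-6, "shortening"),
        (1.5, 1e-6, "none"),     # inside the 2-fold band
        (4.0, 0.2, "none"),      # not significant
    ])
    def test_direction_calls(self, odds, q, expected):
        assert model.cell_type_direction(odds, q) == expected


class TestMultinomial:
    def test_identical_usage_is_null(self):
        mf = model.fit_multinomial({k: [30, 30, 30] for k in "abc"})
        assert mf.lrt_p == pytest.approx(1.0, abs=1e-4)

    def test_two_sites_reduce_to_binomial(self):
        obs = [model.Observation("c1", 70, 30), model.Observation("c2", 35, 65)]
        binom = model.test_gene(obs, "g")
        multi = model.fit_multinomial({"c1": [70, 30], "c2": [35, 65]})
        assert multi.lrt_stat == pytest.approx(binom.lrt_stat, abs=1e-5)

    def test_zero_category_collapsed(self):
        mf = model.fit_multinomial({"a": [10, 0, 30], "b": [20, 0, 20]})
        assert mf.site_labels == ["site1", "site3"]


class TestConfounderAdjustment:
    @staticmethod
    def obs_grid(spec):
        """spec: {(cluster, region): (long, short)} -> observation rows."""
        return [
            model.Observation(c, l, s, (("region", r),))
            for (c, r), (l, s) in spec.items()
        ]

    def region_driven(self):
        # region drives PDUI; region is unbalanced across clusters
        return self.obs_grid({
            ("A", "r1"): (180, 720), ("A", "r2"): (80, 20),
            ("B", "r1"): (20, 80), ("B", "r2"): (720, 180),
        })

    def cluster_driven(self):
        # cluster drives PDUI; regions balanced within clusters
        return self.obs_grid({
            ("A", "r1"): (400, 100), ("A", "r2"): (400, 100),
            ("B", "r1"): (100, 400), ("B", "r2"): (100, 400),
        })

    def null_gene(self):
        return self.obs_grid({
            ("A", "r1"): (250, 250), ("A", "r2"): (250, 250),
            ("B", "r1"): (250, 250), ("B", "r2"): (250, 250),
        })

    def test_difference_set_flags_covariate_driven_gene(self):
        genes = {"region_gene": self.region_driven(),
                 "cluster_gene": self.cluster_driven(),
                 "null_gene": self.null_gene()}
        adjusted, unadjusted, diff = model.confounder_adjusted_run(genes)
        adj = {r.gene_id: r.significant for r in adjusted}
        unadj = {r.gene_id: r.significant for r in unadjusted}
        assert unadj["region_gene"] and not adj["region_gene"]
        assert adj["cluster_gene"] and unadj["cluster_gene"]
        assert not adj["null_gene"] and not unadj["null_gene"]
        assert diff == ["region_gene"]

    def test_single_level_covariate_is_identity(self):
        obs = [
            model.Observation("A", 300, 100, (("region", "r1"),)),
            model.Observation("B", 100, 300, (("region", "r1"),)),
        ]
        adjusted, unadjusted, diff = model.confounder_adjusted_run({"g": obs})
        assert adjusted[0].lrt_stat == pytest.approx(unadjusted[0].lrt_stat, rel=1e-9)
        assert diff == []

    def test_collinear_covariate_errors(self):
        obs = [
            model.Observation("A", 300, 100, (("region", "r1"),)),
            model.Observation("B", 100, 300, (("region", "r2"),)),
        ]
        with pytest.raises(ValueError, match="collinear"):
            model.confounder_adjusted_run({"g": obs})
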