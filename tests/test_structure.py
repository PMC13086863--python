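"""Frequencies, joint SFS, Hudson FST, PCA, hybrid index."""

import numpy as np
import pandas as pd
import pytest

import loxpop as lp
from loxpop import simdata
from loxpop.vcfio import MISSING

from conftest import make_gm, make_meta


class TestPopulationFrequencies:
    def test_counting_example(self):
        gm = make_gm([[1], [2]])
        meta = make_meta(gm, ["p1", "p1"])
        pf = lp.population_frequencies(gm, meta)
        assert pf.p["p1"][0] == pytest.approx(3 / 4)
        assert pf.n["p1"][0] == 4

    def test_polarization_identity(self):
        # ancestral == alt: derived frequency = 1 - alt frequency
        gm = make_gm([[1], [2]], ancestral="G", ref="A", alt="G")
        meta = make_meta(gm, ["p1", "p1"])
        pf_alt = lp.population_frequencies(gm, meta, polarize=False)
        pf_der = lp.population_frequencies(gm, meta, polarize=True)
        assert pf_der.p["p1"][0] == pytest.approx(1 - pf_alt.p["p1"][0])

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(0)
        g = rng.choice([0, 1, 2, MISSING], size=(20, 100),
                       p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8)
        gm = make_gm(g)
        pops = ["pA"] * 10 + ["pB"] * 10
        pf = lp.population_frequencies(gm, make_meta(gm, pops))
        for name, rows in (("pA", range(10)), ("pB", range(10, 20))):
            for j in range(100):
                vals = [g[i, j] for i in rows if g[i, j] != MISSING]
                if vals:
                    assert pf.p[name][j] == pytest.approx(sum(vals) / (2 * len(vals)))
                    assert pf.n[name][j] == 2 * len(vals)
                else:
                    assert np.isnan(pf.p[name][j])

    def test_empty_population_errors(self):
        gm = make_gm([[MISSING], [0]])
        meta = make_meta(gm, ["p1", "p2"])
        with pytest.raises(ValueError, match="p1"):
            lp.population_frequencies(gm, meta)


class TestJointSfs:
    def test_fixed_ancestral_single_count(self):
        gm = make_gm([[0], [0]])
        meta = make_meta(gm, ["pA", "pB"])
        sfs = lp.joint_sfs(gm, meta, "pA", "pB")
        assert sfs.counts[0, 0] == 1 and sfs.counts.sum() == 1

    def test_total_equals_complete_sites(self):
        rng = np.random.default_rng(1)
        g = rng.choice([0, 1, 2, MISSING], size=(8, 200),
                       p=[0.4, 0.3, 0.25, 0.05]).astype(np.int8)
        gm = make_gm(g)
        meta = make_meta(gm, ["pA"] * 4 + ["pB"] * 4)
        sfs = lp.joint_sfs(gm, meta, "pA", "pB")
        complete = (g != MISSING).all(axis=0)
        assert sfs.n_sites == int(complete.sum())

    def test_matches_per_site_tabulation(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=(6, 150)).astype(np.int8)
        gm = make_gm(g)
        meta = make_meta(gm, ["pA"] * 3 + ["pB"] * 3)
        sfs = lp.joint_sfs(gm, meta, "pA", "pB")
        expected = np.zeros((7, 7), dtype=int)
        for j in range(150):
            expected[g[:3, j].sum(), g[3:, j].sum()] += 1
        assert np.array_equal(sfs.counts, expected)


class TestHudsonFst:
    def _pf(self, pa, pb, na=10, nb=10):
        k = len(pa)
        return lp.PopulationFrequencies(
            populations=["a", "b"],
            p={"a": np.asarray(pa, float), "b": np.asarray(pb, float)},
            n={"a": np.full(k, na), "b": np.full(k, nb)},
            sites=pd.DataFrame({"chrom": ["chr1"] * k,
                                "pos": np.arange(1, k + 1) * 1000}),
        )

    def test_fixed_difference_is_one(self):
        pf = self._pf([1.0], [0.0], na=4, nb=20)
        assert lp.hudson_fst(pf, "a", "b") == pytest.approx(1.0)

    def test_symmetric_in_populations(self):
        rng = np.random.default_rng(3)
        pf = self._pf(rng.random(50), rng.random(50))
        assert lp.hudson_fst(pf, "a", "b") == pytest.approx(
            lp.hudson_fst(pf, "b", "a"))

    def test_no_differentiation_near_zero(self):
        # random split of one pool: FST ~ 0 within sampling noise
        rng = np.random.default_rng(4)
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 2000),
                         size=(40, 2000)).astype(np.int8)
        gm = make_gm(g)
        pf = lp.population_frequencies(
            gm, make_meta(gm, ["a"] * 20 + ["b"] * 20))
        assert abs(lp.hudson_fst(pf, "a", "b")) < 0.01

    def test_frequency_and_sfs_routes_agree_exactly(self):
        cfg = lp.SimulationConfig(
            seed=9, n_sites=3000,
            populations=[simdata.PopulationSpec("a", "s", 8, 0.05),
                         simdata.PopulationSpec("b", "s", 8, 0.05)],
            species_drift=0.0)
        gm, meta, _ = lp.simulate_cohort(cfg)
        pf = lp.population_frequencies(gm, meta)
        sfs = lp.joint_sfs(gm, meta, "a", "b")
        assert lp.hudson_fst(pf, "a", "b") == pytest.approx(
            lp.hudson_fst_from_sfs(sfs), rel=1e-12)


class TestPca:
    def test_two_fixed_clusters_separate_on_pc1(self):
        g = np.vstack([np.zeros((5, 50)), np.full((5, 50), 2)]).astype(np.int8)
        # add one polymorphic-within column so variance scaling is defined
        rng = np.random.default_rng(5)
        g[:, 0] = rng.binomial(2, 0.5, 10)
        res = lp.pca(make_gm(g))
        pc1 = res.scores[:, 0]
        assert (np.sign(pc1[:5]) == np.sign(pc1[0])).all()
        assert (np.sign(pc1[5:]) == -np.sign(pc1[0])).all()
        assert res.explained_variance_fraction[0] > 0.8

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.4, size=(6, 100)).astype(np.int8)
        g[5] = g[4]
        res = lp.pca(make_gm(g))
        np.testing.assert_allclose(res.scores[4], res.scores[5], atol=1e-10)

    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 200),
                         size=(20, 200)).astype(np.int8)
        res = lp.pca(make_gm(g))
        # independent oracle: dense eigendecomposition of the standardized
        # genotype covariance
        x = g.astype(float)
        p = x.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        x = (x[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        w, v = np.linalg.eigh(x @ x.T)
        order = np.argsort(w)[::-1]
        for c in range(3):
            expected = v[:, order[c]] * np.sqrt(w[order[c]])
            got = res.scores[:, c]
            sign = np.sign(expected @ got)
            np.testing.assert_allclose(got, sign * expected, atol=1e-8)

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.5, size=(10, 80)).astype(np.int8)
        res = lp.pca(make_gm(g))
        evf = res.explained_variance_fraction
        assert (np.diff(evf) <= 1e-12).all()
        assert evf.sum() <= 1 + 1e-9


class TestHybridIndex:
    def _pca_result(self, pc1):
        scores = np.column_stack([pc1, np.zeros(len(pc1))])
        return lp.PcaResult(scores=scores,
                            explained_variance_fraction=np.array([1.0, 0.0]),
                            loadings=np.zeros((2, 2)),
                            sample_ids=[f"s{i}" for i in range(len(pc1))])

    def test_anchor_endpoints(self):
        res = self._pca_result([-2.0, 3.0, 0.5])
        est = lp.pc1_hybrid_index(res, "s0", "s1")
        assert est.hybrid_index["s0"] == pytest.approx(1.0)  # savanna anchor
        assert est.hybrid_index["s1"] == pytest.approx(0.0)  # forest anchor
        assert est.hybrid_index["s2"] == pytest.approx(0.5)

    def test_affine_invariance(self):
        pc1 = np.array([-2.0, 3.0, 0.7, 5.0])
        a = lp.pc1_hybrid_index(self._pca_result(pc1), "s0", "s1")
        b = lp.pc1_hybrid_index(self._pca_result(3.7 * pc1 - 11), "s0", "s1")
        np.testing.assert_allclose(a.hybrid_index, b.hybrid_index, atol=1e-12)

    def test_identical_anchors_error(self):
        res = self._pca_result([1.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            lp.pc1_hybrid_index(res, "s0", "s1")

    def test_orient_forest_flips(self):
        res = self._pca_result([-2.0, 3.0, 0.5])
        est = lp.pc1_hybrid_index(res, "s0", "s1", orient="forest")
        assert est.hybrid_index["s1"] == pytest.approx(1.0)
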