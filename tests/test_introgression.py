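"""f4/D statistics, block jackknife, F4 ratio, Mantel, great-circle geometry."""

import numpy as np
import pandas as pd
import pytest

import loxpop as lp
from loxpop import simdata
from loxpop.introgression import EARTH_RADIUS_KM


def pf_from_freqs(sites=None, **freqs):
    k = len(next(iter(freqs.values())))
    sites = sites if sites is not None else pd.DataFrame(
        {"chrom": ["chr1"] * k, "pos": np.arange(1, k + 1) * 1000})
    return lp.PopulationFrequencies(
        populations=list(freqs),
        p={n: np.asarray(v, float) for n, v in freqs.items()},
        n={n: np.full(k, 20) for n in freqs},
        sites=sites,
    )


class TestBlockPartition:
    def test_boundary_site_opens_new_block(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1, 5_000_001]})
        part = lp.block_partition(sites)
        assert part.n_blocks == 2

    def test_sites_within_one_mb_single_block(self):
        sites = pd.DataFrame({"chrom": ["chr1"] * 5,
                              "pos": [1, 100, 50_000, 500_000, 1_000_000]})
        assert lp.block_partition(sites).n_blocks == 1

    def test_matches_bruteforce_tiling(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 30_000_000), 500, replace=False))
        chrom = np.where(np.arange(500) < 300, "chr1", "chr2")
        pos[300:] = np.sort(pos[300:])
        sites = pd.DataFrame({"chrom": chrom, "pos": pos})
        part = lp.block_partition(sites, block_size_bp=4_000_000)
        # brute-force greedy tiling
        expected = np.zeros(500, dtype=int)
        cur, start = 0, pos[0]
        for i in range(1, 500):
            if chrom[i] != chrom[i - 1] or pos[i] - start >= 4_000_000:
                cur += 1
                start = pos[i]
            expected[i] = cur
        assert np.array_equal(part.block_ids, expected)
        assert part.block_ids[0] == 0
        assert np.all(np.diff(part.block_ids) >= 0)


class TestBlockJackknife:
    def test_identical_block_ratios_zero_se(self):
        jk = lp.block_jackknife(np.array([2.0, 4.0, 6.0]),
                                np.array([4.0, 8.0, 12.0]))
        assert jk.estimate == pytest.approx(0.5)
        assert jk.se == pytest.approx(0.0, abs=1e-12)

    def test_two_block_leave_one_out_values(self):
        jk = lp.block_jackknife(np.array([1.0, 3.0]), np.array([2.0, 2.0]),
                                weights=np.array([1.0, 1.0]))
        # leaving out block 1 keeps block 2's ratio and vice versa
        assert sorted(jk.block_values.tolist()) == [0.5, 1.5]
        assert jk.estimate == pytest.approx(1.0)

    def test_equal_weights_reduce_to_plain_jackknife(self):
        rng = np.random.default_rng(1)
        num = rng.random(20) + 1
        den = rng.random(20) + 2
        jk = lp.block_jackknife(num, den, weights=np.ones(20))
        # naive unweighted delete-one jackknife
        theta = num.sum() / den.sum()
        loo = np.array([(num.sum() - num[i]) / (den.sum() - den[i])
                        for i in range(20)])
        se = np.sqrt((19 / 20) * ((loo - loo.mean()) ** 2).sum())
        assert jk.se == pytest.approx(se, rel=1e-10)
        assert jk.estimate == pytest.approx(theta)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            lp.block_jackknife(np.array([1.0]), np.array([2.0]))


class TestF4:
    def test_identical_sister_terms_zero(self):
        rng = np.random.default_rng(2)
        px = rng.random(100)
        pf = pf_from_freqs(A=rng.random(100), O=rng.random(100), X=px, B=px)
        part = lp.block_partition(pf.sites, block_size_bp=10_000)
        assert lp.f4(pf, "A", "O", "X", "B", part).estimate == pytest.approx(0.0)

    def test_single_site_value(self):
        pf = pf_from_freqs(A=[1.0], O=[0.0], X=[1.0], B=[0.0])
        part = lp.block_partition(pf.sites)
        assert lp.f4(pf, "A", "O", "X", "B", part).estimate == pytest.approx(1.0)

    def test_two_site_mean(self):
        pf = pf_from_freqs(A=[1, 0], O=[0, 1], X=[1, 1], B=[0, 0])
        part = lp.block_partition(pf.sites)
        assert lp.f4(pf, "A", "O", "X", "B", part).estimate == pytest.approx(0.0)


class TestDStatistic:
    def test_equal_h1_h2_gives_zero(self):
        rng = np.random.default_rng(3)
        p12 = rng.random(50)
        pf = pf_from_freqs(H1=p12, H2=p12, H3=rng.random(50),
                           H4=rng.random(50))
        part = lp.block_partition(pf.sites, block_size_bp=10_000)
        assert lp.d_statistic(pf, "H1", "H2", "H3", "H4", part
                              ).estimate == pytest.approx(0.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        pf = pf_from_freqs(**{k: rng.random(200) for k in "ABCD"})
        part = lp.block_partition(pf.sites, block_size_bp=20_000)
        d1 = lp.d_statistic(pf, "A", "B", "C", "D", part)
        d2 = lp.d_statistic(pf, "B", "A", "C", "D", part)
        assert d1.estimate == pytest.approx(-d2.estimate, rel=1e-12)
        assert d1.z == pytest.approx(-d2.z, rel=1e-9)

    def test_all_zero_denominator_errors(self):
        pf = pf_from_freqs(H1=[1.0], H2=[1.0], H3=[1.0], H4=[1.0])
        part = lp.block_partition(pf.sites)
        with pytest.raises(ValueError, match="denominator"):
            lp.d_statistic(pf, "H1", "H2", "H3", "H4", part)


class TestF4Ratio:
    def _sim_pf(self, alpha, seed, n_sites=30_000):
        cfg = simdata.preset("trace-introgression", seed=seed,
                             n_sites=n_sites)
        cfg.admixture_pulses = [
            simdata.AdmixturePulse("forest_C", "savanna_X", alpha)]
        cfg.__post_init__()
        gm, meta, _ = lp.simulate_cohort(cfg)
        return lp.population_frequencies(gm, meta)

    def test_unadmixed_reference_alpha_zero(self):
        rng = np.random.default_rng(5)
        pa, po, pb, pc = (rng.random(2000) for _ in range(4))
        pf = pf_from_freqs(A=pa, O=po, X=pb, B=pb, C=pc)
        part = lp.block_partition(pf.sites, block_size_bp=200_000)
        est = lp.f4_ratio(pf, "A", "O", "X", "B", "C", part,
                          min_denominator_z=0.0)
        assert est.alpha == pytest.approx(0.0, abs=1e-12)

    def test_fully_admixed_reference_alpha_one(self):
        rng = np.random.default_rng(6)
        pa, po, pb, pc = (rng.random(2000) for _ in range(4))
        pf = pf_from_freqs(A=pa, O=po, X=pc, B=pb, C=pc)
        part = lp.block_partition(pf.sites, block_size_bp=200_000)
        est = lp.f4_ratio(pf, "A", "O", "X", "B", "C", part,
                          min_denominator_z=0.0)
        assert est.alpha == pytest.approx(1.0, abs=1e-12)

    def test_recovers_pulse_proportion(self):
        pf = self._sim_pf(0.2, seed=11)
        est = lp.f4_ratio(
            pf, "forest_A", "outgroup", "savanna_X", "savanna_B", "forest_C",
            lp.block_partition(pf.sites),
        )
        assert abs(est.alpha - 0.2) <= 3 * est.se

    def test_unstable_denominator_raises_with_context(self):
        rng = np.random.default_rng(7)
        pa, po, pb = (rng.random(500) for _ in range(3))
        # C == B: denominator f4 identically zero
        pf = pf_from_freqs(A=pa, O=po, X=rng.random(500), B=pb, C=pb)
        part = lp.block_partition(pf.sites, block_size_bp=100_000)
        with pytest.raises(lp.UnstableRatioError) as exc:
            lp.f4_ratio(pf, "A", "O", "X", "B", "C", part)
        assert exc.value.f4_den is not None


class TestJackknifeScaling:
    def test_se_shrinks_as_inverse_sqrt_sites(self):
        """On iid sites, jackknife SE of f4 scales ~ n^-1/2 (log-log slope)."""
        rng = np.random.default_rng(8)
        sizes = [2000, 8000, 32_000]
        ses = []
        for n in sizes:
            freqs = {k: rng.random(n) for k in ("A", "O", "X", "B")}
            pos = np.sort(rng.choice(np.arange(1, 100_000_000), n,
                                     replace=False))
            pf = pf_from_freqs(
                sites=pd.DataFrame({"chrom": ["chr1"] * n, "pos": pos}),
                **freqs)
            part = lp.block_partition(pf.sites)
            ses.append(lp.f4(pf, "A", "O", "X", "B", part).se)
        slope = np.polyfit(np.log(sizes), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestMantel:
    @staticmethod
    def _dist(n, rng):
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        return d

    def test_identical_matrices_perfect_concordance(self):
        a = self._dist(8, np.random.default_rng(0))
        res = lp.mantel_test(a, a, n_perm=999, seed=1)
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_rank_reversal_gives_minus_one(self):
        a = self._dist(8, np.random.default_rng(1))
        b = a.max() + 1 - a
        np.fill_diagonal(b, 0)
        assert lp.mantel_test(a, b, n_perm=99, seed=2).rho == pytest.approx(-1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        a, b = self._dist(7, rng), self._dist(7, rng)
        r1 = lp.mantel_test(a, b, n_perm=499, seed=7)
        r2 = lp.mantel_test(a, b, n_perm=499, seed=7)
        assert r1.p == r2.p and r1.rho == r2.rho

    def test_rho_matches_scipy_spearman(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(3)
        a, b = self._dist(9, rng), self._dist(9, rng)
        i, j = np.tril_indices(9, k=-1)
        expected = spearmanr(a[i, j], b[i, j]).statistic
        assert lp.mantel_test(a, b, n_perm=9, seed=0).rho == pytest.approx(expected)

    def test_input_validation(self):
        a = self._dist(5, np.random.default_rng(4))
        with pytest.raises(ValueError):
            lp.mantel_test(a, a[:4, :4])
        with pytest.raises(ValueError):
            lp.mantel_test(np.zeros((5, 5)), a)


class TestDistanceToForest:
    def test_point_on_vertex_zero(self):
        boundary = [np.array([[0.0, 10.0], [1.0, 10.0]])]
        d = lp.distance_to_forest(np.array([[0.0, 10.0]]), boundary)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_latitude(self):
        boundary = [np.array([[0.0, 20.0], [0.0, 20.1]])]
        d = lp.distance_to_forest(np.array([[1.0, 20.0]]), boundary)
        assert d[0] == pytest.approx(np.pi * EARTH_RADIUS_KM / 180, rel=1e-3)

    def test_antipodal_maximum(self):
        boundary = [np.array([[0.0, 0.0]])]
        d = lp.distance_to_forest(np.array([[0.0, 180.0]]), boundary)
        assert d[0] == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-3)

    def test_densification_beats_sparse_vertices(self):
        # point near the middle of a long edge: densified boundary must be
        # much closer than either endpoint
        boundary = [np.array([[0.0, 10.0], [0.0, 20.0]])]
        d = lp.distance_to_forest(np.array([[0.5, 15.0]]), boundary)
        assert d[0] < 60  # ~55.6 km to the midpoint vs ~560 km to endpoints

    def test_empty_boundary_errors(self):
        with pytest.raises(ValueError):
            lp.distance_to_forest(np.array([[0.0, 0.0]]), [])
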