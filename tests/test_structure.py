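"""FST, AMOVA, Mantel, binary encoding and co-inertia."""

import numpy as np
import pandas as pd
import pytest

import mhcpop as m
from mhcpop.popgen_stats import MicrosatGenotypeTable
from mhcpop.structure_compare import (
    DistanceBundle,
    binary_encode,
    geographic_distance_matrix,
    microsat_distance_matrix,
    rv_coefficient,
)

from test_popgen import make_table


class TestDistances:
    @pytest.mark.parametrize("g1,g2,want", [
        ((1, 2), (1, 2), 0), ((1, 1), (1, 2), 1), ((1, 1), (2, 2), 2),
        ((1, 2), (3, 4), 2), ((1, 2), (2, 3), 1), ((1, 1), (1, 1), 0),
    ])
    def test_allele_sharing_distance(self, g1, g2, want):
        t = make_table({"i1": g1, "i2": g2}, {"i1": "p", "i2": "p"})
        d = microsat_distance_matrix(t)
        assert d[0, 1] == want

    def test_distance_sums_over_loci(self):
        genos = {"i1": [(1, 2), (3, 3)], "i2": [(1, 1), (4, 4)]}
        t = make_table(genos, {"i1": "p", "i2": "p"})
        d = microsat_distance_matrix(t)
        assert d[0, 1] == 1 + 2

    def test_great_circle_equator_degree(self):
        # one degree of longitude at the equator is about 111.2 km
        coords = pd.DataFrame({"lat": [0.0, 0.0], "lon": [0.0, 1.0]},
                              index=["a", "b"])
        dm = geographic_distance_matrix(coords)
        assert dm.loc["a", "b"] == pytest.approx(111.19, abs=0.2)


class TestAmova:
    def test_no_variance_all_within(self):
        res = m.amova(np.zeros((8, 8)), ["p1"] * 4 + ["p2"] * 4,
                      n_perm=49, seed=0)
        assert res.percentages["within_populations"] == 100.0

    def test_hand_worked_haploid_toy(self):
        """Two fixed populations of two haploid units each: SS_total = 1,
        SS_within = 0, n0 = 2 -> sigma_a = 0.5, 100% among."""
        seqs = [0, 0, 1, 1]
        d2 = np.array([[0.0 if a == b else 1.0 for b in seqs]
                       for a in seqs])
        res = m.amova(d2, ["p1", "p1", "p2", "p2"], n_perm=999, seed=1)
        assert res.components["among_populations"] == pytest.approx(0.5)
        assert res.components["within_populations"] == pytest.approx(0.0)
        assert res.percentages["among_populations"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, small_library):
        model = m.PopulationModel(n_pops=4, pop_sizes=(10, 12, 8, 10),
                                  theta_fst=0.15)
        _, micro, _ = m.simulate_populations(model, small_library, 6,
                                             seed=31)
        d2 = microsat_distance_matrix(micro)
        pops = [micro.populations[i] for i in micro.individuals]
        groups = {"pop1": "g1", "pop2": "g1", "pop3": "g2", "pop4": "g2"}
        res = m.amova(d2, pops, pop_groups=groups, n_perm=49, seed=2)
        assert sum(res.percentages.values()) == pytest.approx(100.0)
        assert set(res.p_values) == {"among_groups",
                                     "among_populations_within_groups"}

    def test_single_level_amova_matches_pairwise_fst(self, small_library):
        model = m.PopulationModel(n_pops=2, pop_sizes=(15, 15),
                                  theta_fst=0.2)
        _, micro, _ = m.simulate_populations(model, small_library, 6,
                                             seed=32)
        d2 = microsat_distance_matrix(micro)
        pops = [micro.populations[i] for i in micro.individuals]
        res = m.amova(d2, pops, n_perm=0, seed=0)
        fst, _ = m.fst_matrix(micro, "microsat_alleles", n_perm=0, seed=0)
        assert res.phi_st == pytest.approx(fst.loc["pop1", "pop2"])


class TestFstMatrix:
    def test_identical_frequencies_near_zero(self, small_library):
        model = m.PopulationModel(n_pops=2, pop_sizes=(30, 30),
                                  theta_fst=1e-6)
        _, micro, _ = m.simulate_populations(model, small_library, 10,
                                             seed=33)
        fst, _ = m.fst_matrix(micro, "microsat_alleles", n_perm=0, seed=0)
        assert abs(fst.loc["pop1", "pop2"]) < 0.05

    def test_fixed_difference_is_one(self):
        genos = {"a1": (1, 1), "a2": (1, 1), "b1": (2, 2), "b2": (2, 2)}
        t = make_table(genos, {"a1": "p1", "a2": "p1",
                               "b1": "p2", "b2": "p2"})
        fst, pv = m.fst_matrix(t, "microsat_alleles", n_perm=99, seed=0)
        assert fst.loc["p1", "p2"] == pytest.approx(1.0)

    def test_ordering_with_drift_intensity(self, small_library):
        """Stronger drift must give larger FST (paired seeds)."""
        wins = 0
        for seed in range(10):
            est = {}
            for theta in (0.05, 0.15):
                model = m.PopulationModel(n_pops=2, pop_sizes=(25, 25),
                                          theta_fst=theta)
                _, micro, _ = m.simulate_populations(model, small_library,
                                                     10, seed=seed)
                est[theta] = m.weir_cockerham_fst(micro)
            wins += est[0.15] > est[0.05]
        assert wins >= 9

    def test_mhc_jc_mode_runs(self, study):
        seqs = dict(study["library"].alleles)
        fst, pv = m.fst_matrix(study["mhc"], "mhc_jc",
                               population_map=study["pop_map"],
                               allele_seqs=seqs, n_perm=49, seed=0)
        assert fst.shape == (2, 2)
        assert np.isfinite(fst.loc["west", "east"])


class TestMantel:
    def _random_sym(self, rng, n):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_identity_correlation_one(self):
        rng = np.random.default_rng(1)
        d = self._random_sym(rng, 10)
        r, p = m.mantel(d, d, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(2)
        d1 = self._random_sym(rng, 9)
        d2 = self._random_sym(rng, 9)
        perm = rng.permutation(9)
        r_a, _ = m.mantel(d1, d2, n_perm=9, seed=0)
        r_b, _ = m.mantel(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)],
                          n_perm=9, seed=0)
        assert r_a == pytest.approx(r_b)

    def test_agrees_with_skbio_mantel(self):
        """Cross-check the statistic and permutation p against the
        independent scikit-bio implementation."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(11)
        base = self._random_sym(rng, 10)
        d2 = base + self._random_sym(rng, 10) * 0.3
        r_mine, p_mine = m.mantel(base, d2, n_perm=999, seed=0)
        r_ref, p_ref, _ = skbio_mantel(DistanceMatrix(base),
                                       DistanceMatrix(d2),
                                       permutations=999)
        assert r_mine == pytest.approx(r_ref)
        assert p_mine == pytest.approx(p_ref, abs=0.05)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            m.mantel(np.zeros((5, 5)), np.eye(5) * 0, n_perm=9, seed=0)

    def test_partial_with_control_equal_to_signal(self):
        rng = np.random.default_rng(3)
        d1 = self._random_sym(rng, 8)
        r, p = m.partial_mantel(d1, d1.copy(), d1, n_perm=99, seed=0)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_partial_removes_shared_component(self):
        rng = np.random.default_rng(4)
        control = self._random_sym(rng, 12)
        noise1 = self._random_sym(rng, 12) * 0.1
        noise2 = self._random_sym(rng, 12) * 0.1
        d1, d2 = control + noise1, control + noise2
        r_plain, _ = m.mantel(d1, d2, n_perm=9, seed=0)
        r_part, _ = m.partial_mantel(d1, d2, control, n_perm=9, seed=0)
        assert abs(r_part) < abs(r_plain)


class TestBinaryEncoding:
    def test_diploid_presence(self):
        genos = {"i1": (1, 2), "i2": (1, 1), "i3": (3, 3)}
        t = make_table(genos, {i: "p" for i in genos})
        b = binary_encode(t, "microsat")
        assert b.loc["i1"].tolist() == [1, 1, 0]
        assert b.loc["i2"].tolist() == [1, 0, 0]  # dosage lost by design

    def test_row_sums_bounded(self, study):
        b_mhc = binary_encode(study["mhc"], "mhc")
        assert b_mhc.values.sum(axis=1).min() >= 1
        assert b_mhc.values.sum(axis=1).max() <= 4
        b_ms = binary_encode(study["microsat"], "microsat")
        # per locus block: 1 or 2 ones per individual
        for loc in study["microsat"].loci:
            block = b_ms[[c for c in b_ms.columns
                          if c.startswith(loc + ".")]]
            sums = block.sum(axis=1)
            assert sums.between(1, 2).all()

    def test_mhc_set_encoding(self):
        sets = {"i1": {"H01", "H07", "H16"}, "i2": {"H16"}}
        b = binary_encode(sets, "mhc")
        assert b.loc["i1"].sum() == 3
        assert b.loc["i2"].sum() == 1


class TestCoinertia:
    def test_self_coinertia_rv_one(self, study):
        b = binary_encode(study["mhc"], "mhc")
        res = m.coinertia(b, b.copy(), study["pop_map"], n_boot=49, seed=0)
        assert res.rv == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_rv_bounds_and_rotation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.random((30, 4)) - 0.5
        y = rng.random((30, 4)) - 0.5
        rv = rv_coefficient(x, y)
        assert 0.0 <= rv <= 1.0
        q, _ = np.linalg.qr(rng.random((4, 4)))
        assert rv_coefficient(x @ q, y) == pytest.approx(rv)

    def test_independent_noise_rv_small(self):
        rng = np.random.default_rng(6)
        inds = [f"i{k}" for k in range(60)]
        pops = pd.Series({i: "p1" if k < 30 else "p2"
                          for k, i in enumerate(inds)})
        a = pd.DataFrame(rng.integers(0, 2, (60, 12)), index=inds)
        b = pd.DataFrame(rng.integers(0, 2, (60, 12)), index=inds)
        res = m.coinertia(a, b, pops, n_boot=199, seed=7)
        assert res.rv < 0.3
        assert res.p_value > 0.05

    def test_eigenvalues_nonincreasing(self, study):
        b_mhc = binary_encode(study["mhc"], "mhc")
        b_ms = binary_encode(study["microsat"], "microsat")
        b_ms = b_ms.loc[b_mhc.index]
        res = m.coinertia(b_mhc, b_ms, study["pop_map"], n_boot=9, seed=0)
        eig = res.eigenvalues
        assert (np.diff(eig) <= 1e-12).all() and (eig >= 0).all()

    def test_concordant_structure_shortens_population_vectors(self, library):
        """When both marker systems carry the same population signal the
        per-population score pairs lie closer together than when the
        second system is an independent permutation."""
        model = m.PopulationModel(n_pops=3, pop_sizes=(20, 20, 20),
                                  theta_fst=0.3)
        mhc, micro, pops = m.simulate_populations(model, library, 10,
                                                  seed=41)
        b = binary_encode(mhc, "mhc")
        rng = np.random.default_rng(8)

        res_same = m.coinertia(b, b.copy(), pops, n_boot=9, seed=0)
        shuffled = b.copy()
        shuffled[:] = b.values[rng.permutation(len(b))]
        res_rand = m.coinertia(b, shuffled, pops, n_boot=9, seed=0)

        def vec_len(res):
            d = res.pop_scores_a.values - res.pop_scores_b.values
            return np.linalg.norm(d, axis=1).mean()

        assert vec_len(res_same) < vec_len(res_rand)


class TestDistanceBundle:
    def test_validation_and_csv_round_trip(self, tmp_path):
        labels = ["a", "b", "c"]
        bundle = DistanceBundle(labels)
        mat = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        bundle.add("geo", mat)
        with pytest.raises(ValueError):
            bundle.add("bad", np.ones((3, 3)))
        path = tmp_path / "geo.csv"
        bundle.to_csv("geo", path)
        back = DistanceBundle.read_matrix_csv(path)
        assert np.allclose(back.values, mat)
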