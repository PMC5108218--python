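"""Diversity statistics, rarefaction, group tests, GenePop round trip."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import mhcpop as m
from mhcpop.popgen_stats import MicrosatGenotypeTable, rarefied_richness


def make_table(genos, pops, loci=None):
    """genos: dict individual -> list of (a, b) per locus."""
    inds = list(genos)
    arr = np.array([genos[i] for i in inds], dtype=int)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    loci = loci or [f"L{k+1}" for k in range(arr.shape[1])]
    return MicrosatGenotypeTable(inds, loci, arr,
                                 pd.Series(pops, name="population"))


class TestHeterozygosity:
    def test_two_homozygotes(self):
        t = make_table({"i1": (1, 1), "i2": (2, 2)},
                       {"i1": "p", "i2": "p"})
        res = m.heterozygosity_stats(t)
        assert res.loc["p", "Ho"] == 0.0
        assert res.loc["p", "He"] == 0.5

    def test_all_heterozygotes_negative_fis(self):
        t = make_table({f"i{k}": (1, 2) for k in range(6)},
                       {f"i{k}": "p" for k in range(6)})
        res = m.heterozygosity_stats(t)
        assert res.loc["p", "Ho"] == 1.0
        assert res.loc["p", "Fis"] < 0

    def test_fis_near_zero_under_random_mating(self, small_library):
        model = m.PopulationModel(n_pops=1, pop_sizes=(200,),
                                  theta_fst=1e-6)
        _, micro, _ = m.simulate_populations(model, small_library, 20,
                                             seed=11)
        fis = m.heterozygosity_stats(micro)["Fis"].iloc[0]
        assert abs(fis) < 0.03

    def test_he_invariant_to_allele_relabeling(self):
        t1 = make_table({"i1": (1, 2), "i2": (1, 1), "i3": (2, 2)},
                        {f"i{k}": "p" for k in (1, 2, 3)})
        t2 = make_table({"i1": (7, 9), "i2": (7, 7), "i3": (9, 9)},
                        {f"i{k}": "p" for k in (1, 2, 3)})
        a = m.heterozygosity_stats(t1)
        b = m.heterozygosity_stats(t2)
        assert a.loc["p", "He"] == b.loc["p", "He"]
        assert a.loc["p", "Fis"] == pytest.approx(b.loc["p", "Fis"])


def exhaustive_ar(copies, g):
    """Mean number of distinct alleles over all C(N, g) subsamples."""
    vals = [len(set(sub)) for sub in itertools.combinations(copies, g)]
    return np.mean(vals)


def exhaustive_par(copies_by_pop, focal, g):
    """Mean count of alleles in the focal subsample absent from every
    other population's subsample, over the full product of subsamples."""
    pops = list(copies_by_pop)
    others = [p for p in pops if p != focal]
    total, n_cases = 0.0, 0
    for sub_f in itertools.combinations(copies_by_pop[focal], g):
        for subs in itertools.product(
                *(itertools.combinations(copies_by_pop[p], g)
                  for p in others)):
            present_elsewhere = set().union(*map(set, subs)) if subs else set()
            total += len(set(sub_f) - present_elsewhere)
            n_cases += 1
    return total / n_cases


class TestRarefaction:
    def test_hand_example_n4(self):
        t = make_table({"i1": (1, 1), "i2": (2, 2)},
                       {"i1": "p", "i2": "p"})
        res = rarefied_richness(t, g=2)
        assert res.loc["p", "Ar"] == pytest.approx(5 / 3)

    def test_g_equal_n_gives_observed_count(self):
        t = make_table({"i1": (1, 2), "i2": (3, 3)},
                       {"i1": "p", "i2": "p"})
        res = rarefied_richness(t, g=4)
        assert res.loc["p", "Ar"] == 3.0

    @pytest.mark.parametrize("copies,g", [
        ((1, 1, 2, 2), 2),
        ((1, 1, 1, 2), 2),
        ((1, 2, 3, 4), 3),
        ((1, 1, 2, 2, 3, 3), 4),
        ((1, 1, 1, 1, 2, 3, 3, 4), 5),
    ])
    def test_matches_exhaustive_enumeration(self, copies, g):
        genos = {f"i{k}": (copies[2 * k], copies[2 * k + 1])
                 for k in range(len(copies) // 2)}
        t = make_table(genos, {i: "p" for i in genos})
        res = rarefied_richness(t, g=g)
        assert res.loc["p", "Ar"] == pytest.approx(exhaustive_ar(copies, g))

    def test_private_richness_matches_enumeration(self):
        copies = {"p1": (1, 1, 2, 2), "p2": (2, 2, 3, 3)}
        genos = {"a1": (1, 1), "a2": (2, 2), "b1": (2, 2), "b2": (3, 3)}
        t = make_table(genos, {"a1": "p1", "a2": "p1",
                               "b1": "p2", "b2": "p2"})
        res = rarefied_richness(t, g=2)
        for pop in ("p1", "p2"):
            assert res.loc[pop, "Par"] == pytest.approx(
                exhaustive_par(copies, pop, 2))

    def test_private_allele_only_in_owner(self):
        genos = {"a1": (1, 2), "a2": (1, 1), "b1": (1, 1), "b2": (1, 1)}
        t = make_table(genos, {"a1": "p1", "a2": "p1",
                               "b1": "p2", "b2": "p2"})
        res = rarefied_richness(t, g=2)
        assert res.loc["p1", "Par"] > 0
        assert res.loc["p2", "Par"] == pytest.approx(0.0)

    def test_monotone_in_g_and_bounded_at_two(self):
        genos = {f"i{k}": g for k, g in
                 enumerate([(1, 2), (2, 3), (3, 4), (1, 4)])}
        t = make_table(genos, {i: "p" for i in genos})
        prev = None
        for g in (2, 4, 6, 8):
            ar = rarefied_richness(t, g=g)["Ar"].iloc[0]
            if g == 2:
                assert ar <= 2.0
            if prev is not None:
                assert ar >= prev - 1e-12
            prev = ar

    def test_invalid_g_names_limit(self):
        t = make_table({"i1": (1, 2), "i2": (2, 2)},
                       {"i1": "p", "i2": "p"})
        with pytest.raises(ValueError, match="p"):
            rarefied_richness(t, g=10)


class TestMhcDiversity:
    def test_individual_diversity_definition(self):
        sets = {"i1": {"H01", "H02", "H03"}, "i2": {"H01"}}
        pops = pd.Series({"i1": "p", "i2": "p"})
        res = m.mhc_diversity(sets, pops)
        assert res.loc["p", "Ad_mean"] == pytest.approx((0.75 + 0.25) / 2)

    def test_monomorphic_population(self):
        sets = {"i1": {"H01"}, "i2": {"H01"}}
        pops = pd.Series({"i1": "p", "i2": "p"})
        res = m.mhc_diversity(sets, pops, {"H01": "AAAA"})
        assert res.loc["p", "H"] == 1
        assert res.loc["p", "k"] == 0.0

    def test_counts_match_simulated_truth(self, study):
        sets = study["mhc"]
        pops = study["pop_map"]
        res = m.mhc_diversity(sets, pops)
        for pop in res.index:
            inds = [i for i in sets if pops[i] == pop]
            want_h = len(set().union(*(sets[i] for i in inds)))
            assert res.loc[pop, "H"] == want_h
        # private counts: alleles in exactly one population
        all_pools = {p: set().union(*(sets[i] for i in sets
                                      if pops[i] == p))
                     for p in res.index}
        for pop in res.index:
            others = set().union(*(v for q, v in all_pools.items()
                                   if q != pop))
            assert res.loc[pop, "Hu"] == len(all_pools[pop] - others)


class TestGroupTests:
    def test_duplicated_groups_give_high_p(self, small_library):
        model = m.PopulationModel(n_pops=2, pop_sizes=(20, 20),
                                  theta_fst=1e-6)
        _, micro, _ = m.simulate_populations(model, small_library, 5,
                                             seed=13)
        # identical data in both groups: observed difference ~ 0
        obs, p = m.permutation_group_test("Ho", micro, ["pop1"], ["pop1"],
                                          n_perm=199, seed=1)
        assert obs == 0.0 and p == 1.0

    def test_detects_large_richness_difference(self, small_library):
        rng = np.random.default_rng(0)
        genos = {}
        pops = {}
        for k in range(30):  # few alleles
            genos[f"a{k}"] = rng.integers(1, 4, size=(3, 2))
            pops[f"a{k}"] = "low"
        for k in range(30):  # many alleles
            genos[f"b{k}"] = rng.integers(1, 9, size=(3, 2))
            pops[f"b{k}"] = "high"
        t = MicrosatGenotypeTable(
            list(genos), ["L1", "L2", "L3"],
            np.stack([genos[i] for i in genos]), pd.Series(pops))
        obs, p = m.permutation_group_test("Ar", t, ["high"], ["low"],
                                          n_perm=199, seed=2)
        assert obs > 0 and p < 0.05


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        vals = [1, 2, 3, 1, 2, 3]
        groups = ["a"] * 3 + ["b"] * 3
        F, dfb, dfw, p, _ = m.anova_tukey(vals, groups)
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_three_group_example(self):
        # hand-computed: group means 5, 9, 12; grand mean 26/3;
        # SSB = 888/9, SSW = 6, F = (888/18)/(6/9) = 74
        vals = [4, 5, 6, 5, 8, 9, 10, 9, 11, 12, 13, 12]
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        F, dfb, dfw, p, tukey = m.anova_tukey(vals, groups)
        assert (dfb, dfw) == (2, 9)
        assert F == pytest.approx(74.0)
        assert len(tukey) == 3

    def test_zero_variance_everywhere_undefined(self):
        F, *_ , tukey = m.anova_tukey([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert np.isnan(F) and tukey is None


class TestPearson:
    def test_perfect_linearity(self):
        r, p = m.pearson_corr([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            m.pearson_corr([1, 1, 1], [1, 2, 3])

    def test_published_summary_correlations(self):
        """Cross-marker correlations across the eight populations from the
        published diversity summary: microsatellite allelic richness vs
        MHC allele count, and private richness vs private MHC alleles."""
        t2 = m.load_diversity_summary()
        r, p = m.pearson_corr(t2["Ar"], t2["H"])
        assert round(r, 2) == 0.77 and p < 0.05
        r2, p2 = m.pearson_corr(t2["Pr"], t2["Hu"])
        assert round(r2, 2) == -0.02 and p2 > 0.9


class TestGenePop:
    def test_round_trip(self, tmp_path, small_library):
        model = m.PopulationModel(n_pops=3, pop_sizes=(8, 6, 7))
        _, micro, _ = m.simulate_populations(model, small_library, 4,
                                             seed=23)
        path = tmp_path / "test.gen"
        m.write_genepop(micro, path)
        back = m.read_genepop(path)
        assert back.loci == micro.loci
        assert np.array_equal(back.genotypes, micro.genotypes)
        # population block structure preserved
        got_sizes = [len(back.individuals_of(p)) for p in back.pops()]
        assert got_sizes == [8, 6, 7]

    def test_missing_data_round_trip(self, tmp_path):
        t = make_table({"i1": (1, 2), "i2": (-1, -1)},
                       {"i1": "p", "i2": "p"})
        path = tmp_path / "m.gen"
        m.write_genepop(t, path, digits=2)
        back = m.read_genepop(path)
        assert np.array_equal(back.genotypes, t.genotypes)
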