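"""Per-population diversity statistics for microsatellite and MHC data.

Microsatellite side: observed/expected heterozygosity, Weir–Cockerham
inbreeding coefficients, and rarefied allelic and private allelic richness
(the HP-RARE style combinatorial rarefaction).  MHC side: allele counts,
private alleles, individual diversity (called alleles / 4), and the mean
number of pairwise nucleotide differences among allele copies.  Group
comparisons: a permutation test over individuals and one-way ANOVA with
Tukey HSD post hoc contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1


@dataclass
class MicrosatGenotypeTable:
    """Diploid genotypes: individuals x loci x 2 allele labels.

    Allele labels are positive integers; missing alleles are coded -1
    (never 0).  ``populations`` maps individual id -> population name.
    """

    individuals: list
    loci: list
    genotypes: np.ndarray  # (n, L, 2) int
    populations: pd.Series

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("genotype array shape mismatch")
        valid = (self.genotypes > 0) | (self.genotypes == MISSING)
        if not valid.all():
            raise ValueError("allele labels must be positive (or -1 missing)")
        self._index = {ind: i for i, ind in enumerate(self.individuals)}

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    def individuals_of(self, pop: str):
        return [i for i in self.individuals if self.populations[i] == pop]

    def pops(self):
        return list(dict.fromkeys(self.populations[self.individuals]))

    def subset(self, individuals) -> "MicrosatGenotypeTable":
        idx = [self.index_of(i) for i in individuals]
        return MicrosatGenotypeTable(
            list(individuals), self.loci, self.genotypes[idx],
            self.populations[list(individuals)])

    def allele_counts(self, locus_idx: int, individuals=None) -> dict:
        """Allele label -> count of gene copies, missing excluded."""
        if individuals is None:
            g = self.genotypes[:, locus_idx]
        else:
            idx = [self.index_of(i) for i in individuals]
            g = self.genotypes[idx, locus_idx]
        vals, counts = np.unique(g[g != MISSING], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _wc_f_components(geno_locus: np.ndarray):
    """Weir–Cockerham within-population variance components at one locus.

    For a single population sample: per allele A with frequency p and
    heterozygote frequency h (share of individuals carrying A with one
    copy), b = n/(n-1) [p(1-p) - (2n-1)/(4n) h] is the between-individual
    and c = h/2 the within-individual component; f = 1 - sum c / sum (b+c)
    accumulated over alleles (and loci, for the multilocus estimator).
    """
    g = geno_locus[(geno_locus != MISSING).all(axis=1)]
    n = len(g)
    if n < 2:
        return 0.0, 0.0
    alleles = np.unique(g)
    b_sum = c_sum = 0.0
    for a in alleles:
        carries = (g == a).sum(axis=1)
        p = carries.mean() / 2.0
        h = np.mean(carries == 1)
        b = n / (n - 1.0) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
        c = h / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def heterozygosity_stats(table: MicrosatGenotypeTable,
                         pops=None, unbiased_he: bool = False) -> pd.DataFrame:
    """Per-population Ho, He and multilocus Weir–Cockerham F_IS.

    Ho is the fraction of heterozygous genotypes, averaged over loci.
    He = 1 - sum p^2 averaged over loci (the uncorrected gene diversity;
    ``unbiased_he`` applies the 2n/(2n-1) small-sample factor).  F_IS is
    the Weir–Cockerham multilocus estimator 1 - sum c / sum (b + c), with
    the variance components accumulated over loci and alleles;
    monomorphic loci contribute nothing to either sum.
    """
    pops = pops or table.pops()
    rows = []
    for pop in pops:
        inds = table.individuals_of(pop)
        idx = [table.index_of(i) for i in inds]
        ho_l, he_l = [], []
        b_tot = c_tot = 0.0
        for l in range(len(table.loci)):
            g = table.genotypes[idx, l]
            g = g[(g != MISSING).all(axis=1)]
            if len(g) < 2:
                continue
            ho = float(np.mean(g[:, 0] != g[:, 1]))
            _, counts = np.unique(g.ravel(), return_counts=True)
            p = counts / counts.sum()
            he = 1.0 - np.sum(p ** 2)
            if unbiased_he:
                n2 = counts.sum()
                he *= n2 / (n2 - 1.0)
            ho_l.append(ho)
            he_l.append(he)
            b, c = _wc_f_components(table.genotypes[idx, l])
            b_tot += b
            c_tot += c
        fis = 1.0 - c_tot / (b_tot + c_tot) if (b_tot + c_tot) > 0 else np.nan
        rows.append(dict(population=pop, n=len(inds),
                         Ho=float(np.mean(ho_l)), He=float(np.mean(he_l)),
                         Fis=fis))
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _presence_prob(n_total: int, n_allele: int, g: int) -> float:
    """P(allele present in a random subsample of g gene copies)."""
    if n_allele == 0:
        return 0.0
    return 1.0 - comb(n_total - n_allele, g) / comb(n_total, g)


def rarefied_richness(table: MicrosatGenotypeTable, pops=None,
                      g: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness A_r(g) and private allelic richness P_ar(g).

    A_r(g) at one locus is the expected number of distinct alleles in a
    random subsample of ``g`` gene copies, sum over alleles of
    1 - C(N - N_i, g)/C(N, g); P_ar(g) is the expected number of alleles
    present in the focal population's subsample but absent from every
    other population's subsample of the same size (the private-allele
    rarefaction of HP-RARE).  Both are averaged over loci.  ``g``
    defaults to the largest even size supported by every population and
    locus.
    """
    pops = pops or table.pops()
    idx_of = {p: [table.index_of(i) for i in table.individuals_of(p)]
              for p in pops}
    # gene copies genotyped per (pop, locus)
    n_copies = {}
    for p in pops:
        for l in range(len(table.loci)):
            gmat = table.genotypes[idx_of[p], l]
            n_copies[(p, l)] = int((gmat != MISSING).sum())
    n_min = min(n_copies.values())
    if g is None:
        g = n_min
    if g < 1 or g > n_min:
        limiting = min(n_copies, key=n_copies.get)
        raise ValueError(
            f"g={g} exceeds the {n_min} genotyped gene copies of "
            f"population {limiting[0]} at locus {table.loci[limiting[1]]}")

    counts = {(p, l): table.allele_counts(l, table.individuals_of(p))
              for p in pops for l in range(len(table.loci))}
    rows = []
    for p in pops:
        ar_l, par_l = [], []
        for l in range(len(table.loci)):
            alleles = set()
            for q in pops:
                alleles |= set(counts[(q, l)])
            ar = par = 0.0
            for a in alleles:
                q_focal = _presence_prob(n_copies[(p, l)],
                                         counts[(p, l)].get(a, 0), g)
                ar += q_focal
                absent_elsewhere = 1.0
                for q in pops:
                    if q == p:
                        continue
                    absent_elsewhere *= 1.0 - _presence_prob(
                        n_copies[(q, l)], counts[(q, l)].get(a, 0), g)
                par += q_focal * absent_elsewhere
            ar_l.append(ar)
            par_l.append(par)
        rows.append(dict(population=p, g=g, Ar=float(np.mean(ar_l)),
                         Par=float(np.mean(par_l))))
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# MHC diversity
# ---------------------------------------------------------------------------

def mhc_diversity(allele_sets: dict, population_map: pd.Series,
                  allele_seqs: dict | None = None,
                  max_alleles: int = 4) -> pd.DataFrame:
    """Per-population MHC diversity from called allele sets.

    Parameters
    ----------
    allele_sets : dict
        individual -> set of allele ids (1–4 alleles).
    allele_seqs : dict, optional
        allele id -> nucleotide sequence; required for ``k`` (mean
        pairwise nucleotide differences among allele copies, each
        individual contributing its called set once).

    Returns per population: H (allele count), Hu (alleles private to the
    population), Ad_mean (mean called alleles / ``max_alleles``), k, and
    the per-allele relative frequencies (individuals carrying the allele
    divided by the total number of allele copies in the population).
    """
    if not allele_sets:
        raise ValueError("no called individuals")
    pops = list(dict.fromkeys(population_map[list(allele_sets)]))
    alleles_of_pop = {}
    for p in pops:
        inds = [i for i in allele_sets if population_map[i] == p]
        if not inds:
            continue
        alleles_of_pop[p] = inds

    pool = {p: set().union(*(allele_sets[i] for i in inds))
            for p, inds in alleles_of_pop.items()}
    rows = []
    freqs = {}
    for p, inds in alleles_of_pop.items():
        others = set().union(*(pool[q] for q in pool if q != p)) \
            if len(pool) > 1 else set()
        private = pool[p] - others
        ad = [len(allele_sets[i]) / max_alleles for i in inds]
        copies = [a for i in inds for a in sorted(allele_sets[i])]
        total_copies = len(copies)
        carrier_n = {}
        for a in pool[p]:
            carrier_n[a] = sum(1 for i in inds if a in allele_sets[i])
        freqs[p] = {a: carrier_n[a] / total_copies for a in sorted(pool[p])}
        k = np.nan
        if allele_seqs is not None:
            seqs = [allele_seqs[a] for a in copies]
            if len(seqs) > 1:
                diffs = [sum(x != y for x, y in zip(s1, s2))
                         for s1, s2 in itertools.combinations(seqs, 2)]
                k = float(np.mean(diffs))
        rows.append(dict(population=p, n=len(inds), H=len(pool[p]),
                         Hu=len(private), Ad_mean=float(np.mean(ad)), k=k))
    out = pd.DataFrame(rows).set_index("population")
    out.attrs["allele_frequencies"] = freqs
    return out


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def _group_stat(table, individuals, stat_name, g=None):
    sub = table.subset(individuals)
    sub.populations = pd.Series("grp", index=sub.individuals)
    if stat_name in ("Ho", "He", "Fis"):
        return float(heterozygosity_stats(sub, ["grp"])[stat_name].iloc[0])
    if stat_name == "Ar":
        return float(rarefied_richness(sub, ["grp"], g=g)["Ar"].iloc[0])
    raise ValueError(f"unknown statistic {stat_name!r}")


def permutation_group_test(stat_name: str, table: MicrosatGenotypeTable,
                           group_a_pops, group_b_pops,
                           n_perm: int = 1000, seed: int = 0):
    """Two-sided permutation test for a diversity difference between groups.

    The observed statistic is |stat(A) - stat(B)| with the statistic
    (``Ho``, ``He``, ``Fis`` or ``Ar``) computed on the pooled individuals
    of each group; the null distribution reassigns individuals at random
    between the two groups, keeping group sizes.  p uses the (b+1)/(m+1)
    estimator.  For ``Ar``, rarefaction size is fixed to the smaller
    group's copy count so it is defined under every permutation.

    Returns (observed difference stat_A - stat_B, p value).
    """
    if n_perm < 100:
        import warnings
        warnings.warn("n_perm < 100 gives a coarse p-value")
    inds_a = [i for p in group_a_pops for i in table.individuals_of(p)]
    inds_b = [i for p in group_b_pops for i in table.individuals_of(p)]
    if not inds_a or not inds_b:
        raise ValueError("both groups must be nonempty")
    g = None
    if stat_name == "Ar":
        g = 2 * min(len(inds_a), len(inds_b)) - 2
        g = max(g, 2)

    if stat_name == "Ho":
        # vectorized path: per-individual heterozygosity indicators are
        # permutation-invariant, only the group assignment changes
        ok = (table.genotypes != MISSING).all(axis=2)
        het = (table.genotypes[:, :, 0] != table.genotypes[:, :, 1]) & ok

        def stat(ind_list):
            idx = np.fromiter((table.index_of(i) for i in ind_list),
                              dtype=int)
            n_ok = ok[idx].sum(axis=0)
            use = n_ok > 0
            return float(np.mean(het[idx].sum(axis=0)[use] / n_ok[use]))
    elif stat_name == "He":
        # vectorized path via per-individual allele-dosage columns
        L = len(table.loci)
        dosage_cols, col_locus = [], []
        for l in range(L):
            g = table.genotypes[:, l]
            alleles = sorted(set(g[g != MISSING].ravel().tolist()))
            for a in alleles:
                dosage_cols.append(((g == a) & (g != MISSING)).sum(axis=1))
                col_locus.append(l)
        dosage = np.column_stack(dosage_cols).astype(float)
        copies = np.column_stack(
            [(table.genotypes[:, l] != MISSING).sum(axis=1)
             for l in col_locus]).astype(float)
        col_locus = np.asarray(col_locus)

        def stat(ind_list):
            idx = np.fromiter((table.index_of(i) for i in ind_list),
                              dtype=int)
            tot = copies[idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p2 = (dosage[idx].sum(axis=0) / tot) ** 2
            he = np.empty(L)
            for l in range(L):
                he[l] = 1.0 - np.nansum(p2[col_locus == l])
            return float(np.mean(he))
    else:
        def stat(ind_list):
            return _group_stat(table, list(ind_list), stat_name, g)

    obs = stat(inds_a) - stat(inds_b)
    pool = np.array(inds_a + inds_b)
    na = len(inds_a)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        d = stat(perm[:na]) - stat(perm[na:])
        if abs(d) >= abs(obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return obs, p


def anova_tukey(values, groups):
    """One-way ANOVA with Tukey HSD post hoc comparisons.

    ``values`` are per-individual observations (e.g. MHC individual
    diversity), ``groups`` the matching population labels.  Returns
    (F, df_between, df_within, p, tukey table).  With zero variance
    everywhere F is undefined and reported as (nan, ..., nan, None).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    samples = [values[groups == lab] for lab in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    dfb, dfw = len(labels) - 1, len(values) - len(labels)
    if np.allclose(values, values[0]):
        return np.nan, dfb, dfw, np.nan, None
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0:
        return np.nan, dfb, dfw, np.nan, None
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    tukey = pairwise_tukeyhsd(values, groups, alpha=0.05)
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    return float(F), dfb, dfw, p, tukey_df


def pearson_corr(x, y):
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
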