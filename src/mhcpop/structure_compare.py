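"""Differentiation and joint-structure machinery for two marker systems.

Implements AMOVA-framework FST (pairwise and hierarchical) on
inter-individual distance matrices, Mantel and partial Mantel matrix
correlations, dominant (presence/absence) binary encoding, and co-inertia
analysis of two ordinations of the same individuals with the RV
coefficient as the global correlation.

Distances: for microsatellites, the inter-individual distance is the
number of different alleles summed over loci; for MHC, each individual's
called alleles are treated as haplotype copies and inter-haplotype
distances are Jukes–Cantor corrected nucleotide distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen_stats import MISSING, MicrosatGenotypeTable
from .selection_tests import jc_correct


@dataclass
class DistanceBundle:
    """Named square symmetric matrices over a common label order."""

    labels: list
    matrices: dict = field(default_factory=dict)

    def add(self, name: str, matrix) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix diagonal not zero")
        self.matrices[name] = m

    def frame(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(self.matrices[name], index=self.labels,
                            columns=self.labels)

    def to_csv(self, name: str, path) -> None:
        self.frame(name).to_csv(path)

    @staticmethod
    def read_matrix_csv(path) -> pd.DataFrame:
        df = pd.read_csv(path, index_col=0)
        df.columns = df.columns.astype(str)
        df.index = df.index.astype(str)
        return df


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in kilometres."""
    rlat1, rlon1, rlat2, rlon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((rlat2 - rlat1) / 2) ** 2
         + np.cos(rlat1) * np.cos(rlat2) * np.sin((rlon2 - rlon1) / 2) ** 2)
    return float(2 * 6371.0088 * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle km from a (pop, lat, lon) table."""
    pops = list(coords.index)
    m = np.zeros((len(pops), len(pops)))
    for i, j in itertools.combinations(range(len(pops)), 2):
        d = great_circle_km(coords.iloc[i]["lat"], coords.iloc[i]["lon"],
                            coords.iloc[j]["lat"], coords.iloc[j]["lon"])
        m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# Inter-individual distances
# ---------------------------------------------------------------------------

def microsat_distance_matrix(table: MicrosatGenotypeTable) -> np.ndarray:
    """Number of different alleles between diploid genotypes, over loci.

    Per locus the distance between genotypes {a,b} and {c,d} is
    2 - |multiset intersection|; loci missing in either individual are
    skipped.  Used as the squared distance in AMOVA (the standard
    microsatellite FST distance).
    """
    g = table.genotypes
    n = g.shape[0]
    d = np.zeros((n, n))
    for l in range(g.shape[1]):
        gl = np.sort(g[:, l], axis=1)
        ok = (gl != MISSING).all(axis=1)
        for i in range(n):
            if not ok[i]:
                continue
            a, b = gl[i]
            cd = gl[i + 1:]
            okj = ok[i + 1:]
            c, dd = cd[:, 0], cd[:, 1]
            shared = ((a == c).astype(int) + (b == dd).astype(int))
            alt = ((a == dd).astype(int) + (b == c).astype(int))
            # multiset intersection size, handling a==b / c==dd correctly
            inter = np.maximum(shared, alt)
            both_same = (a == b) & (c == dd)
            inter = np.where(both_same & (a == c), 2, inter)
            inter = np.where(both_same & (a != c), 0, inter)
            dist_l = np.where(okj, 2 - inter, 0)
            d[i, i + 1:] += dist_l
    return d + d.T


def mhc_haplotype_distances(allele_sets: dict, allele_seqs: dict):
    """Haplotype-copy expansion and JC distance matrix for MHC calls.

    Returns (units, owner, dist): one unit per called allele copy,
    ``owner`` giving the individual of each unit and ``dist`` the JC
    distance between the allele sequences of the units.
    """
    units, owner = [], []
    for ind in sorted(allele_sets):
        for a in sorted(allele_sets[ind]):
            units.append(a)
            owner.append(ind)
    uniq = sorted(set(units))
    seqs = {a: allele_seqs[a] for a in uniq}
    L = len(next(iter(seqs.values())))
    jc = {}
    for a, b in itertools.combinations(uniq, 2):
        p = sum(x != y for x, y in zip(seqs[a], seqs[b])) / L
        jc[(a, b)] = jc[(b, a)] = jc_correct(p)
    n = len(units)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if units[i] != units[j]:
                d[i, j] = d[j, i] = jc[(units[i], units[j])]
    return units, owner, d


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _ss_within(d2, idx):
    if len(idx) < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return sub[np.triu_indices(len(idx), 1)].sum() / len(idx)


@dataclass
class AmovaResult:
    components: dict     # level -> variance component
    percentages: dict    # level -> % of total (floored at 0 when negative)
    p_values: dict
    df: dict
    negative_flag: bool = False

    @property
    def phi_st(self):
        tot = sum(self.components.values())
        within = self.components["within_populations"]
        return (tot - within) / tot if tot > 0 else np.nan


def _amova_two_level(d2, pop_idx):
    """Variance components for units nested in populations."""
    pops = list(pop_idx)
    N = sum(len(v) for v in pop_idx.values())
    r = len(pops)
    ss_wp = sum(_ss_within(d2, pop_idx[p]) for p in pops)
    all_idx = np.concatenate([pop_idx[p] for p in pops])
    ss_tot = _ss_within(d2, all_idx)
    ss_ap = ss_tot - ss_wp
    df_ap, df_wp = r - 1, N - r
    sizes = np.array([len(pop_idx[p]) for p in pops], dtype=float)
    n0 = (N - np.sum(sizes ** 2) / N) / (r - 1)
    sigma_w = ss_wp / df_wp if df_wp > 0 else 0.0
    ms_ap = ss_ap / df_ap
    sigma_a = (ms_ap - sigma_w) / n0
    return sigma_a, sigma_w, (df_ap, df_wp)


def _amova_three_level(d2, pop_idx, group_of):
    """Units in populations in groups (Excoffier sums of squares)."""
    pops = list(pop_idx)
    groups = list(dict.fromkeys(group_of[p] for p in pops))
    N = sum(len(v) for v in pop_idx.values())
    ss_wp = sum(_ss_within(d2, pop_idx[p]) for p in pops)
    ss_wg = 0.0
    for g in groups:
        idx = np.concatenate([pop_idx[p] for p in pops if group_of[p] == g])
        ss_wg += _ss_within(d2, idx)
    all_idx = np.concatenate([pop_idx[p] for p in pops])
    ss_tot = _ss_within(d2, all_idx)
    ss_ap = ss_wg - ss_wp          # among populations within groups
    ss_ag = ss_tot - ss_wg         # among groups
    df_ag = len(groups) - 1
    df_ap = len(pops) - len(groups)
    df_wp = N - len(pops)

    sizes = {p: float(len(pop_idx[p])) for p in pops}
    gsize = {g: sum(sizes[p] for p in pops if group_of[p] == g)
             for g in groups}
    n = ((N - sum(sum(sizes[p] ** 2 for p in pops if group_of[p] == g)
                  / gsize[g] for g in groups)) / df_ap)
    n_p = ((sum(sum(sizes[p] ** 2 for p in pops if group_of[p] == g)
                / gsize[g] for g in groups)
            - sum(sizes[p] ** 2 for p in pops) / N) / df_ag)
    n_pp = (N - sum(gsize[g] ** 2 for g in groups) / N) / df_ag

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    ms_ap = ss_ap / df_ap if df_ap > 0 else 0.0
    sigma_b = (ms_ap - sigma_c) / n if df_ap > 0 else 0.0
    ms_ag = ss_ag / df_ag
    sigma_a = (ms_ag - sigma_c - n_p * sigma_b) / n_pp
    return sigma_a, sigma_b, sigma_c, (df_ag, df_ap, df_wp)


def amova(d2: np.ndarray, unit_pops, pop_groups: dict | None = None,
          n_perm: int = 1000, seed: int = 0) -> AmovaResult:
    """Analysis of molecular variance on a (squared) distance matrix.

    Parameters
    ----------
    d2 : (n, n) ndarray
        Squared inter-unit distances (units are individuals, or haplotype
        copies for sequence data).
    unit_pops : sequence of population labels, one per unit.
    pop_groups : dict, optional
        population -> group; when given, a three-level hierarchy
        (units < populations < groups) is partitioned, otherwise two
        levels.  Percentages are computed on components floored at zero;
        a negative component sets ``negative_flag`` and is reported as
        estimated.
    """
    d2 = np.asarray(d2, dtype=float)
    unit_pops = np.asarray(unit_pops)
    pops = list(dict.fromkeys(unit_pops))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    pop_idx = {p: np.flatnonzero(unit_pops == p) for p in pops}
    if any(len(v) < 2 for v in pop_idx.values()):
        raise ValueError("each population needs >= 2 units")
    rng = np.random.default_rng(seed)

    if pop_groups is None:
        sigma_a, sigma_w, (df_a, df_w) = _amova_two_level(d2, pop_idx)
        comps = {"among_populations": sigma_a, "within_populations": sigma_w}
        dfs = {"among_populations": df_a, "within_populations": df_w}
        obs_stats = {"among_populations": sigma_a}
        perm_hits = {"among_populations": 0}
        for _ in range(n_perm):
            perm = rng.permutation(unit_pops)
            pidx = {p: np.flatnonzero(perm == p) for p in pops}
            sa, _, _ = _amova_two_level(d2, pidx)
            if sa >= obs_stats["among_populations"] - 1e-12:
                perm_hits["among_populations"] += 1
    else:
        group_of = dict(pop_groups)
        sigma_a, sigma_b, sigma_c, (df_g, df_p, df_w) = _amova_three_level(
            d2, pop_idx, group_of)
        comps = {"among_groups": sigma_a,
                 "among_populations_within_groups": sigma_b,
                 "within_populations": sigma_c}
        dfs = {"among_groups": df_g,
               "among_populations_within_groups": df_p,
               "within_populations": df_w}
        perm_hits = {"among_groups": 0,
                     "among_populations_within_groups": 0}
        groups = list(dict.fromkeys(group_of[p] for p in pops))
        for _ in range(n_perm):
            # among groups: permute whole populations among groups
            gperm = dict(zip(pops,
                             rng.permutation([group_of[p] for p in pops])))
            sa, _, _, _ = _amova_three_level(d2, pop_idx, gperm)
            if sa >= sigma_a - 1e-12:
                perm_hits["among_groups"] += 1
            # among pops within groups: permute units among pops within group
            perm_units = unit_pops.copy()
            for g in groups:
                gi = np.flatnonzero(
                    [group_of[p] == g for p in unit_pops])
                perm_units[gi] = rng.permutation(perm_units[gi])
            pidx = {p: np.flatnonzero(perm_units == p) for p in pops}
            if any(len(v) < 2 for v in pidx.values()):
                continue
            _, sb, _, _ = _amova_three_level(d2, pidx, group_of)
            if sb >= sigma_b - 1e-12:
                perm_hits["among_populations_within_groups"] += 1

    floored = {k: max(v, 0.0) for k, v in comps.items()}
    total = sum(floored.values())
    if total > 0:
        pct = {k: 100.0 * v / total for k, v in floored.items()}
    else:
        # no molecular variance at all: by convention everything within
        pct = {k: (100.0 if k == "within_populations" else 0.0)
               for k in floored}
    pvals = {k: (h + 1) / (n_perm + 1) for k, h in perm_hits.items()}
    return AmovaResult(comps, pct, pvals, dfs,
                       negative_flag=any(v < 0 for v in comps.values()))


def fst_matrix(data, mode: str, population_map: pd.Series | None = None,
               allele_seqs: dict | None = None, n_perm: int = 1000,
               seed: int = 0):
    """Pairwise AMOVA-framework FST between populations.

    mode='microsat_alleles': ``data`` is a MicrosatGenotypeTable and the
    inter-individual distance is the number of different alleles.
    mode='mhc_jc': ``data`` is a dict individual -> allele set,
    ``allele_seqs`` the sequences, and individuals contribute their
    called alleles as haplotype copies with JC distances.

    Returns (fst DataFrame, p DataFrame); negative estimates are reported
    as computed.
    """
    if mode == "microsat_alleles":
        table = data
        d2 = microsat_distance_matrix(table)
        unit_pops = np.array([table.populations[i] for i in table.individuals])
        owner = np.array(table.individuals)
    elif mode == "mhc_jc":
        if allele_seqs is None or population_map is None:
            raise ValueError("mhc_jc mode needs allele_seqs and population_map")
        _, owner, d2 = mhc_haplotype_distances(data, allele_seqs)
        owner = np.array(owner)
        unit_pops = np.array([population_map[i] for i in owner])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pops = list(dict.fromkeys(unit_pops))
    rng = np.random.default_rng(seed)
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(1.0, index=pops, columns=pops)
    for pa, pb in itertools.combinations(pops, 2):
        mask = (unit_pops == pa) | (unit_pops == pb)
        idx = np.flatnonzero(mask)
        sub = d2[np.ix_(idx, idx)]
        sub_pops = unit_pops[idx]
        sub_owner = owner[idx]
        sigma_a, sigma_w, _ = _amova_two_level(
            sub, {p: np.flatnonzero(sub_pops == p) for p in (pa, pb)})
        tot = sigma_a + sigma_w
        obs = sigma_a / tot if tot > 0 else 0.0
        fst.loc[pa, pb] = fst.loc[pb, pa] = obs
        # permute individuals (with all their haplotype copies) between pops
        inds = list(dict.fromkeys(sub_owner))
        ind_pop = {i: sub_pops[np.flatnonzero(sub_owner == i)[0]]
                   for i in inds}
        hits = 0
        for _ in range(n_perm):
            labels = rng.permutation([ind_pop[i] for i in inds])
            lab_of = dict(zip(inds, labels))
            perm_pops = np.array([lab_of[i] for i in sub_owner])
            pidx = {p: np.flatnonzero(perm_pops == p) for p in (pa, pb)}
            if any(len(v) < 2 for v in pidx.values()):
                continue
            sa, sw, _ = _amova_two_level(sub, pidx)
            t = sa + sw
            if (sa / t if t > 0 else 0.0) >= obs - 1e-12:
                hits += 1
        pvals.loc[pa, pb] = pvals.loc[pb, pa] = (hits + 1) / (n_perm + 1)
    np.fill_diagonal(pvals.values, np.nan)
    return fst, pvals


def weir_cockerham_fst(table: MicrosatGenotypeTable) -> float:
    """Weir–Cockerham (1984) multilocus theta over all populations.

    Variance components a (among populations), b (among individuals
    within populations) and c (within individuals) are accumulated over
    loci and alleles; theta = sum a / sum (a + b + c).  This is the
    standard nearly unbiased realized-FST estimator used to validate
    drift simulations.
    """
    a_sum = b_sum = c_sum = 0.0
    pops = table.pops()
    for l in range(len(table.loci)):
        groups = []
        for p in pops:
            idx = [table.index_of(i) for i in table.individuals_of(p)]
            g = table.genotypes[idx, l]
            groups.append(g[(g != MISSING).all(axis=1)])
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        alleles = sorted(set().union(*(set(g.ravel().tolist())
                                       for g in groups)))
        r = len(groups)
        ns = np.array([len(g) for g in groups], dtype=float)
        nbar = ns.mean()
        nc = (ns.sum() - np.sum(ns ** 2) / ns.sum()) / (r - 1)
        for al in alleles:
            ps = np.array([np.mean(g == al) for g in groups])
            hs = np.array([np.mean((g == al).sum(axis=1) == 1)
                           for g in groups])
            pbar = np.sum(ns * ps) / ns.sum()
            hbar = np.sum(ns * hs) / ns.sum()
            s2 = np.sum(ns * (ps - pbar) ** 2) / ((r - 1) * nbar)
            a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            a_sum += a
            b_sum += b
            c_sum += c
    tot = a_sum + b_sum + c_sum
    return float(a_sum / tot) if tot != 0 else np.nan


def multilocus_fst(table: MicrosatGenotypeTable,
                   method: str = "wc") -> float:
    """Global multilocus FST: Weir–Cockerham theta ('wc') or the AMOVA
    framework on the number-of-different-alleles distance ('amova')."""
    if method == "wc":
        return weir_cockerham_fst(table)
    if method == "amova":
        d2 = microsat_distance_matrix(table)
        unit_pops = [table.populations[i] for i in table.individuals]
        res = amova(d2, unit_pops, n_perm=0)
        return float(res.phi_st)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _offdiag(m):
    m = np.asarray(m, dtype=float)
    return m[np.triu_indices(m.shape[0], 1)]


def mantel(d1, d2, n_perm: int = 1000, seed: int = 0):
    """Mantel matrix correlation with row/column permutation test.

    M_r is the Pearson correlation of the upper off-diagonal triangles;
    p is two-sided on |M_r| with the (b+1)/(m+1) estimator.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.shape[0] != d1.shape[1]:
        raise ValueError("matrices must be square and conformable")
    v1, v2 = _offdiag(d1), _offdiag(d2)
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")
    obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = d1.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = _offdiag(d1[np.ix_(perm, perm)])
        if abs(np.corrcoef(vp, v2)[0, 1]) >= abs(obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return obs, p


def partial_mantel(d1, d2, control, n_perm: int = 1000, seed: int = 0):
    """Partial Mantel correlation of d1 and d2 controlling for a third matrix.

    Off-diagonal vectors of d1 and d2 are each regressed on the control
    vector; the statistic is the correlation of the residuals, assembled
    back into matrices so the permutation respects the matrix structure
    (rows/columns of the d1 residual matrix are permuted jointly).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    control = np.asarray(control, dtype=float)

    def _residual_matrix(d, c):
        v, vc = _offdiag(d), _offdiag(c)
        beta = np.polyfit(vc, v, 1)
        res = d - (beta[0] * c + beta[1])
        np.fill_diagonal(res, 0.0)
        return res

    r1 = _residual_matrix(d1, control)
    r2 = _residual_matrix(d2, control)
    # control explaining (numerically) all variation of either matrix
    # leaves nothing to correlate: the partial correlation is zero
    for r, d in ((r1, d1), (r2, d2)):
        scale = np.std(_offdiag(d))
        if scale == 0 or np.std(_offdiag(r)) / scale < 1e-9:
            return 0.0, 1.0
    return mantel(r1, r2, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Binary encoding and co-inertia
# ---------------------------------------------------------------------------

def binary_encode(genotypes, mode: str) -> pd.DataFrame:
    """Dominant presence/absence (1/0) encoding of genotypes.

    mode='mhc': ``genotypes`` maps individual -> allele set; columns are
    the observed alleles.  mode='microsat': a MicrosatGenotypeTable;
    columns are locus.allele for every observed allele.  Individuals with
    entirely missing genotypes are dropped with a ``dropped`` attribute.
    """
    if mode == "mhc":
        inds = sorted(genotypes)
        cols = sorted(set().union(*(genotypes[i] for i in inds)))
        m = pd.DataFrame(0, index=inds, columns=cols, dtype=int)
        for i in inds:
            for a in genotypes[i]:
                m.loc[i, a] = 1
        dropped = [i for i in inds if not genotypes[i]]
        m = m.drop(index=dropped)
        m.attrs["dropped"] = dropped
        return m
    if mode == "microsat":
        table = genotypes
        cols, data = [], []
        for l, loc in enumerate(table.loci):
            g = table.genotypes[:, l]
            alleles = sorted(set(g[g != MISSING].ravel().tolist()))
            for a in alleles:
                cols.append(f"{loc}.{a}")
                data.append(((g == a).any(axis=1)).astype(int))
        m = pd.DataFrame(np.column_stack(data), index=table.individuals,
                         columns=cols)
        all_missing = (table.genotypes == MISSING).all(axis=(1, 2))
        dropped = [ind for ind, bad in zip(table.individuals, all_missing)
                   if bad]
        m = m.drop(index=dropped)
        m.attrs["dropped"] = dropped
        return m
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CoinertiaResult:
    rv: float
    eigenvalues: np.ndarray
    row_scores_a: pd.DataFrame   # individuals on co-inertia axes, marker A
    row_scores_b: pd.DataFrame
    pop_scores_a: pd.DataFrame
    pop_scores_b: pd.DataFrame
    canonical_weights_a: pd.DataFrame
    canonical_weights_b: pd.DataFrame
    p_value: float


def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """RV coefficient of two column-centered matrices with matched rows."""
    wx, wy = x @ x.T, y @ y.T
    num = np.sum(wx * wy)
    den = np.sqrt(np.sum(wx * wx) * np.sum(wy * wy))
    return float(num / den) if den > 0 else np.nan


def _pca_scores(m: pd.DataFrame, n_components: int):
    x = m.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > 1e-10))
    k = min(n_components, rank)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T  # columns -> components
    return scores, loadings, k


def coinertia(binary_a: pd.DataFrame, binary_b: pd.DataFrame,
              population_map: pd.Series, n_components: int = 2,
              n_boot: int = 1000, seed: int = 0) -> CoinertiaResult:
    """Co-inertia analysis of two marker matrices over the same individuals.

    Each binary matrix is column-centered and reduced by PCA to
    ``n_components`` axes; the co-inertia decomposition is the SVD of the
    cross-covariance of the two score sets.  The RV coefficient measures
    the global co-structure; per-population scores (the mean of the
    individual scores) give one point per population in each marker
    system, whose separation is the marker discordance.  Significance is
    the proportion of ``n_boot`` row-permutation resamples with RV at
    least the observed, with (b+1)/(m+1) smoothing.
    """
    if list(binary_a.index) != list(binary_b.index):
        raise ValueError("matrices must cover the same individuals in order")
    sa, la, ka = _pca_scores(binary_a, n_components)
    sb, lb, kb = _pca_scores(binary_b, n_components)
    k = min(ka, kb)
    if k < n_components:
        import warnings
        warnings.warn(f"rank deficiency: using {k} components")
    sa, sb = sa[:, :k], sb[:, :k]
    sa_c = sa - sa.mean(axis=0)
    sb_c = sb - sb.mean(axis=0)

    cross = sa_c.T @ sb_c / sa.shape[0]
    u, sv, vt = np.linalg.svd(cross)
    eig = sv ** 2
    axes = [f"CoA{i + 1}" for i in range(len(sv))]
    rsa = sa_c @ u
    rsb = sb_c @ vt.T
    rv = rv_coefficient(sa_c, sb_c)

    inds = list(binary_a.index)
    pops = pd.Series([population_map[i] for i in inds], index=inds)
    row_a = pd.DataFrame(rsa, index=inds, columns=axes)
    row_b = pd.DataFrame(rsb, index=inds, columns=axes)
    pop_a = row_a.groupby(pops).mean()
    pop_b = row_b.groupby(pops).mean()
    cw_a = pd.DataFrame(la[:, :k] @ u, index=binary_a.columns, columns=axes)
    cw_b = pd.DataFrame(lb[:, :k] @ vt.T, index=binary_b.columns,
                        columns=axes)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        perm = rng.permutation(sa.shape[0])
        if rv_coefficient(sa_c[perm], sb_c) >= rv - 1e-12:
            hits += 1
    p = (hits + 1) / (n_boot + 1)
    return CoinertiaResult(rv, eig, row_a, row_b, pop_a, pop_b,
                           cw_a, cw_b, p)
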