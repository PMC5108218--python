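"""Sequence diversity and historical-selection statistics for allele sets.

Implements Jukes–Cantor pairwise distances and a codon-based test of
positive selection: synonymous/nonsynonymous substitution rates by the
(modified) Nei–Gojobori pathway method with Jukes–Cantor correction, and a
one-tailed Z-test of dN > dS with the standard error obtained by
bootstrapping codons.

The peptide-binding region (PBR) is a user-supplied codon mask: PBR site
lists come from crystal-structure studies of human class II molecules and
must be provided as 1-based codon indices over the translated fragment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import CODON_TABLE, STOP_CODONS, NUCLEOTIDES

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a proportion of differences."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return np.nan
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def jc_distance_stats(sequences):
    """Pairwise JC distances, their mean/SD, and segregating sites.

    Parameters
    ----------
    sequences : list of equal-length nucleotide strings, or AlleleLibrary.

    Returns
    -------
    dist : (n, n) ndarray
        JC distance matrix; NaN where p >= 0.75 (correction undefined).
    mean, sd : float
        Mean and (population) SD over defined unordered pairs.
    segregating_sites : int
        Number of alignment columns with more than one state.
    """
    if hasattr(sequences, "sequences"):
        sequences = sequences.sequences
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(s) for s in seqs])
    n, L = arr.shape
    dist = np.zeros((n, n))
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        p = np.mean(arr[i] != arr[j])
        d = jc_correct(p)
        dist[i, j] = dist[j, i] = d
        vals.append(d)
    vals = np.asarray(vals)
    defined = vals[~np.isnan(vals)]
    seg = int(np.sum([len(set(arr[:, c])) > 1 for c in range(L)]))
    return dist, float(defined.mean()), float(defined.std()), seg


# ---------------------------------------------------------------------------
# Nei–Gojobori
# ---------------------------------------------------------------------------

def codon_sites(codon: str, R: float = 1.0):
    """(synonymous, nonsynonymous) site counts of one codon.

    Modified Nei–Gojobori counting: at each position, candidate changes
    are weighted by R for transitions and 1 for transversions; the
    synonymous site fraction is the weighted share of synonymous changes.
    R = 1 reduces to the standard Nei–Gojobori equal-weight count.
    Changes creating a stop codon count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for b in NUCLEOTIDES:
            if b == codon[pos]:
                continue
            w = R if (codon[pos], b) in TRANSITIONS else 1.0
            tot_w += w
            mut = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[mut] == aa:
                syn_w += w
        s += syn_w / tot_w
    return s, 3.0 - s


def codon_differences(c1: str, c2: str):
    """(synonymous, nonsynonymous) differences by pathway enumeration.

    All orderings of the single-base steps between the two codons are
    enumerated; pathways passing through a stop codon are excluded (if all
    pathways are blocked, every pathway is used).  Counts are averaged
    over the admitted pathways.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = float(np.mean([s for s, _ in open_paths]))
    nd = float(np.mean([n for _, n in open_paths]))
    return sd, nd


def _codon_split(seq: str, frame_offset: int):
    return [seq[i:i + 3] for i in range(frame_offset, len(seq) - 2, 3)]


@dataclass(frozen=True)
class CodonPartition:
    """Disjoint PBR / non-PBR split of the complete codons (1-based)."""

    pbr_sites: frozenset
    n_codons: int
    label: str = "pbr"

    def __post_init__(self):
        if not all(1 <= i <= self.n_codons for i in self.pbr_sites):
            raise ValueError("PBR site outside codon range")

    @property
    def non_pbr_sites(self):
        return frozenset(range(1, self.n_codons + 1)) - self.pbr_sites


@dataclass
class SelectionResult:
    """dN/dS summary and one-tailed Z-test for one codon partition."""

    partition: str
    dN: float
    dS: float
    z: float
    p_value: float
    n_codons: int
    applicable: bool = True

    @property
    def omega(self):
        return self.dN / self.dS if self.dS > 0 else np.nan


def _pair_codon_contributions(seqs, codon_idx, frame_offset, R):
    """Per (pair, codon) site and difference counts.

    Returns four (n_pairs, n_codons) arrays: S sites, N sites, syn
    differences, nonsyn differences, averaging site counts over the two
    sequences of each pair.
    """
    codons = [np.array(_codon_split(s, frame_offset))[codon_idx]
              for s in seqs]
    site_cache, diff_cache = {}, {}
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    S = np.zeros((len(pairs), len(codon_idx)))
    N = np.zeros_like(S)
    Sd = np.zeros_like(S)
    Nd = np.zeros_like(S)
    for k, (i, j) in enumerate(pairs):
        for c, (ci, cj) in enumerate(zip(codons[i], codons[j])):
            for cod in (ci, cj):
                if cod not in site_cache:
                    site_cache[cod] = codon_sites(cod, R)
            si, _ = site_cache[ci]
            sj, _ = site_cache[cj]
            S[k, c] = (si + sj) / 2.0
            N[k, c] = 3.0 - S[k, c]
            key = (ci, cj) if ci <= cj else (cj, ci)
            if key not in diff_cache:
                diff_cache[key] = codon_differences(*key)
            Sd[k, c], Nd[k, c] = diff_cache[key]
    return S, N, Sd, Nd


def _mean_dn_ds(S, N, Sd, Nd):
    """Mean JC-corrected dN and dS over pairs from per-codon sums."""
    Ssum, Nsum = S.sum(axis=1), N.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pS = np.where(Ssum > 0, Sd.sum(axis=1) / Ssum, 0.0)
        pN = np.where(Nsum > 0, Nd.sum(axis=1) / Nsum, 0.0)
    dS = np.array([jc_correct(p) for p in pS])
    dN = np.array([jc_correct(p) for p in pN])
    dN_def, dS_def = dN[~np.isnan(dN)], dS[~np.isnan(dS)]
    return (float(dN_def.mean()) if len(dN_def) else np.nan,
            float(dS_def.mean()) if len(dS_def) else np.nan)


def dnds_z_test(sequences, partition: CodonPartition | None = None,
                frame_offset: int = 2, R: float = 1.0,
                n_bootstrap: int = 1000, seed: int = 0):
    """One-tailed Z-test of positive selection (H1: dN > dS).

    For each codon partition (all sites, PBR, non-PBR when a partition is
    given) the modified Nei–Gojobori method counts synonymous and
    nonsynonymous sites and differences per sequence pair, proportions are
    Jukes–Cantor corrected and averaged over pairs, and Z = (dN - dS)/SE
    with SE from ``n_bootstrap`` codon-resampling replicates.

    Returns a dict label -> SelectionResult, labels 'all' and, when a
    partition is supplied, 'pbr' and 'non_pbr'.
    """
    if hasattr(sequences, "sequences"):
        if partition is None and getattr(sequences, "pbr_mask", None):
            partition = CodonPartition(frozenset(sequences.pbr_mask),
                                       sequences.n_codons)
        frame_offset = sequences.frame_offset
        sequences = sequences.sequences
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n_codons = (len(seqs[0]) - frame_offset) // 3
    for s in seqs:
        if any(c in STOP_CODONS for c in _codon_split(s, frame_offset)):
            raise ValueError("sequence contains a stop codon in frame")

    subsets = {"all": np.arange(n_codons)}
    if partition is not None:
        subsets["pbr"] = np.array(sorted(partition.pbr_sites)) - 1
        subsets["non_pbr"] = np.array(sorted(partition.non_pbr_sites)) - 1

    rng = np.random.default_rng(seed)
    out = {}
    for label, idx in subsets.items():
        if len(idx) < 3:
            raise ValueError(
                f"partition '{label}' has {len(idx)} codons; need >= 3")
        S, N, Sd, Nd = _pair_codon_contributions(seqs, idx, frame_offset, R)
        dN, dS = _mean_dn_ds(S, N, Sd, Nd)
        if Sd.sum() == 0 and Nd.sum() == 0:
            out[label] = SelectionResult(label, 0.0, 0.0, np.nan, np.nan,
                                         len(idx), applicable=False)
            continue
        boots = np.empty(n_bootstrap)
        m = len(idx)
        for b in range(n_bootstrap):
            take = rng.integers(0, m, size=m)
            bdN, bdS = _mean_dn_ds(S[:, take], N[:, take],
                                   Sd[:, take], Nd[:, take])
            boots[b] = bdN - bdS
        defined = boots[~np.isnan(boots)]
        se = float(defined.std(ddof=1)) if len(defined) > 1 else np.nan
        z = (dN - dS) / se if se > 0 else np.nan
        p = float(stats.norm.sf(z)) if np.isfinite(z) else np.nan
        out[label] = SelectionResult(label, dN, dS, z, p, len(idx))
    return out
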