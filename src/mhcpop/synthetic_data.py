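"""Synthetic data generation for MHC amplicon genotyping pipelines.

Emulates the statistical structure of a multi-population MHC DRB exon-2
amplicon study: a pool of functional allele sequences, populations whose
allele frequencies drift around an ancestral pool (Balding–Nichols model),
per-individual MHC genotypes of 1–4 alleles (two DRB-like loci sharing one
allele pool, so alleles cannot be assigned to loci), diploid microsatellite
genotypes, and pyrosequencing-like tagged amplicon reads carrying PCR/
sequencing artifacts (1–2 bp substitution copies of true alleles).

Everything is seeded and deterministic given the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUCLEOTIDES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate the complete codons of ``seq`` starting at ``frame_offset``."""
    aa = []
    for i in range(frame_offset, len(seq) - 2, 3):
        aa.append(CODON_TABLE[seq[i:i + 3]])
    return "".join(aa)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AlleleLibrary:
    """A pool of distinct, functional (stop-free) allele sequences.

    Parameters
    ----------
    alleles : list of (id, sequence)
        Equal-length nucleotide sequences, pairwise distinct at both the
        nucleotide and the amino-acid level.
    frame_offset : int
        Reading-frame offset (0–2) such that translation of the complete
        codons contains no stop codon.
    pbr_mask : frozenset of int
        1-based codon indices of putative peptide-binding-region sites.
    """

    alleles: tuple
    frame_offset: int
    pbr_mask: frozenset = field(default_factory=frozenset)

    @property
    def ids(self):
        return [a for a, _ in self.alleles]

    @property
    def sequences(self):
        return [s for _, s in self.alleles]

    @property
    def length(self) -> int:
        return len(self.alleles[0][1])

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def sequence(self, allele_id: str) -> str:
        for aid, seq in self.alleles:
            if aid == allele_id:
                return seq
        raise KeyError(allele_id)

    def validate(self) -> None:
        """Raise ValueError if any library invariant is violated."""
        seqs = self.sequences
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("allele sequences differ in length")
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate nucleotide sequences")
        prots = [translate(s, self.frame_offset) for s in seqs]
        if len(set(prots)) != len(prots):
            raise ValueError("alleles not distinct at the amino-acid level")
        if any("*" in p for p in prots):
            raise ValueError("stop codon in translated allele")
        if not all(1 <= i <= self.n_codons for i in self.pbr_mask):
            raise ValueError("pbr_mask index outside codon range")

    def __len__(self) -> int:
        return len(self.alleles)


def _random_functional_sequence(rng: np.random.Generator, length: int,
                                frame_offset: int) -> str:
    """Random nucleotide sequence with no stop codon in the chosen frame."""
    n_codons = (length - frame_offset) // 3
    head = "".join(rng.choice(list(NUCLEOTIDES), size=frame_offset))
    non_stop = sorted(set(CODON_TABLE) - STOP_CODONS)
    codons = list(rng.choice(non_stop, size=n_codons))
    tail_len = length - frame_offset - 3 * n_codons
    tail = "".join(rng.choice(list(NUCLEOTIDES), size=tail_len))
    return head + "".join(codons) + tail


def generate_allele_library(n_alleles: int, length: int = 185,
                            frame_offset: int = 2, seed: int = 0,
                            n_pbr_sites: int = 14,
                            max_tries: int = 20000) -> AlleleLibrary:
    """Generate a library of distinct functional allele sequences.

    Alleles are built by mutating copies of already-accepted alleles with
    1–3 random substitutions, accepting a candidate only if it remains
    stop-free and is distinct from every existing allele at both the
    nucleotide and amino-acid level.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If the constraints are impossible (too many alleles for the
        sequence space) or not satisfied within ``max_tries`` attempts.
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    n_codons = (length - frame_offset) // 3
    if n_codons < 1:
        raise ValueError("length/frame_offset leave no complete codon")
    if n_alleles > 4 ** length:
        raise ValueError("n_alleles exceeds the sequence space")
    if n_pbr_sites > n_codons:
        raise ValueError("more PBR sites than codons")

    rng = np.random.default_rng(seed)
    base = _random_functional_sequence(rng, length, frame_offset)
    seqs = [base]
    prots = {translate(base, frame_offset)}
    tries = 0
    while len(seqs) < n_alleles:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not build {n_alleles} distinct functional alleles "
                f"in {max_tries} attempts")
        parent = seqs[rng.integers(len(seqs))]
        n_sub = int(rng.integers(1, 4))
        pos = rng.choice(length, size=min(n_sub, length), replace=False)
        cand = list(parent)
        for p in pos:
            cand[p] = rng.choice([b for b in NUCLEOTIDES if b != cand[p]])
        cand = "".join(cand)
        if cand in seqs:
            continue
        prot = translate(cand, frame_offset)
        if "*" in prot or prot in prots:
            continue
        seqs.append(cand)
        prots.add(prot)

    ids = [f"H{i + 1:02d}" for i in range(n_alleles)]
    pbr = frozenset(int(i) + 1 for i in
                    rng.choice(n_codons, size=n_pbr_sites, replace=False))
    lib = AlleleLibrary(tuple(zip(ids, seqs)), frame_offset, pbr)
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# Population model
# ---------------------------------------------------------------------------

#: Observed distribution of MHC allele counts per individual (1, 2, 3, 4).
DEFAULT_COPY_NUMBER_DIST = (0.152, 0.445, 0.318, 0.085)


@dataclass
class PopulationModel:
    """Balding–Nichols drift model over an ancestral allele pool.

    Each population's allele-frequency vector at every marker is drawn from
    Dirichlet(ancestral * (1 - F) / F), so the expected Wright FST among
    populations equals ``theta_fst``.
    """

    n_pops: int = 8
    pop_sizes: tuple = (30, 30, 39, 25, 48, 22, 23, 19)
    theta_fst: float = 0.10
    copy_number_dist: tuple = DEFAULT_COPY_NUMBER_DIST
    pop_names: tuple | None = None
    mhc_ancestral_freqs: np.ndarray | None = None
    microsat_n_alleles: int = 8

    def validate(self, library: AlleleLibrary | None = None) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length != n_pops")
        if not (0.0 < self.theta_fst < 1.0):
            raise ValueError("theta_fst must lie in (0, 1)")
        cnd = np.asarray(self.copy_number_dist, float)
        if not np.isclose(cnd.sum(), 1.0):
            raise ValueError("copy_number_dist must sum to 1")
        if library is not None:
            max_copies = int(np.max(np.nonzero(cnd)[0]) + 1)
            if max_copies > len(library):
                raise ValueError(
                    "copy_number_dist requests more alleles than the "
                    "library holds")
        if self.mhc_ancestral_freqs is not None:
            f = np.asarray(self.mhc_ancestral_freqs, float)
            if not np.isclose(f.sum(), 1.0):
                raise ValueError("ancestral frequencies must sum to 1")

    def names(self):
        if self.pop_names is not None:
            return list(self.pop_names)
        return [f"pop{i + 1}" for i in range(self.n_pops)]


def _dirichlet_freqs(rng, ancestral, theta):
    alpha = np.asarray(ancestral, float) * (1.0 - theta) / theta
    # guard against degenerate alpha: clip to a tiny positive mass
    alpha = np.clip(alpha, 1e-9, None)
    f = rng.dirichlet(alpha)
    return f / f.sum()


def simulate_populations(model: PopulationModel, library: AlleleLibrary,
                         n_microsat_loci: int = 20, seed: int = 0):
    """Simulate structured MHC and microsatellite genotypes.

    Returns
    -------
    mhc_genotypes : dict
        individual id -> frozenset of allele ids (1–4 alleles).
    microsat : MicrosatGenotypeTable
        Diploid genotypes at ``n_microsat_loci`` loci.
    population_map : pandas.Series
        individual id -> population name.
    """
    from .popgen_stats import MicrosatGenotypeTable

    model.validate(library)
    rng = np.random.default_rng(seed)
    pop_names = model.names()
    allele_ids = library.ids

    anc_mhc = model.mhc_ancestral_freqs
    if anc_mhc is None:
        # moderately skewed ancestral pool: one common allele plus a tail,
        # mirroring the single predominant DRB allele seen in real data
        w = rng.dirichlet(np.full(len(allele_ids), 1.5))
        anc_mhc = w / w.sum()
    anc_micro = [rng.dirichlet(np.full(model.microsat_n_alleles, 2.0))
                 for _ in range(n_microsat_loci)]

    copy_sizes = np.arange(1, len(model.copy_number_dist) + 1)
    mhc_genotypes = {}
    pop_of = {}
    geno = np.zeros((sum(model.pop_sizes), n_microsat_loci, 2), dtype=int)
    individuals = []
    row = 0
    for p, (pname, n_ind) in enumerate(zip(pop_names, model.pop_sizes)):
        f_mhc = _dirichlet_freqs(rng, anc_mhc, model.theta_fst)
        f_micro = [_dirichlet_freqs(rng, a, model.theta_fst)
                   for a in anc_micro]
        for i in range(n_ind):
            ind = f"{pname}_{i + 1:03d}"
            individuals.append(ind)
            pop_of[ind] = pname
            k = int(rng.choice(copy_sizes, p=model.copy_number_dist))
            chosen = rng.choice(len(allele_ids), size=k, replace=False,
                                p=f_mhc)
            mhc_genotypes[ind] = frozenset(allele_ids[j] for j in chosen)
            for l in range(n_microsat_loci):
                geno[row, l] = rng.choice(model.microsat_n_alleles, size=2,
                                          p=f_micro[l]) + 1
            row += 1

    population_map = pd.Series(pop_of, name="population")
    loci = [f"loc{l + 1:02d}" for l in range(n_microsat_loci)]
    microsat = MicrosatGenotypeTable(individuals, loci, geno, population_map)
    return mhc_genotypes, microsat, population_map


# ---------------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------------

@dataclass
class ReadModel:
    """Per-amplicon sequencing depth and artifact model.

    Depth is negative-binomial with the given mean and SD, truncated at
    >= 1 read (454-like overdispersion).  Each true allele in an amplicon
    spawns ``artifact_types`` artifact variants (1–2 bp substitution
    copies); each artifact's read count is Binomial(parent reads,
    artifact_sub_rate / artifact_types), so artifacts are always rarer
    than their parent in expectation.  ``amplification_concentration``
    controls how evenly reads split among an individual's true alleles
    (Dirichlet concentration per allele; larger = more even).
    """

    depth_mean: float = 635.0
    depth_sd: float = 436.0
    artifact_sub_rate: float = 0.10
    artifact_types: int = 2
    chimera_rate: float = 0.0
    amplification_concentration: float = 30.0

    def validate(self):
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for r in (self.artifact_sub_rate, self.chimera_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")

    def draw_depth(self, rng, size=None):
        mean, var = self.depth_mean, self.depth_sd ** 2
        if var <= mean:
            d = rng.poisson(mean, size=size)
        else:
            # negative binomial: var = mean + mean^2 / r
            r = mean ** 2 / (var - mean)
            p = r / (r + mean)
            d = rng.negative_binomial(r, p, size=size)
        return np.maximum(d, 1)


DEFAULT_FORWARD_PRIMER = "TCAATGGGACGGAGCGGGTGC"
DEFAULT_REVERSE_PRIMER = "CCGCTGCACAGTGAAACTCTC"


@dataclass(frozen=True)
class Primers:
    forward: str = DEFAULT_FORWARD_PRIMER
    reverse: str = DEFAULT_REVERSE_PRIMER


@dataclass
class TagScheme:
    """Assignment of (forward MID, reverse MID) pairs to amplicons.

    MIDs are short identifier tags ligated to both ends of each amplicon;
    combinations of a small MID set yield many unique amplicon labels.
    """

    forward_mids: tuple
    reverse_mids: tuple
    assignment: dict  # amplicon id -> (fwd mid index, rev mid index)

    @classmethod
    def make_default(cls, amplicon_ids, n_forward: int = 12,
                     n_reverse: int = 8, mid_length: int = 10,
                     seed: int = 0) -> "TagScheme":
        """Random distinct MIDs and a deterministic pairing."""
        rng = np.random.default_rng(seed)
        mids = set()
        while len(mids) < n_forward + n_reverse:
            mids.add("".join(rng.choice(list(NUCLEOTIDES), size=mid_length)))
        mids = sorted(mids)
        fwd, rev = tuple(mids[:n_forward]), tuple(mids[n_forward:])
        combos = list(itertools.product(range(n_forward), range(n_reverse)))
        if len(amplicon_ids) > len(combos):
            raise ValueError(
                f"{len(amplicon_ids)} amplicons exceed the "
                f"{len(combos)} available tag combinations")
        assignment = {a: combos[i] for i, a in enumerate(amplicon_ids)}
        return cls(fwd, rev, assignment)

    def tags_for(self, amplicon_id):
        fi, ri = self.assignment[amplicon_id]
        return self.forward_mids[fi], self.reverse_mids[ri]


def _mutate_copy(rng, seq: str, n_sub: int, forbidden: set) -> str | None:
    """A 1–2 bp substitution copy of ``seq`` not present in ``forbidden``."""
    for _ in range(50):
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        cand = list(seq)
        for p in pos:
            cand[p] = rng.choice([b for b in NUCLEOTIDES if b != cand[p]])
        cand = "".join(cand)
        if cand not in forbidden:
            return cand
    return None


def simulate_amplicon_reads(mhc_genotypes: dict, library: AlleleLibrary,
                            read_model: ReadModel | None = None,
                            tag_scheme: TagScheme | None = None,
                            primers: Primers | None = None,
                            seed: int = 0, run_of: dict | None = None):
    """Emit tagged amplicon reads plus a per-variant truth table.

    Each read is laid out on the forward strand as

        forward MID + forward primer + variant + rc(reverse primer) + rc(reverse MID)

    and roughly half of the reads are emitted reverse-complemented.

    Returns
    -------
    reads : list of (read id, sequence)
    truth : pandas.DataFrame
        One row per (amplicon, variant): columns amplicon, individual, run,
        sequence, count, kind ('true' | 'artifact' | 'chimera'),
        parent_allele, allele_id.
    tag_scheme : TagScheme
    """
    read_model = read_model or ReadModel()
    read_model.validate()
    primers = primers or Primers()
    amplicon_ids = sorted(mhc_genotypes)
    if tag_scheme is None:
        tag_scheme = TagScheme.make_default(amplicon_ids, seed=seed)
    if run_of is None:
        run_of = {a: "run1" for a in amplicon_ids}
    for amp, geno in mhc_genotypes.items():
        for aid in geno:
            library.sequence(aid)  # raises KeyError if absent

    rng = np.random.default_rng(seed)
    reads = []
    truth_rows = []
    seq_of = dict(library.alleles)
    for amp in amplicon_ids:
        geno = sorted(mhc_genotypes[amp])
        fmid, rmid = tag_scheme.tags_for(amp)
        depth = int(read_model.draw_depth(rng))
        weights = rng.dirichlet(
            np.full(len(geno), read_model.amplification_concentration))
        counts = rng.multinomial(depth, weights)
        true_seqs = {seq_of[a] for a in geno}
        variant_counts = []  # (sequence, count, kind, parent, allele_id)
        for aid, n_parent in zip(geno, counts):
            if n_parent == 0:
                n_parent = 1  # every true allele leaves at least one read
            parent_seq = seq_of[aid]
            n_art_total = 0
            if read_model.artifact_sub_rate > 0 and n_parent > 1:
                taken = set(true_seqs)
                for t in range(read_model.artifact_types):
                    c = rng.binomial(
                        n_parent,
                        read_model.artifact_sub_rate / read_model.artifact_types)
                    c = min(c, n_parent - n_art_total - 1)
                    if c <= 0:
                        continue
                    art = _mutate_copy(rng, parent_seq,
                                       int(rng.integers(1, 3)), taken)
                    if art is None:
                        continue
                    taken.add(art)
                    variant_counts.append((art, c, "artifact", aid, None))
                    n_art_total += c
            variant_counts.append(
                (parent_seq, n_parent - n_art_total, "true", None, aid))
        if read_model.chimera_rate > 0 and len(geno) >= 2:
            n_chi = rng.binomial(depth, read_model.chimera_rate)
            if n_chi > 0:
                a, b = rng.choice(geno, size=2, replace=False)
                cut = int(rng.integers(10, library.length - 10))
                chi = seq_of[a][:cut] + seq_of[b][cut:]
                if chi not in {v[0] for v in variant_counts}:
                    variant_counts.append((chi, n_chi, "chimera", a, None))

        i_read = 0
        for seq, count, kind, parent, allele_id in variant_counts:
            truth_rows.append(dict(
                amplicon=amp, individual=amp, run=run_of[amp],
                sequence=seq, count=int(count), kind=kind,
                parent_allele=parent, allele_id=allele_id))
            layout = (fmid + primers.forward + seq
                      + revcomp(primers.reverse) + revcomp(rmid))
            for _ in range(int(count)):
                rid = f"{amp}|r{i_read:05d}"
                emitted = layout if rng.random() < 0.5 else revcomp(layout)
                reads.append((rid, emitted))
                i_read += 1

    truth = pd.DataFrame(truth_rows)
    return reads, truth, tag_scheme


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_fasta(path):
    """Read FASTA into a list of (id, sequence)."""
    from Bio import SeqIO
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
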