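"""Genotype calling from per-amplicon variant tables.

Two callers are provided, both resting on the assumption that PCR and
sequencing artifacts are rarer than the true alleles they derive from:

* the *validation-threshold* method: variants are classified by their
  maximum per-amplicon frequency (MPAF).  Very rare variants (MPAF at or
  below ``artifact_max``) are artifacts; common variants (MPAF at or above
  ``true_min``) carried by more than one amplicon — ideally on independent
  sequencing runs — are true alleles; the intermediate band is screened
  automatically by the three published criteria (1–2 bp distance from a
  parental allele, premature stop codon, frame shift).

* the *degree-of-change* (DOC) method: within each amplicon, variants are
  ranked by read count, the cumulative depth proportion is computed, and
  the genotype boundary is placed at the largest drop between successive
  degree-of-change values — the inflection that separates true alleles
  from the artifact tail.

Both callers cap genotypes at ``max_alleles`` (two duplicated loci → at
most four alleles per individual) and never call a variant that is absent
from the amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon_processing import VariantTable
from .synthetic_data import hamming, translate


def compute_mpaf(table: VariantTable) -> pd.DataFrame:
    """Maximum per-amplicon frequency of every distinct variant.

    MPAF is the maximum, over all amplicons carrying the variant, of the
    variant's share of that amplicon's reads.  Returns one row per variant
    with columns variant_id, sequence, mpaf, n_amplicons, n_runs,
    carriers (list of amplicon ids), proportions (list, same order).
    """
    depth = table.meta.set_index("amplicon")["depth"]
    if (depth <= 0).any():
        raise ValueError("every amplicon must have positive depth")
    run = table.meta.set_index("amplicon")["run"]
    rows = []
    for vid, grp in table.counts.groupby("variant_id"):
        props = (grp["count"].to_numpy()
                 / depth.loc[grp["amplicon"]].to_numpy())
        rows.append(dict(
            variant_id=vid, sequence=grp["sequence"].iloc[0],
            mpaf=float(props.max()), n_amplicons=len(grp),
            n_runs=run.loc[grp["amplicon"]].nunique(),
            carriers=list(grp["amplicon"]), proportions=list(props)))
    return (pd.DataFrame(rows)
            .sort_values("mpaf", ascending=False)
            .reset_index(drop=True))


@dataclass
class GenotypeCalls:
    """Called allele sets per amplicon (1–4 variants each).

    ``calls`` maps amplicon id -> tuple of called variant ids (empty for a
    no-call); ``flags`` maps amplicon id -> list of quality flags;
    ``sequences`` maps variant id -> nucleotide sequence; ``individual_of``
    maps amplicon -> individual id.
    """

    method: str
    calls: dict
    sequences: dict
    individual_of: dict
    flags: dict = field(default_factory=dict)

    def allele_set(self, amplicon):
        return frozenset(self.calls[amplicon])

    def sequence_sets(self):
        """amplicon -> frozenset of called allele sequences."""
        return {a: frozenset(self.sequences[v] for v in vs)
                for a, vs in self.calls.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(amplicon=a, individual=self.individual_of.get(a, a),
                     method=self.method, alleles=";".join(sorted(v)),
                     flags=";".join(self.flags.get(a, [])))
                for a, v in self.calls.items()]
        return pd.DataFrame(rows)

    def validate(self, table: VariantTable | None = None,
                 max_alleles: int = 4) -> None:
        for a, vs in self.calls.items():
            if len(vs) > max_alleles:
                raise ValueError(f"{a}: more than {max_alleles} alleles")
            if not vs and "no_call" not in self.flags.get(a, []):
                raise ValueError(f"{a}: empty genotype without no_call flag")
            if table is not None:
                present = set(table.variants(a)["variant_id"])
                if not set(vs) <= present:
                    raise ValueError(f"{a}: called variant absent from amplicon")


def _is_functional(seq: str, frame_offset: int, expected_length: int) -> bool:
    """No frame shift (expected length) and no premature stop codon."""
    if len(seq) != expected_length:
        return False
    return "*" not in translate(seq, frame_offset)


@dataclass
class ThresholdConfig:
    artifact_max: float = 0.03
    true_min: float = 0.10
    parent_min: float = 0.10
    parent_dist: int = 2
    frame_offset: int = 2


def classify_variants(table: VariantTable, mpaf: pd.DataFrame,
                      config: ThresholdConfig | None = None,
                      overrides: dict | None = None) -> pd.DataFrame:
    """Classify every variant as a true allele or an artifact.

    Rules, applied in order:

    1. MPAF <= artifact_max -> artifact (a parental variant within
       ``parent_dist`` substitutions and MPAF > parent_min in the same
       amplicon is recorded when present).
    2. MPAF >= true_min -> true allele when carried by more than one
       amplicon (or more than one run); a private high-frequency variant
       is accepted if functional (no premature stop, no frame shift) and
       annotated for review — artifacts never reach such frequencies
       under the rarer-than-parent assumption.
    3. Intermediate band: true only if the variant is NOT within
       ``parent_dist`` substitutions of a same-amplicon variant of higher
       MPAF above ``parent_min`` AND is functional.

    ``overrides`` (variant id -> 'true' | 'artifact') replaces the
    automatic decision, replacing what would otherwise be manual review.
    """
    config = config or ThresholdConfig()
    overrides = overrides or {}
    mpaf_of = mpaf.set_index("variant_id")["mpaf"].to_dict()
    seq_of = mpaf.set_index("variant_id")["sequence"].to_dict()
    L = len(next(iter(seq_of.values())))

    # same-amplicon neighbours above the parental threshold
    parent_of = {}
    for amp in table.amplicons():
        vs = table.variants(amp)
        vids = list(vs["variant_id"])
        for v in vids:
            if v in parent_of:
                continue
            for w in vids:
                if w == v or mpaf_of[w] <= config.parent_min:
                    continue
                if mpaf_of[w] <= mpaf_of[v]:
                    continue
                if hamming(seq_of[v], seq_of[w]) <= config.parent_dist:
                    parent_of[v] = w
                    break

    rows = []
    for _, rec in mpaf.iterrows():
        v = rec["variant_id"]
        parent = parent_of.get(v)
        functional = _is_functional(seq_of[v], config.frame_offset, L)
        if v in overrides:
            status, reason = overrides[v], "override"
        elif rec["mpaf"] <= config.artifact_max:
            status, reason = "artifact", "low MPAF"
        elif rec["mpaf"] >= config.true_min:
            if rec["n_amplicons"] > 1 or rec["n_runs"] > 1:
                status, reason = "true", "high MPAF, multiple carriers"
            elif functional:
                status, reason = "true", "high MPAF, private (review)"
            else:
                status, reason = "artifact", "non-functional"
        elif parent is None and functional:
            status, reason = "true", "intermediate band, passed screening"
        elif parent is not None:
            status, reason = "artifact", "within parental distance"
        else:
            status, reason = "artifact", "non-functional"
        rows.append(dict(variant_id=v, status=status, reason=reason,
                         parent=parent, functional=functional,
                         mpaf=rec["mpaf"]))
    return pd.DataFrame(rows)


def call_alleles_threshold(table: VariantTable,
                           mpaf: pd.DataFrame | None = None,
                           config: ThresholdConfig | None = None,
                           overrides: dict | None = None,
                           max_alleles: int = 4) -> GenotypeCalls:
    """Validation-threshold genotyper (see module docstring)."""
    config = config or ThresholdConfig()
    if mpaf is None:
        mpaf = compute_mpaf(table)
    cls = classify_variants(table, mpaf, config, overrides)
    true_ids = set(cls.loc[cls["status"] == "true", "variant_id"])

    calls, flags = {}, {}
    individual_of = table.meta.set_index("amplicon")["individual"].to_dict()
    for amp in table.amplicons():
        vs = table.variants(amp)
        keep = vs[vs["variant_id"].isin(true_ids)]
        amp_flags = []
        if len(keep) > max_alleles:
            amp_flags.append("truncated")
            keep = keep.iloc[:max_alleles]
        if len(keep) == 0:
            amp_flags.append("no_call")
        calls[amp] = tuple(keep["variant_id"])
        flags[amp] = amp_flags
    seqs = mpaf.set_index("variant_id")["sequence"].to_dict()
    out = GenotypeCalls("threshold", calls, seqs, individual_of, flags)
    out.validate(table, max_alleles)
    return out


def doc_breakpoint(counts, max_alleles: int = 4):
    """Degree-of-change breakpoint for one amplicon's ranked read counts.

    ``counts`` must be sorted descending.  With cumulative depth
    proportions c_i (c_0 = 0), the degree of change DOC_i = c_i - c_{i-1}
    is simply the depth share of rank i; the genotype boundary b maximizes
    DOC_b - DOC_{b+1} over b <= max_alleles (DOC beyond the last variant
    is zero).  Returns (b, doc) where doc is the DOC vector.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(np.diff(counts) > 0):
        raise ValueError("counts must be ranked in descending order")
    doc = counts / counts.sum()
    upper = min(max_alleles, len(doc))
    drops = [doc[i] - (doc[i + 1] if i + 1 < len(doc) else 0.0)
             for i in range(upper)]
    b = int(np.argmax(drops)) + 1
    return b, doc


def call_alleles_doc(table: VariantTable, max_alleles: int = 4,
                     min_depth: int = 50) -> GenotypeCalls:
    """Degree-of-change genotyper (see module docstring).

    Amplicons below ``min_depth`` reads are still called but flagged
    ``low_quality``; a tie in read counts at the breakpoint boundary is
    flagged ``ambiguous``.
    """
    calls, flags, seqs = {}, {}, {}
    individual_of = table.meta.set_index("amplicon")["individual"].to_dict()
    for amp in table.amplicons():
        vs = table.variants(amp)  # sorted by count desc, sequence asc
        amp_flags = []
        if len(vs) == 0:
            calls[amp] = ()
            flags[amp] = ["no_call"]
            continue
        depth = int(vs["count"].sum())
        if depth < min_depth:
            amp_flags.append("low_quality")
        b, _ = doc_breakpoint(vs["count"].to_numpy(), max_alleles)
        if b < len(vs) and vs["count"].iloc[b - 1] == vs["count"].iloc[b]:
            amp_flags.append("ambiguous")
        picked = vs.iloc[:b]
        calls[amp] = tuple(picked["variant_id"])
        flags[amp] = amp_flags
        seqs.update(dict(zip(vs["variant_id"], vs["sequence"])))
    out = GenotypeCalls("doc", calls, seqs, individual_of, flags)
    out.validate(table, max_alleles)
    return out


@dataclass
class RepeatabilityReport:
    """Concordance of genotype calls between duplicate runs."""

    n_duplicates: int
    n_full_match: int
    n_one_mismatch: int
    n_full_mismatch: int
    n_excluded: int = 0

    @property
    def proportions(self):
        n = self.n_duplicates
        return dict(full_match=self.n_full_match / n,
                    one_mismatch=self.n_one_mismatch / n,
                    full_mismatch=self.n_full_mismatch / n)

    def validate(self):
        total = self.n_full_match + self.n_one_mismatch + self.n_full_mismatch
        if total != self.n_duplicates:
            raise ValueError("repeatability counts do not sum to n_duplicates")


def genotyping_repeatability(calls_a: GenotypeCalls,
                             calls_b: GenotypeCalls) -> RepeatabilityReport:
    """Compare duplicate calls individual-by-individual.

    Classification: identical sets -> full match; disjoint non-empty
    sets -> full mismatch; a symmetric difference touching at most one
    allele per side -> one-allele mismatch.  Overlapping sets differing
    by more than one allele per side are rated full mismatches
    (conservative).  Comparison is by allele *sequence*, so two call sets
    produced from different variant tables are comparable.  Individuals
    flagged no-call in either run are excluded and counted separately.
    """
    by_ind_a = {calls_a.individual_of.get(a, a): s
                for a, s in calls_a.sequence_sets().items()}
    by_ind_b = {calls_b.individual_of.get(a, a): s
                for a, s in calls_b.sequence_sets().items()}
    shared = sorted(set(by_ind_a) & set(by_ind_b))
    if not shared:
        raise ValueError("no shared individuals between call sets")

    full = one = mismatch = excluded = 0
    for ind in shared:
        sa, sb = by_ind_a[ind], by_ind_b[ind]
        if not sa or not sb:
            excluded += 1
            continue
        if sa == sb:
            full += 1
        elif not (sa & sb):
            mismatch += 1
        elif len(sa - sb) <= 1 and len(sb - sa) <= 1:
            one += 1
        else:
            mismatch += 1
    report = RepeatabilityReport(
        n_duplicates=full + one + mismatch, n_full_match=full,
        n_one_mismatch=one, n_full_mismatch=mismatch, n_excluded=excluded)
    report.validate()
    return report
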