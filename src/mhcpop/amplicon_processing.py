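"""Demultiplexing of tagged amplicon reads and per-amplicon variant tables.

Reads carry a forward MID + forward primer at one end and the reverse
complement of reverse primer + reverse MID at the other.  Demultiplexing
uses exact string matching (MID sets in such designs differ by several
bases, so a single mismatch cannot cause misassignment); reads are
canonicalized to the forward strand before comparison.  Reads without
complete tags/primers, with ambiguous bases, or whose insert is not the
expected allele length are discarded with an explicit reason — no read is
lost silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthetic_data import Primers, TagScheme, revcomp

#: discard reasons
MISSING_TAG = "missing tag"
INCOMPLETE_PRIMER = "incomplete primer"
AMBIGUOUS_TAG = "ambiguous tag"
AMBIGUOUS_BASES = "ambiguous bases"
LENGTH_MISMATCH = "length mismatch"


def _match_end(seq: str, mids, primer: str):
    """Match MID+primer at the start of ``seq``.

    Returns (mid index or None, reason or None, insert start offset).
    """
    hits = [i for i, mid in enumerate(mids) if seq.startswith(mid + primer)]
    if len(hits) == 1:
        mid = mids[hits[0]]
        return hits[0], None, len(mid) + len(primer)
    if len(hits) > 1:
        return None, AMBIGUOUS_TAG, 0
    # distinguish a present tag with a broken primer from a missing tag
    tag_hits = [i for i, mid in enumerate(mids) if seq.startswith(mid)]
    if tag_hits:
        return None, INCOMPLETE_PRIMER, 0
    return None, MISSING_TAG, 0


def demultiplex(reads, tag_scheme: TagScheme, primers: Primers | None = None,
                expected_length: int = 185):
    """Assign reads to amplicons by exact MID/primer matching.

    Parameters
    ----------
    reads : iterable of (read id, sequence) or path to a FASTA file.
    tag_scheme : TagScheme
        Collision-free (forward, reverse) MID assignment per amplicon.
    expected_length : int
        Required insert length; anything else (indels upstream) is
        discarded as a length mismatch.

    Returns
    -------
    assignments : dict
        amplicon id -> list of insert sequences (forward strand).
    discard_log : pandas.DataFrame with columns read_id, reason.
    """
    primers = primers or Primers()
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        from .synthetic_data import read_fasta
        reads = read_fasta(reads)

    pair_to_amp = {}
    for amp, (fi, ri) in tag_scheme.assignment.items():
        key = (fi, ri)
        if key in pair_to_amp:
            raise ValueError(f"tag collision: {key} assigned twice")
        pair_to_amp[key] = amp

    fmids = tag_scheme.forward_mids
    rmids = tag_scheme.reverse_mids
    rprimer_rc = revcomp(primers.reverse)
    rmids_rc = [revcomp(m) for m in rmids]

    assignments = {amp: [] for amp in tag_scheme.assignment}
    discards = []

    def _try_orientation(seq):
        """Return (amp, insert) or (None, reason)."""
        fi, reason, off = _match_end(seq, fmids, primers.forward)
        if fi is None:
            return None, reason
        # reverse end: insert + rc(reverse primer) + rc(reverse MID)
        tail_hits = [i for i, m in enumerate(rmids_rc)
                     if seq.endswith(rprimer_rc + m)]
        if len(tail_hits) > 1:
            return None, AMBIGUOUS_TAG
        if not tail_hits:
            if any(seq.endswith(m) for m in rmids_rc):
                return None, INCOMPLETE_PRIMER
            return None, MISSING_TAG
        ri = tail_hits[0]
        insert = seq[off:len(seq) - len(rprimer_rc) - len(rmids_rc[ri])]
        amp = pair_to_amp.get((fi, ri))
        if amp is None:
            return None, AMBIGUOUS_TAG
        return (amp, insert), None

    for rid, seq in reads:
        seq = seq.upper()
        hit, reason_f = _try_orientation(seq)
        if hit is None:
            hit, reason_r = _try_orientation(revcomp(seq))
        if hit is None:
            # report the more informative of the two failure reasons
            order = [INCOMPLETE_PRIMER, AMBIGUOUS_TAG, MISSING_TAG]
            reason = min((reason_f, reason_r),
                         key=lambda r: order.index(r) if r in order else 99)
            discards.append((rid, reason))
            continue
        amp, insert = hit
        if any(b not in "ACGT" for b in insert):
            discards.append((rid, AMBIGUOUS_BASES))
            continue
        if len(insert) != expected_length:
            discards.append((rid, LENGTH_MISMATCH))
            continue
        assignments[amp].append(insert)

    discard_log = pd.DataFrame(discards, columns=["read_id", "reason"])
    return assignments, discard_log


@dataclass
class VariantTable:
    """Per-amplicon read counts per distinct sequence variant.

    ``counts`` has one row per (amplicon, variant) with columns
    amplicon, variant_id, sequence, count; ``meta`` one row per amplicon
    with columns amplicon, individual, run, depth, n_variants, flags.
    Variant ids are global across the table (same sequence, same id).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def depth(self, amplicon: str) -> int:
        return int(self.meta.set_index("amplicon").loc[amplicon, "depth"])

    def amplicons(self):
        return list(self.meta["amplicon"])

    def variants(self, amplicon: str) -> pd.DataFrame:
        sub = self.counts[self.counts["amplicon"] == amplicon]
        return sub.sort_values(["count", "sequence"],
                               ascending=[False, True]).reset_index(drop=True)

    def sequence_of(self, variant_id: str) -> str:
        row = self.counts[self.counts["variant_id"] == variant_id]
        return row["sequence"].iloc[0]

    def validate(self) -> None:
        if (self.counts["count"] < 1).any():
            raise ValueError("variant counts must be >= 1")
        got = self.counts.groupby("amplicon")["count"].sum()
        want = self.meta.set_index("amplicon")["depth"]
        for amp, d in want.items():
            if got.get(amp, 0) != d:
                raise ValueError(f"depth mismatch for amplicon {amp}")
        lens = self.counts["sequence"].str.len()
        if len(self.counts) and lens.nunique() != 1:
            raise ValueError("variant sequences differ in length")

    def to_csv(self, counts_path, meta_path) -> None:
        self.counts.to_csv(counts_path, index=False)
        self.meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, counts_path, meta_path) -> "VariantTable":
        return cls(pd.read_csv(counts_path), pd.read_csv(meta_path))


def tabulate_variants(assignments: dict, individual_of: dict | None = None,
                      run_of: dict | None = None) -> VariantTable:
    """Collapse identical read sequences within each amplicon.

    Empty amplicons are retained with zero variants and flagged ``empty``.
    Variant ids are assigned across the whole table, ordered by total
    count (descending) then sequence, so the mapping is deterministic.
    """
    if not assignments:
        raise ValueError("no amplicons to tabulate")
    individual_of = individual_of or {a: a for a in assignments}
    run_of = run_of or {a: "run1" for a in assignments}

    rows = []
    meta_rows = []
    for amp in sorted(assignments):
        seq_counts = {}
        for seq in assignments[amp]:
            seq_counts[seq] = seq_counts.get(seq, 0) + 1
        for seq, c in seq_counts.items():
            rows.append(dict(amplicon=amp, sequence=seq, count=c))
        meta_rows.append(dict(
            amplicon=amp, individual=individual_of[amp], run=run_of[amp],
            depth=sum(seq_counts.values()), n_variants=len(seq_counts),
            flags="empty" if not seq_counts else ""))

    counts = pd.DataFrame(rows, columns=["amplicon", "sequence", "count"])
    totals = (counts.groupby("sequence")["count"].sum()
              .sort_values(ascending=False))
    order = sorted(totals.index, key=lambda s: (-totals[s], s))
    vid = {seq: f"V{i + 1:04d}" for i, seq in enumerate(order)}
    counts["variant_id"] = counts["sequence"].map(vid)
    counts = counts[["amplicon", "variant_id", "sequence", "count"]]
    meta = pd.DataFrame(meta_rows)
    table = VariantTable(counts, meta)
    table.validate()
    return table
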