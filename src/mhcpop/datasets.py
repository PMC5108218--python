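"""Bundled and externally supplied datasets.

The package ships one small table of published per-population diversity
summaries for eight American badger populations (20 microsatellite loci
and MHC DRB exon 2): observed/expected heterozygosity, rarefied allelic
and private allelic richness, inbreeding coefficient, MHC allele counts,
private MHC alleles, MHC individual diversity and mean pairwise
differences.  It is the input for the cross-marker correlation analyses.

Primary data (the 26 DRB allele sequences on GenBank and the genotype
archive on Dryad) are not redistributed; loaders below read locally
downloaded copies when present.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

#: GenBank accessions of the 26 published DRB exon-2 allele sequences.
MHC_ALLELE_ACCESSIONS = [f"KU0590{n}" for n in range(84, 110)]


def load_diversity_summary() -> pd.DataFrame:
    """Published per-population diversity summary (eight populations)."""
    with resources.files("mhcpop.data").joinpath(
            "badger_diversity_summary.csv").open() as fh:
        return pd.read_csv(fh).set_index("population")


def load_local_allele_fasta(path) -> list:
    """Read a locally supplied FASTA of published allele sequences.

    Raises FileNotFoundError with download guidance if absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. Download the {len(MHC_ALLELE_ACCESSIONS)} "
            f"allele sequences ({MHC_ALLELE_ACCESSIONS[0]}–"
            f"{MHC_ALLELE_ACCESSIONS[-1]}) from GenBank as FASTA and place "
            f"them at this path.")
    from .synthetic_data import read_fasta
    return read_fasta(path)


def load_local_genepop(path):
    """Read a locally supplied GenePop genotype archive (Dryad qb87r)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. Download the microsatellite genotype "
            f"archive (Dryad doi:10.5061/dryad.qb87r), convert to GenePop, "
            f"and place it at this path.")
    from .genepop import read_genepop
    return read_genepop(path)
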