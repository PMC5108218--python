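import numpy as np
import pandas as pd
import pytest

import mhcpop as m


@pytest.fixture(scope="session")
def library():
    """Default-scale allele library: 26 alleles, 185 bp, frame offset 2."""
    return m.generate_allele_library(26, length=185, frame_offset=2, seed=1)


@pytest.fixture(scope="session")
def small_library():
    return m.generate_allele_library(8, length=30, frame_offset=0, seed=5,
                                     n_pbr_sites=3)


@pytest.fixture(scope="session")
def study(library):
    """A two-population study slice with reads, truth and variant table."""
    model = m.PopulationModel(n_pops=2, pop_sizes=(15, 15), theta_fst=0.10,
                              pop_names=("west", "east"))
    mhc, microsat, pop_map = m.simulate_populations(model, library, 10,
                                                    seed=7)
    reads, truth, scheme = m.simulate_amplicon_reads(
        mhc, library, m.ReadModel(), seed=8)
    assignments, discards = m.demultiplex(reads, scheme)
    table = m.tabulate_variants(assignments)
    return dict(library=library, mhc=mhc, microsat=microsat,
                pop_map=pop_map, reads=reads, truth=truth, scheme=scheme,
                assignments=assignments, discards=discards, table=table)


def true_sequence_sets(truth: pd.DataFrame) -> dict:
    return {a: frozenset(g.loc[g["kind"] == "true", "sequence"])
            for a, g in truth.groupby("amplicon")}


@pytest.fixture()
def toy_table():
    """Hand-built variant table: three amplicons, known proportions."""
    counts = pd.DataFrame([
        # amp1: v1 dominant, v2 at 12%
        ("amp1", "V0001", "AAATTTGGG", 880),
        ("amp1", "V0002", "AAATTTGGA", 120),
        # amp2: v1 at 40/400, v2 at 2%, v3 rest
        ("amp2", "V0001", "AAATTTGGG", 40),
        ("amp2", "V0002", "AAATTTGGA", 8),
        ("amp2", "V0003", "CCCTTTGGG", 352),
        # amp3: v2 at 5%, v3 at 95%-ish
        ("amp3", "V0002", "AAATTTGGA", 25),
        ("amp3", "V0003", "CCCTTTGGG", 475),
    ], columns=["amplicon", "variant_id", "sequence", "count"])
    meta = pd.DataFrame([
        ("amp1", "ind1", "run1", 1000, 2, ""),
        ("amp2", "ind2", "run1", 400, 3, ""),
        ("amp3", "ind3", "run2", 500, 2, ""),
    ], columns=["amplicon", "individual", "run", "depth", "n_variants",
                "flags"])
    from mhcpop.amplicon_processing import VariantTable
    return VariantTable(counts, meta)
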