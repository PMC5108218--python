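"""Minimal GenePop format reader/writer (2- and 3-digit dialects).

GenePop files hold diploid microsatellite genotypes: a title line, one
locus name per line (or comma-separated), then one ``Pop`` block per
population with lines ``individual ,  aabb aabb ...`` where each genotype
concatenates two zero-padded allele codes of 2 or 3 digits; ``00``/``000``
codes a missing allele.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_genepop(path):
    """Parse a GenePop file into a MicrosatGenotypeTable.

    The allele-code width (2 or 3 digits) is inferred from the data.
    Missing alleles (all-zero codes) become -1.
    """
    from .popgen_stats import MicrosatGenotypeTable

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty GenePop file")
    lines = lines[1:]  # title

    loci = []
    i = 0
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if not loci:
        raise ValueError("no locus names found")

    individuals, genos, pops = [], [], []
    pop_idx = 0
    pop_first = None
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            pop_first = None
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ValueError(f"malformed GenePop line: {line!r}")
        name, data = line.split(",", 1)
        name = name.strip()
        if pop_first is None:
            pop_first = name
        fields = data.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"{name}: {len(fields)} genotypes for {len(loci)} loci")
        width = len(fields[0]) // 2
        if width not in (2, 3):
            raise ValueError(f"{name}: unsupported allele-code width")
        row = []
        for f in fields:
            a, b = int(f[:width]), int(f[width:])
            row.append((a if a > 0 else -1, b if b > 0 else -1))
        individuals.append(name)
        genos.append(row)
        pops.append(f"pop{pop_idx}" if pop_first is None else pop_first)

    geno = np.array(genos, dtype=int)
    pop_map = pd.Series(pops, index=individuals, name="population")
    return MicrosatGenotypeTable(individuals, loci, geno, pop_map)


def write_genepop(table, path, title: str = "mhcpop export",
                  digits: int = 3) -> None:
    """Write a MicrosatGenotypeTable as GenePop.

    The last individual of each population names the Pop block (GenePop's
    convention uses the first line after ``Pop``; we emit individuals in
    population order so round-trips preserve the grouping).
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if (table.genotypes >= 10 ** digits).any():
        raise ValueError(f"allele label does not fit in {digits} digits")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in table.loci:
            fh.write(loc + "\n")
        for pop in table.populations.unique():
            fh.write("Pop\n")
            for ind in table.individuals_of(pop):
                row = table.genotypes[table.index_of(ind)]
                codes = []
                for a, b in row:
                    a = 0 if a < 0 else a
                    b = 0 if b < 0 else b
                    codes.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{ind} ,  " + " ".join(codes) + "\n")
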