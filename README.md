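# mhcpop

Genotyping of multi-locus MHC amplicons and comparison of adaptive versus
neutral population structure.

Conservation genetics routinely asks whether small, isolated populations
that have lost neutral genetic diversity still harbour adaptive
(immunogenetic) variation. Answering that requires two things this package
provides end to end:

1. **Reliable MHC genotypes from deep amplicon sequencing.** MHC class II
   loci are often duplicated, so an individual carries 1–4 alleles that
   cannot be assigned to loci, and PCR/sequencing artifacts (1–2 bp
   substitution copies of true alleles) contaminate every amplicon.
   `mhcpop` demultiplexes MID-tagged reads, tabulates per-amplicon
   variants, and calls genotypes by two published filtering strategies:
   the *validation-threshold* method based on the maximum per-amplicon
   frequency (MPAF: artifacts ≤ 3%, true alleles ≥ 10% with replication,
   an automatically screened intermediate band) and the *degree-of-change*
   (DOC) method, which places a breakpoint at the largest drop in
   cumulative read-depth share across depth-ranked variants.
2. **Marker-contrast statistics.** Jukes–Cantor sequence diversity and the
   one-tailed Nei–Gojobori Z-test of positive selection (dN/dS with codon
   bootstrap); observed/expected heterozygosity, Weir–Cockerham
   F<sub>IS</sub>, rarefied allelic and private allelic richness;
   AMOVA-framework F<sub>ST</sub>/Φ<sub>ST</sub> (allele-sharing distances
   for microsatellites, JC haplotype distances for MHC), hierarchical
   AMOVA, Mantel and partial Mantel tests, dominant binary encoding, and
   co-inertia analysis with the RV coefficient.

A fully seeded synthetic-data generator (Balding–Nichols drift across
populations, empirical 1–4 allele copy-number distribution, negative
binomial 454-like depth, substitution artifacts) stands in for raw reads,
so the whole pipeline is testable offline. See `docs/methods.md` for the
models and conventions.

## Worked example

```python
import mhcpop as m

lib = m.generate_allele_library(26, length=185, frame_offset=2, seed=1)
model = m.PopulationModel(n_pops=2, pop_sizes=(15, 15), theta_fst=0.10,
                          pop_names=("west", "east"))
mhc_truth, microsat, pops = m.simulate_populations(model, lib, 10, seed=7)

reads, truth, tags = m.simulate_amplicon_reads(mhc_truth, lib,
                                               m.ReadModel(), seed=8)
assignments, discards = m.demultiplex(reads, tags)
table = m.tabulate_variants(assignments)
calls = m.call_alleles_doc(table)

het = m.heterozygosity_stats(microsat)
print(het.round(3))
```

which prints (two Balding–Nichols populations, 10 loci):

```
             n     Ho     He    Fis
population
west        15  0.753  0.697 -0.047
east        15  0.773  0.726 -0.031
```

and the degree-of-change genotyper recovers nearly every simulated
genotype despite the default artifact model:

```python
want = {a: frozenset(truth.loc[(truth.amplicon == a) & (truth.kind == "true"),
                               "sequence"]) for a in mhc_truth}
acc = sum(calls.sequence_sets()[a] == want[a] for a in want) / len(want)
print(f"exact-genotype accuracy: {acc:.2f}")   # 0.97
```

A thin CLI mirrors the library:
`mhcpop simulate | demux | call | selection | diversity | structure |
coinertia` (see `mhcpop --help`).

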