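# Methods

`mhcpop` implements a complete analysis path for multi-locus MHC amplicon
genotyping and for contrasting adaptive (MHC) with neutral (microsatellite)
population structure. This note records the models, the defaults and the
design choices, in the order data flows through the package.

## Synthetic data generator

The generator produces data with the statistical structure the downstream
analyses assume, so every stage is testable without any external download.

**Allele library.** A pool of `n_alleles` equal-length nucleotide sequences
(default 26 alleles of 185 bp, reading-frame offset 2, hence 61 complete
codons). Alleles are grown by applying 1–3 random substitutions to copies of
already-accepted alleles, rejecting candidates that contain an in-frame stop
codon or that collide with an existing allele at either the nucleotide or
the amino-acid level. This mirrors real class II DRB exon-2 pools, where
every allele differs by at least one amino acid and all alleles are
presumed functional. A peptide-binding-region (PBR) mask of 14 codons is
drawn at random; for real data the PBR mask is a *user input* (the
canonical site lists come from human class II crystal structures and are
study-specific), supplied as 1-based codon indices.

**Population structure.** Populations follow the Balding–Nichols model:
population `p`'s allele-frequency vector at each marker is drawn from
Dirichlet(ancestral × (1 − F)/F) with F = `theta_fst`, so the expected
Wright F<sub>ST</sub> among populations equals `theta_fst` and realized
differentiation is controllable. Defaults: 8 populations with sample sizes
(30, 30, 39, 25, 48, 22, 23, 19), `theta_fst` = 0.10, 20 microsatellite
loci with 8 ancestral alleles each. Frequencies are drawn **independently
per marker and per population**. A consequence worth stating plainly: the
two marker systems share no co-structure by construction, so the co-inertia
RV coefficient between synthetic MHC and microsatellite matrices is near
zero. In real data, shared demographic history correlates the two systems;
the generator does not emulate that, and passing co-inertia tests therefore
demonstrate correctness of the decomposition (self-co-inertia RV = 1,
null RV ≈ 0, rotation invariance), not the magnitude of real co-structure.

**Genotype copy number.** Individuals carry 1–4 MHC alleles, reflecting two
DRB-like loci sharing one allele pool; because alleles cannot be assigned
to loci, copy number is modeled directly as an allele-set size with default
distribution (15.2%, 44.5%, 31.8%, 8.5%) for 1–4 alleles — the proportions
observed in the badger study. Alleles are sampled without replacement with
probability proportional to population frequency.

**Read model.** Per-amplicon depth is negative binomial, parameterized by
mean 635 and SD 436 reads (the study's reported coverage) and truncated at
≥ 1; a negative binomial captures the overdispersion of pyrosequencing
runs. Reads are split among an individual's true alleles with
Dirichlet-multinomial weights (concentration 30 per allele, i.e. moderate
inter-allele amplification variation). Each true allele spawns up to
`artifact_types` (default 2) artifact variants — copies with 1–2 random
substitutions, never colliding with a true allele of the same amplicon —
whose counts are Binomial(parent reads, `artifact_sub_rate`/`artifact_types`).
The default `artifact_sub_rate` = 0.10 is a calibration knob, not a
published value (the study does not report its artifact rate); it puts
artifacts at ~5% of their parent's depth, comfortably below the 10%
validation threshold yet well above zero. Chimeras default off (the
filtering rules do not model them) but can be switched on for robustness
checks. Homopolymer/flowgram errors, indels and quality scores are not
simulated: the upstream filter discards indel-bearing and off-length reads,
so they would only exercise the discard path.

Each read is laid out as forward MID + forward primer + variant +
rc(reverse primer) + rc(reverse MID); about half the reads are emitted
reverse-complemented. A default tag scheme of 12 × 8 MIDs gives 96 unique
combinations. Everything is seeded and byte-reproducible.

## Demultiplexing and variant tables

Tag and primer matching is **exact**: MID sets in such designs differ by
6–10 bp, so a single sequencing error cannot reassign a read, and the
correct behaviour for a damaged tag is rejection. Reads are canonicalized
to the forward strand; rejects are logged with one of five reasons
(missing tag, incomplete primer, ambiguous tag, ambiguous bases, length
mismatch — the last also catches indels). The accounting identity
|assigned| + |discarded| = |input| is enforced by construction and tested.
Identical inserts are collapsed per amplicon into a variant table; variant
ids are global (same sequence ⇒ same id), ordered by total count then
sequence so the mapping is deterministic.

## Genotype calling

Both callers rest on the same assumption: artifacts are rarer than the
true alleles they derive from.

**Validation-threshold method.** For every variant the MPAF (maximum
per-amplicon frequency: the largest share of any carrier amplicon's reads)
is computed. Variants with MPAF ≤ 3% are artifacts. Variants with
MPAF ≥ 10% carried by more than one amplicon (ideally on independent
sequencing runs, tracked through amplicon metadata) are true alleles; a
private variant above 10% is accepted if functional and flagged for
review, since artifacts do not reach such frequencies under the model's
assumption. The 3–10% band — reviewed manually in the original
protocol — is screened automatically by the three published criteria:
within 1–2 substitutions of a same-amplicon variant of higher frequency
(> 10%), premature stop codon, frame shift. An override table can force
any classification, replacing interactive review while keeping the run
reproducible. Genotypes are the surviving variants per amplicon, capped at
four by read depth.

**Degree-of-change (DOC) method.** Within an amplicon, variants are ranked
by read count (ties broken by sequence for determinism); with cumulative
depth proportions c_i (c_0 = 0), the degree of change DOC_i = c_i − c_{i−1}
is rank i's depth share, and the genotype boundary is placed at the rank
maximizing DOC_b − DOC_{b+1} (DOC beyond the last variant is zero) over
b ≤ 4 — the inflection separating the true-allele plateau from the
artifact tail. Amplicons under 50 reads are called but flagged
`low_quality`; a read-count tie across the boundary is flagged
`ambiguous`. The DOC method assumes comparable amplification efficiency
among an individual's alleles: under strongly skewed amplification it
under-calls multi-allele genotypes even without artifacts, which is why
the exact-recovery invariant is stated (and tested) under equal
amplification, while accuracy under the default skew (≈ 97–98% of
amplicons at depth ≥ 200) is measured separately.

**Repeatability.** Duplicate calls are compared by allele sequence:
identical sets are full matches, disjoint sets full mismatches, sets
differing by at most one allele per side one-allele mismatches;
overlapping sets differing by more are conservatively rated full
mismatches. No-calls are excluded and counted separately.

## Sequence diversity and selection

Pairwise distances use the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p); pairs with p ≥ 0.75 are reported as undefined
rather than clamped. Segregating sites are alignment columns with more
than one state.

dN/dS uses the (modified) Nei–Gojobori method: per-codon synonymous site
counts weight candidate changes by the transition/transversion ratio R
(R = 1, the default, reduces to the standard equal-weight count);
synonymous/nonsynonymous differences are averaged over all orderings of
the single-base steps between two codons, excluding pathways through stop
codons (all pathways are used if every one is blocked). Site counts are
averaged over the two sequences of a pair; proportions are JC-corrected
and averaged over pairs. The one-tailed Z-test of dN > dS uses a standard
error from bootstrap over codons (default 1000 replicates, seeded) rather
than the analytical variance — reproducible and directly testable.
Partitions with fewer than 3 codons are refused (unstable variance).
Identical sequences yield dN = dS = 0 and the test is reported not
applicable.

## Diversity statistics

Microsatellites: H<sub>o</sub> is the fraction of heterozygotes,
H<sub>e</sub> = 1 − Σp² averaged over loci (uncorrected, matching the
common spreadsheet output; the small-sample factor is available via
`unbiased_he`). F<sub>IS</sub> accumulates Weir–Cockerham within-population
variance components b and c over loci and alleles: f = 1 − Σc/Σ(b+c).
Rarefied allelic richness A_r(g) is the exact combinatorial expectation
Σ_alleles [1 − C(N−N_i, g)/C(N, g)] per locus, averaged over loci; private
allelic richness P_ar(g) follows the private-allele rarefaction (presence
in the focal subsample × absence in every other population's subsample of
the same size). `g` defaults to the smallest genotyped gene-copy count
over populations and loci.

MHC: per population, H is the distinct allele count, H_u the alleles found
nowhere else, individual diversity A_d = |allele set|/4, and k the mean
pairwise nucleotide difference among allele copies, each individual
contributing its called set once (copy number is unresolved, so dosage is
deliberately ignored — the same convention as the haplotype treatment in
the F<sub>ST</sub> machinery). Relative allele frequency is the number of
carriers divided by the total allele copies in the population.

Group differences use a two-sided permutation test over individuals with
the (b+1)/(m+1) estimator; ties count as exceedances, which makes the
p-value slightly conservative for coarse-grained statistics such as
H<sub>o</sub> on few loci (the calibration test therefore uses
H<sub>e</sub>, whose fine value grid makes ties negligible). A_d contrasts
among populations use one-way ANOVA with Tukey HSD post hoc comparisons
(family-wise α = 0.05).

## Structure comparison

F<sub>ST</sub>/Φ<sub>ST</sub> are computed in the AMOVA framework on
(squared) inter-unit distances: for microsatellites the unit is the
diploid individual and the distance the number of different alleles summed
over loci; for MHC each called allele is a haplotype copy and distances
are JC distances between allele sequences. Negative estimates are reported
as computed. Pairwise significance permutes individuals (with all their
haplotype copies) between the population pair. Hierarchical AMOVA
partitions variance among groups / among populations within groups /
within populations with the Excoffier coefficients; negative components
are reported but floored at zero for percentages (flagged), and
permutation p-values permute whole populations among groups (top level) or
individuals among populations within groups.

The AMOVA estimator on the individual-level allele-sharing distance —
faithful to common practice — overestimates the drift parameter of the
Balding–Nichols model (≈ 0.15 realized for θ = 0.10), because
within-individual variation is not separated out. For validating realized
F<sub>ST</sub> against a simulation target the package therefore provides
`weir_cockerham_fst`, the standard nearly unbiased multilocus θ (verified:
mean 0.098–0.101 over 20 replicates at θ = 0.10, 8 × 30 individuals,
20 loci).

Mantel correlation is the Pearson correlation of upper off-diagonal
triangles with joint row/column permutation; the partial Mantel regresses
both matrices on the control and correlates residual matrices (if the
control numerically absorbs all variation, the partial correlation is
defined as zero). Geographic matrices use great-circle kilometres from
user-supplied population centroids — coordinates are an external optional
input.

Binary encoding treats both systems as dominant markers (presence 1 /
absence 0; dosage deliberately lost). Co-inertia analysis column-centers
each matrix, reduces it by plain PCA to 2 components (a group-constrained
variant was considered and left out: plain PCA with population grouping
for display matches the common ade4 workflow), and decomposes the
cross-covariance of the two score sets by SVD. The RV coefficient is the
global correlation; per-population mean score pairs give one arrow per
population whose length is the marker discordance; canonical weights map
alleles to the co-inertia axes. Significance is a row-permutation test
with (b+1)/(m+1) smoothing (the parameter keeps the name `n_boot` used by
the resampling convention it replaces).

## Problem sizes and numerical conventions

Test and acceptance runs use deliberately modest sizes chosen as adequate
for their statistical purpose: genotyper accuracy pools 20 replicate
studies of 24 individuals; F<sub>ST</sub> recovery uses 20 replicates of
8 × 30 individuals × 20 loci; null calibrations use 200 replicates with
199 permutations each; the full synthetic study for the structure
comparison uses 8 × 12 individuals. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs. Sorting tie-breaks are always (count descending, sequence
lexicographic).

## Limitations

- The generator's artifact model is substitution-only; indels,
  homopolymer noise and chimeras (off by default) are not part of the
  default conditions.
- Drift is independent across markers, so cross-marker co-structure
  (the interesting empirical signal) is absent from synthetic data.
- The DOC breakpoint is the maximal successive drop in degree of change;
  the original spreadsheet implementation fits explicit depth models, and
  its exact statistical form is not reproduced.
- Locus assignment and haplotype phasing of MHC alleles are out of scope
  (not identifiable from pooled amplicons of duplicated loci).
- Bayesian admixture clustering, codon-model site tests (M0–M8, FEL/REL/
  MEME), recombination scans and effective-population-size estimation are
  intentionally outside the package.
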