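# External primary data (not redistributed)

Two acceptance tests operate on the study's deposited primary data, which
this repository does not ship. To run them, place the following files
here:

- `mhc_alleles.fasta` — the 26 MHC DRB exon-2 allele sequences,
  GenBank accessions KU059084–KU059109, as plain FASTA.
- `badger_microsats.gen` — the archived microsatellite genotypes for the
  236 individuals (Dryad doi:10.5061/dryad.qb87r), converted to GenePop
  format with one `Pop` block per sampling region.
- `badger_mhc_binary.csv` — the archived binary-encoded MHC data:
  individuals as rows, allele names as columns, entries 0/1.

Without these files the corresponding tests fail with a message pointing
back to this directory; all other tests are self-contained.
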