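# Named-haplotype definition: an 8-SNP classifier haplotype spanning ~6.7 kb
# of the packaged synthetic locus (positions are 0-based gene coordinates).
# The alt allele at each site is the transition partner of the reference
# base.  For real data, replace the positions (and supply explicit alleles)
# with the published defining SNPs.
name: "Pv1.1"
positions: [700, 1650, 2600, 3550, 4500, 5450, 6400, 7400]
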