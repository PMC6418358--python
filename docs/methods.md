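# Methods

`amplicall` models the analysis of a single long-range PCR amplicon over a
clinically hard locus: a gene of ~8.9 kb whose eleven coding exons share
~96% sequence identity with a nearby pseudogene. The pseudogene attracts
misaligned reads, seeds PCR chimeras, and donates recombinant alleles
(gene-conversion tracts combining an exonic deletion with
pseudogene-derived SNVs). The package provides the whole chain —
simulation, alignment, QC, diploid variant calling, false-positive
filtering, deletion detection, phasing — as a tested library plus a CLI.
This note records the models, the defaults, and the open design choices.

## Synthetic locus and error model (`refsim`)

**Locus.** The gene copy is a seeded uniform-random sequence of 8,911 bases
(the span of the real amplicon, chr1:155,202,296–155,211,206 in the
coordinate label we carry along), with 11 exons of 170 bases spread evenly
across the span. The pseudogene copy is derived from the gene by random
substitutions: enough exonic substitutions to realize 96% exonic identity,
and intronic substitutions to 97% identity. The builder realizes the
requested identity to within rounding (the substitution count is
deterministic; only positions are random), so the exonic-identity invariant
holds at ±0.5 percentage points for any seed. Intronic divergence is a
deliberate extension beyond "exonic identity only": a pseudogene identical
outside exons would make window-level chimera assignment undefined across
introns, and real pseudogenes diverge throughout. Coordinates are 0-based
half-open everywhere internally; VCF output alone is 1-based.

**Diploid samples.** A `SampleSpec` plants het/hom SNVs (het on exactly one
haplotype), an optional recombinant haplotype (a deletion inside one exon
plus linked SNVs in cis; the linked alt alleles are taken from the
pseudogene sequence, as in a gene-conversion tract), and an optional
phased multi-SNP haplotype. `dropout_haplotype` suppresses one parental
haplotype entirely, emulating the allele-dropout failure mode of a
recombinant whose primer site is lost — the case a gene-targeted PCR
cannot amplify and which this package therefore does not attempt to call.

**Reads.** Read lengths are truncated-normal around 0.95 of the haplotype
length (SD 0.05, floor 2 kb), matching a full-length-amplicon protocol
with a 2-kb size cutoff; starts are uniform; strands are fair. Errors are
injected in four layers:

1. *Substitutions* at `sub_rate` = 0.0672 per base, with the alternative
   base drawn from a per-reference-base conditional spectrum in which
   transitions dominate (`G→A` 0.512, `A→G` 0.506, `C→T` 0.478, `T→C`
   0.450 of errors at that base; transversions share the remainder).
   These are calibration constants: with near-uniform base composition and
   the motif hotspot below, they reproduce a measured aligned base
   identity excluding indels (ABID) of ~93.2% and overall spectrum shares
   of ~13.3% / 12.7% / 12.0% for G→A / A→G / C→T — the error structure
   reported for real runs of this protocol. They were derived analytically
   from the injection model and frozen in the defaults; they live in
   configuration, not code paths.
2. *Motif hotspot*: substitution probability is multiplied by 4 at the
   third base of every CAGC occurrence, reproducing the k-mer error
   enrichment seen in real data. With ~35 occurrences this perturbs the
   global spectrum by well under a percentage point.
3. *Homopolymer indels*: each run of length r ≥ 3 suffers a one-base
   insertion or deletion (of the run base) with probability
   0.02·(r − 2) — the canonical nanopore failure mode. These never
   survive calling: candidate thresholds, the homopolymer flag and the
   5-base indel floor all remove them.
4. *Systematic sites*: configured positions where a transition appears in
   a per-read fraction (typically 0.11–0.31) with a strand ratio
   (default 3:1). These model the recurrent, strand-biased,
   transition-only false-positive sites that motivate the filter module.

PCR chimeras are formed at `chimera_rate` (default 0.02) by replacing the
read's suffix, from a uniform junction, with pseudogene sequence at the
same coordinates. Every read carries a truth record (haplotype, span,
strand, chimera junction, every injected error), written as a TSV sidecar
next to the FASTQ.

Determinism: one `numpy` generator seeded per sample drives every draw, so
equal seed and configuration give byte-identical FASTQ output.

## Alignment (`align`)

Reads are aligned with affine-gap local (Smith–Waterman/Gotoh) alignment
against both the gene and the pseudogene; the higher score assigns the
target, with ties going to the gene (the amplicon is gene-targeted) and
flagged ambiguous. Scoring defaults are match +2, mismatch −3, gap open −4
plus −2 per gap base — chosen so a 4%-divergent pseudogene is separable
over ≥1 kb at the simulated error rate. Strand is chosen by an
edit-distance pre-pass (edlib) on the forward and reverse-complement read.

The DP is banded for speed: an edlib infix alignment locates the read and
bounds its indel content, and the band covers that diagonal range plus the
indel total plus a 64-diagonal pad. Because a local alignment path can
leave its start diagonal by at most its number of gap bases, this band
contains the optimum for reads of the simulated kind; the test suite
asserts banded == full-DP score on hundreds of instances, and the full
(unbanded) DP is available by passing `band=None`. The kernel is a numba
routine with full affine traceback (`=`/`X`/`I`/`D` CIGARs).

Chimeras are detected by cutting the read into 256-base windows, scoring
each window against both targets by edit distance, and accepting a single
change-point when both sides have ≥2 confidently assigned windows of
opposite targets at ≥90% purity. The junction estimate is the midpoint of
the uncertainty interval between the flanking informative windows (within
one window of truth in practice). Chimeric reads are retained in SAM
output (with a supplementary record for the second segment) but excluded
from variant pileups — the cleanest interpretation of an artifact class
that would otherwise vote pseudogene bases into gene sites.

## QC (`qc`)

N50 (largest x such that reads ≥ x hold half the bases), ABID
(matches/(matches+mismatches)), IBAB (matches over all aligned columns
including indels), the 12-entry erroneous-substitution spectrum with a
transitions subtotal, and a ranked table of 4-mers by substitution errors
at their third base with enrichment against k-mer frequency. The
in-k-mer error offset is fixed at position 3 of 4 by default (the
convention that makes CAGC the observed hotspot) and is configurable.
Identity metrics are computed over gene-target, non-chimeric alignments;
mismatch columns are found by base comparison, not CIGAR op, so M-style
CIGARs are handled.

## Diploid calling (`caller`)

Candidate SNVs are pileup sites with alternate fraction ≥ 0.2 and depth
≥ 20. Candidates are grouped into windows (gap ≤ 50 bases, width ≤ 100, at
most 8 sites searched exhaustively; larger windows are split). For every
assignment of alt alleles to the two haplotypes of a diploid configuration
(3^S non-reference states per S-site window, enumerated as 2^S × 2^S
haplotype vector pairs), the read-set log-likelihood is computed under a
per-base error model: a read base matches its haplotype base with
probability 1 − e, otherwise e/3, and a read's likelihood is the 50/50
mixture over the two configuration haplotypes. The mixture (the standard
diploid genotype likelihood) is the default rather than per-read hard
assignment because hard assignment makes *any* alternate read favour a het
configuration — its likelihood ratio over reference grows linearly from
zero alternate fraction, which destroys the separation between true hets
(~48% alt) and systematic error sites (11–31% alt) that the adjusted-score
filter depends on. Hard assignment remains available (`hard_assign=True`).
The exhaustive oracle in the test suite uses the same mixture formula,
independently implemented.

Each emitted variant carries

  Q = (log L(best configuration) − log L(hom-reference)) × 10/ln 10,

a Phred-scaled log-likelihood ratio shared by the variants of a window's
winning configuration, and N, the read depth at its site. Ties between
configurations resolve to the fewer-variant configuration (parsimony),
then lexicographically. The per-sample error rate e is estimated from the
same alignments as 1 − ABID/100 unless supplied.

Indel events are clustered from deletion CIGAR operations (D runs merged
within a read when ≤ 5 aligned bases apart, clustered across reads by
midpoint) and genotyped with the same two-allele likelihood. Calls whose
interval lies inside a homopolymer run ≥ 4 are flagged and suppressed;
calls under 5 bases are removed (small nanopore indels are unreliable);
deletions of ≥ 30 bases are left to the `sv` module, giving a clean
5–29 / ≥30 division of labour between the small-indel and SV callers.

## False-positive filtering (`fpfilter`)

The discriminator is the coverage-adjusted quality Q/N. Because Q
accumulates per-read evidence, Q/N is approximately coverage-invariant
(titration CV < 0.15 across 10× downsampling) while separating true hets
from called systematic-error sites by a factor of ~3–5. Since this
caller's Q scale is not that of a signal-space caller, runs are
calibrated: the factor c anchoring the known-true het mean adjusted score
at 3.5 is computed on the packaged benchmark (or any control samples) and
stored in the run manifest. Classification of c·Q/N:

* ≥ 1.8 → true positive; ≤ 1.2 → false positive (defaults; a 2.0/1.6
  "conservative" preset ships alongside, since the score drifts somewhat
  between runs — which is exactly why both pairs are configuration);
* otherwise indeterminate, demoted to false positive only when the call is
  a transition AND recurrent — median aberrant-base fraction ≥ 0.10
  across the other samples of the run (measured in samples lacking the
  call; a site called in *every* sample uses the all-sample median, the
  strongest recurrence evidence). Strand bias (two-sided Fisher exact on
  the ref/alt × strand table) is annotated but never decisive on its own,
  and no evidence ever promotes a call.

The demoted verdict is recorded in `reasons`, so score-classified and
evidence-demoted false positives remain distinguishable.

## Deletion detection (`sv`)

Reads whose CIGAR carries a deletion ≥ 30 bases are clustered by
breakpoint midpoint (±20); a call needs ≥ 10 supporting reads. Consensus
breakpoints are per-read medians, then left-normalized against the
reference (shifted left while the flanking base repeats) for reproducible
placement near homopolymers. The deletion-span fraction of coverage inside
the interval genotypes the call (≥ 0.8 hom, ≥ 0.25 het) and cross-checks
it against the read-level support. Overlapping clusters are both emitted
and flagged rather than silently merged.

## Phasing (`phase`)

Heterozygous SNVs are phased by minimum error correction (MEC): the phase
vector minimizing the number of read bases that must be flipped for every
read to match one of the two haplotypes. Blocks are connected components
of the read–variant co-coverage graph (full-length amplicon reads
typically give one block). Blocks of ≤ 15 variants are solved exactly over
the 2^(k−1) distinct phase vectors; larger blocks use pairwise-linkage
seeding plus local flips. Hom variants attach to both haplotypes for
reporting and are excluded from MEC. On top of blocks: `compound_het`
reports cis/trans/unknown for a variant pair, and `assign_named_haplotype`
scores a sample against a fixed SNP-set definition (hom+/het/hom−, partial
matches flagged mixed). The packaged definition has 8 SNPs over ~6.7 kb of
the synthetic locus with transition alt alleles — placeholders standing in
for a published classifier haplotype whose defining SNPs users supply for
real data.

## Titration (`titrate`)

Alignments are downsampled read-wise (keep probability 1/factor, seeded),
re-called at factors {1, 2, 4, 10}, and summarized per variant: a
least-squares fit of Q against depth over all (factor, replicate)
observations, and the coefficient of variation of Q/N across per-factor
means. Averaging within factor first is deliberate: at a tenth of the
depth the alternate-allele count is binomially noisy, and the constancy
claim is about the systematic dependence of Q/N on coverage, not about
shot noise at 30 reads.

## Orchestration (`cli` / `pipeline`)

`run_pipeline` executes simulate → align → QC → gate → call → filter → SV
→ phase per sample, with cross-sample recurrence and calibration, writing
FASTA/BED/FASTQ/SAM/VCF/TSV artifacts and a JSON manifest (config hash,
per-sample seeds, coverage, gate decisions, calibration factor, stage
parameters). A sample enters calling only if its mean depth over the
exons ± 50 flanking bases (flanks merged before averaging) is ≥ 100
(inclusive); gated samples are recorded, and `--strict` turns a gate
failure into a nonzero exit. Fixed seeds give byte-identical outputs.

## Packaged benchmark

Six samples at depth 140 on the default locus carry eight true variants
(six het, two hom, spread over the exons, a mix of transitions and
transversions) and five intronic systematic error sites (transitions,
3:1 strand ratio, per-sample aberrant fractions drawn from 0.14–0.30).
This is the scenario on which calibration is defined and on which the
filter must separate perfectly: all true variants pass, every other call
(planted systematic sites plus whatever the CAGC hotspot throws up) is
rejected, none left indeterminate.

## Problem sizes

Simulated depths are 140 (benchmark), 300 (recombinant carrier), 50
(QC-calibration and zygosity replicates); property suites use a 1.5 kb
three-exon miniature of the locus where the full amplicon adds nothing to
the property under test. These sizes were chosen as the smallest at which
the binomial margins above are comfortable.

## Limitations

* Likelihoods are base-space; raw-signal information is not modelled, so
  absolute Q values differ from signal-space callers — hence the explicit
  calibration step and configurable thresholds.
* The simulator draws i.i.d. errors (given position effects); it does not
  model basecaller burst errors, read-quality heterogeneity between
  molecules, or barcode cross-talk. Passing tests show the pipeline's
  behaviour under the documented error structure, not under every real
  flow cell's.
* Insertions are simulated (homopolymer class) but only deletions are
  called as SVs; multi-segment (>2) chimeras and fusion/deletion
  recombinants that escape the PCR design are out of scope by
  construction.
* Exhaustive calling is capped at 8 candidate sites per window and exact
  phasing at 15 variants per block; beyond that, windows are split and
  phasing falls back to a greedy heuristic.
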