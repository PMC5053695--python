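# Methods

## Problem and model

Read-through (conjoined-gene) transcripts arise when RNA polymerase reads
through the terminator of one gene into the next gene downstream on the same
genomic strand and splicing removes the intergenic region, producing a
chimeric mRNA with no underlying genomic rearrangement. This package
implements the full analysis chain for such events: identifying them from
chimeric-junction evidence in RNA-Seq, characterizing the joined exons and
the intergenic gap, deciding whether the downstream open reading frame is
preserved, and comparing expression between paired normal and tumor tissue.

The defining acceptance rule for a read-through candidate is structural:
the donor and acceptor genes must lie on the same chromosome and the same
strand, be *adjacent* (consecutive in the strand-specific gene order), and
appear in transcription order (donor upstream). Chimeras failing any part of
the rule are the signature of genomic rearrangement (translocation,
inversion) or artifact, and are rejected with a reason code.

## Annotation and adjacency

Coordinates are 1-based inclusive (GTF convention; BED12 is converted on
read). A gene locus is the union span of its transcripts. For each
(chromosome, strand) genes are ordered by start position; every consecutive
pair is an adjacent pair. Genes on the *opposite* strand between a pair do
not break adjacency — transcription proceeding along one strand never sees
them. This convention is a deliberate design choice where practice varies;
the alternative (any intervening gene breaks adjacency) would only shrink
the candidate set.

The intergenic distance is the number of bases strictly between the
upstream locus end and the downstream locus start. It is computed in
genomic coordinates and is therefore strand-invariant. Abutting loci have
distance 0; overlapping loci have no defined distance and carry an
`OVERLAPPING` sentinel (overlapping adjacent genes can still produce
read-through transcripts and remain eligible events).

One internal convention worth noting: `cds_start`/`cds_end` of a transcript
*include* the stop codon. Frame analysis needs exactly two anchors — the
start codon and the stop-codon position — and a single inclusive convention
avoids off-by-three bookkeeping. The GTF writer emits CDS features with
these bounds.

## Junction filtering

A candidate junction is accepted when it has at least `min_supporting_reads`
independent supporting reads (default 10), mean read quality at least
`min_mean_read_quality` (default 25, Phred scale), and at least
`min_breakpoint_spanning_reads` reads crossing the predicted exonic
breakpoint (default 1). All three thresholds are inclusive. A rejected
record reports the *first* failed criterion in the fixed order
support → quality → spanning, so outputs are deterministic. "Independent
reads" is taken as the deduplicated count supplied by the evidence producer;
no duplicate marking is redone here. Filtering is applied per sample, so an
event's patient count is the number of samples in which it independently
passed all thresholds.

Evidence is consumed as a documented TSV (one row per junction per sample).
A convenience extractor from split/supplementary SAM alignments is provided
(`detect.evidence_from_alignments`) but upstream alignment and junction
calling are out of scope.

## Chimeric transcript and reading frame

The chimeric mRNA is the concatenation of spliced exons 1..k of the donor
transcript and exons j..last of the acceptor transcript, each
strand-corrected to sense orientation. Incomplete exons and retained
intragenic segments are represented by explicit genomic sub-intervals; no
cryptic splice-site inference is attempted.

Frame maintenance is a codon-phase statement. With the chimera translated
in the frame fixed by the donor start codon, let P1 be the chimera phase at
the first acceptor CDS base and P2 that base's native phase in the acceptor
transcript. The frame is maintained iff P1 = P2 and no stop codon occurs in
the translated frame strictly before the codon containing that base (the
second clause matters when 5'UTR or inserted intragenic bases separate the
junction from the acceptor CDS start). A premature stop — any in-frame stop
before the acceptor's native stop codon — is reported as a separate flag: a
hybrid codon straddling the junction can encode a stop without breaking
phase, so the two properties are independent. Events whose donor part lacks
the donor start codon, or whose acceptor part contains no acceptor CDS base
(including fully non-coding partners), are reported `unassessed`.
Translation uses the standard nuclear code (ATG start as annotated, stops
TAA/TAG/TGA).

The test suite checks the phase arithmetic against a brute-force oracle
that splices the chimera base by base, translates it, and demands the
protein suffix aligned to the acceptor CDS equal the native acceptor
protein suffix.

## qPCR relative quantification

Replicate wells of each (sample, gene) are summarized to an arithmetic mean
Ct and a sample standard deviation (n−1 denominator). A measurement is
reliable only with ≥ 2 replicates and Ct SD ≤ 0.5 cycles (configurable).
ΔCt is target minus reference-gene mean Ct (reference default HPRT1);
RQ = 2^−(ΔCt_sample − ΔCt_calibrator) against a pooled calibrator sample,
whose own RQ is exactly 1 by construction. Amplification efficiency is
fixed at perfect doubling; no standard-curve correction. Whether the
reliability rule applies to the reference gene as well as the target is
genuinely open; the stricter reading (both genes, both tissues) is the
default and is configurable (`QpcrConfig.require_reference_reliable`).
A paired row (patient × gene) survives only when both tissues are reliable;
its effect size is the ratio RQ_normal / RQ_tumor, which equals
2^(ΔΔCt_tumor − ΔΔCt_normal) algebraically. Failed wells must be absent
rows, never sentinel Ct values.

## Statistics

*Wilcoxon signed-rank (paired, two-sided).* Differences d = normal − tumor;
zero differences are dropped (Wilcoxon's original reduction, the common
package default, rather than Pratt's method); |d| ranked with ties
averaged; W is the positive-rank sum. For n ≤ 20 without ties the p-value
is exact, from the signed-rank counting distribution (equivalent to
enumerating all 2^n sign assignments); beyond that, a normal approximation
with tie correction and a 0.5 continuity correction. The exactness cutoff
at 20 balances fidelity and runtime. The exact true rejection rate of the
approximate path at n = 25 and α = 0.05 is 0.0483, so the test is slightly
conservative but well calibrated. The approximation tracks the exact
p-value to about 0.02 at n = 12 overall and to < 0.005 in the p < 0.05
tail.

*Rank linear model.* The response (RQ) is rank-transformed across all rows
(ties averaged) and fitted by OLS with an intercept and binary covariates:
tissue (0 = normal, 1 = tumor), sex (0 = female, 1 = male), smoking
(0 = never, 1 = ever), stage (0 = I, 1 = >I). Each tissue sample is an
independent row — no per-patient random effect — which mirrors the original
modeling choice and is recorded as a fidelity decision, not a
recommendation. Standard errors use the unbiased residual variance;
p-values are two-sided t with n − p degrees of freedom. Covariates constant
in the data are dropped with a warning; a rank-deficient design after drops
is an error naming the columns. No multiplicity correction is applied by
default; Benjamini–Hochberg adjusted p-values are available as a labeled
extra.

## Cohort summary and the reference tables

The summarizer counts species by (gene pair, donor exon, acceptor exon)
plus a `variant` tag that distinguishes incomplete-exon or
intragenic-inclusion isoforms sharing exon indices with a plain event —
without the tag, one such isoform pair in the reference cohort would be
merged and the validated-event count would be off by one. The median
intergenic distance is taken over validated gene pairs with a defined
distance; even counts use the midpoint, rounded half-up to whole base
pairs. The reference cohort (52 RNA-Seq species over 37 adjacent pairs;
15 additional Sanger-identified isoforms; 43 validated events over 35
pairs, 17 frame-maintained, median gap 3,941 bp, 7 pairs under 1 kb) ships
as row-level TSVs and every aggregate is recomputed from them at run time;
only the expected-summary file used by the regression check stores numbers
directly. The frame flags in these tables are transcribed calls, not
recomputed from public transcript sequence (that would require external
downloads). Shares such as the fraction of acceptor-exon-2 junctions are
reported but not enforced as regressions: their defining subsets in the
original tabulation are ambiguous.

## Synthetic data

The generators plant known truth for every stage.

*Annotation.* Genes are packed left to right per chromosome with log-uniform
intergenic gaps between 100 bp and 120 kb (bracketing the 139–118,125 bp
range observed across the reference cohort's parent pairs, which cluster at
short distances), 2–8 exons of 60–300 bp, introns of 80–1500 bp, both
strands, one transcript per gene. Coding transcripts (default 90%) get a
clean ORF — ATG start in exon 1, sense codons, single stop in the last
exon — so a donor part truncated before the last exon always cuts the CDS
mid-way. A configurable quota of overlapping same-strand pairs exercises
the `OVERLAPPING` path; overlapping genes may share genomic sequence (later
exon writes win), so frame-analysis tests use overlap-free configurations.

*Junction evidence.* True events are planted on adjacent same-strand pairs
with the donor biased to the penultimate exon and the acceptor to exon 2
(the empirically dominant junction configuration), read support
negative-binomial (mean 30, dispersion 5, clipped to ≥ 10; overdispersion
is the realistic model for junction read counts), quality truncated-normal
(mean 32, SD 4, clipped to ≥ 25), spanning reads ≥ 1. Six decoy classes
each violate exactly one acceptance criterion. Every evidence row carries
the identifier of its truth row.

*qPCR.* Per patient and gene, the normal-tissue ΔCt is uniform on 4–10
cycles; the tumor ΔCt adds the planted effect (default +2.0 cycles =
4-fold down-regulation, matching the middle of the observed normal/tumor
ratio range). Duplicate wells get Gaussian noise (SD 0.15 cycles — typical
instrument repeatability; the exclusion rule is defined on the Ct scale, so
noise is modeled there). A planted fraction of target replicate sets
(default 10%) receives a guaranteed-wide spread (|difference| 0.8–2.0
cycles; duplicate SD = |difference|/√2 ≥ 0.57, strictly above the 0.5
threshold), and
"reliable" sets redraw their noise in the ~10⁻³-probability event the
realized SD crosses the threshold — the truth table therefore matches the
exclusion rule deterministically. All simulated Ct values are quantized to
1/256 cycle, making the ΔCt arithmetic float-exact: in the noise-free limit
every normal/tumor ratio is exactly 2^effect, which the tests assert as an
identity rather than an approximation.

Determinism: each generator draws from a child stream of the single seed;
equal seeds give byte-identical GTF/FASTA/TSV outputs.

*What the simulations do not model:* alignment and sequencing error,
read-level data, multi-transcript genes, tumor purity or heterogeneity,
amplification-efficiency drift, inter-plate effects. Passing recovery tests
therefore demonstrates correctness of the filtering, frame and
quantification logic under the stated generative model, not robustness to
upstream artifacts of real data.

## Problem sizes used in the shipped analyses

The acceptance analyses use 2 chromosomes × 20–40 genes, 6–8 planted true
events with 1–2 decoys per class, 200 random coding chimeras for the
frame oracle, 10,000 sign-flip replicates at n = 25 for type-I calibration,
and 200 simulated cohorts at n = 25 pairs for power and sign-recovery —
sizes at which every stochastic check is stable across seeds.

## Known limitations

* Adjacency is computed from the annotation as given; unannotated genes
  between a pair are invisible.
* Frame analysis evaluates the named transcript isoforms only, and partial
  exons require explicit sub-intervals from the caller.
* The premature-stop position assumes a contiguous acceptor part when
  custom sub-intervals are supplied.
* The rank model treats tissues as independent rows; a mixed model would be
  the statistically stronger choice for paired data.
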