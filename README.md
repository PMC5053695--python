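# readthrough

Detection, characterization and paired-tissue quantification of
**read-through (conjoined-gene) transcripts** — chimeric mRNAs produced
when transcription runs through the end of one gene into the adjacent,
same-strand gene downstream and splicing removes the intergenic region.
Unlike fusion transcripts from translocations or inversions, read-throughs
involve no genomic rearrangement; they occur in normal tissue (notably lung
parenchyma) and can be down-regulated in matched tumor tissue, which makes
their quantification biologically interesting.

The package is aimed at transcriptomics analysts who already have
chimeric-junction calls (or split-read alignments) and qPCR Ct tables and
want a tested, reproducible implementation of the downstream analysis.

## What it computes

1. **Detection** (`readthrough.detect`). Candidate junctions are kept when
   supported by ≥ 10 independent reads with mean read quality ≥ 25 and ≥ 1
   breakpoint-spanning read, then accepted as read-through events only if
   donor and acceptor genes are *adjacent on the same strand, donor
   upstream* — the structural signature of read-through transcription.
   Rejections carry a reason code (`LOW_SUPPORT`, `OPPOSITE_STRAND`,
   `NOT_ADJACENT`, ...).
2. **Characterization** (`readthrough.annotation`, `readthrough.frame`).
   Intergenic distance between the parent loci (bases strictly between the
   locus bounds; `OVERLAPPING` when undefined), junction-exon labels
   (penultimate donor exon, acceptor exon 2), and reading-frame maintenance:
   with the chimera translated from the donor start codon, the frame is
   maintained iff the chimera phase at the first acceptor CDS base equals
   its native phase and no stop intervenes before it; premature stops are
   flagged separately.
3. **Quantification** (`readthrough.qpcr`). Duplicate-well Ct → mean/SD,
   reliability rule (Ct SD ≤ 0.5), ΔCt against a reference gene (HPRT1 by
   default), RQ = 2^−ΔΔCt against a pooled calibrator, and per-patient
   normal/tumor pairs with ratio RQ_N/RQ_T.
4. **Inference** (`readthrough.stats`). Paired two-sided Wilcoxon
   signed-rank test (exact by enumeration distribution for n ≤ 20 without
   ties, tie/continuity-corrected normal approximation otherwise) and an
   OLS model on the rank-transformed RQ with binary tissue/sex/smoking/stage
   covariates.
5. **Cohort summary** (`readthrough.summarize`). Aggregate counts and the
   median intergenic distance, plus a packaged reference cohort of
   read-through events from non-involved lung tissue whose printed
   aggregates are recomputed from the row-level tables.
6. **Simulation** (`readthrough.simulate`). Deterministic generators for
   annotation+genome, junction evidence with per-class decoys, and paired
   qPCR tables with planted effects — every pipeline stage is testable
   against known truth with no downloads.

## Worked example

Generate a synthetic bundle and run the full pipeline:

```bash
readthrough simulate all --seed 5 --out demo/
readthrough detect --annotation demo/annotation.gtf --evidence demo/evidence.tsv --out demo/out
readthrough qpcr --ct demo/ct.tsv --out demo/out/rq.tsv
readthrough stats --rq demo/out/rq.tsv --out demo/out/stats.tsv
```

or in Python:

```python
from readthrough import SimulationConfig, simulate_qpcr, sample_expression, paired_table
from readthrough.stats import analyze_paired_rq

cfg = SimulationConfig(seed=3, unreliable_probability=0.2)
ct, truth = simulate_qpcr(cfg)               # 45 patients, planted +2.0-cycle effect
paired = paired_table(sample_expression(ct))
print(analyze_paired_rq(paired))
```

which prints

```
  gene   n      W  p_wilcoxon  median_ratio_n_over_t
0  RT1  27  378.0    0.000006               4.043557
```

Read: of 45 simulated patients, 27 pairs survived the Ct-SD ≤ 0.5
reliability rule in both tissues; the Wilcoxon statistic W = 378 is the
maximal positive-rank sum (every patient had higher expression in normal
tissue), p ≈ 6×10⁻⁶; the median normal/tumor ratio ≈ 4.04 recovers the
planted 4-fold (+2.0 cycle) tumor down-regulation.

The packaged reference cohort reproduces its printed aggregates:

```bash
$ readthrough summarize --check
n_species	52
n_gene_pairs	37
n_validated_events	43
n_validated_gene_pairs	35
n_frame_maintained	17
median_intergenic_bp	3941
n_validated_pairs_lt_1kb	7
...
all expected aggregates reproduced
```

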