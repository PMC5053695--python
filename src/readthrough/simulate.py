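"""Synthetic annotation, junction-evidence and qPCR generators with truth tables.

Every pipeline stage is testable offline against planted ground truth:

* :func:`simulate_annotation` packs non-overlapping multi-exon genes (plus a
  configurable overlapping-pair quota) on both strands of a small genome,
  with clean ORFs (ATG start, sense codons, single stop in the last exon)
  and intergenic gaps drawn log-uniform between 100 bp and 120 kb — spanning
  the gap range observed for real read-through parent pairs, which cluster
  at short distances.
* :func:`simulate_junction_evidence` plants true read-through junctions on
  adjacent same-strand pairs (donor biased to the penultimate exon, acceptor
  to exon 2, the empirically dominant configuration) with negative-binomial
  read support and truncated-normal mean read quality above the acceptance
  thresholds, plus decoy junctions each violating exactly one criterion:
  opposite_strand, non_adjacent, inter_chromosomal, low_support,
  low_quality, no_spanning.
* :func:`simulate_qpcr` emits duplicate-well Ct tables for paired
  normal/tumor tissue with a planted tumor effect in cycles (default +2.0,
  i.e. 4-fold down-regulation in tumor), Gaussian replicate noise (default
  SD 0.15 cycles), a reference gene, a pooled calibrator, and a planted
  fraction of unreliable replicate sets whose Ct SD is guaranteed to exceed
  the 0.5-cycle exclusion threshold.  All simulated Ct values are quantized
  to 1/256 cycle so that dCt arithmetic is float-exact; in the noise-free
  limit every normal/tumor RQ ratio is then exactly 2^effect.

Determinism: a fixed ``seed`` yields byte-identical output files; the three
generators use independent child streams of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import (
    GeneSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    strand_adjacent_pairs,
)
from .detect import JunctionEvidence

__all__ = [
    "SimulationConfig",
    "SimulatedAnnotation",
    "simulate_annotation",
    "simulate_junction_evidence",
    "simulate_qpcr",
    "write_fasta",
]

_DECOY_CLASSES = (
    "opposite_strand",
    "non_adjacent",
    "inter_chromosomal",
    "low_support",
    "low_quality",
    "no_spanning",
)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the three generators (defaults = study-like conditions)."""

    seed: int = 0
    # --- annotation ---
    n_chromosomes: int = 2
    n_genes_per_chromosome: int = 20
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (60, 300)
    intron_length_range: tuple[int, int] = (80, 1500)
    intergenic_gap_bounds: tuple[float, float] = (100.0, 120_000.0)
    fraction_coding: float = 0.9
    n_overlapping_pairs: int = 0
    # --- junction evidence ---
    n_true_readthroughs: int = 8
    n_decoys: Mapping[str, int] = field(
        default_factory=lambda: {cls: 2 for cls in _DECOY_CLASSES}
    )
    read_support_mean: float = 30.0
    read_support_dispersion: float = 5.0
    quality_mean: float = 32.0
    quality_sd: float = 4.0
    n_patients: int = 10
    # --- qPCR ---
    qpcr_n_patients: int = 45
    qpcr_genes: tuple[str, ...] = ("RT1",)
    reference_gene: str = "HPRT1"
    calibrator_id: str = "CALIBRATOR"
    reference_ct_range: tuple[float, float] = (20.0, 24.0)
    baseline_delta_ct_range: tuple[float, float] = (4.0, 10.0)
    tumor_effect_cycles: float = 2.0
    replicate_noise_sd: float = 0.15
    unreliable_probability: float = 0.1
    n_replicates: int = 2
    max_ct_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and gene")
        if not 0 <= self.fraction_coding <= 1:
            raise ValueError("fraction_coding must be in [0, 1]")
        if not 0 <= self.unreliable_probability <= 1:
            raise ValueError("unreliable_probability must be in [0, 1]")
        unknown = set(self.n_decoys) - set(_DECOY_CLASSES)
        if unknown:
            raise ValueError(f"unknown decoy classes {sorted(unknown)}")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _quantize(x):
    """Snap to 1/256 cycle so downstream dCt arithmetic is float-exact."""
    return np.round(np.asarray(x) * 256.0) / 256.0


@dataclass
class SimulatedAnnotation:
    gene_set: GeneSet
    genome: dict[str, str]


# ---------------------------------------------------------------------------
# Annotation


def _random_mrna(rng: np.random.Generator, length: int, coding: bool):
    """(sequence, cds_u, cds_len) with a clean ORF when coding."""
    bases = "ACGT"
    if not coding or length < 30:
        seq = "".join(rng.choice(list(bases), size=length))
        return seq, None, None
    # start codon near the 5' end, stop codon near the 3' end
    u = int(rng.integers(0, min(30, length // 4)))
    v = int(rng.integers(3, min(30, length // 4)))
    c = length - u - v
    c -= c % 3
    v = length - u - c
    codons = ["ATG"]
    codons += list(rng.choice(_SENSE_CODONS, size=c // 3 - 2))
    codons.append(str(rng.choice(_STOP_CODONS)))
    seq = (
        "".join(rng.choice(list(bases), size=u))
        + "".join(codons)
        + "".join(rng.choice(list(bases), size=v))
    )
    assert len(seq) == length
    return seq, u, c


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_annotation(cfg: SimulationConfig) -> SimulatedAnnotation:
    """Generate a deterministic gene set and matching genome sequence.

    Genes are placed left to right per chromosome with log-uniform gaps;
    the first ``n_overlapping_pairs`` placements on chromosome 1 start the
    next gene inside the previous one (same strand) to exercise the
    overlapping-pair path.  Coding transcripts keep their start codon in
    exon 1 and their stop codon in the last exon, so a donor part truncated
    before the last exon always cuts the CDS mid-way.
    """
    rng = _rng(cfg, 0)
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    overlap_budget = cfg.n_overlapping_pairs
    for ci in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{ci}"
        cursor = 500
        placements = []  # (start, strand, exon_lengths, intron_lengths, coding)
        prev = None
        for gi in range(cfg.n_genes_per_chromosome):
            n_exons = int(rng.integers(*cfg.exon_count_range, endpoint=True))
            exon_lens = rng.integers(
                *cfg.exon_length_range, endpoint=True, size=n_exons
            ).tolist()
            intron_lens = rng.integers(
                *cfg.intron_length_range, endpoint=True, size=max(0, n_exons - 1)
            ).tolist()
            span = sum(exon_lens) + sum(intron_lens)
            strand = "+" if rng.random() < 0.5 else "-"
            if prev is not None and overlap_budget > 0 and ci == 1:
                # start inside the previous gene, same strand, later start
                prev_start, prev_end, prev_strand = prev
                start = int(
                    rng.integers(
                        max(prev_start + 1, prev_end - min(300, prev_end - prev_start)),
                        prev_end,
                    )
                )
                strand = prev_strand
                overlap_budget -= 1
            else:
                gap = int(
                    np.exp(
                        rng.uniform(
                            np.log(cfg.intergenic_gap_bounds[0]),
                            np.log(cfg.intergenic_gap_bounds[1]),
                        )
                    )
                )
                start = cursor + gap if prev is not None else cursor
            coding = rng.random() < cfg.fraction_coding
            placements.append((gi, start, strand, exon_lens, intron_lens, coding))
            end = start + span - 1
            cursor = max(cursor, end + 1)
            prev = (start, end, strand)
        chrom_len = cursor + 500
        seq = rng.choice(list("ACGT"), size=chrom_len)
        for gi, start, strand, exon_lens, intron_lens, coding in placements:
            gene_id = f"{chrom}G{gi + 1:03d}"
            tid = f"{gene_id}T1"
            exons_genomic = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons_genomic.append((pos, pos + el - 1))
                pos += el
                if i < len(intron_lens):
                    pos += intron_lens[i]
            mrna_len = sum(exon_lens)
            mrna, u, c = _random_mrna(rng, mrna_len, coding)
            # transcription order = genomic order on +, reversed on -
            order = exons_genomic if strand == "+" else exons_genomic[::-1]
            off = 0
            for s, e in order:
                chunk = mrna[off : off + (e - s + 1)]
                if strand == "-":
                    chunk = _revcomp(chunk)
                seq[s - 1 : e] = list(chunk)
                off += e - s + 1
            exon_ivs = [
                GenomicInterval(chrom, s, e, strand) for s, e in order
            ]
            span_iv = GenomicInterval(
                chrom, exons_genomic[0][0], exons_genomic[-1][1], strand
            )
            cds_start = cds_end = None
            if u is not None:
                tm_probe = TranscriptModel(tid, gene_id, span_iv, exon_ivs)
                cds_start = _genomic_of(tm_probe, u)
                cds_end = _genomic_of(tm_probe, u + c - 1)
            tm = TranscriptModel(tid, gene_id, span_iv, exon_ivs, cds_start, cds_end)
            genes.append(GeneModel(gene_id, gene_id, [tm]))
        genome[chrom] = "".join(seq)
    if overlap_budget > 0:
        raise ValueError(
            "could not place the requested number of overlapping pairs"
        )
    return SimulatedAnnotation(GeneSet(genes), genome)


def _genomic_of(t: TranscriptModel, mrna_off: int) -> int:
    """Genomic position of a 0-based mRNA offset."""
    off = 0
    for exon in t.exons:
        if mrna_off < off + len(exon):
            within = mrna_off - off
            return exon.start + within if t.strand == "+" else exon.end - within
        off += len(exon)
    raise ValueError(f"mRNA offset {mrna_off} beyond transcript {t.transcript_id}")


def write_fasta(genome: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Junction evidence


def _exon_3p_boundary(t: TranscriptModel, k: int) -> int:
    exon = t.exons[k - 1]
    return exon.end if t.strand == "+" else exon.start


def _exon_5p_boundary(t: TranscriptModel, j: int) -> int:
    exon = t.exons[j - 1]
    return exon.start if t.strand == "+" else exon.end


def _passing_stats(rng, cfg: SimulationConfig) -> tuple[int, float, int]:
    p = cfg.read_support_dispersion / (
        cfg.read_support_dispersion + cfg.read_support_mean
    )
    support = max(10, int(rng.negative_binomial(cfg.read_support_dispersion, p)))
    quality = float(max(25.0, rng.normal(cfg.quality_mean, cfg.quality_sd)))
    spanning = max(1, int(rng.binomial(support, 0.3)))
    return support, round(quality, 2), spanning


def simulate_junction_evidence(
    gs: GeneSet, cfg: SimulationConfig
) -> tuple[list[JunctionEvidence], pd.DataFrame]:
    """Plant true read-through junctions and per-class decoys.

    Returns the evidence rows (one per event x sample) and a truth table
    with one row per planted junction (``junction_id``, ``truth_class``,
    transcripts/exons, samples).  Every evidence row carries the
    ``junction_id`` of its truth row.
    """
    rng = _rng(cfg, 1)
    pairs = strand_adjacent_pairs(gs)
    if len(pairs) < cfg.n_true_readthroughs:
        raise ValueError(
            f"need {cfg.n_true_readthroughs} adjacent same-strand pairs, "
            f"only {len(pairs)} available"
        )
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    used: set[tuple] = set()
    evidence: list[JunctionEvidence] = []
    truth_rows = []

    def pick_exons(t_up: TranscriptModel, t_down: TranscriptModel):
        if t_up.n_exons >= 2:
            k = t_up.n_exons - 1 if rng.random() < 0.7 else int(
                rng.integers(1, t_up.n_exons)
            )
        else:
            k = 1
        if t_down.n_exons >= 2:
            j = 2 if rng.random() < 0.7 else int(rng.integers(2, t_down.n_exons + 1))
        else:
            j = 1
        return k, j

    def add_event(jid: str, cls: str, t_up, t_down, k, j, stats, n_samples=1):
        support, quality, spanning = stats
        samples = sorted(
            rng.choice(patients, size=min(n_samples, len(patients)), replace=False)
        )
        for s in samples:
            evidence.append(
                JunctionEvidence(
                    sample_id=str(s),
                    donor_transcript=t_up.transcript_id,
                    donor_exon=k,
                    donor_breakpoint=_exon_3p_boundary(t_up, k),
                    acceptor_transcript=t_down.transcript_id,
                    acceptor_exon=j,
                    acceptor_breakpoint=_exon_5p_boundary(t_down, j),
                    supporting_reads=support,
                    mean_read_quality=quality,
                    spanning_reads=spanning,
                    junction_id=jid,
                )
            )
        truth_rows.append(
            {
                "junction_id": jid,
                "truth_class": cls,
                "donor_transcript": t_up.transcript_id,
                "donor_exon": k,
                "acceptor_transcript": t_down.transcript_id,
                "acceptor_exon": j,
                "supporting_reads": support,
                "mean_read_quality": quality,
                "spanning_reads": spanning,
                "samples": ";".join(map(str, samples)),
            }
        )

    # true events on distinct adjacent same-strand pairs
    pair_idx = rng.permutation(len(pairs))[: cfg.n_true_readthroughs]
    for i, pi in enumerate(pair_idx):
        pair = pairs[pi]
        t_up = pair.upstream.transcripts[0]
        t_down = pair.downstream.transcripts[0]
        for _ in range(100):
            k, j = pick_exons(t_up, t_down)
            if (t_up.transcript_id, k, t_down.transcript_id, j) not in used:
                break
        used.add((t_up.transcript_id, k, t_down.transcript_id, j))
        n_samples = int(rng.integers(1, 4))
        add_event(
            f"TRUE{i + 1:03d}", "true", t_up, t_down, k, j,
            _passing_stats(rng, cfg), n_samples,
        )

    # structural decoy pickers
    all_genes = list(gs)

    def opposite_strand_pair():
        for _ in range(500):
            g1, g2 = rng.choice(len(all_genes), size=2, replace=False)
            a, b = all_genes[g1], all_genes[g2]
            if a.chrom == b.chrom and a.strand != b.strand:
                return a, b
        raise ValueError("no opposite-strand gene pair available")

    def non_adjacent_pair():
        for _ in range(500):
            key = gs.chrom_strand_keys[rng.integers(len(gs.chrom_strand_keys))]
            genes = gs.genes_on(*key)
            if len(genes) < 3:
                continue
            i = int(rng.integers(0, len(genes) - 2))
            sep = int(rng.integers(2, len(genes) - i))
            a, b = genes[i], genes[i + sep]
            return (a, b) if key[1] == "+" else (b, a)
        raise ValueError("no non-adjacent same-strand pair available")

    def inter_chromosomal_pair():
        for _ in range(500):
            g1, g2 = rng.choice(len(all_genes), size=2, replace=False)
            a, b = all_genes[g1], all_genes[g2]
            if a.chrom != b.chrom:
                return a, b
        raise ValueError("genome has a single chromosome; no such decoy")

    adjacent_pair = lambda: pairs[int(rng.integers(len(pairs)))]

    counter = 0
    for cls in _DECOY_CLASSES:
        for _ in range(int(cfg.n_decoys.get(cls, 0))):
            counter += 1
            stats = _passing_stats(rng, cfg)
            if cls == "opposite_strand":
                ga, gb = opposite_strand_pair()
            elif cls == "non_adjacent":
                ga, gb = non_adjacent_pair()
            elif cls == "inter_chromosomal":
                ga, gb = inter_chromosomal_pair()
            else:
                pair = adjacent_pair()
                ga, gb = pair.upstream, pair.downstream
                support, quality, spanning = stats
                if cls == "low_support":
                    support = int(rng.integers(1, 10))
                    spanning = min(spanning, support)
                elif cls == "low_quality":
                    quality = round(float(rng.uniform(10.0, 24.5)), 2)
                elif cls == "no_spanning":
                    spanning = 0
                stats = (support, quality, spanning)
            t_up, t_down = ga.transcripts[0], gb.transcripts[0]
            for _ in range(100):
                k, j = pick_exons(t_up, t_down)
                if (t_up.transcript_id, k, t_down.transcript_id, j) not in used:
                    break
            used.add((t_up.transcript_id, k, t_down.transcript_id, j))
            add_event(f"DECOY{counter:03d}", cls, t_up, t_down, k, j, stats)

    truth = pd.DataFrame(truth_rows)
    return evidence, truth


# ---------------------------------------------------------------------------
# qPCR


def _replicates(
    rng: np.random.Generator,
    true_ct: float,
    cfg: SimulationConfig,
    reliable: bool,
) -> np.ndarray:
    """Replicate wells with SD guaranteed on the intended side of the cutoff."""
    if not reliable:
        # guaranteed-wide duplicate spread: |diff| in [0.8, 2.0] cycles
        half = rng.uniform(0.4, 1.0)
        reps = np.full(cfg.n_replicates, true_ct)
        reps[0] -= half
        reps[1] += half
        return _quantize(reps)
    if cfg.replicate_noise_sd == 0:
        return _quantize(np.full(cfg.n_replicates, true_ct))
    for _ in range(100):
        reps = _quantize(true_ct + rng.normal(0, cfg.replicate_noise_sd,
                                              cfg.n_replicates))
        if np.std(reps, ddof=1) <= cfg.max_ct_sd:
            return reps
    raise RuntimeError("could not draw a reliable replicate set")


def simulate_qpcr(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired normal/tumor Ct tables with a planted tumor effect.

    Per patient and target gene the normal-tissue dCt is drawn from the
    baseline range; the tumor dCt adds ``tumor_effect_cycles`` (positive =
    lower expression in tumor).  The calibrator is a pool at the mean normal
    dCt.  Returns the well-level Ct table and a truth table with planted
    dCts and reliability flags.
    """
    rng = _rng(cfg, 2)
    patients = [f"Q{i + 1:03d}" for i in range(cfg.qpcr_n_patients)]
    rows = []
    truth_rows = []

    def add_wells(patient, sample, tissue, gene, reps):
        for w, ct in enumerate(reps, start=1):
            rows.append(
                {
                    "patient_id": patient,
                    "sample_id": sample,
                    "tissue": tissue,
                    "gene": gene,
                    "well": f"W{w}",
                    "ct": float(ct),
                }
            )

    baseline = {}
    for gene in cfg.qpcr_genes:
        for patient in patients:
            baseline[(gene, patient)] = float(
                _quantize(rng.uniform(*cfg.baseline_delta_ct_range))
            )

    for patient in patients:
        for tissue, suffix in (("normal", "N"), ("tumor", "T")):
            sample = f"{patient}{suffix}"
            ref_ct = float(_quantize(rng.uniform(*cfg.reference_ct_range)))
            add_wells(
                patient, sample, tissue, cfg.reference_gene,
                _replicates(rng, ref_ct, cfg, reliable=True),
            )
            for gene in cfg.qpcr_genes:
                delta = baseline[(gene, patient)]
                if tissue == "tumor":
                    delta = delta + cfg.tumor_effect_cycles
                reliable = bool(rng.random() >= cfg.unreliable_probability)
                add_wells(
                    patient, sample, tissue, gene,
                    _replicates(rng, ref_ct + delta, cfg, reliable=reliable),
                )
                truth_rows.append(
                    {
                        "patient_id": patient,
                        "gene": gene,
                        "tissue": tissue,
                        "delta_ct_true": delta,
                        "reliable": reliable,
                    }
                )

    # pooled calibrator: mean normal dCt per gene, quantized
    cal_ref = float(_quantize(np.mean(cfg.reference_ct_range)))
    add_wells(
        cfg.calibrator_id, cfg.calibrator_id, "calibrator", cfg.reference_gene,
        _replicates(rng, cal_ref, cfg, reliable=True),
    )
    for gene in cfg.qpcr_genes:
        pool_delta = float(
            _quantize(np.mean([baseline[(gene, p)] for p in patients]))
        )
        add_wells(
            cfg.calibrator_id, cfg.calibrator_id, "calibrator", gene,
            _replicates(rng, cal_ref + pool_delta, cfg, reliable=True),
        )

    ct = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return ct, truth
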