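"""Chimeric-junction filtering and read-through classification.

A junction caller (or the SAM split-read extractor below) produces candidate
chimeric junctions with read-support statistics.  A candidate survives when it
is supported by enough independent reads of adequate mean quality with at
least one read spanning the predicted exonic breakpoint, and it is classified
as a read-through event only when its donor and acceptor genes are adjacent
on the same genomic strand with the donor upstream in transcription order —
the configuration produced by transcription running through the end of one
gene into the next, as opposed to fusions created by genomic rearrangement.

Default thresholds: >= 10 supporting reads, mean read quality >= 25 (Phred),
>= 1 breakpoint-spanning read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .annotation import (
    OVERLAPPING,
    AdjacentPair,
    GeneSet,
    strand_adjacent_pairs,
)

__all__ = [
    "FilterThresholds",
    "JunctionEvidence",
    "ReadThroughEvent",
    "RejectionCode",
    "RejectionReason",
    "EVIDENCE_COLUMNS",
    "read_junction_evidence",
    "write_junction_evidence",
    "filter_evidence",
    "classify_readthrough",
    "collate_events",
    "detect_events",
    "events_to_frame",
    "evidence_from_alignments",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Acceptance thresholds for candidate chimeric junctions."""

    min_supporting_reads: int = 10
    min_mean_read_quality: float = 25.0
    min_breakpoint_spanning_reads: int = 1

    def __post_init__(self) -> None:
        if (
            self.min_supporting_reads < 0
            or self.min_mean_read_quality < 0
            or self.min_breakpoint_spanning_reads < 0
        ):
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class JunctionEvidence:
    """One candidate chimeric junction awaiting filtering."""

    sample_id: str
    donor_transcript: str
    donor_exon: int
    donor_breakpoint: int
    acceptor_transcript: str
    acceptor_exon: int
    acceptor_breakpoint: int
    supporting_reads: int
    mean_read_quality: float
    spanning_reads: int
    junction_id: str = ""

    def __post_init__(self) -> None:
        if self.supporting_reads < 0 or self.spanning_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.spanning_reads > self.supporting_reads:
            raise ValueError(
                "spanning_reads exceeds supporting_reads for junction "
                f"{self.donor_transcript}:{self.acceptor_transcript}"
            )


class RejectionCode(str, Enum):
    LOW_SUPPORT = "LOW_SUPPORT"
    LOW_QUALITY = "LOW_QUALITY"
    NO_SPANNING = "NO_SPANNING"
    DIFFERENT_CHROMOSOME = "DIFFERENT_CHROMOSOME"
    OPPOSITE_STRAND = "OPPOSITE_STRAND"
    NOT_ADJACENT = "NOT_ADJACENT"
    WRONG_ORDER = "WRONG_ORDER"


@dataclass(frozen=True)
class RejectionReason:
    code: RejectionCode
    detail: str = ""


@dataclass
class ReadThroughEvent:
    """An accepted read-through event (one junction on one adjacent pair).

    Event identity is (gene pair, donor exon, acceptor exon) plus an optional
    ``variant`` tag distinguishing e.g. incomplete-exon isoforms that share
    exon indices with a plain event.
    """

    gene_pair: AdjacentPair
    donor_transcript: str
    donor_exon: int
    acceptor_transcript: str
    acceptor_exon: int
    intergenic_bp: object = OVERLAPPING
    samples: set[str] = field(default_factory=set)
    frame_maintained: str = "unassessed"  # yes | no | unassessed
    validation_status: str = "rnaseq_only"
    variant: str = ""

    @property
    def key(self) -> tuple:
        return (
            self.gene_pair.symbol_pair,
            self.donor_transcript,
            self.donor_exon,
            self.acceptor_transcript,
            self.acceptor_exon,
            self.variant,
        )

    @property
    def name(self) -> str:
        return self.gene_pair.symbol_pair


EVIDENCE_COLUMNS = [
    "sample_id",
    "donor_transcript",
    "donor_exon",
    "donor_breakpoint",
    "acceptor_transcript",
    "acceptor_exon",
    "acceptor_breakpoint",
    "supporting_reads",
    "mean_read_quality",
    "spanning_reads",
]

_INT_COLUMNS = [
    "donor_exon",
    "donor_breakpoint",
    "acceptor_exon",
    "acceptor_breakpoint",
    "supporting_reads",
    "spanning_reads",
]


def read_junction_evidence(path: str) -> list[JunctionEvidence]:
    """Read the canonical junction-evidence TSV (row order preserved)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing evidence columns {missing}")
    records: list[JunctionEvidence] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(
                JunctionEvidence(
                    sample_id=str(row.sample_id),
                    donor_transcript=str(row.donor_transcript),
                    donor_exon=int(row.donor_exon),
                    donor_breakpoint=int(row.donor_breakpoint),
                    acceptor_transcript=str(row.acceptor_transcript),
                    acceptor_exon=int(row.acceptor_exon),
                    acceptor_breakpoint=int(row.acceptor_breakpoint),
                    supporting_reads=int(row.supporting_reads),
                    mean_read_quality=float(row.mean_read_quality),
                    spanning_reads=int(row.spanning_reads),
                    junction_id=str(getattr(row, "junction_id", "")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def write_junction_evidence(records: Sequence[JunctionEvidence], path: str) -> None:
    cols = EVIDENCE_COLUMNS + (
        ["junction_id"] if any(r.junction_id for r in records) else []
    )
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df.to_csv(path, sep="\t", index=False)


def filter_evidence(
    evidence: Iterable[JunctionEvidence], thresholds: FilterThresholds | None = None
) -> tuple[list[JunctionEvidence], list[tuple[JunctionEvidence, RejectionReason]]]:
    """Partition evidence into (kept, rejected-with-reason).

    A record is kept iff it meets all three thresholds.  A rejected record
    reports the *first* failed criterion in the fixed order
    support -> quality -> spanning, so outputs are deterministic.
    """
    t = thresholds or FilterThresholds()
    kept: list[JunctionEvidence] = []
    rejected: list[tuple[JunctionEvidence, RejectionReason]] = []
    for ev in evidence:
        if ev.supporting_reads < t.min_supporting_reads:
            rejected.append(
                (ev, RejectionReason(
                    RejectionCode.LOW_SUPPORT,
                    f"{ev.supporting_reads} < {t.min_supporting_reads}",
                ))
            )
        elif ev.mean_read_quality < t.min_mean_read_quality:
            rejected.append(
                (ev, RejectionReason(
                    RejectionCode.LOW_QUALITY,
                    f"{ev.mean_read_quality:g} < {t.min_mean_read_quality:g}",
                ))
            )
        elif ev.spanning_reads < t.min_breakpoint_spanning_reads:
            rejected.append(
                (ev, RejectionReason(
                    RejectionCode.NO_SPANNING,
                    f"{ev.spanning_reads} < {t.min_breakpoint_spanning_reads}",
                ))
            )
        else:
            kept.append(ev)
    return kept, rejected


def _adjacency_map(gs: GeneSet) -> dict[tuple[str, str], AdjacentPair]:
    return {
        (p.upstream.gene_id, p.downstream.gene_id): p
        for p in strand_adjacent_pairs(gs)
    }


def classify_readthrough(
    candidate: JunctionEvidence,
    gs: GeneSet,
    adjacency: dict[tuple[str, str], AdjacentPair] | None = None,
) -> ReadThroughEvent | RejectionReason:
    """Accept a candidate as a read-through event or explain its rejection.

    Accepted iff the donor and acceptor genes lie on the same chromosome and
    strand and form an adjacent pair with the donor gene upstream in
    transcription order.
    """
    donor_gene = gs.gene_of_transcript(candidate.donor_transcript)
    acceptor_gene = gs.gene_of_transcript(candidate.acceptor_transcript)
    if donor_gene.chrom != acceptor_gene.chrom:
        return RejectionReason(
            RejectionCode.DIFFERENT_CHROMOSOME,
            f"{donor_gene.chrom} vs {acceptor_gene.chrom}",
        )
    if donor_gene.strand != acceptor_gene.strand:
        return RejectionReason(
            RejectionCode.OPPOSITE_STRAND,
            f"{donor_gene.symbol}({donor_gene.strand}) vs "
            f"{acceptor_gene.symbol}({acceptor_gene.strand})",
        )
    adjacency = adjacency if adjacency is not None else _adjacency_map(gs)
    pair = adjacency.get((donor_gene.gene_id, acceptor_gene.gene_id))
    if pair is not None:
        return ReadThroughEvent(
            gene_pair=pair,
            donor_transcript=candidate.donor_transcript,
            donor_exon=candidate.donor_exon,
            acceptor_transcript=candidate.acceptor_transcript,
            acceptor_exon=candidate.acceptor_exon,
            intergenic_bp=pair.intergenic_bp,
            samples={candidate.sample_id},
        )
    if (acceptor_gene.gene_id, donor_gene.gene_id) in adjacency:
        return RejectionReason(
            RejectionCode.WRONG_ORDER,
            f"{acceptor_gene.symbol} is upstream of {donor_gene.symbol}",
        )
    return RejectionReason(
        RejectionCode.NOT_ADJACENT,
        f"{donor_gene.symbol} and {acceptor_gene.symbol} are not consecutive "
        "on their strand",
    )


def collate_events(accepted: Iterable[ReadThroughEvent]) -> list[ReadThroughEvent]:
    """Merge events with identical identity, unioning their sample sets."""
    merged: dict[tuple, ReadThroughEvent] = {}
    for ev in accepted:
        if ev.key in merged:
            merged[ev.key].samples |= ev.samples
        else:
            merged[ev.key] = ReadThroughEvent(
                gene_pair=ev.gene_pair,
                donor_transcript=ev.donor_transcript,
                donor_exon=ev.donor_exon,
                acceptor_transcript=ev.acceptor_transcript,
                acceptor_exon=ev.acceptor_exon,
                intergenic_bp=ev.intergenic_bp,
                samples=set(ev.samples),
                frame_maintained=ev.frame_maintained,
                validation_status=ev.validation_status,
                variant=ev.variant,
            )
    return list(merged.values())


def detect_events(
    evidence: Sequence[JunctionEvidence],
    gs: GeneSet,
    thresholds: FilterThresholds | None = None,
) -> tuple[list[ReadThroughEvent], list[tuple[JunctionEvidence, RejectionReason]]]:
    """Run the full per-sample filter -> classify -> collate chain.

    Evidence is filtered per sample, so an event's sample set contains only
    samples in which the junction independently passed all thresholds.
    """
    kept, rejected = filter_evidence(evidence, thresholds)
    adjacency = _adjacency_map(gs)
    accepted: list[ReadThroughEvent] = []
    for ev in kept:
        result = classify_readthrough(ev, gs, adjacency)
        if isinstance(result, RejectionReason):
            rejected.append((ev, result))
        else:
            accepted.append(result)
    return collate_events(accepted), rejected


def events_to_frame(events: Sequence[ReadThroughEvent]) -> pd.DataFrame:
    """Event table mirroring the published per-event layout."""
    rows = []
    for ev in sorted(events, key=lambda e: e.key):
        rows.append(
            {
                "gene_pair": ev.name,
                "chromosome": ev.gene_pair.upstream.chrom,
                "donor_transcript": ev.donor_transcript,
                "donor_exon": ev.donor_exon,
                "acceptor_transcript": ev.acceptor_transcript,
                "acceptor_exon": ev.acceptor_exon,
                "intergenic_bp": (
                    "NA" if ev.intergenic_bp is OVERLAPPING else ev.intergenic_bp
                ),
                "n_patients": len(ev.samples),
                "samples": ";".join(sorted(ev.samples)),
                "validation_status": ev.validation_status,
                "frame_maintained": ev.frame_maintained,
                "variant": ev.variant,
                "source": "rnaseq",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convenience extractor from split/supplementary alignments


def evidence_from_alignments(
    sam_path: str, gs: GeneSet, sample_id: str
) -> list[JunctionEvidence]:
    """Derive junction evidence from split-read (supplementary) alignments.

    Convenience path only: each read with one primary and one supplementary
    alignment segment is treated as one junction-spanning read; segments are
    assigned to transcripts by position, the junction is keyed by the exons
    hit, read quality is the mean base quality of the primary segment, and
    every contributing read counts as spanning.  The canonical input remains
    the junction-evidence TSV produced by a dedicated caller.
    """
    import pysam

    segments: dict[str, list] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary:
                continue
            segments.setdefault(aln.query_name, []).append(aln)

    def locate(chrom: str, pos: int):
        for strand in ("+", "-"):
            for gene in gs.genes_on(chrom, strand):
                for t in gene.transcripts:
                    idx = t.exon_containing(pos)
                    if idx is not None:
                        return t, idx
        return None

    buckets: dict[tuple, dict] = {}
    for name, alns in segments.items():
        if len(alns) != 2:
            continue
        primary = next((a for a in alns if not a.is_supplementary), alns[0])
        supp = next((a for a in alns if a is not primary))
        hit1 = locate(primary.reference_name, primary.reference_start + 1)
        hit2 = locate(supp.reference_name, supp.reference_start + 1)
        if hit1 is None or hit2 is None:
            continue
        (t1, e1), (t2, e2) = hit1, hit2
        if t1.transcript_id == t2.transcript_id:
            continue
        # orient: donor segment covers the 5' part of the read
        key = (t1.transcript_id, e1, t2.transcript_id, e2)
        quals = primary.query_qualities
        q = float(sum(quals)) / len(quals) if quals else 0.0
        b = buckets.setdefault(
            key,
            {
                "donor_breakpoint": primary.reference_end,
                "acceptor_breakpoint": supp.reference_start + 1,
                "qualities": [],
                "n": 0,
            },
        )
        b["qualities"].append(q)
        b["n"] += 1

    out: list[JunctionEvidence] = []
    for (dt, de, at, ae), b in sorted(buckets.items()):
        out.append(
            JunctionEvidence(
                sample_id=sample_id,
                donor_transcript=dt,
                donor_exon=de,
                donor_breakpoint=int(b["donor_breakpoint"]),
                acceptor_transcript=at,
                acceptor_exon=ae,
                acceptor_breakpoint=int(b["acceptor_breakpoint"]),
                supporting_reads=b["n"],
                mean_read_quality=sum(b["qualities"]) / b["n"],
                spanning_reads=b["n"],
            )
        )
    return out
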