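"""Chimeric transcript assembly and reading-frame assessment.

A read-through mRNA is modeled as the spliced exons 1..k of the upstream
(donor) transcript followed by exons j..last of the downstream (acceptor)
transcript, each strand-corrected to sense orientation.  Frame maintenance
asks whether, translating from the donor gene's start codon through the
junction, the acceptor gene's coding sequence is read in its native codon
phase — the condition for a bifunctional fusion protein rather than a
frameshifted (and typically prematurely terminated) product.

Semantics of :func:`assess_frame`:

* ``maintained`` is a codon-phase statement: the chimera phase at the first
  acceptor CDS base equals that base's native phase in the acceptor
  transcript, and no stop codon occurs in the translated frame strictly
  before the codon containing that base (relevant when 5'UTR or inserted
  intragenic bases sit between the junction and the acceptor CDS start).
* ``premature_stop`` is reported separately: an in-frame stop anywhere
  before the acceptor's native stop codon.  A hybrid codon straddling the
  junction can introduce a stop without breaking phase, so the two flags are
  independent.
* Events whose donor part lacks the donor start codon, or whose acceptor
  part contains no acceptor CDS base, are reported unassessed.

Partial ("incomplete") exons and retained intragenic segments are supported
through explicit genomic sub-intervals; no cryptic splice-site inference is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .annotation import GenomicInterval, TranscriptModel

__all__ = [
    "SequenceSource",
    "as_sequence_source",
    "ChimericTranscript",
    "FrameStatus",
    "build_chimera",
    "junction_labels",
    "assess_frame",
    "junction_sequence",
]


class SequenceSource:
    """Uniform 1-based-inclusive fetch over a genome FASTA or mapping."""

    def __init__(self, backend):
        self._backend = backend

    @classmethod
    def from_fasta(cls, path: str) -> "SequenceSource":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls(fa)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SequenceSource":
        return cls({k: str(v).upper() for k, v in mapping.items()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence of ``chrom:start-end`` (1-based, inclusive)."""
        if start < 1 or end < start:
            raise ValueError(f"bad fetch range {chrom}:{start}-{end}")
        seq = str(self._backend[chrom][start - 1 : end]).upper()
        if len(seq) != end - start + 1:
            raise ValueError(
                f"could not fetch {chrom}:{start}-{end} "
                f"(got {len(seq)} of {end - start + 1} bases)"
            )
        return seq


def as_sequence_source(genome) -> SequenceSource:
    if isinstance(genome, SequenceSource):
        return genome
    if isinstance(genome, (str, Path)):
        return SequenceSource.from_fasta(genome)
    if isinstance(genome, Mapping):
        return SequenceSource.from_mapping(genome)
    raise TypeError(f"cannot interpret {type(genome)!r} as a sequence source")


def _segment_seq(iv: GenomicInterval, src: SequenceSource) -> str:
    seq = src.fetch(iv.chrom, iv.start, iv.end)
    if iv.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _offset_in(iv: GenomicInterval, pos: int) -> int:
    """0-based offset of ``pos`` within ``iv`` along the transcription sense."""
    return pos - iv.start if iv.strand == "+" else iv.end - pos


@dataclass
class ChimericTranscript:
    """A read-through mRNA: donor part, optional insert, acceptor part."""

    donor_transcript: TranscriptModel
    acceptor_transcript: TranscriptModel
    donor_exon: int
    acceptor_exon: int
    donor_intervals: list[GenomicInterval]
    acceptor_intervals: list[GenomicInterval]
    insert_intervals: list[GenomicInterval]
    donor_seq: str
    insert_seq: str
    acceptor_seq: str

    @property
    def sequence(self) -> str:
        return self.donor_seq + self.insert_seq + self.acceptor_seq

    @property
    def junction_offset(self) -> int:
        """0-based chimera position of the first base after the donor part."""
        return len(self.donor_seq)

    @property
    def acceptor_offset(self) -> int:
        """0-based chimera position of the first acceptor-part base."""
        return len(self.donor_seq) + len(self.insert_seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def _part_offset(
        self, intervals: Sequence[GenomicInterval], base: int, pos: int
    ) -> int | None:
        off = base
        for iv in intervals:
            if iv.contains(pos):
                return off + _offset_in(iv, pos)
            off += len(iv)
        return None

    def donor_offset_of(self, pos: int) -> int | None:
        return self._part_offset(self.donor_intervals, 0, pos)

    def acceptor_offset_of(self, pos: int) -> int | None:
        return self._part_offset(self.acceptor_intervals, self.acceptor_offset, pos)


def build_chimera(
    t1: TranscriptModel,
    k: int,
    t2: TranscriptModel,
    j: int,
    genome,
    *,
    donor_intervals: Sequence[GenomicInterval] | None = None,
    acceptor_intervals: Sequence[GenomicInterval] | None = None,
    insert: Sequence[GenomicInterval] | None = None,
) -> ChimericTranscript:
    """Assemble the chimeric mRNA joining exon ``k`` of ``t1`` to exon ``j`` of ``t2``.

    ``donor_intervals``/``acceptor_intervals`` override the default full
    exons 1..k / j..last with explicit genomic sub-intervals (transcription
    order) for incomplete-exon events; ``insert`` adds retained intragenic
    segments between the two parts.
    """
    if not 1 <= k <= t1.n_exons:
        raise IndexError(f"donor exon {k} out of range for {t1.transcript_id}")
    if not 1 <= j <= t2.n_exons:
        raise IndexError(f"acceptor exon {j} out of range for {t2.transcript_id}")
    src = as_sequence_source(genome)
    d_ivs = list(donor_intervals) if donor_intervals is not None else t1.exons[:k]
    a_ivs = (
        list(acceptor_intervals)
        if acceptor_intervals is not None
        else t2.exons[j - 1 :]
    )
    i_ivs = list(insert) if insert is not None else []
    return ChimericTranscript(
        donor_transcript=t1,
        acceptor_transcript=t2,
        donor_exon=k,
        acceptor_exon=j,
        donor_intervals=d_ivs,
        acceptor_intervals=a_ivs,
        insert_intervals=i_ivs,
        donor_seq="".join(_segment_seq(iv, src) for iv in d_ivs),
        insert_seq="".join(_segment_seq(iv, src) for iv in i_ivs),
        acceptor_seq="".join(_segment_seq(iv, src) for iv in a_ivs),
    )


def junction_labels(k: int, t1: TranscriptModel, j: int) -> dict[str, bool]:
    """Position flags for the junction exons.

    ``donor_is_penultimate_exon``: the donor exon is the second-to-last exon
    of its transcript (the one before the 3'UTR-bearing final exon) — the
    most frequent donor position.  ``acceptor_is_exon2``: the acceptor exon
    is exon 2 of its transcript — the most frequent acceptor position.
    """
    return {
        "donor_is_penultimate_exon": k == t1.n_exons - 1,
        "acceptor_is_exon2": j == 2,
    }


@dataclass
class FrameStatus:
    """Outcome of the reading-frame assessment of one chimera."""

    assessed: bool
    maintained: bool | None = None
    donor_cds_bases_included: int = 0
    acceptor_native_phase: int | None = None
    chimera_phase_at_acceptor_cds: int | None = None
    first_stop_offset: int | None = None
    premature_stop: bool = False
    reason: str = ""

    @property
    def label(self) -> str:
        if not self.assessed:
            return "unassessed"
        return "yes" if self.maintained else "no"


def _cds_overlap_bases(
    intervals: Sequence[GenomicInterval], t: TranscriptModel
) -> int:
    if not t.is_coding:
        return 0
    lo = min(t.cds_start, t.cds_end)
    hi = max(t.cds_start, t.cds_end)
    return sum(
        max(0, min(iv.end, hi) - max(iv.start, lo) + 1) for iv in intervals
    )


def assess_frame(c: ChimericTranscript) -> FrameStatus:
    """Decide frame maintenance and premature-stop status of a chimera."""
    t1, t2 = c.donor_transcript, c.acceptor_transcript
    if not t1.is_coding:
        return FrameStatus(False, reason="donor transcript is non-coding")
    if not t2.is_coding:
        return FrameStatus(False, reason="acceptor transcript is non-coding")

    a1 = c.donor_offset_of(t1.cds_start)  # chimera offset of donor start codon
    if a1 is None:
        return FrameStatus(
            False, reason="donor part does not include the donor start codon"
        )
    l1 = _cds_overlap_bases(c.donor_intervals, t1)

    # locate the first acceptor-part CDS base, both in chimera coordinates
    # (f) and as an offset from t2's CDS start in native transcript space (d)
    s2 = c.acceptor_offset_of(t2.cds_start)
    if s2 is not None:
        f, delta = s2, 0
    else:
        if not c.acceptor_intervals:
            return FrameStatus(False, reason="empty acceptor part")
        first = c.acceptor_intervals[0]
        first_pos = first.start if first.strand == "+" else first.end
        try:
            t2_off = t2.to_transcript_coord(first_pos)
        except ValueError:
            return FrameStatus(
                False, reason="acceptor part begins outside annotated exons"
            )
        cds_span = t2.cds_transcript_span()
        if t2_off >= cds_span[1]:
            return FrameStatus(
                False, reason="acceptor part contains no acceptor CDS base"
            )
        f, delta = c.acceptor_offset, t2_off - cds_span[0]
        if delta < 0:  # CDS start genomic position absent despite 5'UTR start
            return FrameStatus(
                False, reason="acceptor CDS start not contained in acceptor part"
            )

    p2 = delta % 3
    p1 = (f - a1) % 3

    coding_len = 3 * ((len(c.sequence) - a1) // 3)
    protein = str(Seq(c.sequence[a1 : a1 + coding_len]).translate())
    first_stop_idx = protein.find("*")
    first_stop_offset = a1 + 3 * first_stop_idx if first_stop_idx >= 0 else None

    # stop in the translated frame strictly before the codon holding the
    # first acceptor CDS base (donor 3' bases, insert, or acceptor 5'UTR)
    boundary_codon = (f - a1) // 3
    stop_before_acceptor_cds = 0 <= first_stop_idx < boundary_codon

    maintained = (p1 == p2) and not stop_before_acceptor_cds

    # premature stop: any in-frame stop before t2's native stop codon
    cds_span = t2.cds_transcript_span()
    stop_codon_t2_off = cds_span[1] - 3
    native_stop_chimera = f + (stop_codon_t2_off - (cds_span[0] + delta))
    premature = first_stop_offset is not None and (
        first_stop_offset < native_stop_chimera
    )

    return FrameStatus(
        assessed=True,
        maintained=maintained,
        donor_cds_bases_included=l1,
        acceptor_native_phase=p2,
        chimera_phase_at_acceptor_cds=p1,
        first_stop_offset=first_stop_offset,
        premature_stop=premature,
    )


def junction_sequence(c: ChimericTranscript, flank: int) -> tuple[str, int]:
    """Sequence window of up to ``flank`` bases either side of the junction.

    Returns ``(window, junction_offset_in_window)`` where the junction
    position is the offset of the first acceptor base within the window;
    the window is clipped at the transcript ends.  Useful for placing
    junction-spanning validation primers.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seq = c.sequence
    j = c.acceptor_offset
    lo = max(0, j - flank)
    hi = min(len(seq), j + flank)
    return seq[lo:hi], j - lo
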