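"""Gene and transcript models with strand-aware adjacency.

Read-through (conjoined-gene) transcription joins two *adjacent* genes on the
*same* genomic strand, splicing out the intergenic region.  Everything in this
module exists to make that adjacency rule and the associated intergenic
distance computable from a standard annotation file.

Conventions
-----------
* Coordinates are 1-based and inclusive on both ends (GTF convention).
  BED12 input is converted on read.
* Exons of a :class:`TranscriptModel` are stored in *transcription order*:
  exon 1 is the 5'-most exon of the mRNA, which on the minus strand is the
  exon with the largest genomic coordinate.
* ``cds_start``/``cds_end`` are genomic bounds of the coding sequence
  *including* the stop codon (a single internal convention; the GTF writer
  emits CDS features with these bounds).
* A gene's span is the union span of its transcripts; adjacency and
  intergenic distance are defined on gene spans, not on transcripts.
* "Adjacent" means consecutive in the per-(chromosome, strand) list of genes
  ordered by start position.  Genes on the *opposite* strand lying between a
  pair do not break adjacency: read-through transcription proceeds along one
  strand and never sees them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from gffutils.feature import feature_from_line

__all__ = [
    "OVERLAPPING",
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "GeneSet",
    "AdjacentPair",
    "AnnotationParseError",
    "read_annotation",
    "write_gtf",
    "strand_adjacent_pairs",
    "intergenic_distance",
]


class _Overlapping:
    """Sentinel for gene pairs whose loci overlap (no defined intergenic gap)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "OVERLAPPING"


#: Singleton marking an undefined intergenic distance between overlapping loci.
OVERLAPPING = _Overlapping()


class AnnotationParseError(ValueError):
    """Raised when an annotation record cannot be parsed; names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval on one strand (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus optional CDS bounds.

    ``exons`` are in transcription order (see module docstring); indices used
    throughout the package are 1-based to match how junction exons are
    reported in the field ("exon 2 of the second gene").
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        starts = [e.start for e in self.exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValueError(
                f"exons of {self.transcript_id} not in transcription order"
            )
        for a, b in zip(sorted(self.exons, key=lambda e: e.start), sorted(self.exons, key=lambda e: e.start)[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mrna_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def exon_containing(self, pos: int) -> int | None:
        """1-based transcription-order index of the exon containing ``pos``."""
        for i, exon in enumerate(self.exons, start=1):
            if exon.contains(pos):
                return i
        return None

    def to_transcript_coord(self, pos: int) -> int:
        """0-based mRNA offset of genomic position ``pos`` (must be exonic)."""
        offset = 0
        for exon in self.exons:
            if exon.contains(pos):
                if self.strand == "+":
                    return offset + (pos - exon.start)
                return offset + (exon.end - pos)
            offset += len(exon)
        raise ValueError(f"position {pos} is not exonic in {self.transcript_id}")

    def cds_transcript_span(self) -> tuple[int, int] | None:
        """(start, end) 0-based half-open mRNA span of the CDS, or None."""
        if not self.is_coding:
            return None
        a = self.to_transcript_coord(self.cds_start)
        b = self.to_transcript_coord(self.cds_end)
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing chromosome and strand."""

    gene_id: str
    symbol: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transcripts:
            chroms = {t.chrom for t in self.transcripts}
            strands = {t.strand for t in self.transcripts}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValueError(
                    f"gene {self.gene_id}: transcripts span multiple "
                    "chromosomes or strands"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def interval(self) -> GenomicInterval:
        """Union span of all transcripts (the gene locus)."""
        return GenomicInterval(
            self.chrom,
            min(t.interval.start for t in self.transcripts),
            max(t.interval.end for t in self.transcripts),
            self.strand,
        )


class GeneSet:
    """Genes indexed per (chromosome, strand), ordered by start position."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._transcripts: dict[str, TranscriptModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            for t in g.transcripts:
                if t.transcript_id in self._transcripts:
                    raise ValueError(f"duplicate transcript_id {t.transcript_id}")
                self._transcripts[t.transcript_id] = t
        self._index: dict[tuple[str, str], list[str]] = {}
        for g in self.genes.values():
            self._index.setdefault((g.chrom, g.strand), []).append(g.gene_id)
        for key, ids in self._index.items():
            ids.sort(key=lambda gid: (self.genes[gid].interval.start,
                                      self.genes[gid].interval.end, gid))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def gene(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def transcript(self, transcript_id: str) -> TranscriptModel:
        try:
            return self._transcripts[transcript_id]
        except KeyError:
            raise KeyError(f"unknown transcript id {transcript_id!r}") from None

    def gene_of_transcript(self, transcript_id: str) -> GeneModel:
        return self.genes[self.transcript(transcript_id).gene_id]

    @property
    def chrom_strand_keys(self) -> list[tuple[str, str]]:
        return sorted(self._index)

    def genes_on(self, chrom: str, strand: str) -> list[GeneModel]:
        return [self.genes[gid] for gid in self._index.get((chrom, strand), [])]


@dataclass
class AdjacentPair:
    """Two consecutive same-strand genes, in transcription order.

    ``upstream`` is the gene whose 3' end precedes the ``downstream`` gene's
    5' start along the direction of transcription; ``intergenic_bp`` is the
    number of bases strictly between the two loci, or :data:`OVERLAPPING`.
    """

    upstream: GeneModel
    downstream: GeneModel
    intergenic_bp: int | _Overlapping = 0

    @property
    def symbol_pair(self) -> str:
        return f"{self.upstream.symbol}-{self.downstream.symbol}"


# ---------------------------------------------------------------------------
# Reading / writing


def _sniff_dialect(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".gff", ".gff3")):
        return "gff3"
    if lower.endswith(".bed"):
        return "bed12"
    return "gtf"


def read_annotation(path: str, dialect: str | None = None) -> GeneSet:
    """Load a :class:`GeneSet` from GTF, GFF3 or BED12.

    Exon features must carry transcript and gene identity: ``transcript_id``
    and ``gene_id`` attributes in GTF, ``Parent`` chains (exon -> transcript
    -> gene) or explicit attributes in GFF3. Transcripts without exons are
    dropped with a warning. Malformed records raise
    :class:`AnnotationParseError` naming the line number.
    """
    dialect = dialect or _sniff_dialect(path)
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return _read_gxf(path, dialect)


def _attr(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            values = feature.attributes[key]
            if values:
                return values[0]
    return None


def _read_gxf(path: str, dialect: str) -> GeneSet:
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_symbol: dict[str, str] = {}
    parent_of: dict[str, str] = {}  # GFF3: feature ID -> Parent ID
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise AnnotationParseError(
                    f"{path}: cannot parse line {lineno}: {exc}"
                ) from exc
            fid = _attr(f, "ID")
            parent = _attr(f, "Parent")
            if fid and parent:
                parent_of[fid] = parent
            if f.featuretype not in ("exon", "CDS"):
                if f.featuretype == "gene" and fid:
                    name = _attr(f, "gene_name", "Name", "gene_id") or fid
                    gene_symbol.setdefault(fid, name)
                continue
            tid = _attr(f, "transcript_id") or parent
            if tid is None:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: {f.featuretype} record lacks a "
                    "transcript_id attribute or Parent"
                )
            gid = _attr(f, "gene_id")
            if gid is not None:
                tx_gene.setdefault(tid, gid)
            try:
                iv = GenomicInterval(f.seqid, f.start, f.end, f.strand)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            bucket = exons if f.featuretype == "exon" else cds
            if tid not in exons and tid not in cds:
                order.append(tid)
            bucket.setdefault(tid, []).append(iv)
            name = _attr(f, "gene_name")
            if gid and name:
                gene_symbol.setdefault(gid, name)

    # resolve GFF3 Parent chains for transcripts lacking explicit gene_id
    for tid in order:
        if tid not in tx_gene:
            gid = parent_of.get(tid)
            if gid is None:
                raise AnnotationParseError(
                    f"{path}: cannot resolve a gene for transcript {tid!r}"
                )
            tx_gene[tid] = gid

    genes: dict[str, GeneModel] = {}
    for tid in order:
        if tid not in exons:
            warnings.warn(f"transcript {tid} has no exon records; dropped")
            continue
        ivs = exons[tid]
        strand = ivs[0].strand
        ivs.sort(key=lambda e: e.start, reverse=strand == "-")
        cds_start = cds_end = None
        if tid in cds:
            lo = min(c.start for c in cds[tid])
            hi = max(c.end for c in cds[tid])
            cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
        gid = tx_gene[tid]
        span = GenomicInterval(
            ivs[0].chrom,
            min(e.start for e in ivs),
            max(e.end for e in ivs),
            strand,
        )
        tm = TranscriptModel(tid, gid, span, ivs, cds_start, cds_end)
        if gid not in genes:
            genes[gid] = GeneModel(gid, gene_symbol.get(gid, gid), [])
        genes[gid].transcripts.append(tm)
    return GeneSet(genes.values())


def _read_bed12(path: str) -> GeneSet:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 12 BED columns, "
                    f"got {len(cols)}"
                )
            try:
                chrom, chrom_start, chrom_end = cols[0], int(cols[1]), int(cols[2])
                name, strand = cols[3], cols[5]
                thick_start, thick_end = int(cols[6]), int(cols[7])
                n_blocks = int(cols[9])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: blockCount={n_blocks} does not "
                    "match blockSizes/blockStarts"
                )
            # BED is 0-based half-open; convert to 1-based inclusive
            ivs = [
                GenomicInterval(chrom, chrom_start + s + 1, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            ivs.sort(key=lambda e: e.start, reverse=strand == "-")
            cds_start = cds_end = None
            if thick_end > thick_start:  # coding
                lo, hi = thick_start + 1, thick_end
                cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
            span = GenomicInterval(chrom, chrom_start + 1, chrom_end, strand)
            tm = TranscriptModel(name, name, span, ivs, cds_start, cds_end)
            genes.append(GeneModel(name, name, [tm]))
    return GeneSet(genes)


def write_gtf(gs: GeneSet, path: str, source: str = "readthrough") -> None:
    """Write a :class:`GeneSet` back out as GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for key in gs.chrom_strand_keys:
            for gene in gs.genes_on(*key):
                for t in gene.transcripts:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{t.transcript_id}"; '
                        f'gene_name "{gene.symbol}";'
                    )
                    for exon in sorted(t.exons, key=lambda e: e.start):
                        fh.write(
                            f"{exon.chrom}\t{source}\texon\t{exon.start}\t"
                            f"{exon.end}\t.\t{exon.strand}\t.\t{attrs}\n"
                        )
                    if t.is_coding:
                        lo = min(t.cds_start, t.cds_end)
                        hi = max(t.cds_start, t.cds_end)
                        for exon in sorted(t.exons, key=lambda e: e.start):
                            a, b = max(exon.start, lo), min(exon.end, hi)
                            if a <= b:
                                fh.write(
                                    f"{exon.chrom}\t{source}\tCDS\t{a}\t{b}\t."
                                    f"\t{exon.strand}\t0\t{attrs}\n"
                                )


# ---------------------------------------------------------------------------
# Adjacency


def strand_adjacent_pairs(gs: GeneSet) -> list[AdjacentPair]:
    """All consecutive same-strand gene pairs, in transcription order.

    For each (chromosome, strand) the genes are taken in start-position
    order; every consecutive pair is emitted, including overlapping pairs
    (``intergenic_bp = OVERLAPPING``).  On the minus strand transcription
    runs right-to-left, so the genomically-right gene of each pair is the
    upstream partner.
    """
    pairs: list[AdjacentPair] = []
    for chrom, strand in gs.chrom_strand_keys:
        genes = gs.genes_on(chrom, strand)
        for left, right in zip(genes, genes[1:]):
            if strand == "+":
                up, down = left, right
            else:
                up, down = right, left
            pair = AdjacentPair(up, down)
            pair.intergenic_bp = intergenic_distance(pair)
            pairs.append(pair)
    return pairs


def intergenic_distance(pair: AdjacentPair) -> int | _Overlapping:
    """Base pairs between the upstream locus end and downstream locus start.

    The count is of bases strictly between the two gene spans; it is the
    same number computed in genomic coordinates on either strand. Abutting
    genes have distance 0; overlapping (or out-of-order) spans yield
    :data:`OVERLAPPING`.
    """
    up, down = pair.upstream.interval, pair.downstream.interval
    if up.chrom != down.chrom or up.strand != down.strand:
        raise ValueError("adjacent pair must share chromosome and strand")
    left, right = (up, down) if up.start <= down.start else (down, up)
    gap = right.start - left.end - 1
    if gap < 0:
        return OVERLAPPING
    return gap
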