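"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from readthrough.annotation import (
    GeneModel,
    GeneSet,
    GenomicInterval,
    TranscriptModel,
)
from readthrough.simulate import SimulationConfig, simulate_annotation


def make_transcript(tid, gid, chrom, strand, exon_bounds, cds=None):
    """Build a TranscriptModel from genomic (start, end) exon bounds."""
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    ivs.sort(key=lambda iv: iv.start, reverse=strand == "-")
    span = GenomicInterval(
        chrom,
        min(iv.start for iv in ivs),
        max(iv.end for iv in ivs),
        strand,
    )
    cds_start = cds_end = None
    if cds is not None:
        lo, hi = cds
        cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
    return TranscriptModel(tid, gid, span, ivs, cds_start, cds_end)


def make_gene(gid, chrom, strand, exon_bounds, cds=None, symbol=None):
    t = make_transcript(f"{gid}T1", gid, chrom, strand, exon_bounds, cds)
    return GeneModel(gid, symbol or gid, [t])


@pytest.fixture
def simple_gene_set():
    """Five genes on chr1 (A,B,C on +; D,E on -) and one on chr2."""
    return GeneSet(
        [
            make_gene("A", "chr1", "+", [(1000, 1400), (1600, 2000)]),
            make_gene("B", "chr1", "+", [(6899, 7300), (7600, 8000)]),
            make_gene("C", "chr1", "+", [(12000, 12500), (12800, 13000)]),
            make_gene("D", "chr1", "-", [(3000, 3400), (3600, 4000)]),
            make_gene("E", "chr1", "-", [(9000, 9400), (9600, 9900)]),
            make_gene("F", "chr2", "+", [(500, 900), (1200, 1500)]),
        ]
    )


@pytest.fixture(scope="session")
def sim_annotation():
    cfg = SimulationConfig(seed=11)
    return cfg, simulate_annotation(cfg)


@pytest.fixture(scope="session")
def coding_annotation():
    """All-coding gene set with genome, for frame analysis."""
    cfg = SimulationConfig(
        seed=13, n_genes_per_chromosome=40, fraction_coding=1.0
    )
    return cfg, simulate_annotation(cfg)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_adjacent_pairs(gs: GeneSet) -> set[tuple[str, str]]:
    """O(n^2) adjacency oracle: same chrom/strand, no same-strand gene between."""
    genes = list(gs)
    out = set()
    for a in genes:
        for b in genes:
            if a is b or a.chrom != b.chrom or a.strand != b.strand:
                continue
            lo, hi = sorted([a.interval.start, b.interval.start])
            if lo == a.interval.start:
                between = [
                    c
                    for c in genes
                    if c is not a
                    and c is not b
                    and c.chrom == a.chrom
                    and c.strand == a.strand
                    and lo < c.interval.start < hi
                ]
                if not between:
                    left, right = a, b
                    up, down = (left, right) if a.strand == "+" else (right, left)
                    out.add((up.gene_id, down.gene_id))
    return out


def splice_oracle(t: TranscriptModel, genome: dict, upto=None, from_exon=1) -> str:
    """Base-by-base spliced mRNA of exons [from_exon, upto] of a transcript."""
    upto = upto if upto is not None else t.n_exons
    out = []
    for exon in t.exons[from_exon - 1 : upto]:
        chrom_seq = genome[exon.chrom]
        positions = range(exon.start, exon.end + 1)
        if t.strand == "-":
            for p in reversed(list(positions)):
                out.append(str(Seq(chrom_seq[p - 1]).complement()))
        else:
            for p in positions:
                out.append(chrom_seq[p - 1])
    return "".join(out)


def wilcoxon_enumeration_oracle(d: np.ndarray) -> float:
    """Literal 2^n enumeration of sign assignments for the two-sided p."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for mask in range(2**n):
        signs = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        ws.append(ranks[signs].sum())
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def frame_translation_oracle(chimera, genome: dict) -> bool | None:
    """Suffix-preservation oracle for frame maintenance.

    Translates the chimera in the frame fixed by the donor start codon
    (stops rendered as ``*``) and demands (i) the residues aligned to the
    acceptor CDS equal the native acceptor protein suffix, and (ii) no stop
    codon strictly before the codon holding the first acceptor CDS base.
    Returns None when the chimera is unassessable.
    """
    t1, t2 = chimera.donor_transcript, chimera.acceptor_transcript
    if not (t1.is_coding and t2.is_coding):
        return None
    donor_mrna = splice_oracle(t1, genome, upto=chimera.donor_exon)
    acceptor_mrna = splice_oracle(t2, genome, from_exon=chimera.acceptor_exon)
    seq = donor_mrna + acceptor_mrna
    s1, _ = t1.cds_transcript_span()
    if s1 >= len(donor_mrna):
        return None
    s2, e2 = t2.cds_transcript_span()
    skip = sum(len(e) for e in t2.exons[: chimera.acceptor_exon - 1])
    if skip >= e2:
        return None
    a1 = s1
    prot = str(Seq(seq[a1 : a1 + 3 * ((len(seq) - a1) // 3)]).translate())
    t2_full = splice_oracle(t2, genome)
    t2_prot = str(Seq(t2_full[s2:e2]).translate())
    # first complete native codon fully inside the acceptor part
    first_codon = max(0, -(-(skip - s2) // 3)) if skip > s2 else 0
    codon_chim_off = len(donor_mrna) + (s2 + 3 * first_codon - skip)
    if (codon_chim_off - a1) % 3 != 0:
        return False
    q = (codon_chim_off - a1) // 3
    native_suffix = t2_prot[first_codon:]
    if prot[q : q + len(native_suffix)] != native_suffix:
        return False
    f = len(donor_mrna) + max(0, s2 - skip)  # first acceptor CDS base
    if "*" in prot[: (f - a1) // 3]:
        return False
    return True
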