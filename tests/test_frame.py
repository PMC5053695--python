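"""Chimeric mRNA assembly, junction labels and frame assessment."""

import numpy as np
import pytest

from readthrough.frame import (
    assess_frame,
    build_chimera,
    junction_labels,
    junction_sequence,
)

from conftest import make_transcript, splice_oracle


def _toy_genome(n=2000, fill="C"):
    return {"c": fill * n}


@pytest.fixture
def arithmetic_pair():
    t1 = make_transcript(
        "t1", "g1", "c", "+", [(1, 100), (201, 280), (401, 460)]
    )
    t2 = make_transcript("t2", "g2", "c", "+", [(1001, 1050), (1101, 1140)])
    return t1, t2


class TestBuildChimera:
    def test_length_arithmetic(self, arithmetic_pair):
        t1, t2 = arithmetic_pair
        c = build_chimera(t1, 2, t2, 2, _toy_genome())
        assert len(c) == 100 + 80 + 40 == 220
        assert c.junction_offset == 180

    def test_full_transcript_boundary(self, arithmetic_pair):
        t1, t2 = arithmetic_pair
        genome = {"c": "".join(np.random.default_rng(0).choice(list("ACGT"), 2000))}
        c = build_chimera(t1, t1.n_exons, t2, 1, genome)
        assert c.sequence == splice_oracle(t1, genome) + splice_oracle(t2, genome)

    def test_out_of_range_exon_raises(self, arithmetic_pair):
        t1, t2 = arithmetic_pair
        with pytest.raises(IndexError):
            build_chimera(t1, 4, t2, 1, _toy_genome())
        with pytest.raises(IndexError):
            build_chimera(t1, 1, t2, 0, _toy_genome())

    def test_matches_per_base_splice_oracle(self, coding_annotation):
        _, sim = coding_annotation
        genes = list(sim.gene_set)
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            g1, g2 = rng.choice(len(genes), size=2, replace=False)
            t1 = genes[g1].transcripts[0]
            t2 = genes[g2].transcripts[0]
            k = int(rng.integers(1, t1.n_exons + 1))
            j = int(rng.integers(1, t2.n_exons + 1))
            c = build_chimera(t1, k, t2, j, sim.genome)
            expected = splice_oracle(t1, sim.genome, upto=k) + splice_oracle(
                t2, sim.genome, from_exon=j
            )
            assert c.sequence == expected
            assert len(c) == sum(len(e) for e in t1.exons[:k]) + sum(
                len(e) for e in t2.exons[j - 1 :]
            )
            checked += 1

    def test_strand_mirror_produces_identical_mrna(self):
        rng = np.random.default_rng(3)
        fwd = "".join(rng.choice(list("ACGT"), 3000))
        comp = str.maketrans("ACGT", "TGCA")
        rev = fwd.translate(comp)[::-1]
        L = len(fwd)
        plus1 = make_transcript("p1", "g1", "c", "+", [(101, 200), (301, 400)])
        plus2 = make_transcript("p2", "g2", "c", "+", [(1001, 1100), (1301, 1400)])
        mirror = lambda s, e: (L + 1 - e, L + 1 - s)
        minus1 = make_transcript(
            "m1", "g1", "c", "-", [mirror(101, 200), mirror(301, 400)]
        )
        minus2 = make_transcript(
            "m2", "g2", "c", "-", [mirror(1001, 1100), mirror(1301, 1400)]
        )
        c_plus = build_chimera(plus1, 2, plus2, 1, {"c": fwd})
        c_minus = build_chimera(minus1, 2, minus2, 1, {"c": rev})
        assert c_plus.sequence == c_minus.sequence

    def test_partial_exon_override(self, arithmetic_pair):
        t1, t2 = arithmetic_pair
        from readthrough.annotation import GenomicInterval

        partial = [t1.exons[0], GenomicInterval("c", 201, 240, "+")]
        c = build_chimera(
            t1, 2, t2, 2, _toy_genome(), donor_intervals=partial
        )
        assert c.junction_offset == 140


class TestJunctionLabels:
    def test_penultimate_and_exon2_flags(self):
        t1 = make_transcript(
            "t", "g", "c", "+", [(i * 100 + 1, i * 100 + 50) for i in range(8)]
        )
        assert junction_labels(7, t1, 2) == {
            "donor_is_penultimate_exon": True,
            "acceptor_is_exon2": True,
        }
        assert junction_labels(8, t1, 3) == {
            "donor_is_penultimate_exon": False,
            "acceptor_is_exon2": False,
        }


def _frame_fixture(donor_exon1_end):
    """Donor CDS cut after (donor_exon1_end - 10) coding bases at the junction."""
    seq = ["C"] * 1500
    seq[10:310] = list("ATG" + "GCT" * 99)  # donor CDS bases 11..310
    seq[1000:1300] = list("ATG" + "GAT" * 98 + "TAA")  # acceptor CDS 1001..1300
    genome = {"c": "".join(seq)}
    t1 = make_transcript(
        "t1", "g1", "c", "+", [(1, donor_exon1_end), (1351, 1450)], cds=(11, 1400)
    )
    t2 = make_transcript("t2", "g2", "c", "+", [(1001, 1400)], cds=(1001, 1300))
    return t1, t2, genome


class TestAssessFrame:
    def test_phase_zero_into_cds_start_is_maintained(self):
        t1, t2, genome = _frame_fixture(310)
        c = build_chimera(t1, 1, t2, 1, genome)
        status = assess_frame(c)
        assert status.assessed
        assert status.donor_cds_bases_included == 300
        assert status.chimera_phase_at_acceptor_cds == 0
        assert status.acceptor_native_phase == 0
        assert status.maintained is True
        assert status.premature_stop is False
        # the first in-frame stop is the acceptor's own native stop
        assert status.first_stop_offset == 310 + 297

    def test_one_extra_base_breaks_frame(self):
        t1, t2, genome = _frame_fixture(311)
        c = build_chimera(t1, 1, t2, 1, genome)
        status = assess_frame(c)
        assert status.donor_cds_bases_included == 301
        assert status.chimera_phase_at_acceptor_cds == 1
        assert status.maintained is False

    def test_donor_without_start_codon_is_unassessed(self):
        seq = {"c": "A" * 2000}
        t1 = make_transcript(
            "t1", "g1", "c", "+", [(1, 100), (201, 300)], cds=(250, 290)
        )
        t2 = make_transcript("t2", "g2", "c", "+", [(1001, 1200)], cds=(1001, 1060))
        status = assess_frame(build_chimera(t1, 1, t2, 1, seq))
        assert not status.assessed
        assert "start codon" in status.reason

    def test_noncoding_acceptor_is_unassessed(self):
        seq = {"c": "A" * 2000}
        t1 = make_transcript("t1", "g1", "c", "+", [(1, 300)], cds=(11, 250))
        t2 = make_transcript("t2", "g2", "c", "+", [(1001, 1200)])
        status = assess_frame(build_chimera(t1, 1, t2, 1, seq))
        assert not status.assessed

    def test_acceptor_past_cds_end_is_unassessed(self):
        t1, t2b, genome = _frame_fixture(310)
        t2 = make_transcript(
            "t2", "g2", "c", "+", [(1001, 1300), (1351, 1400)], cds=(1001, 1060)
        )
        status = assess_frame(build_chimera(t1, 1, t2, 2, genome))
        assert not status.assessed


class TestJunctionSequence:
    def test_window_and_clipping(self, arithmetic_pair):
        t1, t2 = arithmetic_pair
        rng = np.random.default_rng(1)
        genome = {"c": "".join(rng.choice(list("ACGT"), 2000))}
        c = build_chimera(t1, 2, t2, 2, genome)
        window, pos = junction_sequence(c, 5)
        assert len(window) == 10 and pos == 5
        assert window == c.sequence[175:185]
        window, pos = junction_sequence(c, 500)
        assert pos == c.junction_offset
        assert window == c.sequence

    def test_random_windows_match_slice_oracle(self, coding_annotation):
        _, sim = coding_annotation
        genes = list(sim.gene_set)
        rng = np.random.default_rng(2)
        for _ in range(20):
            g1, g2 = rng.choice(len(genes), size=2, replace=False)
            t1, t2 = genes[g1].transcripts[0], genes[g2].transcripts[0]
            c = build_chimera(t1, 1, t2, 1, sim.genome)
            flank = int(rng.integers(1, 200))
            window, pos = junction_sequence(c, flank)
            j = c.junction_offset
            lo = max(0, j - flank)
            assert window == c.sequence[lo : min(len(c.sequence), j + flank)]
            assert pos == j - lo
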