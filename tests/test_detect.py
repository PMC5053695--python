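"""Junction-evidence filtering, classification and collation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from readthrough.detect import (
    FilterThresholds,
    JunctionEvidence,
    ReadThroughEvent,
    RejectionCode,
    RejectionReason,
    classify_readthrough,
    collate_events,
    detect_events,
    evidence_from_alignments,
    filter_evidence,
    read_junction_evidence,
    write_junction_evidence,
)
from readthrough.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_junction_evidence,
)


def ev(support=20, quality=30.0, spanning=3, sample="P01", **kw):
    defaults = dict(
        sample_id=sample,
        donor_transcript="AT1",
        donor_exon=1,
        donor_breakpoint=1400,
        acceptor_transcript="BT1",
        acceptor_exon=1,
        acceptor_breakpoint=6899,
        supporting_reads=support,
        mean_read_quality=quality,
        spanning_reads=spanning,
    )
    defaults.update(kw)
    return JunctionEvidence(**defaults)


class TestEvidenceIO:
    def test_round_trip(self, tmp_path, sim_annotation):
        cfg, sim = sim_annotation
        evidence, _ = simulate_junction_evidence(sim.gene_set, cfg)
        path = tmp_path / "ev.tsv"
        write_junction_evidence(evidence, str(path))
        assert read_junction_evidence(str(path)) == evidence

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tdonor_transcript\nP01\tT1\n")
        with pytest.raises(ValueError, match="missing evidence columns"):
            read_junction_evidence(str(path))

    def test_spanning_exceeding_support_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_junction_evidence([ev(), ev(sample="P02")], str(path))
        rows = path.read_text().splitlines()
        rows[2] = rows[2].replace("\t20\t30.0\t3", "\t2\t30.0\t3")
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="row 3"):
            read_junction_evidence(str(path))

    def test_invariant_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ev(support=-1)
        with pytest.raises(ValueError):
            ev(support=2, spanning=5)


class TestFilterEvidence:
    @pytest.mark.parametrize(
        "support,quality,spanning,kept,code",
        [
            (10, 25.0, 1, True, None),  # boundary: thresholds are inclusive
            (9, 40.0, 5, False, RejectionCode.LOW_SUPPORT),
            (50, 24.99, 5, False, RejectionCode.LOW_QUALITY),
            (50, 30.0, 0, False, RejectionCode.NO_SPANNING),
            # first failed criterion wins: support checked before quality
            (3, 10.0, 0, False, RejectionCode.LOW_SUPPORT),
        ],
    )
    def test_threshold_boundaries(self, support, quality, spanning, kept, code):
        records = [ev(support=support, quality=quality, spanning=spanning)]
        got_kept, got_rej = filter_evidence(records, FilterThresholds())
        assert bool(got_kept) is kept
        if code is not None:
            assert got_rej[0][1].code is code

    def test_partitions_input(self):
        rng = np.random.default_rng(0)
        records = [
            ev(
                support=int(rng.integers(0, 30)),
                quality=float(rng.uniform(0, 45)),
                spanning=0,
                sample=f"P{i}",
            )
            for i in range(200)
        ]
        kept, rejected = filter_evidence(records)
        assert len(kept) + len(rejected) == len(records)
        assert {id(r) for r in kept} | {id(r) for r, _ in rejected} == {
            id(r) for r in records
        }

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(1000):
            support = int(rng.integers(0, 25))
            records.append(
                ev(
                    support=support,
                    quality=float(rng.uniform(10, 45)),
                    spanning=int(rng.integers(0, support + 1)),
                    sample=f"P{i}",
                )
            )
        t = FilterThresholds(10, 25.0, 1)
        kept, _ = filter_evidence(records, t)
        oracle = [
            r
            for r in records
            if r.supporting_reads >= 10
            and r.mean_read_quality >= 25.0
            and r.spanning_reads >= 1
        ]
        assert kept == oracle

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        records=st.lists(
            st.tuples(
                st.integers(0, 40),
                st.floats(0, 45, allow_nan=False),
                st.integers(0, 40),
            ),
            max_size=40,
        ),
        base=st.tuples(st.integers(0, 20), st.floats(0, 30), st.integers(0, 5)),
        bump=st.tuples(st.integers(0, 10), st.floats(0, 10), st.integers(0, 5)),
    )
    def test_raising_thresholds_never_enlarges_kept_set(self, records, base, bump):
        evidence = [
            ev(support=s, quality=q, spanning=min(sp, s), sample=str(i))
            for i, (s, q, sp) in enumerate(records)
        ]
        lo = FilterThresholds(base[0], base[1], base[2])
        hi = FilterThresholds(
            base[0] + bump[0], base[1] + bump[1], base[2] + bump[2]
        )
        kept_lo, _ = filter_evidence(evidence, lo)
        kept_hi, _ = filter_evidence(evidence, hi)
        assert set(map(id, kept_hi)) <= set(map(id, kept_lo))


class TestClassify:
    def test_adjacent_same_strand_accepted(self, simple_gene_set):
        result = classify_readthrough(ev(), simple_gene_set)
        assert isinstance(result, ReadThroughEvent)
        assert result.name == "A-B"
        assert result.intergenic_bp == 4898

    def test_opposite_strand_rejected(self, simple_gene_set):
        result = classify_readthrough(
            ev(donor_transcript="AT1", acceptor_transcript="DT1"),
            simple_gene_set,
        )
        assert isinstance(result, RejectionReason)
        assert result.code is RejectionCode.OPPOSITE_STRAND

    def test_wrong_order_rejected(self, simple_gene_set):
        result = classify_readthrough(
            ev(donor_transcript="BT1", acceptor_transcript="AT1"),
            simple_gene_set,
        )
        assert result.code is RejectionCode.WRONG_ORDER

    def test_skipping_a_gene_rejected(self, simple_gene_set):
        result = classify_readthrough(
            ev(donor_transcript="AT1", acceptor_transcript="CT1"),
            simple_gene_set,
        )
        assert result.code is RejectionCode.NOT_ADJACENT

    def test_different_chromosome_rejected(self, simple_gene_set):
        result = classify_readthrough(
            ev(donor_transcript="AT1", acceptor_transcript="FT1"),
            simple_gene_set,
        )
        assert result.code is RejectionCode.DIFFERENT_CHROMOSOME

    def test_unknown_transcript_is_lookup_error(self, simple_gene_set):
        with pytest.raises(KeyError, match="NOPE"):
            classify_readthrough(
                ev(donor_transcript="NOPE"), simple_gene_set
            )


class TestCollate:
    def test_same_event_in_two_samples_merges(self, simple_gene_set):
        events = [
            classify_readthrough(ev(sample=s), simple_gene_set)
            for s in ("P01", "P02")
        ]
        merged = collate_events(events)
        assert len(merged) == 1
        assert merged[0].samples == {"P01", "P02"}

    def test_different_acceptor_exons_stay_distinct(self, simple_gene_set):
        # two junctions on the same gene pair joining different acceptor
        # exons are two species involving one gene pair
        events = [
            classify_readthrough(ev(acceptor_exon=2), simple_gene_set),
            classify_readthrough(ev(acceptor_exon=3), simple_gene_set),
        ]
        merged = collate_events(events)
        assert len(merged) == 2
        assert len({e.name for e in merged}) == 1

    def test_counts_match_set_oracle(self, sim_annotation):
        cfg, sim = sim_annotation
        evidence, truth = simulate_junction_evidence(sim.gene_set, cfg)
        events, _ = detect_events(evidence, sim.gene_set)
        keys = {
            (e.donor_transcript, e.donor_exon, e.acceptor_transcript, e.acceptor_exon)
            for e in events
        }
        assert len(events) == len(keys)
        true_truth = truth[truth.truth_class == "true"]
        assert len(keys) == len(
            set(
                true_truth[
                    [
                        "donor_transcript",
                        "donor_exon",
                        "acceptor_transcript",
                        "acceptor_exon",
                    ]
                ].itertuples(index=False, name=None)
            )
        )


class TestAlignmentExtractor:
    def test_split_reads_become_evidence(self, tmp_path, simple_gene_set):
        import pysam

        header = {
            "HD": {"VN": "1.6"},
            "SQ": [{"LN": 20000, "SN": "chr1"}, {"LN": 5000, "SN": "chr2"}],
        }
        path = tmp_path / "split.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for i in range(3):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"read{i}"
                a.query_sequence = "A" * 40
                a.query_qualities = pysam.qualitystring_to_array("I" * 40)
                a.reference_id = 0
                a.reference_start = 1380  # inside exon 2... exon1 of gene A
                a.cigarstring = "40M"
                a.flag = 0
                fh.write(a)
                b = pysam.AlignedSegment(fh.header)
                b.query_name = f"read{i}"
                b.query_sequence = "A" * 40
                b.reference_id = 0
                b.reference_start = 6900  # gene B exon 1
                b.cigarstring = "40M"
                b.flag = 2048  # supplementary
                fh.write(b)
        out = evidence_from_alignments(str(path), simple_gene_set, "P01")
        assert len(out) == 1
        assert out[0].supporting_reads == 3
        assert out[0].donor_transcript == "AT1"
        assert out[0].acceptor_transcript == "BT1"
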