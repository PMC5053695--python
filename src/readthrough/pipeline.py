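"""End-to-end orchestration of the read-through analysis stages.

``run_pipeline`` composes the stages in order — annotation loading, junction
filtering/classification, frame assessment, qPCR relative quantification,
paired statistics, cohort summary — writing plain-text TSV intermediates
with stable column order plus a JSON manifest (configuration, package
version, SHA-256 checksums of inputs and outputs).  Re-running with
identical inputs reproduces identical outputs; stages whose inputs are not
configured are skipped with a warning rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import read_annotation
from .detect import (
    FilterThresholds,
    detect_events,
    events_to_frame,
    read_junction_evidence,
)
from .frame import as_sequence_source, assess_frame, build_chimera, junction_labels
from .qpcr import QpcrConfig, paired_table, read_ct_table, sample_expression
from .stats import analyze_paired_rq
from .summarize import cohort_summary

logger = logging.getLogger("readthrough")

__all__ = ["PipelineConfig", "run_pipeline", "frame_report"]


@dataclass
class PipelineConfig:
    """Paths and settings for one pipeline run (unset paths skip stages)."""

    annotation: str | None = None
    genome: str | None = None
    evidence: str | None = None
    ct_table: str | None = None
    clinical: str | None = None
    out_dir: str = "readthrough_out"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    validated_only: bool = False
    bh_correction: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = FilterThresholds(**raw.pop("thresholds", {}))
        qpcr = QpcrConfig(**raw.pop("qpcr", {}))
        return cls(thresholds=thresholds, qpcr=qpcr, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def frame_report(events, gs, genome) -> pd.DataFrame:
    """Frame assessment for a list of events against transcript models."""
    src = as_sequence_source(genome)
    rows = []
    for ev in events:
        t1 = gs.transcript(ev.donor_transcript)
        t2 = gs.transcript(ev.acceptor_transcript)
        chimera = build_chimera(t1, ev.donor_exon, t2, ev.acceptor_exon, src)
        status = assess_frame(chimera)
        ev.frame_maintained = status.label
        labels = junction_labels(ev.donor_exon, t1, ev.acceptor_exon)
        rows.append(
            {
                "gene_pair": ev.name,
                "donor_transcript": ev.donor_transcript,
                "donor_exon": ev.donor_exon,
                "acceptor_transcript": ev.acceptor_transcript,
                "acceptor_exon": ev.acceptor_exon,
                "maintained_frame": status.label,
                "premature_stop": status.premature_stop,
                "donor_cds_bases": status.donor_cds_bases_included,
                "chimera_length": len(chimera),
                "junction_offset": chimera.junction_offset,
                **labels,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all configured stages; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    gs = None
    if cfg.annotation:
        logger.info("stage annotation: %s", cfg.annotation)
        gs = read_annotation(cfg.annotation)

    events = None
    if cfg.evidence:
        if gs is None:
            raise ValueError("detect stage requires an annotation")
        logger.info("stage detect: %s", cfg.evidence)
        try:
            evidence = read_junction_evidence(cfg.evidence)
            events, rejected = detect_events(evidence, gs, cfg.thresholds)
        except Exception as exc:
            raise RuntimeError(f"stage detect failed: {exc}") from exc
        ev_df = events_to_frame(events)
        ev_df.to_csv(out / "events.tsv", sep="\t", index=False)
        outputs["events"] = out / "events.tsv"
        rej = pd.DataFrame(
            [
                {
                    "sample_id": e.sample_id,
                    "donor_transcript": e.donor_transcript,
                    "acceptor_transcript": e.acceptor_transcript,
                    "junction_id": e.junction_id,
                    "code": r.code.value,
                    "detail": r.detail,
                }
                for e, r in rejected
            ]
        )
        rej.to_csv(out / "rejections.tsv", sep="\t", index=False)
        outputs["rejections"] = out / "rejections.tsv"

    if events is not None and cfg.genome:
        logger.info("stage frame")
        try:
            fr = frame_report(events, gs, cfg.genome)
        except Exception as exc:
            raise RuntimeError(f"stage frame failed: {exc}") from exc
        fr.to_csv(out / "frame_report.tsv", sep="\t", index=False)
        outputs["frame_report"] = out / "frame_report.tsv"
        # refresh the event table with frame labels
        events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)

    if events is not None:
        summary = cohort_summary(
            events_to_frame(events), validated_only=cfg.validated_only
        )
        pd.DataFrame(
            [{"field": k, "value": v} for k, v in summary.as_dict().items()]
        ).to_csv(out / "summary.tsv", sep="\t", index=False)
        outputs["summary"] = out / "summary.tsv"

    paired = None
    if cfg.ct_table:
        logger.info("stage qpcr: %s", cfg.ct_table)
        try:
            ct = read_ct_table(cfg.ct_table)
            expr = sample_expression(ct, cfg.qpcr)
            paired = paired_table(expr, cfg.qpcr)
        except Exception as exc:
            raise RuntimeError(f"stage qpcr failed: {exc}") from exc
        paired.to_csv(out / "rq.tsv", sep="\t", index=False)
        outputs["rq"] = out / "rq.tsv"

    if paired is not None:
        clinical = None
        if cfg.clinical:
            if Path(cfg.clinical).exists():
                clinical = pd.read_csv(
                    cfg.clinical, sep="\t", dtype={"patient_id": str}
                )
            else:
                warnings.warn(
                    f"clinical table {cfg.clinical} not found; "
                    "model stage skipped"
                )
        logger.info("stage stats")
        stats_df = analyze_paired_rq(paired, clinical, bh=cfg.bh_correction)
        stats_df.to_csv(out / "stats.tsv", sep="\t", index=False)
        outputs["stats"] = out / "stats.tsv"

    manifest = {
        "version": __version__,
        "config": {
            **{
                k: v
                for k, v in asdict(cfg).items()
                if k not in ("thresholds", "qpcr")
            },
            "thresholds": asdict(cfg.thresholds),
            "qpcr": asdict(cfg.qpcr),
        },
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("annotation", cfg.annotation),
                ("genome", cfg.genome),
                ("evidence", cfg.evidence),
                ("ct_table", cfg.ct_table),
                ("clinical", cfg.clinical),
            )
            if p and Path(p).exists()
        },
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
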