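"""Relative quantification (2^-ddCt) from replicate Ct tables.

Raw input is one row per well: ``patient_id, sample_id, tissue, gene, well,
ct``.  Replicate wells of a (sample, gene) are summarized to a mean Ct and a
sample standard deviation; a measurement is *reliable* only when it has at
least two replicates with Ct SD at or below the threshold (default 0.5
cycles).  Target Cts are normalized against a reference gene (default HPRT1)
to give dCt = Ct_target - Ct_reference, then expressed relative to a pooled
calibrator sample: RQ = 2^-(dCt_sample - dCt_calibrator), assuming perfect
doubling per cycle.  Paired normal/tumor tables keep a patient only when
both tissues are reliable (by default the reference-gene replicates must
pass the same SD rule); the normal-to-tumor ratio RQ_N / RQ_T is the
per-patient effect size.

Undetermined or failed wells must be absent rows, never sentinel Ct values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrConfig",
    "CtSummary",
    "summarize_ct",
    "relative_quantification",
    "read_ct_table",
    "sample_expression",
    "paired_table",
]

CT_COLUMNS = ["patient_id", "sample_id", "tissue", "gene", "well", "ct"]


@dataclass(frozen=True)
class QpcrConfig:
    """Normalization and reliability settings for one qPCR experiment."""

    reference_gene: str = "HPRT1"
    calibrator_id: str = "CALIBRATOR"
    max_ct_sd: float = 0.5
    require_reference_reliable: bool = True

    def __post_init__(self) -> None:
        if self.max_ct_sd <= 0:
            raise ValueError("max_ct_sd must be positive")


@dataclass(frozen=True)
class CtSummary:
    mean_ct: float
    ct_sd: float | None
    reliable: bool


def summarize_ct(replicates: Sequence[float], cfg: QpcrConfig | None = None) -> CtSummary:
    """Mean, sample SD (n-1) and reliability of one replicate set.

    A single replicate has no defined SD and therefore cannot pass the SD
    test: it is unreliable by policy.
    """
    cfg = cfg or QpcrConfig()
    values = [float(v) for v in replicates]
    if not values:
        raise ValueError("empty replicate list")
    if any(v <= 0 or not math.isfinite(v) for v in values):
        raise ValueError(f"Ct values must be positive finite numbers: {values}")
    mean = float(np.mean(values))
    if len(values) < 2:
        return CtSummary(mean, None, False)
    sd = float(np.std(values, ddof=1))
    return CtSummary(mean, sd, sd <= cfg.max_ct_sd)


def relative_quantification(
    delta_ct_sample: float, delta_ct_calibrator: float
) -> float:
    """RQ = 2^-(dCt_sample - dCt_calibrator); the calibrator itself gives 1."""
    return float(2.0 ** -(delta_ct_sample - delta_ct_calibrator))


def read_ct_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={c: str for c in CT_COLUMNS if c != "ct"}
    )
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing Ct table columns {missing}")
    return df


def sample_expression(ct: pd.DataFrame, cfg: QpcrConfig | None = None) -> pd.DataFrame:
    """Per-(sample, gene) expression: mean Ct, SD, reliability, dCt, RQ.

    The reference gene itself appears in the output (with dCt = 0 against
    itself left as NaN); target rows carry ``reference_reliable`` so callers
    can apply the stricter both-genes reliability rule.
    """
    cfg = cfg or QpcrConfig()
    rows = []
    for (sample, gene), grp in ct.groupby(["sample_id", "gene"], sort=True):
        summ = summarize_ct(grp["ct"].tolist(), cfg)
        rows.append(
            {
                "patient_id": grp["patient_id"].iloc[0],
                "sample_id": sample,
                "tissue": grp["tissue"].iloc[0],
                "gene": gene,
                "n_replicates": len(grp),
                "mean_ct": summ.mean_ct,
                "ct_sd": summ.ct_sd,
                "reliable": summ.reliable,
            }
        )
    expr = pd.DataFrame(rows)

    ref = expr[expr["gene"] == cfg.reference_gene].set_index("sample_id")
    if ref.empty:
        raise ValueError(f"reference gene {cfg.reference_gene!r} absent from table")

    def ref_mean(sample: str) -> float:
        if sample not in ref.index:
            raise ValueError(f"sample {sample!r} lacks reference-gene wells")
        return float(ref.loc[sample, "mean_ct"])

    targets = expr[expr["gene"] != cfg.reference_gene].copy()
    targets["delta_ct"] = [
        row.mean_ct - ref_mean(row.sample_id)
        for row in targets.itertuples(index=False)
    ]
    targets["reference_reliable"] = [
        bool(ref.loc[s, "reliable"]) for s in targets["sample_id"]
    ]

    cal = targets[targets["sample_id"] == cfg.calibrator_id].set_index("gene")
    if cal.empty:
        raise ValueError(f"calibrator sample {cfg.calibrator_id!r} absent from table")
    rq = []
    for row in targets.itertuples(index=False):
        if row.gene in cal.index:
            rq.append(
                relative_quantification(
                    row.delta_ct, float(cal.loc[row.gene, "delta_ct"])
                )
            )
        else:
            rq.append(float("nan"))
    targets["rq"] = rq
    return targets.reset_index(drop=True)


def paired_table(
    expression: pd.DataFrame, cfg: QpcrConfig | None = None
) -> pd.DataFrame:
    """Per-(patient, gene) paired RQ values for doubly-reliable pairs.

    A pair is kept only when both the normal and the tumor measurement are
    reliable (and, when ``require_reference_reliable``, the reference gene
    passed the same SD rule in both tissues).  Output columns:
    ``patient_id, gene, rq_normal, rq_tumor, ratio_n_over_t``.
    """
    cfg = cfg or QpcrConfig()
    df = expression[expression["sample_id"] != cfg.calibrator_id]
    rows = []
    for (patient, gene), grp in df.groupby(["patient_id", "gene"], sort=True):
        by_tissue = {}
        for row in grp.itertuples(index=False):
            if row.tissue in by_tissue:
                raise ValueError(
                    f"patient {patient!r} has multiple {row.tissue!r} samples "
                    f"for gene {gene!r}"
                )
            by_tissue[row.tissue] = row
        if "normal" not in by_tissue or "tumor" not in by_tissue:
            continue
        ok = all(
            r.reliable and (not cfg.require_reference_reliable or r.reference_reliable)
            for r in by_tissue.values()
        )
        if not ok:
            continue
        rq_n = float(by_tissue["normal"].rq)
        rq_t = float(by_tissue["tumor"].rq)
        rows.append(
            {
                "patient_id": patient,
                "gene": gene,
                "rq_normal": rq_n,
                "rq_tumor": rq_t,
                "ratio_n_over_t": rq_n / rq_t,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "gene", "rq_normal", "rq_tumor", "ratio_n_over_t"]
    )
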