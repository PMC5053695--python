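"""Cohort-level aggregates over read-through event tables.

Ships a reference cohort as packaged TSVs: the read-through species detected
by RNA-Seq in non-involved lung tissue of 64 lung adenocarcinoma patients
(52 events over 37 adjacent gene pairs) and the additional isoforms
identified by Sanger sequencing of junction-spanning PCR amplicons
(15 events).  All printed aggregates — validated event and gene-pair counts,
frame-maintenance count, the median intergenic distance over validated
non-overlapping pairs, gap-size tallies — are recomputed from these row-level
tables; only the expected-summary file used by the regression check stores
the numbers directly.

Scope conventions:

* A *species* is a distinct (gene pair, donor exon, acceptor exon, variant)
  among detection-scope rows (``source == "rnaseq"`` when a source column is
  present).  The ``variant`` tag separates incomplete-exon or
  intragenic-inclusion isoforms sharing exon indices with a plain event.
* *Validated* rows have status ``validated_as_predicted`` (junction
  confirmed as predicted) or ``validated_different_isoform`` (junction newly
  identified by Sanger sequencing).
* The median intergenic distance is over validated gene pairs with a
  defined (non-overlapping) distance; an even count takes the midpoint,
  rounded half-up to whole base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from importlib import resources

import pandas as pd

__all__ = [
    "VALIDATED_STATUSES",
    "CohortSummary",
    "load_rnaseq_events",
    "load_sanger_events",
    "load_reference_events",
    "load_expected_summary",
    "read_events",
    "cohort_summary",
    "compare_to_reference",
]

VALIDATED_STATUSES = frozenset(
    {"validated_as_predicted", "validated_different_isoform"}
)

_KEY_COLS = ["gene_pair", "donor_exon", "acceptor_exon", "variant"]


@dataclass
class CohortSummary:
    """Aggregate counts and medians describing one event table."""

    n_species: int
    n_gene_pairs: int
    n_validated_events: int
    n_validated_as_predicted: int
    n_sanger_isoforms: int
    n_validated_gene_pairs: int
    n_frame_maintained: int
    median_intergenic_bp: int | None
    n_validated_pairs_lt_1kb: int
    n_validated_pairs_gt_10kb: int
    fraction_acceptor_exon2: float | None
    fraction_donor_penultimate: float | None
    n_samples_with_event: int | None
    max_events_per_sample: int | None

    def as_dict(self) -> dict:
        return asdict(self)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("readthrough.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_rnaseq_events() -> pd.DataFrame:
    """Reference cohort: events detected by RNA-Seq (52 rows)."""
    return _normalize(_load_packaged("lung_cohort_rnaseq_events.tsv"))


def load_sanger_events() -> pd.DataFrame:
    """Reference cohort: isoforms identified by Sanger sequencing (15 rows)."""
    return _normalize(_load_packaged("lung_cohort_sanger_events.tsv"))


def load_reference_events() -> pd.DataFrame:
    """Both reference tables concatenated (67 rows)."""
    return pd.concat(
        [load_rnaseq_events(), load_sanger_events()], ignore_index=True
    )


def load_expected_summary() -> dict[str, int]:
    df = _load_packaged("expected_summary.tsv")
    return {row["field"]: int(row["value"]) for _, row in df.iterrows()}


def read_events(path: str) -> pd.DataFrame:
    """Read an event TSV produced by the detection stage or hand-curated."""
    return _normalize(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    required = [
        "gene_pair",
        "donor_exon",
        "acceptor_exon",
        "intergenic_bp",
        "validation_status",
        "frame_maintained",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if "variant" not in df.columns:
        df["variant"] = ""
    df["variant"] = df["variant"].fillna("")
    if "source" not in df.columns:
        df["source"] = "rnaseq"
    for col in ("donor_exon", "acceptor_exon"):
        df[col] = df[col].astype(int)
    bad = ~df["intergenic_bp"].astype(str).str.fullmatch(r"\d+|NA|OVERLAPPING|")
    if bad.any():
        raise ValueError(
            "undefined intergenic_bp values other than NA/OVERLAPPING in rows "
            f"{list(df.index[bad])}"
        )
    return df


def _gap(value) -> int | None:
    s = str(value)
    if s in ("", "NA", "OVERLAPPING", "nan"):
        return None
    return int(s)


def cohort_summary(events: pd.DataFrame, validated_only: bool = False) -> CohortSummary:
    """Compute the cohort aggregates over an event table.

    ``validated_only`` restricts every count to rows whose junction was
    confirmed by sequencing; distance, frame and fraction statistics are
    always over the validated subset (the scope in which they are defined).
    """
    df = _normalize(events) if "variant" not in events.columns else events
    if validated_only:
        df = df[df["validation_status"].isin(VALIDATED_STATUSES)]

    detection = df[df["source"] == "rnaseq"] if "source" in df.columns else df
    validated = df[df["validation_status"].isin(VALIDATED_STATUSES)]

    def n_distinct(frame: pd.DataFrame) -> int:
        return 0 if frame.empty else len(frame[_KEY_COLS].drop_duplicates())

    n_species = n_distinct(detection)
    n_gene_pairs = detection["gene_pair"].nunique()
    n_validated = n_distinct(validated)
    n_as_predicted = n_distinct(
        validated[validated["validation_status"] == "validated_as_predicted"]
    )
    n_sanger = n_distinct(
        validated[validated["validation_status"] == "validated_different_isoform"]
    )
    n_validated_pairs = validated["gene_pair"].nunique()
    n_frame = n_distinct(validated[validated["frame_maintained"] == "yes"])

    # one defined distance per validated gene pair
    gaps: dict[str, int | None] = {}
    for row in validated.itertuples(index=False):
        gaps.setdefault(row.gene_pair, _gap(row.intergenic_bp))
    defined = sorted(v for v in gaps.values() if v is not None)
    if defined:
        mid = (len(defined) - 1) // 2
        if len(defined) % 2:
            median = float(defined[mid])
        else:
            median = (defined[mid] + defined[mid + 1]) / 2.0
        median_bp = int(math.floor(median + 0.5))  # round half up
    else:
        median_bp = None
    lt_1kb = sum(1 for v in defined if v < 1_000)
    gt_10kb = sum(1 for v in defined if v > 10_000)

    if n_validated:
        uniq = validated.drop_duplicates(_KEY_COLS)
        frac_exon2 = float((uniq["acceptor_exon"] == 2).mean())
    else:
        frac_exon2 = None
    frac_penult = None
    if "donor_is_penultimate" in validated.columns and n_validated:
        flags = validated.drop_duplicates(_KEY_COLS)["donor_is_penultimate"]
        flags = flags[flags.astype(str).isin(["True", "False", "yes", "no"])]
        if len(flags):
            frac_penult = float(flags.astype(str).isin(["True", "yes"]).mean())

    n_samples = max_per_sample = None
    if "samples" in df.columns:
        lists = [
            str(s).split(";")
            for s in df["samples"]
            if str(s) not in ("", "nan")
        ]
        if lists:
            counts: dict[str, int] = {}
            for sample_list in lists:
                for s in set(sample_list):
                    counts[s] = counts.get(s, 0) + 1
            n_samples = len(counts)
            max_per_sample = max(counts.values())

    return CohortSummary(
        n_species=n_species,
        n_gene_pairs=n_gene_pairs,
        n_validated_events=n_validated,
        n_validated_as_predicted=n_as_predicted,
        n_sanger_isoforms=n_sanger,
        n_validated_gene_pairs=n_validated_pairs,
        n_frame_maintained=n_frame,
        median_intergenic_bp=median_bp,
        n_validated_pairs_lt_1kb=lt_1kb,
        n_validated_pairs_gt_10kb=gt_10kb,
        fraction_acceptor_exon2=frac_exon2,
        fraction_donor_penultimate=frac_penult,
        n_samples_with_event=n_samples,
        max_events_per_sample=max_per_sample,
    )


def compare_to_reference(
    summary: CohortSummary, expected: dict[str, int] | None = None
) -> list[tuple[str, object, object]]:
    """Field-by-field check against the packaged expected summary.

    Returns the list of ``(field, computed, expected)`` mismatches; an empty
    list means every expected field was reproduced.
    """
    expected = expected if expected is not None else load_expected_summary()
    got = summary.as_dict()
    mismatches = []
    for field, value in expected.items():
        if field not in got:
            mismatches.append((field, None, value))
        elif got[field] != value:
            mismatches.append((field, got[field], value))
    return mismatches
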