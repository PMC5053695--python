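"""Paired nonparametric testing and rank-transformed linear modeling.

Two inferential procedures are used to compare read-through expression
between matched normal and tumor tissue:

1. Wilcoxon's signed-rank test on the per-patient differences
   d_i = value_normal - value_tumor.  Zero differences are dropped
   (Wilcoxon's original reduction), |d| are ranked with ties averaged, and
   W is the sum of positive-signed ranks.  For n_effective <= 20 with no
   ties among |d| the two-sided p-value is exact, from the signed-rank
   counting distribution over all 2^n equally likely sign assignments;
   otherwise a normal approximation with tie correction and a 0.5
   continuity correction is used.

2. An ordinary least-squares model on the rank-transformed response with
   binary-coded covariates (tissue 0=normal/1=tumor, sex 0=female/1=male,
   smoking 0=never/1=ever, stage 0=I/1=>I).  Each tissue sample is one row;
   rank-transforming the response robustifies the fit against the heavy
   right tail of RQ values.

No multiplicity correction is applied by default; Benjamini-Hochberg
adjusted p-values can be added as a labeled extra column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "rank_transform",
    "fit_rank_linear_model",
    "median_ratio",
    "analyze_paired_rq",
]

_EXACT_N_MAX = 20
_COVARIATES = ["tissue", "sex", "smoking", "stage"]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W, sum of positive-signed ranks
    pvalue: float
    n_effective: int
    method: str  # exact | approx | degenerate


def _signed_rank_counts(n: int) -> np.ndarray:
    """Counts of sign assignments per W value for ranks 1..n (2^n total)."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(
    normal: Sequence[float], tumor: Sequence[float]
) -> WilcoxonResult:
    """Two-sided paired signed-rank test of normal vs tumor values."""
    x = np.asarray(normal, dtype=float)
    y = np.asarray(tumor, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("need two equal-length one-dimensional samples")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; no evidence either way")
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= _EXACT_N_MAX and not has_ties:
        counts = _signed_rank_counts(n)
        total = counts.sum()
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w, p, n, "exact")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return WilcoxonResult(w, 1.0, n, "degenerate")
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w, float(p), n, "approx")


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties averaged."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    return sps.rankdata(values)


def fit_rank_linear_model(
    data: pd.DataFrame,
    response: str = "rq",
    covariates: Sequence[str] = tuple(_COVARIATES),
) -> pd.DataFrame:
    """OLS on the rank-transformed response with binary covariates.

    Returns one row per retained covariate: coefficient estimate, standard
    error (unbiased residual variance), t statistic and two-sided p-value
    with n - p degrees of freedom.  Covariates constant in the data are
    dropped with a warning; a design left rank-deficient after the drops is
    an error naming the collinear columns.
    """
    import statsmodels.api as sm

    df = data.dropna(subset=[response, *covariates])
    y = rank_transform(df[response].to_numpy())
    kept = []
    for cov in covariates:
        if df[cov].nunique() < 2:
            warnings.warn(f"covariate {cov!r} is constant; dropped from model")
        else:
            kept.append(cov)
    if not kept:
        raise ValueError("no non-constant covariates to fit")
    design = sm.add_constant(df[kept].astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"design matrix is rank-deficient in columns {kept}")
    fit = sm.OLS(y, design).fit()
    out = pd.DataFrame(
        {
            "covariate": kept,
            "coef": [fit.params[c] for c in kept],
            "se": [fit.bse[c] for c in kept],
            "t": [fit.tvalues[c] for c in kept],
            "p": [fit.pvalues[c] for c in kept],
        }
    )
    return out


def median_ratio(ratios: Sequence[float]) -> float:
    """Sample median of paired normal/tumor RQ ratios (midpoint for even n)."""
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("no ratios to take the median of")
    return float(np.median(arr))


def analyze_paired_rq(
    paired: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-transcript summary: n, W, Wilcoxon p, median N/T ratio, model terms.

    ``paired`` is the output of :func:`readthrough.qpcr.paired_table`;
    ``clinical`` (optional) has columns ``patient_id, sex, smoking, stage``
    binary-coded as in the module docstring and enables the rank linear
    model.  With ``bh=True`` a Benjamini-Hochberg adjusted Wilcoxon p-value
    column is appended.
    """
    rows = []
    for gene, grp in paired.groupby("gene", sort=True):
        res = wilcoxon_signed_rank(
            grp["rq_normal"].to_numpy(), grp["rq_tumor"].to_numpy()
        )
        row = {
            "gene": gene,
            "n": len(grp),
            "W": res.statistic,
            "p_wilcoxon": res.pvalue,
            "median_ratio_n_over_t": median_ratio(grp["ratio_n_over_t"]),
        }
        if clinical is not None:
            long = pd.concat(
                [
                    grp[["patient_id"]].assign(rq=grp["rq_normal"], tissue=0),
                    grp[["patient_id"]].assign(rq=grp["rq_tumor"], tissue=1),
                ],
                ignore_index=True,
            ).merge(clinical, on="patient_id", how="inner")
            covs = ["tissue"] + [c for c in ("sex", "smoking", "stage") if c in long]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_rank_linear_model(long, "rq", covs)
            for r in model.itertuples(index=False):
                row[f"coef_{r.covariate}"] = r.coef
                row[f"se_{r.covariate}"] = r.se
                row[f"p_{r.covariate}"] = r.p
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["p_wilcoxon_bh"] = multipletests(
            out["p_wilcoxon"].to_numpy(), method="fdr_bh"
        )[1]
    return out
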