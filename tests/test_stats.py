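"""Wilcoxon signed-rank, rank transform and rank linear model."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from readthrough.stats import (
    analyze_paired_rq,
    fit_rank_linear_model,
    median_ratio,
    rank_transform,
    wilcoxon_signed_rank,
)

from conftest import wilcoxon_enumeration_oracle


class TestWilcoxon:
    def test_all_positive_distinct_differences(self):
        # 6 pairs, all d > 0, distinct |d|: W = 21, exact p = 2/64
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
        assert res.statistic == 21.0
        assert res.pvalue == pytest.approx(2 / 64)
        assert res.n_effective == 6
        assert res.method == "exact"

    def test_identical_vectors_give_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == 1.0 and res.n_effective == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(wilcoxon_enumeration_oracle(x - y))

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(6, 20))
            x, y = rng.normal(size=n), rng.normal(size=n)
            mine = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, method="exact")
            assert mine.pvalue == pytest.approx(ref.pvalue)

    def test_approximation_close_to_exact(self):
        # the tie/continuity-corrected normal approximation tracks the exact
        # p to ~0.02 at n = 12 overall, and much tighter in the decision-
        # relevant tail
        rng = np.random.default_rng(7)
        for _ in range(25):
            x, y = rng.normal(size=12), rng.normal(size=12)
            exact = wilcoxon_signed_rank(x, y).pvalue
            approx = sps.wilcoxon(x, y, method="approx", correction=True).pvalue
            assert abs(exact - approx) < 0.02
            if exact < 0.05:
                assert abs(exact - approx) < 0.005

    def test_rank_sum_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            ranks = sps.rankdata(np.abs(d))
            w_neg = ranks[d < 0].sum()
            assert res.statistic + w_neg == pytest.approx(
                res.n_effective * (res.n_effective + 1) / 2
            )

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(size=15)
        y = rng.lognormal(size=15)
        p1 = wilcoxon_signed_rank(x, y)
        # signed ranks depend only on the order of |d|... not preserved by
        # arbitrary monotone maps of the values, but scaling is monotone on d
        p2 = wilcoxon_signed_rank(10 * x, 10 * y)
        assert p1.pvalue == p2.pvalue and p1.statistic == p2.statistic


class TestRankTransform:
    def test_distinct_and_tied_values(self):
        assert rank_transform([3, 1, 2]).tolist() == [3.0, 1.0, 2.0]
        assert rank_transform([10, 10, 20]).tolist() == [1.5, 1.5, 3.0]

    def test_matches_sort_oracle_and_sum_identity(self):
        rng = np.random.default_rng(21)
        values = rng.integers(0, 10, size=50).astype(float)
        ranks = rank_transform(values)
        assert ranks.sum() == pytest.approx(50 * 51 / 2)
        assert np.array_equal(ranks, sps.rankdata(values))


class TestRankLinearModel:
    def test_two_group_coefficient_is_mean_rank_difference(self):
        # response equal to its own ranks, one binary covariate splitting
        # low/high halves: coefficient = difference of group mean ranks = 5
        df = pd.DataFrame(
            {"rq": np.arange(1.0, 11.0), "tissue": [0] * 5 + [1] * 5}
        )
        fit = fit_rank_linear_model(df, "rq", ["tissue"])
        assert fit.loc[0, "coef"] == pytest.approx(5.0)

    def test_orthogonal_covariate_has_null_p(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "rq": rng.normal(size=20),
                    "tissue": rng.permutation([0, 1] * 10),
                }
            )
            fit = fit_rank_linear_model(df, "rq", ["tissue"])
            ps.append(fit.loc[0, "p"])
        # null p-values roughly uniform: rejection rate near alpha
        assert 0.005 <= np.mean(np.asarray(ps) < 0.05) <= 0.12

    def test_zero_variance_covariate_dropped_with_warning(self):
        df = pd.DataFrame(
            {
                "rq": np.arange(10.0),
                "tissue": [0, 1] * 5,
                "stage": [0] * 10,
            }
        )
        with pytest.warns(UserWarning, match="stage"):
            fit = fit_rank_linear_model(df, "rq", ["tissue", "stage"])
        assert fit.covariate.tolist() == ["tissue"]

    def test_collinear_design_raises(self):
        df = pd.DataFrame(
            {
                "rq": np.arange(10.0),
                "tissue": [0, 1] * 5,
                "copy": [0, 1] * 5,
            }
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_rank_linear_model(df, "rq", ["tissue", "copy"])


class TestMedianRatio:
    def test_odd_even_and_oracle(self):
        assert median_ratio([1, 2, 3]) == 2.0
        assert median_ratio([1, 2, 3, 10]) == 2.5
        rng = np.random.default_rng(5)
        vals = rng.lognormal(size=31)
        assert median_ratio(vals) == sorted(vals)[15]


class TestAnalyzePairedRq:
    def test_per_gene_table_with_bh(self):
        rng = np.random.default_rng(8)
        rows = []
        for gene in ("RT1", "RT2"):
            for i in range(12):
                rn = float(rng.lognormal())
                rows.append(
                    {
                        "patient_id": f"P{i}",
                        "gene": gene,
                        "rq_normal": rn,
                        "rq_tumor": rn / 4.0,
                        "ratio_n_over_t": 4.0,
                    }
                )
        paired = pd.DataFrame(rows)
        clinical = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(12)],
                "sex": [0, 1] * 6,
                "smoking": [1] * 12,
                "stage": [0, 0, 1] * 4,
            }
        )
        out = analyze_paired_rq(paired, clinical, bh=True)
        assert set(out.gene) == {"RT1", "RT2"}
        assert (out.median_ratio_n_over_t == 4.0).all()
        assert (out.coef_tissue < 0).all()  # tumor rows rank lower
        assert "p_wilcoxon_bh" in out.columns
        assert "coef_smoking" not in out.columns  # constant, dropped
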