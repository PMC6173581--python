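"""NB differential-expression machinery: size factors, dispersion, BH,
thresholded Wald tests and the Model/Results API.

Independent oracles: closed-form size-factor cases, pydeseq2's
median-of-ratios implementation, a literal step-up BH implementation and
statsmodels' fdr_bh.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readthrough.diffexpr import (
    ALPHA_MIN,
    DEResults,
    NBDifferentialExpression,
    bh_adjust,
    classify_de,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)


def counts_frame(mat, prefix="s"):
    mat = np.asarray(mat)
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"{prefix}{j}" for j in range(mat.shape[1])],
    )


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        df = counts_frame([[10, 10], [200, 200], [5, 5]])
        assert np.allclose(size_factors(df), [1.0, 1.0])

    def test_exact_doubling_closed_form(self):
        """B = 2A -> factors (1/sqrt(2), sqrt(2)) after geometric-mean
        rescaling."""
        a = np.array([10, 100, 1000, 37])
        df = counts_frame(np.column_stack([a, 2 * a]))
        sf = size_factors(df)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_planted_depth_recovery(self, rng):
        mu = rng.lognormal(np.log(500), 0.5, size=400)
        depths = np.array([0.7, 1.0, 1.3, 1.1, 0.9, 1.05])
        mat = rng.poisson(mu[:, None] * depths[None, :])
        sf = size_factors(counts_frame(mat))
        expected = depths / np.exp(np.mean(np.log(depths)))
        assert np.allclose(sf, expected, rtol=0.05)

    def test_no_all_positive_feature_errors(self):
        df = counts_frame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(df)

    def test_matches_pydeseq2_median_of_ratios(self, rng):
        """Dual-route check against DESeq2's normalisation (pydeseq2)."""
        from pydeseq2.dds import DeseqDataSet

        mat = rng.poisson(rng.lognormal(4, 1, size=60)[:, None] *
                          np.array([0.8, 1.0, 1.2, 1.0, 0.9, 1.3]))
        df = counts_frame(mat)
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=df.columns)
        dds = DeseqDataSet(counts=df.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        theirs = dds.obs["size_factors"].to_numpy()
        theirs = theirs / np.exp(np.mean(np.log(theirs)))
        assert np.allclose(size_factors(df).to_numpy(), theirs, rtol=1e-9)


class TestEstimateDispersion:
    def _cond(self, n):
        return pd.Series(["A"] * n + ["B"] * n, index=[f"s{j}" for j in range(2 * n)])

    def test_constant_counts_floor(self):
        df = counts_frame(np.full((5, 6), 50))
        disp = estimate_dispersion(df, size_factors(df), self._cond(3), shrink=False)
        assert (disp == ALPHA_MIN).all()

    def test_poisson_limit_near_floor(self, rng):
        mat = rng.poisson(2000, size=(200, 20))
        df = counts_frame(mat)
        disp = estimate_dispersion(df, size_factors(df), self._cond(10), shrink=False)
        # (s^2-mu)/mu^2 for Poisson at mu=2000 is centred on 0 -> tiny alpha
        assert np.median(disp) < 5e-4

    def test_nb_dispersion_recovered_at_n50(self, rng):
        r = 1 / 0.05
        mu = 500.0
        mat = rng.negative_binomial(r, r / (r + mu), size=(300, 100))
        df = counts_frame(mat)
        disp = estimate_dispersion(df, size_factors(df), self._cond(50), shrink=False)
        assert 0.03 <= disp.mean() <= 0.07

    def test_median_floor_shrinkage(self, rng):
        mat = rng.poisson(rng.lognormal(5, 1, size=(100, 6)))
        df = counts_frame(mat)
        raw = estimate_dispersion(df, size_factors(df), self._cond(3), shrink=False)
        shrunk = estimate_dispersion(df, size_factors(df), self._cond(3), shrink=True)
        assert (shrunk >= raw).all()
        assert (shrunk >= np.median(raw)).all()


def bh_oracle(pvals):
    """Literal step-up: padj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for pos, i in enumerate(order):
        cands = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        out[i] = min(1.0, min(cands))
    return out


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_textbook_vector(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([np.nan]))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_step_up_oracle(self, pvals):
        p = np.array(pvals)
        assert np.allclose(bh_adjust(p), bh_oracle(p))
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 200)))
            _, theirs, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), theirs)

    def test_order_preserving(self, rng):
        p = rng.random(500)
        padj = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(padj[order]) >= -1e-12).all()


class TestNbWaldTest:
    def _fixture(self, rng, lfc=0.0, mu=500.0, alpha=0.01, n=3, n_affected=40):
        """400 features; the first ``n_affected`` carry the true fold change
        (an all-feature shift would rightly be normalised away)."""
        r = 1 / alpha
        wt = rng.negative_binomial(r, r / (r + mu), size=(400, n))
        mut = rng.negative_binomial(r, r / (r + mu), size=(400, n))
        mu2 = mu * 2**lfc
        mut[:n_affected] = rng.negative_binomial(r, r / (r + mu2), size=(n_affected, n))
        df = counts_frame(np.hstack([wt, mut]))
        cond = pd.Series(["wt"] * n + ["mut"] * n, index=df.columns)
        return df, cond

    def test_identical_conditions_ns(self):
        df = counts_frame(np.tile([100, 200, 300], (10, 2)))
        cond = pd.Series(["wt"] * 3 + ["mut"] * 3, index=df.columns)
        sf = size_factors(df)
        disp = estimate_dispersion(df, sf, cond)
        res = nb_wald_test(df, sf, disp, cond, ("mut", "wt"))
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert (res["call"] == "ns").all()
        assert (res["pvalue"] == 1.0).all()

    def test_label_swap_negates_lfc_keeps_p(self, rng):
        df, cond = self._fixture(rng, lfc=1.0)
        sf = size_factors(df)
        disp = estimate_dispersion(df, sf, cond)
        fwd = nb_wald_test(df, sf, disp, cond, ("mut", "wt"))
        rev = nb_wald_test(df, sf, disp, cond, ("wt", "mut"))
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_strong_effect_called_up(self, rng):
        df, cond = self._fixture(rng, lfc=2.0)
        sf = size_factors(df)
        disp = estimate_dispersion(df, sf, cond)
        res = nb_wald_test(df, sf, disp, cond, ("mut", "wt"), lfc_threshold=0.5)
        affected = res.iloc[:40]
        null = res.iloc[40:]
        assert (affected["call"] == "up").mean() > 0.9
        assert (null["call"] == "ns").mean() > 0.98

    def test_padj_at_least_p(self, rng):
        df, cond = self._fixture(rng, lfc=0.5)
        sf = size_factors(df)
        disp = estimate_dispersion(df, sf, cond)
        res = nb_wald_test(df, sf, disp, cond, ("mut", "wt"))
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()

    def test_both_zero_flagged_p1(self):
        mat = np.vstack([np.zeros(6), np.full(6, 100.0)])
        df = counts_frame(mat)
        cond = pd.Series(["wt"] * 3 + ["mut"] * 3, index=df.columns)
        sf = pd.Series(1.0, index=df.columns)
        disp = pd.Series(0.05, index=df.index)
        res = nb_wald_test(df, sf, disp, cond, ("mut", "wt"))
        assert res.loc["g0", "pvalue"] == 1.0
        assert res.loc["g0", "baseMean"] == 0.0
        assert res.loc["g0", "log2FoldChange"] == 0.0

    def test_one_sided_presence_test(self, rng):
        df, cond = self._fixture(rng, lfc=1.5)
        sf = size_factors(df)
        disp = estimate_dispersion(df, sf, cond)
        res = nb_wald_test(df, sf, disp, cond, ("mut", "wt"),
                           lfc_threshold=0.0, alternative="greater")
        assert (res.iloc[:40]["call"] == "up").mean() > 0.95
        # one-sided p for a negative effect is > 0.5
        rev = nb_wald_test(df, sf, disp, cond, ("wt", "mut"),
                           lfc_threshold=0.0, alternative="greater")
        assert (rev.iloc[:40]["pvalue"] > 0.5).mean() > 0.9


class TestClassifyDe:
    def test_strict_lfc_boundary(self):
        tab = pd.DataFrame(
            {"log2FoldChange": [0.5, 0.6, -0.5, -0.7], "padj": [0.01, 0.04, 0.01, 0.05]},
            index=["a", "b", "c", "d"],
        )
        up, down = classify_de(tab)
        assert up == ["b"]  # 0.5 exactly is not "superior to 0.5"
        assert down == ["d"]  # padj <= 0.05 is inclusive

    def test_alpha_threshold_inclusive(self):
        tab = pd.DataFrame({"log2FoldChange": [1.0], "padj": [0.050000]}, index=["a"])
        up, _ = classify_de(tab)
        assert up == ["a"]


class TestModelApi:
    def test_fit_summary_and_classify(self, rng):
        r = 1 / 0.02
        wt = rng.negative_binomial(r, r / (r + 300), size=(100, 3))
        mut = wt.copy()
        mut[:10] = rng.negative_binomial(r, r / (r + 1200), size=(10, 3))
        df = counts_frame(np.hstack([wt, mut]))
        cond = pd.Series(["wt"] * 3 + ["mut"] * 3, index=df.columns)
        model = NBDifferentialExpression(df, cond, ("mut", "wt"))
        res = model.fit()
        assert isinstance(res, DEResults)
        up, down = res.classify()
        assert set(up) >= {"g0", "g1"} and len(up) >= 8
        text = res.summary()
        assert "mut vs wt" in text and f"up: {len(res.up)}" in text

    def test_from_dataframe_constructor(self, rng):
        df = counts_frame(rng.poisson(100, size=(20, 6)))
        sheet = pd.DataFrame(
            {"sample": df.columns, "genotype": ["wt"] * 3 + ["mut"] * 3}
        )
        model = NBDifferentialExpression.from_dataframe(df, sheet, ("mut", "wt"))
        res = model.fit()
        assert list(res.table.index) == list(df.index)

    def test_test_features_restricts_bh_family(self, rng):
        df = counts_frame(rng.poisson(100, size=(30, 6)))
        cond = pd.Series(["wt"] * 3 + ["mut"] * 3, index=df.columns)
        sub = [f"g{i}" for i in range(5)]
        res = NBDifferentialExpression(df, cond, ("mut", "wt"), test_features=sub).fit()
        assert list(res.table.index) == sub
        # size factors still estimated from the full table
        assert len(res.size_factors) == 6

    def test_volcano_writes_figure(self, rng, tmp_path):
        df = counts_frame(rng.poisson(100, size=(20, 6)))
        cond = pd.Series(["wt"] * 3 + ["mut"] * 3, index=df.columns)
        res = NBDifferentialExpression(df, cond, ("mut", "wt")).fit()
        out = tmp_path / "v.png"
        res.plot_volcano(out)
        assert out.stat().st_size > 0
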