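"""Negative-binomial two-group differential expression with fold-change
thresholds.

The model: counts K_ij for feature i in sample j follow a negative binomial
with mean s_j * q_i(c_j) and dispersion alpha_i, where s_j is a per-sample
size factor (median-of-ratios), c_j the sample's condition, and
beta_i = log2(q_i(mutant) / q_i(reference)) the log2 fold change.  The test
is a thresholded Wald test: for a threshold theta the two-sided p-value is
2 * Phi-bar((|beta_hat| - theta) / SE) when |beta_hat| > theta and 1
otherwise, so only fold changes exceeding theta can reach significance;
read-through "presence" uses the one-sided variant at theta = 0.  P-values
are Benjamini-Hochberg adjusted and features called up/down with strict
fold-change inequalities at padj <= alpha.

Dispersion is a per-feature method-of-moments estimate on normalised counts,
averaged across conditions and floored at 1e-8; the Wald standard error
comes from the delta method applied to the per-condition mean of normalised
counts under the NB variance function mu + alpha * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

LN2 = np.log(2.0)
ALPHA_MIN = 1e-8

RESULT_COLUMNS = [
    "baseMean", "log2FoldChange", "lfcSE", "pvalue", "padj", "call",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses features with strictly positive counts in every sample as the
    reference set.  Raises if no such feature exists (callers may then fall
    back to a pseudo-reference strategy of their choice).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all samples; "
            "consider a pseudo-reference fallback"
        )
    ref = mat[positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.log(ref) - log_geomean
    logf = np.median(ratios, axis=0)
    logf = logf - logf.mean()  # geometric mean 1
    return pd.Series(np.exp(logf), index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    conditions: pd.Series,
    shrink: bool = True,
) -> pd.Series:
    """Per-feature method-of-moments NB dispersion on normalised counts.

    alpha = max((s^2 - mu) / mu^2, 1e-8) within each condition, averaged over
    conditions with >= 2 replicates.  Constant counts or the Poisson limit
    both collapse to the floor.

    With ``shrink=True`` (the default) per-feature estimates are floored at
    the median estimate across features: with few replicates the moment
    estimator frequently underestimates the variance, and an underestimated
    dispersion inflates Wald statistics; flooring at the trend median trades
    a little power on genuinely low-dispersion features for type-I control.
    """
    norm = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy()
    cond = np.asarray(conditions.loc[counts.columns])
    alphas = np.full((len(counts),), np.nan)
    per_cond = []
    for c in pd.unique(cond):
        sub = norm[:, cond == c]
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        a[~np.isfinite(a)] = np.nan
        per_cond.append(a)
    if not per_cond:
        raise ValueError("need >= 2 replicates in at least one condition")
    stacked = np.vstack(per_cond)
    with np.errstate(invalid="ignore"):
        alphas = np.nanmean(stacked, axis=0)
    alphas = np.where(np.isfinite(alphas), alphas, ALPHA_MIN)
    alphas = np.maximum(alphas, ALPHA_MIN)
    if shrink and alphas.size > 1:
        alphas = np.maximum(alphas, np.median(alphas))
    return pd.Series(alphas, index=counts.index, name="dispersion")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def nb_wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    dispersion: pd.Series,
    conditions: pd.Series,
    contrast: Tuple[str, str],
    lfc_threshold: float = 0.5,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Thresholded NB Wald test for ``contrast = (mutant, reference)``.

    Returns a result table with baseMean (mean normalised count over the two
    groups), log2FoldChange (mutant vs reference), lfcSE, pvalue, padj and
    the up/down/ns call.  Features with zero counts in both conditions are
    reported with p = 1 and call ``ns`` (flagged by baseMean == 0).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    test_level, ref_level = contrast
    cond = conditions.loc[counts.columns]
    cols_test = cond.index[cond == test_level]
    cols_ref = cond.index[cond == ref_level]
    if len(cols_test) == 0 or len(cols_ref) == 0:
        raise ValueError(f"contrast {contrast} not present in conditions")

    sf_t = sf.loc[cols_test].to_numpy()
    sf_r = sf.loc[cols_ref].to_numpy()
    norm_t = counts[cols_test].to_numpy(dtype=float) / sf_t
    norm_r = counts[cols_ref].to_numpy(dtype=float) / sf_r
    mu_t = norm_t.mean(axis=1)
    mu_r = norm_r.mean(axis=1)
    alpha_disp = dispersion.loc[counts.index].to_numpy()

    both_zero = (mu_t == 0) & (mu_r == 0)
    # continuity floor of half a normalised count when one group is all zero
    floor_t = 0.5 / sf_t.mean()
    floor_r = 0.5 / sf_r.mean()
    mu_t_f = np.maximum(mu_t, floor_t)
    mu_r_f = np.maximum(mu_r, floor_r)

    lfc = np.log2(mu_t_f / mu_r_f)

    def _var_log2_mean(mu: np.ndarray, sfs: np.ndarray, a: np.ndarray) -> np.ndarray:
        # Var(mean_j K_j / s_j) with K_j ~ NB(mu * s_j, a), delta method to log2
        var_mean = (mu[:, None] / sfs + a[:, None] * mu[:, None] ** 2).sum(axis=1)
        var_mean /= sfs.size**2
        return var_mean / (mu**2 * LN2**2)

    se = np.sqrt(
        _var_log2_mean(mu_t_f, sf_t, alpha_disp) + _var_log2_mean(mu_r_f, sf_r, alpha_disp)
    )

    theta = float(lfc_threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        if alternative == "two-sided":
            z = (np.abs(lfc) - theta) / se
            pvals = np.where(np.abs(lfc) > theta, 2.0 * stats.norm.sf(z), 1.0)
        else:
            z = (lfc - theta) / se
            pvals = stats.norm.sf(z)
    pvals = np.minimum(pvals, 1.0)
    pvals[both_zero] = 1.0
    lfc[both_zero] = 0.0

    padj = bh_adjust(pvals)
    call = np.full(len(counts), "ns", dtype=object)
    if alternative == "two-sided":
        call[(lfc > theta) & (padj <= alpha)] = "up"
        call[(lfc < -theta) & (padj <= alpha)] = "down"
    else:
        call[(lfc > theta) & (padj <= alpha)] = "up"

    return pd.DataFrame(
        {
            "baseMean": np.concatenate([norm_t, norm_r], axis=1).mean(axis=1),
            "log2FoldChange": lfc,
            "lfcSE": se,
            "pvalue": pvals,
            "padj": padj,
            "call": call,
        },
        index=counts.index,
    )


def classify_de(
    results: pd.DataFrame, lfc: float = 0.5, alpha: float = 0.05
) -> Tuple[List[str], List[str]]:
    """Split a result table into up/down feature id lists.

    Strict fold-change inequalities (a log2FC of exactly ``lfc`` is not
    called), non-strict padj."""
    sig = results["padj"] <= alpha
    up = results.index[sig & (results["log2FoldChange"] > lfc)].tolist()
    down = results.index[sig & (results["log2FoldChange"] < -lfc)].tolist()
    return up, down


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class NBDifferentialExpression:
    """Two-group NB differential-expression model on a count table.

    Parameters
    ----------
    counts
        Feature x sample integer count DataFrame.
    conditions
        Series mapping sample id -> condition label.
    contrast
        (test, reference) condition pair, e.g. ("cut14", "wt").
    lfc_threshold, alternative, alpha
        Thresholded Wald test settings; ``alternative="greater"`` with
        ``lfc_threshold=0`` is the read-through presence test.

    Examples
    --------
    >>> model = NBDifferentialExpression(counts, conditions, ("mut", "wt"))
    >>> res = model.fit()
    >>> up, down = res.classify()
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        conditions: pd.Series,
        contrast: Tuple[str, str],
        lfc_threshold: float = 0.5,
        alternative: str = "two-sided",
        alpha: float = 0.05,
        test_features: Optional[Sequence[str]] = None,
        shrink_dispersion: bool = True,
    ) -> None:
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.conditions = conditions.loc[counts.columns]
        self.contrast = contrast
        self.lfc_threshold = lfc_threshold
        self.alternative = alternative
        self.alpha = alpha
        # normalisation/dispersion use the full table; testing (and the BH
        # family) can be restricted to a feature subset, e.g. the _RT rows
        self.test_features = list(test_features) if test_features is not None else None
        self.shrink_dispersion = shrink_dispersion

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        contrast: Tuple[str, str],
        condition_col: str = "genotype",
        **kwargs,
    ) -> "NBDifferentialExpression":
        """Build from a count DataFrame and a sample sheet with a sample
        column matching ``df``'s columns."""
        conditions = pd.Series(
            sample_sheet[condition_col].to_numpy(), index=sample_sheet["sample"].to_numpy()
        )
        return cls(df, conditions, contrast, **kwargs)

    def fit(self) -> "DEResults":
        sf = size_factors(self.counts)
        disp = estimate_dispersion(self.counts, sf, self.conditions, shrink=self.shrink_dispersion)
        counts = (
            self.counts.loc[self.test_features] if self.test_features is not None else self.counts
        )
        table = nb_wald_test(
            counts,
            sf,
            disp,
            self.conditions,
            self.contrast,
            lfc_threshold=self.lfc_threshold,
            alternative=self.alternative,
            alpha=self.alpha,
        )
        return DEResults(self, table, sf, disp)


class DEResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    table : DataFrame with baseMean, log2FoldChange, lfcSE, pvalue, padj, call
    size_factors : per-sample median-of-ratios factors
    dispersions : per-feature NB dispersion estimates
    """

    def __init__(
        self,
        model: NBDifferentialExpression,
        table: pd.DataFrame,
        size_factors: pd.Series,
        dispersions: pd.Series,
    ) -> None:
        self.model = model
        self.table = table
        self.size_factors = size_factors
        self.dispersions = dispersions

    def classify(self, lfc: Optional[float] = None, alpha: Optional[float] = None):
        lfc = self.model.lfc_threshold if lfc is None else lfc
        alpha = self.model.alpha if alpha is None else alpha
        return classify_de(self.table, lfc=lfc, alpha=alpha)

    @property
    def up(self) -> List[str]:
        return self.table.index[self.table["call"] == "up"].tolist()

    @property
    def down(self) -> List[str]:
        return self.table.index[self.table["call"] == "down"].tolist()

    def summary(self) -> str:
        t, r = self.model.contrast
        n = len(self.table)
        lines = [
            "NB differential expression (thresholded Wald test)",
            f"contrast: {t} vs {r}   features: {n}",
            f"lfc threshold: {self.model.lfc_threshold:g} "
            f"({self.model.alternative}); FDR <= {self.model.alpha:g}",
            f"up: {len(self.up)}   down: {len(self.down)}   "
            f"ns: {n - len(self.up) - len(self.down)}",
            f"size factors: "
            + ", ".join(f"{s}={v:.3f}" for s, v in self.size_factors.items()),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        t, r = self.model.contrast
        write_tsv(
            self.table,
            path,
            index_label="feature",
            header_comment=f"contrast={t}_vs_{r} lfc_threshold={self.model.lfc_threshold:g} "
            f"alternative={self.model.alternative} alpha={self.model.alpha:g}",
        )

    def plot_volcano(self, path=None, ax=None):
        """Volcano plot (log2FC vs -log10 padj); called features in red."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(5, 4))
        else:
            fig = ax.figure
        tab = self.table
        sig = tab["call"] != "ns"
        y = -np.log10(np.maximum(tab["padj"], 1e-300))
        ax.scatter(tab["log2FoldChange"][~sig], y[~sig], s=4, c="grey", alpha=0.5)
        ax.scatter(tab["log2FoldChange"][sig], y[sig], s=6, c="red")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 padj")
        t, r = self.model.contrast
        ax.set_title(f"{t} vs {r}")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax
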