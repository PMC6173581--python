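"""Comparative set statistics: hypergeometric overlaps, chi-square
enrichment, orientation composition, cross-genotype summary reports."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ORIENTATION_CLASSES, GenomeAnnotation, classify_orientation


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two gene sets within a universe of size N."""

    k: int
    n1: int
    n2: int
    N: int
    p: float


def hypergeometric_overlap(k: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for an overlap of k
    between sets of sizes n1 and n2 drawn from a universe of N."""
    if not (0 <= k <= min(n1, n2) and n1 <= N and n2 <= N):
        raise ValueError(f"inconsistent overlap arguments k={k} n1={n1} n2={n2} N={N}")
    # survival function computed stably (log-space internals in scipy)
    return float(stats.hypergeom.sf(k - 1, N, n1, n2))


def log10_hypergeometric_overlap(k: int, n1: int, n2: int, N: int) -> float:
    """log10 of the upper-tail p, usable when p underflows."""
    if not (0 <= k <= min(n1, n2) and n1 <= N and n2 <= N):
        raise ValueError("inconsistent overlap arguments")
    return float(stats.hypergeom.logsf(k - 1, N, n1, n2) / np.log(10))


def overlap_test(set1: Iterable[str], set2: Iterable[str], universe: Iterable[str]) -> OverlapResult:
    s1, s2, uni = set(set1), set(set2), set(universe)
    if not (s1 <= uni and s2 <= uni):
        raise ValueError("sets must be subsets of the universe")
    k = len(s1 & s2)
    return OverlapResult(k, len(s1), len(s2), len(uni), hypergeometric_overlap(k, len(s1), len(s2), len(uni)))


def chisq_enrichment(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [[a, b], [c, d]].  Returns (statistic, p)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    stat, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def orientation_composition(
    gene_set: Iterable[str],
    ann: GenomeAnnotation,
    labels: Optional[Mapping[str, str]] = None,
    empty_ok: bool = False,
) -> pd.DataFrame:
    """Counts and fractions of orientation classes in a gene set vs the
    genome-wide background.

    Returns a DataFrame indexed by orientation class with columns
    set_count/set_fraction/genome_count/genome_fraction.
    """
    gene_set = list(gene_set)
    if labels is None:
        labels = classify_orientation(ann)
    unknown = [g for g in gene_set if g not in ann]
    if unknown:
        raise KeyError(f"unknown gene ids: {unknown[:5]}")
    if not gene_set and not empty_ok:
        raise ValueError("empty gene set (pass empty_ok=True for an all-zero report)")
    rows = {}
    n_set = len(gene_set)
    n_all = len(ann)
    set_labels = pd.Series([labels[g] for g in gene_set], dtype=object)
    all_labels = pd.Series([labels[u.id] for u in ann], dtype=object)
    for cls in ORIENTATION_CLASSES:
        sc = int((set_labels == cls).sum())
        gc = int((all_labels == cls).sum())
        rows[cls] = {
            "set_count": sc,
            "set_fraction": sc / n_set if n_set else 0.0,
            "genome_count": gc,
            "genome_fraction": gc / n_all,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(ORIENTATION_CLASSES)]


def biotype_composition(gene_ids: Iterable[str], ann: GenomeAnnotation) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for g in gene_ids:
        bt = ann[g].biotype
        out[bt] = out.get(bt, 0) + 1
    return out


@dataclass
class ComparisonReport:
    """Cross-genotype summary: DE calls, overlaps, correlation, biotypes,
    read-through counts."""

    genotype_a: str
    genotype_b: str
    up_a: List[str]
    down_a: List[str]
    up_b: List[str]
    down_b: List[str]
    up_overlap: OverlapResult
    deregulated_overlap: OverlapResult
    lfc_correlation: float
    biotypes_up_a: Dict[str, int]
    biotypes_up_b: Dict[str, int]
    rt_a: List[str]
    rt_b: List[str]
    rt_overlap: OverlapResult

    def to_text(self) -> str:
        a, b = self.genotype_a, self.genotype_b
        lines = [
            f"comparison: {a} vs {b}",
            f"{a}: up={len(self.up_a)} down={len(self.down_a)}",
            f"{b}: up={len(self.up_b)} down={len(self.down_b)}",
            f"up-set overlap: k={self.up_overlap.k} of n1={self.up_overlap.n1}, "
            f"n2={self.up_overlap.n2}, N={self.up_overlap.N}, p={self.up_overlap.p:.3g}",
            f"deregulated overlap: k={self.deregulated_overlap.k}, "
            f"p={self.deregulated_overlap.p:.3g}",
            f"log2FC correlation (all features): r={self.lfc_correlation:.3f}",
            f"biotypes of {a} up-set: {self.biotypes_up_a}",
            f"biotypes of {b} up-set: {self.biotypes_up_b}",
            f"read-throughs: {a}={len(self.rt_a)} {b}={len(self.rt_b)} "
            f"overlap k={self.rt_overlap.k} p={self.rt_overlap.p:.3g}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "up_a": len(self.up_a),
            "down_a": len(self.down_a),
            "up_b": len(self.up_b),
            "down_b": len(self.down_b),
            "up_overlap_k": self.up_overlap.k,
            "up_overlap_p": self.up_overlap.p,
            "deregulated_overlap_k": self.deregulated_overlap.k,
            "deregulated_overlap_p": self.deregulated_overlap.p,
            "lfc_correlation": self.lfc_correlation,
            "rt_a": len(self.rt_a),
            "rt_b": len(self.rt_b),
            "rt_overlap_k": self.rt_overlap.k,
            "rt_overlap_p": self.rt_overlap.p,
        }
        return pd.DataFrame({"value": rows})


def summarise_comparison(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    rt_a: Iterable[str],
    rt_b: Iterable[str],
    ann: GenomeAnnotation,
    genotype_a: str = "a",
    genotype_b: str = "b",
    universe: Optional[Iterable[str]] = None,
) -> ComparisonReport:
    """Build a cross-genotype comparison from two DE result tables (indexed
    by feature, with log2FoldChange and call columns) and two read-through
    gene sets.

    The default overlap universe is the features tested in both analyses;
    the read-through universe is all annotated units.
    """
    shared = de_a.index.intersection(de_b.index)
    if len(shared) == 0:
        raise ValueError("DE tables share no features; were they built on the same annotation?")
    uni = list(universe) if universe is not None else list(shared)

    up_a = [g for g in de_a.index[de_a["call"] == "up"] if g in set(uni)]
    down_a = [g for g in de_a.index[de_a["call"] == "down"] if g in set(uni)]
    up_b = [g for g in de_b.index[de_b["call"] == "up"] if g in set(uni)]
    down_b = [g for g in de_b.index[de_b["call"] == "down"] if g in set(uni)]

    up_overlap = overlap_test(up_a, up_b, uni)
    dereg_overlap = overlap_test(up_a + down_a, up_b + down_b, uni)

    lfc = np.corrcoef(
        de_a.loc[shared, "log2FoldChange"], de_b.loc[shared, "log2FoldChange"]
    )[0, 1]

    gene_ids_a = [g[:-3] if g.endswith("_RT") else g for g in up_a]
    gene_ids_b = [g[:-3] if g.endswith("_RT") else g for g in up_b]

    rt_a, rt_b = list(rt_a), list(rt_b)
    rt_overlap = overlap_test(rt_a, rt_b, [u.id for u in ann])

    return ComparisonReport(
        genotype_a=genotype_a,
        genotype_b=genotype_b,
        up_a=up_a,
        down_a=down_a,
        up_b=up_b,
        down_b=down_b,
        up_overlap=up_overlap,
        deregulated_overlap=dereg_overlap,
        lfc_correlation=float(lfc),
        biotypes_up_a=biotype_composition([g for g in gene_ids_a if g in ann], ann),
        biotypes_up_b=biotype_composition([g for g in gene_ids_b if g in ann], ann),
        rt_a=rt_a,
        rt_b=rt_b,
        rt_overlap=rt_overlap,
    )
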