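"""Broad-peak detection in strand-specific coverage of unannotated regions.

The detector is a multiscale sliding-window scan: windows of geometrically
increasing lengths are slid through the searched (intergenic) regions; a
window is significant when its read coverage exceeds a fold-change gate over
the local background rate and its Poisson upper-tail p-value survives
Benjamini-Hochberg correction; significant windows across all scales are then
merged into maximal peaks.  The parameter surface (begin_l/end_l/step,
fragment extension l_frag, read length l_mapp, q-value cutoff) mirrors the
multiscale broad-peak callers used for this kind of data; a q cutoff of 1
disables the q-value filter so that only the fold-change gate applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotation import FORWARD, REVERSE, STRANDS, Interval
from .reads import StrandedCoverage, StrandedReadSet
from .diffexpr import bh_adjust


@dataclass(frozen=True)
class PeakParams:
    """Parameters of the multiscale window scan.

    begin_l/end_l bound the window-length ladder (bases), step is the
    geometric scale factor; l_frag is the 3' fragment extension applied to
    each read before computing coverage; l_mapp records the read length (kept
    for bookkeeping only, no mappability correction is applied); q_threshold
    is the BH q-value cutoff (1.0 keeps every fold-change-passing window);
    min_fold_change gates windows on enrichment over background.
    """

    begin_l: int = 50
    end_l: int = 500
    step: float = 1.1
    l_frag: int = 363
    l_mapp: int = 50
    q_threshold: float = 1.0
    min_fold_change: float = 2.0

    def __post_init__(self) -> None:
        if self.begin_l > self.end_l:
            raise ValueError("begin_l must be <= end_l")
        if self.step <= 1:
            raise ValueError("step must be > 1")
        if not (0 < self.q_threshold <= 1):
            raise ValueError("q_threshold must be in (0, 1]")

    def window_lengths(self) -> List[int]:
        """Geometric ladder of window lengths from begin_l up to end_l."""
        out: List[int] = []
        l = float(self.begin_l)
        while round(l) <= self.end_l:
            li = int(round(l))
            if not out or li != out[-1]:
                out.append(li)
            l *= self.step
        return out


@dataclass(frozen=True)
class Peak:
    """A merged enrichment region; score is the best window's -log10 p."""

    interval: Interval
    score: float
    sample: Optional[str] = None


def coverage_from_reads(
    reads: StrandedReadSet,
    chrom_sizes,
    l_frag: int,
) -> StrandedCoverage:
    """Per-base stranded coverage of reads extended to ``l_frag`` bases 3'.

    Forward reads are extended from their start, reverse reads from their end
    (toward lower coordinates); extensions are clipped at chromosome bounds.
    """
    cov = StrandedCoverage(chrom_sizes)
    for chrom, size in cov.chrom_sizes.items():
        for strand in STRANDS:
            starts, ends = reads.on(chrom, strand)
            if starts.size == 0:
                continue
            if strand == FORWARD:
                s = starts
                e = np.minimum(np.maximum(ends, starts + l_frag), size)
            else:
                e = ends
                s = np.maximum(np.minimum(starts, ends - l_frag), 0)
            diff = np.zeros(size + 1, dtype=float)
            np.add.at(diff, s, 1.0)
            np.add.at(diff, e, -1.0)
            cov.get(chrom, strand)[:] = np.cumsum(diff[:-1])
    return cov


def estimate_background(
    cov: StrandedCoverage, regions: Sequence[Interval]
) -> Dict[str, float]:
    """Mean per-base background rate per strand over the searched regions.

    lambda = total coverage in the regions / total region length, floored at
    a pseudo-rate of 1/total-length so a zero-coverage background never
    yields a degenerate rate.
    """
    totals = {s: 0.0 for s in STRANDS}
    lengths = {s: 0 for s in STRANDS}
    for iv in regions:
        if iv.strand not in STRANDS:
            raise ValueError("background regions must be stranded")
        totals[iv.strand] += float(cov.get(iv.chrom, iv.strand)[iv.start:iv.end].sum())
        lengths[iv.strand] += iv.length
    rates: Dict[str, float] = {}
    for s in STRANDS:
        if lengths[s] == 0:
            raise ValueError(f"no regions on strand {s}")
        rates[s] = max(totals[s] / lengths[s], 1.0 / lengths[s])
    return rates


def _scan_region(
    values: np.ndarray,
    offset: int,
    lam: float,
    params: PeakParams,
) -> List[Tuple[int, int, float, float]]:
    """All fold-change-passing windows in one region.

    Returns (start, end, count, p) tuples in absolute coordinates.  Window
    stride is half the window length; windows are fully contained in the
    region.
    """
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out: List[Tuple[int, int, float, float]] = []
    for l in params.window_lengths():
        if l > n:
            break
        stride = max(1, l // 2)
        starts = np.arange(0, n - l + 1, stride)
        # always include the right-flush window so region ends are covered
        if starts[-1] != n - l:
            starts = np.append(starts, n - l)
        counts = csum[starts + l] - csum[starts]
        expected = lam * l
        keep = counts >= params.min_fold_change * expected
        if not np.any(keep):
            continue
        pvals = stats.poisson.sf(np.round(counts[keep]) - 1, expected)
        for s, c, p in zip(starts[keep], counts[keep], pvals):
            out.append((offset + int(s), offset + int(s) + l, float(c), float(p)))
    return out


def call_peaks(
    cov: StrandedCoverage,
    regions: Sequence[Interval],
    params: PeakParams,
    sample: Optional[str] = None,
    background: Optional[Dict[str, float]] = None,
) -> List[Peak]:
    """Detect broad peaks within the given stranded regions.

    Significant windows (fold-change gate + BH-corrected Poisson upper tail
    at ``q_threshold``) from every scale are pooled and overlapping windows
    merged into maximal peaks; the peak score is the best window's -log10 p.
    """
    regions = list(regions)
    if not regions:
        return []
    if background is None:
        background = estimate_background(cov, regions)

    windows: List[Tuple[str, str, int, int, float]] = []  # chrom,strand,s,e,p
    for iv in regions:
        vals = cov.get(iv.chrom, iv.strand)[iv.start:iv.end]
        for s, e, _c, p in _scan_region(vals, iv.start, background[iv.strand], params):
            windows.append((iv.chrom, iv.strand, s, e, p))
    if not windows:
        return []

    padj = bh_adjust(np.array([w[4] for w in windows]))
    kept = [w for w, q in zip(windows, padj) if q <= params.q_threshold]
    if not kept:
        return []

    peaks: List[Peak] = []
    kept.sort(key=lambda w: (w[0], w[1], w[2], w[3]))
    cur = None  # [chrom, strand, s, e, best_p]
    for chrom, strand, s, e, p in kept:
        if cur is not None and (chrom, strand) == (cur[0], cur[1]) and s < cur[3]:
            cur[3] = max(cur[3], e)
            cur[4] = min(cur[4], p)
        else:
            if cur is not None:
                peaks.append(_finish_peak(cur, sample))
            cur = [chrom, strand, s, e, p]
    if cur is not None:
        peaks.append(_finish_peak(cur, sample))
    return peaks


def _finish_peak(cur, sample) -> Peak:
    chrom, strand, s, e, p = cur
    score = -math.log10(p) if p > 0 else 350.0
    return Peak(Interval(chrom, s, e, strand), score=score, sample=sample)
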