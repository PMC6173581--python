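"""In-memory containers for stranded reads and per-base stranded coverage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import FORWARD, REVERSE, STRANDS, Interval
from . import io as rio


@dataclass
class StrandedReadSet:
    """Aligned single-end reads for one sample, as stranded BED-like intervals.

    ``df`` has columns chrom, start, end, name, score, strand (BED6).  Reads
    are 0-based half-open; strand is the strand of the originating transcript
    (stranded library protocol).
    """

    sample: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(rio.BED6_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"read set missing columns {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def on(self, chrom: str, strand: str) -> Tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of reads on one chromosome and strand."""
        sub = self.df[(self.df["chrom"] == chrom) & (self.df["strand"] == strand)]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def subset(self, mask: np.ndarray, sample: Optional[str] = None) -> "StrandedReadSet":
        return StrandedReadSet(sample or self.sample, self.df[mask].reset_index(drop=True))

    def to_bed(self, path) -> None:
        rio.write_bed(self.df, path)

    @classmethod
    def from_bed(cls, sample: str, path) -> "StrandedReadSet":
        return cls(sample, rio.read_bed(path))


class StrandedCoverage:
    """Dense per-base read coverage, kept separately per strand."""

    def __init__(self, chrom_sizes: Mapping[str, int]) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self._cov: Dict[Tuple[str, str], np.ndarray] = {
            (chrom, strand): np.zeros(size, dtype=float)
            for chrom, size in self.chrom_sizes.items()
            for strand in STRANDS
        }

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self._cov[(chrom, strand)]

    def add_interval(self, chrom: str, start: int, end: int, strand: str, value: float = 1.0) -> None:
        self._cov[(chrom, strand)][start:end] += value

    def total(self, strand: Optional[str] = None) -> float:
        return float(
            sum(v.sum() for (c, s), v in self._cov.items() if strand is None or s == strand)
        )

    def to_bedgraph(self, path_forward, path_reverse) -> None:
        rio.write_bedgraph(
            {c: self.get(c, FORWARD) for c in self.chrom_sizes}, path_forward
        )
        rio.write_bedgraph(
            {c: self.get(c, REVERSE) for c in self.chrom_sizes}, path_reverse
        )

    @classmethod
    def from_bedgraph(cls, path_forward, path_reverse, chrom_sizes) -> "StrandedCoverage":
        cov = cls(chrom_sizes)
        for strand, path in ((FORWARD, path_forward), (REVERSE, path_reverse)):
            dense = rio.read_bedgraph(path, chrom_sizes)
            for chrom, vals in dense.items():
                cov._cov[(chrom, strand)][:] = vals
        return cov
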