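"""Plain-text genomic file I/O: BED6, bedGraph, chrom.sizes, TSV tables.

All tabular outputs are written deterministically (fixed column order, fixed
float formatting) so that fixed-seed pipeline runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .annotation import Interval

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6 file from a DataFrame with the BED6 columns."""
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "score": str, "strand": str},
        comment="#",
    )
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise ValueError(f"{path}: invalid BED interval at data line {bad[0] + 1}")
    return df


def intervals_to_bed(intervals: Iterable[Interval], names: Iterable[str] = None,
                     scores: Iterable = None) -> pd.DataFrame:
    ivs = list(intervals)
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in ivs],
            "start": [i.start for i in ivs],
            "end": [i.end for i in ivs],
            "name": list(names) if names is not None else [f"iv{k}" for k in range(len(ivs))],
            "score": list(scores) if scores is not None else [0] * len(ivs),
            "strand": [i.strand for i in ivs],
        }
    )


def bed_to_intervals(df: pd.DataFrame) -> List[Interval]:
    return [
        Interval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column chromosome size table (name <TAB> length)."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_bedgraph(values_by_chrom: Mapping[str, np.ndarray], path) -> None:
    """Write per-base coverage as a run-length-encoded bedGraph (zero runs
    omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(values_by_chrom):
            vals = np.asarray(values_by_chrom[chrom])
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> Dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-base arrays."""
    out = {chrom: np.zeros(size, dtype=float) for chrom, size in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            if chrom not in out:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            out[chrom][int(s):int(e)] = float(v)
    return out


def write_tsv(df: pd.DataFrame, path, index_label: str = None, header_comment: str = None) -> None:
    """Deterministic TSV writer with an optional '#'-prefixed header line."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, float_format="%.6g")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
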