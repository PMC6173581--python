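"""Fragment counting over transcripts and read-through features.

Reads are extended 3' to the library fragment length and each resulting
fragment is assigned to the same-strand feature with which it shares the
most bases; ties go to the feature whose 5' end is closest to the fragment's
5' end, and fragments still tied (or touching no feature) are tallied in an
``__unassigned__`` audit row.  Two tables are built: transcripts alone, and
transcripts plus the read-through extensions as separate ``<gene>_RT`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import FORWARD, REVERSE, GenomeAnnotation, Interval
from .detect import ReadthroughCall
from .reads import StrandedReadSet

UNASSIGNED = "__unassigned__"


@dataclass
class CountTable:
    """Feature x sample count matrix with feature lengths.

    ``df`` rows are feature ids (unique), columns sample ids in sample-sheet
    order; entries are non-negative integers.  The ``__unassigned__`` row,
    when present, audits fragments that matched no feature.
    """

    df: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate feature ids")

    @property
    def features(self) -> pd.DataFrame:
        return self.df.drop(index=UNASSIGNED, errors="ignore")

    def to_tsv(self, path) -> None:
        from .io import write_tsv

        out = self.df.copy()
        out.insert(0, "length", self.lengths.reindex(out.index).fillna(0).astype(int))
        write_tsv(out, path, index_label="feature")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        from .io import read_tsv

        df = read_tsv(path, index_col=0)
        df.index.name = None
        lengths = df.pop("length")
        return cls(df=df.astype(int), lengths=lengths)


def _feature_list(
    ann: GenomeAnnotation, rt_calls: Optional[Sequence[ReadthroughCall]]
) -> List[Tuple[str, Interval]]:
    feats: List[Tuple[str, Interval]] = [(u.id, u.interval) for u in ann]
    if rt_calls:
        for c in rt_calls:
            feats.append((f"{c.gene_id}_RT", c.extension))
    return feats


def count_fragments(
    reads: StrandedReadSet,
    features: Sequence[Tuple[str, Interval]],
    l_frag: int,
    chrom_sizes: Mapping[str, int],
) -> pd.Series:
    """Counts per feature for one sample (plus the unassigned audit row).

    Assignment is by maximal overlap among same-strand features; ties break
    to the feature whose 5' end is nearest the fragment's 5' end, then drop.
    """
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for idx, (fid, iv) in enumerate(features):
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(iv.start, iv.end, idx)

    counts = np.zeros(len(features) + 1, dtype=np.int64)  # last slot = unassigned
    df = reads.df
    for chrom in sorted({*df["chrom"]}):
        size = chrom_sizes[chrom]
        for strand in (FORWARD, REVERSE):
            sub = df[(df["chrom"] == chrom) & (df["strand"] == strand)]
            if sub.empty:
                continue
            tree = trees.get((chrom, strand))
            rs = sub["start"].to_numpy()
            re_ = sub["end"].to_numpy()
            if strand == FORWARD:
                fs = rs
                fe = np.minimum(np.maximum(re_, rs + l_frag), size)
                five = fs
            else:
                fe = re_
                fs = np.maximum(np.minimum(rs, re_ - l_frag), 0)
                five = fe
            for s, e, fp in zip(fs, fe, five):
                if tree is None:
                    counts[-1] += 1
                    continue
                best_idx = -1
                best_ov = 0
                best_d5 = None
                tied = False
                for hit in tree.overlap(s, e):
                    ov = min(e, hit.end) - max(s, hit.begin)
                    f5 = hit.begin if strand == FORWARD else hit.end
                    d5 = abs(int(fp) - f5)
                    if ov > best_ov or (ov == best_ov and best_idx >= 0 and d5 < best_d5):
                        best_idx, best_ov, best_d5 = hit.data, ov, d5
                        tied = False
                    elif ov == best_ov and best_idx >= 0 and d5 == best_d5 and hit.data != best_idx:
                        tied = True
                if best_idx < 0 or tied:
                    counts[-1] += 1
                else:
                    counts[best_idx] += 1
    index = [fid for fid, _ in features] + [UNASSIGNED]
    return pd.Series(counts, index=index, name=reads.sample)


def build_tables(
    samples: Mapping[str, StrandedReadSet],
    ann: GenomeAnnotation,
    rt_calls: Optional[Sequence[ReadthroughCall]] = None,
    l_frag: int = 363,
) -> Tuple[CountTable, CountTable]:
    """Count tables for transcripts alone and transcripts + read-throughs.

    Column order follows the ``samples`` mapping order (the sample sheet).
    With no read-through annotation the two tables are identical.
    """
    feats_tx = _feature_list(ann, None)
    feats_rt = _feature_list(ann, rt_calls)

    cols_tx, cols_rt = [], []
    for sid, rs in samples.items():
        if rs.sample != sid:
            raise ValueError(f"sample sheet id {sid!r} does not match read set {rs.sample!r}")
        cols_tx.append(count_fragments(rs, feats_tx, l_frag, ann.chrom_sizes))
        cols_rt.append(count_fragments(rs, feats_rt, l_frag, ann.chrom_sizes))

    def _table(cols, feats):
        df = pd.concat(cols, axis=1)
        lengths = pd.Series({fid: iv.length for fid, iv in feats})
        lengths[UNASSIGNED] = 0
        return CountTable(df=df, lengths=lengths)

    return _table(cols_tx, feats_tx), _table(cols_rt, feats_rt)
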