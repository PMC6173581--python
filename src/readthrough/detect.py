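"""Read-through detection: from per-replicate intergenic peaks to a
consensus 3'-extension annotation per genotype.

The filters follow the discovery strategy: reads overlapping same-strand
annotated transcripts are removed first; broad peaks called in the remaining
strand-specific coverage are kept only when they start within two read
lengths of the nearest upstream TTS on the same strand; peaks reaching into a
downstream same-strand gene are truncated at its boundary (or dropped when
fully inside one); a gene's read-through is accepted when supported by at
least ``min_support`` of the replicates, with the consensus far boundary
taken as the median over supporting replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    FORWARD,
    REVERSE,
    STRANDS,
    GenomeAnnotation,
    Interval,
    merge_intervals,
    nearest_tts_assignment,
)
from .peaks import Peak
from .reads import StrandedReadSet


@dataclass(frozen=True)
class ReadthroughCall:
    """A consensus 3' extension of one gene.

    ``extension`` starts exactly at the gene's TTS (half-open) and never
    overlaps a downstream same-strand transcription unit.
    """

    gene_id: str
    extension: Interval
    support: int
    genotype: str


def subtract_annotated(
    reads: StrandedReadSet, ann: GenomeAnnotation
) -> StrandedReadSet:
    """Remove reads with any overlap with a same-strand transcription unit.

    Opposite-strand overlap does not remove a read (the protocol is
    strand-specific).  retained + removed = input size.
    """
    merged: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for strand in STRANDS:
        ivs = merge_intervals([u.interval for u in ann.units_on(strand=strand)])
        by_chrom: Dict[str, List[Interval]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, chrom_ivs in by_chrom.items():
            starts = np.array([i.start for i in chrom_ivs])
            ends = np.array([i.end for i in chrom_ivs])
            merged[(chrom, strand)] = (starts, ends)

    df = reads.df
    keep = np.ones(len(df), dtype=bool)
    for (chrom, strand), (starts, ends) in merged.items():
        mask = (df["chrom"] == chrom) & (df["strand"] == strand)
        if not mask.any():
            continue
        rs = df.loc[mask, "start"].to_numpy()
        re_ = df.loc[mask, "end"].to_numpy()
        # merged intervals are disjoint and sorted: the only candidate
        # overlapping [rs, re) is the rightmost interval starting before re
        idx = np.searchsorted(starts, re_, side="left") - 1
        overlapping = (idx >= 0) & (ends[np.maximum(idx, 0)] > rs)
        keep[np.flatnonzero(mask.to_numpy())[overlapping]] = False
    return reads.subset(keep)


def filter_peaks_by_tts(
    peaks: Sequence[Peak],
    ann: GenomeAnnotation,
    read_length: int = 50,
) -> List[Tuple[Peak, str]]:
    """Keep peaks starting within two read lengths of the nearest TTS.

    A peak whose 5' boundary lies more than ``2 * read_length`` bases past
    the nearest same-strand TTS is discarded (<= is kept, matching the
    stated exclusion of "more than two read-lengths").  Kept peaks are paired
    with their assigned gene; peaks extending into a downstream same-strand
    unit are truncated at its near boundary, and dropped when nothing
    remains.
    """
    max_dist = 2 * read_length
    out: List[Tuple[Peak, str]] = []
    for peak in peaks:
        hit = nearest_tts_assignment(peak.interval, ann)
        if hit is None:
            continue
        gene_id, dist = hit
        if dist > max_dist:
            continue
        trimmed = _truncate_at_downstream(peak, gene_id, ann)
        if trimmed is not None:
            out.append((trimmed, gene_id))
    return out


def _truncate_at_downstream(
    peak: Peak, gene_id: str, ann: GenomeAnnotation
) -> Optional[Peak]:
    iv = peak.interval
    units = ann.units_on(chrom=iv.chrom, strand=iv.strand)
    if iv.strand == FORWARD:
        cut = iv.end
        for u in units:
            if u.id != gene_id and u.interval.end > iv.start and u.interval.start < cut:
                cut = max(u.interval.start, iv.start)
        if cut <= iv.start:
            return None
        if cut == iv.end:
            return peak
        return Peak(Interval(iv.chrom, iv.start, cut, iv.strand), peak.score, peak.sample)
    else:
        cut = iv.start
        for u in units:
            if u.id != gene_id and u.interval.start < iv.end and u.interval.end > cut:
                cut = min(u.interval.end, iv.end)
        if cut >= iv.end:
            return None
        if cut == iv.start:
            return peak
        return Peak(Interval(iv.chrom, cut, iv.end, iv.strand), peak.score, peak.sample)


def replicate_consensus(
    per_replicate_calls: Sequence[Sequence[Tuple[Peak, str]]],
    ann: GenomeAnnotation,
    min_support: int = 2,
    genotype: str = "",
) -> List[ReadthroughCall]:
    """Consensus read-through calls over biological replicates.

    A gene is retained iff peaks assigned to it occur in >= ``min_support``
    replicates (matching is by assigned gene id, which is robust to peak
    boundary jitter).  The consensus extension runs from the TTS to the
    median of each supporting replicate's farthest boundary.
    """
    n_rep = len(per_replicate_calls)
    if min_support > n_rep:
        raise ValueError(f"min_support={min_support} exceeds {n_rep} replicates")
    far_by_gene: Dict[str, List[int]] = {}
    for rep_calls in per_replicate_calls:
        rep_far: Dict[str, int] = {}
        for peak, gene_id in rep_calls:
            strand = ann[gene_id].interval.strand
            far = peak.interval.end if strand == FORWARD else peak.interval.start
            if gene_id not in rep_far:
                rep_far[gene_id] = far
            else:
                rep_far[gene_id] = (
                    max(rep_far[gene_id], far) if strand == FORWARD else min(rep_far[gene_id], far)
                )
        for gene_id, far in rep_far.items():
            far_by_gene.setdefault(gene_id, []).append(far)

    calls: List[ReadthroughCall] = []
    for gene_id, fars in far_by_gene.items():
        if len(fars) < min_support:
            continue
        gene = ann[gene_id]
        tts = gene.tts
        far = int(round(float(np.median(fars))))
        strand = gene.interval.strand
        if strand == FORWARD:
            if far <= tts:
                continue
            ext = Interval(gene.interval.chrom, tts, far, strand)
        else:
            if far >= tts:
                continue
            ext = Interval(gene.interval.chrom, far, tts, strand)
        calls.append(
            ReadthroughCall(gene_id=gene_id, extension=ext, support=len(fars), genotype=genotype)
        )
    calls.sort(key=lambda c: (c.extension.chrom, c.extension.start, c.gene_id))
    return calls


def merge_genotype_annotations(
    a: Sequence[ReadthroughCall], b: Sequence[ReadthroughCall]
) -> List[ReadthroughCall]:
    """Union of two genotypes' read-through annotations, keyed by gene.

    When both genotypes call the same gene the merged extension is the union
    span (TTS to the farther boundary).  Calls built against different
    genomes (conflicting TTS for the same gene) raise.
    """
    by_gene: Dict[str, ReadthroughCall] = {}
    for call in list(a) + list(b):
        prev = by_gene.get(call.gene_id)
        if prev is None:
            by_gene[call.gene_id] = call
            continue
        pe, ce = prev.extension, call.extension
        if pe.chrom != ce.chrom or pe.strand != ce.strand:
            raise ValueError(f"conflicting annotations for gene {call.gene_id}")
        if pe.strand == FORWARD:
            if pe.start != ce.start:
                raise ValueError(f"conflicting TTS for gene {call.gene_id}")
            ext = Interval(pe.chrom, pe.start, max(pe.end, ce.end), pe.strand)
        else:
            if pe.end != ce.end:
                raise ValueError(f"conflicting TTS for gene {call.gene_id}")
            ext = Interval(pe.chrom, min(pe.start, ce.start), pe.end, pe.strand)
        by_gene[call.gene_id] = ReadthroughCall(
            gene_id=call.gene_id,
            extension=ext,
            support=max(prev.support, call.support),
            genotype=f"{prev.genotype}|{call.genotype}" if prev.genotype != call.genotype else call.genotype,
        )
    merged = sorted(by_gene.values(), key=lambda c: (c.extension.chrom, c.extension.start, c.gene_id))
    return merged


def write_readthrough_gff3(calls: Sequence[ReadthroughCall], ann: GenomeAnnotation, path) -> None:
    """Write read-through features as GFF3 (type ``readthrough``, Parent=gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_sizes[chrom]}\n")
        for c in calls:
            iv = c.extension
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "readthrough",
                        "readthrough",
                        str(iv.start + 1),
                        str(iv.end),
                        str(c.support),
                        iv.strand,
                        ".",
                        f"ID={c.gene_id}_RT;Parent={c.gene_id};genotype={c.genotype}",
                    ]
                )
                + "\n"
            )


def calls_to_bed(calls: Sequence[ReadthroughCall]) -> pd.DataFrame:
    from .io import intervals_to_bed

    return intervals_to_bed(
        [c.extension for c in calls],
        names=[f"{c.gene_id}_RT" for c in calls],
        scores=[c.support for c in calls],
    )
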