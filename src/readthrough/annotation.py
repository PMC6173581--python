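"""Strand-aware genome annotation model and interval arithmetic.

The annotation is the backbone of read-through detection: it provides the
transcription termination sites (TTS, the 3' boundary of each transcription
unit), the strand-specific *complement* (intergenic space) in which peaks are
searched, and the convergent/tandem orientation context of every gene.

Coordinates are 0-based half-open throughout (BED convention); GFF3 I/O
converts from/to the 1-based closed convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import gffutils

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"
UNSTRANDED = "."
STRANDS = (FORWARD, REVERSE)

#: orientation classes; "divergent" is part of the reporting vocabulary but the
#: nearest-downstream-neighbour rule used here only ever assigns the other three
#: (see docs/methods.md).
ORIENTATION_CLASSES = ("convergent", "tandem", "divergent", "isolated")

BIOTYPES = ("mRNA", "ncRNA", "tRNA", "rRNA", "snRNA", "snoRNA", "other")

#: default mapping of GFF3 gene-level feature types to biotypes
DEFAULT_BIOTYPE_MAP = {
    "gene": "mRNA",
    "protein_coding_gene": "mRNA",
    "mRNA": "mRNA",
    "ncRNA_gene": "ncRNA",
    "ncRNA": "ncRNA",
    "tRNA_gene": "tRNA",
    "tRNA": "tRNA",
    "rRNA_gene": "rRNA",
    "rRNA": "rRNA",
    "snRNA_gene": "snRNA",
    "snRNA": "snRNA",
    "snoRNA_gene": "snoRNA",
    "snoRNA": "snoRNA",
    "pseudogene": "other",
}

#: GFF3 feature types treated as one transcription unit each.  The broad
#: default (all RNA classes) matches annotations in which every RNA class is a
#: gene-level record.
DEFAULT_FEATURE_TYPES = frozenset(DEFAULT_BIOTYPE_MAP) - {"mRNA"}


class Gff3ParseError(ValueError):
    """Raised for malformed GFF3 input, naming the offending line."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (FORWARD, REVERSE, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptionUnit:
    """A gene-level transcription unit: one stranded interval plus a biotype.

    Exon/intron structure is deliberately ignored; units are single intervals
    as produced by a BED conversion of the gene-level annotation.
    """

    id: str
    biotype: str
    interval: Interval

    def __post_init__(self) -> None:
        if self.interval.strand not in STRANDS:
            raise ValueError(f"transcription unit {self.id} must have a definite strand")

    @property
    def tts(self) -> int:
        """Position of the transcription termination site (3' end)."""
        return three_prime_end(self)


def three_prime_end(tu: TranscriptionUnit) -> int:
    """Return the TTS of a unit in half-open coordinates.

    For a forward-strand unit this is ``end`` (the first base past the
    transcript); for a reverse-strand unit it is ``start``.
    """
    iv = tu.interval
    if iv.strand == FORWARD:
        return iv.end
    if iv.strand == REVERSE:
        return iv.start
    raise ValueError(f"unit {tu.id} is unstranded")


class GenomeAnnotation:
    """A collection of transcription units with chromosome sizes.

    Iteration order is reproducible: sorted by (chrom, start, end, id).
    """

    def __init__(
        self,
        units: Iterable[TranscriptionUnit],
        chrom_sizes: Mapping[str, int],
    ) -> None:
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes)
        self.units: List[TranscriptionUnit] = sorted(
            units, key=lambda u: (u.interval.chrom, u.interval.start, u.interval.end, u.id)
        )
        self._by_id: Dict[str, TranscriptionUnit] = {}
        for u in self.units:
            if u.id in self._by_id:
                raise ValueError(f"duplicate transcription unit id {u.id!r}")
            self._by_id[u.id] = u
            size = self.chrom_sizes.get(u.interval.chrom)
            if size is None:
                raise ValueError(f"unit {u.id} on unknown chromosome {u.interval.chrom!r}")
            if u.interval.end > size:
                raise ValueError(
                    f"unit {u.id} extends past the end of {u.interval.chrom} "
                    f"({u.interval.end} > {size})"
                )

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self) -> Iterator[TranscriptionUnit]:
        return iter(self.units)

    def __getitem__(self, unit_id: str) -> TranscriptionUnit:
        return self._by_id[unit_id]

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._by_id

    def units_on(self, chrom: Optional[str] = None, strand: Optional[str] = None) -> List[TranscriptionUnit]:
        out = self.units
        if chrom is not None:
            out = [u for u in out if u.interval.chrom == chrom]
        if strand is not None:
            out = [u for u in out if u.interval.strand == strand]
        return out

    def biotype_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for u in self.units:
            counts[u.biotype] = counts.get(u.biotype, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def _validate_gff3_lines(path: Path) -> Dict[str, int]:
    """Pre-scan a GFF3 file: syntax check with line numbers, collect
    ##sequence-region chromosome sizes."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise Gff3ParseError(f"{path}:{lineno}: malformed ##sequence-region")
                sizes[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise Gff3ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start < 1 or end < start:
                raise Gff3ParseError(f"{path}:{lineno}: invalid 1-based coordinates {start}..{end}")
    return sizes


def read_gff3(
    path,
    biotype_map: Optional[Mapping[str, str]] = None,
    feature_types: Optional[Iterable[str]] = None,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> GenomeAnnotation:
    """Read gene-level features from a GFF3 file into a :class:`GenomeAnnotation`.

    1-based closed GFF3 coordinates are converted to 0-based half-open.
    Chromosome sizes are taken from ``##sequence-region`` pragmas unless
    supplied explicitly.

    Parameters
    ----------
    biotype_map
        Mapping of GFF3 feature types (or ``biotype`` attribute values) to
        canonical biotypes; defaults to :data:`DEFAULT_BIOTYPE_MAP`.
    feature_types
        GFF3 types that constitute a transcription unit; defaults to all
        gene-level RNA classes.
    """
    path = Path(path)
    bmap = dict(DEFAULT_BIOTYPE_MAP)
    if biotype_map:
        bmap.update(biotype_map)
    ftypes = frozenset(feature_types) if feature_types is not None else DEFAULT_FEATURE_TYPES

    pragma_sizes = _validate_gff3_lines(path)
    sizes = dict(chrom_sizes) if chrom_sizes is not None else pragma_sizes
    if not sizes:
        raise ValueError(
            f"{path}: no ##sequence-region pragmas found; pass chrom_sizes explicitly"
        )

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    units: List[TranscriptionUnit] = []
    for feat in db.all_features():
        if feat.featuretype not in ftypes:
            continue
        if feat.seqid not in sizes:
            raise ValueError(f"{path}: feature {feat.id} on unknown chromosome {feat.seqid!r}")
        biotype = feat.attributes.get("biotype", [None])[0]
        if biotype is None or biotype not in BIOTYPES:
            biotype = bmap.get(biotype or feat.featuretype, "other")
        uid = feat.attributes.get("ID", [feat.id])[0]
        units.append(
            TranscriptionUnit(
                id=uid,
                biotype=biotype,
                interval=Interval(feat.seqid, feat.start - 1, feat.end, feat.strand),
            )
        )
    ann = GenomeAnnotation(units, sizes)
    logger.info("read %d transcription units from %s", len(ann), path)
    return ann


def write_gff3(ann: GenomeAnnotation, path) -> None:
    """Write an annotation back to GFF3 (gene-level features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_sizes[chrom]}\n")
        for u in ann:
            iv = u.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "readthrough",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={u.id};biotype={u.biotype}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Merge overlapping/touching intervals (per chromosome; strand of the
    merged interval is taken from the inputs if uniform, else unstranded)."""
    out: List[Interval] = []
    by_chrom: Dict[str, List[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        strands = {i.strand for i in ivs}
        strand = strands.pop() if len(strands) == 1 else UNSTRANDED
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e, strand))
    return out


def strand_complement(ann: GenomeAnnotation, strand: str) -> List[Interval]:
    """Maximal intervals on ``strand`` covered by no same-strand unit.

    Together with the merged same-strand annotation, the result tiles every
    chromosome exactly once.  This is the strand-split `bedtools complement`
    step that defines where intergenic peaks are searched.
    """
    if strand not in STRANDS:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    merged = merge_intervals([u.interval for u in ann.units_on(strand=strand)])
    by_chrom: Dict[str, List[Interval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[Interval] = []
    for chrom in sorted(ann.chrom_sizes):
        size = ann.chrom_sizes[chrom]
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                out.append(Interval(chrom, pos, iv.start, strand))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(Interval(chrom, pos, size, strand))
    return out


def reverse_complement_annotation(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Mirror all coordinates and swap strands (used for symmetry checks)."""
    units = []
    for u in ann:
        iv = u.interval
        size = ann.chrom_sizes[iv.chrom]
        units.append(
            TranscriptionUnit(
                id=u.id,
                biotype=u.biotype,
                interval=Interval(
                    iv.chrom,
                    size - iv.end,
                    size - iv.start,
                    FORWARD if iv.strand == REVERSE else REVERSE,
                ),
            )
        )
    return GenomeAnnotation(units, ann.chrom_sizes)


# ---------------------------------------------------------------------------
# Orientation and TTS queries
# ---------------------------------------------------------------------------

def _downstream_gap(g: TranscriptionUnit, u: TranscriptionUnit) -> Optional[int]:
    """Gap from g's 3' end to u, if u lies (at least partly) downstream of g.

    Downstream means past g's 3' end in g's direction of transcription.
    Overlapping neighbours count with gap 0.  Returns None if u is not
    downstream of g.
    """
    gi, ui = g.interval, u.interval
    if gi.chrom != ui.chrom:
        return None
    if gi.strand == FORWARD:
        if ui.end <= gi.end:
            return None
        return max(0, ui.start - gi.end)
    else:
        if ui.start >= gi.start:
            return None
        return max(0, gi.start - ui.end)


def classify_orientation(ann: GenomeAnnotation) -> Dict[str, str]:
    """Label every unit by the strand of its nearest downstream neighbour.

    Opposite strand (3' ends facing) -> ``convergent``; same strand ->
    ``tandem``; no downstream neighbour on the chromosome -> ``isolated``.
    Ties are broken by smaller start, then id.
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    labels: Dict[str, str] = {}
    by_chrom: Dict[str, List[TranscriptionUnit]] = {}
    for u in ann:
        by_chrom.setdefault(u.interval.chrom, []).append(u)
    for chrom_units in by_chrom.values():
        for g in chrom_units:
            best: Optional[Tuple[int, int, str]] = None
            best_unit: Optional[TranscriptionUnit] = None
            for u in chrom_units:
                if u.id == g.id:
                    continue
                gap = _downstream_gap(g, u)
                if gap is None:
                    continue
                key = (gap, u.interval.start, u.id)
                if best is None or key < best:
                    best = key
                    best_unit = u
            if best_unit is None:
                labels[g.id] = "isolated"
            elif best_unit.interval.strand == g.interval.strand:
                labels[g.id] = "tandem"
            else:
                labels[g.id] = "convergent"
    return labels


def nearest_tts_assignment(
    iv: Interval, ann: GenomeAnnotation
) -> Optional[Tuple[str, int]]:
    """Assign a stranded interval (a peak) to the nearest upstream TTS.

    Considers same-strand units whose TTS lies at or upstream of the peak's
    5' boundary (start on +, end on -) and returns ``(unit id, distance)``
    with the minimal non-negative distance, or None if no unit qualifies.
    """
    if iv.strand not in STRANDS:
        raise ValueError("interval must have a definite strand")
    best: Optional[Tuple[int, str]] = None
    for u in ann.units_on(chrom=iv.chrom, strand=iv.strand):
        tts = u.tts
        if iv.strand == FORWARD:
            dist = iv.start - tts
        else:
            dist = tts - iv.end
        if dist < 0:
            continue
        key = (dist, u.id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[0]
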