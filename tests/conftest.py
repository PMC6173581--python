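"""Shared fixtures: toy annotations, random-annotation builders, RNG."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from readthrough.annotation import (
    GenomeAnnotation,
    Interval,
    TranscriptionUnit,
)

TOY_GFF3 = """\
##gff-version 3
##sequence-region chrI 1 10000
##sequence-region chrII 1 8000
chrI\ttoy\tgene\t11\t20\t.\t+\t.\tID=geneA;biotype=mRNA
chrI\ttoy\tgene\t501\t1500\t.\t-\t.\tID=geneB;biotype=ncRNA
chrII\ttoy\tgene\t2001\t4000\t.\t+\t.\tID=geneC;biotype=mRNA
"""

#: hand-derived 0-based half-open intervals for the toy GFF3 above
TOY_UNITS = {
    "geneA": ("chrI", 10, 20, "+", "mRNA"),
    "geneB": ("chrI", 500, 1500, "-", "ncRNA"),
    "geneC": ("chrII", 2000, 4000, "+", "mRNA"),
}

#: hand-derived TTS positions (end for +, start for -)
TOY_TTS = {"geneA": 20, "geneB": 500, "geneC": 4000}


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path


def make_annotation(units, chrom_sizes):
    """Build a GenomeAnnotation from (id, chrom, start, end, strand[, biotype])
    tuples."""
    tus = []
    for spec in units:
        uid, chrom, start, end, strand = spec[:5]
        biotype = spec[5] if len(spec) > 5 else "mRNA"
        tus.append(TranscriptionUnit(uid, biotype, Interval(chrom, start, end, strand)))
    return GenomeAnnotation(tus, chrom_sizes)


def random_annotation(rng, n_genes=50, chrom_sizes=None, allow_overlap=False):
    """Random annotation for oracle comparisons (may contain overlapping
    genes when allow_overlap)."""
    if chrom_sizes is None:
        chrom_sizes = {"c1": 100_000, "c2": 80_000}
    chroms = sorted(chrom_sizes)
    units = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = chrom_sizes[chrom]
        length = int(rng.integers(100, 3000))
        start = int(rng.integers(0, size - length))
        strand = "+" if rng.random() < 0.5 else "-"
        units.append((f"u{i:03d}", chrom, start, start + length, strand))
    if not allow_overlap:
        # keep first occurrence per overlapping cluster (any strand)
        kept, occupied = [], {c: [] for c in chroms}
        for spec in sorted(units, key=lambda s: (s[1], s[2])):
            _, chrom, start, end, _ = spec
            if all(e <= start or end <= s for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                kept.append(spec)
        units = kept
    return make_annotation(units, chrom_sizes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
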