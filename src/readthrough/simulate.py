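"""Synthetic stranded single-end RNA-seq with planted read-throughs.

The generator emulates the study design the pipeline is built for: three
biological replicates per genotype (a wild type and two mutants), 50 nt
single-end stranded reads from a fragment library of mean length 363
(sd 85.5), gene-level counts drawn from a negative binomial around
log-normal baseline means, a planted subset of genes with true up/down fold
changes in each mutant, and a planted subset of expressed genes whose
transcripts extend past their TTS in the mutants, with read coverage
decaying geometrically along the extension.  Everything is derived
deterministically from a single seed, and the ground truth (true fold
changes, read-through genes, extension lengths, per-sample counts) is
retained for recovery testing.

Reads are modelled as aligned intervals (BED), not sequences: trimming and
alignment are upstream of this pipeline's scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    FORWARD,
    REVERSE,
    GenomeAnnotation,
    Interval,
    TranscriptionUnit,
    classify_orientation,
    read_gff3,
    three_prime_end,
    write_gff3,
)
from .reads import StrandedCoverage, StrandedReadSet
from . import io as rio


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults reproduce the emulated experiment: 3 replicates per genotype,
    50 nt reads, 363/85.5 fragment length, ncRNA fraction 0.22, NB
    dispersion 0.05.  See docs/methods.md for the rationale behind the
    desk-scale genome defaults.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 300_000
    n_genes: int = 250
    ncrna_fraction: float = 0.22
    gene_length_median: int = 1300
    gene_length_sigma: float = 0.35
    min_gene_length: int = 200
    min_gap: int = 200
    # library
    read_length: int = 50
    fragment_length_mean: float = 363.4
    fragment_length_sd: float = 85.53354
    replicates: int = 3
    genotypes: Tuple[str, ...] = ("wt", "cut14", "rrp6")
    size_factor_sd: float = 0.1
    # expression
    mu_median: float = 120.0
    mu_sigma: float = 1.0
    dispersion: float = 0.05
    # differential expression truth
    de_fraction: float = 0.10
    de_lfc_magnitude: float = 1.0
    de_up_fraction: float = 0.8
    # read-through truth
    rt_gene_fraction: float = 0.10
    rt_read_fraction: float = 0.5
    rt_min_mean: float = 50.0
    ext_mean: float = 300.0
    ext_min: int = 60
    # fraction of the second mutant's planted sets shared with the first
    shared_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ncrna_fraction", "de_fraction", "de_up_fraction",
                     "rt_gene_fraction", "rt_read_fraction", "shared_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length >= self.fragment_length_mean:
            raise ValueError("read_length must be smaller than the mean fragment length")
        if len(self.genotypes) < 2:
            raise ValueError("need a reference genotype and at least one mutant")

    @property
    def reference(self) -> str:
        return self.genotypes[0]

    @property
    def mutants(self) -> Tuple[str, ...]:
        return self.genotypes[1:]

    @property
    def l_frag(self) -> int:
        return int(round(self.fragment_length_mean))

    def sample_names(self) -> List[str]:
        return [f"{g}_r{r}" for g in self.genotypes for r in range(1, self.replicates + 1)]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["genotypes"] = list(d["genotypes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["genotypes"] = tuple(d["genotypes"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``genes`` is indexed by gene id with columns mu (baseline mean),
    ext_len (true extension length, 0 when never read-through) and, per
    mutant genotype g, ``lfc_<g>`` and ``rt_<g>``.  ``counts`` holds the NB
    counts actually drawn per gene and sample; ``size_factors`` the planted
    per-sample depth factors.
    """

    genes: pd.DataFrame
    size_factors: pd.Series
    counts: pd.DataFrame

    def rt_genes(self, genotype: str) -> List[str]:
        return self.genes.index[self.genes[f"rt_{genotype}"]].tolist()

    def de_genes(self, genotype: str) -> Tuple[List[str], List[str]]:
        lfc = self.genes[f"lfc_{genotype}"]
        return (
            self.genes.index[lfc > 0].tolist(),
            self.genes.index[lfc < 0].tolist(),
        )


@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: GenomeAnnotation
    truth: SimTruth
    samples: Dict[str, StrandedReadSet]
    sample_sheet: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------

def generate_annotation(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> GenomeAnnotation:
    """Draw a non-overlapping gene annotation on ``n_chroms`` chromosomes.

    Gene lengths are log-normal; genes are separated by gaps of at least
    ``min_gap`` bases with the remaining space spread randomly (so packing
    always succeeds when the minimum footprint fits, and errors otherwise).
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 0])
    chrom_sizes = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    units: List[TranscriptionUnit] = []
    gid = 0
    for ci, chrom in enumerate(sorted(chrom_sizes)):
        k = per_chrom[ci]
        if k == 0:
            continue
        lengths = np.maximum(
            rng.lognormal(np.log(cfg.gene_length_median), cfg.gene_length_sigma, size=k),
            cfg.min_gene_length,
        ).astype(int)
        footprint = int(lengths.sum()) + (k + 1) * cfg.min_gap
        if footprint > cfg.chrom_length:
            raise ValueError(
                f"infeasible packing: {k} genes need {footprint} bases on "
                f"{chrom} of length {cfg.chrom_length}"
            )
        extra = cfg.chrom_length - footprint
        gaps = cfg.min_gap + np.floor(rng.dirichlet(np.ones(k + 1)) * extra).astype(int)
        strands = rng.choice([FORWARD, REVERSE], size=k)
        biotypes = np.where(rng.random(k) < cfg.ncrna_fraction, "ncRNA", "mRNA")
        pos = 0
        for i in range(k):
            pos += int(gaps[i])
            start, end = pos, pos + int(lengths[i])
            gid += 1
            units.append(
                TranscriptionUnit(
                    id=f"g{gid:04d}",
                    biotype=str(biotypes[i]),
                    interval=Interval(chrom, start, end, str(strands[i])),
                )
            )
            pos = end

    ann = GenomeAnnotation(units, chrom_sizes)
    if cfg.n_genes >= 10:
        ann = _ensure_orientation_mix(ann)
    return ann


def _ensure_orientation_mix(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Guarantee that both convergent and tandem contexts occur (flip a
    couple of strands deterministically in the vanishingly rare degenerate
    draw)."""
    labels = set(classify_orientation(ann).values())
    if {"convergent", "tandem"} <= labels:
        return ann
    units = list(ann.units)
    fixed = []
    for i, u in enumerate(units):
        if i == 0 or i == 1:
            strand = FORWARD  # two forward genes in series -> tandem
        elif i == 2:
            strand = FORWARD
        elif i == 3:
            strand = REVERSE  # +/- facing pair -> convergent
        else:
            strand = u.interval.strand
        iv = u.interval
        fixed.append(
            TranscriptionUnit(u.id, u.biotype, Interval(iv.chrom, iv.start, iv.end, strand))
        )
    return GenomeAnnotation(fixed, ann.chrom_sizes)


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def _downstream_room(ann: GenomeAnnotation) -> pd.Series:
    """Bases available past each gene's TTS before the next same-strand unit
    (or the chromosome end)."""
    room = {}
    for u in ann:
        iv = u.interval
        tts = u.tts
        same = ann.units_on(chrom=iv.chrom, strand=iv.strand)
        if iv.strand == FORWARD:
            nxt = [v.interval.start for v in same if v.interval.start >= iv.end and v.id != u.id]
            room[u.id] = (min(nxt) if nxt else ann.chrom_sizes[iv.chrom]) - tts
        else:
            prv = [v.interval.end for v in same if v.interval.end <= iv.start and v.id != u.id]
            room[u.id] = tts - (max(prv) if prv else 0)
    return pd.Series(room)


def _pick_shared(
    rng: np.random.Generator,
    pool: np.ndarray,
    n: int,
    previous: Optional[np.ndarray],
    shared_fraction: float,
) -> np.ndarray:
    """Sample ``n`` ids from ``pool``, reusing about ``shared_fraction`` of a
    previous selection (emulating partially overlapping mutant phenotypes)."""
    n = min(n, pool.size)
    if previous is None or previous.size == 0:
        return rng.choice(pool, size=n, replace=False)
    prev_in_pool = np.array([g for g in previous if g in set(pool)])
    n_shared = min(int(round(shared_fraction * n)), prev_in_pool.size)
    shared = rng.choice(prev_in_pool, size=n_shared, replace=False) if n_shared else np.array([], dtype=pool.dtype)
    rest_pool = np.array([g for g in pool if g not in set(shared)])
    fresh = rng.choice(rest_pool, size=min(n - n_shared, rest_pool.size), replace=False)
    return np.concatenate([shared, fresh])


def generate_truth(
    ann: GenomeAnnotation, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimTruth:
    """Draw baseline means, planted fold changes, read-through genes and
    extension lengths, plus per-sample library size factors."""
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    ids = np.array([u.id for u in ann])
    n = ids.size
    mu = rng.lognormal(np.log(cfg.mu_median), cfg.mu_sigma, size=n)
    room = _downstream_room(ann).loc[ids].to_numpy()

    genes = pd.DataFrame(
        {
            "chrom": [u.interval.chrom for u in ann],
            "start": [u.interval.start for u in ann],
            "end": [u.interval.end for u in ann],
            "strand": [u.interval.strand for u in ann],
            "biotype": [u.biotype for u in ann],
            "mu": mu,
            "downstream_room": room,
        },
        index=pd.Index(ids, name="gene_id"),
    )

    # planted fold changes: drawn once per gene, applied where flagged
    n_de = int(round(cfg.de_fraction * n))
    sign = np.where(rng.random(n) < cfg.de_up_fraction, 1.0, -1.0)
    lfc_value = sign * cfg.de_lfc_magnitude
    prev_de = None
    for g in cfg.mutants:
        chosen = _pick_shared(rng, ids, n_de, prev_de, cfg.shared_fraction)
        flags = pd.Series(False, index=genes.index)
        flags.loc[chosen] = True
        genes[f"lfc_{g}"] = np.where(flags, lfc_value, 0.0)
        prev_de = chosen

    # planted read-throughs: only observable from expressed genes with room
    eligible = ids[(mu >= cfg.rt_min_mean) & (room >= cfg.ext_min + 10)]
    n_rt = int(round(cfg.rt_gene_fraction * n))
    prev_rt = None
    rt_any = pd.Series(False, index=genes.index)
    for g in cfg.mutants:
        chosen = _pick_shared(rng, eligible, n_rt, prev_rt, cfg.shared_fraction)
        flags = pd.Series(False, index=genes.index)
        flags.loc[chosen] = True
        genes[f"rt_{g}"] = flags
        rt_any |= flags
        prev_rt = chosen

    ext = np.zeros(n, dtype=int)
    draw = rng.geometric(1.0 / cfg.ext_mean, size=n)
    cap = np.maximum(room - 10, cfg.ext_min)
    ext_vals = np.clip(draw, cfg.ext_min, cap)
    ext[rt_any.to_numpy()] = ext_vals[rt_any.to_numpy()]
    genes["ext_len"] = ext

    samples = cfg.sample_names()
    sf = pd.Series(
        np.exp(rng.normal(0.0, cfg.size_factor_sd, size=len(samples))),
        index=samples,
        name="size_factor",
    )
    counts = pd.DataFrame(0, index=genes.index, columns=samples, dtype=int)
    return SimTruth(genes=genes, size_factors=sf, counts=counts)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _draw_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _simulate_sample_counts_and_reads(
    ann: GenomeAnnotation,
    truth: SimTruth,
    genotype: str,
    replicate: int,
    cfg: SimConfig,
) -> Tuple[pd.Series, StrandedReadSet]:
    sample = f"{genotype}_r{replicate}"
    gi = cfg.genotypes.index(genotype)
    rng = np.random.default_rng([cfg.seed, 2, gi, replicate])
    sf = float(truth.size_factors[sample])

    genes = truth.genes
    lfc = genes[f"lfc_{genotype}"].to_numpy() if genotype != cfg.reference else np.zeros(len(genes))
    rt_flags = (
        genes[f"rt_{genotype}"].to_numpy() if genotype != cfg.reference else np.zeros(len(genes), bool)
    )
    means = sf * genes["mu"].to_numpy() * np.power(2.0, lfc)
    counts = _draw_counts(rng, means, cfg.dispersion)

    rl = cfg.read_length
    chroms: List[np.ndarray] = []
    starts: List[np.ndarray] = []
    strands: List[np.ndarray] = []
    for i, u in enumerate(ann):
        c = int(counts[i])
        if c == 0:
            continue
        iv = u.interval
        # read-through fragments are *additional*: the 3'-extended transcript
        # still contains the full gene body, so gene-body coverage is
        # preserved and the extension accumulates extra signal
        n_rt = int(rng.binomial(c, cfg.rt_read_fraction)) if rt_flags[i] else 0
        n_norm = c
        c = c + n_rt
        pos = np.empty(c, dtype=np.int64)
        if n_norm:
            u_off = rng.integers(0, max(1, iv.length - rl) + 1, size=n_norm)
            pos[:n_norm] = iv.start + u_off
        if n_rt:
            ext = int(genes["ext_len"].iloc[i])
            offmax = max(1, ext - rl)
            # geometric decay of read starts along the extension
            x = np.clip(rng.geometric(min(1.0, 3.0 / max(ext, 1)), size=n_rt), 1, offmax)
            tts = u.tts
            if iv.strand == FORWARD:
                pos[n_norm:] = tts + x - 1
            else:
                pos[n_norm:] = tts - x + 1 - rl
        size = ann.chrom_sizes[iv.chrom]
        pos = np.clip(pos, 0, size - rl)
        chroms.append(np.full(c, iv.chrom, dtype=object))
        starts.append(pos)
        strands.append(np.full(c, iv.strand, dtype=object))

    if chroms:
        chrom_arr = np.concatenate(chroms)
        start_arr = np.concatenate(starts)
        strand_arr = np.concatenate(strands)
    else:
        chrom_arr = np.array([], dtype=object)
        start_arr = np.array([], dtype=np.int64)
        strand_arr = np.array([], dtype=object)
    df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "start": start_arr,
            "end": start_arr + rl,
            "name": [f"{sample}.{k}" for k in range(start_arr.size)],
            "score": 0,
            "strand": strand_arr,
        }
    )
    return (
        pd.Series(counts, index=genes.index, name=sample),
        StrandedReadSet(sample, df),
    )


def simulate_sample(
    ann: GenomeAnnotation,
    truth: SimTruth,
    genotype: str,
    replicate: int,
    cfg: SimConfig,
) -> StrandedReadSet:
    """Simulate the aligned reads of one replicate of one genotype."""
    _counts, reads = _simulate_sample_counts_and_reads(ann, truth, genotype, replicate, cfg)
    return reads


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full deterministic dataset: annotation, truth and every sample."""
    ann = generate_annotation(cfg)
    truth = generate_truth(ann, cfg)
    samples: Dict[str, StrandedReadSet] = {}
    rows = []
    for g in cfg.genotypes:
        for r in range(1, cfg.replicates + 1):
            counts, reads = _simulate_sample_counts_and_reads(ann, truth, g, r, cfg)
            truth.counts[reads.sample] = counts
            samples[reads.sample] = reads
            rows.append({"sample": reads.sample, "genotype": g, "replicate": r})
    sheet = pd.DataFrame(rows)
    return SimulatedDataset(config=cfg, annotation=ann, truth=truth, samples=samples, sample_sheet=sheet)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset as plain-text files: GFF3 annotation, chrom sizes,
    per-sample BED6 reads and per-strand bedGraph coverage, truth tables,
    sample sheet and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gff3(ds.annotation, outdir / "annotation.gff3")
    rio.write_chrom_sizes(ds.annotation.chrom_sizes, outdir / "chrom.sizes")
    ds.config.to_yaml(outdir / "config.yaml")

    sheet = ds.sample_sheet.copy()
    sheet["bed"] = [f"{s}.bed" for s in sheet["sample"]]
    rio.write_tsv(sheet, outdir / "samples.tsv")

    for sample, reads in ds.samples.items():
        reads.to_bed(outdir / f"{sample}.bed")
        cov = StrandedCoverage(ds.annotation.chrom_sizes)
        for row in reads.df.itertuples(index=False):
            cov.add_interval(row.chrom, row.start, row.end, row.strand)
        cov.to_bedgraph(outdir / f"{sample}.fwd.bedgraph", outdir / f"{sample}.rev.bedgraph")

    rio.write_tsv(ds.truth.genes, outdir / "truth_genes.tsv", index_label="gene_id")
    rio.write_tsv(ds.truth.counts, outdir / "truth_counts.tsv", index_label="gene_id")
    rio.write_tsv(
        ds.truth.size_factors.to_frame(), outdir / "truth_size_factors.tsv", index_label="sample"
    )


def load_dataset(indir) -> SimulatedDataset:
    """Read a written dataset back (lossless round trip for fixed seeds)."""
    indir = Path(indir)
    cfg = SimConfig.from_yaml(indir / "config.yaml")
    sizes = rio.read_chrom_sizes(indir / "chrom.sizes")
    ann = read_gff3(indir / "annotation.gff3", chrom_sizes=sizes)
    sheet = rio.read_tsv(indir / "samples.tsv")
    samples = {
        row["sample"]: StrandedReadSet.from_bed(row["sample"], indir / row["bed"])
        for _, row in sheet.iterrows()
    }
    genes = rio.read_tsv(indir / "truth_genes.tsv", index_col=0)
    counts = rio.read_tsv(indir / "truth_counts.tsv", index_col=0)
    sf = rio.read_tsv(indir / "truth_size_factors.tsv", index_col=0)["size_factor"]
    truth = SimTruth(genes=genes, size_factors=sf, counts=counts)
    return SimulatedDataset(
        config=cfg,
        annotation=ann,
        truth=truth,
        samples=samples,
        sample_sheet=sheet[["sample", "genotype", "replicate"]],
    )
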