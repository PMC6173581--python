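"""End-to-end orchestration: simulate -> peaks -> read-through consensus ->
quantification -> differential tests -> comparison report.

Each stage writes plain-text files into the output directory, so any stage
can be re-run from (or replaced by) external files.  All randomness derives
from one seed; fixed-seed runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import io as rio
from .annotation import GenomeAnnotation, Interval, strand_complement, STRANDS
from .detect import (
    ReadthroughCall,
    calls_to_bed,
    filter_peaks_by_tts,
    merge_genotype_annotations,
    replicate_consensus,
    subtract_annotated,
    write_readthrough_gff3,
)
from .diffexpr import NBDifferentialExpression
from .peaks import Peak, PeakParams, call_peaks, coverage_from_reads
from .quantify import UNASSIGNED, build_tables
from .reads import StrandedReadSet
from .setstats import summarise_comparison
from .simulate import SimConfig, SimulatedDataset, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with the pipeline's standard defaults: 50 nt
    reads, a two-read-length TTS filter, >= 2 of 3 replicate support, DE
    thresholds |log2FC| > 0.5 at FDR <= 0.05, and the broad-peak scan
    parameters."""

    sim: SimConfig = field(default_factory=SimConfig)
    peaks: PeakParams = field(default_factory=PeakParams)
    min_support: int = 2
    lfc_threshold: float = 0.5
    alpha: float = 0.05

    @property
    def read_length(self) -> int:
        return self.sim.read_length

    @property
    def contrasts(self) -> List[Tuple[str, str]]:
        return [(m, self.sim.reference) for m in self.sim.mutants]

    def to_yaml(self, path) -> None:
        import yaml

        d = {
            "sim": {**dataclasses.asdict(self.sim), "genotypes": list(self.sim.genotypes)},
            "peaks": dataclasses.asdict(self.peaks),
            "min_support": self.min_support,
            "lfc_threshold": self.lfc_threshold,
            "alpha": self.alpha,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.get("sim", {})
        if "genotypes" in sim:
            sim["genotypes"] = tuple(sim["genotypes"])
        return cls(
            sim=SimConfig(**sim),
            peaks=PeakParams(**d.get("peaks", {})),
            min_support=d.get("min_support", 2),
            lfc_threshold=d.get("lfc_threshold", 0.5),
            alpha=d.get("alpha", 0.05),
        )


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    config: PipelineConfig
    dataset: SimulatedDataset
    per_replicate_peaks: Dict[str, List[Peak]]
    consensus: Dict[str, List[ReadthroughCall]]
    merged_rt: List[ReadthroughCall]
    counts_tx: "pd.DataFrame"
    counts_rt: "pd.DataFrame"
    de_results: Dict[str, "pd.DataFrame"]
    rt_results: Dict[str, "pd.DataFrame"]
    report_text: Optional[str]
    outdir: Path

    def rt_present(self, genotype: str) -> List[str]:
        """Genes whose read-through the presence test declares in ``genotype``."""
        tab = self.rt_results[genotype]
        return [f[:-3] for f in tab.index[tab["call"] == "up"]]

    def rt_detected(self, genotype: str) -> List[str]:
        return [c.gene_id for c in self.consensus[genotype]]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def detect_readthroughs_for_genotype(
    ds: SimulatedDataset,
    genotype: str,
    params: PeakParams,
    min_support: int,
    read_length: int,
    regions: Optional[Sequence[Interval]] = None,
) -> Tuple[Dict[str, List[Peak]], List[ReadthroughCall]]:
    """Per-replicate peak calling + TTS filtering + replicate consensus for
    one genotype."""
    ann = ds.annotation
    if regions is None:
        regions = strand_complement(ann, "+") + strand_complement(ann, "-")
    per_rep_peaks: Dict[str, List[Peak]] = {}
    per_rep_calls = []
    sheet = ds.sample_sheet
    for sample in sheet.loc[sheet["genotype"] == genotype, "sample"]:
        reads = ds.samples[sample]
        intergenic = subtract_annotated(reads, ann)
        cov = coverage_from_reads(intergenic, ann.chrom_sizes, params.l_frag)
        peaks = call_peaks(cov, regions, params, sample=sample)
        per_rep_peaks[sample] = peaks
        per_rep_calls.append(filter_peaks_by_tts(peaks, ann, read_length))
    consensus = replicate_consensus(per_rep_calls, ann, min_support=min_support, genotype=genotype)
    return per_rep_peaks, consensus


def run_pipeline(
    cfg: PipelineConfig,
    outdir,
    seed: Optional[int] = None,
    write_plots: bool = False,
) -> PipelineResult:
    """Run every stage on a synthetic dataset and write all outputs.

    ``seed`` overrides the simulation seed in the config.  Outputs: the
    dataset under ``data/``, per-replicate peak BEDs, per-genotype and merged
    read-through annotations (BED + GFF3), both count tables, DE and
    read-through presence tables per contrast, a comparison report, and a
    machine-readable run manifest.
    """
    if seed is not None:
        cfg = dataclasses.replace(cfg, sim=dataclasses.replace(cfg.sim, seed=seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: seed=%d", cfg.sim.seed)
    ds = simulate_dataset(cfg.sim)
    write_dataset(ds, outdir / "data")
    ann = ds.annotation

    regions = strand_complement(ann, "+") + strand_complement(ann, "-")
    per_replicate_peaks: Dict[str, List[Peak]] = {}
    consensus: Dict[str, List[ReadthroughCall]] = {}
    for genotype in cfg.sim.mutants:
        logger.info("stage callpeaks/readthrough: genotype=%s", genotype)
        rep_peaks, cons = detect_readthroughs_for_genotype(
            ds, genotype, cfg.peaks, cfg.min_support, cfg.read_length, regions
        )
        per_replicate_peaks.update(rep_peaks)
        consensus[genotype] = cons
        for sample, peaks in rep_peaks.items():
            rio.write_bed(
                rio.intervals_to_bed(
                    [p.interval for p in peaks],
                    names=[f"peak{k}" for k in range(len(peaks))],
                    scores=[f"{p.score:.3f}" for p in peaks],
                ),
                outdir / f"peaks_{sample}.bed",
            )
        rio.write_bed(calls_to_bed(cons), outdir / f"readthrough_{genotype}.bed")
        write_readthrough_gff3(cons, ann, outdir / f"readthrough_{genotype}.gff3")

    merged_rt: List[ReadthroughCall] = []
    for genotype in cfg.sim.mutants:
        merged_rt = merge_genotype_annotations(merged_rt, consensus[genotype])
    rio.write_bed(calls_to_bed(merged_rt), outdir / "readthrough_merged.bed")
    write_readthrough_gff3(merged_rt, ann, outdir / "readthrough_merged.gff3")

    # quantification assigns the reads themselves (no 3' fragment extension):
    # a read wholly within an unannotated extension carries no transcript
    # sequence and must not be attributed to the downstream gene
    logger.info("stage quantify: %d read-through features", len(merged_rt))
    table_tx, table_rt = build_tables(ds.samples, ann, merged_rt, l_frag=cfg.read_length)
    table_tx.to_tsv(outdir / "counts_transcripts.tsv")
    table_rt.to_tsv(outdir / "counts_transcripts_plus_rt.tsv")

    conditions = pd.Series(
        ds.sample_sheet["genotype"].to_numpy(), index=ds.sample_sheet["sample"].to_numpy()
    )
    de_results: Dict[str, pd.DataFrame] = {}
    rt_results: Dict[str, pd.DataFrame] = {}
    rt_features = [f"{c.gene_id}_RT" for c in merged_rt]
    for mutant, ref in cfg.contrasts:
        logger.info("stage test: %s vs %s", mutant, ref)
        model = NBDifferentialExpression(
            table_tx.features,
            conditions,
            (mutant, ref),
            lfc_threshold=cfg.lfc_threshold,
            alpha=cfg.alpha,
        )
        res = model.fit()
        res.to_tsv(outdir / f"de_{mutant}_vs_{ref}.tsv")
        de_results[mutant] = res.table
        if write_plots:
            res.plot_volcano(outdir / f"volcano_{mutant}_vs_{ref}.png")
        if rt_features:
            rt_model = NBDifferentialExpression(
                table_rt.features,
                conditions,
                (mutant, ref),
                lfc_threshold=0.0,
                alternative="greater",
                alpha=cfg.alpha,
                test_features=rt_features,
            )
            rt_res = rt_model.fit()
            rt_res.to_tsv(outdir / f"rt_presence_{mutant}_vs_{ref}.tsv")
            rt_results[mutant] = rt_res.table
        else:
            rt_results[mutant] = pd.DataFrame(
                columns=["baseMean", "log2FoldChange", "lfcSE", "pvalue", "padj", "call"]
            )

    report_text = None
    if len(cfg.sim.mutants) >= 2:
        a, b = cfg.sim.mutants[0], cfg.sim.mutants[1]
        rt_a = [f[:-3] for f in rt_results[a].index[rt_results[a]["call"] == "up"]]
        rt_b = [f[:-3] for f in rt_results[b].index[rt_results[b]["call"] == "up"]]
        report = summarise_comparison(
            de_results[a], de_results[b], rt_a, rt_b, ann, genotype_a=a, genotype_b=b
        )
        report_text = report.to_text()
        (outdir / "report.txt").write_text(report_text + "\n")
        rio.write_tsv(report.to_frame(), outdir / "report.tsv", index_label="quantity")

    manifest = {
        "package": "readthrough",
        "version": __version__,
        "seed": cfg.sim.seed,
        "parameters": {
            "peaks": dataclasses.asdict(cfg.peaks),
            "min_support": cfg.min_support,
            "lfc_threshold": cfg.lfc_threshold,
            "alpha": cfg.alpha,
            "sim": {**dataclasses.asdict(cfg.sim), "genotypes": list(cfg.sim.genotypes)},
        },
        "inputs": {
            p.name: _sha256(p) for p in sorted((outdir / "data").glob("*")) if p.is_file()
        },
        "outputs": sorted(p.name for p in outdir.glob("*") if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config=cfg,
        dataset=ds,
        per_replicate_peaks=per_replicate_peaks,
        consensus=consensus,
        merged_rt=merged_rt,
        counts_tx=table_tx.features,
        counts_rt=table_rt.features,
        de_results=de_results,
        rt_results=rt_results,
        report_text=report_text,
        outdir=outdir,
    )


# ---------------------------------------------------------------------------
# truth-aware evaluation (recovery harness)
# ---------------------------------------------------------------------------

def evaluate_against_truth(result: PipelineResult) -> pd.DataFrame:
    """Sensitivity/precision of read-through detection and observed FDR /
    sensitivity of the DE calls, per mutant genotype, against the simulation
    ground truth."""
    ds = result.dataset
    rows = {}
    for genotype in result.config.sim.mutants:
        true_rt = set(ds.truth.rt_genes(genotype))
        detected = set(result.rt_detected(genotype))
        present = set(result.rt_present(genotype))
        tp = len(detected & true_rt)
        rows[f"rt_sensitivity_{genotype}"] = tp / len(true_rt) if true_rt else np.nan
        rows[f"rt_precision_{genotype}"] = tp / len(detected) if detected else np.nan
        tp_p = len(present & true_rt)
        rows[f"rt_present_sensitivity_{genotype}"] = tp_p / len(true_rt) if true_rt else np.nan
        rows[f"rt_present_precision_{genotype}"] = tp_p / len(present) if present else np.nan

        true_up, true_down = ds.truth.de_genes(genotype)
        true_de = set(true_up) | set(true_down)
        tab = result.de_results[genotype]
        called = set(tab.index[tab["call"] != "ns"])
        fp = len(called - true_de)
        rows[f"de_fdr_{genotype}"] = fp / len(called) if called else 0.0
        rows[f"de_sensitivity_{genotype}"] = (
            len(called & true_de) / len(true_de) if true_de else np.nan
        )
    return pd.DataFrame({"value": rows})
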