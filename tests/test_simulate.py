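"""Synthetic-data generator: determinism, design parameters, NB marginals,
planted read-through geometry, dataset round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from readthrough import io as rio
from readthrough.annotation import classify_orientation
from readthrough.reads import StrandedCoverage
from readthrough.simulate import (
    SimConfig,
    SimulatedDataset,
    generate_annotation,
    generate_truth,
    load_dataset,
    simulate_dataset,
    simulate_sample,
    write_dataset,
)

SMALL = SimConfig(seed=7, n_chroms=1, chrom_length=120_000, n_genes=40)


class TestGenerateAnnotation:
    def test_single_gene_inside_bounds(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=10_000, n_genes=1)
        ann = generate_annotation(cfg)
        assert len(ann) == 1
        u = ann.units[0]
        assert 0 <= u.interval.start < u.interval.end <= 10_000

    def test_deterministic_for_fixed_seed(self):
        a = generate_annotation(SMALL)
        b = generate_annotation(SMALL)
        assert [(u.id, u.biotype, u.interval) for u in a] == [
            (u.id, u.biotype, u.interval) for u in b
        ]

    def test_genes_never_overlap_and_respect_min_gap(self):
        ann = generate_annotation(SMALL)
        for chrom in ann.chrom_sizes:
            units = ann.units_on(chrom=chrom)
            for prev, nxt in zip(units, units[1:]):
                assert nxt.interval.start - prev.interval.end >= SMALL.min_gap

    def test_ncrna_fraction_within_binomial_bounds(self):
        cfg = SimConfig(seed=3, n_chroms=4, chrom_length=800_000, n_genes=1000)
        ann = generate_annotation(cfg)
        n_nc = sum(u.biotype == "ncRNA" for u in ann)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.22)
        assert lo <= n_nc <= hi

    def test_orientation_mix_present(self):
        labels = set(classify_orientation(generate_annotation(SMALL)).values())
        assert {"convergent", "tandem"} <= labels

    def test_infeasible_packing_errors(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=5_000, n_genes=50)
        with pytest.raises(ValueError, match="infeasible"):
            generate_annotation(cfg)


class TestGenerateTruth:
    def test_extension_never_reaches_next_same_strand_gene(self):
        ann = generate_annotation(SMALL)
        truth = generate_truth(ann, SMALL)
        genes = truth.genes
        rt = genes[genes[["rt_cut14", "rt_rrp6"]].any(axis=1)]
        assert len(rt) > 0
        assert (rt["ext_len"] < rt["downstream_room"]).all()
        assert (genes.loc[~genes[["rt_cut14", "rt_rrp6"]].any(axis=1), "ext_len"] == 0).all()

    def test_rt_genes_are_expressed(self):
        ann = generate_annotation(SMALL)
        truth = generate_truth(ann, SMALL)
        rt = truth.genes[truth.genes["rt_cut14"]]
        assert (rt["mu"] >= SMALL.rt_min_mean).all()

    def test_planted_lfc_magnitude(self):
        ann = generate_annotation(SMALL)
        truth = generate_truth(ann, SMALL)
        for g in ("cut14", "rrp6"):
            lfc = truth.genes[f"lfc_{g}"]
            assert set(np.abs(lfc[lfc != 0])) == {SMALL.de_lfc_magnitude}


class TestSimulateSample:
    def test_zero_mean_gene_yields_zero_reads(self):
        cfg = SimConfig(seed=5, n_chroms=1, chrom_length=60_000, n_genes=10)
        ann = generate_annotation(cfg)
        truth = generate_truth(ann, cfg)
        truth.genes.loc[:, "mu"] = 0.0
        reads = simulate_sample(ann, truth, "wt", 1, cfg)
        assert len(reads) == 0

    def test_nb_mean_recovered_over_replicates(self):
        """Mean count over 200 NB draws is within 3 SE of the planted mean."""
        cfg = SimConfig(seed=11, n_chroms=1, chrom_length=60_000, n_genes=10,
                        replicates=200, size_factor_sd=0.0, de_fraction=0.0,
                        rt_gene_fraction=0.0)
        ann = generate_annotation(cfg)
        truth = generate_truth(ann, cfg)
        from readthrough.simulate import _simulate_sample_counts_and_reads

        mats = []
        for r in range(1, 201):
            c, _ = _simulate_sample_counts_and_reads(ann, truth, "wt", r, cfg)
            mats.append(c.to_numpy())
        mat = np.stack(mats)
        mu = truth.genes["mu"].to_numpy()
        se = np.sqrt((mu + cfg.dispersion * mu**2) / 200)
        assert (np.abs(mat.mean(axis=0) - mu) <= 3 * se + 1e-9).all()

    def test_nb_variance_matches_dispersion(self):
        """Sample variance tracks mu + alpha mu^2 for high-mean genes."""
        cfg = SimConfig(seed=13, n_chroms=1, chrom_length=60_000, n_genes=10,
                        replicates=200, size_factor_sd=0.0, de_fraction=0.0,
                        rt_gene_fraction=0.0, mu_median=500.0, mu_sigma=0.2)
        ann = generate_annotation(cfg)
        truth = generate_truth(ann, cfg)
        from readthrough.simulate import _simulate_sample_counts_and_reads

        mat = np.stack(
            [
                _simulate_sample_counts_and_reads(ann, truth, "wt", r, cfg)[0].to_numpy()
                for r in range(1, 201)
            ]
        )
        mu = truth.genes["mu"].to_numpy()
        expected = mu + cfg.dispersion * mu**2
        observed = mat.var(axis=0, ddof=1)
        # chi2-based Monte-Carlo band on the variance ratio at n=200
        assert (observed / expected > 0.6).all() and (observed / expected < 1.6).all()

    def test_rt_fraction_one_puts_every_extra_fragment_past_tts(self):
        cfg = SimConfig(seed=17, n_chroms=1, chrom_length=60_000, n_genes=10,
                        rt_gene_fraction=1.0, rt_read_fraction=1.0, rt_min_mean=0.0)
        ann = generate_annotation(cfg)
        truth = generate_truth(ann, cfg)
        reads = simulate_sample(ann, truth, "cut14", 1, cfg)
        rt_ids = set(truth.rt_genes("cut14"))
        assert rt_ids  # some genes were eligible
        # fragments (reads extended to l_frag) of rt genes: 3' end past the TTS
        for u in ann:
            if u.id not in rt_ids:
                continue
            iv = u.interval
            sub = reads.df[(reads.df["chrom"] == iv.chrom) & (reads.df["strand"] == iv.strand)]
            if iv.strand == "+":
                in_ext = sub[sub["start"] >= iv.end]
                frag_3p = in_ext["start"] + cfg.l_frag
                assert (frag_3p > u.tts).all()
            else:
                in_ext = sub[sub["end"] <= iv.start]
                frag_3p = in_ext["end"] - cfg.l_frag
                assert (frag_3p < u.tts).all()

    def test_wt_reads_stay_inside_genes(self):
        ann = generate_annotation(SMALL)
        truth = generate_truth(ann, SMALL)
        reads = simulate_sample(ann, truth, "wt", 2, SMALL)
        for row in reads.df.itertuples(index=False):
            assert any(
                u.interval.start <= row.start and row.end <= u.interval.end
                for u in ann.units_on(chrom=row.chrom, strand=row.strand)
            )


class TestDatasetRoundTrip:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=23, n_chroms=1, chrom_length=80_000, n_genes=20)
        write_dataset(simulate_dataset(cfg), tmp_path / "a")
        write_dataset(simulate_dataset(cfg), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_write_load_round_trip(self, tmp_path):
        cfg = SimConfig(seed=23, n_chroms=1, chrom_length=80_000, n_genes=20)
        ds = simulate_dataset(cfg)
        write_dataset(ds, tmp_path / "d")
        back = load_dataset(tmp_path / "d")
        assert back.config == cfg
        assert len(back.annotation) == len(ds.annotation)
        for sid, reads in ds.samples.items():
            pd.testing.assert_frame_equal(
                back.samples[sid].df[["chrom", "start", "end", "strand"]],
                reads.df[["chrom", "start", "end", "strand"]],
            )

    def test_sample_sheet_covers_design(self, tmp_path):
        cfg = SimConfig(seed=23, n_chroms=1, chrom_length=80_000, n_genes=20)
        ds = simulate_dataset(cfg)
        assert len(ds.sample_sheet) == len(cfg.genotypes) * cfg.replicates
        assert set(ds.sample_sheet["genotype"]) == set(cfg.genotypes)

    def test_bedgraph_matches_read_recount(self, tmp_path):
        cfg = SimConfig(seed=29, n_chroms=1, chrom_length=80_000, n_genes=20)
        ds = simulate_dataset(cfg)
        write_dataset(ds, tmp_path / "d")
        sample = "cut14_r1"
        cov = StrandedCoverage.from_bedgraph(
            tmp_path / "d" / f"{sample}.fwd.bedgraph",
            tmp_path / "d" / f"{sample}.rev.bedgraph",
            ds.annotation.chrom_sizes,
        )
        for strand in "+-":
            dense = np.zeros(cfg.chrom_length)
            starts, ends = ds.samples[sample].on("chr1", strand)
            for s, e in zip(starts, ends):
                dense[s:e] += 1
            assert np.array_equal(cov.get("chr1", strand), dense)
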