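# Methods

This note documents the models, parameter choices and known limitations of
the `readthrough` package: what each stage assumes, why the defaults are
what they are, and what the synthetic benchmark does and does not show.

## Coordinate and annotation model

All coordinates are 0-based half-open (BED convention); GFF3 I/O converts
from the 1-based closed convention. Transcription units are single stranded
intervals — no exon structure — because read-through detection only needs
each unit's span and its TTS (the 3' boundary: `end` on the forward strand,
`start` on the reverse). Overlapping same-strand units are merged only when
computing the strand-specific complement (the searched intergenic space);
they stay distinct everywhere else.

**Orientation classes.** Each gene is labelled by the strand of its nearest
*downstream* neighbour — the nearest unit extending past the gene's 3' end
in its direction of transcription, by gap distance, with overlapping
neighbours at gap 0 and ties broken by smaller start then id. An
opposite-strand downstream neighbour faces the gene's 3' end, so the label
is *convergent*; a same-strand neighbour gives *tandem*; genes with no
downstream neighbour on their chromosome are *isolated*. Under this rule a
"divergent" label cannot arise (divergence is an upstream-neighbour
notion); the class is kept in the reporting vocabulary for completeness and
always counts zero. Published convergent/tandem tallies depend on the exact
convention, which is rarely stated; counts from other conventions
(pairwise, overlap-aware) will differ.

## Peak calling

The detector is a multiscale sliding-window Poisson scan, parameterised
like the multiscale broad-peak callers commonly applied to this data
(smallest window `begin_l` = 50, largest `end_l` = 500, geometric step 1.1,
fragment extension `l_frag` = 363, read length `l_mapp` = 50 recorded for
bookkeeping, q-value cutoff 1.0, fold-change gate 2.0). Reads are extended
to `l_frag` bases in their 3' direction before computing coverage. For each
window length the stride is half the window; a window is a candidate when
its count is at least `min_fold_change × λ·l`, where λ is the per-strand
background rate over the searched regions (total coverage / total length,
floored at 1/total-length so an empty background cannot produce a zero
rate). Candidate windows receive Poisson upper-tail p-values at mean λ·l,
are BH-corrected jointly across all scales and regions, filtered at
`q_threshold` (1.0 disables the filter, leaving the fold-change gate as the
only criterion), and merged into maximal peaks scored by the best window's
−log10 p. No mappability correction is applied. Median-filter multiscale
decomposition, as used by some broad-peak callers, is deliberately not
reproduced: the downstream TTS-distance and replicate-consensus filters
dominate specificity, and the windowed Poisson scan recovers ≥ 95% of
planted ≥5×-background blocks with exactly one peak each (tested).

## Read-through calling

Filters applied in order: (i) reads overlapping a same-strand annotated
unit are removed before peak calling (strand-specific protocol, so
antisense overlap does not remove a read); (ii) peaks must start within two
read lengths (2 × 50 = 100 bases, **inclusive** — the stated rule excludes
peaks *more than* two read lengths away) of the nearest same-strand TTS at
or upstream of the peak's 5' boundary; (iii) peaks reaching into a
downstream same-strand unit are truncated at its near boundary, and dropped
when nothing remains; (iv) a gene's read-through is accepted when peaks
assigned to it (by gene id, which is robust to peak-boundary jitter across
replicates) occur in at least `min_support` = 2 of the 3 replicates, with
the consensus extension running from the TTS to the median over supporting
replicates of each replicate's farthest boundary. Detection runs per
genotype; the per-genotype annotations are merged (union span per gene) to
give a common feature set for cross-genotype quantification.

## Quantification

Each read is assigned to the same-strand feature with maximal overlap; ties
break to the feature whose 5' end is nearest the read's 5' end, and
still-tied reads join the `__unassigned__` audit row (counts are conserved:
assigned + unassigned = total). `count_fragments` accepts an `l_frag`
extension for fragment-level counting; the pipeline deliberately counts the
**un-extended reads** (`l_frag` = read length): a 50 nt read lying wholly
within an unannotated extension carries no transcript sequence and would
never be attributed to the downstream gene by a sequence-based quantifier,
whereas extending it by 313 bases would push it into that gene and inflate
the neighbour's counts exactly when a read-through is present. Two tables
are built — transcripts alone, and transcripts plus `<gene>_RT` extension
features — mirroring the two quantification passes of the analysis design.
No TPM or effective-length normalisation is applied; depth is handled by
size factors downstream.

## Differential expression

A two-group negative-binomial model: K_ij ~ NB(mean s_j·q_i(c_j),
dispersion α_i), with

- **size factors** s_j by median-of-ratios over features positive in all
  samples, rescaled to geometric mean 1;
- **dispersion** α_i by method of moments on normalised counts,
  (s² − μ)/μ² per condition averaged over conditions, floored at 1e-8.
  By default per-feature estimates are additionally floored at the
  across-feature median ("median-floor shrinkage"): with three replicates
  the raw moment estimator underestimates the variance often enough that a
  handful of features per thousand acquire inflated Wald statistics;
  flooring at the trend median restores type-I control at a small cost in
  power for genuinely low-dispersion features (`shrink=False` recovers the
  raw estimator);
- **thresholded Wald test**: β̂ = log2(μ̂_mut/μ̂_ref) from the normalised
  group means, SE by the delta method under the NB variance function;
  two-sided p = 2·Φ̄((|β̂|−θ)/SE) when |β̂| > θ, else 1, with θ = 0.5 for
  transcript calls; the read-through presence test is one-sided at θ = 0.
  When one group's mean is zero, a continuity floor of half a normalised
  count enters the mean and variance; features at zero in both groups are
  reported with p = 1 and flagged by baseMean = 0. P-values are BH-adjusted
  within each analysis (transcript tests and read-through presence tests
  are separate families), and calls use strict fold-change inequalities
  with padj ≤ 0.05 inclusive.

This is not a reimplementation of a full count-model framework: GLM fitting
with shrinkage priors, Cook's-distance outlier handling and independent
filtering are out of scope, and results on real data will differ in detail
from such tools even though the calling rule (thresholded Wald + BH at the
same thresholds) is the same. The presence test is applied to the `_RT`
extension features as their own rows (not to concatenated
transcript+extension counts); this choice is configurable by constructing
the count table differently.

**Power under the default benchmark.** With three replicates, dispersion
0.05 and planted |log2FC| = 1, a θ = 0.5 threshold test has little power:
the Wald z for a typical gene is ((1 − 0.5)/≈0.28) ≈ 1.8 before multiplicity
correction, so most analyses call few or no transcripts. This is a property
of the study conditions, not a defect: the acceptance metric for DE is the
observed FDR of whatever is called (≤ 0.1 pooled over ten seeds; measured
0.0), and the separate power benchmark (log2FC = 2 at μ = 500, dispersion
0.01) detects ≥ 95% (measured 100%).

## Synthetic data generator

The generator emulates the study design the pipeline targets: three biological
replicates per genotype (wild type plus two mutants), 50 nt single-end
stranded reads from a fragment library of mean 363.4 / sd 85.5 (the
fragment-length figures enter as the peak-caller's `l_frag` extension and
the library model), gene-level NB counts with dispersion 0.05 around
log-normal baseline means, and an ncRNA fraction of 0.22.

Desk-scale genome defaults, chosen once: 2 chromosomes × 300 kb, 250
non-overlapping genes (log-normal lengths, median 1.3 kb), minimum
intergenic gap 200 bases with the remaining space spread by a Dirichlet
draw (packing always succeeds when the minimum footprint fits, and errors
otherwise), random strands, baseline means log-normal with median 120 and
σ = 1, per-sample depth factors log-normal with σ = 0.1.

Planted truth per mutant genotype: 10% of genes receive a true log2FC of
±1 (80% up, emulating predominantly increased transcript levels in these
backgrounds); 10% of genes become read-through genes, restricted to
eligible genes (baseline mean ≥ 50 and enough same-strand downstream room)
because read-throughs are only observable from expressed genes; extension
lengths are truncated-geometric with mean 300 nt, capped short of the next
same-strand gene; the second mutant shares about half of each planted set
with the first, emulating the partially overlapping phenotypes such
experiments report. Read-through reads are **additional** to the gene-body
reads (expected extra reads per gene-body read = `rt_read_fraction` = 0.5):
a 3'-extended transcript still contains its full gene body, so gene-body
coverage is preserved and the extension accumulates extra signal; read
starts along the extension decay geometrically, emulating the decaying 3'
tails seen in coverage profiles. Everything derives from a single seed;
fixed-seed datasets are byte-identical.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: no sequence (no mappability artefacts,
multimapping, or GC bias), no gene-length or positional coverage bias, no
exon structure or overlapping transcription, clean wild-type backgrounds
with zero intergenic noise reads outside planted extensions, and NB counts
with a single shared dispersion rather than a fitted mean–dispersion trend.
Recovery at sensitivity/precision 1.0 on this benchmark bounds
implementation correctness, not real-data performance.

## Numerical and degenerate-input choices

- BH adjustment is an exact step-up (mergesort ties), verified against a
  literal implementation and an external one on random vectors.
- Poisson survival p-values of value 0 map to a peak score of 350
  (−log10 of the smallest positive double is ≈ 323).
- Window ladders deduplicate rounded lengths; the right-flush window is
  always scanned so region ends are covered.
- Consensus far boundaries use the median (rounded to integer); with two
  supporting replicates this is the midpoint.
- `estimate_background` refuses strands with no searched regions;
  `replicate_consensus` refuses `min_support` larger than the number of
  replicate sets; hypergeometric and chi-square helpers validate their
  argument consistency rather than returning NaN.
- Merging read-through annotations across genotypes validates that both
  sets agree on each gene's TTS, which catches accidental cross-genome
  merges.

## Known limitations

- Two-group contrasts only; no multi-factor designs.
- No 5'-extension or internal aberrant-transcript detection.
- The peak caller's `l_p` -style internal significance modes of the
  original multiscale tools are not reproduced; `l_mapp` is recorded but
  unused (no mappability model).
- Orientation analysis of a real genome depends on the labelling
  convention (above); the packaged convention is one reasonable choice.
- On deeply sequenced real data the Poisson background model is
  overdispersed; the fold-change gate and replicate consensus compensate,
  but λ should then be interpreted as a lower bound on noise.
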