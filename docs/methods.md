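# Methods

This package extracts four genome-wide feature modalities from fragment-level
cell-free DNA (cfDNA) whole-methylome sequencing data, combines them into a
single cancer-detection probability, and localizes the tissue of a detected
cancer signal. This note records the models, the defaults and why they were
chosen, what the synthetic cohort generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Fragment model

A *fragment* is one plasma DNA molecule, reconstructed from a proper read
pair: its span is the outer mate distance (template semantics, so size gates
act on molecule length), its mapping quality is the minimum over mates, and
its methylation record is the aggregate of per-read methylation call strings
(`Z`/`z` methylated/unmethylated CpG, `X/H` vs `x/h` unconverted/converted
non-CpG cytosine). Where mates overlap, the leftmost mate's calls win — the
reader reproduces the effect of upstream overlap clipping so no base is
counted twice. Reads that are secondary, supplementary, duplicate-flagged,
unpaired or discordant are skipped and tallied. The 5′ end motif on the
Crick strand is taken from the *reference* sequence (the reverse complement
of the four reference bases ending at the fragment's right coordinate)
rather than from read bases, so enzymatic conversion cannot distort the
motif alphabet.

All coordinates are 0-based half-open; SAM input is converted at the reader
boundary.

## The four modalities

**MFR (methylated fragment ratio).** Autosomes are tiled into adjacent
1-Mb windows (terminal partial tiles dropped; tiles overlapping any
exclusion interval by ≥1 bp dropped). A fragment qualifies when it covers
≥3 CpGs, its length lies in [80, 250] bp, and its non-CpG conversion
exceeds 95% (a fragment with no non-CpG observation passes — absence of
evidence of conversion failure). Per window, MFR is the fraction of
qualifying fragments whose observed CpGs are *all* methylated. Tumor
genomes are globally hypomethylated, so MFR falls with tumor burden.

**FSI (fragment size index).** Fragments of 100–166 bp count as short,
169–240 bp as long (bounds inclusive; 167–168 bp are deliberately in
neither class). Per 100-kb bin the short/long count ratio is computed with
a +1 pseudocount on both counts (bounded bias, vanishes at realistic
depth), GC-corrected (below), averaged over the 50 bins of each 5-Mb
window, and z-scored across the genome per sample (mean 0, sd 1). A 5-Mb
terminal group is kept iff it holds ≥50% of the nominal bin complement.

**CAFF / PA score.** Coverage is restricted to fragments <151 bp or
>220 bp — the size classes enriched for tumor-derived molecules — binned at
100 kb by fragment midpoint, GC-corrected, filtered against the healthy
baseline (below), normalized to the genome-wide retained total (so depth
and global size-distribution shifts cancel), and summed per chromosome
arm. Each arm total is z-scored against the baseline cohort's arm totals,
and the plasma aneuploidy (PA) score is the sum of |z| over the five most
extreme arms (per sample; ties broken by arm label). The ensemble consumes
log10(PA + 1); the +1 keeps PA values below 1 finite on the log scale.

**FEM (fragment end motif).** For fragments shorter than 171 bp with a
known Crick 5′ end motif, the frequency vector over the 256 possible
4-mers. The vector sums to 1 whenever any motif is observed.

## GC correction and bin filtering

Coverage (and FSI ratio) bias in GC is removed by LOESS: a locally
weighted regression of the per-bin value on bin GC fraction (span 0.75,
fit over unmasked bins), with the corrected value defined as residual plus
the unmasked mean. The residuals are recentred exactly, so the unmasked
mean is preserved to machine precision regardless of the smoother's
internals. The smoother is locally *linear* (the `statsmodels` lowess);
the correction's cited ancestry specifies no polynomial degree, and at
span 0.75 over ~300–26,000 bins the degree is immaterial next to the
recentring contract.

Unstable bins are removed using the healthy training samples ("baseline"):
per bin, z-scores across the baseline cohort; a bin is dropped when
|z| > 2 in more than ~17% of baseline samples (the published absolute
count, 60 of 352, generalized to a fraction so small cohorts behave
sensibly; the absolute count remains available as an override), or
|z| > 4 in any sample, or the bin's baseline variance is zero, or raw
coverage exceeded 100 while GC-corrected coverage was ≤0. Baseline
statistics are pooled (not leave-one-out) for baseline samples themselves.

## Detection models

Each of MFR, FSI and FEM gets a *base model*: 10 bootstraps of the
training cohort, each a stratified 70/30 split (stratification prevents
single-class folds in small cohorts). Per bootstrap, PCA is fit on the
70% fold and the smallest number of components explaining ≥95% (MFR),
≥90% (FSI) or ≥95% (FEM) of its variance is kept; a support-vector
machine (MFR, FSI; cost ∈ {0.1, 1, 10, 100} × {RBF, linear} kernels) or a
logistic regression (FEM; C ∈ {0.01 … 100}) is selected by tenfold
cross-validated AUC. SVM decision values are mapped to probabilities by
cross-validated sigmoid (Platt) calibration fit on out-of-fold decision
values (3 calibration folds). A sample's base score is the
mean probability over the 10 sub-models; training-cohort samples are
scored out-of-fold (mean over the sub-models in whose 30% validation fold
they fell) to limit leakage into the ensemble.

The ensemble is a logistic regression with elastic-net penalty over
(MFR score, FSI score, log10 PA, FEM score), with mixing parameter
∈ {0, 0.25, 0.5, 0.75, 1} and 20 penalty strengths chosen by 20-fold
cross-validated deviance (folds reduced with a warning when the minority
class is smaller). Inputs are standardized internally and coefficients
returned on the original scale; when every input is constant the model
degenerates explicitly to the prevalence-only intercept (the saga solver
mis-converges on all-zero design matrices). The published
fixed-coefficient model

    Z = 0.57 + 0.33·MFR + 0.34·FSI + 0.06·CAFF + 0.58·FEM
    Pr(cancer) = exp(Z) / (1 + exp(Z))

ships as `themis.models.PUBLISHED_ENSEMBLE` and is evaluated exactly.

## Cancer signal origin

Over 18 clusters of tissue-specific 500-bp accessible-chromatin (ATAC)
peaks, three per-cluster quantities are computed per sample: mean
methylation of cancer-hypomethylated peaks (peaks retained by a one-sided
rank-sum test, cancer < healthy, p < 0.05, on the training cohort; the
same retained subset is used for healthy baselines), and aggregate short-
and long-fragment counts within peak regions (normalized by the sample's
total fragment count for depth robustness). Fragment-to-peak attribution
uses the fragment midpoint, consistent with window binning. Each
18-vector is z-scored against healthy controls and min-max scaled to
[0, 1] within the sample; a degenerate (constant or missing) vector maps
to 0.5. The 54 features feed a random forest (2000 trees by default, √p
features per split, trees grown to purity) evaluated by leave-one-out
cross-validation. Accuracy is also reported after merging closely related
types (ESCA/STAD/COREAD → digestive; LIHC/PACA → hepatopancreatic);
merged accuracy can never fall below raw accuracy.

## Evaluation

AUC is the rank statistic (ties count ½) with a 95% percentile CI from
label-stratified bootstrap (2000 replicates). Sensitivity at fixed
specificity uses the smallest observed score threshold achieving at least
the target specificity on healthy samples (ties at the threshold call
positive) and a Wilson 95% interval (z = 1.959964). The clinical limit of
detection (cLOD) fits a logistic regression of binarized detection on
log10 mean variant-allele fraction; the LOD is 10^(−intercept/slope),
with a delta-method Gaussian CI on the crossing point. The screening
projection is exact arithmetic: TP = N·incidence·sensitivity,
FP = N·(1−incidence)·(1−specificity), PPV = TP/(TP+FP). Robustness
harnesses (hold-one-group-out across all combinations; repeated
stratified 7:3 splits) are generic over a fit/score callable so any
pipeline stage can be plugged in.

## Synthetic cohorts

The generator is the package's test substrate; its defaults are fixed
study conditions, not tuning knobs.

*Toy genome*: 4 chromosomes × 30 Mb, CpG sites forced every 80 bp, GC
fraction varying smoothly (0.5 ± 0.10, ~7.3-Mb wavelength) so the LOESS
correction is exercised against a real covariate; coverage is biased
log-linearly in block GC (coefficient 1.5).

*Fragments*: sizes are discretized lognormal with healthy mode 167 bp
(σ = 0.16, the plasma mononucleosome peak); tumor fragments shift the
mode 20 bp shorter. Positions are drawn block-wise (20-kb blocks) with
GC-coverage weights; tumor fragments re-weight blocks by the configured
arm copy ratios, so a copy-ratio-r arm at tumor fraction t is enriched by
1 + t(r−1) before renormalization. Per-CpG methylation is Bernoulli
(healthy 0.85; 0.70 inside accessibility peaks; tumor fragments
multiplied by the hypomethylation factor 0.85, and by a 0.40 cluster
factor inside the sample's affected peak cluster). Non-CpG cytosine
observations are Binomial(length, 0.05) with a 0.6% conversion-failure
rate (matching the high conversion of enzymatic library chemistry). A
configurable fraction (default 30%) of tumor fragment ends snaps to the
nearest site whose Crick 4-mer starts with `CC`, distorting the end-motif
spectrum; motifs are always re-derived from the reference at the final
end coordinate, so reader-computed motifs match the generative model by
construction. A small fraction (5%) of tumor fragments relocates into the
affected cluster's peaks (elevated accessibility). Stages map to tumor-
fraction bands (I: 0.1–1%, II: 0.5–2%, III: 2–8%, IV: 5–20%); the
strong-signal preset draws 5–25% and the null preset 0%.

*What is not emulated*: sequence errors beyond conversion failure,
mappability structure (the toy genome has no repeats, so exclusion tracks
are empty by default), chromatin-state fragmentation phasing, batch and
center effects, and single-CpG resolution biology. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under its assumed generative structure — not clinical
performance on real plasma.

## Problem sizes

Desk-scale runs keep full suites fast: unit fixtures use 2–4 chromosomes
of 4–8 Mb with thousands of fragments; cohort-level checks use a
120-sample cohort at 20,000 fragments per sample (detection), a 30-sample
tumor-fraction ladder at 60,000 fragments with a three-arm CNA profile
(aneuploidy monotonicity — arm-share noise scales as the inverse square
root of gated fragment count, and multi-arm profiles reflect advanced
tumors), an 84-sample 7-type cohort with 40 × 1-kb peaks per cluster
(signal origin; wider peaks keep per-cluster fragment counts informative
at desk depth), and n = 200 for the cLOD recovery. The signal-origin
forest runs with 300 trees in the test harnesses; accuracy is flat in
tree count well below the 2000-tree default.

## Known limitations

- The published 1846/502 window counts arise from hg19 plus specific
  exclusion tracks; the tiling operation reproduces the rule (≥1 bp
  exclusion overlap drops a tile) but the counts themselves require those
  external files.
- Whether the published aneuploidy score fixed the five arms cohort-wide
  or per sample is ambiguous in its source; this implementation selects
  per sample, which is the variant that needs no extra state.
- The FSI 100-kb bins are plain tiles; A/B-compartment boundaries are
  carried as optional annotations only and do not alter arithmetic.
- Quantile normalization and the association profiling operate on
  matrices the caller aligns; no attempt is made to re-derive the
  published 1795-window intersection without its inputs.
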