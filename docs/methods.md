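# Methods

## Traveling-ratio model

A gene's traveling ratio (TR, also called pausing index) is the ratio of mean
ChIP coverage in a promoter-proximal window to mean coverage over the gene
body. We use the convention common in the pausing literature — promoter
[TSS − 30 bp, TSS + 300 bp), body [TSS + 300 bp, TES) along the direction of
transcription — and expose every bound as a `TRWindows` parameter, because
published pausing analyses vary in their exact windows and rarely state them.
On the − strand both windows are mirrored base-exactly, so mirroring the
genome layout (coordinates reversed, strands flipped) leaves every TR
unchanged; this strand symmetry is a tested invariant.

The body pseudocount (default 1e-3 reads/bp) sits in the denominator only: it
prevents division blow-ups for empty bodies while leaving the promoter signal
visible, and genes with body density below `min_body_density` (default 0.01
reads/bp) carry a `low_coverage` flag instead of being silently dropped. TRs
are scale-free up to the pseudocount: multiplying a track by any constant
changes TRs of coverage-passing genes by well under 1% at the defaults, and
exactly 0% with the pseudocount off. Genes shorter than 1 kb are excluded
(their body window would be degenerate), as are genes whose windows leave the
chromosome; both exclusions are reported, not raised.

Tracks are normalized to a common total signal (counts-per-ten-million
equivalents) before conditions are compared. This is a documented choice, not
a reproduction of any published pipeline: TRs are largely scale-free, but
metagene panels and densities are not.

## Distribution shift and paused-gene calling

Two complementary readouts of increased pausing are exposed:

- a global two-sample Kolmogorov–Smirnov test on log TR over the shared,
  coverage-filtered gene universe (`tr_shift_test`), plus the empirical CDF
  over log10 TR for display;
- a per-gene fold rule (`call_paused_genes`): paused ⇔ coverage passes in both
  conditions and TR_treated/TR_control ≥ `min_fold` (default 1.5).

The defaults recover planted 3× TR effects with sensitivity ≥ 0.9 at a
false-positive rate ≤ 0.05 under the simulation conditions below. No claim is
made that any particular published paused-gene count is reproduced; the
fold threshold is recorded in every output.

A calibration caveat that drives one design choice: the control and treated
TR estimates of the same gene share that gene's baseline TR. When baseline
TRs vary widely across genes, the two "samples" handed to the KS test are
strongly positively dependent and the test becomes arbitrarily conservative —
its null rejection rate collapses toward zero. The type-I calibration run
therefore uses a common baseline TR (the i.i.d. sampling model the KS test
assumes), under which the rejection rate at p < 0.05 sits inside the exact
binomial 95% band around 0.05 over 200 null simulations. On real data the
global KS p-value should be read as conservative.

## Metagene profiles and ratio normalization

Profiles average binned coverage over `[anchor − flank, anchor + flank)`
(defaults ±2000 bp, 10 bp bins); gene anchors use the TSS and are reversed on
the − strand (with the half-open window shifted by one base so the anchor
lands symmetrically — this makes the − strand profile exactly the mirror of
the + strand profile on the mirrored genome). A gene-scaled variant rescales
TSS→TES to 100 bins between fixed flanks. Occupancy heatmaps keep per-anchor
rows sorted by descending mean; rows are reduced in one canonical order
(descending row mean, ties by anchor id) in both the profile and the heatmap,
so heatmap column means equal the profile exactly, bit for bit.

Elongating-polymerase profiles (Ser2-phosphorylated RNAP2) are normalized
bin-wise to total RNAP2 with a pseudocount in the denominator; with the
numerator generated as Poisson with mean α × denominator, the mean ratio
profile is an unbiased estimate of α and recovers α = 0.6 within 5% over 200
genes. Site-level binding concordance uses Pearson correlation on
log10(density + 1e-3) — binding densities are right-skewed, so the log is
taken first; zero-variance inputs return a flagged degenerate result rather
than raising, so batch runs survive.

## Differential expression and integration

The DE test is deliberately transparent and dependency-light: counts →
counts-per-million → log2(CPM + 1) → Welch's unequal-variance t per gene →
Benjamini–Hochberg across tested genes. Genes with zero counts everywhere are
excluded and reported. "Down" means log2FC ≤ −0.585 (a 1.5-fold drop) at
q ≤ 0.05; both thresholds travel with the output. Under the null count
simulation the pooled type-I error is within the binomial band around 0.05.
With 5 replicates this test is underpowered for |log2FC| ≲ 1 — the worked
example shows that honestly — and a negative-binomial GLM would be the
higher-power substitute on real data.

CDK9-dependent genes are the intersection of the paused calls and the down
calls. TF-set enrichment builds the 2×2 table of a query set against each TF
target set over the universe of TR-measured (coverage-passing) genes, takes
the two-sided Fisher exact p on the uncorrected table, reports the sample
odds ratio with the Haldane–Anscombe +0.5 correction only when a cell is
empty, adjusts across TFs by BH, and ranks by descending OR, ties by
ascending p then name.

The single-sample gene-set score ranks genes by descending expression (ties
broken by gene id for determinism) and walks a weighted Kolmogorov running
sum — in-set steps weighted by |centered rank|^0.25, out-of-set steps uniform
— reporting the mean running-sum deviation. Using ranks alone makes the score
invariant under any strictly monotone transform of expression; the symmetric
centered-rank weights make it exactly antisymmetric under rank reversal and
mean-zero over random sets. It is deliberately not the absolute-expression
weighting some single-sample methods use, which breaks monotone invariance.

The BH3-profiling rule labels a line MCL-1 dependent iff its depolarization
exceeds 10% at either MS1 dose or is higher at the higher dose. The rule is
monotone in the high-dose value but intentionally not in the low-dose value:
a sub-threshold dose-responsive line (4%/8%) loses the call if only its
low-dose reading rises (9%/8%). ΔΔCt fold changes and the 18S/47S processing
ratio are direct arithmetic with explicit zero-denominator errors.

## Image statistics

Nucleolar segmentation is a global threshold (Otsu by default; invariant to
affine intensity rescaling; a constant image is an explicit error) followed by
8-connected component labeling and removal of components under 4 px. Median
nucleolus area uses the even-count mean-of-middle-two convention. Components
are assigned to nuclei by rounded-centroid containment — the simplest
deterministic rule; overlap-fraction assignment would differ only for
components straddling a nucleus boundary. A cell is aggregate-positive iff it
contains a component of at least `min_aggregate_area` px (default 9 px; no
field-standard value exists, so it is a free parameter). Z-stacks are assumed
maximum-intensity-projected upstream; analysis is strictly 2-D.

## Synthetic data: what it emulates and what it does not

ChIP coverage is modeled as independent per-base Poisson counts: mean
`mean_body_density` (default 5 reads/bp) over the gene body,
TR × that over the promoter window, 0.01 reads/bp intergenic background —
non-zero so metagene flanks are realistic but near-empty. TR only depends on
mean densities, so this reproduces exactly the statistic under study while
skipping read-level artifacts (fragment-length smearing, GC bias, mappability
gaps, duplicate reads). Consequently, recovery rates measured here are upper
bounds for real data, where window densities are spatially correlated.
Baseline TRs are uniform on [2, 8]; treatment multiplies TR by `tr_effect`
(default 3) in `frac_affected` (default 20%) of genes. Genes (default 500 on
a 10 Mb chromosome, 2–10 kb long, ≥ 1 kb apart, ~50/50 strands) never
overlap — real genomes do overlap, and the TR code does not attempt to
deconvolve shared windows.

RNA-seq counts are negative-binomial with gene means uniform on [20, 2000]
and common dispersion 0.1 (variance μ + 0.1μ²) — typical bulk RNA-seq scale —
with `frac_down` genes knocked down by `2^lfc_down` in the treated group;
dispersion 0 degrades to Poisson. TF target sets are sampled without
replacement with a weight ratio (`enrichment`, default 10) favoring the
planted paused genes for one driver set. Depolarization tables are built to
satisfy or violate the dependence rule by construction, so the classifier
round-trips the truth exactly. Images place digital disks (the k nearest
pixels to a center) of exact requested areas with ≥ 3 px clearance on
Gaussian noise, so truth areas are pixel-exact.

All generators draw from `numpy` Generators seeded by (seed, stream tag) with
no global state; identical seeds give byte-identical outputs, which the
pipeline-level determinism check verifies end to end through the CLI.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to keep the whole suite fast while
leaving comfortable statistical margins: 500 genes × 2 kb on a 2 Mb
chromosome × 200 seeds for KS calibration; 500 genes × 5 replicates × 200
seeds for DE calibration; 500 genes × 10 kb for paused-gene recovery; 100
seeds for driver-TF ranking. The exhaustive Fisher check covers every 2×2
table with total ≤ 60 through canonical margin classes (p and OR are
invariant under row swap, column swap and transpose; the symmetry itself is
asserted on a random sample), comparing against direct hypergeometric tail
enumeration; the empty table is skipped as trivially p = 1. Floats in all
TSV outputs use a fixed `%.10g` format so equal results are byte-equal.

## Known limitations

- The DE test is a per-gene Welch t on log-CPM, not a count GLM; power at
  small fold changes and few replicates is modest.
- The global KS shift test is conservative under per-gene baseline-TR
  heterogeneity (see above); the fold rule is the per-gene instrument.
- No read-level simulation, peak calling, spike-in normalization, BAM/bigWig
  I/O, or 3-D image analysis; inputs arrive as bedGraph/BED/TSV/2-D images.
- Nucleus assignment by centroid can misassign a component whose centroid
  falls just outside its visual nucleus; acceptable at the densities tested.
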