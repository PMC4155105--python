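# Methods

This note records the models and procedures `tilemark` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Data model and coordinates

All genomic coordinates are 0-based half-open internally; "overlap" always
means at least one shared base, so abutting intervals never overlap. BED is
written natively; GFF3 is converted to 1-based inclusive at the I/O boundary
and back losslessly (values are serialized with 17 significant digits so
float64 round-trips are exact). The genome build is an opaque label carried
in file headers; there is no liftover.

A layout fixes the probe geometry: promoter tiles spanning TSS−7000 to
TSS+3000 in transcription orientation at constant probe spacing (100 bp
default, 50 bp probes), and long contiguously tiled regions. Probe tracks
are vectors of log2(ChIP/input) values aligned to the layout. Proximal
promoter windows span TSS−3500 to TSS+750, strand-aware.

## Peak calling

* Ceiling: mean + 6·SD of the track, with the **sample** SD (n−1). The
  choice of denominator is immaterial at array scale (≥10⁴ probes) but is
  fixed for reproducibility.
* Cutoff ladder: fractions (0.90, 0.80, 0.70, 0.60, 0.50, 0.40, 0.30,
  0.25, 0.20, 0.15) of the ceiling. The ladder is a parameter
  (`PeakCallerParams.cutoff_fractions`) so sensitivity analyses can vary it.
* Window rule: windows are anchored at every probe start and span 500 bp;
  a window qualifies when it contains ≥4 probes strictly above the cutoff.
  If the window holds fewer than 4 probes, 3 are required, then 2. Probes
  qualify on strict inequality; windows never cross chromosomes.
* Merging: qualifying probes from all qualifying windows at a cutoff are
  unioned; maximal runs with inter-probe gaps ≤ the window width form one
  peak, bounded by the first qualifying probe start and last qualifying
  probe end. Because lowering the cutoff only adds qualifying probes, the
  generous set equals the peaks at the lowest cutoff, and each peak's
  `best_cutoff` is the highest ladder level reaching any of its probes.
* Degenerate rule: if the ceiling is ≤ 0 (possible when the track mean is
  sufficiently negative), no peaks are called — a non-positive ceiling
  would invert the sign of every cutoff.
* FDR: the data are permuted across the whole track (permutation leaves
  the ceiling unchanged) n_randomizations = 20 times with seeded
  substreams; FDR(c) = min(1, mean randomized count / observed count) per
  cutoff level, undefined (NaN) where nothing was observed. Each peak
  inherits the FDR of its best cutoff; the stringent set keeps FDR
  strictly below 0.2. Defining the estimator per cutoff level rather than
  per individual peak is a design choice; the per-peak assignment through
  `best_cutoff` makes strong peaks (high best cutoff, near-zero randomized
  counts) robustly stringent.

## Promoter scoring

* Quantile normalization operates across same-mark arrays: every output
  track's sorted vector is the mean of the input order statistics. Tied
  input values receive the mean of the reference values their rank block
  spans (midrank method), so ties stay tied and degenerate
  (e.g. zero-noise) tracks do not acquire artificial structure.
* The three-point median smooth runs within contiguous tiles only; the
  first and last probe of each tile are copied. Smoothing across
  unrelated genomic locations (adjacent tiles in the probe vector) would
  blend signal between loci.
* maxfour scans all runs of 4 consecutive in-window probes and returns
  the largest run mean, computed with left-to-right summation so it is
  bit-identical to direct evaluation of each window. Promoters with
  fewer than 4 probes return the mean of what they have and are flagged
  under-powered; they are excluded from bivalent calling but reported.
  Promoters with no probes yield a missing value, never 0.
* The preprocessing chain for bivalent calling is normalize → smooth →
  maxfour. Whether the >1.0 threshold should instead apply to raw values
  is an open choice; the pipeline records which variant produced each
  number, and raw-track maxfour remains available for validation plots.
* Top-k rank sets break boundary ties by lexicographic promoter id so
  results are deterministic and exactly k in size.

## Calls, sets, bivalents, broad domains

A promoter is positive for (cell, mark) when ≥1 peak shares a base with
its window; the call matrix is complete over promoters × cell types ×
marks. The main analyses use the generous peak set; the stringent
(FDR < 0.2) run is a config switch. Core = intersection and universe =
union of group-cell positive sets; "lost in all" relative to a reference
cell type means reference-positive and absent from the whole universe
(not merely from the core).

Bivalent calls require, for each mark of the pair, peak-positivity AND
maxfour > 1.0 — two independent lines of evidence. Overlap morphology is
only assessed for promoters whose contributing peaks lie entirely within
the window; others are `not_assessable` because outside mass could fake
or hide an overlap. Chromatin-fragment size inflates apparent overlap
(peaks are wider than the underlying modification); no deconvolution is
attempted — the raw classification is reported. In the cross-cell
resolution report, mark positivity is peak-positivity alone; the maxfour
arm applies only to the bivalent definition itself.

Broad domains: within each long region, probes above the occupancy
threshold (default: the peak caller's most generous cutoff, 15% of the
ceiling) are merged across gaps ≤ 5 kb (absorbing probe dropouts), and
merged spans strictly longer than 50 kb are kept if at least half of
their probes are positive. The `min_occupancy` requirement operationalizes
"continuously modified": without it, on noisy tracks the ~5% of background
probes above the generous threshold sit ~2 kb apart on average — closer
than the gap tolerance — and would chain into arbitrarily long spurious
spans. A domain is differential against another cell type when that
cell's same-mark domains cover less than `differential_coverage_fraction`
(0.5) of it; the per-(region, mark) summary counts regions where any cell
pair differs. These explicit rules replace a by-eye assessment, so
region-difference counts are qualitative characterizations, not exact
reproductions of any visual judgment.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the level the analysis operates on (log2 ratios): per-probe value =
baseline + planted amplitudes + i.i.d. N(0, σ). It does **not** model
hybridization chemistry, probe GC/sequence effects, dye bias or spatial
artifacts — so passing tests demonstrate correctness of the algorithms
under the stated noise model, not robustness to platform artifacts the
analysis itself never models.

Default study conditions: 2000 promoters (alternating strands, ≥15 kb
apart), four 500 kb long regions, five cell types (one reference + four
group) × four marks, σ = 0.3, focal amplitude 2.0 (log2), broad amplitude
1.5, baseline −0.25. The slightly negative baseline reflects globally
centered two-channel ratios: enrichment mass pulls the distribution mean
up, leaving unenriched background below zero. Focal prevalence per cell:
H3K4me3 0.45, meC 0.30, H3K27me3 0.22, H3K9me3 0.12, with H3K9me3 scaled
to 0.3× in one group cell type to emulate a line with strongly reduced
activity of that mark's production/maintenance system. Per mark, 55% of
the smallest per-cell positive count is planted in every cell type
(core), 2% of promoters are group-only (gained), 4% reference-only
(lost), the rest cell-variable. Bivalent promoters are planted in the
reference with controlled fates across the group (still bivalent /
active-only / repressive-only / lost-both / mixed), 60% with overlapping
morphology (the two marks' intervals share two-thirds of their span) and
40% adjacent (same window, ≥1 probe gap between intervals). Broad
domains (80–100 kb) are planted such that one long region is covered in
every cell type (not differential), two H3K27me3 contrasts differ, and
one H3K9me3 domain exists in a single cell type — the
single-line-repressive-domain scenario.

All randomness derives from one integer seed through `SeedSequence`
spawn keys, one substream per (cell type, mark), so tracks are
independent and adding one never perturbs another. Zero-noise variants
(`design.with_sigma(0.0)`) make every downstream call exact, which the
truth-recovery tests exploit; `StudyDesign.scaled(n)` shrinks the study
proportionally for fast runs.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on scaled designs (250–400 promoters, 1–2
long regions) where the full pipeline completes in seconds; the
planted-recovery and normalization checks run at the full default scale
(2000 promoters, ~222k probes, all 20 tracks with 20-fold permutation
FDR). Pure-noise FDR behavior is measured on a 500-promoter + 100 kb
layout across 10 seeds. These sizes were chosen so the whole suite and
the acceptance script each finish in about half a minute while keeping
every statistical check at the scale its expected behavior is
well-separated from noise.

## Known limitations

* Exact reproduction of vendor-software peak lists is not guaranteed:
  the merging of windows into peaks and the per-peak FDR estimator of the
  original array software are not published, so counts on real deposited
  arrays can deviate even with identical thresholds.
* Broad-domain detection is restricted to declared long tiled regions;
  the promoter-tile portion of a layout cannot reveal >50 kb domains by
  construction.
* The bivalent overlap analysis reports apparent (fragment-size-inflated)
  overlap; morphology fractions on real data are upper bounds on true
  co-occupancy.
* Under-powered promoters (<4 probes in the window) never enter the
  conservative bivalent set, which biases that set toward well-tiled
  promoters.
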