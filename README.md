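# tilemark

Promoter-centric analysis of tiled-microarray epigenome data.

Tiling arrays (ChIP-chip for histone modifications, MeDIP-chip for DNA
methylation) measure log2(ChIP/input) enrichment at fixed probes covering
promoter tiles — typically 7 kb upstream to 3 kb downstream of each TSS at
100 bp spacing — plus a handful of long contiguously tiled survey regions.
`tilemark` implements the standard promoter-centric workflow for comparing
epigenetic mark localization across several cell types (e.g. a panel of
brain-tumor stem-cell lines against fetal neural stem cells as the normal
reference), together with a synthetic-data generator that plants known
features so every stage can be validated against ground truth.

## What it computes

**Peak calling with a cutoff ladder and permutation FDR.** For a track with
probe values $x_i$, the *theoretical maximum* is $T = \bar{x} + 6\,s$
(sample SD). For each cutoff $c \in \{0.90, 0.80, \dots, 0.20, 0.15\}$, a
500 bp window qualifies when it holds at least 4 probes with $x_i > cT$
(falling back to 3, then 2, when the window contains fewer probes);
qualifying probes merge into peaks. The union over the ladder is the
*generous* set. Permuting the probe values across the track 20 times and
re-counting peaks per cutoff gives each level an FDR; filtering at
FDR < 0.2 yields the *stringent* set.

**Promoter calls and maxfour.** Peaks are mapped onto proximal-promoter
windows (TSS − 3.5 kb to TSS + 750 bp, strand-aware, half-open overlap
semantics): one overlapping peak makes the promoter positive.
Independently, after quantile normalization across same-mark arrays and a
three-point median smooth, the *maxfour* score of a promoter is the largest
mean of four consecutive probes in its window; maxfour > 1.0 log2
(i.e. > 2-fold) is maxfour-positive.

**Set algebra.** Per mark, the *core* set is positive in every group cell
type, the *universe* in at least one. Against the reference cell type:
gained-in-all = core − reference; lost-in-all = reference − universe.

**Bivalent promoters.** A promoter is bivalent (H3K4me3 with H3K27me3 or
H3K9me3) only when each mark passes *both* evidence criteria
(peak-positive and maxfour-positive). Bivalent promoters whose peaks lie
entirely inside the window are classified *overlapping* vs
*non_overlapping*; reference-bivalent promoters are resolved across the
group into still-bivalent / active-only / repressive-only / lost-both /
mixed fates.

**Broad domains.** Within long tiled regions, probes above an occupancy
threshold (15% of $T$ by default) merge across gaps ≤ 5 kb; merged spans
strictly longer than 50 kb with at least 50% positive probes are *broad
modifications*, and a domain is differential against another cell type
covering less than half of it.

## Worked example

`python examples/02_peak_calling.py` simulates a 400-promoter study with
one 500 kb long region, calls peaks on the BTSC1 H3K27me3 track and
prints

```
theoretical maximum: 2.379 log2 units
generous peaks: 111  (stringent: 111)
 cutoff  n_observed  mean_randomized   fdr
  0.900           0            0.000   NaN
  0.800           2            0.050 0.025
  0.700          46            0.050 0.001
  0.600         105            0.150 0.001
```

The ceiling of this track is 2.38 log2 units, so the 80% cutoff (1.90)
already captures the strongest planted peaks; randomized data almost never
produces a qualifying window, hence FDRs near zero. The generous union
contains 111 peaks — matching the 110 promoters planted positive for
H3K27me3 in that simulated cell line plus one long-region domain — and all
of them survive FDR < 0.2.

The `examples/` directory walks through each capability (simulation, peak
calling, maxfour scoring, set comparisons, bivalent promoters, broad
domains, the full pipeline); each script runs in seconds and prints what
its numbers mean. The `tilemark` CLI wraps the same library
(`tilemark run --config run.yaml`, `tilemark simulate`,
`tilemark callpeaks`, ...).

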