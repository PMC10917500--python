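# Methods

## Overview

`initdir` quantifies transcription-initiation directionality at gene
promoters and gene-proximal intergenic accessible regions (IARs) from
coverage tracks of nascent transcription and chromatin features. The
pipeline is: interval extraction → per-region signal aggregation →
metaprofiles/heatmap matrices → k-means clustering → upstream/downstream
skew testing. A synthetic-epigenome generator provides ground-truth-
labelled data for end-to-end validation.

## Coordinate conventions and interval arithmetic

All internal coordinates are 0-based half-open; GFF3 (1-based closed) and
BED (0-based half-open) conversion happens only in the readers/writers.
Gene isoforms sharing a `gene_id` are collapsed to one spanning interval.
Intersect and subtract are implemented directly (merge + binary search)
and validated against a per-base bitmap oracle; `subtract(a,b)` and
`intersect(a,b)` tile `a` exactly (conservation of bases, property-tested).

## IAR extraction

Accessible regions are first clipped against gene bodies; fragments
narrower than `min_width` (default 50 bp) are dropped. A fragment is an
IAR when the gap between its closest edge and the **nearest gene
boundary** lies in `[min_dist, max_dist]` (defaults 100 and 2000 bp).
Distance is measured edge-to-boundary (bedtools-window semantics); an
`anchor="tss"` option measures to the nearest TSS instead. Regions in
range of several genes are counted once and assigned to the nearest gene,
ties resolving to the leftmost gene by coordinate, which makes extraction
deterministic and independent of input order. Midpoints of odd-length
intervals round down (integer division). Flanks are
`[midpoint − flank, midpoint)` and `[midpoint, midpoint + flank)` in
genomic coordinates, clipped at chromosome bounds with the clipping
flagged.

## Signal model

Coverage tracks hold per-base values per chromosome. Per-region means use
the `mean0` convention (uncovered bases count as zero), matching
`bigWigAverageOverBed`. RPKM follows the `bamCoverage` convention
`rpkm = count × 1e9 / (bin_length × total_reads)`; the bin length
defaults to the track's native bin size, and double normalization is an
error. For nascent-transcription data, each metaprofile bin's value
distribution can be trimmed two-sidedly (default 10%/10%, floor
semantics) before averaging; this is the guard against high-signal
artifacts dominating the metaplots, and it is applied per profile column
rather than to raw reads because that is the stage at which outliers
distort the displayed mean.

## Profiles

Point-anchored matrices average signal in fixed bins (default 50 bp)
across `[anchor − upstream, anchor + downstream)`; minus-strand anchors
are mirrored so bin 0 is biologically upstream. Scaled-body matrices bin
the two flanks at `flank_bin` bp and resample the gene body to exactly
`body_bins` bins with fractional-base weighting at bin edges, so genes
shorter than the bin count are handled without error and constant tracks
stay constant under resampling. Bins extending past a chromosome end are
NaN and excluded from summaries. Summary curves report the per-bin mean,
SE = sd/√n, and the normal-approximation 95% CI (1.96·SE; region counts
in real uses are ≫ 30). The z-score option transforms the mean/SE/CI
curves jointly by the mean and standard deviation of the per-bin means
(per track), so the displayed mean curve has mean 0 and sd 1 across bins;
per-region z-scoring is available separately. Default bin sizes (50 bp
point-anchored, 100 body bins) follow common metaplot practice and are
configurable.

## Clustering

Heatmap features are the log2(x+1)-transformed, horizontally concatenated
binned tracks (the displayed heatmap signal; the +1 offset keeps zeros
finite). k-means uses Lloyd's algorithm with k-means++ initialization and
the best of `n_init` restarts, with a mandatory seed. Clusters are
relabeled deterministically by descending size, then descending mean
signal, so labels are comparable across seeds and row permutations.
Options: per-track standardization; a `crop_bp` restriction of the
feature window to the element-intrinsic core (see below); and
`orient="dominant"`, which flips each region's rows so the heavier side
of a reference track (typically nascent signal) is downstream. Dominant
orientation exists for *class* benchmarks — in genomic coordinates,
left- and right-transcribing unidirectional elements are mirror-image
feature blobs that no k=3 partition can merge; orientation canonicalizes
them. Skew testing always stays in genomic coordinates: flipping by
dominant side before a signed comparison would bias every group toward
"downstream" and is therefore never applied there.

## Skew test

Per locus, the upstream/downstream flank means are log2(x+1)-transformed;
loci with zero signal on **both** sides are removed (a one-sided locus is
informative and kept). Within each group the up values and down values
are compared as two samples with a two-sided Wilcoxon rank-sum test —
matching the published analysis design, which tests the two sides as
independent samples rather than as per-locus pairs; a paired signed-rank
variant is available as a non-default option. The test is exact
(enumeration of the rank-split distribution by subset-sum dynamic
programming over doubled midranks) for combined samples up to 25, and a
normal approximation with tie and continuity corrections above that;
identical pooled values give p = 1. The Bonferroni divisor m is the
number of groups actually tested in one invocation; groups with fewer
than `min_n` (default 10) loci after filtering are reported as
"insufficient data" and do not count toward m. Significant groups are
called unidirectional with the favored side taken from the larger median;
non-significant groups with signal are called bidirectional. By default
the plus and minus nascent tracks are summed before aggregation
(`strand_mode="combined"`, matching a single unstranded quantification
pass); `strand_mode="oriented"` assigns the minus track to the upstream
flank and the plus track to the downstream flank, the geometry of
divergent initiation.

## Synthetic epigenome

The generator emulates the statistical structure the analysis assumes,
directly at the coverage level (no sequences or reads):

- **Genome**: 1 chromosome of 2 Mb, 200 non-overlapping genes with
  log-normal lengths (median ≈ 1.5 kb) and ≥ 4 kb spacing, placed
  uniformly; strand random.
- **Accessibility**: every gene gets a 200 bp nucleosome-depleted region
  (NDR) 50–250 bp upstream of its TSS — inside the typical promoter-peak
  offset and deliberately closer than the 100 bp IAR distance floor, so
  promoter NDRs are excluded from IAR extraction. 150 intergenic CREs
  (width 200–400 bp) are placed 1200–1800 bp from a gene boundary, and
  20% additional decoy sites are placed ≥ 2.5 kb from every gene; decoys
  must never survive extraction. CREs sit in the distal part of the
  100–2000 bp proximal window so that their ±2 kb windows are dominated
  by element-intrinsic signal rather than the neighbouring gene's
  promoter; the extraction logic itself is exercised across the whole
  window by hand-built proximal fixtures.
- **Directionality labels**: 30% of CREs bidirectional, 20% inactive,
  the rest unidirectional (half leftward, half rightward); 15% of TSSs
  initiate divergently at `divergent_strength` (0.8) times the sense
  rate over a short (~500 bp) non-elongating antisense window, reflecting
  initiation-proximal upstream antisense transcription.
- **Nascent coverage**: sense signal decays exponentially 5′→3′ along
  gene bodies (rate 0.5 reads/bp at the TSS, decay length 3 kb); CRE
  eRNAs are 500 bp windows at 0.4 reads/bp on the transcribed side(s);
  uniform background 0.02 reads/bp on both strands.
- **Chromatin marks**: Gaussian bumps on the transcribed side(s) of each
  element — H3K4me3 at 300 bp (σ 150), H3K4me1 at 800 bp (σ 300, the
  near end of its distal 800–1500 bp range), H3K27ac at 250 bp, H2A.Z at
  200 bp; H3K27me3 broadly covers inactive elements; accessibility peaks
  at every accessible-site center; H3 is a uniform nucleosome baseline
  with an NDR dip.
- **Noise**: one count per 10 bp bin, Poisson with the bin's expected
  rate (the simplest model consistent with read-count data); a
  negative-binomial overdispersion option exists for robustness tests;
  noiseless mode emits exact expectations for closed-form checks. All
  outputs are bit-for-bit reproducible from (config, seed) via
  per-purpose seeded streams.

What the generator does **not** emulate: mappability artifacts, copy-
number and GC biases, overlapping/nested genes, isoform structure,
replicate-to-replicate variation, and spatial autocorrelation of
read-count noise beyond the bin scale. Passing tests therefore show the
pipeline's operations are correct and calibrated under the stated model,
not that every biological confound in real data is handled.

## Validation design and problem sizes

The validation suite (and `scripts/acceptance.py`) measures: bitmap-
oracle agreement of the interval arithmetic (500 random instances on
≤ 10 kb genomes); exact-enumeration agreement of the Wilcoxon p-value
(all size pairs with n₁+n₂ ≤ 12, 200 value sets, tolerance 1e−12);
type-I error of the skew pipeline on symmetric Poisson flank counts
(1000 replicate groups of 100 loci at α = 0.05, checked against the
binomial 95% interval); power on a fourfold asymmetry (Poisson means 20
vs 5, 100 loci, 200 replicates, ≥ 99% correct unidirectional calls); and
an end-to-end 2 Mb run in which per-group directionality calls are
compared with ground truth over the planted label groups and k = 3
clustering (dominant orientation, ±1 kb core window) is compared with
the planted classes by adjusted Rand index. Inactive elements are
excluded from the directionality-recovery denominator: their flanks
carry only symmetric background noise, and directionality is only
meaningful for groups with nascent signal. These problem sizes keep the
full validation run in the tens of seconds while leaving the binomial
and ARI checks well-powered.

## Known limitations

- The rank-sum exact branch enumerates up to combined n = 25; beyond
  that the normal approximation's continuity correction makes the test
  very slightly conservative.
- IARs equidistant from two genes are assigned to the leftmost gene; a
  per-gene (duplicated) accounting is not offered.
- Real analyses cluster heatmaps with display binning; cluster count k
  is a configuration value, and no automatic model selection is
  provided.
- bigWig output is not written (bedGraph is the canonical text output);
  bigWig input is supported.
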