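# Methods

This note documents the statistical model, the numerical choices and the
synthetic-data design behind `peakshape`, and what the test suite does and
does not demonstrate.

## Coverage model and the CV score

Per-nucleotide read counts within one peak are treated as draws from a
negative binomial X ~ NB(r, p) in the trials-for-r-successes
parameterization: mean m = r/p, variance v = r(1−p)/p². Moment matching
gives p = m/(v+m) and r = m²/(v+m), and the model coefficient of variation

    CV = sqrt((1 − p)/r)

then reduces *identically* to the empirical sd/mean of the depth vector
(population variance, ddof 0). This identity is the reason moment matching
was chosen as the estimator: it makes the score well-defined even for
underdispersed profiles (v < m), where a literal NB fit would not exist but
sd/mean still behaves sensibly. Degenerate inputs are mapped explicitly:
an all-zero profile to NB(1, 1) and a zero-variance positive profile to
NB(m, 1), both of which give CV = 0 — flat coverage carries no evidence of
specific binding.

Normalization of CVs to [0, 1] is min–max by default. With a user
`scale_max` s the score becomes min(CV, s)/s, which keeps normalized CVs
comparable across experiments with different read depths and peak sizes.
The specificity label applies the threshold (default 0.2) to the
*normalized* CV by default; a config switch (`threshold_basis="raw"`)
applies it to the raw CV instead, since both conventions are in use. The
sharp/broad cluster rule (below) always uses the raw CV.

### Border penalty

Peaks that cover the edge of a broad read stack (a "small appendage of a
plateau") can score a deceptively high CV. The optional penalty multiplies
the CV by `1 − min(1, (d_first + d_last)/(2 d_max))`: 1 when the profile's
boundary depths are 0 (fully interior signal), 0 when the profile is flat
at its maximum. The exact functional form is this package's own choice;
it is isolated in one function (`evaluate.border_penalty`) so it can be
swapped without touching anything else.

## Peak preparation

Re-centering convolves the coverage of an extended window (the peak plus
one harmonized-length flank on each side) with a discrete Gaussian kernel —
sigma = halfwidth/3, truncated at ±halfwidth, normalized to sum 1, with
halfwidth defaulting to half the harmonized peak length so centering is
scale-free. The convolution argmax, restricted to ±search_flank and with
ties broken leftmost, gives the shift; the `summit` scheme uses the raw
depth argmax instead (appropriate for nucleotide-resolution events such as
crosslink truncations). Shifts are strand-aware: a positive 5'→3' shift
moves a minus-strand peak toward smaller genomic coordinates.

Length harmonization brings every peak to one target length (default: the
maximum observed length) symmetrically about its midpoint, the odd
remainder going to the 5' side. Windows are slid inward at chromosome
edges so length is preserved; peaks on contigs shorter than the target are
dropped with a warning rather than failing the run. The stage order is
center → harmonize → recompute coverage, and running the prep twice with
the same configuration is a no-op.

Coverage itself counts full aligned read spans; spliced alignments
contribute only through their aligned blocks. The default `same-strand`
mode counts only reads on the peak's strand (CLIP libraries are
strand-specific); peaks with strand "." accept all reads, and
`ignore-strand` is available for non-stranded assays.

## Shape classification

Profiles are max–min normalized per peak (a constant profile maps to all
zeros, deliberately distinct from "empty"), smoothed, summarized and
clustered:

- **Smoothing** is a P-spline: a cubic B-spline basis with a knot every
  other nucleotide, fit by ridge regression with a second-difference
  penalty on the coefficients. The penalty is
  `5 · smoothing_factor⁴`; the fourth power makes the user factor act on
  the smoothing length scale, so raising it visibly underfits (a noisy
  bimodal profile loses its second mode around factor 10) and lowering it
  overfits. The base penalty was calibrated once on the four canonical
  profile families at 5% noise so that within-family noise is damped while
  both modes of a bimodal profile survive. A P-spline was chosen over a
  knot-selecting smoothing spline because its output varies continuously
  with the input: knot selection quantizes near-identical profiles into
  discretely different smooth curves, which the neighborhood embedding
  then tears into spurious islands. Profiles shorter than 4 nt are
  returned unsmoothed with a warning; fits are clipped at 0.
- **Curve features**: number of maxima, trapezoidal area under the curve,
  and arc length `Σ sqrt(1 + Δx²)`. Maxima counting uses an absolute
  prominence floor of 0.05 on the normalized [0, 1] scale (plateau runs
  count once, boundary maxima are eligible); a strict count is unusably
  sensitive to quantization wiggles, and a *relative* floor inflates the
  count on near-flat profiles. The three features are z-scored across the
  peak set to be commensurate with the [0, 1] profile values and appended
  to the smoothed profiles.
- **Embedding**: UMAP with 2 components, 5000 epochs, min_dist 0.01,
  neighborhood size 5, seeded (default 42) for reproducibility. Fewer than
  7 profiles fall back to the first two principal components with a
  warning.
- **Clustering**: k-means with 100 initializations and up to 10000
  iterations. Without a forced k, k runs from 1 to k_max (default 15) and
  the chosen k is the smallest at which the WSS curve has converged: the
  k→k+1 improvement falls below 5% of the k−1→k improvement, or below 1%
  of the total (k=1) WSS. Improvement relative to the *previous*
  improvement is used because any fixed fraction of the current WSS never
  converges on tight clusters (splitting a tight cluster keeps removing a
  roughly constant share of what remains). The AIC curve,
  `AIC(k) = n·d·ln(WSS/(n·d)) + 2kd` with d = 2, is recorded and plotted
  as a diagnostic; on well-separated tight clusters it keeps decreasing
  with k and is therefore not used for selection.
- **Sharp/broad rule**: a cluster is sharp iff its median raw CV strictly
  exceeds the peak-set median (a single cluster is never sharp); a peak is
  sharp iff its CV > 0.2 *and* its cluster is sharp.

The embedding input is the smoothed profile plus features; feeding raw and
smoothed profiles together was considered and rejected as redundant —
smoothing exists precisely to remove the noise dimensions.

## Synthetic data

The generator emulates the essential structure of a CLIP peak landscape:
seven profile families (uniform, linear, unimodal Gaussian, bimodal
Gaussian — the canonical classifier test set — plus plateau, constant and
sharp-spike for CV contrasts), each parameterized by length (default 77
nt), amplitude (default 100×, a realistic eCLIP peak coverage) and a noise
level. Noise drives two mechanisms:

- per-position multiplicative log-normal noise with unit mean, its
  log-variance split half i.i.d. and half autocorrelated on an 8-nt scale —
  neighboring positions share reads, so real coverage noise is correlated;
- peak-to-peak shape variability: mode widths get a log-normal factor and
  mode centers a normal offset (sd = noise × length). Real binding sites
  within one shape class form a continuum, not copies of one curve; this
  also matters technically, because UMAP's manifold assumption breaks on
  exact-duplicate clusters and it can tear them apart.

At noise 0 the generator returns the exact family curve, rounded to
integer counts. Reads realizing a target profile are built greedily
(sweeping 5'→3', start enough reads at each position to reach the target),
which is exact wherever the target never falls faster than reads expire —
always, for read length 1. The dataset writer lays peaks on one synthetic
chromosome with alternating strands and emits BED6 peaks, a sorted indexed
BAM, a chrom.sizes table and a truth manifest.

What the generator does *not* model: PCR duplicates, crosslink-site
truncation patterns, spliced reads, mappability gaps, or background
binding. Passing tests therefore demonstrate correctness of the method's
mechanics and its behavior on idealized shape families, not performance on
real CLIP libraries.

## Problem sizes and determinism

The test suite and the acceptance script use 4 × 50 profiles of length 77
for shape recovery, 100 peaks at ~100× mean depth for the pseudo-replicate
check, and 48-peak end-to-end runs — sizes at which every stage, including
a 5000-epoch seeded UMAP, completes in seconds. Seeding UMAP makes it
single-threaded and fully reproducible: two runs with the same inputs,
flags and seed produce byte-identical result tables.

## Known limitations

- The CV threshold 0.2 is an empirical convention carried over from CLIP
  practice, not an estimated quantity.
- The border-penalty formula is a pragmatic stand-in (see above).
- k-selection on data without clear cluster structure tends toward k_max;
  the WSS/AIC diagnostic plot should be inspected in that case.
- Cross-sample shape comparison (matching clusters between experiments) is
  out of scope.
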