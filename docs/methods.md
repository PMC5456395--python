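# Methods

## The segmentation model

Nucleolar association is measured per probe as the log2 ratio
*E* = log2(nucleolar intensity) − log2(background intensity), where the
background channel may be genomic input or the non-nucleolar
supernatant — the two are treated as interchangeable denominators.
Raw intensities are quantile-normalized across samples first (each
column is mapped onto the across-sample mean of order statistics, so
every sample shares one value distribution while probe ranks are
preserved).  Probes with a non-positive intensity in any sample are
masked and counted, never silently dropped.

*E* is smoothed per sample with sliding medians in 100 kb windows
(truncated at chromosome ends), then averaged across replicates of a
condition.  The genome-wide distribution of the smoothed averaged *E*
is bimodal — one mode per association state — which motivates a
two-state hidden Markov model with Gaussian emissions:

- Emission family: Gaussian per state.  This is a convention of this
  package; heavier-tailed emissions (e.g. Student-t) would behave
  similarly on smoothed data because the sliding median already clips
  outliers.
- Initialization is deterministic: emission means at the 25th/75th
  percentiles of the data, equal variances (overall variance / 4),
  symmetric sticky transitions (0.99 self-transition), uniform start
  probabilities.  No random restarts by default, so fits are exactly
  reproducible; if a fit degenerates (a state's sd collapses below
  1e-4 or Viterbi never visits a state) the fit restarts from wider
  percentile pairs (10/90, then 40/60, 5/95) and raises
  `DegenerateFitError` after those fail.  Unimodal inputs therefore
  end either in one dominant state or in an explicit error — never in
  a confident two-state segmentation.
- Chromosomes are independent sequences: Baum–Welch and Viterbi never
  carry state across a chromosome boundary.
- The state with the larger fitted mean is labeled NAD, always.
- The monitor records the full log-likelihood trajectory; monotone
  non-decrease (within float noise ~1e-6) is asserted in tests.

Decoding uses the Viterbi path (not posterior marginals): domains are
contiguous by construction and the path is what the minimum-length rule
operates on.  Segment boundaries sit at the first probe position of the
next segment; the final segment of a chromosome extends one probe
spacing past its last probe.  NAD segments shorter than 10 kb are
relabeled iNAD and merged into their neighbors — the minimum length is
phrased as a property of NADs only, so no minimum is imposed on iNAD
gaps.  Each domain's score is the mean smoothed *E* of its probes.

Differential domains between two conditions are pure base-pair set
algebra on the NAD interval sets: young-only = Y \ S, senescent-only =
S \ Y, constitutive = Y ∩ S.  The three sets are pairwise disjoint and
reconstruct the inputs by union; both properties are asserted in tests.

## Interval statistics

All coordinates are 0-based half-open (BED).  Complement, intersection,
subtraction, union and overlap counts are implemented as sweeps over
sorted disjoint interval arrays and are validated exhaustively against
a per-basepair boolean-array oracle (200 random interval sets on a 1 Mb
chromosome agree bp-exactly).  The Jaccard index is intersecting bp /
union bp, the bedtools convention.

Conventions that were genuinely open and are fixed here:

- Feature-to-class assignment (gene/repeat densities): a feature counts
  in the domain class covering the majority of its length; an exact
  50/50 tie goes to NAD.  Densities are emitted both per Mb of the
  domain class and per Mb of the analyzed extent, since the two
  normalizations answer different questions.
- Chromatin-state composition requires the state annotation to
  partition (overlaps are rejected).  Fractions are class-size
  normalized; a state absent from one class yields an explicit ±inf
  log2 ratio, never a dropped row.
- Per-base segment means zero-fill bases without signal coverage (the
  conservative bedGraph reading).
- Border metaprofiles: only domains wider than 500 kb contribute; the
  5' border is the domain start on the p→q axis and the 3' border
  (domain end) is mirrored before averaging, so in every profile
  negative offsets lie outside the domain and positive offsets inside.
  Windows extending past the analyzed chromosome extent are excluded
  from the per-bin average rather than zero-filled.
- Boxplot class summaries report n, median, quartiles
  (linear-interpolation percentiles) and the notch 1.58·IQR/√n.

## Hi-C contact classes

Input is the sparse GSE63525-style dialect: whitespace triplets
(bin_i start, bin_j start, raw count) at 10 kb bins plus a per-bin
normalization vector, one value per line.  Normalized frequency =
raw / (v_i · v_j); records touching a NaN or zero vector entry are
dropped and counted, and loaded = classified + dropped is a conserved
invariant through the pipeline.

Each bin gets a domain label by majority-bp overlap with the NAD set
(tie → NAD).  Pair classes: NAD-NAD, iNAD-iNAD, mixed.  Arm classes
come from the centromere interval of the layout table (a required
input, not hard-coded): bins entirely before the gap are p, entirely
after are q, bins overlapping the gap are unlabeled and their contacts
dropped with a count.  Distance is start-to-start (bin_j − bin_i).

Distance profiles average normalized frequencies per class per distance
bin.  The default denominator is observed pairs only; an all-pairs mode
(unobserved pairs count as zero) computes possible pair counts per
distance per class from the bin-label autocorrelation (FFT) and is the
better choice for sparse, depth-limited maps.  Band summaries use
10–50 Mb and >100 Mb by default; the 10 Mb lower bound excludes
intra-domain contacts and is configurable; chromosomes shorter than a
band are omitted with a warning.  Matrix masking for heatmaps blanks
rows/columns outside the kept class with NaN and is idempotent.

## Imaging

Shell ROIs have a fixed physical depth, default 240 nm, converted to
whole pixels by nearest rounding (240 / 80.25 nm ≈ 2.99 → 3 px).
Distances are Euclidean on the pixel grid (scipy's exact distance
transform), not chessboard.  The lamina shell is the set of nucleus
pixels within depth of the nucleus boundary (inward); the perinucleolar
shell is the set of nucleus pixels outside the nucleolus within depth
of the nucleolus boundary (outward).  The two shells may overlap; no
exclusivity is imposed.

Per-ROI metrics: intensity fraction (ROI sum / nuclear sum), C.V.
(population sd / mean over ROI pixels; NaN sentinel for a zero-mean
ROI), and the bright-pixel share.  "Brightest pixels" has two
non-equivalent readings and both are provided: threshold at 90% of the
maximal nuclear intensity (default) and the rank-based top decile; on
images with a single extreme pixel the two disagree strongly, so the
mode is an explicit flag.  All metrics are invariant to positive
rescaling of the image.  Object counting uses 8-connectivity in 2D and
26-connectivity in 3D; volume = voxel count × voxel volume (default
voxels 80.25 × 80.25 nm × 500 nm z-step).

## What the synthetic data emulates — and what it does not

- **Domain truth**: alternating NAD/iNAD tilings with exponential
  segment lengths (mean 400 kb by default, the size scale of structural
  chromosomal domains), truncated at chromosome ends — the length law of
  a two-state Markov process.  Real NAD landscapes have
  chromosome-specific biases (acrocentric p-arms, centromere
  proximity) that the generator does not model.
- **Array signals**: per-probe log2 enrichment drawn from the state's
  Gaussian (±1, σ 0.3 by default; two replicates; probes on a regular
  1 kb grid, a convention — real array spacing is irregular).  The
  background channel gets independent lognormal intensity so that
  quantile normalization and the log-ratio step are exercised
  non-trivially.  No probe-GC or spatial artifacts are simulated.
- **Annotations**: a 5-state toy chromatin segmentation with the
  heterochromatin state enriched inside NADs (p = 0.7 vs 0.2); five
  percentage-normalized replication fractions switching from an early
  to a late profile exactly at NAD borders; genes with activity classes
  coupled to domain state; per-gene fold-changes whose sign couples to
  the domain-change class (loss of association → activation).  Setting
  the couplings to their null values (equal state probabilities, zero
  effect) must and does propagate to null downstream results.
- **Hi-C**: power-law distance decay (exponent 1), a multiplicative
  homotypic boost (default 2) for NAD-NAD pairs in the 10–50 Mb band,
  lognormal multiplicative noise (CV 0.2, mean-corrected so class means
  are unbiased), and a uniform [0.5, 2] normalization vector applied in
  reverse (raw = normalized · v_i · v_j) with a 2% NaN fraction to
  exercise the loader's dropping logic.  A `keep_fraction` parameter
  subsamples bin pairs uniformly, emulating finite sequencing depth;
  class means are unbiased under it.  No TAD structure, compartment
  checkerboard, or interchromosomal contacts are simulated.
- **Nuclei**: a circular nucleus (radius 7.5 µm at 80.25 nm pixels) with
  up to three disjoint circular nucleoli kept clear of the lamina shell,
  target intensity shares deposited in the two shells (defaults
  0.095 lamina / 0.052 perinucleolar, proliferating-fibroblast-like),
  lognormal pixel noise and bright foci.  After noise and foci the
  region sums are rescaled so the deposited fractions hold exactly;
  the closed-loop test therefore validates the ROI machinery, not the
  noise model.  Real confocal sections have PSF blur, background
  outside the nucleus and imperfect masks, none of which is modeled.

Because the generators share the package's own shell/binning/interval
conventions, passing recovery tests demonstrates internal consistency
and correctness of the statistics under the stated model — not
robustness to real-data artifacts such as array platform effects,
copy-number variation, or segmentation errors in microscopy masks.

## Problem sizes and numerical choices

The recovery suites run at sizes chosen to make sampling error small
relative to the asserted tolerances: 10 × 10 Mb chromosomes (100k
probes) for segmentation accuracy (≥95% bp asserted, ~99% typical);
one 120 Mb chromosome at 10 kb bins with pair subsampling (12–15%,
several million pairs retained) for boost recovery (±10% asserted,
±2% typical); 50 nuclei for shell-fraction medians (±0.01 asserted,
exact-to-float typical); 200 random interval sets for the bp oracle
(exact agreement required).  `scripts/acceptance.py` re-runs all of
these from a single `--seed` and writes the measured values as JSON.

Tie-breaks and degenerate inputs are fixed as follows: majority-overlap
ties go to NAD (features and Hi-C bins alike); zero-denominator ratios
become ±inf/NaN sentinels; empty masks or classes warn and return
empty results; chromosomes with fewer than two probes are skipped with
a warning.

## Known limitations

- Sex chromosomes and repeat clusters (satellite, rDNA/NOR) are out of
  scope, matching the mappability limits of tiling-array NAD maps.
- The HMM assumes homoskedastic-per-state Gaussian emissions on
  smoothed data; strongly skewed enrichment distributions would bias
  the fitted means.
- The all-pairs Hi-C denominator ignores the mappability filtering that
  produced NaN normalization entries (dropped bins still count as
  possible pairs).
- 3D imaging support covers object counting and volumes only; shell
  ROIs are 2D single-section constructs, as in the quantification they
  reproduce.
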