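# Methods

This note records the models, numerical choices and limitations behind
`scpriq`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what each component assumes, which defaults matter,
and what the synthetic benchmarks do and do not demonstrate.

## Reporter channels and analytic masses

Reporter channels are defined by the elemental composition of the reporter
cation; theoretical m/z is the sum of monoisotopic atomic masses (NIST
values via `pyteomics.mass`) minus one electron mass (5.48579909e-4 Da).
The packaged table covers TMT 11-plex and the TMTPro series through 135N.
Heavy-isotope placement follows the reagent chemistry: the *N* channels use
the single ¹⁵N plus (nominal − 127) ¹³C substitutions, the *C* channels use
(nominal − 126) ¹³C only. Adjacent N/C channels of equal nominal mass are
therefore split by (¹³C−¹²C) − (¹⁵N−¹⁴N) = 0.00632 Th, the fine structure
that drives resolution requirements for >9-plex work.

The acetyl-lysine diagnostic ion is the immonium-derived fragment C₇H₁₂NO⁺
at 126.09134 Th, 0.03639 Th below the 126 reporter (C₈H₁₆N⁺, 126.12773 Th).
At m/z 126 that gap is ≈289 ppm; `detect_diagnostic_ion` uses exact
arithmetic and refuses tolerance windows that reach the reporter mass
(ambiguous assignment) rather than attempting a probabilistic split.

## Reporter extraction

Per channel, the most intense peak within the tolerance window (default
0.005 Da; ppm mode available) of the theoretical m/z is taken; ties break
to the nearest m/z. A peak can satisfy at most one channel — the one whose
theoretical mass it is nearest — so a single intense interference cannot
double-count into two channels. Zero-intensity matches are coerced to
missing: absence of evidence is represented as missing throughout, never as
zero, matching the minimum-average-intensity filtering philosophy
downstream.

## Impurity correction

Isotopic impurity leakage is modelled as observed = M·true, where column j
of M gives the fractions of channel j's signal appearing in each channel.
The inverse solve uses non-negative least squares (`scipy.optimize.nnls`),
which cannot produce the negative "corrected" intensities plain inversion
yields on noisy low-count data. Missing channels enter the solve as zeros
and are restored to missing afterwards. Matrices must be column-stochastic
(sums ≤ 1) and diagonally dominant; singular matrices are rejected.

## Mass recalibration

TOF mass error is modelled as a single constant relative (ppm) offset per
file — the observed behaviour is a per-file scalar drift, and a per-file
adjustment factor suffices. The offset is estimated as the *median* of
1e6·(obs − theo)/theo over all reporter anchor matches within the search
window (default 50 ppm); the median resists the asymmetric outliers that
co-isolated background peaks produce. Correction replaces mz by
mz/(1 + offset·1e-6) for peaks inside the user range only (default: the
plex reporter region padded by 0.5 Th); peak counts, order and intensities
are untouched. Piecewise or per-scan drift models are out of scope.

## QC filtering

An MS2 spectrum is retained iff at least one *required* channel (the
single-cell wells, by default 127N–131N) shows a reporter within 0.005 Da
of its exact mass. A run passes the blank rule iff the number of spectra
with signal in any single-cell channel strictly exceeds 3× the number with
signal in the 126 method-blank channel; spectra are *counted* (not
intensity-summed), the natural reading of a spectra-count criterion.
Binning windows for the 12-per-100-Da complexity filter are half-open,
contiguous and anchored at m/z 0; the bin phase is unspecified upstream and
anchoring at zero is the deterministic choice.

## Quant matrices and ratios

Feature values are sums (not means) of reporter intensity over the
feature's spectra, per channel — intensity-based quantification with summed
roll-up. Features with mean intensity (over detected channels) below 10 are
dropped. Total-sum normalization rescales each selected column so its sum
equals the mean of the pre-scaling column sums; a fixed scaling target is
equivalent up to a global constant and the mean keeps the matrix in its
original intensity regime.

Ratios between channel groups are the median of all pairwise value ratios,
taken on the log scale: ratios are multiplicative, and the log-scale median
(geometric mean of the middle pair for even counts) keeps
ratio(a,b) = 1/ratio(b,a) exact. Ratios are capped at 100-fold, the ceiling
common in quantitative tools; features detected in only one group are
reported *at* the cap rather than dropped, so presence/absence responses
(a protein appearing only in treated cells) survive roll-up instead of
vanishing. P-values come from a two-sided one-sample t-test of the log2
pairwise ratios against 0; the upstream description requires a p-value per
rolled-up ratio without naming the test, and the t-test on log ratios is
the standard choice. PTM ratios are normalized by dividing by the parent
protein's ratio (cap re-applied); callers are expected to build protein
ratios from >1 unique unmodified peptide.

## Cell-cycle scoring

The estimator is deliberately simple: each detected marker row is min-max
scaled across cells, each stage with ≥3 detected markers (`min_markers`)
is scored as the mean scaled abundance of its markers, and a cell is
assigned the argmax stage with the top-minus-runner-up margin as
confidence. Row scaling removes per-protein dynamic-range differences, and
per-cell global intensity scaling is absorbed provided normalization has
equalized loadings. This is a flagging tool, not a removal/regression
method. The packaged panel is a small synthetic stand-in of well-known
stage markers (6 per stage across G1/S/G2M/prophase/prometaphase) for tests
and examples; real analyses should load a curated panel (e.g. a
119-protein marker set) from a two-column file.

## Synthetic data: what it emulates and what it does not

`simulate_run` emulates the statistical structure that the processing stack
actually touches:

- per-channel reporter intensities Poisson-distributed around
  design abundance × mean ion count (default 1e4 ions in the top channel —
  a healthy reporter in an accumulating TOF instrument);
- mass error = systematic per-file offset + N(0, σ) scatter with
  σ = 3 ppm, the scan-to-scan mass precision scale of a calibrated TOF;
- impurity leakage applied to expected signal *before* counting noise;
- a carrier channel at a configurable fold-excess, a 126 blank, uniform
  noise peaks (kept out of 0.02 Th guard bands around reporter/diagnostic
  masses so occupancy ground truth aligns exactly with extractable signal),
  and backbone fragment peaks above m/z 200;
- optionally a shared ion-sampling budget: signal scales by
  B/(B + total ions including carrier) while an additive co-isolation
  floor does not, which reproduces the carrier proteome effect — known
  ratios stay flat while the carrier is small relative to the budget and
  compress toward 1 when the carrier dominates (a planted 5:1 reads ≈2:1
  at 4000×, with budget 5e4 and floor 30 ions in the benchmarks).

It does *not* simulate peptide fragmentation chemistry (no b/y series from
sequences), chromatography, ion-mobility-dependent interference, or
detector saturation. Passing benchmarks therefore demonstrate that the
*algorithms* are correct under a realistic counting-statistics model, not
that real-instrument headline figures are reproduced; real-data values
(e.g. a dilution-series R² of exactly 0.982) depend on deposited raw runs
and are out of scope.

`simulate_matrix` plants structure for recovery tests: log-normal protein
baselines (log10 mean 4.0, sd 0.5), a uniformly drawn cycle stage per cell
with that stage's markers elevated 4-fold by default (the scale of
cycle-driven abundance swings), per-cell log-normal measurement noise
(sd 0.15 in log10), treatment effects that are either uniform folds or
subpopulation-exclusive expression, and logistic dropout in log10 abundance
(midpoint 2.0, scale 0.3) so low-abundance values vanish first.

## Problem sizes and numerical conventions

The test suite and acceptance script use 150–1000 spectra per simulated
run, 75–200 features, and 100–230 cells — sizes at which the estimated
quantities (median offsets, median ratios, stage accuracies) are stable
across seeds while the whole suite runs in well under a minute. All
randomness flows through `numpy.random.default_rng` seeds, so every result
is exactly reproducible. Intensity ties in top-N and binning filters break
to the lower m/z; merged-spectrum precursor fields are intensity-weighted
means; records with unknown 1/k0 merge only with other unknown-1/k0
records; MGF m/z values are printed at 5 decimals, making
write → read → write byte-stable.

## Known limitations

- The interference-free index formula (1 − mean(ko)/mean(parent), clamped
  to [0,1], missing as zero) is this package's explicit construction for
  knockout-standard diagnostics; other tools may scale differently.
- Constant-ppm calibration cannot capture mass-dependent residuals across
  a wide m/z range; it is intended for the narrow reporter region.
- The impurity model ignores coupling between impurity leakage and the
  counting noise of the leaked ions.
- `merge_redundant_spectra` is O(n²) in the number of spectra per
  connected-tolerance comparison batch; it targets the small redundant
  groups produced per precursor, not whole-run clustering.
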