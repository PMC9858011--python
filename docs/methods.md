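# Methods

This note documents the models behind `waspmon`, the defaults and why,
what the synthetic data does and does not emulate, and the numerical
choices made where the design was genuinely open.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A `SpectraSet` couples an n×p absorbance matrix (AU) to a strictly
increasing, near-uniform wavelength grid (max/min adjacent-spacing ratio
≤ 1.01, ≥ 8 channels) and per-row metadata `(specimen_id, day, zone,
position, scan)`, unique per row.  The default grid is 125 channels over
908–1670 nm (~6.1 nm pitch), the layout of the handheld spectrometer class
used for this kind of produce monitoring; the channel count is
configurable because instruments differ.  Replicate averaging
(`average_scans`) marks collapsed fields with the sentinel 0 so the
metadata schema never changes shape.  Wavelengths are stored as floating
nm and matched to the grid by nearest channel (ties to the lower
wavelength); band labels in reports are conventionally printed as integer
nm.

Both wide (one column per channel) and long (tidy records) CSV dialects
round-trip losslessly; wide is the canonical fixture format.  Inner and
outer leaf zones live in one file as a metadata field and every analysis
stage filters by zone, because the zones behave differently and are
analysed separately throughout.

## Synthetic study design

The generator emulates a 5 heads × 6 days × 2 zones × 3 positions × 5
scans acquisition (900 spectra).  A spectrum is

    baseline(head, placement) + (1 + m) · Σ_b amp_b(zone, day) · G(λ; c_b, σ_b) + ε

with Gaussian band shapes `G` (standard for NIR overtone sub-bands and
analytically convenient; the line shape is this package's choice), a
dominant water band at 1450 nm (σ = 35 nm, 0.9 AU) carrying a +0.05 AU
inner-zone offset (inner leaves hold more water), a broad 1400 nm shoulder,
and 19 satellite bands at the consensus WAMAC wavelengths (σ = 8 nm, base
0.05 AU) with linear day trends: positive in 1350–1400 nm (weakly bound
water increases as moisture is lost to transpiration) and 1500–1600 nm
(structural water fraction grows), negative in 1400–1500 nm (free/hydration
water is lost).  Outer-zone slopes are 1.5× the inner-zone slopes (exposed
leaves respond faster); an optional inner-zone plateau day freezes trends
after day 2.  Trend magnitudes are ±0.004–0.005 AU/day with one dominant
band per region (1385, 1441, 1534 at 0.010; 1571 at 0.008), mirroring which
difference-spectrum peaks are most prominent in this kind of data.  These
effect sizes are synthetic calibrations — the source study reports band
dynamics only graphically — chosen once so that band structure is
recoverable by the pipeline, and not revisited.

Noise is hierarchical: a per-head additive offset (sd 0.02 AU), a baseline
intercept + slope in scaled wavelength redrawn at every instrument
placement (sd 0.04 / 0.02 AU, doubled for the inner zone, which shows more
baseline variation), a multiplicative factor on the band sum per placement
(sd 0.02), and white per-scan noise (sd 0.002 AU).  All draws come from a
single `numpy` generator seeded from the config, so a seed pins the
dataset bit-for-bit.

**What this does not emulate:** head×day interactions (every head ages
identically up to its static offset), nonlinear or non-monotone band
trajectories, wavelength-correlated noise, temperature effects, or any
VIS-region pigment chemistry.  Because the day effect is deterministic
given the day, classification and regression on synthetic data are much
easier than on real produce: passing the recovery thresholds (LDA LOLO
≥ 80 %, PLS R²_cv ≥ 0.7) demonstrates that the pipeline plumbing recovers
programmed structure without specimen leakage — not that real lettuce is
predictable to that accuracy.

## Pre-treatments

All transforms are strictly row-wise and shape-preserving, and append
their name to the set's provenance.

* **Savitzky–Golay** — least-squares local polynomial smoothing; 2nd
  order/11 points ahead of difference spectra, 2nd order/17 points ahead
  of aquagrams, 0th derivative in both uses.  Edges evaluate the
  polynomial fitted to the terminal full window (no reflection padding —
  no fabricated data where water-band tails reach the grid ends).
* **SNV** — per-spectrum centring and scaling to unit (n−1)-denominator
  sd; removes offset and multiplicative scatter.
* **Detrend** — per-spectrum subtraction of a least-squares polynomial in
  wavelength, degree 2 by default (the convention coupled with SNV in the
  scatter-correction literature; degree 1 available).  "Detrended"
  analysis recipes apply detrend to raw absorbance without prior SNV; a
  combined recipe is expressible in config.

## Difference spectra and peak picking

Spectra of one zone are pre-treated (default SG(11,2)+SNV), pooled with
equal weight per day, and the reference-day (day 1) mean is subtracted
from every other day's mean — five difference spectra for a six-day
design.  Peaks are interior channels whose |value| exceeds both
neighbours and a relative threshold (default 0.10 of the global maximum);
plateau ties resolve to the lowest wavelength, edge channels are never
peaks, and the rule is invariant to positive rescaling.  The rule is this
package's construction (the protocol literature says only that major
peaks were "investigated"); the threshold and tie-breaks are config-
exposed.

Parameter-recovery tests compare day-6 difference peaks of *raw* day
means against the generator's truth table: SG(11) smoothing of the narrow
synthetic bands shifts extrema by up to two channels, so the ±1-channel
recovery claim is about generator→difference fidelity, with the smoother
assessed separately against its own polynomial-fit oracle.

## PCA

Mean-centred SVD; loadings carry a deterministic sign convention (largest
|element| positive) so peak signs reproduce.  Outlier screening uses
Hotelling T² over the retained components against its F-distribution
limit and the Q residual against the Jackson–Mudholkar limit, either
statistic flagging at α = 0.01 — the criterion is this package's choice
(the protocol names none).  Under a Gaussian null with a clean
latent/residual split both statistics flag ≈ α (checked by Monte-Carlo at
n = 5000).  The storage-trend component (PC 6/PC 7 in the motivating
study) is named in config, not auto-selected: the visual ordering
criterion used to choose it does not reduce to a formula.

## PCA-LDA

Spectra are compressed to `nr_pcs` PC scores; Fisher LDA solves
S_b·w = λ·S_w·w in PC space (within-class scatter checked for rank before
solving) and predicts by nearest class mean in discriminant space, ties
to the lowest label.  `nr_pcs` is chosen by threefold stratified CV over
1..30: highest validation accuracy, ties broken by smallest
calibration−validation gap, then fewer components.  Validation is
leave-one-lettuce-out with the PCA refit inside every fold — the protocol
is silent on this, but refitting is the only honest choice (no specimen
leakage).  Pooled fold predictions form percentage confusion matrices,
columns per true class summing to 100, average accuracy = unweighted
diagonal mean; this reproduces the arithmetic of published tables of this
layout exactly.  Per-channel contributions back-project each discriminant
through the PCA loadings and combine |b_d(λ)| with
discriminant-eigenvalue weights (a sum-of-squares variant is selectable);
the result is normalised to max 1 and is invariant to orthogonal
re-rotations of the retained PC basis.  The formula is this package's
construction.

Under label permutation, LOLO validation accuracy sits slightly *below*
chance (≈ 13–14 % vs 16.7 % on the seeded data) — the well-known
pessimistic bias of cross-validated accuracy under the null — so the null
test asserts proximity to chance within simulation error rather than
exact 1/6.

## PLS

NIPALS PLS1 on centred X and y (integer day 1–6), regression vector
folded to channel space so prediction is exactly
`(x − x̄)·b + ȳ`; at full rank it reproduces OLS, and it matches
scikit-learn's PLS implementation on fixtures (the library is used only as
a cross-check, never as the implementation).  The latent-variable count
minimises LOLO-CV RMSE (ties to fewer); R² = 1 − SS_res/SS_tot on pooled
held-out predictions, the common chemometrics convention.  Outlier
exclusion iteratively removes rows with |CV residual| > 2.5·RMSE_CV (≤ 3
iterations, abort if half the data would go); both threshold and
iteration cap are package choices, and a model fitting to numerical
precision (RMSE below 1e-8·max|y|) excludes nothing.  Overlapping
collinear bands delocalise PLS coefficients, so only the dominant
programmed slope tier is asserted to rank in the top-10 |b| channels.

## Consensus WAMACs and aquagrams

Peak tables from the four evidence streams are pooled per zone, snapped
to the nearest grid channel (warning beyond half a spacing) and
deduplicated per (source, context, wavelength).  The frozen selection
rule — nominated by ≥ 2 distinct source categories (contexts pooled) in
at least one zone, and present in both zones — applied to the bundled
published prominent-wavelength tables reproduces the 19 published WAMAC
wavelengths exactly (a band highlighted once in a single zone, e.g.
1497 nm, is correctly excluded); the rule is monotone in evidence.
Thresholds remain config-exposed.

Aquagrams pre-treat all spectra in scope (default SG(17,2)+SNV),
standardise each channel over the pooled scope ((A − μ)/σ), average per
group at the WAMAC channels, and subtract the reference group's vector.
Pooling the normalisation over all days of a zone (rather than per day)
is deliberate: it makes day-to-day values comparable, which the radar
overlay requires, and makes the aquagram invariant to global affine
transforms of the spectra.  The C1–C12 class ranges and band assignments
ship as a static annotation table; wavelengths in unlabelled table ranges
are reported "unclassified" rather than guessed.

## Reference statistics

Paired two-tailed t-test (t = mean(d)/(sd(d)/√n), df = n−1) for pigment
band comparisons at 454/479/678 nm on a VIS grid, erroring on
zero-variance differences; group summaries report mean, (n−1) sd and SEM,
with singleton groups flagged and given sd 0 rather than NaN.  Published
pigment t-values cannot be recomputed without the per-pair raw data and
are not targets.

## Problem sizes and limitations

The full 900-spectrum design is small enough that tests and the
acceptance script run it end-to-end in seconds; nothing is scaled down.
Known limitations: no JCAMP-DX/SPC ingestion (CSV only), no
reflectance→absorbance conversion, no robust PCA or regularised
discriminants, no interval-PLS variable selection, and the synthetic data
caveats above — in particular, synthetic recovery metrics must not be
read as expected real-data performance.
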