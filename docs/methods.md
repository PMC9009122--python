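# Methods

This note documents the models, conventions and numerical choices behind
`lysoquant`, in the spirit of a methods section: what each stage computes,
what the synthetic generator does and does not emulate, and where the
design was genuinely open.

## The measurement model

The pipeline mirrors a manual confocal workflow for single z-planes. A
cell mask comes from the cell-body marker channel (or from segmentation
provided as labeled images); organelle channels are denoised with a
difference of Gaussians (band-pass; small sigma near the spot scale,
large sigma capturing background), thresholded automatically inside the
cell mask, and binarized. Connected components (8-connectivity by default,
matching ImageJ's particle analyzer; 4 selectable) smaller than
`min_area_px = 10` are discarded — the filter keeps area ≥ 10, i.e. the
strict reading of "smaller than 10 px" (the alternative ≥ 11 reading is a
one-flag change). "10 px" is interpreted as an *area*, not a diameter,
because pixel-count filters in particle analysis are area-based. Every
automatic threshold that was applied is recorded on the resulting mask and
propagated into the per-cell output tables. Isodata is the default
automatic method because it is the historical ImageJ default; Otsu is
selectable and both are computed from the in-mask histogram only.

### Colocalization

Pearson's r is the sample correlation of paired raw intensities within the
whole-cell mask (cytoplasm ∪ nucleus); a constant channel makes the
coefficient undefined and yields NaN with a warning, never a silent 0.
Manders coefficients are the intensity-weighted, thresholded form: M1 is
the fraction of channel-A intensity (summed over A's mask) that lies in
pixels positive for both masks, M2 symmetrically. Restricting the
numerator to the mask intersection keeps both coefficients in [0, 1];
summing A over *all* B-positive pixels, including those below A's own
threshold, could exceed the denominator. Swapping the channel arguments
swaps M1 and M2 exactly.

### LMP score

Lysosomal membrane permeabilization is scored as the non-lysosomal
fraction of the lysosomal-enzyme signal. The default, area-based score
follows binary-mask subtraction: lysosomal area = |enzyme ∧ membrane|,
cytosolic fraction = 1 − lysosomal/total. Cells with an empty enzyme mask
are excluded (logged), since 0/0 is undefined.

The area score cannot, by construction, measure what fraction of the
*intensity* is diffuse: a faint cytosolic haze below threshold contributes
no area. The intensity-weighted variant (`lmp_score_intensity`) therefore
integrates the enzyme channel over the membrane mask dilated by 6 px — so
the PSF tails of lysosome-confined spots are attributed to lysosomes —
after subtracting the mean cytosolic level estimated from the cytoplasm
proper (eroded 3 px away from the cell rim, nucleus and lysosome
neighbourhoods excluded, so PSF dimming at edges does not bias the
estimate). The camera/noise floor is taken from outside the cell. Sums are
left unclipped pixel-wise so zero-mean noise cancels; the lysosomal total
is clamped to [0, total] at the end. On simulated ground truth this
recovers a designed diffuse fraction of 0, 0.3 or 0.6 within ±0.03.

### Tandem reporter

Yellow (autophagosome) pixels are GFP ∧ mCherry; red (autolysosome) pixels
are the remaining mCherry-positive pixels. The two areas partition the
mCherry mask *exactly*, before any size filtering; dot counts then apply
the same ≥ 10 px component filter as puncta detection. Both the raw
partition areas and the filtered areas are reported, because the exact
partition identity and the size-filtered counts cannot be carried by one
pair of numbers.

### Positioning

The nuclear ROI is summarized by its moment-equivalent ellipse (centroid +
second central moments; semi-axis = 2·√eigenvalue, which is exact for a
filled ellipse). The distance of a lysosome to the nuclear border is
defined by subtraction: Euclidean distance from its centroid to the
ellipse centre, minus the ellipse's mean radius (a+b)/2. This is *not* the
true point-to-boundary distance for eccentric nuclei; it is the plainer
"average radius" convention, with the geometric mean √(ab)
(area-preserving) available as an option. Negative values — centroids
inside the mean-radius circle — are retained; they carry positional
information. Cells enter the analysis only if cytoplasm:nucleus area
≥ 2.0 (boundary inclusive). A minimum-ratio reading was chosen because an
exact-equality gate would admit almost no cells; the threshold is
configurable. Summaries (median and linear-interpolation quartiles) are
produced both per cell and per animal (aggregating cell medians), since
pooling conventions differ between labs.

## Statistics for nested data

Cells sampled within an animal are not independent; the animal is the
experimental unit. `nested_t` averages cells within each animal and runs a
pooled-variance unpaired two-tailed t on the animal means, df =
n_animals − 2. For balanced data this equals the mixed-model nested t.
With unequal cells per animal, animal means are weighted equally by
default (each animal counts once, regardless of how many cells were
imaged); cell-count weighting is available but changes the estimand.
Simulation with strong between-animal variance confirms the expected
behaviour: a naive cell-level t is anticonservative relative to the nested
test.

`two_way_anova` uses the classic balanced-design sums-of-squares
decomposition (SSA, SSB, SSAB, SSE with the usual degrees of freedom),
written directly so that large null simulations are cheap; it is verified
against a regression-based (type-II) fit, which also serves as the
documented fallback for unbalanced designs. With zero residual variance
the F statistics degenerate; they are reported as 0 (p = 1) when the
effect sum of squares is also 0 and ∞ otherwise, never silently. Tukey HSD
compares the a×b design-cell means via the studentized-range distribution
with the ANOVA residual df (equivalent to a one-way Tukey on the combined
factor, since the residual SS coincide). A Kruskal–Wallis omnibus with
Dunn-style pairwise z comparisons (pooled mean ranks, tie-corrected
variance, Bonferroni adjustment) is provided as a thin rank-based
alternative; "Kruskal–Wallis post hoc" phrasing in the field is
nonstandard, and omnibus + Dunn is the interpretation implemented.

Null calibration: both tests hold their nominal α = 0.05 within ±0.01
over 5000 simulated null datasets (the acceptance suite re-measures this).

### pH calibration

The standard curve is ordinary least squares of the 440/535 emission ratio
on calibration pH — ratio-on-pH rather than pH-on-ratio, because the
calibration pH values are clamped (controlled) while the measured ratio
carries the noise — and inverted at read-out: pH = (ratio − intercept)/slope.
At least three distinct levels spanning one pH unit are required; readings
outside the fitted range are returned but flagged as extrapolated.
Held-out samples are treated as wells read in triplicate, as plate-reader
assays are in practice; at 2 % multiplicative noise a triplicate-mean
reading has a pH standard error near 0.03, so the ±0.1 recovery band
checked by the tests corresponds to roughly three standard errors — single
wells would sit at ±2σ and fail it regularly.

### Scalar estimators

The optical-fractionator estimate is N = ΣQ⁻ / (ssf · asf · tsf) — counted
objects divided by the section, area and thickness sampling fractions
(1-of-4 serial sections give ssf = 1/4). DAB staining burden is the
thresholded stained area over the ROI area, divided by the same ratio on
the contralateral side, expressed as percent of the control-group mean;
it is exactly scale-invariant in the areas. Cytosolic enzyme activity is
normalized by the activity of the matched lysosomal fraction, with
percent-of-control rescaling as a separate step.

## The synthetic generator

`simulate_cell_image` emulates the study conditions of the tissue
analysis: 80 nm pixels, one or more cells per field, each an elliptical
nucleus (semi-axes drawn from configurable ranges) inside a jittered
superelliptical cell body whose area is (1 + ratio) × the nuclear area
(default cytoplasm:nucleus ratio 5, comfortably past the 2:1 gate).
Puncta are isotropic Gaussian spots of scale `puncta_radius_px` (default
2 px ≈ 160 nm sigma, a diffraction-limited vesicle after blur); for
ground-truth bookkeeping a punctum "occupies" the disk of radius
2·`puncta_radius_px`. Same-channel centres are kept at least one such
puncta diameter (4·sigma) apart by rejection sampling, so each thresholded
blob corresponds 1:1 to a true punctum at adequate SNR — with spots of
width sigma, any smaller separation lets neighbouring blobs merge above
threshold and would break count recovery by construction. A designed
fraction of enzyme-channel puncta shares centres *exactly* with
lysosome-channel puncta (making Manders ground truth unambiguous), the
rest stay at least one puncta diameter from every lysosome; a designed
fraction of the enzyme channel's total signal is spread uniformly over the
cytoplasm as the leaked component, with the punctate/diffuse split exact
to < 10⁻⁶ before noise. Signals are blurred by a Gaussian PSF (sigma 1 px
= 80 nm, of the order of a confocal PSF at high NA) and corrupted by
Poisson photon noise (default 200 photons at spot peak) plus additive
Gaussian read noise (sd 1 photon) — the standard fluorescence noise
model; the source images give no noise figures, so these SNR defaults are
choices of this package, not claims about any particular instrument.
`simulate_tandem_image` renders the reporter geometry (AP puncta in both
channels at identical centres, AL puncta in mCherry only);
`simulate_ph_table` produces linear ratio-vs-pH wells over the clamped
3.5–7.0 range with lognormal noise of a given CV; and
`simulate_grouped_measurements` produces nested tables — group mean +
N(0, sd_between) animal effect + N(0, sd_within) cell noise — defaulting
to the in vivo design of two groups × 8 animals × 15 cells.

What the generator deliberately does **not** emulate: 3D stacks (the
quantitative analyses are single-plane), chromatic mis-registration,
non-Gaussian optical aberrations, spatially varying background,
vesicle-size heterogeneity, and spot overlap/clumping. Passing the
recovery tests therefore shows the *measurement chain* is correct and
unbiased under the stated imaging model; it does not certify performance
on crowded or aberrated real data, where segmentation error dominates.

Determinism: all randomness flows from a single integer seed through
numpy Generators; identical parameters and seed give bit-identical images
and tables.

## Problem sizes used in validation

The test and acceptance runs use one cell per field at 320² px (448² px
with 30–50 puncta per channel for count-recovery runs, where rejection
sampling needs room), 10–20 fields per condition, 5000 replicates for the
type-I-error simulations, and 200 random 64×64 masks for the exact
labelling-oracle comparison — sizes chosen so the full validation
completes in about a minute while keeping every check statistically
meaningful.

## Known limitations

- Cell segmentation is taken as given (manual or simulated); no automatic
  instance segmentation is attempted.
- The subtraction-based border distance under-reports true boundary
  distance for eccentric nuclei along the minor axis (the definition, not
  an approximation error); the true point-to-ellipse distance is not
  currently implemented.
- Commercial deconvolution used on wide-field images has no counterpart
  here; DoG denoising is the deliberate, documented substitute.
- The ImageJ ROI-zip dialect is not read; segmentations are exchanged as
  labeled TIFF/PNG images.
- The intensity LMP variant assumes the diffuse component is spatially
  uniform within the cytoplasm; strongly compartmentalized "leak" would
  bias its background estimate.
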