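# Methods

This note documents the models implemented in `digibead`, the default
parameters and why they were chosen, the numerical conventions, and what the
synthetic validation does and does not demonstrate about real data.

## The digital readout model

Each bead is assumed to capture analyte molecules independently, so the
number of labeled molecules per bead is Poisson distributed with mean

λ = κ · C · η

where C is the analyte concentration (ng/mL), κ the capture coefficient
(molecules per bead per ng/mL) and η the labeling efficiency (probability
that a captured molecule yields an amplified, fluorescent product). A bead
is "on" when it carries at least one labeled molecule, so the true
on-fraction is 1 − e^(−λ) and the estimator

AMB = −ln(1 − f_on)

inverts the measured on-fraction back to molecules per bead. This inversion
is what makes digital counting quantitative above the single-molecule
regime: at λ = 1 the raw fraction 1 − e^(−1) ≈ 0.632 underestimates the
rate by a factor (1 − e^(−λ))/λ ≈ 0.63, while AMB is asymptotically
unbiased.

**Saturation guard.** When f_on reaches within one bead of unity
(n_on ≥ n_total − 1), AMB is capped at −ln(1 − (n_total − 0.5)/n_total) =
ln(2·n_total) and flagged `saturated`, so calibration never receives an
infinite or NaN response.

**Thresholding.** The blank condition's per-bead maximum intensities are
fitted to a Gaussian by moment estimators (sample mean; SD with the n−1
denominator — with moment estimators the fitted SD and the sample SD
coincide by construction). The on/off threshold is mean + 2 SD, and beads
strictly above it are "on" (ties count as off, the conservative choice for
false positives). The 2σ rule fixes the blank false-positive rate at the
one-sided Gaussian tail mass, 2.275%, so blank conditions read
AMB ≈ −ln(1 − 0.02275) ≈ 0.0230 *by construction*. AMB is additive in this
floor — 1 − f_meas = (1 − f_true)(1 − fp) implies
AMB_meas = λ − ln(1 − fp) — so `blank_corrected_amb` subtracts the mean
blank AMB to obtain an exactly unbiased estimate of the analyte-driven
rate; its delta-method standard error is sqrt(f/((1−f)·n)) combined over
sample and blank.

**Analog readout.** The grand mean pixel intensity over all fluorescence
frames, beads and background included, with no masking. It is the
conventional bulk-fluorescence readout the digital scheme is compared
against.

## Bead detection

Beads are localized in the non-fluorescence channel (dark disks on a bright
background for brightfield, the opposite polarity for darkfield). The
detector is a gradient-based circular Hough accumulator: Canny edges
(σ = 1.2 on the contrast-normalized frame) vote into
`skimage.transform.hough_circle` over an integer radius grid, peaks are
taken above a normalized-accumulator threshold (`sensitivity`, default
0.45, where a complete circle scores ≈ 1), and every candidate is then
refined to the centroid of the connected component of above-half-contrast
pixels around it. Refinement before merging is what makes the detector
robust: duplicate votes for one bead (neighboring radii, off-center
small-radius circles) collapse onto the same centroid and are merged by
`min_separation`, keeping the strongest vote. The component's area also
re-estimates the radius (sqrt(area/π), clamped to the search range), and
candidates whose component is far smaller than the admissible radius range
are discarded as noise specks.

Two guards keep degenerate frames safe: a constant frame returns an empty
list, and a frame whose full intensity range is explained by pixel noise
(range ≤ 10 × 1.4826 × MAD) is treated as object-free rather than having
its noise stretched to full contrast by normalization.

Conventions: coordinates are 0-based (row, col) with the center-of-pixel
convention; a pixel belongs to a circle when its center lies within the
radius, boundary inclusive; circles whose disk extends past the frame
border are discarded (the simulator never places clipped beads, so this
costs no ground truth). Default search range is the nominal bead radius
± 40% with `min_separation` = 1.5 radii. On noiseless non-overlapping
disks the detector achieves recall and precision 1.0 with maximum center
error ≈ 0.25 px and radius error well under 1 px; no flat-field or
illumination correction is applied, and overlapping-bead declumping is out
of scope.

## Calibration and LOD

The dose–response curve is the standard Hill-form four-parameter logistic
f(x) = d + (a − d)/(1 + (x/c)^b), fitted by least squares on the linear
concentration scale (log–log axes are presentation only). The blank is a
removable boundary of the Hill form at x = 0, so it anchors the
initialization of `a` and defines the LOD level but is excluded from the
residuals. Slope and inflection are optimized in log space (enforcing
b, c > 0) with a multi-start grid over b ∈ {0.5, 1, 2} and the geometric
quartiles of the positive concentrations; the lowest-RSS converged fit
wins. Flat responses and fits whose asymptotes coincide or whose inflection
lands many decades outside the data raise a fit-failure error rather than
returning a spurious curve.

By default the fit is unweighted. For responses spanning several decades
(an AMB series from the blank floor to near saturation) the replicate SDs
are strongly heteroscedastic and unweighted least squares lets the large
high-concentration residuals distort the low-concentration plateau; the
`weighted=True` flag applies inverse-replicate-SD weights, and the
experiment-level comparisons in this package use it for both readouts
symmetrically.

The LOD is the concentration whose predicted response equals the blank
mean + 3 SD across blank replicates, computed from the closed-form inverse
x = c·((a − d)/(y − d) − 1)^(1/b) and cross-checked against Brent root
finding to 10⁻⁶ relative; a response level outside the open asymptote
interval raises an explicit lod-undefined error instead of being clipped.
Because a 3-replicate sample SD is a 2-dof chi estimate, it collapses below
the known counting noise with substantial probability; the digital blank SD
is therefore floored at the mean delta-method SE of the blank replicates —
the physical lower bound on replicate scatter — before forming y_lod.
Masses are concentration × volume with ng/mL × µL = pg, evaluated in
decimal arithmetic so printed decimal inputs convert exactly.

## The synthetic assay generator

The generator emulates the statistical structure of the acquisition the
analysis assumes: a bead population with Poisson molecule counts; a
Binomial(n_beads, imaged_fraction) subset of beads — default 21% — spread
uniformly over many frames (the regime of scanning ~100–150 fields to image
about a fifth of the beads); rejection-sampled placement so no two beads in
a frame are closer than 2.2× their radius and no disk clips the border; and
paired rasters in which the localization channel shows contrast disks and
the fluorescence channel shows each bead as a uniform disk at its drawn
peak intensity over background.

Default optics (16-bit a.u. scale) were chosen once as a realistic regime,
since assay papers do not publish camera-unit distribution parameters:

| parameter | default | rationale |
| --- | --- | --- |
| image_shape | 256 × 256 px | desk-scale field; statistics scale with bead count, not FOV |
| bead_radius_px | 4.0 (±5% jitter) | 2.8 µm bead at 20× on a ~6.5 µm-pixel camera |
| blank_mean, blank_sd | 8000, 600 | off-bead maxima well above background, CV 7.5% |
| on_intensity | LogNormal(ln 30000, 0.35) | positive, right-skewed, median ≫ blank + 2 SD (separable regime, enforced) |
| background_level | 3000 | dark background with headroom below the blank band |
| read_noise_sd | 50 | per-pixel additive camera noise |
| background_drift_sd | 150 (5%) | per-frame background offset: field-to-field illumination and autofluorescence variation across a scanned slide |
| capture_coeff κ | experiment-specific | sets λ = κC; dilution grids are chosen so λ spans ~0.005–5 |

The per-frame background drift exists because a simulator with only
per-pixel read noise makes the analog grand mean unrealistically precise —
averaging a million pixels suppresses read noise to nothing, leaving only
bead-count shot noise, which does not reflect how bulk-fluorescence
readouts behave on real scanned slides. A 5% field-to-field background
variation is ordinary for epifluorescence scanning and barely perturbs the
digital readout (it shifts per-bead maxima by a fraction of the blank SD,
and the blank fit absorbs it).

What the generator deliberately does **not** model: optical
point-spread-function physics (beads are uniform disks, so the noiseless
maximum equals the drawn peak exactly), amplification kinetics, bead
aggregation or overlap (an opt-in overlap mode exists for stress tests),
saliva-matrix interference beyond elevated-blank/reduced-κ presets, and
capture-kinetics effects of bead number (bead-count trade-offs enter only
through λ = κC with κ ∝ 1/n_beads for a fixed analyte amount). Passing the
synthetic validation therefore demonstrates the correctness of the
*analysis chain* under the model's assumptions — not detector performance
on aberrated, clumped, or unevenly illuminated real micrographs.

## Problem sizes in the validation experiments

The packaged experiments run at desk scale, chosen so each validates the
statistics it targets: rate recovery uses 2 × 10⁴ beads per condition over
120 frames at the 21% imaged fraction (≈ 4 200 measured beads, matching the
bead-count regime of a real run); the detector contract uses 500 noiseless
disks; the digital-vs-analog comparison uses 8 concentrations × 3
replicates × 24 frames with 5 000 beads per condition, both readouts
computed from the same FrameSets. Blank-floor checks use 10⁵ direct
intensity draws. All randomness flows from explicit integer seeds;
identical seeds reproduce identical populations, rasters, and tables
bit-for-bit.

## Known limitations

- The detector contract is specified (and met) for resolvable,
  non-overlapping disks; dense fields beyond the 2.2-radius spacing rule
  degrade recall and are rejected at generation rather than declumped.
- Near saturation (f_on → 1) AMB variance diverges as off-beads become
  rare; the saturation cap bounds the value but calibration points there
  carry little information, which is why weighted fitting is recommended
  for full-range series.
- With an AMB response that has not reached its upper plateau, the fitted
  4PL upper asymptote d and inflection c are extrapolations; the LOD,
  which lives at the well-constrained low end, is unaffected.
- Frames are treated as independent samples; beads appearing near the
  borders of adjacent fields are not deduplicated.
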