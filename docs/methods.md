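# Methods

This note records how `lfaquant` turns a strip photograph into a
concentration estimate, which assumptions and parameter choices that
involves, and what the synthetic-data tests do and do not demonstrate.

## Signal model and canonical raster

The assay is a competitive gold-nanoparticle LFA: analyte in the sample
blocks probe binding at the test line, so the test-line color falls as
concentration rises while the control line confirms flow. All internal
math works on **darkness**: loaded images are scaled to [0, 1] by their
bit depth (8-bit ÷ 255, 16-bit ÷ 65535), a single channel is selected and
inverted (`signal = 1 − channel`), so colored bands are maxima.

*Channel policy.* Default `green`: gold-nanoparticle bands are red/pink,
so green carries the strongest absorbance contrast. `luminance`
(Rec. 601) is the fallback for grayscale imagers; `red`/`blue` exist for
unusual labels.

*Orientation.* The flow axis is taken to be the longer image axis. With
`flow_direction_hint='auto'` the band pair is located and the image
flipped so the pair's midpoint lies in the downstream half — strips are
cut with more free membrane on the sample-pad side, so the printed lines
sit past the middle. When that cue is degenerate (square raster, bands
centered, no bands) an explicit `tl_first`/`cl_first` hint is required;
the batch pipeline then proceeds as-given and flags the measurement
`orientation_assumed`. Canonicalization is idempotent.

*Resolution.* Photographs rarely carry a px/mm scale. When absent it is
estimated from the detected tl–cl separation and the printed 5 mm line
spacing, which is the one piece of physical geometry the strip guarantees.

## Densitometry

1. **Profile**: mean darkness of the central 60% of columns
   (`roi_width_fraction`), per row. Edges are excluded because membrane
   borders and shadows concentrate there; at least 3 columns are required.
2. **Baseline**: default `flank_linear` fits a straight line by iterative
   trimming — fit to all points, drop points more than 3 robust sigma
   *above* the line (the bands), refit until stable. A band-free profile
   reproduces itself exactly, so corrected values collapse to ~0.
   `rolling_min` (morphological opening, window ≥ ~3 band widths,
   default 3 mm) is offered for curved backgrounds that a line cannot
   follow. Corrected values are floored at 0.
3. **Band detection**: the corrected profile is smoothed with a moving
   average one nominal band-width wide (forced odd so symmetric peaks keep
   their center); local maxima with prominence above
   `max(0.01, 5% of the profile maximum)` are candidates. The absolute
   floor of 0.01 darkness (~2–3 gray levels of an 8-bit camera) rejects
   sensor-noise ripples on bandless strips. Candidate pairs whose
   separation is within ±25% of `5 mm × px_per_mm` qualify; the pair with
   the largest summed prominence wins, upstream peak = tl, downstream =
   cl. Exact prominence ties raise an ambiguity error rather than
   guessing.
4. **Integration**: band quantity is the **area** (sum of corrected
   darkness) over `center ± 1.5 × band_width/2`, half-open pixel
   intervals clipped to the profile. Area rather than peak height because
   smartphone photos are visibly softer than imager photos and blur
   preserves area but not height.

The response ratios are `normalized = cl/tl` (primary; defined only when
tl > 0) and `standardized = tl/cl`. Ratios cancel global exposure because
both bands share the multiplicative illumination factor once the additive
background is removed. If more than 1% of ROI pixels sit at the 0/1 rails
before inversion the measurement is flagged `saturated` but still
computed.

*Polarity.* The competitive format makes the test line fade with rising
concentration, so cl/tl increases with concentration. (One can encounter
strips and write-ups with the opposite sign convention; fitting the
standardized ratio, or a negative slope, covers that case — the math is
sign-agnostic.)

## Calibration and detection limits

The calibration is a single straight line fitted by OLS to **individual
replicates** (not per-concentration means), matching how replicate error
bars are usually displayed around such fits. Reported per fit: slope,
intercept, their 95% CIs, R², Pearson r between observed and predicted
ratios (for simple OLS, r² = R² to machine precision — asserted as an
invariant), and per-concentration mean / sample SD (n−1) / Student-*t* CI.
Weighted or four-parameter-logistic calibration is deliberately out of
scope: over the 0–100 nM working range the response is linear by
construction and the narrow therapeutic window of the target analyte
favors a simple, auditable model.

Detection limits use blank replicate statistics on the **ratio scale**:

* method 1: LOD = m₀ + 3·s₀, LOQ = m₀ + 10·s₀
* method 2: LOB = m₀ + 1.645·s₀, LOD = LOB + 1.645·s₁ₙₘ,
  LOQ = m₀ + 10·s₀

where m₀, s₀ are the mean and SD of the 0 nM ratios and s₁ₙₘ the SD at
1 nM. Both are mapped to nmol·L⁻¹ through the inverse fitted line
`(value − β₀)/β₁`; the intensity scale and the concentration scale are
always reported together, and the conversion route is noted in the output,
because the inverse-model route is a choice — concentration-scale
statistics computed directly would differ. Ordering guarantees
(LOD ≤ LOQ for method 1, LOB ≤ LOD for method 2) hold for any
nonnegative SD and are property-tested. Negative inverse predictions are
returned as-is and flagged below-range rather than clipped.

## Synthetic strips: what they emulate and what they don't

The generator renders what the densitometry chain actually sees: two
Gaussian absorbance bands (default σ = 0.4 mm, centers 4 mm and 9 mm —
the printed 5 mm spacing) on a 12 × 3 mm strip at 10 px/mm, a linear
background gradient (offset 0.08, slope 5·10⁻⁴ per px), optional i.i.d.
Gaussian pixel noise, rendered as a pink-band RGB photo
(`green = 1 − darkness`). The manifest stores band centers, analytic
areas `A·σ·√(2π)` and the noiseless profile, so every stage can be checked
against closed-form truth. Writing quality-85 JPEG adds realistic
compression noise on request.

A calibration scenario draws each strip's target ratio from the
ground-truth line `r = β₀ + β₁·c + ε`, ε ~ N(0, ratio-noise²), and sets
band amplitudes `A_cl = A_ref·r/(1+r)`, `A_tl = A_ref/(1+r)` so the
analytic cl/tl area ratio equals `r` exactly. This was chosen over a
mechanistic competitive-binding model precisely so the calibration truth
is exact by construction. Scenario defaults mirror the laboratory
designs the pipeline is meant for: the 0, 1, 20, 40, 60, 80, 100 nM
series with five replicates (a denser 12-level serum series with three
replicates is provided as an alternative), β₀ = 0.5, β₁ = 0.02 per nM —
a blank ratio of 0.5 tripling by 100 nM, comfortably inside the
amplitude budget — and ratio noise 0.01, i.e. ~2% CV at blank, typical of
a well-behaved strip lot. Every output is a pure function of
(parameters, seed).

Not emulated: membrane texture, shadows, perspective, lens distortion,
multi-strip photos, band asymmetry, and kinetic effects. Passing the
synthetic suite therefore shows the *algorithmic* chain is correct and
stable under pixel noise; it does not certify performance on arbitrary
real photographs, where illumination structure may violate the
linear-background assumption (use `rolling_min` there) and band shapes
may be skewed.

## Numerical choices and known limitations

* 0-based positions, half-open `[start, stop)` windows throughout;
  detected centers are integer local maxima.
* Moving-average windows are forced odd so symmetric peaks do not shift;
  boundary handling is reflection.
* Baseline trimming threshold: 3 × (1.4826 × MAD), floored at 1e−12 so a
  noise-free profile converges immediately; at most 50 iterations.
* Tie-break in band pairing: largest summed prominence, then leftmost
  pair; ties within 1e−9 raise an error instead of picking silently.
* Replicate SD uses the n−1 denominator; CIs use Student *t*. A single
  replicate yields a mean with SD/CI undefined (NaN), not zero.
* **Peak-jitter ratio bias**: with per-pixel noise enabled, the detected
  integer center jitters by ~1 px and the fixed integration window then
  clips slightly more of the weaker band's area, biasing cl/tl toward 1
  by a few tenths of a percent at the noise levels tested. Consequently
  scenario simulations driven purely by ratio noise keep per-image pixel
  noise off by default; when pixel noise is switched on, slope estimates
  acquire a sub-percent bias and nominal CI coverage degrades
  accordingly. Averaging replicate strips, or wider windows, mitigates
  this on real data.
* Strips whose bands lie closer to the image edge than half the smoothing
  window cannot form a local maximum and are reported as band-not-found;
  profiles should be at least twice the band spacing long.

## Problem sizes used in the automated checks

Unit and property tests run on 60–160 px profiles and single strips.
End-to-end checks use the full 35-strip calibration design; detection
accuracy is measured over 100 seeded strips (SNR ≥ 10) and parameter
recovery over 100 replicate experiments (3 500 rendered strip images),
which keeps the whole suite in the tens of seconds on one core.
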