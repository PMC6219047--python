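# Methods

## Measurement model

A rigidly mounted camera images a translucent conical pipette tip holding a
red-dyed reagent against a matte grey background. Under these conditions
segmentation reduces to colour arithmetic:

* **Luminance.** `Y = 0.299R + 0.587G + 0.114B` (ITU-R BT.601), rounded
  half-up to an 8-bit integer. BT.601 is the standard weighting for 8-bit
  video sensors of this class.
* **Pure red.** `P = clip(R − Y, 0, 255)`. For any achromatic pixel
  `R = Y`, so the background and grey tip walls map to ≈0 while red reagent
  maps far above 100 (e.g. pure red (255,0,0) → 179; the generator default
  (180,30,30) → 105). The difference is computed as R−Y (not Y−R) precisely
  so that a single upper-side threshold separates reagent from background;
  an `invert_red` switch selects the opposite convention should a device's
  optics require it.
* **Despeckle + threshold.** A 3×3 median filter (edge replication, so the
  shape is preserved) removes isolated sensor-noise pixels, then a fixed
  strict threshold (`pixel > t`, default `t = 40`) produces the binary
  reagent mask. The threshold is configuration, not learned: matte
  backgrounds sit at `P ≈ 0–10` and reagent at `P ≳ 100`, leaving a wide
  margin on both sides of 40.

The mask is collapsed into projection profiles (per-row and per-column
foreground counts). The **support** of a profile is its set of non-zero
positions. Three scalars follow:

* **volume length** `L` — support length of the row profile, i.e. the count
  of all rows intersecting reagent. This is deliberately a count of
  non-zero positions rather than the first-to-last span, so unfilled gaps
  (segmentation dropouts) shorten it; the upstream median filter is the
  mitigation for such dropouts.
* **tip position** — midpoint of the first and last non-zero column
  (floored for even supports, a deterministic tie-break); an empty support
  is reported as "absent", a detection outcome rather than an error.
* **holder top** — first non-zero row of the holder mask's row profile.
  The holder is dark rather than red, so its mask comes from a dark-object
  threshold on the luminance (`Y < t_holder`, default 100) inside its own
  ROI. Tip and holder use two independently configurable ROIs.

## Calibration and the pump check

The liquid body in a cone of half-angle θ satisfies
`V = (π tan²θ / 3) h³`, so commanded volume (∝ pump steps `s`) is linear in
the cube of the column height. The calibration is therefore an ordinary
least squares fit

    L³ = a·s + b

over a sweep of step levels, with `R²` recorded, and a frame's step
estimate is the analytic inverse `ŝ = (L³ − b)/a`. The regression is fit in
this orientation (response = L³) and inverted, rather than regressing `s`
on `L³`; with `R² ≈ 1` the two differ negligibly and the forward
orientation matches how the calibration is reported. Negative `ŝ` (length
below the calibrated range) is returned as-is so callers can flag it.

The pump check fails when the estimate deviates from the commanded steps
beyond a bound, strictly: `|ŝ − s| > bound` in absolute mode or
`100·|ŝ − s|/s > bound` in relative mode. The default is relative 5 %,
the customary inaccuracy specification for these dispensers; exactly 5.0 %
passes.

Replicate precision uses the sample standard deviation (n−1) and
`CV = 100·σ/μ`, reported in **percent**. (The shipped characterisation
tables label this column "ppm" as originally printed, but the values are
numerically percent — 0.26/5.28 = 4.9 % — and this package labels them
percent throughout.) Step-estimation error is summarised as
`dev = sqrt(mean((ŝᵢ − s)²))` measured from the *commanded* steps rather
than the sample mean — the bias is part of the error, on the reasoning that
the mean error converges to zero only asymptotically — and
`rel_dev = 100·dev/s`.

Reported statistics are rounded as in the characterisation tables: 1
decimal for CV and relative deviation, 3 decimals for R², nearest integer
for the cube-fit slope.

## Synthetic scene generator

`tipqc.synthcam` renders the imaging geometry parametrically so every
pipeline stage has an exact oracle:

* upright cone, apex at the bottom (cylinder-topped tips are excluded so
  the cube law stays exact), default half-angle 10°, 2-px grey walls;
* liquid drawn as the cone cross-section from the apex up to
  `h = (3V/(π tan²θ))^{1/3}` rows, colour (180,30,30) on background
  (200,200,200); the liquid is drawn at least 3 px wide at the apex,
  because a real apex images wider than a geometric point (optical blur,
  wall contact) and a 1-px spike would otherwise be removed by the 3×3
  median that the generator exists to exercise;
* a dark holder bar above the tip, an optional vertical illumination ramp,
  and additive per-channel Gaussian noise (the simplest sensor-noise
  stand-in), clamped to [0,255];
* deterministic rendering: one seed per scene; sweeps derive per-element
  seeds from a master seed via `numpy.random.SeedSequence`, so each element
  is individually reproducible.

Default frame and dosing parameters (360×160 px, 900 volume units per pump
step, apex at row 340) place a 640-step aspiration at ≈260 occupied rows —
the same working range as the published volume-length table (72–259 px over
40–640 steps), so synthetic sweeps exercise realistic magnitudes. Test
problem sizes are 16–20 volumes per sweep with 3–5 replicates, matching the
published experiment's 16 levels × 5 replicates.

What the generator does *not* emulate: meniscus curvature and refraction,
specular highlights, lens distortion, motion blur, and non-Gaussian sensor
noise. Passing synthetic tests therefore certifies the arithmetic of the
chain (segmentation, projection, calibration, inversion, decision rule) and
its noise robustness at the modelled amplitude — not photometric robustness
on real devices, which the fixed-threshold design instead buys by
controlling illumination and background finish in hardware.

## Shipped characterisation tables

`tipqc.tables` loads three published summary tables for a reference
dispenser (16 step levels, 40–640 by 40, five replicates each): gravimetric
reagent mass, image-measured volume length, and step-estimation error. Raw
replicates were never published, only mean/STD summaries, so derived
statistics are recomputed from those summaries; the originally printed
derived rows are carried alongside (`cv_printed`, `rel_dev_printed`) for
cross-checking. Because the printed means/STDs are rounded to 2 decimals,
two derived entries differ from the printed ones by one final-digit ulp
(mass CV at 80 steps, 3.0 vs 2.9; relative deviation at 120 steps, 1.6 vs
1.5); the tests assert agreement to within that rounding resolution.

## Numerical and design choices

* OLS via `scipy.stats.linregress`; an independent normal-equations solver
  exists only in the tests as a cross-check.
* Strict inequalities in both thresholding (`> t`) and the pump bound are
  documented contracts, chosen once and fixed.
* Degenerate inputs: empty ROIs and out-of-range thresholds raise; an
  all-zero mask yields length 0 and "absent" positions (legal outcomes);
  a single replicate makes the sample std an explicit error rather than 0
  or NaN; constant step designs raise a degenerate-design error.
* The estimator surface follows scikit-learn: `ReagentSegmenter` is a
  stateless transformer (its `fit` validates configuration) and
  `CubeLinearCalibrator` a regressor with `slope_`, `intercept_`,
  `r_squared_` fitted attributes, `get_params`/`clone` support and JSON
  persistence. Module-level functions (`segment_reagent`, `fit_cube_linear`,
  `check_pump`, …) are thin wrappers for scripting.

## Limitations

Single tip per frame; no connected-component analysis or sub-pixel meniscus
localisation (integer row counts quantise `L`, which dominates the residual
error at small volumes); the cube law assumes a conical liquid body, so
tips with cylindrical sections need a different volume model; the fixed
threshold presumes the device's controlled illumination and will not
transfer to uncontrolled scenes.
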