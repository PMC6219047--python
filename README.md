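# tipqc

Image-based pipette-failure monitoring for point-of-care testing (POCT)
devices.

Compact diagnostic readers aspirate reagents through a disposable conical
pipette tip driven by a stepper-motor pump. Because these devices are
operated by non-experts, a worn pump, a missing tip or a misaligned holder
must be caught by the device itself. `tipqc` implements the camera-based
check: a fixed, cheap camera photographs the tip, the red reagent column is
segmented from the frame, its vertical extent is measured, and the pump is
declared faulty when the volume implied by that extent disagrees with the
commanded step count.

It is aimed at instrument-QC engineers and at anyone who wants a fully
testable reference implementation of projection-profile liquid-level
measurement: every stage can be exercised against a built-in synthetic
scene generator with exact ground truth, so no device is needed.

## Method

For a frame `I` with a fixed region of interest (the camera and holder are
rigidly mounted):

1. **Pure-red channel.** `P = clip(R − Y, 0, 255)` with BT.601 luminance
   `Y = 0.299R + 0.587G + 0.114B`. `P ≈ 0` on any grey surface and large
   inside red reagent.
2. **Mask.** 3×3 median filter, then a fixed threshold `t` (default 40):
   `M = [P > t]`. Controlled illumination and a matte background make a
   fixed threshold sufficient.
3. **Volume length.** Project `M` along rows and count the rows with a
   non-zero foreground count (the support length of the profile). The
   column-profile support centre locates the tip; an empty support signals
   a missing tip.
4. **Cube-linear calibration.** The tip is conical, so liquid volume scales
   with the cube of the column height. Ordinary least squares fits
   `L³ = a·s + b` over a calibration sweep of pump steps `s`; inversion
   gives the step estimate `ŝ = (L³ − b)/a` for a single frame.
5. **Pump check.** Fail when `|ŝ − s|` exceeds a bound — by default 5 %
   relative, the usual dispenser inaccuracy specification.

Replicate precision is summarised as CV = 100·σ/μ per step level, and
estimation error as the RMS deviation of `ŝ` from the *commanded* steps
(not the sample mean) together with its percentage of the commanded steps.

The package ships the published 16-level characterisation tables of the
reference dispenser (gravimetric masses, image volume lengths, and step
estimation errors) as CSV data, and a parametric scene generator
(`tipqc.synthcam`) that renders the tip/holder geometry with additive
Gaussian sensor noise and known volume-to-height mapping.

## Worked example

Render four synthetic aspirations (sensor noise σ = 2), measure them,
calibrate, and check a nominal and an under-aspirated frame:

```bash
tipqc synth --out-dir frames --seed 1 --steps 40 --steps 240 --steps 400 --steps 640 --noise 2
tipqc measure frames/*.png --config config.toml --out meas.csv
```

`meas.csv` (volume length in pixels, tip centre column):

```text
image,volume_length_px,tip_column,holder_row
frames/steps0040.png,103,80,absent
frames/steps0240.png,188,80,absent
frames/steps0400.png,223,80,absent
frames/steps0640.png,261,80,absent
```

Lengths grow as the cube root of the commanded steps (103 → 261 px for
40 → 640 steps). Pairing them with their step counts in `table.csv` and
fitting:

```bash
$ tipqc calibrate table.csv --out cal.json
y = 27811x + -25896.4, R^2 = 1.000  (y = cubed volume length, x = pump steps)

$ tipqc check frames/steps0400.png --steps 400 --config config.toml --calibration cal.json
{ "commanded_steps": 400.0, "estimated_steps": 399.68, ...  "verdict": "pass" }   # exit 0
```

An under-aspiration failure (70 % of the commanded volume) is caught
immediately — the cube law maps a 0.7× volume to a ≈0.888× column length,
hence a step estimate near 0.7× the command:

```bash
$ tipqc synth --out-dir bad --seed 9 --steps 400 --noise 2 --failure under_aspiration --fraction 0.7
$ tipqc check bad/steps0400.png --steps 400 --config config.toml --calibration cal.json
{ ... "estimated_steps": 280.05, "relative_deviation_percent": 29.99, "verdict": "fail" }  # exit 2
```

Exit codes: 0 pass, 2 malfunction, 1 processing error.

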