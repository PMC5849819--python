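# sdrmon

Automatic detection of defective ultrasound linear-array transducers from
stored clinical B-mode images.

A defective element (dead element, cable break, delamination) darkens the
same lateral position in **every** image a transducer produces, while the
anatomy changes from frame to frame. Median-stacking many stored clinical
frames therefore suppresses anatomy and leaves the systematic dark streaks.
`sdrmon` turns this into a continuously runnable quality-assurance check for
medical physicists and service teams: it selects usable frames straight from
a DICOM archive, extracts and resizes the B-mode rectangle so that one image
column corresponds to one transducer element, computes a **systematic dark
region (SDR) curve** per rolling window of images, and raises a notification
when the area under that curve crosses a threshold — no phantom, no
electrical tester, no access to the scanner required.

## The SDR algorithm

For a stack of the latest `N_stack` resized images (default 150), each row of
each image is first centered by subtracting its own mean. Three detection
paths then each produce a nonnegative curve over the image columns:

* **green** — `N_rep` = 100 times, a pixel-wise median of `N_select` = 15
  randomly drawn images is formed; the column-wise mean (CWM) of the
  superficial rows `R_upper..R_lower` = 1..19 is inverted, an order-6
  polynomial baseline is subtracted, and peaks are detected. Peaks are
  clustered across repetitions by position (±1 column); clusters with mean
  height above `T_green` = 2 gray levels are rendered as Gaussians

  `f(x) = Σₖ heightₖ · exp(−((x − posₖ)/(widthₖ/2))²)`,

  which catches narrow streaks locked to one lateral position;
* **red** — the inverted CWM of the whole stack's median image, baseline-
  subtracted at order 6, thresholded at `T_red` = 5: broad diffuse dark
  regions;
* **blue** — the same inverted CWM without baseline subtraction,
  thresholded at `T_blue` = 10 within the outer `P_include` = 25 % of columns
  at each end, where polynomial baselines adapt to the data and go blind.

The SDR curve is the element-wise maximum of the three, with the first and
last `P_exclude` = 2 % of columns zeroed (functional transducers darken the
very borders). Its trapezoidal area divided by the element count is the
scalar nonuniformity indicator; a threshold in 0.5–1 (default 0.75) drives
rising-edge notifications.

Since clinical archives cannot be shipped, `sdrmon.synthetic` generates
clinical-like stacks and DICOM fixtures with known injected defects
(position, width, strength, depth decay, intermittency), making the whole
pipeline testable against ground truth.

## Worked example

```python
import numpy as np
from sdrmon import (PROFILES, AlgorithmParams, BackgroundModel, DefectSpec,
                    compute_sdr_curve, generate_stack)

profile = PROFILES["ML 6-15"]          # 336 elements, 50 mm aperture
bg = BackgroundModel()                  # clinical-like anatomy + speckle
defect = DefectSpec(center_column=168, width_columns=3, strength=20)

stack = generate_stack(150, profile, bg, [defect], seed=42)
curve = compute_sdr_curve(stack, AlgorithmParams(seed=7))
print(f"area = {curve.area:.3f}, peak at column {np.argmax(curve.values)}")
```

prints

```
area = 0.231, peak at column 167
```

A persistent 3-column, 20-gray-level defect injected at column 168 of a
336-element array is recovered within one column, with a clearly positive
area; the same run without the defect prints `area = 0.000`. An area of 0.231
sits below the 0.75 notification level — a weak fault worth watching;
stronger or wider defects (e.g. strength 40 over 8 columns) push the area
above 1 and trigger an alert.

The same workflow from the shell:

```sh
sdrmon simulate --config config.yaml --out fixtures/   # DICOM fixtures + ground truth
sdrmon analyze  --config config.yaml --in fixtures/ --out results/
sdrmon report   --series results/
```

`analyze` writes the selection report, per-curve CSV, area series, a
curve-index × element surface (CSV + heatmap) and a JSON-lines notification
log.

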