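# Methods

## Model and assumptions

`sdrmon` assumes a 1-D linear (or virtually convex) array whose image
columns map one-to-one onto transducer elements after lateral calibration,
and that a given transducer stays attached to one scanner (DICOM carries no
transducer serial number, only station and model). A defective element
depresses gray levels in a fixed lateral band of every image; anatomy is
frame-to-frame variable. Under these assumptions the pixel-wise median of
many stored frames estimates a uniformity image in which anatomy cancels
and systematic streaks persist; the detection problem reduces to finding
localized depressions in the column-wise mean (CWM) of the superficial row
band of median images. Only the superficial band is analyzed because dark
streaks are strongest near the transducer face and axial zoom leaves the
superficial columns-to-elements correspondence intact, while laterally
zoomed images break it and are rejected outright.

## Pipeline

1. **Selection** (`ingest`): frames of one station/transducer are kept when
   `SequenceOfUltrasoundRegions` has exactly one item and the stored width
   does not exceed a per-scanner `max_single_image_cols` (multi-region or
   wide layouts are Doppler-curve/side-by-side displays; color Doppler
   without curves presents as one region and passes). RGB frames are
   converted to gray with Rec.601 luma weights (0.299, 0.587, 0.114),
   rounded — a bit-reproducible, de facto standard conversion. Records with
   missing tags are skipped with a warning and tallied, never fatal.
2. **Extraction** (`extraction`): the B-mode rectangle is the largest
   8-connected component of nonzero pixels; all other pixels are zeroed.
   Corners come from the projections of the surviving mask: top/bottom from
   the row projection; left/right from the columns occupied within the top
   5 % of the region's rows, so a virtually convex region is extracted with
   the width of its most superficial part and its full height. The physical
   width `(right − left) × PhysicalDeltaX` (tag native unit cm, converted
   to mm) must fall in the closed interval 49.5–51.5 mm around the 50 mm
   aperture; otherwise the frame is rejected as `width_under`/`width_over`
   (`no_calibration` when the tag is absent or non-positive). Accepted
   rectangles are resized bicubically — without anti-alias prefiltering —
   to `element_count × 500` (336 × 500 for the ML 6-15 profile, 256 × 500
   for L12-5).
3. **SDR curve** (`sdr`): see README for the three paths. Implementation
   notes below.
4. **Monitoring** (`monitor`): a FIFO buffer of the newest `n_stack` resized
   frames, one SDR curve per update once full (curves emitted =
   `fed − n_stack + 1`), rising-edge notifications when the area series
   crosses the threshold.

## Parameters

| name | default | unit | role |
|---|---|---|---|
| `n_stack` | 150 | images | window size; larger = fewer false positives, slower response |
| `n_select` | 15 | images | green-path median subset |
| `n_rep` | 100 | — | green-path repetitions |
| `r_upper`, `r_lower` | 1, 19 | rows (1-based) | superficial band, 19/500 ≈ 4 % of depth |
| `o_poly_green`, `o_poly_red` | 6 | — | baseline polynomial orders |
| `t_green`, `t_red`, `t_blue` | 2, 5, 10 | gray levels | path thresholds |
| `p_include` | 25 | % | blue-path end zones |
| `p_exclude` | 2 | % | columns zeroed at each curve end |
| notification threshold | 0.75 | area units | inside the recommended 0.5–1 interval |

Percent-to-column conversions use `floor` (e.g. `floor(0.02·336) = 6`
excluded columns per side). All gray-level quantities are on the 8-bit
0–255 scale of stored images.

## Numerical choices

* **Inversion is negation.** Rows are mean-centered before any path, so CWM
  curves oscillate around zero and dark streaks become positive peaks under
  multiplication by −1 (a 255-complement would be wrong on signed data).
* **Baseline fits** evaluate the polynomial on an abscissa rescaled to
  [−1, 1]; an order-6 Vandermonde system on raw column indices 0..335 is
  numerically singular, the rescaled fit is mathematically the same.
* **Peak definition**: a sample strictly greater than both neighbors; for a
  flat-topped plateau the first plateau sample is reported. Height is the
  raw curve value at the peak (not the prominence); width is the full width
  at half prominence with interpolated crossings.
* **Cross-repetition clustering** (green path): transitively chaining peaks
  whose positions differ by ≤1 column percolates under noise — across 100
  repetitions essentially every column hosts some peak, and one giant
  cluster would dilute real defects. Instead, clusters are seeded greedily
  at the column holding the most unassigned peaks (ties: lowest column) and
  absorb all peaks within ±1 column. A cluster's mean position, height and
  width average over the repetitions in which it appears, not over all
  repetitions — a persistent defect recurs in ~all repetitions and keeps
  its full height, while scattered noise clusters keep noise-level heights
  well below `t_green`.
* **Gaussian rendering**: the exponent is `((x − pos)/(width/2))²`, so the
  rendered bump falls to `height/e` exactly half a detected width from its
  center — widths represent the dark regions' lateral extent.
* **Median with even counts** averages the two middle values (`n_select`
  = 15 is odd by default, but the API accepts any count).
* **Green-path economy**: the per-repetition median is computed on the
  superficial row band only; the pixel-wise median commutes with row
  slicing, so this equals slicing the full median image, at a fraction of
  the cost.
* **Determinism**: the red and blue paths are invariant to frame order
  (medians are order-free); the green path draws subset indices from a
  generator seeded by `params.seed` and is reproducible bit-for-bit, but
  permuting the frames permutes the index meaning and may change its
  output. Both properties are tested.
* **Degenerate inputs**: all-zero stored frames (`no_region`), missing
  calibration, undersized stacks, empty peak sets and empty series raise or
  return defined empties; an SDR curve is all-zero exactly when its area
  is 0.

## Synthetic study conditions

The generator emulates what matters statistically to median-stack
detection, not ultrasound physics. Each frame is a constant gray level
(default 110) plus `blob_count` = 8 separable Gaussian bumps with random
centers, scales (8–30 % of each dimension) and amplitudes uniform in
±30 gray levels — anatomy that varies per frame with zero-mean column
structure in expectation — multiplied by per-pixel Rayleigh-like speckle
standardized to mean 1, σ = 0.1 (a moderate level for 8-bit display
images). Defects subtract `strength` gray levels over `width_columns`
columns, attenuating linearly with depth by `depth_decay` per row, and are
present i.i.d. per frame with probability `1 − intermittency`. All
randomness derives from `(seed, frame_index)`, so stacks are bit-identical
across runs.

These defaults were fixed once from the above reasoning. What the model
does **not** reproduce: spatially correlated speckle, depth-dependent gain
and focus banding, vendor post-processing (spatial compounding reduces
defect visibility), burned-in annotations in the superficial band, or
logotypes overlapping the B-mode area. Passing tests therefore demonstrate
the algorithm's contract (soundness on uniform data, recovery of injected
systematic streaks, monotone response) — not clinical sensitivity or
specificity, which require real archives.

DICOM fixtures embed an 8-bit RGB frame in a zero-filled surround at a
declared offset, with deterministic text-like logotype boxes, a declared
ultrasound-region count and `PhysicalDeltaX` in cm (`PhysicalUnitsXDirection`
= 3, the ultrasound calibration convention); the ingest reader converts to
mm. Fixture UIDs derive from the tags and file name, so manifests and files
are reproducible.

## Problem sizes used in tests and the acceptance script

Soundness and localization use 20 independently seeded 150-frame stacks at
full 336 × 500 geometry; strength monotonicity uses strengths
{0, 5, 10, 20, 40} at a fixed seed; oracle-equivalence checks use 100
randomized small inputs per primitive; the rolling contract uses a reduced
window (`n_stack` = 20) with 50 fed frames, chosen to exercise several
full stack replacements while keeping the demonstration compact.

## Known limitations

* One monitor per (station, transducer model): swapped or shared
  transducers blur attribution, as the underlying assumption requires.
* Broad defects spanning a large fraction of the aperture can be partially
  absorbed by the order-6 baseline; the red path threshold trades this off
  against false positives.
* Intermittent defects present in a small fraction of the window dilute out
  of the median; shrinking `n_stack` trades detection latency against false
  positives.
* The area indicator is unitless and setting-dependent (dynamic range,
  compounding differ between exams); it flags the need for a controlled
  check rather than measuring element sensitivity.
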