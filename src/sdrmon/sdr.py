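"""Systematic-dark-region (SDR) detection on stacks of resized B-mode images.

A defective transducer element darkens the same lateral position in every
image it produces, while anatomy changes from frame to frame.  Median-stacking
therefore suppresses anatomy and leaves systematic vertical streaks, which are
quantified here as an *SDR curve*: one nonnegative detection value per image
column (one column corresponds to one transducer element after resizing).

The curve is built from three parallel analyses of an image stack:

* the **green path** detects narrow streaks that sit at the same lateral
  position in many images, by repeatedly median-combining random subsets of
  the stack and peak-detecting the baseline-subtracted, inverted column-wise
  mean (CWM) of the superficial row band;
* the **red path** detects wider, more diffuse dark regions from the median
  of the whole stack, again after polynomial baseline subtraction;
* the **blue path** detects dark regions at the horizontal endpoints, where
  polynomial baselines adapt to the data and the other paths go blind.

The element-wise maximum of the three curves, with a small excluded border,
is the SDR curve.  Its trapezoidal area, normalized by the element count, is
the scalar nonuniformity indicator used for notification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "AlgorithmParams",
    "ImageStack",
    "PeakSet",
    "SDRCurve",
    "subtract_row_means",
    "median_image",
    "column_wise_mean",
    "baseline_subtract",
    "detect_peaks",
    "gaussian_peak_vector",
    "green_path",
    "red_path",
    "blue_path",
    "combine_paths",
    "sdr_area",
    "compute_sdr_curve",
]


@dataclass(frozen=True)
class AlgorithmParams:
    """Tunable parameters of the SDR detection algorithm.

    Defaults are the published operating point of the method; thresholds are
    in gray-level units on the 0–255 scale of 8-bit images.

    Attributes
    ----------
    n_stack : int
        Number of images in one analysis window.
    n_select : int
        Images drawn (without replacement) per green-path median.
    n_rep : int
        Number of green-path repetitions.
    r_upper, r_lower : int
        First/last row of the superficial band (1-based, inclusive).  With
        the defaults (1, 19) on 500-row images the band covers the top
        19/500 ≈ 4 % of the imaged depth.
    o_poly_green, o_poly_red : int
        Polynomial orders of the baseline fits.
    t_green, t_red, t_blue : float
        Detection thresholds of the three paths.
    p_include : float
        Percent of columns at each end eligible for the blue path.
    p_exclude : float
        Percent of columns zeroed at each end of the SDR curve.
    seed : int
        Seed driving the green path's random subset sampling.
    """

    n_stack: int = 150
    n_select: int = 15
    n_rep: int = 100
    r_upper: int = 1
    r_lower: int = 19
    o_poly_green: int = 6
    o_poly_red: int = 6
    t_green: float = 2.0
    t_red: float = 5.0
    t_blue: float = 10.0
    p_include: float = 25.0
    p_exclude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_select > self.n_stack:
            raise ValueError("n_select must not exceed n_stack")
        if not (1 <= self.r_upper <= self.r_lower):
            raise ValueError("require 1 <= r_upper <= r_lower")
        if min(self.t_green, self.t_red, self.t_blue) <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not (0 <= self.p_exclude <= self.p_include <= 50):
            raise ValueError("require 0 <= p_exclude <= p_include <= 50")
        if self.n_rep < 1 or self.n_select < 1 or self.n_stack < 1:
            raise ValueError("n_stack, n_select, n_rep must be >= 1")

    @property
    def band_rows(self) -> int:
        """Number of rows in the superficial band."""
        return self.r_lower - self.r_upper + 1

    def with_seed(self, seed: int) -> "AlgorithmParams":
        return replace(self, seed=seed)


class ImageStack:
    """Ordered collection of same-sized grayscale frames.

    Frames are stored as one float array of shape ``(n, rows, cols)``;
    ``indices`` preserves each frame's acquisition order index.
    """

    def __init__(self, frames: Sequence[np.ndarray] | np.ndarray,
                 indices: Sequence[int] | None = None):
        arr = np.asarray(frames, dtype=float)
        if arr.ndim != 3:
            raise ValueError("frames must form an (n, rows, cols) array")
        if arr.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        self.frames = arr
        if indices is None:
            indices = range(arr.shape[0])
        self.indices = list(indices)
        if len(self.indices) != arr.shape[0]:
            raise ValueError("one index per frame required")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class PeakSet:
    """Peaks of a detection curve: positions, raw heights and widths.

    Positions are column indices (integer for raw detections, possibly
    fractional for cross-repetition cluster means); heights are the curve
    values at the peaks; widths are full widths at half prominence, in
    columns.
    """

    positions: np.ndarray
    heights: np.ndarray
    widths: np.ndarray

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class SDRCurve:
    """Per-column detection values plus the normalized trapezoidal area."""

    values: np.ndarray
    area: float
    index: object = None  # timestamp/order index of the newest contributing image

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SDR values must be nonnegative")


# ---------------------------------------------------------------------------
# elementary operations


def subtract_row_means(stack: ImageStack) -> ImageStack:
    """Subtract each row's own mean from that row, in every frame.

    Centers every row at zero so that the inverted CWM curves of the
    downstream paths oscillate around zero and "inversion" is plain negation.
    """
    frames = stack.frames
    centered = frames - frames.mean(axis=2, keepdims=True)
    return ImageStack(centered, stack.indices)


def median_image(frames: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Pixel-wise median of a list of frames.

    For an even number of frames the mean of the two middle values is used.
    """
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] < 1 or arr.size == 0:
        raise ValueError("median_image requires at least one frame")
    return np.median(arr, axis=0)


def column_wise_mean(image: np.ndarray, r_upper: int, r_lower: int) -> np.ndarray:
    """Mean over the row band ``r_upper..r_lower`` (1-based, inclusive) per column."""
    image = np.asarray(image, dtype=float)
    if not (1 <= r_upper <= r_lower <= image.shape[0]):
        raise ValueError(
            f"row band {r_upper}..{r_lower} outside image of height {image.shape[0]}"
        )
    return image[r_upper - 1:r_lower].mean(axis=0)


def baseline_subtract(curve: np.ndarray, order: int) -> np.ndarray:
    """Remove a least-squares polynomial baseline of the given order.

    The fit abscissa is rescaled to [-1, 1] for conditioning (order-6 fits on
    hundreds of points are badly conditioned on the raw column index).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size <= order:
        raise ValueError("curve must be longer than the polynomial order")
    x = np.arange(curve.size)
    fit = Polynomial.fit(x, curve, order)  # maps x to window [-1, 1]
    return curve - fit(x)


def _baseline_residuals(curves: np.ndarray, order: int) -> np.ndarray:
    """Vectorized `baseline_subtract` for a (n_curves, length) array."""
    n = curves.shape[1]
    if n <= order:
        raise ValueError("curves must be longer than the polynomial order")
    x = np.linspace(-1.0, 1.0, n)
    v = np.vander(x, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(v, curves.T, rcond=None)
    return curves - (v @ coef).T


def detect_peaks(curve: np.ndarray) -> PeakSet:
    """Locate local maxima of a curve with their raw heights and widths.

    A peak is a sample strictly greater than its neighbors; for a flat-top
    plateau the first sample of the plateau is reported.  Height is the curve
    value at the peak; width is the full width at half prominence, in
    columns.
    """
    curve = np.asarray(curve, dtype=float)
    peaks, props = find_peaks(curve, plateau_size=1)
    if len(peaks) == 0:
        empty = np.empty(0)
        return PeakSet(np.empty(0, dtype=int), empty, empty)
    positions = props["left_edges"]
    widths = peak_widths(curve, peaks, rel_height=0.5)[0]
    return PeakSet(positions, curve[positions], widths)


def gaussian_peak_vector(peaks: PeakSet, length: int) -> np.ndarray:
    """Render selected peaks as a sum of Gaussians sampled at integer columns.

    ``f(x) = sum_k height_k * exp(-((x - pos_k) / (width_k / 2))**2)`` —
    each Gaussian drops to ``height_k / e`` exactly half a width away from
    its center, so the rendered bumps represent the dark regions in both
    width and strength.
    """
    if peaks.n == 0:
        return np.zeros(length)
    widths = np.asarray(peaks.widths, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("peak widths must be strictly positive")
    positions = np.asarray(peaks.positions, dtype=float)
    if np.any((positions < 0) | (positions >= length)):
        raise ValueError("peak positions must lie within [0, length)")
    x = np.arange(length, dtype=float)
    out = np.zeros(length)
    for pos, height, width in zip(positions, peaks.heights, widths):
        out += height * np.exp(-(((x - pos) / (width / 2.0)) ** 2))
    return out


# ---------------------------------------------------------------------------
# the three paths


def _cluster_repetition_peaks(positions: np.ndarray, heights: np.ndarray,
                              widths: np.ndarray, length: int) -> PeakSet:
    """Cluster per-repetition peaks by lateral position with ±1 column tolerance.

    Greedy mode-seeded clustering: repeatedly take the column hosting the
    largest number of unassigned peaks (ties: lowest column), absorb every
    unassigned peak within one column of it, and record the cluster's mean
    position, height and width over the repetitions in which it appears.
    Systematic defects recur at the same column in (nearly) every repetition
    and are therefore seeded first; scattered noise peaks form small
    clusters whose mean heights stay low.
    """
    positions = np.asarray(positions)
    counts = np.bincount(positions, minlength=length).astype(int)
    assigned = np.zeros(len(positions), dtype=bool)
    c_pos, c_h, c_w = [], [], []
    while counts.max() > 0:
        col = int(np.argmax(counts))
        members = ~assigned & (np.abs(positions - col) <= 1)
        sel_pos = positions[members]
        c_pos.append(sel_pos.mean())
        c_h.append(heights[members].mean())
        c_w.append(widths[members].mean())
        np.subtract.at(counts, sel_pos, 1)
        assigned |= members
    return PeakSet(np.array(c_pos), np.array(c_h), np.array(c_w))


def green_path(stack: ImageStack, params: AlgorithmParams) -> np.ndarray:
    """Detect narrow, laterally stable dark streaks.

    Expects a row-mean-subtracted stack.  For each of ``n_rep`` repetitions a
    median image of ``n_select`` randomly drawn frames (without replacement)
    is formed, its superficial-band CWM is inverted and baseline-subtracted,
    and peaks are detected.  Peaks are clustered across repetitions by
    position (±1 column); clusters whose mean height exceeds ``t_green`` are
    rendered as a Gaussian peak vector.

    The median is evaluated on the superficial band only: the pixel-wise
    median commutes with row slicing, so this equals the CWM of the
    full-frame median image.
    """
    n = len(stack)
    if params.n_select > n:
        raise ValueError(f"n_select={params.n_select} exceeds stack size {n}")
    band = stack.frames[:, params.r_upper - 1:params.r_lower, :]
    if band.shape[1] != params.band_rows:
        raise ValueError("superficial band lies outside the frame")
    length = band.shape[2]

    rng = np.random.default_rng(params.seed)
    draws = np.stack([rng.choice(n, size=params.n_select, replace=False)
                      for _ in range(params.n_rep)])
    medians = np.median(band[draws], axis=1)          # (n_rep, band_rows, cols)
    cwm = medians.mean(axis=1)                        # (n_rep, cols)
    residuals = _baseline_residuals(-cwm, params.o_poly_green)

    all_pos, all_h, all_w = [], [], []
    for rep in range(params.n_rep):
        pk = detect_peaks(residuals[rep])
        all_pos.append(pk.positions)
        all_h.append(pk.heights)
        all_w.append(pk.widths)
    positions = np.concatenate(all_pos)
    if len(positions) == 0:
        return np.zeros(length)
    clusters = _cluster_repetition_peaks(
        positions, np.concatenate(all_h), np.concatenate(all_w), length)
    keep = (clusters.heights > params.t_green) & (clusters.widths > 0)
    selected = PeakSet(clusters.positions[keep], clusters.heights[keep],
                       clusters.widths[keep])
    return gaussian_peak_vector(selected, length)


def red_path(inverted_cwm: np.ndarray, params: AlgorithmParams) -> np.ndarray:
    """Detect broad diffuse dark regions in the full-stack median CWM.

    The inverted CWM of the whole stack's median image is baseline-subtracted
    at order ``o_poly_red``; residual values above ``t_red`` are kept, the
    rest are zeroed.
    """
    residual = baseline_subtract(np.asarray(inverted_cwm, dtype=float),
                                 params.o_poly_red)
    return np.where(residual > params.t_red, residual, 0.0)


def blue_path(inverted_cwm: np.ndarray, params: AlgorithmParams) -> np.ndarray:
    """Detect dark regions at the horizontal endpoints.

    No baseline is subtracted (a polynomial fit would adapt to end-of-curve
    structure); instead raw inverted-CWM values above ``t_blue`` within the
    first and last ``floor(p_include % of length)`` columns are kept.
    """
    curve = np.asarray(inverted_cwm, dtype=float)
    length = curve.size
    zone = int(np.floor(params.p_include / 100.0 * length))
    mask = np.zeros(length, dtype=bool)
    mask[:zone] = True
    if zone > 0:
        mask[length - zone:] = True
    return np.where(mask & (curve > params.t_blue), curve, 0.0)


def combine_paths(green: np.ndarray, red: np.ndarray, blue: np.ndarray,
                  params: AlgorithmParams, index: object = None) -> SDRCurve:
    """Element-wise maximum of the three path curves, with excluded borders.

    The first and last ``floor(p_exclude % of length)`` columns are zeroed:
    fully functional transducers show dark streaks at the very image borders,
    which must not trigger detections.
    """
    green = np.asarray(green, dtype=float)
    if not (green.shape == np.shape(red) == np.shape(blue)):
        raise ValueError("path curves must have equal lengths")
    values = np.maximum(np.maximum(green, red), blue)
    cut = int(np.floor(params.p_exclude / 100.0 * values.size))
    if cut > 0:
        values[:cut] = 0.0
        values[-cut:] = 0.0
    return SDRCurve(values, sdr_area(values, values.size), index)


def sdr_area(curve: np.ndarray, element_count: int) -> float:
    """Trapezoidal area under the curve, normalized by the element count."""
    return float(np.trapezoid(np.asarray(curve, dtype=float)) / element_count)


def compute_sdr_curve(stack: ImageStack, params: AlgorithmParams,
                      index: object = None) -> SDRCurve:
    """Run the full three-path algorithm on one image stack.

    Deterministic given ``params.seed``: the red and blue paths are
    order-free (a median ignores frame order); only the green path's subset
    sampling consumes randomness, and it draws frame indices from a generator
    seeded with ``params.seed``.
    """
    if len(stack) != params.n_stack:
        raise ValueError(
            f"stack holds {len(stack)} frames but n_stack={params.n_stack}")
    rows, _ = stack.frame_shape
    if params.r_lower > rows:
        raise ValueError("superficial band lies outside the frames")
    centered = subtract_row_means(stack)
    green = green_path(centered, params)
    full_median = median_image(centered.frames[:, params.r_upper - 1:params.r_lower, :])
    inverted_cwm = -full_median.mean(axis=0)
    red = red_path(inverted_cwm, params)
    blue = blue_path(inverted_cwm, params)
    return combine_paths(green, red, blue, params, index)
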