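"""Extraction of the B-mode rectangle from stored ultrasound frames.

Stored frames surround the anatomical B-mode image with zero-filled fields
carrying patient data, scales and vendor logotypes.  The B-mode rectangle is
recovered as the largest 8-connected component of nonzero pixels; laterally
zoomed images — where image columns no longer map one-to-one onto transducer
elements — are rejected by comparing the rectangle's physical width against
the transducer aperture; accepted rectangles are resized to
``element_count × resized_height`` so that one column corresponds to one
element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from skimage.measure import label
from skimage.transform import resize

__all__ = [
    "TransducerProfile",
    "PROFILES",
    "Corners",
    "BModeExtract",
    "REJECT_REASONS",
    "find_bmode_region",
    "check_lateral_zoom",
    "resize_bmode",
    "extract_bmode",
    "prepare_frame",
]

#: enumerated rejection reasons surfaced by the pipeline
REJECT_REASONS = ("doppler", "width_over", "width_under", "no_calibration",
                  "no_region")


@dataclass(frozen=True)
class TransducerProfile:
    """Per-transducer geometry driving resizing and the zoom check.

    ``accepted_width_mm`` is a closed interval in mm around the physical
    aperture; images whose extracted B-mode width falls outside it are
    laterally zoomed (or mis-extracted) and must be rejected.
    """

    model_name: str
    element_count: int
    aperture_mm: float = 50.0
    accepted_width_mm: tuple[float, float] = (49.5, 51.5)
    resized_height: int = 500

    def __post_init__(self) -> None:
        if self.element_count < 2:
            raise ValueError("element_count must be >= 2")
        low, high = self.accepted_width_mm
        if not (low <= self.aperture_mm <= high):
            raise ValueError("accepted_width_mm must contain aperture_mm")


#: shipped linear-array profiles
PROFILES: dict[str, TransducerProfile] = {
    "ML 6-15": TransducerProfile("ML 6-15", element_count=336),
    "L12-5": TransducerProfile("L12-5", element_count=256),
}


class Corners(NamedTuple):
    """Rectangle in stored-frame coordinates, 0-based, half-open."""

    top: int
    bottom: int
    left: int
    right: int


@dataclass
class BModeExtract:
    """An extracted B-mode rectangle plus its provenance."""

    image: np.ndarray
    corners: Corners
    physical_width_mm: float | None = None


def find_bmode_region(gray: np.ndarray) -> Corners:
    """Locate the B-mode rectangle as the largest nonzero connected area.

    The largest 8-connected component of nonzero pixels is kept and all
    other pixels are discarded; the rectangle is then read off the row and
    column projections of the surviving mask.  For regions that narrow with
    depth (virtually convex scans) the left/right edges come from the top
    5 % of the region's rows, so the rectangle has the width of the most
    superficial part and the full region height.
    """
    gray = np.asarray(gray)
    mask = gray > 0
    if not mask.any():
        raise ValueError("no B-mode region found (image is all zero)")
    labels = label(mask, connectivity=2)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    mask = labels == largest

    row_any = mask.any(axis=1)
    top = int(np.argmax(row_any))
    bottom = len(row_any) - int(np.argmax(row_any[::-1]))
    band = max(1, math.ceil(0.05 * (bottom - top)))
    col_any = mask[top:top + band].any(axis=0)
    left = int(np.argmax(col_any))
    right = len(col_any) - int(np.argmax(col_any[::-1]))
    return Corners(top, bottom, left, right)


def check_lateral_zoom(corners: Corners, physical_delta_x: float | None,
                       profile: TransducerProfile
                       ) -> tuple[bool, float | None, str | None]:
    """Accept or reject the extracted rectangle based on its physical width.

    ``physical_delta_x`` is in mm per pixel (unit normalization from the
    DICOM tag's native cm happens at ingest).  Returns ``(accepted,
    physical_width_mm, reason)`` where reason is one of ``width_over``,
    ``width_under``, ``no_calibration`` or None.
    """
    if physical_delta_x is None or physical_delta_x <= 0:
        return False, None, "no_calibration"
    width_mm = (corners.right - corners.left) * physical_delta_x
    low, high = profile.accepted_width_mm
    if width_mm < low:
        return False, width_mm, "width_under"
    if width_mm > high:
        return False, width_mm, "width_over"
    return True, width_mm, None


def resize_bmode(extract: BModeExtract | np.ndarray,
                 profile: TransducerProfile) -> np.ndarray:
    """Bicubic resize to ``element_count`` columns × ``resized_height`` rows.

    No anti-alias prefiltering is applied; output is clipped to [0, 255].
    """
    image = extract.image if isinstance(extract, BModeExtract) else np.asarray(extract)
    if image.shape[0] <= 1 or image.shape[1] <= 1:
        raise ValueError("degenerate extract: both dimensions must exceed 1 px")
    out = resize(image.astype(float),
                 (profile.resized_height, profile.element_count),
                 order=3, anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 255.0)


def extract_bmode(gray: np.ndarray, physical_delta_x: float | None,
                  profile: TransducerProfile
                  ) -> tuple[BModeExtract | None, str | None]:
    """Full extraction decision: every input yields an extract or a reason."""
    gray = np.asarray(gray)
    try:
        corners = find_bmode_region(gray)
    except ValueError:
        return None, "no_region"
    accepted, width_mm, reason = check_lateral_zoom(corners, physical_delta_x,
                                                    profile)
    if not accepted:
        return None, reason
    # pixels outside the chosen component are zeroed before cropping
    labels = label(gray > 0, connectivity=2)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    masked = np.where(labels == largest, gray, 0)
    image = masked[corners.top:corners.bottom, corners.left:corners.right]
    return BModeExtract(image, corners, width_mm), None


def prepare_frame(gray: np.ndarray, physical_delta_x: float | None,
                  profile: TransducerProfile
                  ) -> tuple[np.ndarray | None, str | None]:
    """Extract and resize in one step; returns ``(resized, None)`` or ``(None, reason)``."""
    extract, reason = extract_bmode(gray, physical_delta_x, profile)
    if extract is None:
        return None, reason
    return resize_bmode(extract, profile), None
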