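"""Clinical-like synthetic image stacks and DICOM fixtures with known defects.

Real archives of stored B-mode frames are not shippable, so this module
emulates their relevant statistics: smooth anatomy-like structures that vary
frame to frame (and hence cancel under median stacking), multiplicative
speckle, a zero-filled surround with optional logotype/text boxes, and
injected systematic dark column-bands standing in for defective elements.
Ground truth is explicit (`DefectSpec`), which makes every downstream module
testable against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .sdr import ImageStack
from .extraction import TransducerProfile

__all__ = [
    "DefectSpec",
    "BackgroundModel",
    "FixtureLayout",
    "generate_frame",
    "generate_stack",
    "scale_defect",
    "write_dicom_fixture",
    "write_ground_truth",
    "save_frame_png",
]


@dataclass(frozen=True)
class DefectSpec:
    """Ground truth for one injected defect.

    center_column/width_columns are in resized-image coordinates (one column
    per transducer element).  ``strength`` is the gray-level depression at
    the top row; it attenuates linearly with depth by ``depth_decay`` per
    row.  ``intermittency`` is the fraction of frames in which the defect is
    absent (0 = persistent fault, 1 = never present).
    """

    center_column: int
    width_columns: int = 1
    strength: float = 20.0
    depth_decay: float = 0.0
    intermittency: float = 0.0

    def __post_init__(self) -> None:
        if self.width_columns < 1:
            raise ValueError("width_columns must be >= 1")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if not (0.0 <= self.intermittency <= 1.0):
            raise ValueError("intermittency must lie in [0, 1]")


@dataclass(frozen=True)
class BackgroundModel:
    """Statistical model of the anatomical background.

    Each frame is ``mean_level`` plus ``blob_count`` randomly placed smooth
    radial bumps with amplitudes in ``±blob_amplitude/2`` (anatomy that
    differs between frames but has zero-mean column structure in
    expectation), multiplied by Rayleigh-like speckle standardized to mean 1
    and standard deviation ``speckle_sigma``.
    """

    mean_level: float = 110.0
    blob_count: int = 8
    blob_amplitude: float = 60.0
    speckle_sigma: float = 0.1
    seed: int = 0


@dataclass(frozen=True)
class FixtureLayout:
    """Geometry of a stored full frame embedding a B-mode rectangle.

    ``full_frame_size`` is (rows, cols); ``bmode_offset`` the top-left corner
    of the embedded B-mode rectangle; ``logotype_boxes`` rectangles
    (r0, c0, r1, c1), half-open, filled with nonzero text-like pixels;
    ``physical_delta_x`` is the pixel pitch in cm (the DICOM ultrasound
    region calibration convention); ``region_count`` the number of ultrasound
    regions declared in the metadata (more than one marks Doppler-curve /
    side-by-side layouts).
    """

    full_frame_size: tuple[int, int] = (720, 960)
    bmode_offset: tuple[int, int] = (100, 200)
    logotype_boxes: tuple[tuple[int, int, int, int], ...] = ()
    physical_delta_x: float = 0.01
    region_count: int = 1


# ---------------------------------------------------------------------------


def _apply_defect(img: np.ndarray, defect: DefectSpec) -> None:
    rows, cols = img.shape
    depth = defect.strength * np.clip(
        1.0 - defect.depth_decay * np.arange(rows), 0.0, None)
    start = defect.center_column - (defect.width_columns - 1) // 2
    stop = start + defect.width_columns
    img[:, max(start, 0):min(stop, cols)] -= depth[:, None]


def generate_frame(background: BackgroundModel, defects: list[DefectSpec],
                   frame_index: int,
                   shape: tuple[int, int] = (500, 336)) -> np.ndarray:
    """One synthetic grayscale frame with the given defects applied.

    Reproducible: all randomness derives from ``(background.seed,
    frame_index)``, so the same frame index always yields the same frame.
    Returns floats clipped to [0, 255].
    """
    rows, cols = shape
    for d in defects:
        if not (0 <= d.center_column < cols):
            raise ValueError(
                f"defect column {d.center_column} outside frame width {cols}")
    rng = np.random.default_rng((background.seed, frame_index))
    img = np.full((rows, cols), float(background.mean_level))
    r = np.arange(rows, dtype=float)
    c = np.arange(cols, dtype=float)
    for _ in range(background.blob_count):
        r0 = rng.uniform(0, rows)
        c0 = rng.uniform(0, cols)
        sr = rng.uniform(0.08 * rows, 0.3 * rows)
        sc = rng.uniform(0.08 * cols, 0.3 * cols)
        amp = rng.uniform(-0.5, 0.5) * background.blob_amplitude
        img += amp * np.outer(np.exp(-((r - r0) ** 2) / (2 * sr ** 2)),
                              np.exp(-((c - c0) ** 2) / (2 * sc ** 2)))
    if background.speckle_sigma > 0:
        z = rng.rayleigh(1.0, size=(rows, cols))
        z = (z - math.sqrt(math.pi / 2)) / math.sqrt(2 - math.pi / 2)
        img *= 1.0 + background.speckle_sigma * z
    # presence draws come after the background draws, so a frame's background
    # realization does not depend on the defect list
    for d in defects:
        u = rng.random()
        if u < d.intermittency or d.strength <= 0:
            continue
        _apply_defect(img, d)
    return np.clip(img, 0.0, 255.0)


def generate_stack(n: int, profile: TransducerProfile,
                   background: BackgroundModel,
                   defects: list[DefectSpec], seed: int) -> ImageStack:
    """Stack of ``n`` frames at the profile's resized geometry.

    Per-frame backgrounds are independent realizations; defects are shared.
    Equal seeds give bit-identical stacks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bg = replace(background, seed=seed)
    shape = (profile.resized_height, profile.element_count)
    frames = [generate_frame(bg, defects, i, shape) for i in range(n)]
    return ImageStack(np.stack(frames))


def scale_defect(defect: DefectSpec, from_width: int, to_width: int) -> DefectSpec:
    """Map a defect between column grids (resized ↔ stored-frame coordinates)."""
    factor = to_width / from_width
    return replace(
        defect,
        center_column=int(round(defect.center_column * factor)),
        width_columns=max(1, int(round(defect.width_columns * factor))),
    )


# ---------------------------------------------------------------------------
# DICOM fixtures


def _render_logotype(full: np.ndarray, box: tuple[int, int, int, int]) -> None:
    r0, c0, r1, c1 = box
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    text_like = ((rr // 2) + (cc // 3)) % 2 == 0
    full[r0:r1, c0:c1][text_like] = 230


def write_dicom_fixture(frame: np.ndarray, layout: FixtureLayout,
                        tags: dict, path: str | Path) -> Path:
    """Write an 8-bit RGB DICOM file embedding ``frame`` in a zero surround.

    ``tags`` must provide StationName and StudyDate; TransducerData and
    StudyTime are honored when present.  The declared ultrasound region
    sequence has ``layout.region_count`` items, each calibrated with
    ``layout.physical_delta_x`` (cm per pixel, PhysicalUnitsXDirection = 3).
    """
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frame = np.asarray(frame)
    rows, cols = layout.full_frame_size
    h, w = frame.shape
    r0, c0 = layout.bmode_offset
    if not (r0 >= 1 and c0 >= 1 and r0 + h <= rows - 1 and c0 + w <= cols - 1):
        raise ValueError("B-mode rectangle must lie strictly inside the frame")

    full = np.zeros((rows, cols), dtype=np.uint8)
    full[r0:r0 + h, c0:c0 + w] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    for box in layout.logotype_boxes:
        _render_logotype(full, box)
    rgb = np.repeat(full[:, :, None], 3, axis=2)

    path = Path(path)
    station = str(tags["StationName"])
    study_date = str(tags["StudyDate"])

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.6.1"  # US Image Storage
    meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[station, study_date, str(tags.get("StudyTime", "")), path.name])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientName = "SYNTHETIC^FIXTURE"
    ds.PatientID = "SIM"
    ds.StationName = station
    ds.TransducerData = str(tags.get("TransducerData", ""))
    ds.StudyDate = study_date
    ds.StudyTime = str(tags.get("StudyTime", "000000"))

    ds.SamplesPerPixel = 3
    ds.PhotometricInterpretation = "RGB"
    ds.PlanarConfiguration = 0
    ds.Rows, ds.Columns = rows, cols
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = rgb.tobytes()

    regions = []
    for _ in range(layout.region_count):
        item = Dataset()
        item.RegionSpatialFormat = 1      # 2D B-mode
        item.RegionDataType = 1           # tissue
        item.RegionFlags = 0
        item.RegionLocationMinX0 = c0
        item.RegionLocationMinY0 = r0
        item.RegionLocationMaxX1 = c0 + w
        item.RegionLocationMaxY1 = r0 + h
        item.PhysicalUnitsXDirection = 3  # cm
        item.PhysicalUnitsYDirection = 3
        item.PhysicalDeltaX = layout.physical_delta_x
        item.PhysicalDeltaY = layout.physical_delta_x
        regions.append(item)
    ds.SequenceOfUltrasoundRegions = regions

    ds.save_as(path, enforce_file_format=True)
    return path


def write_ground_truth(defects: list[DefectSpec], path: str | Path,
                       extra: dict | None = None) -> Path:
    """Serialize injected-defect ground truth as YAML next to a stack/fixture set."""
    path = Path(path)
    doc = {"defects": [asdict(d) for d in defects]}
    if extra:
        doc.update(extra)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def save_frame_png(frame: np.ndarray, path: str | Path) -> Path:
    """Lossless raster export of a raw frame for visual debugging."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, np.clip(np.rint(np.asarray(frame)), 0, 255).astype(np.uint8))
    return path
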