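"""Selection of usable frames from a DICOM archive.

Frames are grouped per scanner (StationName) and transducer (TransducerData);
Doppler-curve and side-by-side layouts are rejected via the
SequenceOfUltrasoundRegions item count and the stored column count.  Color
Doppler images without curves present as single-region frames and are kept.
Archives are messy: records missing required tags are skipped with a warning
and counted, never fatal, so monitoring continues.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pydicom

log = logging.getLogger(__name__)

__all__ = [
    "DicomRecord",
    "SelectionReport",
    "read_dicom",
    "read_dicom_dir",
    "select_images",
    "to_grayscale",
    "sort_by_study_date",
]

#: Rec.601 luma weights for RGB → gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class DicomRecord:
    """One stored clinical frame plus the metadata the selection rules consult.

    ``physical_delta_x`` is normalized to mm per pixel (the DICOM ultrasound
    region calibration stores cm when PhysicalUnitsXDirection is 3, the usual
    convention).
    """

    station_name: str | None
    transducer_label: str | None
    region_count: int
    physical_delta_x: float | None
    study_date: dt.date | None
    study_time: dt.time | None
    pixel_data: np.ndarray
    rows: int
    cols: int
    source_path: Path | None = None


@dataclass
class SelectionReport:
    """Tally of every selection decision; counts conserve the input count.

    ``n_collected = n_rejected_doppler + n_rejected_width +
    n_rejected_other + n_used`` at all times (``n_rejected_other`` collects
    extraction failures without calibration or region and is zero in the
    normal flow).  Records skipped for missing tags are counted separately in
    ``n_skipped`` and are not part of ``n_collected``.
    """

    n_collected: int = 0
    n_rejected_doppler: int = 0
    n_rejected_width: int = 0
    n_rejected_other: int = 0
    n_used: int = 0
    n_skipped: int = 0

    def record_width_rejection(self) -> None:
        """Move one previously accepted record from used to width-rejected."""
        self.n_rejected_width += 1
        self.n_used -= 1

    def record_other_rejection(self) -> None:
        self.n_rejected_other += 1
        self.n_used -= 1

    def summary(self) -> str:
        return (f"collected={self.n_collected} doppler={self.n_rejected_doppler} "
                f"width={self.n_rejected_width} other={self.n_rejected_other} "
                f"used={self.n_used} skipped={self.n_skipped}")


def _parse_date(value) -> dt.date | None:
    try:
        return dt.datetime.strptime(str(value), "%Y%m%d").date()
    except (TypeError, ValueError):
        return None


def _parse_time(value) -> dt.time | None:
    if value is None:
        return None
    text = str(value).split(".")[0].ljust(6, "0")
    try:
        return dt.datetime.strptime(text, "%H%M%S").time()
    except ValueError:
        return None


def read_dicom(path: str | Path) -> DicomRecord:
    """Read one DICOM file into a `DicomRecord`."""
    path = Path(path)
    ds = pydicom.dcmread(path)
    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    region_count = len(regions) if regions is not None else 0
    pdx_mm = None
    if regions:
        item = regions[0]
        delta = getattr(item, "PhysicalDeltaX", None)
        if delta is not None:
            units = getattr(item, "PhysicalUnitsXDirection", 3)
            pdx_mm = float(delta) * (10.0 if units == 3 else 1.0)
    pixels = ds.pixel_array
    transducer = getattr(ds, "TransducerData", None)
    if transducer is not None and not isinstance(transducer, str):
        transducer = "\\".join(str(v) for v in transducer)
    return DicomRecord(
        station_name=getattr(ds, "StationName", None),
        transducer_label=transducer,
        region_count=region_count,
        physical_delta_x=pdx_mm,
        study_date=_parse_date(getattr(ds, "StudyDate", None)),
        study_time=_parse_time(getattr(ds, "StudyTime", None)),
        pixel_data=pixels,
        rows=int(ds.Rows),
        cols=int(ds.Columns),
        source_path=path,
    )


def read_dicom_dir(directory: str | Path) -> list[DicomRecord]:
    """Read every ``*.dcm`` file under a directory tree (sorted by name)."""
    records = []
    for path in sorted(Path(directory).rglob("*.dcm")):
        try:
            records.append(read_dicom(path))
        except Exception as exc:  # unreadable file: warn, continue
            log.warning("skipping unreadable DICOM %s: %s", path, exc)
    return records


def select_images(records: Iterable[DicomRecord], station_name: str,
                  transducer_label: str | None,
                  max_single_image_cols: int
                  ) -> tuple[list[DicomRecord], SelectionReport]:
    """Keep frames of one scanner/transducer, rejecting Doppler/side-by-side.

    A record is accepted when its station and transducer labels match, its
    region count is exactly 1, and its stored width does not exceed
    ``max_single_image_cols`` (side-by-side layouts are wider than a single
    image; the bound is a per-scanner configuration value).  Idempotent:
    re-running on the accepted output changes nothing.
    """
    accepted: list[DicomRecord] = []
    report = SelectionReport()
    for rec in records:
        if rec.station_name is None:
            log.warning("record %s missing StationName; skipped", rec.source_path)
            report.n_skipped += 1
            continue
        if rec.station_name != station_name:
            continue
        if transducer_label is not None and (
                (rec.transducer_label or "").strip() != transducer_label):
            continue
        report.n_collected += 1
        if rec.region_count != 1 or rec.cols > max_single_image_cols:
            report.n_rejected_doppler += 1
            log.info("rejected %s: doppler/side-by-side (regions=%d, cols=%d)",
                     rec.source_path, rec.region_count, rec.cols)
            continue
        accepted.append(rec)
        report.n_used += 1
    return accepted, report


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """RGB → 8-bit gray via Rec.601 luma weights, rounded to nearest integer."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (rows, cols, 3) RGB image")
    return np.rint(rgb.astype(float) @ _LUMA).astype(np.uint8)


def sort_by_study_date(records: Iterable[DicomRecord]) -> list[DicomRecord]:
    """Stable ascending sort by StudyDate, ties broken by StudyTime.

    Records without a parseable date are excluded with a warning.
    """
    kept = []
    for rec in records:
        if rec.study_date is None:
            log.warning("record %s has unparseable StudyDate; excluded",
                        rec.source_path)
            continue
        kept.append(rec)
    return sorted(kept, key=lambda r: (r.study_date,
                                       r.study_time or dt.time.min))
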