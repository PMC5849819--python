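"""Rolling monitoring of SDR curves and area-based notification.

One monitor is kept per (station, transducer model) pair — the method
presumes a transducer stays attached to one scanner.  Each newly stored
image updates a FIFO stack of the latest ``n_stack`` resized frames; once
the stack is full, every update yields one SDR curve, and the curve areas
form the time series watched for threshold crossings.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sdr import AlgorithmParams, ImageStack, SDRCurve, compute_sdr_curve

__all__ = ["SDRSeries", "Notification", "RollingMonitor", "notify",
           "export_surface", "write_series_csv"]


@dataclass
class SDRSeries:
    """Ordered SDR curves and areas for one scanner/transducer pair."""

    station: str = ""
    transducer: str = ""
    curves: list[SDRCurve] = field(default_factory=list)

    @property
    def areas(self) -> list[float]:
        return [c.area for c in self.curves]

    def __len__(self) -> int:
        return len(self.curves)


@dataclass(frozen=True)
class Notification:
    """One alert: the area series rose to or above the threshold."""

    curve_index: int
    area: float
    threshold: float
    timestamp: object = None


class RollingMonitor:
    """FIFO stack of the newest ``n_stack`` frames, emitting one curve per update."""

    def __init__(self, params: AlgorithmParams,
                 frame_shape: tuple[int, int] | None = None,
                 station: str = "", transducer: str = ""):
        self.params = params
        self.frame_shape = frame_shape
        self.buffer: deque[np.ndarray] = deque(maxlen=params.n_stack)
        self.series = SDRSeries(station=station, transducer=transducer)
        self._last_timestamp = None
        self._n_fed = 0

    def update(self, image: np.ndarray, timestamp=None) -> SDRCurve | None:
        """Append one resized frame; return a new SDR curve once the stack is full.

        Images must arrive in StudyDate order (pre-sort with
        ``ingest.sort_by_study_date``); non-decreasing timestamps are
        asserted when given.  Before the stack holds ``n_stack`` frames no
        curve is emitted; afterwards the oldest frame is evicted and one
        curve is computed per update.
        """
        image = np.asarray(image, dtype=float)
        if self.frame_shape is None:
            self.frame_shape = image.shape
        if image.shape != tuple(self.frame_shape):
            raise ValueError(
                f"frame shape {image.shape} does not match configured "
                f"{tuple(self.frame_shape)}")
        if timestamp is not None and self._last_timestamp is not None:
            if timestamp < self._last_timestamp:
                raise ValueError("images must be fed in StudyDate order")
        if timestamp is not None:
            self._last_timestamp = timestamp
        self.buffer.append(image)
        self._n_fed += 1
        if len(self.buffer) < self.params.n_stack:
            return None
        stack = ImageStack(np.stack(self.buffer))
        curve = compute_sdr_curve(stack, self.params,
                                  index=timestamp if timestamp is not None
                                  else self._n_fed - 1)
        self.series.curves.append(curve)
        return curve

    @property
    def n_fed(self) -> int:
        return self._n_fed


def notify(series: SDRSeries, threshold: float = 0.75) -> list[Notification]:
    """Rising-edge notifications: alert once per excursion above the threshold.

    An alert fires at every index where the area crosses from below the
    threshold to ≥ threshold, so a persistent fault alerts once until it
    clears, avoiding alert storms in continuous monitoring.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    below = True
    for i, curve in enumerate(series.curves):
        if curve.area >= threshold:
            if below:
                out.append(Notification(i, curve.area, threshold, curve.index))
            below = False
        else:
            below = True
    return out


def export_surface(series: SDRSeries, csv_path: str | Path,
                   fig_path: str | Path | None = None) -> pd.DataFrame:
    """Write the curve-index × column surface as CSV and render a heatmap.

    The surface is what the method's 3D monitoring plot shows: time running
    along one axis, elements along the other, detection strength as height.
    """
    if len(series) == 0:
        raise ValueError("cannot export an empty series")
    matrix = np.stack([c.values for c in series.curves])
    df = pd.DataFrame(matrix)
    df.index.name = "curve"
    df.to_csv(csv_path)
    if fig_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.pcolormesh(matrix, shading="auto")
        ax.set_xlabel("element / column")
        ax.set_ylabel("SDR curve index")
        fig.colorbar(im, ax=ax, label="SDR value")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
    return df


def write_series_csv(series: SDRSeries, curves_path: str | Path,
                     areas_path: str | Path) -> None:
    """Export curves (index, timestamp, per-column values, area) and areas."""
    rows = []
    for i, c in enumerate(series.curves):
        rows.append([i, c.index, *c.values, c.area])
    ncol = len(series.curves[0].values) if series.curves else 0
    cols = ["index", "timestamp", *[f"c{j}" for j in range(ncol)], "area"]
    pd.DataFrame(rows, columns=cols).to_csv(curves_path, index=False)
    pd.DataFrame({"index": range(len(series)),
                  "area": series.areas}).to_csv(areas_path, index=False)


def write_notifications(notifications: list[Notification],
                        path: str | Path) -> None:
    """JSON-lines event log, one object per alert."""
    with open(path, "w") as fh:
        for n in notifications:
            fh.write(json.dumps({
                "curve_index": n.curve_index,
                "area": n.area,
                "threshold": n.threshold,
                "timestamp": str(n.timestamp) if n.timestamp is not None else None,
            }) + "\n")
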