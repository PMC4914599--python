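"""Head-movement summaries from rigid-body realignment parameter series.

Between-acquisition head movement is tracked by realigning short anatomical
scans to the first scan of each session, giving six rigid-body parameters per
scan (translations tx/ty/tz in mm, rotations pitch/roll/yaw in degrees).  The
session-level summary is the maximum absolute excursion per parameter; the
scalar movement covariate is the displacement magnitude d = sqrt(x²+y²+z²)
over the three translations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PARAMS",
    "RealignmentSeries",
    "MovementSummary",
    "displacement_magnitude",
    "session_max_displacement",
    "summarize_movement",
    "read_realignment",
]

PARAMS = ["tx", "ty", "tz", "pitch", "roll", "yaw"]
_TRANS = PARAMS[:3]


@dataclass(frozen=True)
class RealignmentSeries:
    """Ordered rigid-body parameters for the scans of one session.

    ``scans`` is an (n, 6) array ordered (tx, ty, tz [mm], pitch, roll, yaw
    [deg]) relative to the reference scan (row ``reference_index``), whose
    parameters are all zero by construction.
    """

    scans: np.ndarray
    reference_index: int = 0
    subject: str = ""
    session: int = 0

    def __post_init__(self):
        arr = np.asarray(self.scans, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("scans must be an (n, 6) array")
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 scans (reference plus one)")
        if not np.allclose(arr[self.reference_index], 0.0, atol=1e-9):
            raise ValueError("reference scan must have all-zero parameters")
        object.__setattr__(self, "scans", arr)

    def __len__(self) -> int:
        return self.scans.shape[0]


@dataclass(frozen=True)
class MovementSummary:
    """Mean, SD and range of per-session parameter maxima over a batch of sessions."""

    mean: pd.Series  # per parameter
    sd: pd.Series
    range_min: pd.Series
    range_max: pd.Series
    n_sessions: int
    maxima: pd.DataFrame  # session x parameter

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd,
             "range_min": self.range_min, "range_max": self.range_max}
        )


def displacement_magnitude(x: float, y: float, z: float) -> float:
    """Euclidean displacement d = sqrt(x² + y² + z²) over the three translations."""
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise ValueError("displacement components must be finite")
    return math.sqrt(x * x + y * y + z * z)


def session_max_displacement(series: RealignmentSeries) -> pd.Series:
    """Maximum absolute excursion per parameter over the session's scans."""
    return pd.Series(np.abs(series.scans).max(axis=0), index=PARAMS)


def summarize_movement(sessions: list[RealignmentSeries]) -> MovementSummary:
    """Per-session maxima averaged over sessions, with SD and range.

    With a single session the mean equals that session's maxima and the SD is 0.
    """
    if len(sessions) < 1:
        raise ValueError("need at least one session")
    maxima = pd.DataFrame([session_max_displacement(s) for s in sessions])
    maxima.index = range(len(sessions))
    sd = maxima.std(ddof=1) if len(sessions) > 1 else pd.Series(0.0, index=PARAMS)
    return MovementSummary(
        mean=maxima.mean(), sd=sd,
        range_min=maxima.min(), range_max=maxima.max(),
        n_sessions=len(sessions), maxima=maxima,
    )


def read_realignment(
    path: str | Path, rotation_units: str = "rad",
    subject: str = "", session: int = 0,
) -> RealignmentSeries:
    """Read one session's realignment parameters.

    Accepts the whitespace-delimited six-column ``rp_*.txt`` convention (three
    translations in mm, three rotations in radians - converted to degrees on
    ingest unless ``rotation_units="deg"``) or a headed CSV with columns
    tx,ty,tz,pitch,roll,yaw.
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().splitlines()[0]
    try:
        [float(tok) for tok in first.replace(",", " ").split()]
        headed = False
    except ValueError:
        headed = True
    if headed:  # headed CSV
        frame = pd.read_csv(path)
        missing = [c for c in PARAMS if c not in frame.columns]
        if missing:
            raise ValueError(f"realignment CSV lacks column(s): {', '.join(missing)}")
        arr = frame[PARAMS].to_numpy(dtype=float)
    else:
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] != 6:
            raise ValueError(f"expected 6 columns, got {arr.shape[1]}")
    if rotation_units == "rad":
        arr = arr.copy()
        arr[:, 3:] = np.rad2deg(arr[:, 3:])
    elif rotation_units != "deg":
        raise ValueError("rotation_units must be 'rad' or 'deg'")
    return RealignmentSeries(scans=arr, subject=subject, session=session)
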