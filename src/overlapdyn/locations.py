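"""Reading, windowing and round-tripping location and overlap-series tables.

Location tables are delimited text with an animal id, a timestamp and
planar x/y coordinates (projected units such as meters; geographic
coordinates must be projected before use). Locations are partitioned into
a-priori, contiguous, half-open time windows; each window later receives
one utilization distribution per individual and one overlap value per dyad.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column names expected in a location table
DEFAULT_COLUMN_MAP = {"id": "id", "time": "time", "x": "x", "y": "y"}

#: columns every overlap (BA) series table must carry, in this order
BA_SERIES_COLUMNS = ["window_index", "window_start", "n_A", "n_B", "ba"]


@dataclass
class LocationSeries:
    """Timestamped planar positions of one individual, time-sorted."""

    animal_id: str
    times: pd.DatetimeIndex
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x and y must have equal length")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("times must be non-decreasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class WindowSpec:
    """Contiguous half-open windows [origin + k*width, origin + (k+1)*width).

    ``count`` limits the number of windows; ``None`` means open-ended
    (windows run up to the last fix). The origin is a required user choice:
    weekly overlap series differ materially between calendar-anchored and
    deployment-anchored weeks, so no default anchoring is guessed.
    """

    origin: pd.Timestamp
    width: pd.Timedelta
    count: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", pd.Timestamp(self.origin))
        object.__setattr__(self, "width", pd.Timedelta(self.width))
        if self.width <= pd.Timedelta(0):
            raise ValueError("window width must be positive")
        if self.count is not None and self.count < 1:
            raise ValueError("window count must be positive")

    def start(self, index: int) -> pd.Timestamp:
        return self.origin + index * self.width


@dataclass
class WindowedLocations:
    """Locations of one individual falling in window ``window_index``."""

    window_index: int
    points: np.ndarray  # (n, 2)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.n = len(self.points)


def read_locations(
    path,
    column_map: dict[str, str] | None = None,
    timestamp_format: str | None = None,
    *,
    sep: str = ",",
    tz: str | None = None,
) -> dict[str, LocationSeries]:
    """Read a delimited location table into one :class:`LocationSeries` per id.

    Rows with unparseable timestamps or non-finite coordinates are dropped
    and counted in the log. Timestamps are interpreted in the caller-stated
    timezone ``tz`` (naive if ``None``); no DST guessing is performed.

    Raises ``ValueError`` if a mapped column is missing or no parseable
    rows remain.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    table = pd.read_csv(path, sep=sep)
    for role, name in colmap.items():
        if name not in table.columns:
            raise ValueError(
                f"column {name!r} (mapped as {role!r}) not found in {path}; "
                f"available: {list(table.columns)}"
            )
    times = pd.to_datetime(
        table[colmap["time"]], format=timestamp_format, errors="coerce"
    )
    if tz is not None:
        times = times.dt.tz_localize(tz)
    xs = pd.to_numeric(table[colmap["x"]], errors="coerce")
    ys = pd.to_numeric(table[colmap["y"]], errors="coerce")
    ok = times.notna() & np.isfinite(xs) & np.isfinite(ys)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("read_locations: dropped %d unparseable row(s)", n_dropped)
    if not ok.any():
        raise ValueError(f"no parseable rows in {path}")
    clean = pd.DataFrame(
        {
            "id": table[colmap["id"]][ok].astype(str),
            "time": times[ok],
            "x": xs[ok].astype(float),
            "y": ys[ok].astype(float),
        }
    )
    out: dict[str, LocationSeries] = {}
    for animal_id, grp in clean.groupby("id", sort=True):
        grp = grp.sort_values("time", kind="stable")
        out[animal_id] = LocationSeries(
            animal_id=animal_id,
            times=pd.DatetimeIndex(grp["time"]),
            x=grp["x"].to_numpy(),
            y=grp["y"].to_numpy(),
        )
    return out


def assign_windows(
    series: LocationSeries, spec: WindowSpec
) -> list[WindowedLocations]:
    """Partition a location series into the windows of ``spec``.

    Every fix at or after the origin lands in exactly one window by the
    half-open convention (a fix exactly on a boundary belongs to the later
    window). Empty windows are retained with ``n=0`` so dyad series stay
    index-aligned. Fixes before the origin, or beyond ``spec.count`` windows
    when a count is given, are dropped with a logged count.
    """
    if len(series) == 0:
        return (
            []
            if spec.count is None
            else [WindowedLocations(t, np.empty((0, 2))) for t in range(spec.count)]
        )
    idx = ((series.times - spec.origin) // spec.width).astype(int)
    keep = idx >= 0
    if spec.count is not None:
        keep &= idx < spec.count
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "assign_windows(%s): %d fix(es) outside the window range dropped",
            series.animal_id,
            n_dropped,
        )
    idx = np.asarray(idx)[np.asarray(keep)]
    pts = np.column_stack([series.x[np.asarray(keep)], series.y[np.asarray(keep)]])
    n_windows = spec.count if spec.count is not None else (int(idx.max()) + 1 if len(idx) else 0)
    return [
        WindowedLocations(t, pts[idx == t]) for t in range(n_windows)
    ]


def write_series(series: pd.DataFrame, path) -> None:
    """Write an overlap-series table (window_index, window_start, n_A, n_B,
    ba, then covariates) as comma-delimited text, lossless for doubles."""
    missing = [c for c in BA_SERIES_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"series table missing required column(s): {missing}")
    cols = BA_SERIES_COLUMNS + [c for c in series.columns if c not in BA_SERIES_COLUMNS]
    series[cols].to_csv(path, index=False, float_format="%.17g")


def read_series(path) -> pd.DataFrame:
    """Read an overlap-series table written by :func:`write_series`.

    Raises ``ValueError`` naming the offending row if an overlap value lies
    outside [0, 1] (missing values are allowed and denote windows with too
    few fixes).
    """
    table = pd.read_csv(path)
    missing = [c for c in BA_SERIES_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path} missing required column(s): {missing}")
    ba = table["ba"]
    bad = ba.notna() & ((ba < 0) | (ba > 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: ba={ba.iloc[row]} outside [0, 1] at data row {row + 1}"
        )
    return table
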