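"""Core domain types and CSV readers/writers.

The atomic object is a :class:`SpikeTrain` — one sorted unit's spike times
over a known recording window.  Units carry quality-control attributes
(ISI-violation rate, signal-to-noise ratio, firing rate) produced upstream by
the spike sorter, and optionally the index of the electrode whose footprint
contains the unit.  A :class:`RecordingSession` bundles the units recorded
simultaneously in one network assay, together with the developmental age of
the culture in days post induction (dpi) and an experimental condition label.

Conventions
-----------
* Time is seconds everywhere; spatial coordinates are micrometres; culture
  age is an integer dpi.
* The recording window is half-open ``[t_start, t_stop)``: a spike exactly at
  ``t_stop`` is invalid, so rate denominators are unambiguous.
* CSV is the canonical exchange format.  Spike tables use the header
  ``unit_id,time_s[,isi_violation_rate,snr,firing_rate,electrode_index]``;
  tracking tables use ``track_id,dpi,x_um,y_um`` (an ImageJ Manual Tracking
  importer is also provided).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpikeTrain",
    "UnitRecord",
    "RecordingSession",
    "Trajectory",
    "Condition",
    "load_spike_table",
    "write_spike_table",
    "load_tracking_table",
    "load_imagej_tracking_table",
    "load_config",
]

#: Allowed experimental condition labels for a session.
Condition = ("baseline", "treatment", "washout", "none")

# Tolerance for the firing_rate-vs-train consistency invariant.
_RATE_ATOL = 1e-9


class ValidationError(ValueError):
    """A domain invariant was violated."""


class ParseError(ValueError):
    """A table row could not be parsed; the message names the line."""


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one sorted unit over the window ``[t_start, t_stop)``.

    Parameters
    ----------
    unit_id
        Identifier of the sorted unit.
    spike_times
        Strictly increasing spike times in seconds; all within the window.
    t_start, t_stop
        Recording window in seconds, ``t_stop > t_start``.
    """

    unit_id: str
    spike_times: np.ndarray
    t_start: float = 0.0
    t_stop: float = 300.0

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.t_stop <= self.t_start:
            raise ValidationError(
                f"unit {self.unit_id!r}: t_stop ({self.t_stop}) must exceed "
                f"t_start ({self.t_start})"
            )
        if times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id!r}: spike_times must be 1-D")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValidationError(
                    f"unit {self.unit_id!r}: spike times must be strictly increasing"
                )
            if times[0] < self.t_start or times[-1] >= self.t_stop:
                raise ValidationError(
                    f"unit {self.unit_id!r}: spike times outside "
                    f"[{self.t_start}, {self.t_stop})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (not first-to-last spike span)."""
        return self.t_stop - self.t_start

    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds (length ``n_spikes - 1``)."""
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class UnitRecord:
    """A spike train plus sorter-derived quality attributes.

    QC fields may be left unset (``None``); only curation requires them.
    When both a train and a ``firing_rate`` are present they must agree to
    within 1e-9 (count / window duration).
    """

    train: SpikeTrain
    isi_violation_rate: float | None = None
    snr: float | None = None
    firing_rate: float | None = None
    electrode_index: int | None = None
    amplitude_uv: float | None = None

    def __post_init__(self) -> None:
        if self.isi_violation_rate is not None and not (
            0.0 <= self.isi_violation_rate <= 1.0
        ):
            raise ValidationError(
                f"unit {self.unit_id!r}: isi_violation_rate must be in [0, 1]"
            )
        if self.snr is not None and self.snr < 0:
            raise ValidationError(f"unit {self.unit_id!r}: snr must be >= 0")
        if self.firing_rate is not None:
            if self.firing_rate < 0:
                raise ValidationError(
                    f"unit {self.unit_id!r}: firing_rate must be >= 0"
                )
            expected = self.train.n_spikes / self.train.duration
            if not math.isclose(
                self.firing_rate, expected, rel_tol=0.0, abs_tol=_RATE_ATOL
            ):
                raise ValidationError(
                    f"unit {self.unit_id!r}: firing_rate {self.firing_rate} "
                    f"inconsistent with train ({expected})"
                )

    @property
    def unit_id(self) -> str:
        return self.train.unit_id

    def with_computed_rate(self) -> "UnitRecord":
        """Return a copy whose ``firing_rate`` is computed from the train."""
        rate = self.train.n_spikes / self.train.duration
        return replace(self, firing_rate=rate)


@dataclass(frozen=True)
class RecordingSession:
    """Units recorded simultaneously in one network assay.

    All trains share the window ``[0, duration)``; unit ids are unique.
    """

    session_id: str
    units: tuple[UnitRecord, ...]
    duration: float
    dpi: int = 0
    condition: str = "none"
    drug: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        if self.duration <= 0:
            raise ValidationError("session duration must be positive")
        if self.dpi < 0:
            raise ValidationError("dpi must be >= 0")
        if self.condition not in Condition:
            raise ValidationError(
                f"condition must be one of {Condition}, got {self.condition!r}"
            )
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValidationError("unit ids must be unique within a session")
        for u in self.units:
            if u.train.t_start != 0.0 or u.train.t_stop != self.duration:
                raise ValidationError(
                    f"unit {u.unit_id!r}: train window must be [0, {self.duration})"
                )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> UnitRecord:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


@dataclass(frozen=True)
class Trajectory:
    """One tracked soma's (dpi, x, y) position sequence, coordinates in μm."""

    neuron_id: str
    samples: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        samples = tuple(
            (int(d), float(x), float(y)) for d, x, y in self.samples
        )
        object.__setattr__(self, "samples", samples)
        if not samples:
            raise ValidationError(
                f"trajectory {self.neuron_id!r}: at least one sample required"
            )
        dpis = [s[0] for s in samples]
        if any(b <= a for a, b in zip(dpis, dpis[1:])):
            raise ValidationError(
                f"trajectory {self.neuron_id!r}: dpi must be strictly increasing"
            )

    @property
    def dpis(self) -> list[int]:
        return [s[0] for s in self.samples]

    def positions(self) -> np.ndarray:
        """(n, 2) array of x, y coordinates in μm."""
        return np.array([[s[1], s[2]] for s in self.samples], dtype=float)


# ---------------------------------------------------------------------------
# Spike-table I/O
# ---------------------------------------------------------------------------

_SPIKE_COLUMNS = ["unit_id", "time_s"]
_QC_COLUMNS = ["isi_violation_rate", "snr", "firing_rate", "electrode_index"]
_AMP_COLUMN = "amplitude_uv"


def load_spike_table(
    path: str | Path,
    duration: float,
    *,
    session_id: str | None = None,
    dpi: int = 0,
    condition: str = "none",
) -> RecordingSession:
    """Read a spike-time CSV into a validated :class:`RecordingSession`.

    The file must carry columns ``unit_id`` and ``time_s``; QC columns
    (``isi_violation_rate``, ``snr``, ``firing_rate``, ``electrode_index``,
    ``amplitude_uv``) are optional and constant per unit.  Times are sorted
    ascending per unit on load.  A time outside ``[0, duration)`` raises a
    validation error; a malformed row raises a parse error naming the line.
    """
    path = Path(path)
    if duration <= 0:
        raise ValidationError("duration must be positive")
    try:
        df = pd.read_csv(path, dtype={"unit_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (no header)") from exc
    missing = [c for c in _SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")

    times_raw = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.flatnonzero(times_raw.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering
        raise ParseError(f"{path}: malformed time_s on line {bad[0] + 2}")
    df = df.assign(time_s=times_raw)
    out_of_range = df[(df["time_s"] < 0) | (df["time_s"] >= duration)]
    if not out_of_range.empty:
        t = float(out_of_range["time_s"].iloc[0])
        raise ValidationError(
            f"{path}: spike time {t} outside [0, {duration})"
        )

    units: list[UnitRecord] = []
    for unit_id, group in df.groupby("unit_id", sort=False):
        times = np.sort(group["time_s"].to_numpy(dtype=float))
        train = SpikeTrain(str(unit_id), times, 0.0, float(duration))
        kwargs: dict = {}
        for col in _QC_COLUMNS + [_AMP_COLUMN]:
            if col in group.columns:
                val = group[col].iloc[0]
                if pd.notna(val):
                    kwargs[col] = int(val) if col == "electrode_index" else float(val)
        units.append(UnitRecord(train, **kwargs))
    return RecordingSession(
        session_id=session_id or path.stem,
        units=tuple(units),
        duration=float(duration),
        dpi=dpi,
        condition=condition,
    )


def write_spike_table(session: RecordingSession, path: str | Path) -> Path:
    """Write a session to CSV (rows grouped by unit, times ascending).

    Column order is deterministic; times are printed with 9 decimal places so
    a write → load round trip is exact at double precision of the data the
    generators produce.  QC columns are emitted only if any unit sets them.
    """
    path = Path(path)
    opt_cols = [
        c
        for c in _QC_COLUMNS + [_AMP_COLUMN]
        if any(getattr(u, c if c != "electrode_index" else "electrode_index") is not None
               for u in session.units)
    ]
    rows = []
    for u in session.units:
        extras = {c: getattr(u, c) for c in opt_cols}
        for t in u.train.spike_times:
            rows.append({"unit_id": u.unit_id, "time_s": f"{t:.9f}", **extras})
    df = pd.DataFrame(rows, columns=_SPIKE_COLUMNS + opt_cols)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Tracking-table I/O
# ---------------------------------------------------------------------------


def _trajectories_from_frame(
    df: pd.DataFrame, *, pixel_size_um: float, path: Path
) -> list[Trajectory]:
    df = df.copy()
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric {col} coordinate on line {bad[0] + 2}"
            )
        df[col] = vals * pixel_size_um
    dup = df.duplicated(subset=["track_id", "dpi"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (track {row['track_id']}, dpi {row['dpi']}) row"
        )
    out = []
    for track_id, group in df.groupby("track_id", sort=False):
        group = group.sort_values("dpi")
        samples = tuple(
            (int(r.dpi), float(r.x), float(r.y)) for r in group.itertuples()
        )
        out.append(Trajectory(str(track_id), samples))
    return out


def load_tracking_table(
    path: str | Path, *, pixel_size_um: float = 1.0
) -> list[Trajectory]:
    """Read a ``track_id,dpi,x_um,y_um`` CSV into trajectories.

    ``pixel_size_um`` rescales coordinates when the file stores pixels rather
    than μm (the default 1.0 means the file is already in μm).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"track_id": str})
    missing = [c for c in ("track_id", "dpi", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns={"x_um": "x", "y_um": "y"})
    return _trajectories_from_frame(df, pixel_size_um=pixel_size_um, path=path)


def load_imagej_tracking_table(
    path: str | Path,
    slice_to_dpi: dict[int, int],
    *,
    pixel_size_um: float = 1.0,
) -> list[Trajectory]:
    """Read an ImageJ Manual Tracking export (``Track n°, Slice n°, X, Y``).

    ``slice_to_dpi`` maps the image-stack slice number of each time point to
    the culture age in dpi; ``pixel_size_um`` converts pixel coordinates to μm.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}

    def _find(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise ParseError(f"{path}: missing required column (one of {names})")

    track = _find("Track n°", "Track n°", "Track")
    slc = _find("Slice n°", "Slice n°", "Slice")
    x = _find("X")
    y = _find("Y")
    out = pd.DataFrame(
        {
            "track_id": df[track].astype(str),
            "dpi": df[slc].map(lambda s: slice_to_dpi[int(s)]),
            "x": df[x],
            "y": df[y],
        }
    )
    return _trajectories_from_frame(out, pixel_size_um=pixel_size_um, path=path)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
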