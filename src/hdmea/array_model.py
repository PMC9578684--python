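"""HD-MEA geometry, active-electrode criteria and activity maps.

Models a high-density CMOS micro-electrode array as a rectangular grid
(default 120 rows x 220 columns at 17.5 μm pitch, i.e. 26,400 electrodes
covering a 3.85 x 2.10 mm sensor).  Because only ~1,000 electrodes can be
read out simultaneously, a full activity scan records electrode blocks one
after another; the resulting per-electrode firing rates and amplitudes form
an :class:`ActivityMap`, from which active electrodes (> 0.1 Hz and > 20 μV)
are selected and the top 1,024 most active routed to the network assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import RecordingSession
from .metrics import ap_frequency

__all__ = [
    "ElectrodeGrid",
    "ActivityMap",
    "ScanConfig",
    "electrode_position",
    "active_electrode_mask",
    "select_top_k",
    "emulate_full_scan",
    "map_from_session",
]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular electrode grid; 0-based row-major indexing, origin at
    the top-left corner, y increasing downward (image convention)."""

    n_rows: int = 120
    n_cols: int = 220
    pitch: float = 17.5

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def total(self) -> int:
        return self.n_rows * self.n_cols

    def bounding_box_um(self) -> tuple[float, float]:
        """(width, height) in μm, counting one full pitch cell per electrode
        so the default grid reproduces the 3.85 x 2.10 mm sensor area."""
        return self.n_cols * self.pitch, self.n_rows * self.pitch


@dataclass(frozen=True)
class ActivityMap:
    """Per-electrode firing rate (Hz) and mean spike amplitude (μV) for one
    session frame; values are stored unnormalized."""

    grid: ElectrodeGrid
    firing_rate: np.ndarray
    mean_amplitude: np.ndarray
    frame_label: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.firing_rate, dtype=float)
        a = np.asarray(self.mean_amplitude, dtype=float)
        object.__setattr__(self, "firing_rate", r)
        object.__setattr__(self, "mean_amplitude", a)
        if r.size != self.grid.total or a.size != self.grid.total:
            raise ValueError("array lengths must equal the grid's electrode count")
        if np.any(r < 0):
            raise ValueError("firing rates must be >= 0")

    def normalized_rate(self) -> np.ndarray:
        """Min–max normalized rates for rendering this frame; normalization
        is per frame and applied only at export, never stored."""
        lo, hi = self.firing_rate.min(), self.firing_rate.max()
        if hi == lo:
            return np.zeros_like(self.firing_rate)
        return (self.firing_rate - lo) / (hi - lo)


@dataclass(frozen=True)
class ScanConfig:
    """Blockwise full-scan parameters: electrodes per block and dwell time."""

    block_size: int = 1000
    dwell: float = 30.0

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")


def electrode_position(grid: ElectrodeGrid, index: int) -> tuple[float, float]:
    """(x, y) position in μm of an electrode index (row-major, 0-based)."""
    if not 0 <= index < grid.total:
        raise ValueError(f"electrode index {index} outside [0, {grid.total})")
    row, col = divmod(index, grid.n_cols)
    return col * grid.pitch, row * grid.pitch


def active_electrode_mask(
    amap: ActivityMap, min_rate: float = 0.1, min_amp: float = 20.0
) -> np.ndarray:
    """Boolean mask of active electrodes: rate > min_rate AND amplitude >
    min_amp, both strict."""
    return (amap.firing_rate > min_rate) & (amap.mean_amplitude > min_amp)


def select_top_k(
    amap: ActivityMap, mask: np.ndarray | None = None, k: int = 1024
) -> np.ndarray:
    """Indices of up to ``k`` most active electrodes, rate descending.

    Ties break by ascending electrode index.  Fewer than ``k`` indices are
    returned when fewer electrodes are active.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if mask is None:
        mask = active_electrode_mask(amap)
    candidates = np.flatnonzero(mask)
    # stable sort on -rate keeps ascending-index order within ties
    order = np.argsort(-amap.firing_rate[candidates], kind="stable")
    return candidates[order][:k]


def emulate_full_scan(
    grid: ElectrodeGrid, scan: ScanConfig = ScanConfig()
) -> list[tuple[np.ndarray, float, float]]:
    """Partition the grid into scan blocks with recording time offsets.

    Returns ``(indices, t_start, t_stop)`` per block; block *i* records
    during ``[i·dwell, (i+1)·dwell)``.  Blocks cover every electrode exactly
    once; the block count is ``ceil(total / block_size)``.
    """
    n_blocks = math.ceil(grid.total / scan.block_size)
    all_idx = np.arange(grid.total)
    return [
        (
            all_idx[i * scan.block_size : (i + 1) * scan.block_size],
            i * scan.dwell,
            (i + 1) * scan.dwell,
        )
        for i in range(n_blocks)
    ]


def map_from_session(
    session: RecordingSession, grid: ElectrodeGrid = ElectrodeGrid(),
) -> ActivityMap:
    """Accumulate a session's units onto their electrodes.

    Electrode rate is the sum of its units' AP frequencies; amplitude is the
    mean of the units' provided amplitudes (0 where none).  Units without an
    electrode index are ignored; an index outside the grid raises.
    """
    rates = np.zeros(grid.total)
    amp_sum = np.zeros(grid.total)
    amp_n = np.zeros(grid.total, dtype=int)
    for unit in session.units:
        idx = unit.electrode_index
        if idx is None:
            continue
        if not 0 <= idx < grid.total:
            raise ValueError(
                f"unit {unit.unit_id!r}: electrode index {idx} outside grid"
            )
        rates[idx] += ap_frequency(unit.train)
        if unit.amplitude_uv is not None:
            amp_sum[idx] += unit.amplitude_uv
            amp_n[idx] += 1
    amplitude = np.divide(amp_sum, amp_n, out=np.zeros_like(amp_sum), where=amp_n > 0)
    return ActivityMap(
        grid=grid, firing_rate=rates, mean_amplitude=amplitude,
        frame_label=session.dpi,
    )
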