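"""Soma-displacement analytics over tracked positions.

Developing cultures reorganize continuously: initially dispersed somata
migrate, aggregate into clusters, and drag the network's activity footprint
across the sensor.  Given per-soma (dpi, x, y) trajectories exported from
manual tracking, this module computes per-interval displacements, cumulative
displacement in two explicitly-labelled senses — total path length and net
displacement from the first sample — cohort distributions, and the number of
electrode pitches a given mean displacement spans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import Trajectory
from .stats import summarize_mean_sem

__all__ = [
    "DisplacementReport",
    "interval_displacements",
    "cumulative_displacement",
    "displacement_distribution",
    "displacement_in_pitches",
    "cohort_report",
]


@dataclass(frozen=True)
class DisplacementReport:
    """Cohort displacement summary.

    ``interval_mean_sem`` maps each (dpi_from, dpi_to) interval to the mean
    ± SEM of the per-neuron displacement over that interval; the two
    cumulative metrics are reported side by side and labelled unambiguously
    (path length ≥ net displacement for every neuron).
    """

    per_neuron_path_length: dict[str, float]
    per_neuron_net_displacement: dict[str, float]
    interval_mean_sem: dict[tuple[int, int], tuple[float, float]]


def interval_displacements(traj: Trajectory) -> list[tuple[tuple[int, int], float]]:
    """Euclidean distance moved between consecutive samples.

    Returns ``((dpi_from, dpi_to), distance_um)`` per interval; empty for a
    single-sample trajectory.
    """
    pos = traj.positions()
    if len(pos) < 2:
        return []
    dists = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dpis = traj.dpis
    return [
        ((dpis[i], dpis[i + 1]), float(d)) for i, d in enumerate(dists)
    ]


def cumulative_displacement(traj: Trajectory, mode: str = "path_length") -> float:
    """Cumulative movement of one soma, in μm.

    ``mode='path_length'`` sums all interval distances (total distance
    travelled); ``mode='net'`` is the straight-line distance between the
    first and last sample.  Path length ≥ net always.
    """
    if mode not in ("path_length", "net"):
        raise ValueError("mode must be 'path_length' or 'net'")
    pos = traj.positions()
    if len(pos) < 2:
        return 0.0
    if mode == "net":
        return float(np.linalg.norm(pos[-1] - pos[0]))
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def displacement_distribution(
    cohort: Sequence[Trajectory],
    bin_edges: Sequence[float] = (0.0, 50.0, 200.0, np.inf),
    mode: str = "path_length",
) -> np.ndarray:
    """Percentage of neurons per displacement bin (half-open ``[lo, hi)``).

    With an unbounded final bin the percentages sum to 100.
    """
    if not cohort:
        raise ValueError("empty cohort")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, >= 2 of them")
    values = np.array([cumulative_displacement(t, mode) for t in cohort])
    counts = np.zeros(edges.size - 1, dtype=float)
    for v in values:
        idx = np.searchsorted(edges, v, side="right") - 1
        if 0 <= idx < counts.size:
            counts[idx] += 1
    return 100.0 * counts / len(cohort)


def displacement_in_pitches(mean_displacement: float, pitch: float) -> int:
    """Whole number of electrode pitches a mean displacement spans."""
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    return int(math.floor(mean_displacement / pitch))


def cohort_report(cohort: Sequence[Trajectory]) -> DisplacementReport:
    """Per-neuron cumulative metrics and per-interval cohort mean ± SEM."""
    if not cohort:
        raise ValueError("empty cohort")
    path = {t.neuron_id: cumulative_displacement(t, "path_length") for t in cohort}
    net = {t.neuron_id: cumulative_displacement(t, "net") for t in cohort}
    by_interval: dict[tuple[int, int], list[float]] = {}
    for t in cohort:
        for interval, dist in interval_displacements(t):
            by_interval.setdefault(interval, []).append(dist)
    interval_stats = {
        k: summarize_mean_sem(v) for k, v in sorted(by_interval.items())
    }
    return DisplacementReport(
        per_neuron_path_length=path,
        per_neuron_net_displacement=net,
        interval_mean_sem=interval_stats,
    )
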