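"""Firing-rate analytics: AP frequency, instantaneous frequency, and
fast-spiking classification.

AP frequency is the plain rate: spike count divided by recording duration.
Instantaneous firing frequency resolves the temporal structure the mean
hides: each interspike interval yields one *event* whose frequency is the
inverse ISI, timestamped at the second (closing) spike of the pair.  Units
whose instantaneous-frequency events exceed 150 Hz for at least 5% of events
are classified fast-spiking, the signature of putative inhibitory
interneurons; both cut-offs are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curation import classify_active_units
from .data_model import RecordingSession, SpikeTrain
from .stats import summarize_mean_sem

__all__ = [
    "InstFreqSeries",
    "FastSpikingConfig",
    "ap_frequency",
    "frequency_domain_histogram",
    "DEFAULT_FREQ_EDGES",
    "instantaneous_frequencies",
    "fast_event_fraction",
    "classify_fast_units",
    "mean_instantaneous_frequency",
]

#: Default frequency-domain bin edges (Hz) for per-unit rate histograms.
DEFAULT_FREQ_EDGES = (0.0, 1.0, 2.0, 5.0, 10.0, np.inf)


@dataclass(frozen=True)
class InstFreqSeries:
    """Instantaneous-frequency events of one unit.

    ``event_times[i]`` is the time of the second spike of ISI pair *i* and
    ``event_freqs[i] = 1 / ISI_i``.  There are ``n_spikes - 1`` events.
    """

    unit_id: str
    event_times: np.ndarray
    event_freqs: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        f = np.asarray(self.event_freqs, dtype=float)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "event_freqs", f)
        if t.size != f.size:
            raise ValueError("event_times and event_freqs must have equal length")
        if f.size and np.any(f <= 0):
            raise ValueError("event frequencies must be positive")

    @property
    def n_events(self) -> int:
        return int(self.event_freqs.size)


@dataclass(frozen=True)
class FastSpikingConfig:
    """Thresholds for the fast/slow instantaneous-frequency split.

    ``fast_threshold`` (strict, default 150 Hz) separates fast from slow
    events; ``upper_bound`` (default 600 Hz) flags implausibly fast events;
    a unit is fast-spiking when at least ``neuron_fast_event_fraction``
    (inclusive, default 5%) of its events are fast.
    """

    fast_threshold: float = 150.0
    upper_bound: float = 600.0
    neuron_fast_event_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fast_threshold < self.upper_bound:
            raise ValueError("require 0 < fast_threshold < upper_bound")
        if not 0.0 <= self.neuron_fast_event_fraction <= 1.0:
            raise ValueError("neuron_fast_event_fraction must be in [0, 1]")


def ap_frequency(train: SpikeTrain) -> float:
    """Mean firing rate: spike count / recording duration (Hz)."""
    return train.n_spikes / train.duration


def frequency_domain_histogram(
    session: RecordingSession,
    bin_edges=DEFAULT_FREQ_EDGES,
    *,
    min_active_rate: float = 0.1,
) -> np.ndarray:
    """Count active units per AP-frequency bin.

    Bins are half-open ``[lo, hi)``; a unit exactly at an edge falls in the
    higher bin.  Only active units (rate > ``min_active_rate``) are counted,
    so the counts sum to the number of active units when the edges cover
    ``(min_active_rate, inf)``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("at least two bin edges required")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    active, _ = classify_active_units(session, min_active_rate)
    active = set(active)
    rates = [
        ap_frequency(u.train) for u in session.units if u.unit_id in active
    ]
    counts = np.zeros(edges.size - 1, dtype=int)
    for r in rates:
        idx = np.searchsorted(edges, r, side="right") - 1
        if 0 <= idx < counts.size:
            counts[idx] += 1
    return counts


def instantaneous_frequencies(train: SpikeTrain) -> InstFreqSeries:
    """Inverse-ISI event series of a train; empty when fewer than 2 spikes."""
    isis = train.isis()
    if isis.size and np.any(isis <= 0):
        raise ValueError(
            f"unit {train.unit_id!r}: duplicate timestamps give zero ISI"
        )
    return InstFreqSeries(
        unit_id=train.unit_id,
        event_times=train.spike_times[1:].copy(),
        event_freqs=1.0 / isis if isis.size else np.array([]),
    )


def fast_event_fraction(
    series: InstFreqSeries, cfg: FastSpikingConfig = FastSpikingConfig()
) -> tuple[float, dict]:
    """Fraction of events strictly above the fast threshold, with flags.

    Events above ``cfg.upper_bound`` still count as fast but are reported in
    the flags (``n_above_upper_bound``); an empty series yields fraction 0
    with ``no_events=True``.
    """
    flags = {"no_events": series.n_events == 0, "n_above_upper_bound": 0}
    if series.n_events == 0:
        return 0.0, flags
    fast = series.event_freqs > cfg.fast_threshold
    flags["n_above_upper_bound"] = int(
        np.count_nonzero(series.event_freqs > cfg.upper_bound)
    )
    return float(np.count_nonzero(fast) / series.n_events), flags


def classify_fast_units(
    session: RecordingSession, cfg: FastSpikingConfig = FastSpikingConfig()
) -> tuple[list[str], list[str]]:
    """Partition unit ids into (fast, slow) spikers.

    A unit is fast iff at least ``cfg.neuron_fast_event_fraction`` of its
    instantaneous-frequency events exceed ``cfg.fast_threshold`` (the "at
    least" is inclusive).  Units with no events are slow.
    """
    fast, slow = [], []
    for unit in session.units:
        series = instantaneous_frequencies(unit.train)
        frac, _ = fast_event_fraction(series, cfg)
        if series.n_events and frac >= cfg.neuron_fast_event_fraction:
            fast.append(unit.unit_id)
        else:
            slow.append(unit.unit_id)
    return fast, slow


def mean_instantaneous_frequency(
    session: RecordingSession, *, pooled: bool = False
) -> tuple[dict[str, float], float, float]:
    """Per-unit mean instantaneous frequency and the session aggregate.

    Returns ``(per_unit, session_mean, session_sem)``.  The aggregate is by
    default the mean over units of the per-unit means (each neuron weighted
    equally); with ``pooled=True`` it is the mean over all events pooled
    across units.  Units with fewer than two spikes are excluded; an error
    is raised when no unit is eligible.
    """
    per_unit: dict[str, float] = {}
    all_events: list[np.ndarray] = []
    for unit in session.units:
        series = instantaneous_frequencies(unit.train)
        if series.n_events:
            per_unit[unit.unit_id] = float(series.event_freqs.mean())
            all_events.append(series.event_freqs)
    if not per_unit:
        raise ValueError("no unit with >= 2 spikes; mean frequency undefined")
    if pooled:
        pooled_events = np.concatenate(all_events)
        mean, sem = summarize_mean_sem(pooled_events)
    else:
        mean, sem = summarize_mean_sem(np.array(list(per_unit.values())))
    return per_unit, mean, sem
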