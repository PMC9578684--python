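"""Poisson-surprise burst detection and network-burst analysis.

A burst is a contiguous run of spikes whose density is improbably high under
the unit's own mean firing rate.  For a window of length ``T`` seconds
containing ``N`` spikes from a unit with mean rate ``λ``, the Poisson
surprise is

    S = −log P,    P = Σ_{n≥N} e^{−λT} (λT)^n / n!

i.e. minus the log upper-tail probability of seeing ``N`` or more spikes in
``T`` under a homogeneous Poisson process at rate ``λ``.  Detection follows
the classic surprise-maximization protocol: a candidate burst is seeded
where three consecutive spikes have both ISIs below half the train's mean
ISI, extended while the next ISI stays at or below the mean ISI, the
extension length maximizing S is selected, and the burst is emitted when it
passes the minimum-surprise, minimum-duration and minimum-spike-count
thresholds (defaults 4, 20 ms, 4 spikes).  Scanning then resumes after the
emitted burst, so bursts are disjoint and time-ordered.

Network bursts are epochs where single-unit bursts co-occur across a
sufficient number of active units, found by binning time and merging
adjacent qualifying bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .curation import classify_active_units
from .data_model import RecordingSession, SpikeTrain

__all__ = [
    "SurpriseParams",
    "Burst",
    "BurstSummary",
    "NetworkBurst",
    "NetworkBurstConfig",
    "poisson_surprise",
    "detect_bursts",
    "detect_session_bursts",
    "burst_summary",
    "detect_network_bursts",
    "units_in_network_bursts",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SurpriseParams:
    """Parameters of the surprise-maximization burst detector.

    ``seed_isi_factor`` and ``extension_isi_factor`` are fractions of the
    train's global mean ISI: a candidate is seeded where both ISIs of a
    spike triplet fall strictly below ``seed_isi_factor x mean ISI`` and
    extended while the next ISI is at most ``extension_isi_factor x mean
    ISI``.  ``trim_start`` enables an optional backward refinement that
    drops leading spikes when doing so raises the surprise.
    """

    min_surprise: float = 4.0
    min_duration: float = 0.020
    min_spikes: int = 4
    seed_isi_factor: float = 0.5
    extension_isi_factor: float = 1.0
    log_base: str = "natural"
    trim_start: bool = False

    def __post_init__(self) -> None:
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if self.seed_isi_factor <= 0 or self.extension_isi_factor <= 0:
            raise ValueError("ISI factors must be positive")
        if self.log_base not in ("natural", "base10"):
            raise ValueError("log_base must be 'natural' or 'base10'")
        if self.min_surprise < 0 or self.min_duration < 0:
            raise ValueError("min_surprise and min_duration must be >= 0")


@dataclass(frozen=True)
class Burst:
    """A detected burst: spikes ``t_start`` through ``t_end`` inclusive."""

    unit_id: str
    t_start: float
    t_end: float
    n_spikes: int
    surprise: float

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def overlaps(self, lo: float, hi: float) -> bool:
        """True if the burst span intersects the closed interval [lo, hi]."""
        return self.t_start <= hi and self.t_end >= lo


@dataclass(frozen=True)
class BurstSummary:
    """Per-unit burst features over one recording.

    ``mean_burst_duration`` is ``None`` when the unit had no bursts.
    """

    unit_id: str
    burst_frequency: float
    mean_burst_duration: float | None
    pct_aps_in_burst: float
    n_bursts: int


@dataclass(frozen=True)
class NetworkBurst:
    """A network-burst interval and the units whose bursts overlap it."""

    t_start: float
    t_end: float
    members: tuple[str, ...]


@dataclass(frozen=True)
class NetworkBurstConfig:
    """Binned-coincidence criterion for network bursts.

    A time bin of width ``bin_width`` qualifies when at least
    ``max(min_units_absolute, ceil(min_unit_fraction x active units))``
    units have an ongoing single-unit burst in it; adjacent qualifying bins
    merge into one network-burst interval.
    """

    bin_width: float = 0.1
    min_unit_fraction: float = 0.2
    min_units_absolute: int = 5

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not 0.0 < self.min_unit_fraction <= 1.0:
            raise ValueError("min_unit_fraction must be in (0, 1]")


def poisson_surprise(
    n_spikes: int, window: float, rate: float, log_base: str = "natural"
) -> float:
    """Poisson surprise S = −log P(X ≥ N) for X ~ Poisson(rate x window).

    Computed through the numerically stable log-survival function of the
    Poisson distribution (regularized incomplete gamma), so S is accurate
    even when P underflows double precision.  S = 0 when ``n_spikes`` is 0
    (the tail is the whole distribution).
    """
    if rate <= 0 or window <= 0:
        raise ValueError("surprise undefined for non-positive rate or window")
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    if n_spikes == 0:
        return 0.0
    mu = rate * window
    # P(X >= N) = sf(N - 1).  When the lower tail is small, P is close to 1
    # and log(sf) would lose relative precision in S; -log1p(-cdf) keeps it.
    lower = sps.poisson.cdf(n_spikes - 1, mu)
    if lower < 0.5:
        s = -math.log1p(-lower)
    else:
        s = -sps.poisson.logsf(n_spikes - 1, mu)
    if log_base == "base10":
        s /= _LN10
    return float(max(s, 0.0))


def detect_bursts(
    train: SpikeTrain, params: SurpriseParams = SurpriseParams()
) -> list[Burst]:
    """Detect bursts in one train by surprise maximization.

    The unit's rate λ is its whole-train mean (count / recording duration)
    and the mean ISI is computed once globally; both stay fixed during
    scanning.  The surprise window T is the span from the first to the last
    spike of the candidate.  On equal maximal surprise the shortest
    extension wins.  A seeded candidate that fails the emission thresholds
    does not advance the scan past its seed: scanning resumes at the next
    spike after the seed's first spike.
    """
    times = train.spike_times
    n = times.size
    if n < params.min_spikes:
        return []
    rate = n / train.duration
    isis = np.diff(times)
    mean_isi = float(isis.mean())
    seed_th = params.seed_isi_factor * mean_isi
    ext_th = params.extension_isi_factor * mean_isi

    bursts: list[Burst] = []
    i = 0
    while i <= n - 3:
        if not (isis[i] < seed_th and isis[i + 1] < seed_th):
            i += 1
            continue
        # Extension limit: keep appending spikes while the next ISI <= ext_th.
        j_max = i + 2
        while j_max < n - 1 and isis[j_max] <= ext_th:
            j_max += 1
        best_j, best_s = -1, -math.inf
        ends = np.arange(i + params.min_spikes - 1, j_max + 1)
        if ends.size:
            counts = ends - i + 1
            spans = times[ends] - times[i]
            s_vals = np.maximum(-sps.poisson.logsf(counts - 1, rate * spans), 0.0)
            if params.log_base == "base10":
                s_vals /= _LN10
            k = int(np.argmax(s_vals))  # first max: shortest extension wins ties
            best_j, best_s = int(ends[k]), float(s_vals[k])
        start = i
        if best_j >= 0 and params.trim_start:
            start, best_s = _trim_start(times, start, best_j, rate, params, best_s)
        if (
            best_j >= 0
            and best_s >= params.min_surprise
            and times[best_j] - times[start] >= params.min_duration
        ):
            bursts.append(
                Burst(
                    unit_id=train.unit_id,
                    t_start=float(times[start]),
                    t_end=float(times[best_j]),
                    n_spikes=best_j - start + 1,
                    surprise=best_s,
                )
            )
            i = best_j + 1
        else:
            i += 1
    return bursts


def _trim_start(
    times: np.ndarray,
    start: int,
    end: int,
    rate: float,
    params: SurpriseParams,
    current_s: float,
) -> tuple[int, float]:
    """Drop leading spikes while that strictly increases the surprise."""
    while end - start >= params.min_spikes:  # candidate after dropping one
        s = poisson_surprise(
            end - start, times[end] - times[start + 1], rate, params.log_base
        )
        if s > current_s:
            start += 1
            current_s = s
        else:
            break
    return start, current_s


def detect_session_bursts(
    session: RecordingSession, params: SurpriseParams = SurpriseParams()
) -> dict[str, list[Burst]]:
    """Run burst detection on every unit of a session."""
    return {u.unit_id: detect_bursts(u.train, params) for u in session.units}


def burst_summary(train: SpikeTrain, bursts: Sequence[Burst]) -> BurstSummary:
    """Burst frequency, mean duration, and percentage of spikes in bursts."""
    duration = train.duration
    n_bursts = len(bursts)
    if n_bursts:
        in_burst = 0
        for b in bursts:
            in_burst += int(
                np.count_nonzero(
                    (train.spike_times >= b.t_start) & (train.spike_times <= b.t_end)
                )
            )
        pct = 100.0 * in_burst / train.n_spikes if train.n_spikes else 0.0
        mean_dur = float(np.mean([b.duration for b in bursts]))
    else:
        pct = 0.0
        mean_dur = None
    return BurstSummary(
        unit_id=train.unit_id,
        burst_frequency=n_bursts / duration,
        mean_burst_duration=mean_dur,
        pct_aps_in_burst=pct,
        n_bursts=n_bursts,
    )


def detect_network_bursts(
    session: RecordingSession,
    unit_bursts: Mapping[str, Sequence[Burst]],
    cfg: NetworkBurstConfig = NetworkBurstConfig(),
) -> list[NetworkBurst]:
    """Find epochs where enough active units burst simultaneously.

    Time is discretized at ``cfg.bin_width``; a bin qualifies when the
    number of units with an ongoing burst reaches
    ``max(min_units_absolute, ceil(min_unit_fraction x active units))``.
    Adjacent qualifying bins are merged; members of an interval are the
    units with at least one burst overlapping it.
    """
    active, _ = classify_active_units(session)
    threshold = max(
        cfg.min_units_absolute, math.ceil(cfg.min_unit_fraction * len(active))
    )
    n_bins = math.ceil(session.duration / cfg.bin_width)
    counts = np.zeros(n_bins, dtype=int)
    for uid, bursts in unit_bursts.items():
        if not bursts:
            continue
        marked = np.zeros(n_bins, dtype=bool)
        for b in bursts:
            lo = int(b.t_start / cfg.bin_width)
            hi = min(int(b.t_end / cfg.bin_width), n_bins - 1)
            marked[lo : hi + 1] = True
        counts += marked

    qualifying = counts >= threshold
    events: list[NetworkBurst] = []
    k = 0
    while k < n_bins:
        if not qualifying[k]:
            k += 1
            continue
        k0 = k
        while k < n_bins and qualifying[k]:
            k += 1
        lo, hi = k0 * cfg.bin_width, k * cfg.bin_width
        members = tuple(
            sorted(
                uid
                for uid, bursts in unit_bursts.items()
                if any(b.overlaps(lo, hi) for b in bursts)
            )
        )
        events.append(NetworkBurst(t_start=lo, t_end=hi, members=members))
    return events


def units_in_network_bursts(
    session: RecordingSession, network_bursts: Sequence[NetworkBurst]
) -> tuple[int, set[str]]:
    """Units participating in at least one network burst.

    A unit counts when one of its bursts overlaps one network-burst
    interval — exactly the membership recorded on each event.
    """
    members: set[str] = set()
    for nb in network_bursts:
        members.update(nb.members)
    return len(members), members
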