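"""Seeded generators for sessions, pharmacology experiments and trajectories.

These generators emulate the regimes seen in developing neuronal cultures on
high-density micro-electrode arrays: sparse background firing in the first
weeks, single-unit bursts in the second month, and partially synchronized
network-wide bursts later on, plus a fast-spiking subpopulation and migrating
somata that aggregate into clusters.  Every generated object comes with an
explicit ground truth (injected burst intervals, network-event membership,
true rates, fast/slow labels) so each downstream analysis stage can be tested
without recorded data.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning; there is no global RNG state and
identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import RecordingSession, SpikeTrain, UnitRecord

__all__ = [
    "StageParams",
    "GroundTruth",
    "gen_stage_session",
    "gen_pharmacology_experiment",
    "gen_trajectories",
    "STAGE_PRESETS",
]

#: Coincident spikes closer than this are collapsed after burst injection (s).
_DUPLICATE_TOL = 1e-4


@dataclass(frozen=True)
class StageParams:
    """Parameters of one developmental stage of the simulated network.

    The defaults describe a mature third-month culture: ~1 Hz background
    firing, frequent single-unit bursts, and partially synchronized network
    bursts at a combined per-unit burst rate of ~0.23 bursts/s, with a
    fast-spiking subpopulation firing spike doublets at 4 ms intervals.

    Attributes
    ----------
    n_units
        Number of sorted units in the session.
    baseline_rate
        Homogeneous-Poisson background firing rate per unit (Hz).
    burst_rate_per_unit
        Rate of unit-local (asynchronous) injected bursts (bursts/s).
    burst_duration_mean
        Mean injected burst duration (s); durations are gamma-distributed
        (shape 4) about this mean.
    intra_burst_rate
        Mean within-burst firing rate (Hz); within-burst spikes are
        quasi-regular (evenly spaced with small jitter), as in real
        high-rate discharges, rather than Poisson.
    sync_fraction
        Fraction of units participating in each network burst; membership is
        resampled per event.
    network_burst_rate
        Rate of network-wide burst events (events/s).
    jitter_sd
        SD of the Gaussian start-time jitter of each member's burst within a
        network event (s).
    fast_unit_fraction
        Fraction of units labelled fast-spiking; these receive spike
        doublets/triplets at ``fast_isi_ms`` intervals.
    fast_isi_ms
        Interspike interval of injected fast doublets (ms).
    doublet_prob
        Probability that a background spike of a fast unit spawns a doublet
        partner (and, with the same conditional probability, a triplet).
    duration
        Recording duration (s); the study's network assay is 5 min.
    seed
        Base seed for all randomness.
    snr_range
        Range from which per-unit signal-to-noise ratios are drawn uniformly.
    network_refractory
        Minimum quiet gap between consecutive network events (s).  Network
        bursts are discrete all-or-none events followed by quiescence; the
        dead time keeps injected events non-overlapping so each corresponds
        to one observable epoch of synchrony.
    """

    n_units: int = 50
    baseline_rate: float = 1.0
    burst_rate_per_unit: float = 0.1
    burst_duration_mean: float = 0.15
    intra_burst_rate: float = 100.0
    sync_fraction: float = 0.5
    network_burst_rate: float = 0.25
    jitter_sd: float = 0.02
    fast_unit_fraction: float = 0.2
    fast_isi_ms: float = 4.0
    doublet_prob: float = 0.3
    duration: float = 300.0
    seed: int = 0
    snr_range: tuple[float, float] = (6.0, 20.0)
    network_refractory: float = 0.5

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        for name in (
            "baseline_rate",
            "burst_rate_per_unit",
            "burst_duration_mean",
            "intra_burst_rate",
            "network_burst_rate",
            "jitter_sd",
            "fast_isi_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sync_fraction", "fast_unit_fraction", "doublet_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


#: Stage presets sketching the developmental progression (free modelling
#: choices, documented in the methods note): sparse uncorrelated firing in
#: the first month, local bursting in the second, synchronized network
#: bursting with a growing fast-spiking population in the third.
STAGE_PRESETS: dict[str, StageParams] = {
    "sparse": StageParams(
        baseline_rate=0.3,
        burst_rate_per_unit=0.005,
        network_burst_rate=0.0,
        sync_fraction=0.0,
        fast_unit_fraction=0.02,
    ),
    "local_bursting": StageParams(
        baseline_rate=1.0,
        burst_rate_per_unit=0.05,
        burst_duration_mean=0.28,
        network_burst_rate=0.02,
        sync_fraction=0.3,
        fast_unit_fraction=0.05,
    ),
    "synchronized": StageParams(),
}


@dataclass
class GroundTruth:
    """What was injected into a generated session.

    Attributes
    ----------
    unit_bursts
        Per unit id, the injected burst intervals as ``(start, end,
        n_spikes)`` tuples (seconds, absolute).
    network_events
        Injected network bursts as ``(start, end, member_unit_ids)`` where
        the interval covers the union of the members' jittered bursts.
    true_rate
        Per unit id, the realised mean firing rate implied by the injected
        process (background intensity plus injected spikes / duration), Hz.
    fast_units
        Unit ids labelled fast-spiking (doublets injected).
    """

    unit_bursts: dict[str, list[tuple[float, float, int]]]
    network_events: list[tuple[float, float, tuple[str, ...]]]
    true_rate: dict[str, float]
    fast_units: set[str]

    def to_jsonable(self) -> dict:
        return {
            "unit_bursts": {
                k: [list(b) for b in v] for k, v in self.unit_bursts.items()
            },
            "network_events": [
                [s, e, list(members)] for s, e, members in self.network_events
            ],
            "true_rate": self.true_rate,
            "fast_units": sorted(self.fast_units),
        }


def _burst_spikes(
    rng: np.random.Generator, start: float, dur: float, intra_rate: float
) -> np.ndarray:
    """Quasi-regular spike times filling [start, start+dur].

    The count follows the duration deterministically (durations are random
    upstream), so intra-burst ISIs never undercut the nominal rate and
    cannot masquerade as fast-spiking doublets.
    """
    n = max(2, int(round(intra_rate * dur)))
    base = np.linspace(start, start + dur, n)
    # jitter kept well below the nominal ISI so intra-burst intervals stay
    # quasi-regular and never masquerade as fast-spiking doublets
    jitter = rng.normal(0.0, 0.05 / max(intra_rate, 1e-9), size=n)
    times = np.clip(base + jitter, start, start + dur)
    times.sort()
    return times


def _dedupe(times: np.ndarray) -> np.ndarray:
    """Sort and collapse near-coincident spikes (< 0.1 ms apart)."""
    times = np.sort(times)
    if times.size < 2:
        return times
    keep = np.empty(times.size, dtype=bool)
    keep[0] = True
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last >= _DUPLICATE_TOL:
            keep[i] = True
            last = times[i]
        else:
            keep[i] = False
    return times[keep]


def gen_stage_session(
    params: StageParams, *, session_id: str = "synthetic", dpi: int = 0,
    condition: str = "none",
) -> tuple[RecordingSession, GroundTruth]:
    """Generate one session at the given stage, with its ground truth.

    Background spikes are homogeneous Poisson at ``baseline_rate``.  Local
    bursts are injected additively at ``burst_rate_per_unit`` per unit;
    network events at ``network_burst_rate`` place co-occurring bursts in
    ``ceil(sync_fraction * n_units)`` randomly chosen units with Gaussian
    start jitter.  Fast units additionally receive doublet/triplet spikes at
    ``fast_isi_ms`` intervals.  QC attributes: SNR uniform over
    ``snr_range``; ISI-violation rate and firing rate computed from the
    generated train.
    """
    T = params.duration
    ss = np.random.SeedSequence(params.seed)
    unit_seeds, event_seed, qc_seed = ss.spawn(3)
    unit_rngs = [np.random.default_rng(s) for s in unit_seeds.spawn(max(params.n_units, 1))]
    event_rng = np.random.default_rng(event_seed)
    qc_rng = np.random.default_rng(qc_seed)

    unit_ids = [f"u{i:04d}" for i in range(params.n_units)]
    n_fast = int(math.ceil(params.fast_unit_fraction * params.n_units)) if params.fast_unit_fraction else 0
    fast_units = set(
        np.array(unit_ids)[event_rng.choice(params.n_units, size=n_fast, replace=False)]
    ) if n_fast else set()

    unit_bursts: dict[str, list[tuple[float, float, int]]] = {u: [] for u in unit_ids}
    spikes: dict[str, list[np.ndarray]] = {u: [] for u in unit_ids}

    # Background Poisson + unit-local bursts.
    for uid, rng in zip(unit_ids, unit_rngs):
        n_bg = rng.poisson(params.baseline_rate * T)
        spikes[uid].append(rng.uniform(0.0, T, size=n_bg))
        n_local = rng.poisson(params.burst_rate_per_unit * T)
        for _ in range(n_local):
            dur = rng.gamma(4.0, params.burst_duration_mean / 4.0)
            dur = min(dur, T * 0.5)
            # bursts are discrete episodes: redraw starts that would overlap
            # an already-placed burst of this unit
            for _attempt in range(20):
                start = rng.uniform(0.0, max(T - dur, 1e-9))
                if all(
                    start + dur <= s or start >= e
                    for s, e, _ in unit_bursts[uid]
                ):
                    break
            else:
                continue
            st = _burst_spikes(rng, start, dur, params.intra_burst_rate)
            spikes[uid].append(st)
            unit_bursts[uid].append((start, start + dur, int(st.size)))

    # Network events: membership resampled per event.
    network_events: list[tuple[float, float, tuple[str, ...]]] = []
    n_members = int(math.ceil(params.sync_fraction * params.n_units))
    if params.network_burst_rate > 0 and n_members > 0 and params.n_units > 0:
        # Renewal process: exponential gaps at the nominal rate plus a
        # refractory dead time, so events never overlap.
        event_times = []
        t = event_rng.exponential(1.0 / params.network_burst_rate)
        while t < T:
            event_times.append(t)
            t += params.network_refractory + event_rng.exponential(
                1.0 / params.network_burst_rate
            )
        event_times = np.asarray(event_times)
        for t0 in event_times:
            members = event_rng.choice(params.n_units, size=n_members, replace=False)
            lo, hi = np.inf, -np.inf
            member_ids = []
            for idx in members:
                uid = unit_ids[idx]
                rng = unit_rngs[idx]
                dur = rng.gamma(4.0, params.burst_duration_mean / 4.0)
                dur = min(dur, T * 0.5)
                start = t0 + rng.normal(0.0, params.jitter_sd)
                start = float(np.clip(start, 0.0, max(T - dur, 0.0)))
                st = _burst_spikes(rng, start, dur, params.intra_burst_rate)
                st = st[st < T]
                if st.size < 2:
                    continue
                spikes[uid].append(st)
                unit_bursts[uid].append((start, start + dur, int(st.size)))
                member_ids.append(uid)
                lo, hi = min(lo, start), max(hi, start + dur)
            if member_ids:
                network_events.append((lo, hi, tuple(member_ids)))

    # Fast-spiking doublets/triplets on background spikes.
    dt_fast = params.fast_isi_ms / 1000.0
    for uid in fast_units:
        rng = unit_rngs[unit_ids.index(uid)]
        bg = spikes[uid][0]
        pick = bg[rng.random(bg.size) < params.doublet_prob]
        extra = [pick + dt_fast]
        triplet = pick[rng.random(pick.size) < params.doublet_prob]
        extra.append(triplet + 2 * dt_fast)
        spikes[uid].append(np.concatenate(extra))

    # Assemble units.
    units: list[UnitRecord] = []
    true_rate: dict[str, float] = {}
    for uid in unit_ids:
        times = _dedupe(np.concatenate(spikes[uid])) if spikes[uid] else np.array([])
        times = times[(times >= 0.0) & (times < T)]
        train = SpikeTrain(uid, times, 0.0, T)
        n_injected = sum(b[2] for b in unit_bursts[uid])
        true_rate[uid] = params.baseline_rate + n_injected / T
        isis = train.isis()
        viol = float(np.mean(isis < 1.5e-3)) if isis.size else 0.0
        units.append(
            UnitRecord(
                train,
                isi_violation_rate=viol,
                snr=float(qc_rng.uniform(*params.snr_range)),
                firing_rate=train.n_spikes / T,
            )
        )
    # Keep ground-truth interval ends inside the window.
    for uid in unit_ids:
        unit_bursts[uid] = [
            (s, min(e, T), n) for s, e, n in sorted(unit_bursts[uid])
        ]
    session = RecordingSession(
        session_id=session_id, units=tuple(units), duration=T,
        dpi=dpi, condition=condition,
    )
    truth = GroundTruth(
        unit_bursts=unit_bursts,
        network_events=sorted(network_events),
        true_rate=true_rate,
        fast_units=fast_units,
    )
    return session, truth


def gen_pharmacology_experiment(
    base: StageParams,
    effect: dict[str, float],
    seed: int,
    *,
    washout_persistence: float = 0.5,
    drug: str = "drug",
) -> tuple[dict[str, RecordingSession], dict[str, GroundTruth]]:
    """Generate baseline / treatment / washout sessions for a drug scenario.

    ``effect`` maps any of ``rate``, ``burst_rate``, ``burst_duration`` to a
    positive multiplier applied to the treatment session's parameters
    (``burst_rate`` scales both the local and the network burst rates).  The
    washout session applies ``1 + persistence * (multiplier - 1)``, so
    ``washout_persistence=0`` restores baseline parameters and ``1`` keeps
    the full treatment effect.
    """
    unknown = set(effect) - {"rate", "burst_rate", "burst_duration"}
    if unknown:
        raise ValueError(f"unknown effect keys: {sorted(unknown)}")
    if any(m <= 0 for m in effect.values()):
        raise ValueError("effect multipliers must be positive")
    if not 0.0 <= washout_persistence <= 1.0:
        raise ValueError("washout_persistence must be in [0, 1]")

    def _apply(params: StageParams, strength: float, sub_seed: int) -> StageParams:
        def m(key: str) -> float:
            return 1.0 + strength * (effect.get(key, 1.0) - 1.0)

        return replace(
            params,
            baseline_rate=params.baseline_rate * m("rate"),
            burst_rate_per_unit=params.burst_rate_per_unit * m("burst_rate"),
            network_burst_rate=params.network_burst_rate * m("burst_rate"),
            burst_duration_mean=params.burst_duration_mean * m("burst_duration"),
            seed=sub_seed,
        )

    child = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint32)
    strengths = {"baseline": 0.0, "treatment": 1.0, "washout": washout_persistence}
    sessions: dict[str, RecordingSession] = {}
    truths: dict[str, GroundTruth] = {}
    for i, (cond, strength) in enumerate(strengths.items()):
        p = _apply(base, strength, int(child[i] % (2**31)))
        sess, truth = gen_stage_session(
            p, session_id=f"{drug}-{cond}", condition=cond,
        )
        sessions[cond] = replace(sess, drug=drug)
        truths[cond] = truth
    return sessions, truths


def gen_trajectories(
    n_neurons: int,
    n_timepoints: int,
    step_scale: float = 15.0,
    n_attractors: int = 12,
    attraction_gain: float = 0.2,
    seed: int = 0,
    *,
    arena_um: tuple[float, float] = (3850.0, 2100.0),
    start_dpi: int = 22,
    dpi_step: int = 7,
    return_attractors: bool = False,
):
    """Generate soma trajectories: random walks drifting toward attractors.

    Each neuron starts uniformly in the arena (default: the sensor area of a
    120 x 220 electrode grid at 17.5 μm pitch) and at each weekly time point
    takes an isotropic Gaussian step of scale ``step_scale`` μm plus a drift
    of ``attraction_gain`` times the vector to its nearest attractor — the
    mechanism by which initially dispersed somata aggregate into clusters.
    With ``attraction_gain`` approaching 1 positions converge onto the
    attractors within a few steps.  With ``return_attractors=True`` the
    attractor coordinates are returned alongside the trajectories as ground
    truth.
    """
    from .data_model import Trajectory

    if n_neurons < 1 or n_timepoints < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = arena_um
    pos = rng.uniform([0, 0], [w, h], size=(n_neurons, 2))
    attractors = rng.uniform([0, 0], [w, h], size=(max(n_attractors, 1), 2))
    dpis = [start_dpi + dpi_step * k for k in range(n_timepoints)]
    history = [pos.copy()]
    for _ in range(n_timepoints - 1):
        d = attractors[None, :, :] - pos[:, None, :]
        nearest = np.argmin(np.einsum("ijk,ijk->ij", d, d), axis=1)
        drift = attraction_gain * (attractors[nearest] - pos)
        pos = pos + drift + step_scale * rng.standard_normal((n_neurons, 2))
        np.clip(pos, [0, 0], [w, h], out=pos)
        history.append(pos.copy())
    stacked = np.stack(history)  # (n_timepoints, n_neurons, 2)
    trajs = [
        Trajectory(
            f"n{i:04d}",
            tuple(
                (dpis[k], float(stacked[k, i, 0]), float(stacked[k, i, 1]))
                for k in range(n_timepoints)
            ),
        )
        for i in range(n_neurons)
    ]
    if return_attractors:
        return trajs, attractors
    return trajs
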