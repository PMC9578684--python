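"""Automated post-sorting unit curation and the active-unit rule.

A sorted unit is removed when it fails any one of three quality rules:
ISI-violation rate above 0.2, signal-to-noise ratio smaller than 5, or
firing rate below 0.1 Hz.  The boundary semantics follow those words
exactly: "above" and "below"/"smaller than" are strict, so a unit sitting
exactly on a threshold is kept.  Separately, a unit counts as *active* when
its firing rate strictly exceeds 0.1 Hz.

The ISI-violation rate is defined here as the fraction of interspike
intervals shorter than a refractory period (default 1.5 ms); the threshold
value 0.2 reads naturally as a fraction, and no rate-corrected estimator is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import RecordingSession, SpikeTrain, UnitRecord

__all__ = [
    "CurationThresholds",
    "isi_violation_rate",
    "curate_units",
    "classify_active_units",
]


@dataclass(frozen=True)
class CurationThresholds:
    """Quality thresholds for automated unit removal.

    ``refractory_ms`` is used to compute the ISI-violation rate for units
    that did not carry one from the sorter.
    """

    max_isi_violation: float = 0.2
    min_snr: float = 5.0
    min_rate: float = 0.1
    refractory_ms: float = 1.5

    def __post_init__(self) -> None:
        for name in ("max_isi_violation", "min_snr", "min_rate", "refractory_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def isi_violation_rate(train: SpikeTrain, refractory_ms: float = 1.5) -> float:
    """Fraction of ISIs shorter than the refractory period.

    Returns 0 for trains with fewer than two spikes (no ISIs).
    """
    if refractory_ms < 0:
        raise ValueError("refractory_ms must be >= 0")
    isis = train.isis()
    if isis.size == 0:
        return 0.0
    return float(np.count_nonzero(isis < refractory_ms / 1000.0) / isis.size)


def _qc_triplet(unit: UnitRecord, th: CurationThresholds) -> tuple[float, float, float]:
    """The three curation quantities, computing from the train where possible."""
    viol = unit.isi_violation_rate
    if viol is None:
        viol = isi_violation_rate(unit.train, th.refractory_ms)
    rate = unit.firing_rate
    if rate is None:
        rate = unit.train.n_spikes / unit.train.duration
    if unit.snr is None:
        raise ValueError(
            f"unit {unit.unit_id!r}: SNR missing and cannot be derived from "
            "spike times; supply an 'snr' QC column from the sorter"
        )
    return viol, unit.snr, rate


def curate_units(
    session: RecordingSession, th: CurationThresholds = CurationThresholds()
) -> tuple[RecordingSession, list[dict]]:
    """Remove units failing any quality rule; report why each was removed.

    A unit is removed iff its ISI-violation rate is strictly above
    ``max_isi_violation``, OR its SNR is strictly below ``min_snr``, OR its
    firing rate is strictly below ``min_rate``.  The report lists every
    removed unit with all triggering rules (a unit may fail several).
    Curation is idempotent: re-curating the kept session removes nothing.
    """
    kept: list[UnitRecord] = []
    report: list[dict] = []
    for unit in session.units:
        viol, snr, rate = _qc_triplet(unit, th)
        rules = []
        if viol > th.max_isi_violation:
            rules.append("isi_violation")
        if snr < th.min_snr:
            rules.append("snr")
        if rate < th.min_rate:
            rules.append("firing_rate")
        if rules:
            report.append(
                {
                    "unit_id": unit.unit_id,
                    "rules": rules,
                    "isi_violation_rate": viol,
                    "snr": snr,
                    "firing_rate": rate,
                }
            )
        else:
            kept.append(unit)
    return replace(session, units=tuple(kept)), report


def classify_active_units(
    session: RecordingSession, min_rate: float = 0.1
) -> tuple[list[str], list[str]]:
    """Partition unit ids into (active, inactive) by firing rate.

    A unit is active iff its firing rate strictly exceeds ``min_rate``
    (default 0.1 Hz); a unit exactly at the threshold is inactive.
    """
    active, inactive = [], []
    for unit in session.units:
        rate = unit.firing_rate
        if rate is None:
            rate = unit.train.n_spikes / unit.train.duration
        (active if rate > min_rate else inactive).append(unit.unit_id)
    return active, inactive
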