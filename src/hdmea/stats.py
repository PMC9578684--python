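"""Nonparametric comparison of activity features across conditions or days.

Measurements are grouped with one value per neuron (the neuron is the
statistical unit of analysis, and groups are treated as independent).  The
omnibus test is Kruskal–Wallis with tie correction; significant omnibus
results are followed by Dunn's multiple-comparison test, whose pairwise z
statistics use mean-rank differences with a tie-corrected pooled variance,
adjusted by Bonferroni (default) or Holm over all pairs.  Summaries are
mean ± standard error of the mean; significance is declared at α = 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedMeasurements",
    "PairwiseResult",
    "StatReport",
    "kruskal_wallis",
    "dunn_posthoc",
    "summarize_mean_sem",
    "compare_conditions",
]


@dataclass(frozen=True)
class GroupedMeasurements:
    """Labelled groups of per-neuron values (e.g. dpi or drug conditions)."""

    labels: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        vals = tuple(np.asarray(v, dtype=float) for v in self.values)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.labels) != len(vals):
            raise ValueError("labels and value vectors must align")
        if len(self.labels) < 2:
            raise ValueError("at least two groups required")
        for lbl, v in zip(self.labels, vals):
            if v.size == 0:
                raise ValueError(f"group {lbl!r} is empty")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {lbl!r} contains non-finite values")

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]]) -> "GroupedMeasurements":
        return cls(tuple(d.keys()), tuple(np.asarray(v, float) for v in d.values()))


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool
    #: +1 when group_b's mean rank exceeds group_a's, −1 otherwise, 0 on tie.
    direction: int


@dataclass(frozen=True)
class StatReport:
    """Omnibus + post hoc results for one metric."""

    metric: str
    h_statistic: float
    p_omnibus: float
    pairwise: tuple[PairwiseResult, ...]
    group_mean_sem: dict[str, tuple[float, float]]
    alpha: float = 0.05
    adjust: str = "bonferroni"

    def significant_pairs(self) -> list[PairwiseResult]:
        return [p for p in self.pairwise if p.significant]


def kruskal_wallis(data: GroupedMeasurements) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    When every pooled value is identical there is no rank variation; H is 0
    and p is 1 by convention.
    """
    pooled = np.concatenate(data.values)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*data.values)
    return float(h), float(p)


def dunn_posthoc(
    data: GroupedMeasurements, adjust: str = "bonferroni", alpha: float = 0.05
) -> list[PairwiseResult]:
    """Dunn's pairwise mean-rank comparisons with multiplicity adjustment.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T)(1/n_i + 1/n_j)] with the tie
    term T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values are adjusted
    over all pairs by the chosen method (``bonferroni``, ``holm`` or
    ``none``).
    """
    if adjust not in ("bonferroni", "holm", "none"):
        raise ValueError("adjust must be 'bonferroni', 'holm' or 'none'")
    pooled = np.concatenate(data.values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [v.size for v in data.values]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(sizes))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(sizes)), 2))
    zs, ps, dirs = [], [], []
    for i, j in pairs:
        se = math.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        diff = mean_ranks[i] - mean_ranks[j]
        z = diff / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
        dirs.append(int(np.sign(mean_ranks[j] - mean_ranks[i])))
    if adjust == "none":
        adj = np.minimum(ps, 1.0)
        reject = adj < alpha
    else:
        reject, adj, _, _ = multipletests(ps, alpha=alpha, method=adjust)
    return [
        PairwiseResult(
            group_a=data.labels[i],
            group_b=data.labels[j],
            z=float(z),
            p_raw=float(min(p, 1.0)),
            p_adjusted=float(a),
            significant=bool(r),
            direction=d,
        )
        for (i, j), z, p, a, r, d in zip(pairs, zs, ps, adj, reject, dirs)
    ]


def summarize_mean_sem(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD, n − 1 denominator).

    SEM is 0 for a single value.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


#: Metrics compare_conditions understands.
_METRICS = ("ap_frequency", "burst_frequency", "mean_burst_duration", "pct_aps_in_burst")


def _metric_vectors(session, metric: str, unit_bursts) -> np.ndarray:
    from .bursts import burst_summary
    from .metrics import ap_frequency

    vals = []
    for unit in session.units:
        if metric == "ap_frequency":
            vals.append(ap_frequency(unit.train))
            continue
        summ = burst_summary(unit.train, unit_bursts[unit.unit_id])
        if metric == "burst_frequency":
            vals.append(summ.burst_frequency)
        elif metric == "pct_aps_in_burst":
            vals.append(summ.pct_aps_in_burst)
        elif metric == "mean_burst_duration":
            if summ.mean_burst_duration is not None:
                vals.append(summ.mean_burst_duration)
    return np.asarray(vals, dtype=float)


def compare_conditions(
    sessions: Mapping[str, "RecordingSession"],
    metrics: Sequence[str] = _METRICS,
    *,
    surprise_params=None,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> dict[str, StatReport]:
    """Kruskal–Wallis + Dunn chain over per-unit metrics across conditions.

    ``sessions`` maps condition labels (typically baseline / treatment /
    washout) to curated sessions.  For each requested metric the per-unit
    values of every condition are fed to the omnibus test and, regardless of
    its outcome, to Dunn's post hoc (the omnibus p is reported so callers
    can gate on it).  A metric with an empty value vector in any condition
    (e.g. burst duration when no unit bursts) is skipped with a warning
    entry rather than raising.
    """
    import warnings

    from .bursts import SurpriseParams, detect_session_bursts

    sp = surprise_params or SurpriseParams()
    unknown = set(metrics) - set(_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    needs_bursts = any(m != "ap_frequency" for m in metrics)
    bursts = {
        label: detect_session_bursts(sess, sp) if needs_bursts else {}
        for label, sess in sessions.items()
    }
    reports: dict[str, StatReport] = {}
    for metric in metrics:
        vectors = {
            label: _metric_vectors(sess, metric, bursts[label])
            for label, sess in sessions.items()
        }
        if any(v.size == 0 for v in vectors.values()):
            warnings.warn(
                f"metric {metric!r} unavailable in at least one condition; skipped"
            )
            continue
        data = GroupedMeasurements.from_dict(vectors)
        h, p = kruskal_wallis(data)
        pairwise = dunn_posthoc(data, adjust=adjust, alpha=alpha)
        reports[metric] = StatReport(
            metric=metric,
            h_statistic=h,
            p_omnibus=p,
            pairwise=tuple(pairwise),
            group_mean_sem={
                label: summarize_mean_sem(v) for label, v in vectors.items()
            },
            alpha=alpha,
            adjust=adjust,
        )
    return reports
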