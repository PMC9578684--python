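"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and the scipy special functions)
used by the package: the surprise oracle sums the Poisson tail series term
by term in log space, and the burst oracle re-runs the seeding/extension
protocol naively in pure Python, evaluating the surprise of every admissible
contiguous window with the series oracle.
"""

from __future__ import annotations

import math

import numpy as np


def series_surprise(n_spikes: int, window: float, rate: float) -> float:
    """−ln P(X ≥ N) by direct term-by-term series summation.

    Sums whichever side of the tail is small: when the lower sum
    Σ_{n<N} pmf(n) is below 1/2 (so P(X ≥ N) is near 1 and −log of it is
    tiny), S = −log1p(−lower) keeps full relative precision; otherwise the
    upper tail is accumulated in log space until the increments vanish.
    """
    if n_spikes == 0:
        return 0.0
    mu = rate * window

    def log_pmf(n: int) -> float:
        return -mu + n * math.log(mu) - math.lgamma(n + 1)

    lower = 0.0
    for n in range(n_spikes):
        lower += math.exp(log_pmf(n))
    if lower < 0.5:
        return max(-math.log1p(-lower), 0.0)

    log_p = log_pmf(n_spikes)
    n = n_spikes + 1
    while True:
        term = log_pmf(n)
        new = np.logaddexp(log_p, term)
        if new - log_p < 1e-16:
            break
        log_p = new
        n += 1
    return max(-log_p, 0.0)


def exhaustive_detect_bursts(times, duration, params):
    """Reference burst detector: same seeding/extension domain as the
    package's protocol, but every admissible window is scored explicitly
    with the series-summation surprise.

    Returns a list of (start_index, end_index, surprise) tuples.
    """
    times = list(map(float, times))
    n = len(times)
    if n < params.min_spikes:
        return []
    rate = n / duration
    isis = [b - a for a, b in zip(times, times[1:])]
    mean_isi = sum(isis) / len(isis)
    seed_th = params.seed_isi_factor * mean_isi
    ext_th = params.extension_isi_factor * mean_isi

    out = []
    i = 0
    while i <= n - 3:
        if not (isis[i] < seed_th and isis[i + 1] < seed_th):
            i += 1
            continue
        j_max = i + 2
        while j_max < n - 1 and isis[j_max] <= ext_th:
            j_max += 1
        scored = [
            (series_surprise(j - i + 1, times[j] - times[i], rate), j)
            for j in range(i + params.min_spikes - 1, j_max + 1)
        ]
        if scored:
            best_s = max(s for s, _ in scored)
            best_j = min(j for s, j in scored if s == best_s)
        else:
            best_s, best_j = -1.0, -1
        if (
            best_j >= 0
            and best_s >= params.min_surprise
            and times[best_j] - times[i] >= params.min_duration
        ):
            out.append((i, best_j, best_s))
            i = best_j + 1
        else:
            i += 1
    return out


def random_bursty_train(rng: np.random.Generator, max_spikes: int = 200):
    """A random train mixing Poisson background with dense clusters, for
    detector-vs-oracle comparisons.  Returns (times, duration)."""
    duration = float(rng.uniform(30.0, 120.0))
    bg_rate = float(rng.uniform(0.2, 3.0))
    times = list(rng.uniform(0.0, duration, size=rng.poisson(bg_rate * duration)))
    for _ in range(rng.poisson(3.0)):
        start = rng.uniform(0.0, duration * 0.95)
        n = int(rng.integers(3, 15))
        cluster_rate = rng.uniform(30.0, 200.0)
        t = start
        for _ in range(n):
            t += rng.exponential(1.0 / cluster_rate)
            if t < duration:
                times.append(t)
    times = np.unique(np.asarray(times))
    if times.size > max_spikes:
        times = np.sort(rng.choice(times, size=max_spikes, replace=False))
    return times, duration
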