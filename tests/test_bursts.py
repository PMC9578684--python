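import math

import numpy as np
import pytest

from hdmea import (
    Burst,
    NetworkBurstConfig,
    SpikeTrain,
    SurpriseParams,
    burst_summary,
    detect_bursts,
    detect_network_bursts,
    detect_session_bursts,
    gen_stage_session,
    poisson_surprise,
    units_in_network_bursts,
)
from hdmea.synthetic import StageParams

from _oracles import exhaustive_detect_bursts, random_bursty_train, series_surprise
from conftest import make_session


class TestPoissonSurprise:
    def test_zero_spikes_zero_surprise(self):
        assert poisson_surprise(0, 1.0, 10.0) == 0.0

    def test_one_spike_matches_closed_form(self):
        # P(X >= 1) = 1 - exp(-mu)
        for mu in (0.1, 1.0, 5.0):
            expected = -math.log(1.0 - math.exp(-mu))
            assert poisson_surprise(1, 1.0, mu) == pytest.approx(expected)

    def test_five_spikes_unit_mass(self):
        """lam=10 Hz, T=0.1 s, N=5: S = -ln(1 - sum_{n<5} e^-1/n!) ~ 5.611."""
        tail = 1.0 - sum(math.exp(-1) / math.factorial(n) for n in range(5))
        assert poisson_surprise(5, 0.1, 10.0) == pytest.approx(-math.log(tail))
        assert poisson_surprise(5, 0.1, 10.0) == pytest.approx(5.611, abs=1e-3)

    def test_matches_series_oracle_on_grid(self):
        for n in (1, 2, 5, 10, 30):
            for mu in (0.01, 0.5, 1.0, 5.0, 20.0):
                impl = poisson_surprise(n, 1.0, mu)
                oracle = series_surprise(n, 1.0, mu)
                assert impl == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_monotone_in_n_and_in_mu(self):
        mus = np.linspace(0.1, 10, 25)
        for mu in mus:
            s = [poisson_surprise(n, 1.0, mu) for n in range(1, 40)]
            assert all(b > a for a, b in zip(s, s[1:]))
        for n in (3, 10, 25):
            s = [poisson_surprise(n, 1.0, mu) for mu in mus]
            assert all(b < a for a, b in zip(s, s[1:]))

    def test_base10_scaling(self):
        nat = poisson_surprise(5, 0.1, 10.0)
        b10 = poisson_surprise(5, 0.1, 10.0, log_base="base10")
        assert b10 == pytest.approx(nat / math.log(10))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_surprise(1, 0.0, 1.0)
        with pytest.raises(ValueError):
            poisson_surprise(1, 1.0, -1.0)


class TestDetectBursts:
    def test_empty_and_tiny_trains(self):
        assert detect_bursts(SpikeTrain("u", np.array([]), 0.0, 10.0)) == []
        assert detect_bursts(SpikeTrain("u", np.array([1.0, 2.0, 3.0]), 0.0, 10.0)) == []

    def test_regular_train_has_no_bursts(self, regular_train):
        # constant ISI: nothing is below half the mean ISI, so no seed
        assert detect_bursts(regular_train) == []

    def test_injected_dense_cluster_recovered_exactly(self):
        """1 Hz regular background with a 100 Hz 10-spike cluster: one
        burst whose spike set equals the cluster (the background itself has
        no ISI below half the mean, so it cannot seed)."""
        background = np.arange(0.5, 300.0, 1.0)
        background = background[(background < 150.0) | (background > 152.0)]
        cluster = 150.2 + np.arange(10) * 0.01
        times = np.sort(np.concatenate([background, cluster]))
        train = SpikeTrain("u", times, 0.0, 300.0)
        bursts = detect_bursts(train)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.t_start == pytest.approx(cluster[0])
        assert b.t_end == pytest.approx(cluster[-1])
        assert b.n_spikes == 10
        assert b.surprise >= 4.0

    def test_emitted_bursts_satisfy_all_thresholds(self):
        params = SurpriseParams()
        rng = np.random.default_rng(12)
        for _ in range(20):
            times, duration = random_bursty_train(rng)
            if times.size < 4:
                continue
            train = SpikeTrain("u", times, 0.0, duration)
            for b in detect_bursts(train, params):
                assert b.surprise >= params.min_surprise
                assert b.duration >= params.min_duration
                assert b.n_spikes >= params.min_spikes

    def test_bursts_pairwise_disjoint_and_ordered(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            times, duration = random_bursty_train(rng)
            if times.size < 4:
                continue
            train = SpikeTrain("u", times, 0.0, duration)
            bursts = detect_bursts(train)
            for a, b in zip(bursts, bursts[1:]):
                assert a.t_end < b.t_start

    def test_matches_exhaustive_oracle(self):
        """Spike membership and surprise agree with the naive reference
        detector on random bursty trains."""
        params = SurpriseParams()
        rng = np.random.default_rng(7)
        compared = 0
        for _ in range(50):
            times, duration = random_bursty_train(rng)
            if times.size < 4:
                continue
            train = SpikeTrain("u", times, 0.0, duration)
            got = detect_bursts(train, params)
            expected = exhaustive_detect_bursts(times, duration, params)
            assert len(got) == len(expected)
            for b, (i, j, s) in zip(got, expected):
                assert b.t_start == pytest.approx(times[i])
                assert b.t_end == pytest.approx(times[j])
                assert b.surprise == pytest.approx(s, rel=1e-6)
            compared += len(expected)
        assert compared > 20  # the corpus actually contained bursts

    def test_time_rescaling_leaves_surprise_unchanged(self):
        """t -> c*t rescales lambda by 1/c: every S is invariant."""
        rng = np.random.default_rng(3)
        times, duration = random_bursty_train(rng)
        train = SpikeTrain("u", times, 0.0, duration)
        bursts = detect_bursts(train)
        c = 3.7
        scaled = SpikeTrain("u", times * c, 0.0, duration * c)
        bursts_c = detect_bursts(scaled)
        assert len(bursts) == len(bursts_c)
        for a, b in zip(bursts, bursts_c):
            assert a.surprise == pytest.approx(b.surprise, rel=1e-9)
            assert a.n_spikes == b.n_spikes

    def test_trim_start_output_is_locally_optimal(self):
        """With start refinement on, dropping the first spike of any
        emitted burst cannot raise its surprise further."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            times, duration = random_bursty_train(rng)
            if times.size < 4:
                continue
            train = SpikeTrain("u", times, 0.0, duration)
            rate = times.size / duration
            for b in detect_bursts(train, SurpriseParams(trim_start=True)):
                idx = np.searchsorted(times, b.t_start)
                end = idx + b.n_spikes - 1
                assert times[end] == pytest.approx(b.t_end)
                if b.n_spikes - 1 >= 4:
                    s_dropped = poisson_surprise(
                        b.n_spikes - 1, times[end] - times[idx + 1], rate
                    )
                    assert s_dropped <= b.surprise + 1e-12


class TestBurstSummary:
    def test_no_bursts(self, regular_train):
        s = burst_summary(regular_train, [])
        assert s.burst_frequency == 0.0
        assert s.pct_aps_in_burst == 0.0
        assert s.mean_burst_duration is None

    def test_arithmetic(self):
        times = np.sort(np.concatenate([
            np.linspace(1, 299, 270),
            50.0 + np.arange(10) * 0.01,
            150.0 + np.arange(10) * 0.01,
            250.0 + np.arange(10) * 0.01,
        ]))
        train = SpikeTrain("u", times, 0.0, 300.0)
        bursts = [
            Burst("u", 50.0, 50.09, 10, 20.0),
            Burst("u", 150.0, 150.09, 10, 20.0),
            Burst("u", 250.0, 250.09, 10, 20.0),
        ]
        s = burst_summary(train, bursts)
        assert s.burst_frequency == pytest.approx(0.01)
        assert s.mean_burst_duration == pytest.approx(0.09)
        # 30 injected spikes inside the burst windows out of 300 total
        assert s.pct_aps_in_burst == pytest.approx(100 * 30 / 300, abs=0.5)

    def test_ground_truth_pct_recovered(self):
        """Detected %APs-in-burst tracks the injected share at defaults."""
        session, truth = gen_stage_session(StageParams(seed=2, n_units=10))
        for u in session.units:
            bursts = detect_bursts(u.train)
            s = burst_summary(u.train, bursts)
            injected = sum(n for _, _, n in truth.unit_bursts[u.unit_id])
            true_pct = 100.0 * injected / u.train.n_spikes
            assert s.pct_aps_in_burst == pytest.approx(true_pct, abs=5.0)


class TestNetworkBursts:
    def test_single_unit_session_has_none(self):
        session, _ = gen_stage_session(StageParams(seed=1, n_units=1))
        per_unit = detect_session_bursts(session)
        assert detect_network_bursts(session, per_unit) == []

    def test_asynchronous_bursts_do_not_qualify(self):
        params = StageParams(
            seed=6, network_burst_rate=0.0, sync_fraction=0.0,
            burst_rate_per_unit=0.05,
        )
        session, _ = gen_stage_session(params)
        per_unit = detect_session_bursts(session)
        assert detect_network_bursts(session, per_unit) == []

    def test_event_count_close_to_injected(self):
        session, truth = gen_stage_session(StageParams(seed=14))
        per_unit = detect_session_bursts(session)
        events = detect_network_bursts(session, per_unit)
        assert abs(len(events) - len(truth.network_events)) <= max(
            2, 0.1 * len(truth.network_events)
        )

    def test_members_cover_injected_membership(self):
        session, truth = gen_stage_session(StageParams(seed=14))
        per_unit = detect_session_bursts(session)
        events = detect_network_bursts(session, per_unit)
        n, members = units_in_network_bursts(session, events)
        injected_members = set()
        for _, _, m in truth.network_events:
            injected_members.update(m)
        assert n == len(members)
        assert len(injected_members - members) <= 0.05 * len(injected_members)

    def test_no_network_bursts_means_no_participants(self):
        session, _ = gen_stage_session(StageParams(seed=1, n_units=3))
        n, members = units_in_network_bursts(session, [])
        assert n == 0 and members == set()
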