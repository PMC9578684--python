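import dataclasses

import numpy as np
import pytest

import hdmea
from hdmea import StageParams, gen_pharmacology_experiment, gen_stage_session, gen_trajectories


def _quiet(**kw):
    """Bursts and network events off unless overridden."""
    base = dict(
        burst_rate_per_unit=0.0, network_burst_rate=0.0, sync_fraction=0.0,
        fast_unit_fraction=0.0,
    )
    base.update(kw)
    return StageParams(**base)


class TestStageSession:
    def test_null_process_generates_no_spikes(self):
        session, _ = gen_stage_session(_quiet(baseline_rate=0.0, seed=1))
        assert all(u.train.n_spikes == 0 for u in session.units)

    def test_same_seed_is_bit_identical(self):
        a, ta = gen_stage_session(StageParams(seed=7))
        b, tb = gen_stage_session(StageParams(seed=7))
        for ua, ub in zip(a.units, b.units):
            np.testing.assert_array_equal(ua.train.spike_times, ub.train.spike_times)
            assert ua.snr == ub.snr
        assert ta.network_events == tb.network_events
        assert ta.unit_bursts == tb.unit_bursts

    def test_different_seeds_differ(self):
        a, _ = gen_stage_session(StageParams(seed=1))
        b, _ = gen_stage_session(StageParams(seed=2))
        assert not np.array_equal(
            a.units[0].train.spike_times, b.units[0].train.spike_times
        )

    def test_background_rate_matches_poisson_expectation(self):
        """Grand-mean empirical rate within 3 SE of the nominal 2 Hz."""
        params = _quiet(baseline_rate=2.0, n_units=50, duration=300.0, seed=11)
        session, _ = gen_stage_session(params)
        rates = [u.train.n_spikes / 300.0 for u in session.units]
        se = np.sqrt(2.0 / 300.0) / np.sqrt(50)
        assert abs(np.mean(rates) - 2.0) < 3 * se

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            StageParams(duration=0.0)

    def test_injected_bursts_contain_expected_spikes(self):
        """Each ground-truth interval holds about intra_rate x duration
        spikes (recorded count matches the actual train content)."""
        params = StageParams(seed=5, n_units=10)
        session, truth = gen_stage_session(params)
        checked = 0
        for uid, intervals in truth.unit_bursts.items():
            times = session.unit(uid).train.spike_times
            for start, end, n_inj in intervals:
                inside = np.count_nonzero((times >= start) & (times <= end))
                # merged coincidences may drop a spike or two; background adds some
                assert inside >= 0.8 * n_inj
                expected = params.intra_burst_rate * (end - start)
                assert n_inj >= expected - 4 * np.sqrt(expected + 1)
                checked += 1
        assert checked > 50

    def test_rate_converges_with_duration(self):
        errs = []
        for dur in (100.0, 3000.0):
            session, truth = gen_stage_session(
                _quiet(baseline_rate=1.5, n_units=20, duration=dur, seed=13)
            )
            emp = np.mean([u.train.n_spikes / dur for u in session.units])
            errs.append(abs(emp - 1.5))
        assert errs[1] < errs[0]

    def test_fast_units_labelled_and_fraction_respected(self):
        session, truth = gen_stage_session(StageParams(seed=3, fast_unit_fraction=0.2))
        assert len(truth.fast_units) == 10  # ceil(0.2 * 50)
        assert truth.fast_units <= set(session.unit_ids)

    def test_network_event_members_exist_and_intervals_in_window(self):
        session, truth = gen_stage_session(StageParams(seed=9))
        ids = set(session.unit_ids)
        for start, end, members in truth.network_events:
            assert 0 <= start <= end <= session.duration
            assert set(members) <= ids


class TestPharmacology:
    def test_unit_multipliers_give_exchangeable_sessions(self):
        sessions, truths = gen_pharmacology_experiment(
            StageParams(n_units=30), {"rate": 1.0, "burst_rate": 1.0}, seed=2
        )
        counts = {
            c: sum(len(b) for b in t.unit_bursts.values())
            for c, t in truths.items()
        }
        # same injection process, independent seeds: counts within Poisson error
        lam = np.mean(list(counts.values()))
        for c in counts.values():
            assert abs(c - lam) < 4 * np.sqrt(lam)

    def test_burst_rate_multiplier_scales_injected_count(self):
        sessions, truths = gen_pharmacology_experiment(
            StageParams(), {"burst_rate": 1.5}, seed=4
        )
        n_base = sum(len(b) for b in truths["baseline"].unit_bursts.values())
        n_treat = sum(len(b) for b in truths["treatment"].unit_bursts.values())
        ratio = n_treat / n_base
        assert 1.3 < ratio < 1.7

    def test_burst_duration_multiplier_scales_mean_duration(self):
        sessions, truths = gen_pharmacology_experiment(
            StageParams(), {"burst_duration": 0.6}, seed=4
        )

        def mean_dur(t):
            durs = [e - s for bs in t.unit_bursts.values() for s, e, _ in bs]
            return np.mean(durs)

        ratio = mean_dur(truths["treatment"]) / mean_dur(truths["baseline"])
        assert 0.5 < ratio < 0.7

    def test_washout_persistence_interpolates(self):
        _, t_full = gen_pharmacology_experiment(
            StageParams(), {"burst_rate": 2.0}, seed=6, washout_persistence=1.0
        )
        _, t_none = gen_pharmacology_experiment(
            StageParams(), {"burst_rate": 2.0}, seed=6, washout_persistence=0.0
        )
        n_full = sum(len(b) for b in t_full["washout"].unit_bursts.values())
        n_none = sum(len(b) for b in t_none["washout"].unit_bursts.values())
        assert n_full > 1.5 * n_none

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError):
            gen_pharmacology_experiment(StageParams(), {"burst_rate": 0.0}, seed=1)
        with pytest.raises(ValueError):
            gen_pharmacology_experiment(StageParams(), {"bogus": 1.5}, seed=1)

    def test_condition_labels_set(self):
        sessions, _ = gen_pharmacology_experiment(
            StageParams(n_units=5), {"rate": 1.2}, seed=1, drug="gabazine"
        )
        assert sessions["treatment"].condition == "treatment"
        assert sessions["treatment"].drug == "gabazine"


class TestTrajectories:
    def test_zero_step_zero_gain_is_static(self):
        trajs = gen_trajectories(10, 5, step_scale=0.0, attraction_gain=0.0, seed=1)
        for t in trajs:
            pos = t.positions()
            assert np.allclose(pos, pos[0])

    def test_same_seed_identical(self):
        a = gen_trajectories(5, 4, seed=9)
        b = gen_trajectories(5, 4, seed=9)
        for ta, tb in zip(a, b):
            assert ta.samples == tb.samples

    def test_attraction_pulls_toward_attractors(self):
        """With gain 0.5 over 10 steps the mean distance to the nearest
        attractor shrinks (Monte Carlo over 100 seeds)."""
        initial, final = [], []
        for seed in range(100):
            trajs, attr = gen_trajectories(
                20, 11, step_scale=10.0, attraction_gain=0.5, seed=seed,
                return_attractors=True,
            )

            def mean_dist(points):
                d = np.linalg.norm(points[:, None, :] - attr[None], axis=2)
                return d.min(axis=1).mean()

            initial.append(mean_dist(np.stack([t.positions()[0] for t in trajs])))
            final.append(mean_dist(np.stack([t.positions()[-1] for t in trajs])))
        assert np.mean(final) < np.mean(initial)

    def test_attraction_converges_to_generator_attractors(self):
        """Strong gain collapses final positions into tight clusters."""
        trajs = gen_trajectories(
            50, 12, step_scale=5.0, attraction_gain=0.8, seed=2
        )
        final = np.stack([t.positions()[-1] for t in trajs])
        first = np.stack([t.positions()[0] for t in trajs])
        # dispersion around the 12 implicit cluster centres drops sharply:
        # nearest-neighbour distances shrink relative to the initial layout
        def mean_nn(points):
            d = np.linalg.norm(points[:, None] - points[None], axis=2)
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).mean()

        assert mean_nn(final) < 0.5 * mean_nn(first)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            gen_trajectories(0, 5)
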