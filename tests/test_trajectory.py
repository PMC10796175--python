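"""Gillespie trajectory simulation: exactness, replay, punctual semantics."""

import numpy as np
import pytest

import reactree as rt
from reactree.trajectory import ConditionError, PunctualCountError

from conftest import SAMPLE, make_model


class TestSimulateTrajectory:
    def test_pure_death_fires_once_per_individual(self):
        m = make_model(reactions=[rt.Reaction.from_string("A -> 0", 1.0)],
                       pops=[rt.Population("A", 5)], t_end=1e6)
        traj = rt.simulate_trajectory(m, 3)
        assert len(traj.events) == 5
        assert traj.final_counts() == {"A": 0}

    def test_yule_ensemble_mean_matches_exponential_growth(self, yule_model):
        # E[N(t)] = exp(lambda t); 3-standard-error band.
        finals = [
            rt.simulate_trajectory(yule_model, rt.replicate_rng(41, i))
            .final_counts()["A"]
            for i in range(4000)
        ]
        mean, se = np.mean(finals), np.std(finals) / np.sqrt(len(finals))
        assert abs(mean - np.e) < 3 * se

    def test_seir_counts_non_negative_and_conserved(self):
        # With only non-removing sampling, S+E+I+R is conserved throughout.
        sp = SAMPLE
        serial = rt.Reaction.from_string("I -> I + sample",
                                         rt.RateFunction((0.0, 1.0), (5.0,)), sp)
        m = make_model(
            reactions=[
                rt.Reaction.from_string("I + S -> I + E", 0.1, sp),
                rt.Reaction.from_string("E -> I", 1.0, sp),
                rt.Reaction.from_string("I -> R", 0.5, sp),
                serial,
            ],
            pops=[rt.Population("S", 99), rt.Population("E", 0),
                  rt.Population("I", 1), rt.Population("R", 0),
                  rt.Population("sample", is_sample=True)],
            t_end=10.0,
        )
        traj = rt.simulate_trajectory(m, 11)
        counts = dict(traj.initial)
        total0 = sum(counts[p] for p in "SEIR")
        for ev in traj.events:
            for p, c in ev.delta.items():
                counts[p] = counts.get(p, 0) + c
                assert counts[p] >= 0
            assert sum(counts[p] for p in "SEIR") == total0

    def test_identical_seeds_identical_event_logs(self, bd_sampling_model):
        t1 = rt.simulate_trajectory(bd_sampling_model, 99)
        t2 = rt.simulate_trajectory(bd_sampling_model, 99)
        assert [(e.time, e.multiplicity, e.delta) for e in t1.events] == \
               [(e.time, e.multiplicity, e.delta) for e in t2.events]

    def test_condition_retry_exhaustion_reports(self):
        # Sampling rate zero: the >=1 sample condition can never be met.
        sp = SAMPLE
        m = rt.Model(
            (rt.Population("A", 1), rt.Population("sample", is_sample=True)),
            (rt.Reaction.from_string("A -> A + sample", 0.0, sp),),
            t_end=1.0,
            conditions=rt.Conditions(min_samples=1, max_retries=5),
        )
        with pytest.raises(ConditionError, match="attempts"):
            rt.simulate_trajectory(m, 0)

    def test_exact_reversibility_of_event_log(self, seir_model):
        traj = rt.simulate_trajectory(seir_model, 17)
        counts = traj.final_counts()
        for ev in reversed(traj.events):
            for p, c in ev.delta.items():
                counts[p] = counts.get(p, 0) - c
        counts = {p: c for p, c in counts.items() if c or p in traj.initial}
        assert counts == traj.initial


class TestPunctual:
    def test_binomial_mode_mean(self):
        sp = SAMPLE
        m = rt.Model(
            (rt.Population("I", 100), rt.Population("sample", is_sample=True)),
            (),
            (rt.PunctualReaction.from_string(
                "I -> sample", times=(5.0,), p=0.1, sample_populations=sp),),
            t_end=5.0,
            conditions=rt.Conditions(min_samples=0),
        )
        ns = [rt.simulate_trajectory(m, rt.replicate_rng(5, i)).n_samples
              for i in range(3000)]
        mean, se = np.mean(ns), np.std(ns) / np.sqrt(len(ns))
        assert abs(mean - 10.0) < 3 * se

    def test_count_zero_is_identity(self, rng):
        pr = rt.PunctualReaction.from_string("A -> 0", times=(1.0,), n=0)
        counts, ev = rt.apply_punctual_reaction({"A": 7}, pr, 1.0, rng)
        assert counts == {"A": 7}
        assert ev.multiplicity == 0

    def test_count_exceeding_population_is_an_error(self, rng):
        pr = rt.PunctualReaction.from_string("A -> 0", times=(1.0,), n=5)
        with pytest.raises(PunctualCountError, match="only 3 present"):
            rt.apply_punctual_reaction({"A": 3}, pr, 1.0, rng)

    def test_punctual_at_t_end_fires(self):
        sp = SAMPLE
        m = rt.Model(
            (rt.Population("A", 4), rt.Population("sample", is_sample=True)),
            (),
            (rt.PunctualReaction.from_string(
                "A -> sample", times=(1.0,), n=4, sample_populations=sp),),
            t_end=1.0,
        )
        traj = rt.simulate_trajectory(m, 1)
        assert traj.n_samples == 4


class TestReplay:
    def test_initial_and_final_states(self):
        m = make_model(reactions=[rt.Reaction.from_string("A -> 0", 1.0)],
                       pops=[rt.Population("A", 5)], t_end=50.0)
        traj = rt.simulate_trajectory(m, 3)
        assert rt.replay_counts(traj, 0.0) == traj.initial
        assert rt.replay_counts(traj, traj.t_end)["A"] == 0

    def test_matches_independent_cumulative_sum(self, seir_model, rng):
        traj = rt.simulate_trajectory(seir_model, 23)
        times = np.asarray([ev.time for ev in traj.events])
        pops = set(traj.initial) | {p for ev in traj.events for p in ev.delta}
        for t in rng.uniform(0.0, traj.t_end, size=20):
            # oracle: vectorised cumulative sums per population
            expected = {
                p: traj.initial.get(p, 0)
                + sum(ev.delta.get(p, 0) for ev in traj.events
                      if ev.time <= t)
                for p in pops
            }
            got = rt.replay_counts(traj, float(t))
            assert {p: got.get(p, 0) for p in pops} == expected
        assert len(times) == len(traj.events)

    def test_outside_span_rejected(self, seir_model):
        traj = rt.simulate_trajectory(seir_model, 23)
        with pytest.raises(ValueError):
            rt.replay_counts(traj, -0.5)


class TestTrajectoryGrid:
    def test_two_point_grid_is_endpoints(self):
        m = make_model(reactions=[rt.Reaction.from_string("A -> 0", 1.0)],
                       pops=[rt.Population("A", 5)], t_end=50.0)
        traj = rt.simulate_trajectory(m, 3)
        grid = rt.log_trajectory_grid(traj, 2)
        assert grid.iloc[0]["A"] == 5 and grid.iloc[0]["t"] == 0.0
        assert grid.iloc[1]["A"] == 0 and grid.iloc[1]["t"] == 50.0

    def test_rows_equal_replay(self, seir_model):
        traj = rt.simulate_trajectory(seir_model, 29)
        grid = rt.log_trajectory_grid(traj, 11)
        for _, row in grid.iterrows():
            counts = rt.replay_counts(traj, row["t"])
            for p in ("S", "E", "I", "R"):
                assert row[p] == counts.get(p, 0)

    def test_yule_grid_is_non_decreasing(self, yule_model):
        traj = rt.simulate_trajectory(yule_model, 31)
        grid = rt.log_trajectory_grid(traj, 25)
        assert (np.diff(grid["A"].to_numpy()) >= 0).all()

    def test_too_few_points_rejected(self, yule_model):
        traj = rt.simulate_trajectory(yule_model, 31)
        with pytest.raises(ValueError):
            rt.log_trajectory_grid(traj, 1)
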