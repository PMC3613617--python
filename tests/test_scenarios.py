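"""Conditioning protocols: schedules, action selection, closed-loop runs."""

import numpy as np
import pytest

from rchp import (
    ClassicalConfig,
    NetworkParams,
    OperantConfig,
    PlasticityParams,
    PlasticityState,
    RewardPolicy,
    build_network,
    generate_classical_schedule,
    run_classical,
    run_operant,
    select_action,
    step_network,
    plasticity_step,
)
from rchp.recording import pathway_synapse_indices
from rchp.scenarios import EventSchedule

SMALL = NetworkParams(n_excitatory=200, n_inhibitory=50, group_size=20)
SMALL_OPERANT = NetworkParams(n_excitatory=300, n_inhibitory=75, group_size=20)


def _small_classical_net(seed, n_stimuli=3):
    rng = np.random.default_rng(seed)
    cfg = ClassicalConfig(n_stimuli=n_stimuli, total_time=120.0)
    spec = [(lb, "input") for lb in cfg.stimulus_labels] + [("A0", "output")]
    net = build_network(SMALL, spec, rng)
    return net, cfg, rng


# --------------------------------------------------------------------------
# schedules


class TestClassicalSchedule:
    def test_zero_appear_prob_gives_empty_schedule(self):
        cfg = ClassicalConfig(appear_prob=0.0, total_time=1000.0)
        sched = generate_classical_schedule(cfg, np.random.default_rng(0))
        assert sched.stimulus_events == [] and sched.reward_events == []

    def test_appearance_count_matches_renewal_oracle(self):
        # Onsets follow a Bernoulli-per-step process blocked while the
        # stimulus is on: a renewal process with mean cycle
        # 1/appear_prob + mean(duration), hence ~10.5 appearances per
        # stimulus over 2 h at 0.15%/s with durations U[3, 30] s.
        cfg = ClassicalConfig(total_time=7200.0)
        cycle = 1.0 / cfg.appear_prob + np.mean(cfg.duration_range)
        expected = cfg.total_time / cycle
        counts = []
        for seed in range(40):
            sched = generate_classical_schedule(cfg, np.random.default_rng(seed))
            counts.append(
                sum(1 for e in sched.stimulus_events if e[0] == cfg.cs_label)
            )
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 0.3

    def test_each_cs_appearance_schedules_one_delayed_reward(self):
        cfg = ClassicalConfig(total_time=7200.0)
        sched = generate_classical_schedule(cfg, np.random.default_rng(1))
        cs_events = [e for e in sched.stimulus_events if e[0] == cfg.cs_label]
        in_horizon = [
            e for e in cs_events
            if e[1] + cfg.reward_delay_range[1] <= cfg.total_time
        ]
        assert len(sched.reward_events) >= len(in_horizon)
        for (_, onset, _), (t_r, mag) in zip(cs_events, sched.reward_events):
            assert onset <= t_r <= onset + cfg.reward_delay_range[1]
            assert mag == cfg.reward_magnitude

    def test_brief_variant_rewards_arrive_after_offset(self):
        cfg = ClassicalConfig(total_time=7200.0, brief_variant=True)
        sched = generate_classical_schedule(cfg, np.random.default_rng(2))
        for _, onset, offset in sched.stimulus_events:
            assert cfg.brief_duration_range[0] <= offset - onset \
                <= cfg.brief_duration_range[1] + 1e-9
        cs_offsets = [e[2] for e in sched.stimulus_events if e[0] == cfg.cs_label]
        for t_r, _ in sched.reward_events:
            gaps = [t_r - off for off in cs_offsets if 0 <= t_r - off]
            assert gaps and min(gaps) <= cfg.reward_delay_range[1]

    def test_schedule_validation_rejects_out_of_horizon_events(self):
        sched = EventSchedule(stimulus_events=[("S1", 5.0, 3.0)])
        with pytest.raises(ValueError):
            sched.validate(100.0)


# --------------------------------------------------------------------------
# action selection


class TestSelectAction:
    CFG = OperantConfig()

    def test_clear_winner(self):
        hist = np.full((5, 8), 0.05)
        hist[:, 3] = 0.9
        assert select_action(hist, self.CFG) == 3

    def test_subthreshold_margin_winner(self):
        hist = np.full((5, 8), 0.2)
        hist[-1, 3] = 0.21          # highest at window end, below 30%
        assert select_action(hist, self.CFG) == 3

    def test_exact_tie_breaks_to_lowest_index(self):
        hist = np.zeros((5, 8))
        hist[:, 2] = 0.5
        hist[:, 5] = 0.5
        assert select_action(hist, self.CFG) == 2
        sub = np.full((5, 8), 0.1)  # nobody crosses, exact tie at end
        assert select_action(sub, self.CFG) == 0

    def test_earliest_crossing_wins_over_later_higher(self):
        hist = np.full((5, 8), 0.05)
        hist[1, 2] = 0.4            # crosses first
        hist[3, 6] = 0.95           # crosses later, higher
        assert select_action(hist, self.CFG) == 2

    def test_same_step_crossing_resolved_by_activity(self):
        hist = np.full((5, 8), 0.05)
        hist[1, 0] = 0.33
        hist[1, 4] = 0.96
        assert select_action(hist, self.CFG) == 4

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            select_action(np.empty((0, 8)), self.CFG)


# --------------------------------------------------------------------------
# closed-loop runs


class TestRunClassical:
    def test_no_rewards_and_zero_baseline_freeze_weights(self):
        net, cfg, rng = _small_classical_net(0)
        plast = PlasticityState.create(
            PlasticityParams(baseline_b=0.0), net.n_synapses, SMALL.dt
        )
        sched = generate_classical_schedule(cfg, rng, SMALL.dt)
        sched.reward_events = []
        w0 = net.weights.copy()
        rec = run_classical(net, plast, sched, cfg, rng)
        assert np.array_equal(net.weights, w0)
        first, last = rec.pathways.iloc[0], rec.pathways.iloc[-1]
        for c in rec.pathways.columns:
            if c != "time":
                assert last[c] == first[c]

    def test_recording_is_well_formed_and_deterministic(self):
        def run(seed):
            net, cfg, rng = _small_classical_net(seed)
            plast = PlasticityState.create(
                PlasticityParams(), net.n_synapses, SMALL.dt
            )
            sched = generate_classical_schedule(cfg, rng, SMALL.dt)
            return run_classical(net, plast, sched, cfg, rng, meta={"seed": seed})

        rec1, rec2 = run(5), run(5)
        assert rec1.equals(rec2)
        t = rec1.scalars["time"].to_numpy()
        assert (np.diff(t) > 0).all()
        for e in rec1.events:
            assert 0.0 <= e["time"] <= 120.0 + 1e-9

    def test_extinction_under_negative_baseline(self):
        # a grown pathway, stimulated but never rewarded, slowly decays:
        # traces form on the pathway and the tonic b < 0 converts them
        # into small decrements
        net, cfg, rng = _small_classical_net(1)
        plast = PlasticityState.create(
            PlasticityParams(), net.n_synapses, SMALL.dt
        )
        idx = pathway_synapse_indices(net, net.groups["S1"], net.groups["A0"])
        net.weights[idx] = 0.5
        sched = EventSchedule(
            stimulus_events=[("S1", 10.0 * k, 10.0 * k + 5.0) for k in range(1, 12)]
        )
        before = net.weights[idx].mean()
        run_classical(net, plast, sched, cfg, rng)
        after = net.weights[idx].mean()
        assert after < before


class TestDelayDependence:
    def _single_episode_increment(self, delay, seed=3):
        """Weight change of a driven pathway from one reward at ``delay``."""
        rng = np.random.default_rng(seed)
        net = build_network(SMALL, [("S1", "input"), ("A0", "output")], rng)
        plast = PlasticityState.create(
            PlasticityParams(baseline_b=0.0), net.n_synapses, SMALL.dt
        )
        idx = pathway_synapse_indices(net, net.groups["S1"], net.groups["A0"])
        net.weights[idx] = 0.4        # mid-range: responsive, no clipping
        dt = SMALL.dt
        stim_steps = int(round(2.0 / dt))
        reward_step = stim_steps + int(round(delay / dt))
        before = None
        for step in range(reward_step + int(round(8.0 / dt))):
            on = {"S1"} if step < stim_steps else set()
            r = 1.0 if step == reward_step else 0.0
            if step == reward_step:
                before = net.weights[idx].mean()
            step_network(net, on, None, rng)
            plasticity_step(net, plast, r)
        return net.weights[idx].mean() - before

    def test_increment_positive_and_decays_with_delay(self):
        # same seed across delays: identical trajectory up to the reward,
        # so the increments isolate the trace decay e^(-d/tau_c)
        delays = [0.5, 1.0, 2.0, 4.0]
        incs = [self._single_episode_increment(d) for d in delays]
        assert all(i > 0 for i in incs)
        assert all(a >= b for a, b in zip(incs, incs[1:]))
        tau_c = PlasticityParams().tau_c
        for d, inc in zip(delays[1:], incs[1:]):
            expected_ratio = np.exp(-(d - delays[0]) / tau_c)
            assert np.log(inc / incs[0]) == pytest.approx(
                np.log(expected_ratio), abs=0.35
            )


class TestOperant:
    def _operant(self, seed, cfg, policy=None):
        rng = np.random.default_rng(seed)
        spec = [(lb, "input") for lb in cfg.color_labels]
        spec += [(lb, "output") for lb in cfg.action_labels]
        net = build_network(SMALL_OPERANT, spec, rng)
        plast = PlasticityState.create(
            PlasticityParams(), net.n_synapses, SMALL_OPERANT.dt
        )
        if policy is None:
            policy = RewardPolicy(
                mapping={c: cfg.action_labels[k]
                         for k, c in enumerate(cfg.color_labels)}
            )
        return run_operant(net, plast, cfg, policy, rng, meta={"seed": seed})

    def test_trial_bookkeeping(self):
        cfg = OperantConfig(n_colors=2, total_time=200.0)
        rec = self._operant(0, cfg)
        trials = rec.events_of("action")
        assert len(trials) == 10
        # sequential-circular presentation
        assert [e["stimulus"] for e in trials[:4]] == ["S10", "S11", "S10", "S11"]
        for e in trials:
            assert e["reward_time"] - e["time"] <= cfg.reward_delay_range[1]
            assert e["reward_magnitude"] in (
                cfg.reward_correct, cfg.reward_wrong
            )

    def test_early_choices_are_exploratory(self):
        # near-uniform pathways: the first 10 trials of a color should not
        # concentrate on a single action
        cfg = OperantConfig(n_colors=1, total_time=200.0)
        chosen = set()
        for seed in (0, 1):
            rec = self._operant(seed, cfg)
            chosen |= {e["action"] for e in rec.events_of("action")}
        assert len(chosen) >= 3

    def test_reward_symmetry_of_single_episode(self):
        # a punishment of magnitude |r| undoes about as much as a reward
        # of magnitude |r| builds, at equal delay (identical seeds twin runs)
        def twin(sign, seed=11):
            rng = np.random.default_rng(seed)
            net = build_network(
                SMALL_OPERANT, [("S10", "input"), ("A1", "output")], rng
            )
            plast = PlasticityState.create(
                PlasticityParams(baseline_b=0.0), net.n_synapses,
                SMALL_OPERANT.dt,
            )
            idx = pathway_synapse_indices(net, net.groups["S10"], net.groups["A1"])
            net.weights[idx] = 0.5
            dt = SMALL_OPERANT.dt
            reward_step = int(round(4.0 / dt))
            before = None
            for step in range(reward_step + int(round(8.0 / dt))):
                on = {"S10"} if step < 10 else set()
                fb = ("A1", []) if 5 <= step < 10 else None
                if step == reward_step:
                    before = net.weights[idx].mean()
                step_network(net, on, fb, rng)
                plasticity_step(net, plast, sign * 5.0 if step == reward_step else 0.0)
            return net.weights[idx].mean() - before

        up = twin(+1)
        down = twin(-1)
        assert up > 0 > down
        assert abs(abs(down) - up) / up < 0.25
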