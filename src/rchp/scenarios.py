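"""Simulated conditioning protocols.

Three closed-loop experiments drive the plastic network:

* **Classical conditioning with disturbances** — nine binary stimuli
  (one per "person") arrive by independent Bernoulli-per-step (Poisson)
  processes; one designated conditioned stimulus (CS) triggers a reward
  at a random delay.  Learning manifests as growth of the CS-to-output
  pathway while the eight disturbing pathways stay low.
* **Brief-stimulus variant** — stimuli last only 1-2 s and the reward
  arrives up to 5 s *after* the CS has ceased, so the association must
  be carried entirely by eligibility traces (the distal-reward case).
* **Operant color learning / behavior reversal** — five color stimuli
  presented sequentially and circularly every 20 s; eight action groups
  compete winner-take-all; the chosen action earns +5 (delayed) when it
  matches the tutor's mapping, -0.5 otherwise.  A reversal spec flips
  the rewarded action for one color mid-run, with punishments (-5) for
  perseverating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .network import (
    NetworkParams,
    NetworkState,
    build_network,
    group_activity,
    step_network,
)
from .plasticity import PlasticityParams, PlasticityState, plasticity_step
from .recording import Recording, pathway_synapse_indices
import pandas as pd

__all__ = [
    "ClassicalConfig",
    "OperantConfig",
    "EventSchedule",
    "RewardPolicy",
    "ReversalSpec",
    "generate_classical_schedule",
    "run_classical",
    "select_action",
    "run_operant",
    "run_reversal",
    "classical_experiment",
    "operant_experiment",
    "reversal_experiment",
]


# --------------------------------------------------------------------------
# configurations


@dataclass
class ClassicalConfig:
    """Stimulus/reward statistics of the classical-conditioning scenario."""

    n_stimuli: int = 9
    cs_index: int = 0
    appear_prob: float = 0.0015        # per-second probability of onset
    duration_range: tuple = (3.0, 30.0)
    reward_delay_range: tuple = (0.0, 5.0)
    reward_magnitude: float = 1.0
    #: the tutor's touch is sustained: r holds its value this long [s]
    reward_pulse_width: float = 1.0
    total_time: float = 7200.0
    brief_variant: bool = False
    brief_duration_range: tuple = (1.0, 2.0)
    #: fixed post-offset reward delay (overrides the range; used by the
    #: delay-capacity sweep together with brief_variant)
    fixed_reward_delay: float | None = None
    #: flag a conditioned response when the output activity reaches this
    conditioned_response_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.appear_prob <= 1.0):
            raise ValueError("appear_prob must lie in [0, 1]")
        for rng_ in (self.duration_range, self.reward_delay_range,
                     self.brief_duration_range):
            if rng_[0] > rng_[1]:
                raise ValueError("ranges must be ordered")
        if not (0 <= self.cs_index < self.n_stimuli):
            raise ValueError("cs_index out of range")

    @property
    def stimulus_labels(self) -> list[str]:
        return [f"S{k + 1}" for k in range(self.n_stimuli)]

    @property
    def cs_label(self) -> str:
        return self.stimulus_labels[self.cs_index]

    output_label: str = "A0"


@dataclass
class OperantConfig:
    """Trial structure of the operant color-learning scenario."""

    n_colors: int = 5
    n_actions: int = 8
    presentation_period: float = 20.0
    reward_correct: float = 5.0
    reward_wrong: float = -0.5
    reward_delay_range: tuple = (0.0, 5.0)
    #: graded operant rewards are brief events: one sampling step
    reward_pulse_width: float = 0.2
    decision_window: float = 1.0
    decision_threshold_frac: float = 0.30
    #: winner/loser +-input_drive is applied this long (action enunciation)
    feedback_duration: float = 1.0
    #: stimulus stays on for propagation lag + decision window + feedback,
    #: then switches off
    stimulus_duration: float = 2.2
    total_time: float = 1800.0
    #: activity of a fully driven group (tanh saturates at 1)
    max_activity: float = 1.0

    def __post_init__(self) -> None:
        if self.n_colors > self.n_actions:
            raise ValueError("n_colors must not exceed n_actions")
        if self.presentation_period <= self.decision_window:
            raise ValueError("presentation period must exceed decision window")

    @property
    def color_labels(self) -> list[str]:
        return [f"S{10 + k}" for k in range(self.n_colors)]

    @property
    def action_labels(self) -> list[str]:
        return [f"A{1 + k}" for k in range(self.n_actions)]


@dataclass
class EventSchedule:
    """Timed stimulus and reward events driving an open-loop scenario."""

    stimulus_events: list = field(default_factory=list)  # (label, onset, offset)
    reward_events: list = field(default_factory=list)    # (time, magnitude)

    def validate(self, total_time: float) -> None:
        for label, onset, offset in self.stimulus_events:
            if not (0.0 <= onset < offset <= total_time):
                raise ValueError(f"bad stimulus event ({label}, {onset}, {offset})")
        for t, _ in self.reward_events:
            if not (0.0 <= t <= total_time):
                raise ValueError(f"reward event at {t} outside horizon")


@dataclass
class ReversalSpec:
    """Mid-run policy switch: punish the old action, reward a new one."""

    switch_time: float
    stimulus: str
    old_action: str
    new_action: str


@dataclass
class RewardPolicy:
    """Tutor's mapping from color stimulus to the rewarded action."""

    mapping: dict                     # stimulus label -> correct action label
    punishment_mode: str = "punish_wrong"   # or "ignore_wrong"
    reversal: ReversalSpec | None = None

    def correct_action(self, stimulus: str, t: float) -> str:
        r = self.reversal
        if r is not None and stimulus == r.stimulus and t >= r.switch_time:
            return r.new_action
        return self.mapping[stimulus]

    def outcome(self, stimulus: str, t: float, action: str,
                config: OperantConfig) -> tuple[bool, float]:
        """(correct?, reward magnitude) for a chosen action."""
        correct = self.correct_action(stimulus, t)
        if action == correct:
            return True, config.reward_correct
        r = self.reversal
        if (r is not None and stimulus == r.stimulus and t >= r.switch_time
                and action == r.old_action):
            return False, -config.reward_correct   # punishment, same magnitude
        if self.punishment_mode == "punish_wrong":
            return False, config.reward_wrong
        return False, 0.0


# --------------------------------------------------------------------------
# classical conditioning


def generate_classical_schedule(
    config: ClassicalConfig, rng: np.random.Generator, dt: float = 0.2
) -> EventSchedule:
    """Draw the Poisson stimulus pattern and CS-triggered rewards.

    Each currently-absent stimulus switches on with probability
    ``appear_prob * dt`` per step; durations are uniform on the
    configured range.  Every CS appearance schedules one reward at
    onset + delay (standard) or offset + delay (brief variant, so the
    reward always arrives after the stimulus has ceased).
    """
    sched = EventSchedule()
    T = config.total_time
    q = config.appear_prob * dt
    dur_range = (
        config.brief_duration_range if config.brief_variant else config.duration_range
    )
    for k, label in enumerate(config.stimulus_labels):
        t = 0.0
        if q <= 0.0:
            continue
        while True:
            gap = int(rng.geometric(q))
            onset = t + gap * dt
            if onset >= T:
                break
            duration = rng.uniform(*dur_range)
            offset = min(onset + duration, T)
            sched.stimulus_events.append((label, onset, offset))
            if k == config.cs_index:
                if config.fixed_reward_delay is not None:
                    delay = config.fixed_reward_delay
                else:
                    delay = rng.uniform(*config.reward_delay_range)
                base = offset if config.brief_variant else onset
                r_time = base + delay
                if r_time <= T:
                    sched.reward_events.append((r_time, config.reward_magnitude))
            t = offset
    sched.stimulus_events.sort(key=lambda e: e[1])
    sched.reward_events.sort(key=lambda e: e[0])
    return sched


def _member_matrix(state: NetworkState, labels: list[str]) -> np.ndarray:
    return np.stack([state.groups[lb].members for lb in labels])


def run_classical(
    net: NetworkState,
    plast: PlasticityState,
    schedule: EventSchedule,
    config: ClassicalConfig,
    rng: np.random.Generator,
    meta: dict | None = None,
) -> Recording:
    """Closed-loop classical conditioning run driven by a schedule.

    Records per-step scalars, per-second pathway strengths from every
    stimulus group to the output group, and flags a conditioned response
    whenever output activity reaches the threshold while the CS is the
    only stimulus present (once per CS presentation).
    """
    dt = net.params.dt
    n_steps = int(round(config.total_time / dt))
    schedule.validate(config.total_time)
    labels = config.stimulus_labels
    out_label = config.output_label
    n_stim = len(labels)

    active = np.zeros((n_steps, n_stim), dtype=bool)
    lab_index = {lb: k for k, lb in enumerate(labels)}
    for label, onset, offset in schedule.stimulus_events:
        active[int(np.floor(onset / dt)): int(np.ceil(offset / dt)), lab_index[label]] = True
    rewards = np.zeros(n_steps)
    pulse_steps = max(1, int(round(config.reward_pulse_width / dt)))
    for t_r, mag in schedule.reward_events:
        step = min(int(np.floor(t_r / dt)), n_steps - 1)
        rewards[step : step + pulse_steps] += mag

    members = _member_matrix(net, labels + [out_label])
    pw_idx = [
        pathway_synapse_indices(net, net.groups[lb], net.groups[out_label])
        for lb in labels
    ]
    pw_cols = [f"{lb}->{out_label}" for lb in labels]
    record_stride = max(1, int(round(1.0 / dt)))
    n_rec = n_steps // record_stride + 1

    sc_time = np.empty(n_steps)
    sc_m = np.empty(n_steps)
    sc_rate = np.empty(n_steps)
    sc_th = np.empty((n_steps, 2))
    sc_act = np.empty((n_steps, n_stim + 1))
    pw_time = np.empty(n_rec)
    pw_vals = np.empty((n_rec, n_stim))

    events: list[dict] = []
    for label, onset, offset in schedule.stimulus_events:
        events.append({"time": onset, "type": "stimulus_on", "stimulus": label})
        events.append({"time": offset, "type": "stimulus_off", "stimulus": label})
    for t_r, mag in schedule.reward_events:
        events.append({"time": t_r, "type": "reward", "magnitude": mag})

    cs_col = config.cs_index
    cr_armed = True
    window_nsyn = plast.params.window * net.n_synapses
    rec_i = 0
    for step in range(n_steps):
        row = active[step]
        on = {labels[k] for k in np.flatnonzero(row)}
        step_network(net, on, None, rng)
        plasticity_step(net, plast, float(rewards[step]))

        acts = net.v[members].mean(axis=1)
        sc_time[step] = net.time
        sc_m[step] = plast.trace.m
        sc_rate[step] = plast.thresholds.corr_queue.total / window_nsyn * 100.0
        sc_th[step, 0] = plast.thresholds.theta_hi
        sc_th[step, 1] = plast.thresholds.theta_lo
        sc_act[step] = acts

        cs_only = row[cs_col] and row.sum() == 1
        if cs_only and cr_armed and acts[-1] >= config.conditioned_response_threshold:
            events.append(
                {"time": net.time, "type": "conditioned_response",
                 "stimulus": labels[cs_col], "activity": float(acts[-1])}
            )
            cr_armed = False
        if not row[cs_col]:
            cr_armed = True

        if step % record_stride == 0:
            pw_time[rec_i] = net.time
            for k in range(n_stim):
                pw_vals[rec_i, k] = net.weights[pw_idx[k]].mean()
            rec_i += 1

    scalars = pd.DataFrame(
        {"time": sc_time, "m": sc_m, "corr_rate": sc_rate,
         "theta_hi": sc_th[:, 0], "theta_lo": sc_th[:, 1]}
    )
    for k, lb in enumerate(labels + [out_label]):
        scalars[f"act_{lb}"] = sc_act[:, k]
    pathways = pd.DataFrame({"time": pw_time[:rec_i]})
    for k, c in enumerate(pw_cols):
        pathways[c] = pw_vals[:rec_i, k]

    events.sort(key=lambda e: e["time"])
    full_meta = {
        "scenario": "classical_brief" if config.brief_variant else "classical",
        "config": asdict(config),
        "cs_pathway": f"{config.cs_label}->{out_label}",
    }
    if meta:
        full_meta.update(meta)
    return Recording(scalars=scalars, pathways=pathways, events=events, meta=full_meta)


# --------------------------------------------------------------------------
# operant conditioning


def select_action(activity_history: np.ndarray, config: OperantConfig) -> int:
    """Winner-take-all action choice from the decision-window activities.

    ``activity_history`` has one row per step of the window and one
    column per action group.  If any group reaches
    ``decision_threshold_frac * max_activity`` during the window, the
    earliest-crossing group wins; when several groups cross at the same
    earliest step, the one with the highest activity at that step wins,
    and an exact activity tie falls to the lowest group index.  If no
    group crosses, the group with the highest activity at the window end
    wins, even by a small margin (again lowest index on an exact tie).
    """
    hist = np.asarray(activity_history, dtype=float)
    if hist.ndim != 2 or hist.size == 0:
        raise ValueError("activity history must be a non-empty 2-D array")
    thresh = config.decision_threshold_frac * config.max_activity
    crossed = hist >= thresh
    if crossed.any():
        first_step = np.where(crossed.any(axis=0), crossed.argmax(axis=0), hist.shape[0])
        earliest = int(first_step.min())
        contenders = np.flatnonzero(first_step == earliest)
        return int(contenders[np.argmax(hist[earliest, contenders])])
    return int(np.argmax(hist[-1]))


def run_operant(
    net: NetworkState,
    plast: PlasticityState,
    config: OperantConfig,
    policy: RewardPolicy,
    rng: np.random.Generator,
    meta: dict | None = None,
) -> Recording:
    """Closed-loop operant learning (and, with a reversal policy, reversal).

    Every ``presentation_period`` the next color (sequential-circular)
    switches on; output-group activities are monitored for the decision
    window, starting one propagation step after onset (the first step's
    outputs predate the stimulus and carry no information about it); the
    winner-take-all choice is enunciated with +-input_drive action
    feedback for ``feedback_duration``; rewards/punishments are delivered
    at a uniformly drawn delay after the action.
    """
    dt = net.params.dt
    n_steps = int(round(config.total_time / dt))
    per = int(round(config.presentation_period / dt))
    d_steps = int(round(config.decision_window / dt))
    f_steps = int(round(config.feedback_duration / dt))
    s_steps = int(round(config.stimulus_duration / dt))
    colors = config.color_labels
    actions = config.action_labels
    all_labels = colors + actions

    members = _member_matrix(net, all_labels)
    action_members = members[len(colors):]
    pw_idx = {}
    pw_cols = []
    for c in colors:
        for a in actions:
            pw_idx[(c, a)] = pathway_synapse_indices(net, net.groups[c], net.groups[a])
            pw_cols.append(f"{c}->{a}")
    record_stride = max(1, int(round(1.0 / dt)))
    n_rec = n_steps // record_stride + 1

    sc_time = np.empty(n_steps)
    sc_m = np.empty(n_steps)
    sc_rate = np.empty(n_steps)
    sc_th = np.empty((n_steps, 2))
    sc_act = np.empty((n_steps, len(all_labels)))
    pw_time = np.empty(n_rec)
    pw_vals = np.empty((n_rec, len(pw_cols)))

    events: list[dict] = []
    pending: dict[int, float] = {}
    act_hist = np.zeros((d_steps, len(actions)))
    window_nsyn = plast.params.window * net.n_synapses
    rec_i = 0
    current_winner: int | None = None
    t_offset = net.time   # supports continuing a pre-trained network

    for step in range(n_steps):
        trial = step // per
        within = step % per
        stim = colors[trial % len(colors)] if within < s_steps else None
        t_now = t_offset + step * dt

        if within == 0 and stim is not None:
            events.append({"time": t_now, "type": "stimulus_on", "stimulus": stim})
        if within == s_steps:
            events.append(
                {"time": t_now, "type": "stimulus_off",
                 "stimulus": colors[trial % len(colors)]}
            )

        if within == d_steps + 1 and stim is not None:
            choice = select_action(act_hist, config)
            current_winner = choice
            correct, mag = policy.outcome(stim, t_now, actions[choice], config)
            delay = rng.uniform(*config.reward_delay_range)
            r_time = t_now + delay
            r_step = min(int(np.floor((r_time - t_offset) / dt)), n_steps - 1)
            pulse = max(1, int(round(config.reward_pulse_width / dt)))
            for k in range(pulse):
                s = r_step + k
                if s < n_steps:
                    pending[s] = pending.get(s, 0.0) + mag
            events.append(
                {"time": t_now, "type": "action", "stimulus": stim,
                 "action": actions[choice], "correct": bool(correct),
                 "reward_magnitude": mag, "reward_time": r_time}
            )

        feedback = None
        if (current_winner is not None
                and d_steps + 1 <= within < d_steps + 1 + f_steps):
            win = actions[current_winner]
            feedback = (win, [a for a in actions if a != win])
        elif within >= d_steps + 1 + f_steps:
            current_winner = None

        on = {stim} if stim is not None else set()
        step_network(net, on, feedback, rng)
        r = pending.pop(step, 0.0)
        plasticity_step(net, plast, r)
        if r != 0.0:
            events.append({"time": net.time, "type": "reward", "magnitude": r})

        acts = net.v[members].mean(axis=1)
        if 1 <= within <= d_steps:
            act_hist[within - 1] = acts[len(colors):]
        sc_time[step] = net.time
        sc_m[step] = plast.trace.m
        sc_rate[step] = plast.thresholds.corr_queue.total / window_nsyn * 100.0
        sc_th[step, 0] = plast.thresholds.theta_hi
        sc_th[step, 1] = plast.thresholds.theta_lo
        sc_act[step] = acts

        if step % record_stride == 0:
            pw_time[rec_i] = net.time
            for k, (c, a) in enumerate(pw_idx):
                pw_vals[rec_i, k] = net.weights[pw_idx[(c, a)]].mean()
            rec_i += 1

    scalars = pd.DataFrame(
        {"time": sc_time, "m": sc_m, "corr_rate": sc_rate,
         "theta_hi": sc_th[:, 0], "theta_lo": sc_th[:, 1]}
    )
    for k, lb in enumerate(all_labels):
        scalars[f"act_{lb}"] = sc_act[:, k]
    pathways = pd.DataFrame({"time": pw_time[:rec_i]})
    for k, c in enumerate(pw_cols):
        pathways[c] = pw_vals[:rec_i, k]

    full_meta = {
        "scenario": "operant",
        "config": asdict(config),
        "policy": dict(policy.mapping),
    }
    if policy.reversal is not None:
        full_meta["scenario"] = "reversal"
        full_meta["reversal"] = asdict(policy.reversal)
    if meta:
        full_meta.update(meta)
    return Recording(scalars=scalars, pathways=pathways, events=events, meta=full_meta)


def run_reversal(
    net: NetworkState,
    plast: PlasticityState,
    config: OperantConfig,
    reversal: ReversalSpec,
    policy: RewardPolicy,
    rng: np.random.Generator,
    meta: dict | None = None,
) -> Recording:
    """Continue the operant loop under a reversed reward policy."""
    rev_policy = RewardPolicy(
        mapping=dict(policy.mapping),
        punishment_mode=policy.punishment_mode,
        reversal=reversal,
    )
    return run_operant(net, plast, config, rev_policy, rng, meta=meta)


# --------------------------------------------------------------------------
# one-call experiments (build + schedule + run)


def classical_experiment(
    seed: int,
    config: ClassicalConfig | None = None,
    net_params: NetworkParams | None = None,
    plast_params: PlasticityParams | None = None,
    return_state: bool = False,
) -> Recording:
    """Build a fresh classical network and run one full scenario."""
    config = config or ClassicalConfig()
    net_params = net_params or NetworkParams()
    plast_params = plast_params or PlasticityParams()
    rng = np.random.default_rng(seed)
    spec = [(lb, "input") for lb in config.stimulus_labels]
    spec.append((config.output_label, "output"))
    net = build_network(net_params, spec, rng)
    plast = PlasticityState.create(plast_params, net.n_synapses, net_params.dt)
    schedule = generate_classical_schedule(config, rng, net_params.dt)
    rec = run_classical(net, plast, schedule, config, rng, meta={"seed": seed})
    return (rec, net, plast) if return_state else rec


def operant_experiment(
    seed: int,
    config: OperantConfig | None = None,
    net_params: NetworkParams | None = None,
    plast_params: PlasticityParams | None = None,
    policy: RewardPolicy | None = None,
    return_state: bool = False,
) -> Recording:
    """Build a fresh operant network and run one color-learning scenario."""
    config = config or OperantConfig()
    net_params = net_params or NetworkParams()
    plast_params = plast_params or PlasticityParams()
    rng = np.random.default_rng(seed)
    spec = [(lb, "input") for lb in config.color_labels]
    spec += [(lb, "output") for lb in config.action_labels]
    net = build_network(net_params, spec, rng)
    plast = PlasticityState.create(plast_params, net.n_synapses, net_params.dt)
    if policy is None:
        mapping = {c: config.action_labels[k] for k, c in enumerate(config.color_labels)}
        policy = RewardPolicy(mapping=mapping)
    rec = run_operant(net, plast, config, policy, rng, meta={"seed": seed})
    return (rec, net, plast) if return_state else rec


def reversal_experiment(
    seed: int,
    config: OperantConfig | None = None,
    net_params: NetworkParams | None = None,
    plast_params: PlasticityParams | None = None,
    learn_time: float = 300.0,
    reversal_time: float = 1500.0,
    new_action_index: int = 1,
    return_state: bool = False,
) -> Recording:
    """Learn one color-action association, then reverse it under punishment.

    The run uses a single color; after ``learn_time`` of ordinary operant
    learning the tutor's policy switches: the old action is punished with
    the full reward magnitude and a new action becomes correct.
    """
    config = config or OperantConfig(n_colors=1, total_time=reversal_time)
    net_params = net_params or NetworkParams()
    plast_params = plast_params or PlasticityParams()
    rng = np.random.default_rng(seed)
    spec = [(lb, "input") for lb in config.color_labels]
    spec += [(lb, "output") for lb in config.action_labels]
    net = build_network(net_params, spec, rng)
    plast = PlasticityState.create(plast_params, net.n_synapses, net_params.dt)
    color = config.color_labels[0]
    mapping = {color: config.action_labels[0]}
    reversal = ReversalSpec(
        switch_time=learn_time,
        stimulus=color,
        old_action=config.action_labels[0],
        new_action=config.action_labels[new_action_index],
    )
    policy = RewardPolicy(mapping=mapping, reversal=reversal)
    rec = run_operant(net, plast, config, policy, rng, meta={"seed": seed})
    return (rec, net, plast) if return_state else rec
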