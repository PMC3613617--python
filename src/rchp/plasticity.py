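"""Rarely correlating Hebbian plasticity (RCHP) with eligibility traces.

The learning engine couples four pieces:

* **Rare-correlation detection.**  A thresholded Hebbian rule emits a
  discrete event per synapse and step:

      RCHP_ji(t) = +alpha  if v_j(t - t_pt) * v_i(t) > theta_hi
                   -beta   if v_j(t - t_pt) * v_i(t) < theta_lo
                   0       otherwise,

  with t_pt equal to one sampling step.  Thresholds are tuned online so
  that only a rare fraction (target mu ~ 0.5%/s of synapses) of all
  products registers as a correlation.

* **Homeostatic threshold adaptation.**  A FIFO queue keeps the per-step
  correlation counts of the last ``window`` seconds.  When the windowed
  rate exceeds 5*mu the threshold rises by a small step eta per second;
  below mu/5 it falls (theta_hi floored at 0, theta_lo capped at 0).
  The decorrelation threshold is adapted symmetrically from its own queue.

* **Eligibility traces.**  Each synapse carries a signed trace c_ji with
  dynamics  dc/dt = -c/tau_c + RCHP_ji(t);  events are added impulsively
  at full magnitude, then decay geometrically.

* **Modulation and weight update.**  A network-wide scalar m follows
  dm/dt = -m/tau_m + lambda*r(t) + b, where r(t) is the exogenous reward
  and b a small (typically negative) tonic baseline.  Weights change as
  dw/dt = m * c on plastic synapses only, clipped to [weight_min,
  weight_max].

All integrations are explicit first-order (Euler) at the network's dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkState

__all__ = [
    "PlasticityParams",
    "ThresholdState",
    "TraceState",
    "RchpEvents",
    "PlasticityState",
    "detect_correlations",
    "update_thresholds",
    "update_traces",
    "update_modulation",
    "apply_weight_update",
    "plasticity_step",
]


@dataclass
class PlasticityParams:
    alpha: float = 0.1              # correlation event magnitude
    beta: float = 0.1               # decorrelation event magnitude
    tau_c: float = 4.0              # eligibility-trace time constant [s]
    tau_m: float = 1.0              # modulation time constant [s]
    lambda_gain: float = 0.25       # reward-to-modulation gain
    baseline_b: float = -0.001      # tonic modulation drive [1/s]
    mu_target: float = 0.005        # target correlation rate [fraction of synapses / s]
    eta: float = 0.002              # threshold adaptation step [1/s]
    window: float = 10.0            # homeostasis queue horizon [s]
    band_hi_factor: float = 5.0
    band_lo_factor: float = 0.2
    theta_hi_init: float = 0.1
    theta_lo_init: float = -0.1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.tau_c <= 0 or self.tau_m <= 0:
            raise ValueError("time constants must be positive")
        if not (0.0 < self.mu_target < 1.0):
            raise ValueError("mu_target must lie in (0, 1)")
        if self.window <= 0:
            raise ValueError("window must be positive")


class _CountQueue:
    """Fixed-length FIFO of per-step event counts with a running total."""

    def __init__(self, maxlen: int) -> None:
        self.buf = np.zeros(maxlen, dtype=np.int64)
        self.maxlen = maxlen
        self.pos = 0
        self.filled = 0
        self.total = 0

    def push(self, count: int) -> None:
        self.total += count - self.buf[self.pos]
        self.buf[self.pos] = count
        self.pos = (self.pos + 1) % self.maxlen
        self.filled = min(self.filled + 1, self.maxlen)


@dataclass
class ThresholdState:
    """Adaptive detection thresholds plus their event-count queues."""

    theta_hi: float
    theta_lo: float
    corr_queue: _CountQueue
    decorr_queue: _CountQueue

    @classmethod
    def create(cls, params: PlasticityParams, dt: float) -> "ThresholdState":
        maxlen = max(1, round(params.window / dt))
        return cls(
            theta_hi=params.theta_hi_init,
            theta_lo=params.theta_lo_init,
            corr_queue=_CountQueue(maxlen),
            decorr_queue=_CountQueue(maxlen),
        )


@dataclass
class TraceState:
    """Per-synapse eligibility traces and the scalar modulation level."""

    C: np.ndarray
    m: float = 0.0

    @classmethod
    def create(cls, n_synapses: int) -> "TraceState":
        return cls(C=np.zeros(n_synapses), m=0.0)


@dataclass
class RchpEvents:
    """Sparse RCHP outcome of one step: indices into the synapse arrays."""

    idx_hi: np.ndarray
    idx_lo: np.ndarray
    alpha: float
    beta: float

    @property
    def n_corr(self) -> int:
        return int(self.idx_hi.size)

    @property
    def n_decorr(self) -> int:
        return int(self.idx_lo.size)

    def as_map(self, syn_pre: np.ndarray, syn_post: np.ndarray) -> dict:
        """Dict view {(j, i): +alpha | -beta} for small fixtures/tests."""
        out = {}
        for k in self.idx_hi:
            out[(int(syn_pre[k]), int(syn_post[k]))] = self.alpha
        for k in self.idx_lo:
            out[(int(syn_pre[k]), int(syn_post[k]))] = -self.beta
        return out


@dataclass
class PlasticityState:
    """Bundle of threshold and trace state for one network."""

    thresholds: ThresholdState
    trace: TraceState
    params: PlasticityParams = field(default_factory=PlasticityParams)

    @classmethod
    def create(
        cls, params: PlasticityParams, n_synapses: int, dt: float
    ) -> "PlasticityState":
        return cls(
            thresholds=ThresholdState.create(params, dt),
            trace=TraceState.create(n_synapses),
            params=params,
        )


def detect_correlations(
    v_prev: np.ndarray,
    v_curr: np.ndarray,
    syn_pre: np.ndarray,
    syn_post: np.ndarray,
    thresholds: ThresholdState,
    params: PlasticityParams,
) -> RchpEvents:
    """Apply the RCHP rule to every existing synapse.

    ``v_prev`` must be the output one sampling step (= the propagation
    time) before ``v_curr``.  Inequalities are strict; a product exactly
    at a threshold produces no event.
    """
    prod = v_prev[syn_pre] * v_curr[syn_post]
    idx_hi = np.flatnonzero(prod > thresholds.theta_hi)
    idx_lo = np.flatnonzero(prod < thresholds.theta_lo)
    return RchpEvents(idx_hi=idx_hi, idx_lo=idx_lo, alpha=params.alpha, beta=params.beta)


def update_thresholds(
    thresholds: ThresholdState,
    n_corr: int,
    n_decorr: int,
    n_synapses: int,
    params: PlasticityParams,
    dt: float,
) -> ThresholdState:
    """Push this step's counts and nudge the thresholds homeostatically.

    The windowed rate rho = (sum of queued counts) / (window * n_synapses)
    is a per-second fraction of synapses.  Above 5*mu the corresponding
    threshold magnitude grows by eta*dt; below mu/5 it shrinks, floored
    so that theta_hi >= 0 >= theta_lo.
    """
    if n_synapses <= 0:
        raise ValueError("n_synapses must be positive")
    p = params
    hi_band = p.band_hi_factor * p.mu_target
    lo_band = p.band_lo_factor * p.mu_target
    step = p.eta * dt

    thresholds.corr_queue.push(n_corr)
    rho_c = thresholds.corr_queue.total / (p.window * n_synapses)
    if rho_c > hi_band:
        thresholds.theta_hi += step
    elif rho_c < lo_band:
        thresholds.theta_hi = max(0.0, thresholds.theta_hi - step)

    thresholds.decorr_queue.push(n_decorr)
    rho_d = thresholds.decorr_queue.total / (p.window * n_synapses)
    if rho_d > hi_band:
        thresholds.theta_lo -= step
    elif rho_d < lo_band:
        thresholds.theta_lo = min(0.0, thresholds.theta_lo + step)
    return thresholds


def update_traces(
    trace: TraceState, events: RchpEvents, params: PlasticityParams, dt: float
) -> TraceState:
    """Decay all traces geometrically and add this step's events impulsively."""
    if dt > params.tau_c:
        raise ValueError("dt must not exceed tau_c")
    trace.C *= 1.0 - dt / params.tau_c
    if events.idx_hi.size:
        trace.C[events.idx_hi] += events.alpha
    if events.idx_lo.size:
        trace.C[events.idx_lo] -= events.beta
    return trace


def update_modulation(
    trace: TraceState, reward_r: float, params: PlasticityParams, dt: float
) -> TraceState:
    """One Euler step of dm/dt = -m/tau_m + lambda*r + b."""
    trace.m = trace.m * (1.0 - dt / params.tau_m) + (
        params.lambda_gain * reward_r + params.baseline_b
    ) * dt
    return trace


def apply_weight_update(
    weights: np.ndarray,
    n_plastic: int,
    trace: TraceState,
    dt: float,
    weight_min: float,
    weight_max: float,
) -> np.ndarray:
    """One Euler step of dw/dt = m*c on the plastic prefix, with clipping.

    Fixed synapses (entries beyond ``n_plastic``) are untouched; with
    m = 0 the array is returned bit-identical.
    """
    if trace.m != 0.0:
        w = weights[:n_plastic]
        w += trace.m * dt * trace.C[:n_plastic]
        np.clip(w, weight_min, weight_max, out=w)
    return weights


def plasticity_step(
    net: NetworkState, plast: PlasticityState, reward_r: float
) -> RchpEvents:
    """Run one full learning step against a freshly stepped network.

    Order: detect correlations on the lagged outputs, adapt thresholds,
    integrate traces, integrate modulation (so a reward arriving this
    step acts on this step's weight change), then update weights.
    """
    p = plast.params
    dt = net.params.dt
    events = detect_correlations(
        net.v_prev, net.v, net.syn_pre, net.syn_post, plast.thresholds, p
    )
    update_thresholds(
        plast.thresholds, events.n_corr, events.n_decorr, net.n_synapses, p, dt
    )
    update_traces(plast.trace, events, p, dt)
    update_modulation(plast.trace, reward_r, p, dt)
    apply_weight_update(
        net.weights, net.n_plastic, plast.trace, dt,
        net.params.weight_min, net.params.weight_max,
    )
    return events
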