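"""Rate-based neural substrate.

A network of excitatory and inhibitory rate neurons with random sparse
connectivity.  Neuron ``i`` integrates its presynaptic outputs,

    u_i(t) = sum_j w_ji * v_j(t) * kappa_j,

where ``kappa_j`` is +1 for excitatory and -5 for inhibitory presynaptic
neurons, and emits

    v_i(t + dt) = tanh(gamma * u_i) + xi_i    if u_i >= 0
                  xi_i                        otherwise,

with ``xi_i`` fresh uniform noise in [-noise_halfwidth, +noise_halfwidth].
One sampling step ``dt`` is also the synaptic propagation time, so the
lagged product v_j(t - dt) * v_i(t) used by the plasticity rule spans
exactly one step.

Stimuli and actions are mediated by disjoint 60-neuron groups of excitatory
neurons.  Input-group members receive no connections from the network
(their state is set purely by external drive) and output-group members
project none back into it; this prevents self-sustained activity under
the long, persistent stimuli these simulations use.

Synapses are stored as a ``scipy.sparse`` CSR matrix ``A`` with
``A[i, j] = w_ji`` (row = postsynaptic neuron).  Excitatory neurons occupy
indices ``0 .. n_excitatory-1``, so the plastic synapses — afferents of
excitatory neurons — form a contiguous prefix of ``A.data``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NetworkParams",
    "NeuronGroup",
    "NetworkState",
    "build_network",
    "step_network",
    "group_activity",
]


@dataclass
class NetworkParams:
    """Structural and dynamical constants of the neural substrate.

    All defaults are the values used by the conditioning experiments:
    800 excitatory + 200 inhibitory neurons, connection probability 0.1,
    a 200-ms sampling/propagation step, and an external drive of +10 to
    the state of every member of an active stimulus group.
    """

    n_excitatory: int = 800
    n_inhibitory: int = 200
    connect_prob: float = 0.1
    gain_gamma: float = 0.5
    kappa_excitatory: float = 1.0
    kappa_inhibitory: float = -5.0
    noise_halfwidth: float = 0.1
    dt: float = 0.2
    weight_min: float = 0.0
    weight_max: float = 1.0
    input_drive: float = 10.0
    group_size: int = 60
    #: upper bound of the uniform distribution of initial weights; kept small
    #: so that pre-learning responses to a driven group stay noise-dominated,
    #: which is what makes off-pathway correlation/decorrelation events cancel
    init_weight_max: float = 0.05  # see docs/methods.md

    def __post_init__(self) -> None:
        if self.n_excitatory < 0 or self.n_inhibitory < 0:
            raise ValueError("neuron counts must be non-negative")
        if not (0.0 <= self.connect_prob <= 1.0):
            raise ValueError("connect_prob must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.weight_min >= self.weight_max:
            raise ValueError("weight_min must be below weight_max")

    @property
    def n_total(self) -> int:
        return self.n_excitatory + self.n_inhibitory


@dataclass
class NeuronGroup:
    """A set of excitatory neurons serving as one stimulus or action channel."""

    label: str
    role: str  # "input" or "output"
    members: np.ndarray  # sorted excitatory neuron indices

    def __post_init__(self) -> None:
        if self.role not in ("input", "output"):
            raise ValueError(f"unknown group role {self.role!r}")
        self.members = np.asarray(self.members, dtype=np.int64)


@dataclass
class NetworkState:
    """Full dynamical state of the substrate.

    ``A.data``, ``syn_pre`` and ``syn_post`` are parallel arrays over the
    existing directed synapses in CSR (postsynaptic-major) order; the
    first ``n_plastic`` entries are the plastic synapses.
    """

    params: NetworkParams
    A: sp.csr_matrix            # A[i, j] = w_ji
    syn_pre: np.ndarray         # presynaptic index j per synapse
    syn_post: np.ndarray        # postsynaptic index i per synapse
    n_plastic: int              # synapses into excitatory neurons (data prefix)
    kappa: np.ndarray           # per-neuron sign/magnitude factor
    u: np.ndarray               # neuron state
    v: np.ndarray               # neuron output
    v_prev: np.ndarray          # output one step earlier
    groups: dict = field(default_factory=dict)  # label -> NeuronGroup
    time: float = 0.0

    @property
    def weights(self) -> np.ndarray:
        """Flat synapse weight array (view onto the CSR data)."""
        return self.A.data

    @property
    def n_synapses(self) -> int:
        return self.A.nnz

    def group(self, label: str) -> NeuronGroup:
        return self.groups[label]


def build_network(
    params: NetworkParams,
    group_spec: list[tuple[str, str]],
    rng: np.random.Generator,
) -> NetworkState:
    """Construct a randomly connected network with stimulus/action groups.

    Each ordered neuron pair (j, i), j != i, is connected with probability
    ``connect_prob``, excluding connections into input-group members and
    out of output-group members.  Initial weights (plastic and fixed alike)
    are uniform on [0, init_weight_max].  Group memberships are sampled
    without replacement from the excitatory pool, so groups are disjoint.

    Parameters
    ----------
    group_spec
        List of ``(label, role)`` pairs, role in {"input", "output"}.
    """
    n = params.n_total
    n_exc = params.n_excitatory
    demand = len(group_spec) * params.group_size
    if demand > n_exc:
        raise ValueError(
            f"group demand {demand} exceeds excitatory pool of {n_exc}"
        )
    chosen = rng.choice(n_exc, size=demand, replace=False)
    groups: dict[str, NeuronGroup] = {}
    for k, (label, role) in enumerate(group_spec):
        members = np.sort(chosen[k * params.group_size : (k + 1) * params.group_size])
        groups[label] = NeuronGroup(label=label, role=role, members=members)

    conn = rng.random((n, n)) < params.connect_prob
    np.fill_diagonal(conn, False)
    for g in groups.values():
        if g.role == "input":
            conn[g.members, :] = False   # no afferents into input members
        else:
            conn[:, g.members] = False   # no efferents out of output members

    A = sp.csr_matrix(conn)
    A.data = rng.uniform(0.0, params.init_weight_max, size=A.nnz)
    syn_pre = A.indices.astype(np.int64)
    syn_post = np.repeat(np.arange(n, dtype=np.int64), np.diff(A.indptr))
    n_plastic = int(A.indptr[n_exc])

    kappa = np.empty(n)
    kappa[:n_exc] = params.kappa_excitatory
    kappa[n_exc:] = params.kappa_inhibitory

    zeros = np.zeros(n)
    return NetworkState(
        params=params,
        A=A,
        syn_pre=syn_pre,
        syn_post=syn_post,
        n_plastic=n_plastic,
        kappa=kappa,
        u=zeros.copy(),
        v=zeros.copy(),
        v_prev=zeros.copy(),
        groups=groups,
    )


def step_network(
    state: NetworkState,
    active_input_groups: set[str] | frozenset[str] = frozenset(),
    action_feedback: tuple[str, list[str]] | None = None,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the substrate by one sampling step (in place).

    Order within a step: (1) integrate the previous outputs into u,
    (2) add +input_drive to members of each active input group and
    apply winner/loser action feedback of +/-input_drive, (3) emit the
    new outputs.  Returns the same (mutated) state.

    Parameters
    ----------
    action_feedback
        Optional ``(winner_label, loser_labels)`` applied while an action
        is being enunciated: the winner group's states are raised by
        ``input_drive`` and every loser group's lowered by the same amount.
    """
    if rng is None:
        raise ValueError("an explicit random generator is required")
    p = state.params
    u = state.A @ (state.kappa * state.v)
    for label in active_input_groups:
        u[state.groups[label].members] += p.input_drive
    if action_feedback is not None:
        winner, losers = action_feedback
        u[state.groups[winner].members] += p.input_drive
        for label in losers:
            u[state.groups[label].members] -= p.input_drive
    noise = rng.uniform(-p.noise_halfwidth, p.noise_halfwidth, size=u.shape)
    v_new = np.where(u >= 0.0, np.tanh(p.gain_gamma * u) + noise, noise)
    state.v_prev = state.v
    state.v = v_new
    state.u = u
    state.time += p.dt
    return state


def group_activity(v: np.ndarray, group: NeuronGroup) -> float:
    """Mean output of the group's members (the macroscopic channel readout)."""
    if group.members.size == 0:
        raise ValueError(f"group {group.label!r} is empty")
    return float(v[group.members].mean())
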