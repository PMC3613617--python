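"""Abstract model of credit assignment by rare correlations.

A population of N synapses; one designated synapse sigma triggers every
reward.  Network-wide correlations tag a fraction ``corr_rate`` of
synapses per second with eligibility traces that are negligible after
``eligibility_horizon`` seconds, so at any time a fraction

    p = corr_rate * eligibility_horizon

of the synapses is eligible.  Each delayed reward therefore reinforces
about N*p synapses — sigma plus a random crowd.  Synapses reinforced at
every one of k consecutive episodes number about N*p^k in expectation:
the crowd thins geometrically while sigma survives by construction, so a
handful of episodes suffices to single out the reward-triggering synapse.

The Monte-Carlo treats episodes as independent eligibility draws over
synapses (hard eligibility window), which is the abstraction behind the
closed-form attrition arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ToyConfig",
    "ToyEpisodeRecord",
    "expected_eligible",
    "expected_consecutive",
    "run_toy",
    "attrition_table",
]


@dataclass
class ToyConfig:
    n_synapses: int = 100_000
    corr_rate: float = 0.01          # fraction of synapses tagged per second
    trace_tau: float = 1.0           # trace decay time constant [s]
    eligibility_horizon: float = 3.0  # traces negligible beyond this [s]
    reward_delay_range: tuple = (1.0, 3.0)
    sigma_index: int = 0
    n_episodes: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.sigma_index < self.n_synapses):
            raise ValueError("sigma_index out of range")
        if self.corr_rate * self.eligibility_horizon > 1.0:
            raise ValueError("eligible fraction would exceed 1")

    @property
    def eligible_fraction(self) -> float:
        return self.corr_rate * self.eligibility_horizon


def expected_eligible(config: ToyConfig) -> float:
    """Expected number of synapses eligible at any instant: N * rate * horizon."""
    return config.n_synapses * config.eligible_fraction


def expected_consecutive(config: ToyConfig, k: int) -> float:
    """Expected non-sigma synapses eligible at k consecutive reward episodes.

    With eligible fraction p per episode and independent episodes this is
    N * p^k (k = 1 reduces to the instantaneous eligible count).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    return config.n_synapses * config.eligible_fraction ** k


@dataclass
class ToyEpisodeRecord:
    """Per-episode attrition record of one replication."""

    eligible_counts: list = field(default_factory=list)     # per episode
    survivor_counts: list = field(default_factory=list)     # non-sigma survivors
    sigma_survived: list = field(default_factory=list)      # always True


def run_toy(config: ToyConfig, rng: np.random.Generator) -> ToyEpisodeRecord:
    """Simulate the per-episode eligible sets and the survivor attrition.

    Per episode each non-sigma synapse is eligible independently with
    probability p = corr_rate * eligibility_horizon; sigma is always
    eligible because its activity triggers the reward.  Survivors after
    episode k are the synapses eligible in all episodes 1..k.  The
    eligible-set size is drawn from its exact Binomial marginal and the
    survivor set by Bernoulli thinning of the previous survivors, which
    is distributionally identical to drawing full eligibility masks.
    """
    if config.n_episodes < 1:
        raise ValueError("need at least one episode")
    p = config.eligible_fraction
    rec = ToyEpisodeRecord()
    n_other = config.n_synapses - 1
    survivors = n_other
    for _ in range(config.n_episodes):
        n_eligible = 1 + int(rng.binomial(n_other, p))   # sigma + random crowd
        survivors = int(rng.binomial(survivors, p))
        rec.eligible_counts.append(n_eligible)
        rec.survivor_counts.append(survivors)
        rec.sigma_survived.append(True)
    return rec


def attrition_table(
    config: ToyConfig, n_replications: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Analytic vs. simulated survivor counts per episode.

    Columns: episode k, the closed-form expectation N*p^k, and the mean /
    median / std of the simulated non-sigma survivor counts over
    replications.
    """
    counts = np.empty((n_replications, config.n_episodes))
    eligible = np.empty((n_replications, config.n_episodes))
    for r in range(n_replications):
        rec = run_toy(config, rng)
        counts[r] = rec.survivor_counts
        eligible[r] = rec.eligible_counts
    rows = []
    for k in range(1, config.n_episodes + 1):
        rows.append(
            {
                "episode": k,
                "expected_survivors": expected_consecutive(config, k),
                "mean_survivors": counts[:, k - 1].mean(),
                "median_survivors": float(np.median(counts[:, k - 1])),
                "std_survivors": counts[:, k - 1].std(ddof=1),
                "mean_eligible": eligible[:, k - 1].mean(),
            }
        )
    return pd.DataFrame(rows)
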