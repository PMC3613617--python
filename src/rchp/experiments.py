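"""Multi-run experiments and their headline measurements.

These wrap the single-run scenarios into the repeated protocols whose
outcomes summarize the model: CS-pathway dominance counts over
independent classical runs, color-learning times over operant runs, and
the delay-capacity sweep (the largest post-stimulus reward delay at
which conditioning still succeeds in a majority of seeds).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .network import NetworkParams
from .plasticity import PlasticityParams
from .recording import Recording, learned_at_times
from .scenarios import ClassicalConfig, OperantConfig, classical_experiment, operant_experiment

__all__ = [
    "derive_seeds",
    "cs_dominant",
    "classical_dominance",
    "operant_learning_times",
    "delay_capacity_sweep",
]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Independent per-run seeds derived from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def cs_dominant(recording: Recording) -> bool:
    """Did the CS pathway end strictly above every disturbing pathway?"""
    cs = recording.meta["cs_pathway"]
    final = recording.pathways.iloc[-1]
    others = [c for c in recording.pathways.columns if c not in ("time", cs)]
    return bool(all(final[cs] > final[c] for c in others))


def classical_dominance(
    n_runs: int,
    base_seed: int,
    config: ClassicalConfig | None = None,
    net_params: NetworkParams | None = None,
    plast_params: PlasticityParams | None = None,
) -> dict:
    """Run independent classical scenarios and count CS-dominant outcomes."""
    config = config or ClassicalConfig()
    seeds = derive_seeds(base_seed, n_runs)
    dominant = []
    final_cs = []
    for seed in seeds:
        rec = classical_experiment(seed, config, net_params, plast_params)
        dominant.append(cs_dominant(rec))
        final_cs.append(float(rec.pathways.iloc[-1][rec.meta["cs_pathway"]]))
    return {
        "n_runs": n_runs,
        "seeds": seeds,
        "dominant": dominant,
        "n_dominant": int(sum(dominant)),
        "final_cs_strengths": final_cs,
    }


def operant_learning_times(
    n_runs: int,
    base_seed: int,
    config: OperantConfig | None = None,
    net_params: NetworkParams | None = None,
    plast_params: PlasticityParams | None = None,
) -> dict:
    """Per-run times by which every color was learned (correct thereafter).

    A run's time is the latest learned-at time over its colors; a run in
    which some color is never learned reports the run horizon.
    """
    config = config or OperantConfig()
    seeds = derive_seeds(base_seed, n_runs)
    per_run = []
    all_learned = []
    for seed in seeds:
        rec = operant_experiment(seed, config, net_params, plast_params)
        learned = learned_at_times(rec)
        ok = all(t is not None for t in learned.values()) and len(learned) == config.n_colors
        all_learned.append(bool(ok))
        per_run.append(
            max(learned.values()) if ok else config.total_time
        )
    return {
        "n_runs": n_runs,
        "seeds": seeds,
        "all_learned": all_learned,
        "learned_by_seconds": per_run,
        "max_learned_by_seconds": float(max(per_run)),
    }


def delay_capacity_sweep(
    delays: list[float],
    n_seeds: int = 5,
    base_seed: int = 0,
    total_time: float = 2400.0,
    config: ClassicalConfig | None = None,
    net_params: NetworkParams | None = None,
    plast_params: PlasticityParams | None = None,
) -> dict:
    """Sweep fixed post-offset reward delays in the brief-stimulus scenario.

    For each delay d, run ``n_seeds`` independent brief-stimulus classical
    runs with the reward fixed at d seconds after CS offset, and record
    the fraction of runs in which the CS pathway ends dominant.  The
    reported capacity is the largest swept delay with a strict-majority
    success fraction.
    """
    base_cfg = config or ClassicalConfig(total_time=total_time, brief_variant=True)
    success_fraction: dict[float, float] = {}
    per_delay: dict[float, list[bool]] = {}
    for i, d in enumerate(delays):
        cfg = replace(base_cfg, brief_variant=True, fixed_reward_delay=float(d))
        res = classical_dominance(
            n_seeds, base_seed + 1000 * i, cfg, net_params, plast_params
        )
        per_delay[d] = res["dominant"]
        success_fraction[d] = res["n_dominant"] / n_seeds
    reliable = [d for d in delays if success_fraction[d] > 0.5]
    return {
        "delays": list(delays),
        "n_seeds": n_seeds,
        "success_fraction": success_fraction,
        "per_delay_dominant": per_delay,
        "max_reliable_delay": max(reliable) if reliable else None,
    }
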