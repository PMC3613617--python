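"""Measurement and run summaries.

The macroscopic readout of learning is the *pathway strength*: the mean
weight over the existing synapses from one stimulus group to one action
group.  A ``Recording`` collects, for one closed-loop run, the per-step
scalar series (modulation, group activities, correlation rate, thresholds),
the per-second pathway-strength series, and the discrete event log
(stimulus on/off, rewards, actions, conditioned responses).
``summarize_runs`` reduces a set of recordings to box-plot statistics per
time bin plus per-run verdicts (CS dominance, per-color learned-at times,
reversal phase boundaries).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkState, NeuronGroup

__all__ = [
    "Recording",
    "RunSummary",
    "pathway_strength",
    "pathway_synapse_indices",
    "summarize_runs",
    "learned_at_times",
    "segment_reversal",
]


def pathway_synapse_indices(
    state: NetworkState, from_group: NeuronGroup, to_group: NeuronGroup
) -> np.ndarray:
    """Indices (into the flat synapse arrays) of the from->to synapses."""
    n = state.params.n_total
    in_from = np.zeros(n, dtype=bool)
    in_from[from_group.members] = True
    in_to = np.zeros(n, dtype=bool)
    in_to[to_group.members] = True
    return np.flatnonzero(in_from[state.syn_pre] & in_to[state.syn_post])


def pathway_strength(
    state: NetworkState,
    from_group: NeuronGroup | str,
    to_group: NeuronGroup | str,
) -> float:
    """Mean weight over existing synapses from one group to another.

    Absent synapses are excluded from the mean.  A pathway with no
    existing synapse is reported as 0 with a warning; identical groups
    are an error (no within-group pathway is defined).
    """
    if isinstance(from_group, str):
        from_group = state.groups[from_group]
    if isinstance(to_group, str):
        to_group = state.groups[to_group]
    if from_group.label == to_group.label:
        raise ValueError("pathway requires two distinct groups")
    idx = pathway_synapse_indices(state, from_group, to_group)
    if idx.size == 0:
        warnings.warn(
            f"no synapses exist from {from_group.label} to {to_group.label}",
            stacklevel=2,
        )
        return 0.0
    return float(state.weights[idx].mean())


@dataclass
class Recording:
    """Time series, pathway series, and event log of one run."""

    scalars: pd.DataFrame          # per-step: time, m, corr_rate, theta_hi, ...
    pathways: pd.DataFrame         # per-second: time + one column per pathway
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def events_of(self, kind: str) -> list:
        return [e for e in self.events if e["type"] == kind]

    # ---- persistence (plain-text formats) --------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.scalars.to_csv(d / "scalars.csv", index=False)
        self.pathways.to_csv(d / "pathways.csv", index=False)
        with open(d / "events.jsonl", "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")
        with open(d / "meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, default=str)

    @classmethod
    def load(cls, directory: str | Path) -> "Recording":
        d = Path(directory)
        events = []
        with open(d / "events.jsonl") as fh:
            for line in fh:
                if line.strip():
                    events.append(json.loads(line))
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
        return cls(
            scalars=pd.read_csv(d / "scalars.csv"),
            pathways=pd.read_csv(d / "pathways.csv"),
            events=events,
            meta=meta,
        )

    def equals(self, other: "Recording", atol: float = 1e-9) -> bool:
        """Field-by-field comparison (numeric columns to round-trip precision)."""
        for a, b in ((self.scalars, other.scalars), (self.pathways, other.pathways)):
            if list(a.columns) != list(b.columns) or a.shape != b.shape:
                return False
            if not np.allclose(a.to_numpy(float), b.to_numpy(float), atol=atol):
                return False
        return self.events == other.events and self.meta == other.meta


def learned_at_times(recording: Recording) -> dict[str, float | None]:
    """Earliest time per stimulus after which every trial is answered correctly.

    A stimulus counts as learned at time T if its trial at T and all its
    subsequent trials chose the rewarded action.  Returns None for a
    stimulus whose final trial is incorrect (never learned within the run).
    """
    trials: dict[str, list] = {}
    for e in recording.events_of("action"):
        trials.setdefault(e["stimulus"], []).append(e)
    out: dict[str, float | None] = {}
    for stim, evs in trials.items():
        evs.sort(key=lambda e: e["time"])
        learned: float | None = None
        for e in evs:
            if e["correct"]:
                if learned is None:
                    learned = e["time"]
            else:
                learned = None
        out[stim] = learned
    return out


def segment_reversal(
    recording: Recording, convergence_tol: float = 0.05
) -> dict[str, tuple[float, float]]:
    """Segment a reversal run into its four behavioral phases.

    Operational boundaries, for the reversed stimulus:

    * ``exploit_old``: from the policy switch until the first trial on
      which the previously rewarded action is NOT chosen.  Punishments
      already erode the old pathway during this phase; the behavioral
      switch lags the weight decline.
    * ``converge``: until the old pathway first stops being strictly
      dominant, i.e. its strength exceeds the best other pathway by less
      than ``convergence_tol``.
    * ``explore``: until the first trial of the final consecutive run of
      new-action choices (may be brief — a single rewarded guess can
      re-establish exploitation).
    * ``exploit_new``: the remainder of the run.
    """
    rev = recording.meta.get("reversal")
    if rev is None:
        raise ValueError("recording has no reversal metadata")
    switch = float(rev["switch_time"])
    stim, old_action = rev["stimulus"], rev["old_action"]
    new_action = rev["new_action"]
    end = float(recording.scalars["time"].iloc[-1])

    trials = sorted(
        (e for e in recording.events_of("action") if e["stimulus"] == stim),
        key=lambda e: e["time"],
    )
    post = [e for e in trials if e["time"] >= switch]

    t1 = end
    for e in post:
        if e["action"] != old_action:
            t1 = e["time"]
            break

    old_col = f"{stim}->{old_action}"
    other_cols = [
        c for c in recording.pathways.columns
        if c.startswith(f"{stim}->") and c != old_col
    ]
    pw = recording.pathways
    t2 = end
    after = pw["time"].to_numpy() >= switch
    if other_cols and old_col in pw.columns and after.any():
        margin = (
            pw.loc[after, old_col].to_numpy()
            - pw.loc[after, other_cols].to_numpy().max(axis=1)
        )
        hit = np.flatnonzero(margin < convergence_tol)
        if hit.size:
            t2 = float(pw.loc[after, "time"].to_numpy()[hit[0]])
    t2 = max(t2, t1)

    t3 = end
    streak_start = None
    for e in post:
        if e["action"] == new_action:
            if streak_start is None:
                streak_start = e["time"]
        else:
            streak_start = None
    if streak_start is not None:
        t3 = streak_start
    t3 = max(t3, t2)

    return {
        "exploit_old": (switch, t1),
        "converge": (t1, t2),
        "explore": (t2, t3),
        "exploit_new": (t3, end),
    }


@dataclass
class RunSummary:
    """Aggregate statistics and verdicts over a set of runs."""

    pathway_stats: pd.DataFrame     # bin_start x pathway -> median/q25/q75/lo/hi
    verdicts: list = field(default_factory=list)   # one dict per run
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "meta": self.meta,
            "verdicts": self.verdicts,
            "pathway_stats": self.pathway_stats.to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_runs(recordings: list[Recording], bin_seconds: float = 180.0) -> RunSummary:
    """Box-plot statistics per time bin plus per-run verdicts.

    Each run contributes its within-bin mean pathway strength; the
    median, quartiles and extremes are then taken across runs, per bin
    and pathway (the statistics a box plot over independent runs shows).
    """
    if not recordings:
        raise ValueError("no recordings to summarize")
    cols = [c for c in recordings[0].pathways.columns if c != "time"]
    rows = []
    binned = []
    for rec in recordings:
        pw = rec.pathways.copy()
        pw["bin"] = (pw["time"] // bin_seconds) * bin_seconds
        binned.append(pw.groupby("bin")[cols].mean())
    stacked = pd.concat(binned, keys=range(len(binned)), names=["run"])
    for (b), grp in stacked.groupby(level="bin"):
        for c in cols:
            vals = grp[c].to_numpy()
            rows.append(
                {
                    "bin_start": float(b),
                    "pathway": c,
                    "median": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                    "lo": float(vals.min()),
                    "hi": float(vals.max()),
                    "n": int(vals.size),
                }
            )
    stats = pd.DataFrame(rows)

    verdicts = []
    for k, rec in enumerate(recordings):
        v: dict = {"run": k, "seed": rec.meta.get("seed")}
        cs = rec.meta.get("cs_pathway")
        if cs is not None and cs in rec.pathways.columns:
            final = rec.pathways.iloc[-1]
            others = [c for c in cols if c != cs]
            v["cs_dominant"] = bool(
                all(final[cs] > final[c] for c in others)
            )
            v["final_cs_strength"] = float(final[cs])
        if rec.events_of("action"):
            learned = learned_at_times(rec)
            v["learned_at"] = learned
            if all(t is not None for t in learned.values()) and learned:
                v["all_learned_by"] = max(learned.values())
            else:
                v["all_learned_by"] = None
        if rec.meta.get("reversal") is not None:
            v["reversal_phases"] = segment_reversal(rec)
        verdicts.append(v)

    meta = {"n_runs": len(recordings), "bin_seconds": bin_seconds}
    return RunSummary(pathway_stats=stats, verdicts=verdicts, meta=meta)
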