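"""State snapshots and configuration files.

Network + plasticity state round-trips through a single HDF5 file
(weights, sparse topology, traces, thresholds, modulation, groups), so a
long run can be resumed or inspected offline.  Scenario and model
parameters load from plain YAML mappings keyed by section.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
import yaml

from .network import NetworkParams, NetworkState, NeuronGroup
from .plasticity import PlasticityParams, PlasticityState, ThresholdState, TraceState

__all__ = [
    "save_state",
    "load_state",
    "load_config",
    "config_hash",
]


def save_state(
    path: str | Path, net: NetworkState, plast: PlasticityState | None = None
) -> None:
    """Write the full dynamical state to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["time"] = net.time
        f.attrs["n_plastic"] = net.n_plastic
        f.attrs["params"] = json.dumps(asdict(net.params))
        f.create_dataset("weights", data=net.A.data)
        f.create_dataset("indices", data=net.A.indices)
        f.create_dataset("indptr", data=net.A.indptr)
        f.create_dataset("u", data=net.u)
        f.create_dataset("v", data=net.v)
        f.create_dataset("v_prev", data=net.v_prev)
        g = f.create_group("groups")
        for label, grp in net.groups.items():
            d = g.create_dataset(label, data=grp.members)
            d.attrs["role"] = grp.role
        if plast is not None:
            p = f.create_group("plasticity")
            p.attrs["params"] = json.dumps(asdict(plast.params))
            p.attrs["m"] = plast.trace.m
            p.attrs["theta_hi"] = plast.thresholds.theta_hi
            p.attrs["theta_lo"] = plast.thresholds.theta_lo
            p.create_dataset("C", data=plast.trace.C)
            for name, q in (
                ("corr_queue", plast.thresholds.corr_queue),
                ("decorr_queue", plast.thresholds.decorr_queue),
            ):
                d = p.create_dataset(name, data=q.buf)
                d.attrs["pos"] = q.pos
                d.attrs["filled"] = q.filled


def load_state(path: str | Path) -> tuple[NetworkState, PlasticityState | None]:
    """Reload a snapshot written by :func:`save_state`."""
    with h5py.File(path, "r") as f:
        params = NetworkParams(**json.loads(f.attrs["params"]))
        n = params.n_total
        A = sp.csr_matrix(
            (f["weights"][:], f["indices"][:], f["indptr"][:]), shape=(n, n)
        )
        syn_pre = A.indices.astype(np.int64)
        syn_post = np.repeat(np.arange(n, dtype=np.int64), np.diff(A.indptr))
        groups = {}
        for label in f["groups"]:
            d = f["groups"][label]
            groups[label] = NeuronGroup(
                label=label, role=d.attrs["role"], members=d[:]
            )
        kappa = np.empty(n)
        kappa[: params.n_excitatory] = params.kappa_excitatory
        kappa[params.n_excitatory :] = params.kappa_inhibitory
        net = NetworkState(
            params=params,
            A=A,
            syn_pre=syn_pre,
            syn_post=syn_post,
            n_plastic=int(f.attrs["n_plastic"]),
            kappa=kappa,
            u=f["u"][:],
            v=f["v"][:],
            v_prev=f["v_prev"][:],
            groups=groups,
            time=float(f.attrs["time"]),
        )
        plast = None
        if "plasticity" in f:
            p = f["plasticity"]
            pparams = PlasticityParams(**json.loads(p.attrs["params"]))
            thr = ThresholdState.create(pparams, params.dt)
            thr.theta_hi = float(p.attrs["theta_hi"])
            thr.theta_lo = float(p.attrs["theta_lo"])
            for name, q in (("corr_queue", thr.corr_queue), ("decorr_queue", thr.decorr_queue)):
                q.buf[:] = p[name][:]
                q.pos = int(p[name].attrs["pos"])
                q.filled = int(p[name].attrs["filled"])
                q.total = int(q.buf.sum())
            trace = TraceState(C=p["C"][:], m=float(p.attrs["m"]))
            plast = PlasticityState(thresholds=thr, trace=trace, params=pparams)
    return net, plast


_SECTIONS = {
    "network": NetworkParams,
    "plasticity": PlasticityParams,
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config; 'network'/'plasticity' sections become dataclasses.

    Any other top-level section (e.g. scenario settings) is passed
    through as a plain mapping for the caller to interpret.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    for key, value in raw.items():
        cls = _SECTIONS.get(key)
        if cls is not None:
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            out[key] = cls(**value)
        else:
            out[key] = value
    return out


def config_hash(*objects) -> str:
    """Stable short hash stamped into run metadata for reproducibility."""
    blob = json.dumps(
        [asdict(o) if hasattr(o, "__dataclass_fields__") else o for o in objects],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
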