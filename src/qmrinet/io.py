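"""Array-container I/O: one NPZ convention shared by every artifact.

Dictionaries, subspace bases, CRB tables and network checkpoints are stored
as NPZ files with a JSON ``meta`` entry carrying provenance (config values,
seeds, package version).  Reports are CSV/JSON; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import MLP, NetworkSpec
from .subspace import SubspaceBasis

__all__ = [
    "save_container",
    "load_container",
    "save_network",
    "load_network",
    "save_basis",
    "load_basis",
]


def save_container(path, meta: dict | None = None, **arrays) -> None:
    """Write arrays plus a JSON metadata record atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "wb") as fh:  # file handle: savez must not append an extension
        np.savez(fh, meta=json.dumps(meta or {}), **arrays)
    tmp.replace(path)


def load_container(path) -> tuple[dict, dict]:
    """Return ``(arrays, meta)``."""
    with np.load(path, allow_pickle=False) as data:
        arrays = {k: data[k] for k in data.files if k != "meta"}
        meta = json.loads(str(data["meta"])) if "meta" in data.files else {}
    return arrays, meta


def save_basis(path, basis: SubspaceBasis, meta: dict | None = None) -> None:
    save_container(path, meta=meta, u=basis.u, singular_values=basis.singular_values,
                   rank=np.array(basis.rank))


def load_basis(path) -> SubspaceBasis:
    arrays, _ = load_container(path)
    return SubspaceBasis(u=arrays["u"], singular_values=arrays["singular_values"],
                         rank=int(arrays["rank"]))


def save_network(path, net: MLP, meta: dict | None = None) -> None:
    spec = net.spec
    arrays = {}
    for i, (w, b) in enumerate(zip(net.weights, net.biases)):
        arrays[f"w{i}"], arrays[f"b{i}"] = w, b
    for i, (g, b, m, v) in enumerate(zip(net.gamma, net.beta, net.run_mean, net.run_var)):
        arrays[f"bn_gamma{i}"], arrays[f"bn_beta{i}"] = g, b
        arrays[f"bn_mean{i}"], arrays[f"bn_var{i}"] = m, v
    meta = dict(meta or {})
    meta["spec"] = {
        "input_dim": spec.input_dim,
        "hidden_widths": list(spec.hidden_widths),
        "output_dim": spec.output_dim,
        "output_caps": list(spec.output_caps),
        "batch_norm": spec.batch_norm,
    }
    save_container(path, meta=meta, **arrays)


def load_network(path) -> MLP:
    arrays, meta = load_container(path)
    s = meta["spec"]
    spec = NetworkSpec(
        input_dim=s["input_dim"], hidden_widths=tuple(s["hidden_widths"]),
        output_dim=s["output_dim"], output_caps=tuple(s["output_caps"]),
        batch_norm=s["batch_norm"],
    )
    net = MLP(spec, seed=0)
    n_layers = len(net.weights)
    net.weights = [arrays[f"w{i}"] for i in range(n_layers)]
    net.biases = [arrays[f"b{i}"] for i in range(n_layers)]
    if spec.batch_norm:
        n_h = len(spec.hidden_widths)
        net.gamma = [arrays[f"bn_gamma{i}"] for i in range(n_h)]
        net.beta = [arrays[f"bn_beta{i}"] for i in range(n_h)]
        net.run_mean = [arrays[f"bn_mean{i}"] for i in range(n_h)]
        net.run_var = [arrays[f"bn_var{i}"] for i in range(n_h)]
    return net


def save_report(path, report: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, index=False)
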