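"""YAML configuration loading and network checkpointing.

A config file holds up to five blocks — ``network:``, ``encoding:``,
``schedule:``, ``data:`` and ``experiment:`` — each mapping directly onto
the corresponding dataclass/constructor keywords.  Checkpoints are JSON
documents carrying the network config and both weight matrices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .curiosity import ScheduleConfig
from .data_io import LabeledDataset, read_csv_dataset, read_idx, synth_clusters
from .lif_core import NeuronParams
from .network import Network, NetworkConfig, SynapseMatrix

__all__ = ["load_config", "build_network_config", "build_schedule",
           "build_dataset", "save_checkpoint", "load_checkpoint"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of blocks")
    return cfg


def build_network_config(block: dict, n_inputs: int, n_classes: int,
                         seed: int) -> NetworkConfig:
    block = dict(block or {})
    neuron = NeuronParams(**block.pop("neuron", {}))
    sizes = block.pop("layer_sizes", None)
    hidden = block.pop("hidden", None)
    if sizes is None:
        sizes = (n_inputs, hidden or min(64, max(10, 4 * n_inputs)), n_classes)
    return NetworkConfig(layer_sizes=tuple(sizes), neuron=neuron, seed=seed,
                         **block)


def build_schedule(block: dict, **overrides: Any) -> ScheduleConfig:
    merged = {**(block or {}),
              **{k: v for k, v in overrides.items() if v is not None}}
    return ScheduleConfig(**merged)


def build_dataset(block: dict) -> LabeledDataset:
    block = dict(block or {})
    kind = block.pop("kind", "synthetic")
    if kind == "synthetic":
        return synth_clusters(**block)
    if kind == "csv":
        return read_csv_dataset(block["path"], block.get("label_column", "label"))
    if kind == "idx":
        return read_idx(block["images"], block["labels"])
    raise ValueError(f"unknown data kind {kind!r}")


def save_checkpoint(net: Network, path: str | Path) -> None:
    cfg = net.config
    doc = {
        "format": "cbsnn-checkpoint-v1",
        "config": {
            "layer_sizes": list(cfg.layer_sizes), "T": cfg.T, "dt": cfg.dt,
            "eta_i": cfg.eta_i, "eta_c": cfg.eta_c,
            "stdp_rate": cfg.stdp_rate, "w_bounds": list(cfg.w_bounds),
            "es_threshold_mode": cfg.es_threshold_mode,
            "vprime_mode": cfg.vprime_mode, "seed": cfg.seed,
            "neuron": cfg.neuron.__dict__,
        },
        "W1": net.W1.W.tolist(),
        "W2": net.W2.W.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path: str | Path) -> Network:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "cbsnn-checkpoint-v1":
        raise ValueError(f"{path}: not a cbsnn checkpoint")
    c = doc["config"]
    cfg = NetworkConfig(
        layer_sizes=tuple(c["layer_sizes"]), T=c["T"], dt=c["dt"],
        eta_i=c["eta_i"], eta_c=c["eta_c"], stdp_rate=c["stdp_rate"],
        w_bounds=tuple(c["w_bounds"]),
        es_threshold_mode=c["es_threshold_mode"],
        vprime_mode=c["vprime_mode"], seed=c["seed"],
        neuron=NeuronParams(**c["neuron"]))
    bounds = cfg.w_bounds
    return Network(cfg, SynapseMatrix(np.array(doc["W1"]), bounds),
                   SynapseMatrix(np.array(doc["W2"]), bounds))
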