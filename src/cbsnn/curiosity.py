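"""Curiosity-driven training: novelty estimation, sample selection, schedule.

The scheduler wraps the network trainer in four repeating phases:

1. For the first ``T_start`` epochs, every sample is trained and its novelty
   ``NE_k = 1 - cos(V_k, V_T)`` (cosine distance between the sample's readout
   potentials and its teacher vector) is recorded.
2. Afterwards, each epoch trains only the samples whose novelty meets the
   threshold (``NE_k >= NE_th``), refreshing their novelty from the new
   readout; unselected samples keep their stale estimate.
3. Every ``I_re`` epochs a mandatory full-dataset epoch retrains and
   re-scores everything, countering overfitting to the novel subpopulation
   and forgetting of the learned one.
4. Phases 2-3 repeat for the remaining epochs.

Computation is accounted in sample-presentations (one presentation = one
T-step window for one sample), a hardware-independent proxy for training
cost; the computation ratio of two runs is the quotient of their cumulative
presentations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import LabeledDataset
from .encoding import encode_dataset
from .network import Network, NetworkConfig, init_network, present_batch
from .plasticity import apply_updates, batch_weight_deltas

__all__ = ["ScheduleConfig", "NoveltyTable", "TrainingLog",
           "novelty_estimate", "select_samples", "epoch_kind",
           "train_cbsnn", "train_baseline", "train_random_subset",
           "computation_ratio", "evaluate"]


@dataclass(frozen=True)
class ScheduleConfig:
    """Hyperparameters of the curiosity schedule.

    Defaults are the standard operating point: one seeding epoch, novelty
    threshold 0.05, full retrain every 5 epochs.
    """

    T_start: int = 1
    NE_th: float = 0.05
    I_re: int = 5
    n_epochs: int = 20
    batch_size: int = 8
    refresh_all_novelty: bool = False
    early_stop_tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.T_start < 1:
            raise ValueError("T_start must be >= 1")
        if self.I_re < 1:
            raise ValueError("I_re must be >= 1")
        if self.n_epochs < self.T_start:
            raise ValueError("n_epochs must be >= T_start")
        if not 0 <= self.NE_th <= 2:
            raise ValueError("NE_th must lie in [0, 2], the cosine-distance range")


@dataclass
class NoveltyTable:
    """Per-sample novelty estimates plus the epoch each was last refreshed."""

    NE: np.ndarray
    last_updated: np.ndarray

    @classmethod
    def fresh(cls, n_samples: int) -> "NoveltyTable":
        # before any training every sample is maximally novel
        return cls(NE=np.full(n_samples, 2.0), last_updated=np.zeros(n_samples, int))

    def update(self, ids: np.ndarray, values: np.ndarray, epoch: int) -> None:
        self.NE[ids] = values
        self.last_updated[ids] = epoch

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": np.arange(self.NE.size),
                             "NE": self.NE, "last_updated": self.last_updated})


@dataclass
class TrainingLog:
    """Per-epoch accounting of what was trained and how well."""

    dataset_size: int
    records: list[dict] = field(default_factory=list)

    def append(self, epoch: int, kind: str, selected: int,
               loss: float, accuracy: float) -> None:
        prev = self.records[-1]["cumulative"] if self.records else 0
        self.records.append({
            "epoch": epoch, "kind": kind, "selected": selected,
            "presentations": selected, "cumulative": prev + selected,
            "loss": loss, "accuracy": accuracy})

    @property
    def n_epochs(self) -> int:
        return len(self.records)

    @property
    def cumulative_presentations(self) -> int:
        return self.records[-1]["cumulative"] if self.records else 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def novelty_estimate(V_k: np.ndarray, V_T: np.ndarray) -> float:
    """Cosine-distance novelty NE = 1 - V_k.V_T / (|V_k| |V_T|), in [0, 2].

    A silent output (|V_k| = 0) is maximally novel and scores 2.0.
    """
    V_k = np.asarray(V_k, dtype=float)
    V_T = np.asarray(V_T, dtype=float)
    nt = np.linalg.norm(V_T)
    if nt == 0:
        raise ValueError("teacher vector must have nonzero norm")
    nk = np.linalg.norm(V_k)
    if nk == 0:
        return 2.0
    ne = 1.0 - float(V_k @ V_T) / (nk * nt)
    return float(min(max(ne, 0.0), 2.0))


def _novelty_batch(V_k: np.ndarray, V_T: np.ndarray) -> np.ndarray:
    """Vectorised novelty for stacked (batch, n_out) readouts and teachers."""
    nk = np.linalg.norm(V_k, axis=1)
    nt = np.linalg.norm(V_T, axis=1)
    dot = np.einsum("ij,ij->i", V_k, V_T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = 1.0 - dot / (nk * nt)
    ne = np.where(nk == 0, 2.0, ne)
    return np.clip(ne, 0.0, 2.0)


def select_samples(table: NoveltyTable, NE_th: float) -> np.ndarray:
    """Indices of samples whose novelty meets the threshold (NE_k >= NE_th)."""
    return np.flatnonzero(table.NE >= NE_th)


def epoch_kind(e: int, e_0: int, schedule: ScheduleConfig) -> tuple[str, int]:
    """Kind of epoch ``e`` and the updated last-full-epoch marker.

    Epochs up to ``T_start`` are full (seeding); afterwards an epoch is full
    exactly when ``e - e_0 == I_re``, which also resets the marker.
    """
    if e < 1:
        raise ValueError("epochs are 1-based")
    if e <= schedule.T_start:
        return "full", schedule.T_start
    if e - e_0 == schedule.I_re:
        return "full", e
    return "selective", e_0


def _epoch_pass(net: Network, trains: np.ndarray, teachers: np.ndarray,
                labels: np.ndarray, ids: np.ndarray, epoch: int,
                seed: int, batch_size: int
                ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Train one epoch over ``ids``: shuffle, batch, present, update weights.

    Returns (ids in training order, their fresh readouts V_k, mean loss,
    training accuracy).  Weight deltas are averaged within each batch and
    applied once per batch.
    """
    rng = np.random.default_rng([seed, 1_000_003, epoch])
    order = rng.permutation(ids)
    V_ks = np.zeros((order.size, teachers.shape[1]))
    total_loss = 0.0
    correct = 0
    for start in range(0, order.size, batch_size):
        batch = order[start:start + batch_size]
        trace = present_batch(net, trains[batch], teachers[batch])
        d1, d2 = batch_weight_deltas(net.config, trace)
        net.W1 = apply_updates(net.W1, d1)
        net.W2 = apply_updates(net.W2, d2)
        V_ks[start:start + batch.size] = trace.V_k
        diff = trace.V_k - teachers[batch]
        total_loss += float(np.sum(diff * diff))
        correct += int(np.sum(np.argmax(trace.V_k, axis=1) == labels[batch]))
    mean_loss = total_loss / order.size if order.size else math.nan
    acc = correct / order.size if order.size else math.nan
    return order, V_ks, mean_loss, acc


def _prepare(dataset: LabeledDataset, config: NetworkConfig,
             encoding_mode: str, max_rate: float, seed: int,
             teacher_amplitude: float = 0.5
             ) -> tuple[Network, np.ndarray, np.ndarray]:
    n_out = config.layer_sizes[2]
    if dataset.n_samples == 0:
        raise ValueError("dataset is empty")
    if dataset.labels.max() >= n_out:
        raise ValueError(
            f"label {dataset.labels.max()} exceeds output width {n_out}")
    net = init_network(config)
    trains = encode_dataset(dataset.features, mode=encoding_mode,
                            max_rate=max_rate, duration=config.T, seed=seed)
    # teacher amplitude sits below the firing threshold so the target output
    # can hold its teacher potential without being reset by a spike; cosine
    # novelty is scale-invariant, so the amplitude does not affect NE
    teachers = np.zeros((dataset.n_samples, n_out))
    teachers[np.arange(dataset.n_samples), dataset.labels] = teacher_amplitude
    return net, trains, teachers


def train_cbsnn(dataset: LabeledDataset, net_config: NetworkConfig,
                schedule: ScheduleConfig, seed: int = 0,
                encoding_mode: str = "current", max_rate: float = 0.5,
                teacher_amplitude: float = 0.5
                ) -> tuple[Network, TrainingLog, NoveltyTable]:
    """Run the four-phase curiosity schedule over the dataset.

    Full epochs train every sample; selective epochs train only samples
    with ``NE >= NE_th``.  Every trained sample's novelty is refreshed from
    its new readout; untrained samples keep their stale value until the next
    full epoch (set ``refresh_all_novelty`` to re-score them too, at the
    presentation cost that implies — those extra scoring passes are counted
    in the log since they are presentations).
    """
    net, trains, teachers = _prepare(dataset, net_config, encoding_mode,
                                     max_rate, seed, teacher_amplitude)
    table = NoveltyTable.fresh(dataset.n_samples)
    log = TrainingLog(dataset_size=dataset.n_samples)
    e_0 = schedule.T_start
    all_ids = np.arange(dataset.n_samples)
    last_full_loss: Optional[float] = None
    for e in range(1, schedule.n_epochs + 1):
        kind, e_0 = epoch_kind(e, e_0, schedule)
        ids = all_ids if kind == "full" else select_samples(table, schedule.NE_th)
        order, V_ks, mean_loss, acc = _epoch_pass(
            net, trains, teachers, dataset.labels, ids, e,
            seed, schedule.batch_size)
        if order.size:
            table.update(order, _novelty_batch(V_ks, teachers[order]), e)
        presented = order.size
        if kind == "selective" and schedule.refresh_all_novelty:
            rest = np.setdiff1d(all_ids, order, assume_unique=False)
            if rest.size:
                trace = present_batch(net, trains[rest], teachers[rest])
                table.update(rest, _novelty_batch(trace.V_k, teachers[rest]), e)
                presented += rest.size
        log.append(e, kind, presented, mean_loss, acc)
        if kind == "full" and schedule.early_stop_tol is not None:
            if (last_full_loss is not None
                    and abs(mean_loss - last_full_loss) < schedule.early_stop_tol):
                break
            last_full_loss = mean_loss
    return net, log, table


def train_baseline(dataset: LabeledDataset, net_config: NetworkConfig,
                   n_epochs: int, seed: int = 0, batch_size: int = 8,
                   encoding_mode: str = "current", max_rate: float = 0.5,
                   teacher_amplitude: float = 0.5
                   ) -> tuple[Network, TrainingLog, NoveltyTable]:
    """Plain full-data training: every sample, every epoch (the reference
    the curiosity schedule is measured against)."""
    net, trains, teachers = _prepare(dataset, net_config, encoding_mode,
                                     max_rate, seed, teacher_amplitude)
    table = NoveltyTable.fresh(dataset.n_samples)
    log = TrainingLog(dataset_size=dataset.n_samples)
    all_ids = np.arange(dataset.n_samples)
    for e in range(1, n_epochs + 1):
        order, V_ks, mean_loss, acc = _epoch_pass(
            net, trains, teachers, dataset.labels, all_ids, e, seed, batch_size)
        table.update(order, _novelty_batch(V_ks, teachers[order]), e)
        log.append(e, "full", order.size, mean_loss, acc)
    return net, log, table


def train_random_subset(dataset: LabeledDataset, net_config: NetworkConfig,
                        n_epochs: int, subset_fraction: float, seed: int = 0,
                        batch_size: int = 8, fixed_subset: bool = False,
                        encoding_mode: str = "current", max_rate: float = 0.5,
                        teacher_amplitude: float = 0.5
                        ) -> tuple[Network, TrainingLog, NoveltyTable]:
    """Control strategy: train a uniformly random fraction of samples.

    By default a fresh subset is drawn each epoch; ``fixed_subset`` draws
    one subset up front and reuses it.
    """
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must lie in (0, 1]")
    net, trains, teachers = _prepare(dataset, net_config, encoding_mode,
                                     max_rate, seed, teacher_amplitude)
    table = NoveltyTable.fresh(dataset.n_samples)
    log = TrainingLog(dataset_size=dataset.n_samples)
    n_pick = max(1, int(round(subset_fraction * dataset.n_samples)))
    fixed = np.sort(np.random.default_rng([seed, 2_000_003]).choice(
        dataset.n_samples, n_pick, replace=False)) if fixed_subset else None
    for e in range(1, n_epochs + 1):
        if fixed is not None:
            ids = fixed
        else:
            rng = np.random.default_rng([seed, 2_000_003, e])
            ids = np.sort(rng.choice(dataset.n_samples, n_pick, replace=False))
        order, V_ks, mean_loss, acc = _epoch_pass(
            net, trains, teachers, dataset.labels, ids, e, seed, batch_size)
        table.update(order, _novelty_batch(V_ks, teachers[order]), e)
        log.append(e, "subset", order.size, mean_loss, acc)
    return net, log, table


def computation_ratio(log_cbsnn: TrainingLog, log_baseline: TrainingLog) -> float:
    """Cumulative presentations of one schedule over the reference's."""
    if log_cbsnn.n_epochs != log_baseline.n_epochs:
        raise ValueError(
            f"logs cover {log_cbsnn.n_epochs} vs {log_baseline.n_epochs} epochs")
    if log_cbsnn.dataset_size != log_baseline.dataset_size:
        raise ValueError("logs refer to different dataset sizes")
    return log_cbsnn.cumulative_presentations / log_baseline.cumulative_presentations


def evaluate(net: Network, dataset: LabeledDataset, seed: int = 0,
             encoding_mode: str = "current", max_rate: float = 0.5,
             batch_size: int = 64) -> float:
    """Classification accuracy: present without teacher, decode by argmax."""
    trains = encode_dataset(dataset.features, mode=encoding_mode,
                            max_rate=max_rate, duration=net.config.T,
                            seed=seed + 1)
    correct = 0
    for start in range(0, dataset.n_samples, batch_size):
        sl = slice(start, start + batch_size)
        trace = present_batch(net, trains[sl], None)
        correct += int(np.sum(np.argmax(trace.V_k, axis=1) == dataset.labels[sl]))
    return correct / dataset.n_samples
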