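"""Model/Results interface over the curiosity trainer.

`CBSNN` is constructed from a labelled dataset (statsmodels-style); `fit()`
trains under one of three strategies and returns a `CBSNNResults` carrying
the trained network, the per-epoch training log, the novelty table and
summary diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import curiosity
from .curiosity import (NoveltyTable, ScheduleConfig, TrainingLog,
                        computation_ratio, evaluate)
from .data_io import LabeledDataset
from .encoding import encode_dataset
from .network import Network, NetworkConfig, present_batch

__all__ = ["CBSNN", "CBSNNResults"]


class CBSNN:
    """Curiosity-based spiking neural network classifier.

    Parameters
    ----------
    dataset : LabeledDataset
        Training data, features already in [0, 1].
    net_config : NetworkConfig, optional
        Architecture and tuning rates; the output width must cover the
        label range.  When omitted, a config sized to the data is built.
    schedule : ScheduleConfig, optional
        Curiosity schedule (T_start / NE_th / I_re / n_epochs).
    encoding_mode : {'current', 'rate'}
        Input coding: deterministic constant-current injection (default,
        reproducible — suited to analog feature tables) or Bernoulli rate
        coding (Poisson-style, suited to image intensities).
    teacher_amplitude : float
        Target potential of the correct class; kept below the firing
        threshold so the clamped output is not cut down by spike resets.
    """

    def __init__(self, dataset: LabeledDataset,
                 net_config: Optional[NetworkConfig] = None,
                 schedule: Optional[ScheduleConfig] = None,
                 encoding_mode: str = "current", max_rate: float = 0.5,
                 teacher_amplitude: float = 0.5):
        self.dataset = dataset
        if net_config is None:
            hidden = min(128, max(64, 4 * dataset.n_dims))
            net_config = NetworkConfig(
                layer_sizes=(dataset.n_dims, hidden, dataset.n_classes))
        if net_config.layer_sizes[0] != dataset.n_dims:
            raise ValueError("network input width must equal feature count")
        self.net_config = net_config
        self.schedule = schedule or ScheduleConfig()
        self.encoding_mode = encoding_mode
        self.max_rate = max_rate
        self.teacher_amplitude = teacher_amplitude

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str,
                       **kwargs) -> "CBSNN":
        feats = df.drop(columns=[label_column]).to_numpy(dtype=float)
        lo, hi = feats.min(axis=0), feats.max(axis=0)
        rng = np.where(hi - lo == 0, 1.0, hi - lo)
        feats = (feats - lo) / rng
        labels, _ = pd.factorize(df[label_column])
        ds = LabeledDataset(feats, labels.astype(int), name="dataframe")
        return cls(ds, **kwargs)

    def fit(self, mode: str = "cbsnn", seed: int = 0,
            subset_fraction: float = 0.5,
            fixed_subset: bool = False) -> "CBSNNResults":
        """Train and return a results object.

        mode 'cbsnn' runs the curiosity schedule; 'baseline' trains every
        sample every epoch; 'random_subset' trains a random fraction.
        """
        cfg = self.net_config
        if cfg.seed != seed:
            cfg = NetworkConfig(**{**cfg.__dict__, "seed": seed})
        common = dict(encoding_mode=self.encoding_mode, max_rate=self.max_rate,
                      teacher_amplitude=self.teacher_amplitude)
        if mode == "cbsnn":
            net, log, table = curiosity.train_cbsnn(
                self.dataset, cfg, self.schedule, seed=seed, **common)
        elif mode == "baseline":
            net, log, table = curiosity.train_baseline(
                self.dataset, cfg, self.schedule.n_epochs, seed=seed,
                batch_size=self.schedule.batch_size, **common)
        elif mode == "random_subset":
            net, log, table = curiosity.train_random_subset(
                self.dataset, cfg, self.schedule.n_epochs, subset_fraction,
                seed=seed, batch_size=self.schedule.batch_size,
                fixed_subset=fixed_subset, **common)
        else:
            raise ValueError(f"unknown training mode {mode!r}")
        return CBSNNResults(model=self, mode=mode, seed=seed, network=net,
                            log=log, novelty=table)


@dataclass
class CBSNNResults:
    """Outcome of one training run: network, log, novelty table, diagnostics."""

    model: CBSNN
    mode: str
    seed: int
    network: Network
    log: TrainingLog
    novelty: NoveltyTable

    def predict(self, dataset: LabeledDataset) -> np.ndarray:
        """Predicted class per sample (teacher-free presentation, argmax)."""
        trains = encode_dataset(dataset.features, mode=self.model.encoding_mode,
                                max_rate=self.model.max_rate,
                                duration=self.network.config.T,
                                seed=self.seed + 1)
        preds = np.empty(dataset.n_samples, dtype=int)
        for start in range(0, dataset.n_samples, 64):
            sl = slice(start, start + 64)
            trace = present_batch(self.network, trains[sl], None)
            preds[sl] = np.argmax(trace.V_k, axis=1)
        return preds

    def accuracy(self, dataset: Optional[LabeledDataset] = None) -> float:
        """Teacher-free classification accuracy on `dataset` (default: train)."""
        ds = dataset if dataset is not None else self.model.dataset
        return evaluate(self.network, ds, seed=self.seed,
                        encoding_mode=self.model.encoding_mode,
                        max_rate=self.model.max_rate)

    def computation_ratio(self, other: "CBSNNResults") -> float:
        """Presentations of this run relative to `other` (usually a baseline)."""
        return computation_ratio(self.log, other.log)

    @property
    def presentations(self) -> int:
        return self.log.cumulative_presentations

    def summary(self) -> str:
        """Human-readable run summary (mode, schedule, accounting, novelty)."""
        df = self.log.to_dataframe()
        sched = self.model.schedule
        lines = [
            "Curiosity-based SNN training results",
            "=" * 44,
            f"mode:                 {self.mode}",
            f"layers:               {self.network.config.layer_sizes}",
            f"epochs:               {self.log.n_epochs}",
            f"schedule:             T_start={sched.T_start} "
            f"NE_th={sched.NE_th} I_re={sched.I_re}",
            f"full epochs:          {int((df['kind'] == 'full').sum())}",
            f"presentations:        {self.presentations}",
            f"final train accuracy: {df['accuracy'].iloc[-1]:.4f}",
            f"final mean loss:      {df['loss'].iloc[-1]:.4f}",
            f"mean novelty (final): {float(np.mean(self.novelty.NE)):.4f}",
        ]
        return "\n".join(lines)
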