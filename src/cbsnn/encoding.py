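"""Input encoding, teacher signals, and output decoding.

Feature vectors in [0, 1] are turned into spike trains either by Poisson-style
Bernoulli rate coding (each input neuron fires independently per step with
probability ``feature * max_rate``) or by a deterministic constant-current
mode that injects the feature value itself as per-step drive.  Class labels
become one-hot teacher potential vectors, and output-layer potentials are
decoded by argmax with a lowest-index tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpikeTrain", "TeacherSignal", "rate_encode", "current_encode",
           "make_teacher", "decode_prediction", "encode_dataset"]


@dataclass(frozen=True)
class SpikeTrain:
    """Encoded input: array of shape (duration, n_inputs).

    Rate-coded trains contain 0/1 entries; constant-current trains contain
    the feature values repeated every step (see :func:`current_encode`).
    """

    spikes: np.ndarray
    duration: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.spikes.shape[0] != self.duration:
            raise ValueError("spike array first axis must equal duration")


@dataclass(frozen=True)
class TeacherSignal:
    """Target output-potential vector for a labelled sample."""

    V_T: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if np.linalg.norm(self.V_T) == 0:
            raise ValueError("teacher signal must have nonzero norm")


def rate_encode(features: np.ndarray, max_rate: float = 0.5,
                duration: int = 100, seed: int | None = 0) -> SpikeTrain:
    """Bernoulli rate coding of a feature vector.

    Each input neuron i spikes independently at every step with probability
    ``features[i] * max_rate``.  Reproducible for a given seed.
    """
    features = np.asarray(features, dtype=float)
    if features.min() < 0 or features.max() > 1:
        raise ValueError(
            "features must be normalized to [0, 1] before rate encoding; "
            "apply min-max normalization first")
    if not (0 < max_rate <= 1):
        raise ValueError("max_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p = features * max_rate
    spikes = (rng.random((duration, features.size)) < p).astype(float)
    return SpikeTrain(spikes=spikes, duration=duration, seed=seed)


def current_encode(features: np.ndarray, max_rate: float = 0.5,
                   duration: int = 100) -> SpikeTrain:
    """Deterministic constant-current encoding.

    Injects ``features[i] * max_rate`` as the per-step input value of neuron
    i — the expectation of the rate code without sampling noise.  Useful for
    reproducible unit tests and noise-free training.
    """
    features = np.asarray(features, dtype=float)
    if features.min() < 0 or features.max() > 1:
        raise ValueError("features must be normalized to [0, 1]")
    row = features * max_rate
    return SpikeTrain(spikes=np.tile(row, (duration, 1)), duration=duration)


def encode_dataset(features: np.ndarray, mode: str = "rate",
                   max_rate: float = 0.5, duration: int = 100,
                   seed: int = 0) -> np.ndarray:
    """Encode a feature matrix to an array of shape (n_samples, T, n_inputs).

    Each sample's randomness derives from (seed, sample index) so a sample's
    train does not depend on batch composition or epoch order.
    """
    n = features.shape[0]
    out = np.empty((n, duration, features.shape[1]))
    for k in range(n):
        if mode == "rate":
            out[k] = rate_encode(features[k], max_rate, duration,
                                 seed=np.random.SeedSequence([seed, k])).spikes
        elif mode == "current":
            out[k] = current_encode(features[k], max_rate, duration).spikes
        else:
            raise ValueError(f"unknown encoding mode {mode!r}")
    return out


def make_teacher(label: int, n_classes: int, amplitude: float = 1.0,
                 baseline: float = 0.0) -> TeacherSignal:
    """One-hot teacher potentials: ``amplitude`` at the label, ``baseline`` elsewhere."""
    if not 0 <= label < n_classes:
        raise IndexError(f"label {label} out of range for {n_classes} classes")
    if amplitude == baseline:
        raise ValueError("amplitude must differ from baseline")
    v = np.full(n_classes, float(baseline))
    v[label] = amplitude
    return TeacherSignal(V_T=v, label=int(label))


def decode_prediction(V_out: np.ndarray) -> int:
    """Class of the maximal output potential; ties go to the lowest index."""
    V_out = np.asarray(V_out, dtype=float)
    if V_out.size == 0:
        raise ValueError("empty output vector")
    if not np.all(np.isfinite(V_out)):
        raise FloatingPointError("non-finite output potentials")
    return int(np.argmax(V_out))
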