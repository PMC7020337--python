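"""Bilinear (bi-)STDP: dw_ji proportional to V_j * V_i'.

The weight change between presynaptic neuron j and postsynaptic neuron i is
the product of j's time-averaged activity and i's potential "derivative" —
by default the teacher-driven displacement of i's potential per unit window.
A neuron whose potential the teacher no longer needs to correct (converged)
stops driving plasticity on its afferents.  Deltas are averaged over a batch
and applied once per batch, with optional clipping to the weight bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkConfig, PresentationTrace, SynapseMatrix

__all__ = ["WeightDelta", "bistdp_delta", "apply_updates", "batch_weight_deltas"]


@dataclass(frozen=True)
class WeightDelta:
    """A batch-accumulated weight update for one synapse matrix."""

    dW: np.ndarray
    source: str = ""
    batch_size: int = 1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dW)):
            raise FloatingPointError("non-finite weight delta")


def bistdp_delta(V_pre: np.ndarray, dV_post: np.ndarray, rate: float,
                 source: str = "") -> WeightDelta:
    """Outer-product plasticity: dW[j, i] = rate * V_pre[j] * dV_post[i].

    For batched inputs (2-D arrays, samples on the first axis) the deltas
    are summed over the batch and ``batch_size`` records the divisor to be
    applied later.
    """
    V_pre = np.atleast_2d(np.asarray(V_pre, dtype=float))
    dV_post = np.atleast_2d(np.asarray(dV_post, dtype=float))
    if V_pre.shape[0] != dV_post.shape[0]:
        raise ValueError("pre/post batch sizes differ")
    dW = rate * (V_pre.T @ dV_post)
    return WeightDelta(dW=dW, source=source, batch_size=V_pre.shape[0])


def apply_updates(W: SynapseMatrix, delta: WeightDelta) -> SynapseMatrix:
    """Return a new matrix W + dW / batch_size, clipped to bounds if set."""
    if W.shape != delta.dW.shape:
        raise ValueError(
            f"weight shape {W.shape} != delta shape {delta.dW.shape}")
    newW = W.W + delta.dW / delta.batch_size
    if W.bounds is not None:
        newW = np.clip(newW, *W.bounds)
    return SynapseMatrix(newW, W.bounds)


def batch_weight_deltas(config: NetworkConfig, trace: PresentationTrace
                        ) -> tuple[WeightDelta, WeightDelta]:
    """Both layers' STDP deltas from one presentation trace.

    The postsynaptic derivative follows ``vprime_mode``: the accumulated
    teacher-clamp correction per unit window ('supervised', default), the raw
    accumulated applied potential change per unit window ('window_total'),
    or the final step's change ('last_step').  Presynaptic activity is the
    window-averaged potential (input layer: mean drive) also used for the
    readout.
    """
    if config.vprime_mode == "supervised":
        # potential displacement attributable to the teaching signal: the
        # accumulated clamp corrections, per unit window.  Hidden neurons
        # receive no teaching signal in a strictly feed-forward network, so
        # their derivative is zero and the hidden weights act as a fixed
        # random projection.  This is the stable, error-corrective mode: the
        # update vanishes exactly when the clamped trajectory tracks V_T.
        vp_hid = np.zeros_like(trace.dv_hidden)
        vp_out = trace.supervised_dv / config.T
    elif config.vprime_mode == "window_total":
        vp_hid = trace.dv_hidden / config.T
        vp_out = trace.dv_out / config.T
    else:
        vp_hid = trace.dv_hidden_last
        vp_out = trace.dv_out_last
    d1 = bistdp_delta(trace.pre_avg_input, vp_hid, config.stdp_rate,
                      source="hidden-input")
    d2 = bistdp_delta(trace.pre_avg_hidden, vp_out, config.stdp_rate,
                      source="output-hidden")
    return d1, d2
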