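"""Three-layer fully connected spiking network and its per-sample tuning.

The network is input -> hidden -> output, fully connected.  Within one
presentation window of ``T`` steps each simulated layer receives two
membrane-potential corrections:

* a feed-forward delta ``dV_FF`` from the conductance-based LIF dynamics, and
* an equilibrium-state delta ``dV_ES`` relaxing each neuron toward
  consistency with its weighted presynaptic potentials,

blended with a time-dependent schedule ``dV = (t/T) dV_FF + (1 - t/T) dV_ES``
so that the window starts equilibrium-dominated and ends dynamics-dominated.
With a teacher signal present, the output layer is additionally clamped each
step by ``dV = -eta_c (V - V_T)``, minimising the quadratic readout loss
``C = sum_i (V_i - V_T,i)^2``.

Presentations are vectorised over a batch axis; samples in a batch evolve
independently (states carry shape ``(batch, width)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lif_core import (LayerState, NeuronParams, fire_and_reset,
                       update_conductance, update_membrane)
from .encoding import SpikeTrain, TeacherSignal

__all__ = ["NetworkConfig", "SynapseMatrix", "PresentationTrace", "Network",
           "init_network", "equilibrium_delta", "blended_update",
           "supervised_clamp", "loss", "present_sample", "present_batch"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and tuning rates of the three-layer network.

    Parameters
    ----------
    layer_sizes : (int, int, int)
        Input, hidden and output widths.
    T : int
        Presentation window in steps.
    dt : float
        Euler step size.
    eta_i : float
        Equilibrium-state tuning rate.
    eta_c : float
        Supervised clamp rate.
    stdp_rate : float
        Proportionality constant of the bilinear STDP rule.
    es_threshold_mode : str
        'single' (threshold term = V_th, default) or 'presyn_count'
        (threshold term = fan_in * V_th) in the equilibrium correction.
        The presynaptic-count reading shifts every neuron by -fan_in * V_th,
        which at realistic fan-ins drowns the input-dependent drive; the
        single-threshold reading keeps the correction centred.
    vprime_mode : str
        'supervised' (default): postsynaptic derivative = accumulated
        teacher-clamp correction over the window / T (zero for the hidden
        layer, which no teaching signal reaches); 'window_total': raw
        accumulated applied potential change / T; 'last_step': final step's
        change only.  The Hebbian variants drift toward the weight bounds on
        long runs and are kept for comparison experiments.
    """

    layer_sizes: tuple[int, int, int] = (4, 64, 3)
    T: int = 100
    dt: float = 1.0
    eta_i: float = 0.1
    eta_c: float = 0.1
    stdp_rate: float = 0.75
    w_bounds: tuple[float, float] = (-8.0, 8.0)
    es_threshold_mode: str = "single"
    vprime_mode: str = "supervised"
    neuron: NeuronParams = field(default_factory=NeuronParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != 3:
            raise ValueError("the network has exactly three layers")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.T < 1:
            raise ValueError("presentation window T must be >= 1")
        if self.eta_i <= 0 or self.eta_c <= 0 or self.stdp_rate <= 0:
            raise ValueError("tuning rates must be positive")
        if self.es_threshold_mode not in ("presyn_count", "single"):
            raise ValueError("es_threshold_mode must be 'presyn_count' or 'single'")
        if self.vprime_mode not in ("supervised", "window_total", "last_step"):
            raise ValueError(
                "vprime_mode must be 'supervised', 'window_total' or 'last_step'")


@dataclass
class SynapseMatrix:
    """Dense feed-forward weights; W[j, i] connects presynaptic j to postsynaptic i."""

    W: np.ndarray
    bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("weight matrix must be 2-D")
        if self.bounds is not None:
            lo, hi = self.bounds
            if self.W.min() < lo or self.W.max() > hi:
                raise ValueError("weights outside declared bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape


@dataclass
class PresentationTrace:
    """Per-window record of one presentation (batched).

    ``V_hist`` holds output potentials per step (T, batch, n_out);
    ``dv_*`` hold the accumulated applied potential changes available to the
    plasticity rule's postsynaptic "derivative"; ``pre_avg_*`` the
    window-averaged presynaptic activities.
    """

    V_hist: np.ndarray
    dff_parts: np.ndarray
    des_parts: np.ndarray
    blended_parts: np.ndarray
    dv_hidden: np.ndarray
    dv_out: np.ndarray
    dv_hidden_last: np.ndarray
    dv_out_last: np.ndarray
    pre_avg_input: np.ndarray
    pre_avg_hidden: np.ndarray
    V_k: np.ndarray
    supervised_dv: np.ndarray


@dataclass
class Network:
    """A three-layer spiking network: config plus its two weight matrices."""

    config: NetworkConfig
    W1: SynapseMatrix
    W2: SynapseMatrix

    def copy(self) -> "Network":
        return Network(self.config,
                       SynapseMatrix(self.W1.W.copy(), self.W1.bounds),
                       SynapseMatrix(self.W2.W.copy(), self.W2.bounds))

    def checksum(self) -> float:
        return float(np.sum(self.W1.W) + np.sum(self.W2.W))


def init_network(config: NetworkConfig) -> Network:
    """Fresh network with uniform weights in [-w0, w0], w0 = 1/sqrt(fan_in)."""
    n_in, n_hid, n_out = config.layer_sizes
    rng = np.random.default_rng(config.seed)
    w0_1 = 1.0 / np.sqrt(n_in)
    w0_2 = 1.0 / np.sqrt(n_hid)
    W1 = rng.uniform(-w0_1, w0_1, size=(n_in, n_hid))
    W2 = rng.uniform(-w0_2, w0_2, size=(n_hid, n_out))
    return Network(config,
                   SynapseMatrix(W1, config.w_bounds),
                   SynapseMatrix(W2, config.w_bounds))


def equilibrium_delta(V: np.ndarray, W_in: SynapseMatrix, V_pre: np.ndarray,
                      g_E: np.ndarray, params: NeuronParams, eta_i: float,
                      threshold_mode: str = "presyn_count") -> np.ndarray:
    """Equilibrium-state correction of layer potentials.

    dV_ES,i = -eta_i * [ (V_i - (sum_j w_ji V_j - Th_i))
                         + (V_i - V_L)
                         + (g_E/g_L) (V_i - V_E) ]

    where Th_i is fan_in * V_th ('presyn_count' mode) or V_th ('single').
    The whole bracket is a damped relaxation: the first term pulls each
    neuron toward its weighted presynaptic prediction, the second toward
    rest, the third accounts for the conductance drive.
    """
    V = np.asarray(V, dtype=float)
    V_pre = np.asarray(V_pre, dtype=float)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(V_pre))):
        raise FloatingPointError("non-finite potentials in equilibrium update")
    fan_in = W_in.shape[0]
    th = fan_in * params.V_th if threshold_mode == "presyn_count" else params.V_th
    prediction = V_pre @ W_in.W - th
    bracket = (V - prediction) + (V - params.V_L) \
        + (g_E / params.g_L) * (V - params.V_E)
    return -eta_i * bracket


def blended_update(delta_ff: np.ndarray, delta_es: np.ndarray,
                   t: int, T: int) -> np.ndarray:
    """Time-blended combination (t/T) dV_FF + (1 - t/T) dV_ES."""
    if T == 0:
        raise ValueError("presentation window T must be nonzero")
    if not 0 <= t <= T:
        raise ValueError(f"step t={t} outside [0, T={T}]")
    a = t / T
    return a * np.asarray(delta_ff) + (1.0 - a) * np.asarray(delta_es)


def supervised_clamp(V_out: np.ndarray, teacher: TeacherSignal,
                     eta_c: float) -> np.ndarray:
    """Supervised correction dV_i = -eta_c (V_i - V_T,i) toward the teacher."""
    V_out = np.asarray(V_out, dtype=float)
    V_T = teacher.V_T if V_out.ndim == 1 else np.asarray(teacher.V_T)
    if V_out.shape[-1] != np.shape(V_T)[-1]:
        raise ValueError("output / teacher dimension mismatch")
    return -eta_c * (V_out - V_T)


def loss(V_out: np.ndarray, teacher: TeacherSignal | np.ndarray) -> float:
    """Quadratic readout loss C = sum_i (V_i - V_T,i)^2."""
    V_T = teacher.V_T if isinstance(teacher, TeacherSignal) else np.asarray(teacher)
    V_out = np.asarray(V_out, dtype=float)
    if V_out.shape != np.shape(V_T):
        raise ValueError("output / teacher shape mismatch")
    return float(np.sum((V_out - V_T) ** 2))


def present_batch(net: Network, spike_trains: np.ndarray,
                  teachers: Optional[np.ndarray] = None) -> PresentationTrace:
    """Simulate one window for a batch of encoded samples.

    Parameters
    ----------
    spike_trains : array (batch, T, n_in)
        Encoded inputs; entries are spike indicators (or constant-current
        drive values in [0, 1]).
    teachers : array (batch, n_out), optional
        Stacked teacher vectors; when given, the output layer is clamped
        toward them every step.

    Returns
    -------
    PresentationTrace with the readout ``V_k`` (mean output potential over
    the window, which averages out spike-reset sawtooth and encoder noise)
    and the accumulated potential changes needed by the plasticity rule.
    Weights are not modified here.
    """
    cfg = net.config
    n_in, n_hid, n_out = cfg.layer_sizes
    B, T, width = spike_trains.shape
    if width != n_in:
        raise ValueError(f"input width {width} != network input size {n_in}")
    if T != cfg.T:
        raise ValueError(f"spike train duration {T} != window T {cfg.T}")
    p = cfg.neuron

    hid = LayerState.at_rest(n_hid, p, batch=B)
    out = LayerState.at_rest(n_out, p, batch=B)

    dv_hidden = np.zeros((B, n_hid))
    dv_out = np.zeros((B, n_out))
    sup_dv = np.zeros((B, n_out))
    dv_hidden_last = np.zeros((B, n_hid))
    dv_out_last = np.zeros((B, n_out))
    V_hist = np.zeros((T, B, n_out))
    dff_hist = np.zeros((T, B, n_out))
    des_hist = np.zeros((T, B, n_out))
    blended_hist = np.zeros((T, B, n_out))

    in_sum = np.zeros((B, n_in))
    hid_sum = np.zeros((B, n_hid))

    for step in range(1, T + 1):
        delta_in = spike_trains[:, step - 1, :]

        # hidden layer: conductance from input spikes, FF + ES blend
        drive_h = p.eta_g * (delta_in @ net.W1.W)
        hid = update_conductance(hid, drive_h, p, cfg.dt)
        hid, dff_h = update_membrane(hid, p, cfg.dt)
        des_h = equilibrium_delta(hid.V, net.W1, delta_in, hid.g_E, p,
                                  cfg.eta_i, cfg.es_threshold_mode)
        des_h = np.where(hid.ref_remaining > 0, 0.0, des_h)
        bl_h = blended_update(dff_h, des_h, step, T)
        hid.V = hid.V + bl_h
        dv_hidden += bl_h
        dv_hidden_last = bl_h
        hid, spikes_h = fire_and_reset(hid, p)

        # output layer: conductance from hidden spikes, FF + ES blend + clamp
        drive_o = p.eta_g * (spikes_h @ net.W2.W)
        out = update_conductance(out, drive_o, p, cfg.dt)
        out, dff_o = update_membrane(out, p, cfg.dt)
        des_o = equilibrium_delta(out.V, net.W2, hid.V, out.g_E, p,
                                  cfg.eta_i, cfg.es_threshold_mode)
        des_o = np.where(out.ref_remaining > 0, 0.0, des_o)
        bl_o = blended_update(dff_o, des_o, step, T)
        out.V = out.V + bl_o
        dv_step_o = bl_o.copy()
        if teachers is not None:
            clamp = -cfg.eta_c * (out.V - teachers)
            clamp = np.where(out.ref_remaining > 0, 0.0, clamp)
            out.V = out.V + clamp
            sup_dv += clamp
            dv_step_o = dv_step_o + clamp
        dv_out += dv_step_o
        dv_out_last = dv_step_o
        out, _ = fire_and_reset(out, p)

        V_hist[step - 1] = out.V
        dff_hist[step - 1] = dff_o
        des_hist[step - 1] = des_o
        blended_hist[step - 1] = bl_o
        in_sum += delta_in
        hid_sum += hid.V

    V_k = V_hist.mean(axis=0)
    return PresentationTrace(
        V_hist=V_hist, dff_parts=dff_hist, des_parts=des_hist,
        blended_parts=blended_hist,
        dv_hidden=dv_hidden, dv_out=dv_out,
        dv_hidden_last=dv_hidden_last, dv_out_last=dv_out_last,
        pre_avg_input=in_sum / T, pre_avg_hidden=hid_sum / T,
        V_k=V_k, supervised_dv=sup_dv)


def present_sample(net: Network, spike_train: SpikeTrain,
                   teacher: Optional[TeacherSignal] = None,
                   learn: bool = False) -> tuple[np.ndarray, PresentationTrace]:
    """Simulate one sample for one window; optionally apply plasticity.

    Returns the readout potentials ``V_k`` and the full trace.  With
    ``learn=True`` the bilinear STDP deltas computed from the trace are
    applied to the network's weights in place.
    """
    trains = spike_train.spikes[None, :, :]
    teachers = teacher.V_T[None, :] if teacher is not None else None
    trace = present_batch(net, trains, teachers)
    if learn:
        from .plasticity import batch_weight_deltas, apply_updates
        d1, d2 = batch_weight_deltas(net.config, trace)
        net.W1 = apply_updates(net.W1, d1)
        net.W2 = apply_updates(net.W2, d2)
    return trace.V_k[0], trace
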