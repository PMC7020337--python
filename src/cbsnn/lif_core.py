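"""Conductance-based leaky integrate-and-fire dynamics in discrete time.

The neuron model is the standard LIF with a single excitatory conductance
channel, integrated with forward Euler.  Per time step ``dt``:

    tau_E dg_E/dt = -g_E + eta * sum_j w_ji * spike_j
    tau_m dV/dt   = -(V - V_L) - (g_E / g_L) * (V - V_E)

A neuron whose potential reaches the firing threshold ``V_th`` emits a spike,
is reset to ``V_reset`` and held there for ``t_ref`` refractory steps, during
which it receives no membrane updates.

All operations are vectorised over an arbitrary leading (batch) axis: a
:class:`LayerState` may hold arrays of shape ``(n,)`` or ``(batch, n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "LayerState",
    "update_conductance",
    "update_membrane",
    "fire_and_reset",
]


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of one layer of LIF neurons.

    All quantities are dimensionless by default; any consistent unit system
    works as long as time constants and ``dt`` share a unit.

    Attributes
    ----------
    C_m, R_m : float
        Membrane capacitance and resistance (kept for completeness; the
        simulated update uses the time-constant form).
    g_L : float
        Leak conductance, > 0.
    V_L : float
        Leak (resting) potential.
    V_E : float
        Excitatory reversal potential; the conductance drive pulls the
        membrane toward this value.
    tau_E, tau_m : float
        Conductance and membrane time constants, > 0.
    V_th : float
        Firing threshold.
    V_reset : float
        Post-spike reset potential.
    t_ref : int
        Refractory duration in steps, >= 0.
    eta_g : float
        Gain applied to the summed presynaptic spike input feeding g_E.
    """

    C_m: float = 1.0
    R_m: float = 1.0
    g_L: float = 1.0
    V_L: float = 0.0
    V_E: float = 5.0
    tau_E: float = 5.0
    tau_m: float = 10.0
    V_th: float = 1.0
    V_reset: float = 0.0
    t_ref: int = 2
    eta_g: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_m <= 0:
            raise ValueError("time constants tau_E, tau_m must be positive")
        if self.t_ref < 0:
            raise ValueError("refractory duration t_ref must be >= 0")
        if self.g_L <= 0:
            raise ValueError("leak conductance g_L must be positive")
        if not (self.V_reset <= self.V_L < self.V_th < self.V_E):
            raise ValueError(
                "potentials must satisfy V_reset <= V_L < V_th < V_E, got "
                f"V_reset={self.V_reset}, V_L={self.V_L}, "
                f"V_th={self.V_th}, V_E={self.V_E}"
            )


@dataclass
class LayerState:
    """Dynamic state of one layer: potentials, conductances, spikes, refraction.

    Arrays share a trailing layer-width axis and may carry a leading batch
    axis.  ``spiked`` holds the current step's 0/1 spike indicators;
    ``ref_remaining`` counts remaining refractory steps.
    """

    V: np.ndarray
    g_E: np.ndarray
    spiked: np.ndarray = field(default=None)  # type: ignore[assignment]
    ref_remaining: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.g_E = np.asarray(self.g_E, dtype=float)
        if self.spiked is None:
            self.spiked = np.zeros_like(self.V)
        if self.ref_remaining is None:
            self.ref_remaining = np.zeros(self.V.shape, dtype=int)
        shapes = {self.V.shape, self.g_E.shape, np.shape(self.spiked),
                  np.shape(self.ref_remaining)}
        if len(shapes) != 1:
            raise ValueError(f"state arrays must share one shape, got {shapes}")

    @property
    def width(self) -> int:
        return self.V.shape[-1]

    @classmethod
    def at_rest(cls, width: int, params: NeuronParams,
                batch: int | None = None) -> "LayerState":
        shape = (width,) if batch is None else (batch, width)
        return cls(V=np.full(shape, params.V_L), g_E=np.zeros(shape))

    def copy(self) -> "LayerState":
        return LayerState(self.V.copy(), self.g_E.copy(),
                          self.spiked.copy(), self.ref_remaining.copy())


def update_conductance(state: LayerState, weighted_spike_input: np.ndarray,
                       params: NeuronParams, dt: float = 1.0) -> LayerState:
    """One Euler step of the excitatory-conductance ODE.

    ``weighted_spike_input`` is the already-reduced presynaptic drive
    ``eta_g * sum_j w_ji * spike_j`` for each postsynaptic neuron.  Negative
    drive (from negative weights) is allowed; g_E is floored at zero after
    the step so it remains a conductance.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    inp = np.asarray(weighted_spike_input, dtype=float)
    if inp.shape[-1] != state.width:
        raise ValueError(
            f"input width {inp.shape[-1]} != layer width {state.width}")
    g = state.g_E + (dt / params.tau_E) * (-state.g_E + inp)
    out = state.copy()
    out.g_E = np.maximum(g, 0.0)
    return out


def update_membrane(state: LayerState, params: NeuronParams,
                    dt: float = 1.0) -> tuple[LayerState, np.ndarray]:
    """One Euler step of the membrane equation; returns the feed-forward delta.

    Refractory neurons are skipped: their potential stays at ``V_reset`` and
    their returned delta is zero.  The delta is returned separately because
    the training loop blends it with the equilibrium-state correction before
    applying it.
    """
    if not np.all(np.isfinite(state.V)) or not np.all(np.isfinite(state.g_E)):
        raise FloatingPointError("non-finite membrane state")
    drive = -(state.V - params.V_L) - (state.g_E / params.g_L) * (state.V - params.V_E)
    delta_ff = (dt / params.tau_m) * drive
    delta_ff = np.where(state.ref_remaining > 0, 0.0, delta_ff)
    out = state.copy()
    out.V = np.where(state.ref_remaining > 0, params.V_reset, state.V)
    return out, delta_ff


def fire_and_reset(state: LayerState,
                   params: NeuronParams) -> tuple[LayerState, np.ndarray]:
    """Threshold crossing, reset and refractory bookkeeping.

    Neurons at or above ``V_th`` and out of refraction spike, reset to
    ``V_reset`` and enter ``t_ref`` refractory steps; refractory counters of
    the others are decremented.  Returns the new state and the 0/1 spike
    vector.
    """
    can_fire = state.ref_remaining <= 0
    spikes = ((state.V >= params.V_th) & can_fire).astype(float)
    fired = spikes > 0
    out = state.copy()
    out.V = np.where(fired, params.V_reset, state.V)
    out.V = np.where(~fired & ~can_fire, params.V_reset, out.V)
    out.ref_remaining = np.where(
        fired, params.t_ref, np.maximum(state.ref_remaining - 1, 0))
    out.spiked = spikes
    return out, spikes
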