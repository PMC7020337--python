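# Methods

## Model overview

`cbsnn` trains a three-layer, fully connected spiking classifier without
backpropagation.  Per presentation window, three potential-update channels
act together:

1. **Feed-forward LIF dynamics.**  Conductance-based leaky
   integrate-and-fire neurons integrated with forward Euler (`dt = 1`
   dimensionless time unit, window `T = 100` steps).  Input spikes drive the
   excitatory conductance `g_E`, which pulls the membrane toward the
   excitatory reversal potential.  Spiking resets the potential and opens a
   refractory period during which the neuron is excluded from all updates.
2. **Equilibrium-state tuning.**  A relaxation step nudges each neuron
   toward the potential predicted by its weighted presynaptic potentials,
   minus the firing threshold, with leak and conductance corrections.  The
   feed-forward and equilibrium deltas are blended as
   `(t/T)·dV_FF + (1−t/T)·dV_ES`, so a window starts
   equilibrium-dominated (fast, analog) and ends dynamics-dominated
   (spiking).
3. **Supervised clamping.**  With a label present, the output layer is
   pulled toward the one-hot teacher vector every step,
   `dV = −eta_c (V − V_T)`.

The sample readout `V_k` is the mean output potential over the whole
window.  Averaging over the full window rather than a terminal slice matters
twice over: it smooths the spike-reset sawtooth, and it keeps the readout
coupled to the equilibrium channel (which carries most of the
input-dependence early in the window) so that what the plasticity rule fits
is also what evaluation measures.

## Plasticity

Weights change by a bilinear rule, the outer product of presynaptic activity
and a postsynaptic potential "derivative", averaged over a batch and applied
once per batch with clipping to `w_bounds`.

The definition of the postsynaptic derivative is the load-bearing numerical
choice, exposed as `vprime_mode`:

- `supervised` (default): the accumulated teacher-clamp correction per unit
  window, `eta_c · mean_t(V_T − V(t))`.  This is a delta rule on the clamped
  trajectory: it vanishes exactly when the clamped output tracks the
  teacher, giving a finite, stable fixed point at which the free-running
  output also reproduces the teacher pattern.  Hidden neurons receive no
  teaching signal in a strictly feed-forward network, so their derivative is
  identically zero and the hidden weights act as a fixed random projection
  (reservoir): classification capacity lives in the learned readout.
- `window_total`: the raw sum of applied potential changes per unit window.
  Because applied changes telescope to (final − initial potential) plus one
  threshold-to-reset jump per spike, this is effectively a firing-rate
  Hebbian term for any tonically active neuron.  It has no error-corrective
  fixed point; on runs longer than a few epochs it drifts the weights into
  the bounds.  Kept for comparison experiments.
- `last_step`: the final step's applied change only; error-like but two
  orders of magnitude weaker than the clamp integral, and subject to the
  same Hebbian drift on the hidden layer.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `V_L`, `V_reset`, `V_th`, `V_E` | 0, 0, 1, 5 | dimensionless potential scale |
| `tau_m`, `tau_E`, `t_ref` | 10, 5, 2 steps | standard LIF time constants at `dt = 1` |
| `eta_g` | 5 | conductance input gain; chosen so hidden neurons operate in a graded spiking regime — at unit gain the hidden layer is silent and the conductance channel carries no information |
| `eta_i` | 0.1 | equilibrium tuning rate; a damped relaxation step |
| `eta_c` | 0.1 | clamp rate; strong enough to supply an error signal, weak enough that the clamped readout still reflects the feed-forward mismatch the novelty score needs |
| `stdp_rate` | 0.75 | plasticity constant; with the clamp-integral derivative this puts the readout's least-mean-squares learning in its stable step-size range |
| `w_bounds` | ±8 | wide enough that clipping is not the binding constraint at convergence |
| teacher amplitude | 0.5 | target potential of the correct class.  Deliberately **below** `V_th`: a target equal to the threshold is unreachable on average (the neuron fires and resets), which leaves a permanent error signal and drives weight runaway.  Cosine novelty is scale-invariant, so the amplitude does not affect NE |
| `es_threshold_mode` | `single` | the threshold term in the equilibrium prediction.  The alternative (`presyn_count`) subtracts `fan_in · V_th`, which at realistic fan-ins (64 hidden inputs) shifts every output by tens of units and drowns the input-dependent signal |
| batch size | 8 | small batches give the readout more stochastic-gradient steps per epoch, which is what limits convergence inside a 20-epoch budget |
| `T_start`, `NE_th`, `I_re` | 1, 0.05, 5 | curiosity schedule operating point |

Encoding defaults to deterministic constant-current injection (each input
neuron receives `feature · max_rate` per step): reproducible, and the
natural choice for analog feature tables.  Bernoulli rate coding
(`mode="rate"`, per-step spike probability `feature · max_rate`) is provided
for image-style data; its per-window sampling noise costs a few accuracy
points on low-dimensional tasks.

## Curiosity schedule and accounting

Novelty is `NE_k = 1 − cos(V_k, V_T)` in `[0, 2]`, with a silent output
scored 2.  Selection uses `NE_k ≥ NE_th` (boundary included).  Epoch kinds
follow the four-phase recursion: `T_start` seeding epochs, selective epochs,
a mandatory full epoch whenever `e − e_0 = I_re`.  Every trained sample's
novelty is refreshed from its fresh readout; unselected samples keep their
stale estimate until the next full epoch — re-scoring them would cost
exactly the presentations the method is designed to save
(`refresh_all_novelty` flips this, and the extra scoring passes are then
counted in the log).  Sample order is shuffled per epoch with a seed derived
from the master seed; within a batch samples are simulated independently and
weight deltas applied once per batch.  An optional early stop halts when the
mean loss of two consecutive full epochs changes by less than a tolerance;
it is off by default so that runs of equal length stay comparable.

Computation is counted in sample-presentations (one presentation = one
`T`-step window for one sample), a hardware-independent proxy for training
cost.  With `NE_th = 0` the scheduler degenerates to full-data training and
reproduces the plain baseline trainer bit for bit — the central regression
test.

## Synthetic data

The generator produces `n_classes` Gaussian clusters (unit variance) with
means separated by `separation`, plus an `overlap_fraction` of each class
drawn around the midpoint between that class's mean and an adjacent one.
The midpoint subpopulations are the "hard" samples: they stay novel after
the seeding epoch, so selective epochs have a genuine subpopulation to work
on — the property the curiosity schedule exploits.  Because each midpoint
cluster carries a single label, the task remains almost perfectly learnable;
at the standard conditions (3 × 200 samples, separation 6, overlap 0.2,
4 dimensions) roughly 20–60 % of samples remain novel after one epoch.

What the generator does **not** emulate: high-dimensional correlated inputs
(images), label noise, class imbalance, and within-class multimodality
beyond the single midpoint cluster.  Passing tests on this task demonstrate
that the scheduler saves presentations without losing accuracy when a
nontrivial hard subpopulation exists; they do not predict absolute accuracy
on real image benchmarks.

## Numerical choices

- Forward Euler throughout; the unit-test suite verifies first-order
  convergence (halving `dt` halves the worst-case error against the
  closed-form exponentials).
- `g_E` is floored at zero after every step: negative weights may reduce the
  drive but conductances stay physical.
- Refractory neurons are frozen at `V_reset` and excluded from feed-forward,
  equilibrium and clamp updates.
- Prediction is the argmax of `V_k` with ties broken toward the lowest
  index; an empty selective epoch trains nothing and is logged with a
  selected count of zero, not treated as an error.
- Initial novelty is 2.0 (maximally novel) for every sample, so the seeding
  epoch always trains everything.
- Weight initialisation is uniform in `±1/√fan_in` from the run seed; all
  randomness (init, shuffling, rate encoding, subset draws) derives from the
  master seed, making every training mode bit-reproducible.

## Known limitations

- The hidden layer does not learn under the default derivative; tasks whose
  classes are not separable under a random projection of this width would
  need a wider hidden layer rather than hidden plasticity.
- The clamp biases the novelty score downward (trained outputs are partly
  teacher-shaped), so `NE_th` is not comparable across different `eta_c`.
- Accuracy on a 150-sample test split is quantised in steps of ~0.7
  percentage points; single-seed comparisons near a threshold are noisy, and
  the end-to-end checks therefore aggregate over seeds.
- Runs much longer than ~50 epochs with the Hebbian `vprime_mode` variants
  saturate the weight bounds by construction; the default mode does not.
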