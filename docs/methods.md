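# Methods

## Model

`spikecoding` simulates populations of leaky integrate-and-fire neurons
that learn to represent a set of analog signals in their spike trains so
that a linear readout can reconstruct the signals with as few spikes as
possible. All quantities are dimensionless: time is measured in units of
the membrane time constant τ (for reporting rates in Hz the package adopts
τ = 10 ms, `spikecoding.metrics.TAU_SECONDS`), and voltages in units of the
firing threshold scale.

The membrane dynamics of the simplified (non-Dale) population are

    dV_i/dt = -V_i + Σ_j F_ij c_j(t) + Σ_k Ω_ik o_k(t),

where `c(t)` are input currents, `F` the feedforward weights, `o_k(t)` the
spike trains and `Ω` the recurrent weights; the diagonal Ω_ii < 0 is the
self-reset (a spike resets the neuron to V = T_i + Ω_ii). The signals the
network represents are the leaky integrals `x(t)` of the currents
(dx/dt = -x + c), and the readout is x̂ = D r with r the spike trains
filtered by the same unit leak. The efficiency objective is the
time-averaged squared reconstruction error plus a firing cost with linear
(ν) and quadratic (μ) terms (`readout.coding_loss`).

When Ω = -F D, each voltage becomes a projection of the global coding
error, V = F (x - x̂) (plus -μ r when the quadratic cost is wired into Ω).
In the discrete-time scheme used here this identity is *exact* (see
Discretization), which makes it the core correctness oracle of the test
suite.

Two spike-gated local rules learn this connectivity:

* recurrent rule, at each spike of presynaptic neuron k:
  ΔΩ_ik = -η_r (β (V_i + μ r_i) + Ω_ik + μ δ_ik), with V_i the
  postsynaptic voltage just before the spike's arrival. Its stationary
  point is Ω = -F D for the spike-triggered-error decoder
  D_jk = β⟨x_j - x̂_j⟩_k.
* feedforward rule, at each spike of postsynaptic neuron i:
  ΔF_ij = η_f (x_j - α F_ij), a Hebbian drift of the input weights toward
  the signals that make the neuron fire. For correlated inputs the decay
  term α F_ij is replaced by α·Cov(x_j, g_i), with g_i = Σ_j F_ij x_j the
  neuron's input drive tracked by an exponentially weighted covariance
  estimator (`RunningCovariance`, time constant `cov_tau`).

The Dale-partitioned variant (`EINetwork`) splits the population into
excitatory cells (which receive the analog input) and inhibitory cells
(which receive the excitatory spike trains as their "feedforward" input).
Input→E and E→I weights follow the feedforward rule (the latter with the
filtered excitatory trains r_E in place of x); E→E, I→E and I→I follow the
recurrent rule with the target neuron's voltage. For selective-plasticity
experiments the E→I weights are gated together with the recurrent rule:
they are part of the fast balancing loop, while the input→E weights are
the slow "feedforward" pathway.

## Discretization

Forward Euler with dt = 10⁻³ τ throughout; with instantaneous synapses the
dominant error source is event ordering within a step, not integrator
order. Per step: (1) integrate the voltage leak and feedforward drive,
(2) decay the filtered trains, (3) spike decision, (4) apply the firing
neuron's recurrent column and the unit jump in its filtered train. At most
one spike is fired per step network-wide: among all neurons at or above
threshold, the largest excess V_i - T_i fires and its column is applied
within the step (serializing simultaneous crossings resolves the
ill-posedness of instantaneous mutual resets; the simulator counts
multi-crossing steps as a diagnostic, `SimResult.n_multi`). Plasticity
reads the pre-spike voltage and the pre-jump filtered trains. Under these
conventions the voltage-error identity holds to machine precision, not
merely to O(dt).

A consequence worth knowing: total network throughput is capped at one
spike per step (10³ spikes per τ). Well-trained networks operate far below
the cap, but a large *untrained* network at full drive can saturate the
scheduler, which (artificially) decorrelates its spike trains. Comparisons
of pairwise correlations against untrained references are therefore made
at matched firing rates (reduced input gain), mirroring the rate-matching
used in the robustness experiments.

## Perturbations

* **Sparsity** (`sparsify`): a random off-diagonal mask of prescribed
  density, sampled without replacement; masked synapses are zero and
  frozen (plasticity never writes them); self-resets always survive.
* **Noise**: per-step voltage increment σ·T_i·√dt·ξ with ξ standard
  normal; σ is the noise magnitude in threshold-per-τ units (roughly the
  firing rate the noise alone would cause).
* **Delays** (`make_delay_kernel`): synaptic currents follow an
  alpha-function profile s·e^{-s/τ_d}, normalized to unit charge, with
  τ_d located numerically so the leaky-integrated postsynaptic potential
  peaks at the requested time-to-peak d. Self-resets remain instantaneous
  (a neuron's own reset is intrinsic, and delaying it makes the model
  fire pathologically). d = 0 reproduces the instantaneous simulator
  exactly.

## Dale rectification

Whether sign constraints are enforced by clipping or only by
initialization is genuinely open; the package rectifies, but on a *latent*
weight: the plasticity rules act on an unclipped latent matrix, and the
transmitted weight is its sign-rectified value (excitatory rows ≥ 0,
inhibitory rows ≤ 0, self-resets ≤ 0). Hard clipping of the transmitted
weight itself turns near-zero E→E synapses into a ratchet — negative-going
updates are clipped away, positive ones accumulate — which charges the
network with broad instantaneous E→E excitation and causes recurring
population bursts. The latent ("silent synapse") scheme removes the
ratchet; `EINetwork.dale_rectify=False` disables clipping entirely. The
latent state lives inside a training run and is re-initialized from the
transmitted weights when training resumes.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| dt | 1e-3 τ | forward-Euler step |
| T_i | 0.5 | firing threshold; with unit-norm feedforward rows this matches the efficient operating point T = ‖F‖²/2 |
| Ω_ii (init) | -0.5 | reset to V = 0; learnt thereafter through the rule's δ term |
| β | 1.0 | voltage gain of the recurrent rule; sets the decoder scale D = β⟨e⟩. β = 2 makes each correction a full sign-flip of the error component, which is marginal and rings in the quantized E→I→E loop at scale; β = 1 is dissipative and stable at every size tested |
| μ | 0.05 | quadratic rate cost |
| α | 1.9 | feedforward decay; paired with the default signal gain so the learnt rows settle near unit norm (fixed point F_i = ⟨x⟩_spike/α) |
| α_IE | 1.0 | decay of the E→I feedforward rule (the r_E scale differs from the x scale) |
| η_rec | 0.01 | recurrent learning rate per presynaptic spike |
| η_ff, η_IE | 0.001 | feedforward rates; an order of magnitude slower than η_rec so the network stays balanced while the input map drifts |
| ridge | 1e-4·n_steps | decoder regularization; evaluation always on held-out data |
| v_floor | off | optional clip of V at -T_i. Off by default: the floor pins the deeply hyperpolarized voltages of *unbalanced* networks near threshold and thereby hides the large coding error of the naive state that learning is supposed to remove. It remains available as a stabilizer for extreme regimes |
| guard | 100× max T | simulations abort (training runs flag and truncate) when any voltage exceeds this |

The learning-rate schedule (optional) divides all rates by (1 + t/t_decay).
The full-size EI protocol (300 E / 75 I) uses β = 0.8 with
t_decay = 3000 τ over 16 000 τ of training: at this size the E→E
excitatory mass is large enough that β = 1 still leaves the end state
intermittently bursty for some seeds, while the gentler coupling scale
plus annealing settles it reliably (CV ≈ 1, Fano ≈ 0.7) without changing
the converged correlation level. Small networks need neither.

## Synthetic signals

The training signal is smoothed Gaussian noise: per-channel
Ornstein–Uhlenbeck currents (correlation time `smoothing_tau`, default
0.5 τ) mixed through the Cholesky factor of a prescribed covariance and
normalized so the leaky-integrated signals x have the requested stationary
covariance. Defaults (gain 1.5 per channel) were chosen so that untrained
networks fire in the ~100 Hz range and trained networks settle at
~5–30 Hz — the regime the learning experiments describe. Sine/cosine
pairs, constant-angle probes (for tuning curves) and a low-rank,
non-negative, temporally smooth 25-channel bank (a synthetic stand-in for
spectrogram-like input; no audio is parsed) cover the remaining stimulus
classes. Every generator stores currents c and signals x that are exact
leaky-integration partners, and is bit-reproducible from its seed.

What the generators do *not* emulate: natural-signal nonstationarity,
heavy tails, and the hierarchical temporal structure of real speech.
Results on the structured bank show that the machinery handles correlated,
non-negative inputs; they do not certify performance on real audio.

## Evaluation protocol

Coding error is always measured on held-out signals: a fresh signal is
split in half, a ridge decoder is fitted on the first half and the mse is
reported on the second. Decoder fits need ~100 τ of signal to be stable
(30 τ fits are decoder-starved and noisy by a factor of several); stage
comparisons in the lesion experiment additionally average over three
independent test signals. The Poisson baseline (`poisson_matched_error`)
matches each neuron's trained rate, and is given its best ridge value from
a small grid — a deliberately generous baseline, since sparse random
regressors overfit a fixed small ridge.

The stationarity check of the recurrent rule estimates the self-consistent
decoder D = β⟨e⟩_k by damped fixed-point iteration (the undamped map is
not a contraction) and then tests the mean per-synapse update on a fresh
run against a combined standard error that includes the decoder's own
estimation noise; across ~400 synapses a chance-level fraction beyond 3 SE
is expected and tolerated (≤ 1%).

## Problem sizes used in tests and the acceptance script

Identity/greedy checks: 20 neurons, 20 τ. Stationarity: 500 τ estimation
and test runs. Two-signal learning: 20 neurons, 600 τ recurrent-only plus
2000 τ joint. EI comparisons: N_I ∈ {10, 20, 50} with N_E = 2 N_I, 2000 τ
of training. Delays: {0, 0.1, 0.5} τ (0, 1, 5 ms), three seeds each.
Lesion: 40 E / 20 I, 1000 τ retraining. Decorrelation: the full
300 E / 75 I network with three signals, 16 000 τ of training with the
annealed β = 0.8 protocol. Under these conditions the trained full-size
network reaches mean pairwise correlations of binned spike counts of
≈ 0.008–0.009 (1 τ bins), CV ≈ 1.0 and Fano factor ≈ 0.7 at ~5 Hz
excitatory rates.

## Known limitations

* The one-spike-per-step scheduler caps throughput and biases statistics
  of pathologically overdriven (untrained) networks; see Discretization.
* The quantized E→I→E loop limits how aggressive β can be; the package's
  β = 1 default trades a somewhat higher error floor for stability.
* Mean pairwise correlations of the trained full-size network settle near
  0.009 under the default study conditions, not arbitrarily close to
  zero: the residual is carried by co-tuned excitatory pairs co-modulated
  by the shared signal, and depends on the (free) signal statistics, cost
  constants and bin width.
* Training state (the latent Dale weights, covariance estimators) is not
  serialized; resuming training from a saved network re-initializes it.
* The E coding error of the full-size network under default drive is
  dominated by its very low firing rates; the acceptance surface
  constrains orderings and statistics, not its absolute value.
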