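# Methods

## Model

Both the recognition model q_φ(z|x) and the generative model p_θ(x|z)
are *stochastic recurrent networks*: a two-layer fully connected network
with ELU hidden units outputs the mean and log standard deviation of a
diagonal Gaussian; a reparameterized sample s from that Gaussian is fed
to a *recurrence network* of identical architecture, whose own
reparameterized sample r is recombined with the original as (s + r)/2.
One recurrence step is the default (`recurrence_steps`, 0 disables it).
The head and recurrence networks use independent seeded noise streams.
Because of the nonlinearity and the interpolation, the conditional
distributions are not Gaussian and units within a layer are dependent
given the previous layer — the regime in which likelihood-based
objectives are mis-specified and the adversarial objective is not.

The prior over latents is N(0, I). Activity batches are laid out
(batch, units); images are flattened row-major.

Numerical choice: the raw log-std output is squashed to (−4, 4) with
`4·tanh(raw/4)`. Near zero this is the identity (an all-zero network
still parameterizes N(0, 1)), but it prevents a pathology of the
recurrent composition in which one step's sample drives the next step's
log-std head into overflow. Without the bound, both ELBO and adversarial
training diverge within one epoch at float64.

## Objectives

**Wasserstein wake/sleep.** The discriminator maximizes
mean(D on wake) − mean(D on sleep) minus the gradient penalty
λ·mean((‖∇D‖ − 1)² ) evaluated at per-element random interpolates
u·wake + (1−u)·sleep, u ~ U(0, 1) (two-sided penalty; a one-sided option
exists but is off by default). The inference network minimizes its wake
score mean; the generative network maximizes its sleep score mean. Sign
convention: both models descend the same objective the discriminator
ascends; the overall sign of D is arbitrary (flipping D and both phases
gives an equivalent game). Updates alternate 1:1 per batch —
discriminator first, then both models against the updated discriminator.

**Oscillatory (layerwise).** Discriminator cells are restricted so each
observes units from a single layer. In addition to the wake/sleep terms,
each wake batch is reconstructed (x → z → x′) and the input-layer cells
score x against x′, with a second gradient penalty on that pair; the
models additionally minimize the discriminator-cell hidden-feature
distance between x and x′ (coefficient 1.0, configurable). The local
discriminators also receive the plain wake-vs-sleep comparison, so the
layerwise game remains a superset of the joint one restricted to local
observations.

**ELBO baseline.** The standard variational bound with the entropy and
KL terms computed from the *pre-recurrence* Gaussian parameters, and the
reconstruction term from the generator's pre-recurrence Gaussian head,
while the latent sample itself still runs through the recurrence. With
recurrence disabled this is exactly the textbook Gaussian-VAE bound
(verified against an independent closed form); with recurrence active it
is deliberately mis-specified — that mis-specification is the point of
the comparison.

**Plasticity rules.** For a linear-nonlinear cell
D = σ(W_x·x + W_z·z), the Wasserstein update is ±x⊙σ′ (wake/sleep), an
exact phase reflection; the standard (log-loss) GAN update is
x⊙σ′/σ in wake and −x⊙σ′/(1−σ) in sleep — Hebbian/anti-Hebbian in
character but not an exact reflection. W_z updates mirror the W_x form
with z as the presynaptic factor. The REINFORCE form of the model
gradient, E_q[D·∇_φ log q_φ], is implemented for the Gaussian head (the
tractable pre-recurrence density) and is checked against the pathwise
gradient; training itself uses pathwise (reparameterized) gradients.

## Optimization

Adam with β₁ = 0.5, β₂ = 0.99, decoupled weight decay 2×10⁻⁵.
`TrainConfig` defaults hold the full-scale configuration: batch 512,
model learning rate 1e-4, discriminator 4e-4, 400 epochs, λ = 1, with
rates decaying ×0.96 per epoch between epochs 200 and 250 (the decay is
applied per epoch within the window; a single total decay over the
window is the other defensible reading).

The scikit-learn estimators default to a desk-scale configuration that
trains in minutes on one CPU: 16×16 images, hidden width 64, latent 16,
discriminator cells of width 64, batch 128, 30 epochs. At ~10³ updates
the full-scale learning rates leave the minimax game far from
equilibrium, so the estimator defaults are model 1e-3 / discriminator
4e-3 (same 1:4 ratio); under these the discriminator objective settles
near zero and generated pixel statistics approach the data's.

Discriminator ensembles default to 4 cells, each observing a uniformly
drawn 50% of eligible units (fixed at construction by seed). Cells are
3-layer networks with LeakyReLU(0.2) hidden units and a linear scalar
output; the ensemble decision is the arithmetic mean over cells.

## The 4-neuron toy experiment

Teacher T drives B and C (weights w_TB, w_TC); B drives C (w_BC,
default 1.0); all units sum linearly with unit-variance Gaussian
postsynaptic noise; sources T and A are N(0, 1). Teacher weights are
drawn once from N(0, 1) with published seed 5, giving
(w_TB, w_TC) = (−0.802, −1.324); student weights are N(0, 1) per run
seed, shared between both trainers.

The *independent-prediction baseline* does least-squares prediction of
each teacher-driven node from the shared source activity
(−log N(B; w_AB·a, s_B²) − log N(C; w_AC·a, s_C²), a local delta rule,
plain gradient descent at 1e-3, 5000 steps ≈ 5 time constants). Its
optimum absorbs the recurrent path into the direct weight
(w_AC → w_TC + w_BC·w_TB), which double-counts recurrence once the
student population runs with its internal connection — so the joint
distribution fails exactly when w_BC ≠ 0, and is exact when w_BC = 0.

The *adversarial trainer* pits a one-hidden-layer (20 LeakyReLU(0.2)
units, small-initialized linear output) discriminator over (B, C)
against the student weights, Wasserstein objective with gradient penalty
0.1, RMSProp 1e-3 on all weights, 2000 steps, batch 256. A config flag
lets the discriminator additionally observe the source activity.

Alignment is scored by the empirical KL between hexagonally binned 2-D
histograms — 25 bins per side over extent [−5, 5] × [−5, 10] (the
binning geometry matches matplotlib's hexbin exactly and is
cross-checked against it), pseudocount 1 per bin, samples outside the
extent clipped to its boundary — and by the parameter error
min_{s=±1} ‖(w_AB, w_AC) − s·(w_TB, w_TC)‖₂, sign-invariant because ±w
induce the same joint distribution under a symmetric source.

## Pattern-alignment diagnostics

Activity vectors from both phases are rounded to the nearest integer
(half away from zero), a seeded random subset of 16 input and 16 latent
units is fixed across phases, and exact multiset counts of the 32-unit
patterns are compared: the paired wake/sleep frequency table is the data
behind the diagonal scatter, and the scalar summary is the
Jensen–Shannon divergence (symmetric, bounded by log 2, finite on
disjoint supports; the divergence the original visual comparison does
not name).

Known limitation: the sleep-phase latent activity is a raw draw from the
N(0, I) prior, and 16 i.i.d. rounded standard normals span ≈ 2³⁴
effective patterns, so at feasible sample sizes the wake and sleep
supports over the *joint* 32 units are disjoint for any model, well or
badly trained, and the joint divergence saturates at log 2. The
informative part of the statistic at this scale is the input block,
where quantized patterns repeat heavily: after training, the adversarial
model's generated inputs share a large fraction of wake pattern mass
(≈ 0.2–0.5 in our runs) while the ELBO baseline's share is zero — the
qualitative contrast the diagnostic is meant to expose. The acceptance
script therefore reports both the joint 32-unit divergence and the
input-block divergence/shared mass.

## Synthetic digits

`generate_digits` renders seven-segment-style stroke templates
(n_classes ≤ 10) with Gaussian-profile strokes and per-image jitter in
position, scale, thickness and intensity, normalized to [−1, 1]. The
batches are multi-modal (nearest-template accuracy ≈ 0.99 at the default
scale) and low-rank (top 20 principal components ≈ 0.97 of variance) —
the two properties of handwritten-digit data the pipeline exercises.
What they do not emulate: stroke curvature/topology variation, label
noise, or pixel-value distributions of photographs; conclusions about
real MNIST require the IDX path. Labels are generated but unused by
training (the method is unsupervised).

## Autodiff

All gradients come from a package-internal reverse-mode engine over
numpy arrays (`wakesleep.autodiff`). Every vector-Jacobian product is
itself composed of primitive ops, so gradients of gradients are exact —
required because the gradient penalty differentiates the discriminator's
input gradient with respect to its parameters. The engine implements
only the ops the package needs; first- and second-order outputs are
tested against central finite differences. The penalty's norm is
computed without an epsilon so a 1-Lipschitz linear scorer yields a
penalty of exactly zero; the general `row_norm` helper keeps a 1e-12
epsilon to protect degenerate zero-gradient rows elsewhere.

## Determinism

Every sampling operation takes an explicit seed or Generator;
training derives per-epoch streams from (config seed, epoch). Identical
configurations reproduce loss reports, trajectories and CSV artifacts
bit-for-bit.
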