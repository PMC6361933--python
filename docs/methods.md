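# Methods

This note documents the model, the analysis chain, the calibration
choices, and the limitations of `critsync`. It is the place where design
decisions that the code cannot explain by itself are written down.

## Network model

The substrate is the deterministic hierarchical scale-free construction
of Ravasz and Barabási with modules of five. Step 1 builds five complete
5-cliques and wires the four peripheral nodes of each replica clique
(positions 1–4; position 0 is the replica's own centre) to node 0, the
hub, giving 25 nodes with a hub of degree 20. Step 2 replicates the
25-node unit four more times and wires each replica's 16 outer
peripheral nodes to node 0, giving 125 nodes, one global hub of degree
84 and four local hubs of degree 20. Five independent step-2 units form
the 625-node assembly: 5 global and 20 local hubs, i.e. hubs are 4% of
the nodes. The assembly adds **no** edges between replicas — all
inter-replica coupling comes from the rich club.

Rich-club wiring connects every unordered, non-adjacent hub pair —
global–global, global–local and local–local, across replicas —
independently with probability κ. At κ = 1 global hubs reach degree 108
(≥ 100) and local hubs degree 44, which is where the quoted hub degree
windows (local 20–44, global ≥ 100) come from; the classifier itself is
structural (construction role), and the degree windows are asserted as
invariants rather than used to classify, because they differ between the
125-node (global ≥ 80) and 625-node (global ≥ 100) systems.

All edges are bidirectional (two directed links); every outgoing link
carries the sign of its source neuron (Dale's law). Two supplementary
variants are provided: keeping one random direction per edge, and
redrawing every incoming link's source uniformly (preserving indegrees,
destroying hierarchy and clustering).

### Degree-distribution exponent

The family's exponent is γ = 1 + ln 5 / ln 4 ≈ 2.16: each hierarchy
level multiplies hub degree by ~4 and divides hub count by ~5. A finite
instance concentrates its degrees on five atoms (4, 5, 6, 20, 84), which
makes pmf-based estimators meaningless here: a discrete zeta-ML fit with
KS-selected cutoff returns γ ≈ 3.3 regardless of cutoff, because it fits
the shape of the atom spacing, not the inter-level scaling. The package
default `degree_exponent` therefore regresses the log survival function
over the top-5% tail (the hub hierarchy; hubs are 4% of nodes by
construction), which returns 2.12 on the 625-node instance and recovers
the exponents of synthetic Pareto-tailed samples within ±0.1. The
discrete-ML variant is kept as `degree_exponent_ml` for cross-checks.

## Neuron model and input

Neurons follow the two-variable Izhikevich model: dv/dt = 0.04v² + 5v +
140 − u + I + s, du/dt = a(bv − u), with reset v ← c, u ← u + d when
v ≥ 30 mV. Heterogeneity uses one uniform draw r per neuron:
excitatory a = 0.02, b = 0.2, c = −65 + 15r, d = 8 − 6r (regular spiking
→ chattering); inhibitory a = 0.02 + 0.08r, b = 0.25 − 0.05r, c = −65,
d = 2 (low-threshold → fast spiking). Integration is midpoint RK-2 at
h = 0.1 ms, with inputs held constant within a step; spike detection and
reset follow the update, and stored traces cap spikes at 30 mV (so the
global state S(t) — the mean membrane potential, conserved exactly as
the mean of the stored traces — uses capped values).

**Thalamic drive.** The literature states the input magnitudes (I = 5
excitatory, I = 2 inhibitory) but not the distribution of the "noisy"
input, and at h = 0.1 ms this choice decides everything: a zero-mean
Gaussian of std 5 per step leaves the network completely silent, while a
constant drive of 5 makes every excitatory cell a 15 spks/s tonic
oscillator. We use

    I_t = μ·I_i + σ·I_i·ξ_t / √h,   ξ_t ~ N(0, 1) i.i.d.,

with (μ, σ) = (0.65, 0.10), fixed once by two published operating
characteristics: the mean excitatory rate must cross 5 spks/s near
w = 40 mV at h = 0.1 ms (we measure 4.75 ± 0.38 across network
realizations), and the dynamics must live in the excitable avalanche
regime in which an excitatory hub can ignite collective firing while an
inhibitory hub quenches it. At μ = 0.65 an excitatory cell rests ~9 mV
below its saddle-node, so the h·w = 4 mV synaptic kicks propagate
cascades that the noise ignites. The 1/√h scaling makes the stochastic
drive accumulated per millisecond independent of the resolution; since
the synaptic impulse is h·w (a spike injects ±w for a single step),
rate-versus-weight curves at different h collapse when w is rescaled by
the step-size ratio — which is exactly the collapse the calibration
experiment verifies. We verified that the DFA and lability exponents
reported by the acceptance experiments are insensitive to where on the
rate-matching ridge of (μ, σ) the calibration sits; they are properties
of the avalanche regime, not of the calibration point.

Synapses deliver for exactly one step, at step t+1 after a spike at t,
with equal magnitude for excitatory and inhibitory links (±w); there are
no delays, kernels, or plasticity.

## Detrended fluctuation analysis

DFA-1: mean-subtract, integrate, split the profile into non-overlapping
windows (trailing partial window discarded), detrend each window with
its own least-squares line, pool residuals, and fit log F(n) against
log n. The default fit range for 10⁴-step recordings is n ∈ [10, 1000]
with 20 log-spaced window sizes; for shorter series the upper end drops
to a quarter of the length. α = 0.5 / 1.0 / 1.5 mark white / 1/f /
Brownian signals (β = 2α − 1 for the spectral slope); on 10⁴-sample
surrogates the estimator recovers these anchors within ±0.05 averaged
over 20 seeds.

## Global lability of synchronization

The 625 recorded membrane traces are averaged over the 125 five-node
clusters. Phases come from the FFT-based analytic signal of each
mean-removed cluster signal. For a pair (i, j), the phase difference is
the argument of z_i·conj(z_j) (unit phasors of the analytic signals).
The printed form of the phase-difference formula in the source
literature has a minus sign in its denominator where the standard
trigonometric identity requires a plus; we implement the standard
identity, which is what makes Δθ equal θ_i − θ_j.

A pair is synchronized at t when |Δθ(t)| < π/4 **and** the mean
resultant length of Δθ over the forward window [t, t+ν), ν = 50 steps,
exceeds √½. M(t) counts synchronized pairs (≤ C(125,2) = 7750); the
first and last ν samples of each phase series are excluded (FFT edge
distortion) and the last ν samples of the remainder carry no complete
window. The lability is ℓ(t) = |M(t+1) − M(t)|².

Its density G(ℓ) is estimated in log-spaced bins over the positive
values (ℓ = 0 means no rearrangement and is excluded). The exponent of
G(ℓ) ~ ℓ^−δ is a maximum-likelihood fit of a power law with bounded
exponent 0 < δ ≤ 1 on the finite support [1, 99th percentile of positive
ℓ] — the percentile guards the fit against single extreme global events;
the reported mse is the mean squared log₁₀ residual of the binned
density against the fitted law. On synthetic bounded power-law samples
(inverse-CDF generator in `signals`) the fit recovers
δ ∈ {0.3, 0.5, 0.7, 0.9} within ±0.05 at 10⁴ samples. A constant M
(fully locked or unlocked ensemble) yields no fit and is reported as
undefined rather than forced.

## Experiments and problem sizes

`experiments.sweep` averages the DFA exponent per (κ, η) cell over
independently seeded runs (seeds derive from a base seed and the cell
coordinates, so any pixel can be regenerated in isolation);
`experiments.lability_grid` pools ℓ across runs per cell before the
density and fit. Full-scale phase diagrams use 50 runs per pixel and
lability distributions 100 runs; the test suite and the acceptance
script run the same pipelines at desk scale — 5 seeds per DFA
configuration, 10 runs per lability cell, and a 6-cell spot-check per
phase-diagram region — sizes at which the cell means are stable to
±0.05 (α) and ±0.03 (δ).

Each simulation discards 8000 transient steps and records 10⁴ steps
(1 s at h = 0.1 ms); the synaptic weight is fixed globally at the
calibrated w = 40 for every cell.

## What the generators emulate — and what they do not

The surrogate module provides exactly the statistical structure the
analyses assume: stationary zero-mean Gaussian noise with prescribed
spectral slope (spectral synthesis, unit variance — DFA's α is
scale-invariant, so fixtures are comparable across β), common-frequency
sinusoid ensembles with controlled phase offsets for the synchrony
pipeline, and bounded power-law samples for the exponent fit. Passing
those tests validates the estimators, not the simulation: the surrogates
have none of the nonstationarity, spikiness or cross-correlation
structure of real membrane potentials, so simulation-level checks rest
on the end-to-end acceptance experiments.

## Known limitations

- The thalamic input model is a calibrated convention; only its
  operating point, not its form, is constrained by published values.
  With it, the case-2 (excitatory global hubs) regime synchronizes
  slightly more strongly than the published exponents suggest: the
  sparse-rich-club case-2 cell measures α ≈ 1.53 where ≈ 1.38 is
  expected, and the strongly coupled case-2 cell stays continuously
  synchronized (M pinned near 7750), so its lability density is not
  flat (fitted δ rails at 1 instead of ≈ 0.24). The case-1 1/f region,
  the calibration curve, the hub-contrast phenomenology and the case-1
  lability exponents do reproduce.
- The bounded-exponent ML fit caps δ at 1 by construction; steeper
  densities are reported as δ = 1 with a large mse rather than
  extrapolated.
- Hub classification and cluster labels are only defined for the 25-,
  125- and 625-node systems; the construction is not generalized to
  other branching factors or depths.
- The rich-club coefficient's null model uses degree-preserving double
  edge swaps (default 10 swaps per edge, 100 replicates), which mixes
  slowly on graphs this small; Φ_norm values very close to 1 should not
  be over-interpreted.
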