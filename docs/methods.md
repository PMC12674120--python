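# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Probability model

**Amplitude priors.** Structure factor components are Gaussian by the central
limit theorem over atomic contributions. With symmetry multiplicity ε, the
per-component variance is ε for centric reflections (one real component) and
ε/2 for acentrics (real and imaginary). Amplitudes therefore follow

- centric: p(F) = √(2/(πε))·exp(−F²/(2ε)),
- acentric: p(F) = (2F/ε)·exp(−F²/ε),

and E[F²] = ε in both classes. For a child dataset whose components are
correlated with its parent's at level r, the conditional amplitude law is
folded normal (centric) with scale √(ε(1−r²)) or Rice (acentric) with
noncentrality r·F_parent and scale √(ε(1−r²)/2). These scales are pinned by
the requirement that the child *marginal* be exactly Wilson — a property the
suite verifies by KS test — which resolves the σ-versus-σ² ambiguity a reader
might otherwise face in the conditional parametrization. At r = 0, and only
at r = 0, the conditionals coincide with the univariate Wilson law; a
systematically absent parent is handled by evaluating the conditional at
F_parent = 0, which is Wilson with *reduced* effective multiplicity ε(1−r²).

All densities are evaluated in log space; the Rice density uses the
exponentially scaled Bessel I₀ (`i0e`) with the argument added back on the
log scale, so ν·x/σ² beyond 700 cannot overflow. Negative r is not supported:
anti-correlated datasets do not occur in the intended applications.

**Amplitude correlation.** The Pearson correlation between parent and child
amplitudes is often quoted as ≈ r². The exact value for the bivariate
Rayleigh case is CC = (π/2·₂F₁(−½,−½;1;r²) − π/2)/(2 − π/2), which is
0.2326 / 0.6988 / 0.9771 at r = 0.5 / 0.85 / 0.99 — up to 0.024 below r².
Unit tests check the sampler against the exact closed form; for intensities
the law is exact, corr(F²_parent, F²_child) = r².

**Likelihood.** I ~ Normal(Σ·F², σ_I) by default; a location-scale student-t
with configurable degrees of freedom is available as a robustness option.
Reported σ_I are taken at face value.

**Scale model.** qΣ is log-normal: a multilayer perceptron maps standardized
metadata features to (location, softplus dispersion), guaranteeing positive
scales and a one-line reparameterized sampler. Features: Miller indices,
1/d², user metadata columns, sin/cos positional encodings of detector
coordinates (L = 8 frequency pairs per coordinate, frequencies geometric from
π to 2⁷π on the coordinate mapped to [−1, 1]), dataset one-hots, and image
one-hots up to 512 images (a standardized scalar image id beyond that).
Zero-variance columns are dropped with a warning. Default architecture: 6
hidden layers × 32 units with SiLU activations; the desk-scale benchmarks use
3 × 16, which is ample for the simulated scale fields and several times
faster.

The location head carries a **trainable linear skip connection** initialized
from a classical scaling pass — an ordinary least-squares regression of log
intensities on the image / dataset / resolution features. Without it, the
smooth resolution falloff of the scales stays stuck inside the 300 individual
amplitude parameters where the per-reflection initialization put it, because
migrating a coherent trend out of hundreds of independent surrogates is a
slow, flat direction of the ELBO. With the moments initialization the trend
starts inside Σ and the network only learns corrections. This mirrors
long-standing practice of seeding iterative scaling with a direct fit.

## Variational inference

The surrogate over each (dataset, hkl, Friedel-sign) amplitude is an
independent truncated normal on [0, ∞), sampled by inverse-CDF
reparameterization (u → μ + σ·Φ⁻¹(Φ(−μ/σ) + u(1−Φ(−μ/σ)))), with the CDF
argument clipped to [1e−12, 1−1e−12]. The Monte-Carlo ELBO (default S = 8
joint samples per step) evaluates the structured prior for each child at the
same-sample parent amplitude; parents precede children because reflections
are ordered topologically. A child hkl missing from the parent dataset falls
back to the univariate Wilson prior. Bijvoet halves produced by
`split_friedel_halves` are matched across the edge by hkl, preferring the
same sign.

Optimization is Adam over (μ_q, softplus-inverse σ_q, θ) with a geometric
learning-rate decay from 1e−3 to 1e−4 over the run (default 2000 steps,
full batch). The decay matters for difference signals: after the bivariate
prior shrinks ΔF, the residual signal is small and would otherwise be buried
under the stationary stochastic-gradient jitter of the surrogate means. When
r is optimized it is parameterized as a sigmoid of an unconstrained logit and
updated by a separate Adam instance at 10× the base rate, since useful moves
span several logit units. Initialization: μ_q from baseline-corrected
per-reflection mean intensities on the global scale Σ₀ = mean(I) (floored at
√(0.1ε)), σ_q = 0.1·μ_q. Training is fully deterministic given the seed; a
non-finite ELBO aborts with the step index.

`scale_mode="fixed"` replaces the MLP by the constant Σ₀. It exists for
problems whose scales are known to be flat — including simulation studies
that isolate the effect of the prior, and tiny problems where the brute-force
log evidence is computable by quadrature.

## Merging and analytics

Merged amplitudes are the closed-form mean/SD of the truncated-normal
surrogate, evaluated with `log_ndtr`-based hazard ratios so extreme μ/σ in
either direction is stable. Difference sets use
w = (1 + σ²(ΔF)/⟨σ²(ΔF)⟩ + α|ΔF|²/⟨|ΔF|²⟩)⁻¹ with unweighted means over the
shared Miller indices (resolution-binned averaging was considered and left
out: the desk-scale sets are too small to bin meaningfully). CC1/2 bisects
observations at random (observation level, not image level — the convention
is exposed as a seedable repeat), scales and merges each half independently,
and correlates merged amplitudes overall and per equal-population resolution
bin. CCpred correlates observed with predicted intensities (posterior-mean F²
× posterior-mean Σ) separately on scaling and held-out observations. CCanom
correlates half-dataset Bijvoet differences. The r-scan re-runs scaling on
the grid r_k = 1 − 0.5^k, optionally on the first fraction of images per
dataset (ascending image id), holding out 10% of observations for CCpred at
every grid point.

r can also be estimated *post hoc* from two independently merged datasets:
amplitudes are first normalized per equal-population resolution shell so that
mean F²/ε = 1 (shells below 10 reflections are merged with a warning), then r
maximizes the per-pair conditional log-likelihood over [0, 1−1e−6] by bounded
scalar search (Brent, xatol 1e−6), initialized if desired from
√max(0, CC(F_a, F_b)). Estimates from noisy merged amplitudes are attenuated
toward 0 — visible in the README example — so the scan or direct ELBO
optimization is the recommended route when data are weak. Near r = 0 the
likelihood is flat to O(r²) and the MLE fluctuates on the n^(−1/4) scale;
tests bound r̂² rather than r̂ there.

## Synthetic data

The generator draws distinct Miller indices (labels only — no lattice
geometry), resolutions with 1/d² uniform between the configured limits,
centric flags at the configured fraction, ε from a configurable distribution,
and complex components along the dataset DAG by the exact double-Wilson
construction. A configurable fraction of reflections receives an extra
child-only Gaussian kick — the localized "perturbation" a difference map
should find. An atomistic mode builds phasor sums over jittered point
scatterers (acentric only) to confirm that fitted r tracks physical
coordinate change. Anomalous signal adds ±i·s·H to Friedel mates with a
heavy-substructure H drawn like F; centric H is real, so phase-restricted
reflections keep exact Friedel symmetry at any strength. Observations get
Poisson-distributed multiplicities (min 1) across distinct images, true
scales Σ = exp(a_img + b/d² − g·(x²+y²)/2) smooth in image, resolution, and
detector position, and Gaussian noise with σ = noise_floor·√max(Σ F²,
noise_floor) reported honestly in sigI (an error-model mismatch can be
emulated by editing sigI).

**Benchmark conditions.** Two fixed configurations anchor the test suite and
the acceptance script:

- *single-dataset recovery*: 300 reflections, 30 images, mean multiplicity 6,
  noise floor 0.05 — measures CC(merged F, true F) and CC(Σ̂, Σ_true);
- *comparative*: 800 reflections, mean multiplicity 3, noise floor 0.5, true
  r = 0.99, 5% perturbed at magnitude 0.5 — the sparse, noisy regime
  (serial-type data) where pseudoredundancy between related datasets has the
  most to offer. Scales are flat and merging uses the fixed global scale so
  the comparison isolates the prior; an exact-Bayes quadrature oracle on the
  same data confirms both the direction and the approximate size of the
  bivariate-over-univariate gap, i.e. the variational approximation is not
  manufacturing the effect. With the MLP in the loop both arms acquire the
  same extra scale-fit noise, which at these problem sizes is comparable to
  the post-shrinkage ΔF signal itself; separating the two questions keeps
  each test sharp.

Problem sizes throughout (hundreds of reflections, thousands of
observations, 1–2k optimizer steps) are chosen so the full suite runs on a
single CPU in a few minutes.

## What passing tests do and do not show

The generator produces data from exactly the model the method assumes —
Gaussian noise with truthful sigI, multiplicative smooth scales, a single
global r. Passing tests therefore demonstrate correctness of the densities,
the construction, the optimizer, and the comparative advantage *under the
model*; they do not demonstrate robustness to misspecified error models,
non-isomorphism that varies with resolution (per-shell r is not implemented),
partiality, absorption, or detector artifacts that real unmerged data
contain. No space-group machinery exists: hkl must arrive mapped to one
asymmetric unit with centric/ε supplied, as the simulator does. Phase
information and map-space analysis are out of scope; outputs stop at merged
amplitudes, differences, and weights.
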