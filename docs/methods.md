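# Methods

## Model

Each of N cells moves in the plane according to an Itô SDE with isotropic
diffusion,

    dx_i = a_i(x) dt + σ_i dW_i,        Σ_i = σ_i I,

where the drift is the negative gradient of a summed pairwise potential,
`a_i = −Σ_{j≠i} ∇ U(‖x_i − x_j‖)`. All interactions are pairwise and
identical across pairs, and the interaction function is treated as known;
only the per-cell diffusion parameters σ_i are inferred. Lengths are in
average cell diameters, times in seconds, so σ has units diameter·s^(−1/2);
the MSD-literature diffusion coefficient is D = σ²/2 and appears only in
the labelled helper `sigma2_to_diffusion`.

The pair potential is

    U(r) = D_e [1 − (φ(r)/φ(r₀))^a]² − D_e,

with φ(r) = e^(−r) (Morse) by default and φ(r) = 1/r (Lennard–Jones) as an
alternative. D_e is the well depth (U(r₀) = −D_e), `a` the well steepness,
and r₀ the equilibrium separation, fixed at one cell diameter in all
shipped experiments. Drift and its Jacobian are computed analytically from
the radial/tangential decomposition of the Hessian of U(‖·‖); the Jacobian
is assembled from its three unique components, so it is symmetric to the
bit, which the transition covariance's positive-definiteness guarantee
requires.

## Transition densities

Over one observation gap Δt, two Gaussian approximations of
`x_i(t_k + Δt) | x(t_k)` are available:

* **Euler–Maruyama** (`euler_transition`): mean `x + aΔt`, covariance
  `σ²Δt·I`. This is exactly the free-Brownian increment model behind MSD.
* **Higher order** (`hom_transition`): same mean, covariance
  `S = S₁ᵀS₁ + S₂ᵀS₂` with `S₁ = σ√Δt(I + Δt/2·A)` and
  `S₂ = σΔt^{3/2}/√12·A`, where `A` is the drift Jacobian at `t_k`. The
  update behind this law is `x + aΔt + σZ₁ + σA·Z₂`, with Z₁ the Wiener
  increment and Z₂ its time integral; per dimension,
  Var(Z₁) = Δt, Var(Z₂) = Δt³/3, Cov(Z₁, Z₂) = Δt²/2, realised in
  `sample_z1_z2` as Z₁ = √Δt·U₁, Z₂ = Δt^{3/2}/2·(U₁ + U₂/√3).

For symmetric A the higher-order covariance is positive definite for every
Δt; its smallest eigenvalue has a closed form in the trace and determinant
(`smallest_eigenvalue_closed_form`), whose discriminant is a sum of
squares, so the eigenvalues are always real and positive. Asymmetric
Jacobians (possible if a user supplies a non-potential drift) fall outside
the guarantee: beyond a 1e−9 symmetry tolerance the code warns and falls
back to a numerical positive-definiteness check, rejecting non-PD results
rather than symmetrising silently.

σ enters the covariance only as a global factor, so the code always builds
the σ-free normalized covariance S̄ = S/σ² first; likelihood scans over σ
and the conjugate update never rebuild matrices.

## Inference

With K observed transitions and precision τ = σ⁻², a Gamma(α₀, β₀) prior
is conjugate under either transition model:

    α_K = α₀ + K,
    β_K = β₀ + ½ Σ_k (x_{k+1} − m_k)ᵀ S̄_k⁻¹ (x_{k+1} − m_k),

with m = x (previous position) and S̄ = Δt·I for the MSD route, and the
higher-order m, S̄ otherwise. The shape grows by one full unit per 2-D
observation (the exponent contributes τ^{d/2} per step with d = 2). The
MLE is σ̂² = β_K/K under the improper prior α₀ = β₀ = 0, which is the
default in every shipped experiment; with interactions off it reduces
exactly to the MSD per-increment estimator Σ‖Δx‖²/(2KΔt). Point estimates
are posterior modes taken on the τ scale and mapped to σ,
σ̂ = √(β/(α−1)), defined for α > 1. Each particle gets its own posterior;
a pooled (shared-σ) variant that sums the α- and β-increments across
particles is provided as an option. Quadratic forms use the closed-form
symmetric 2×2 inverse with a determinant guard at 1e−300. The Gaussian
log-likelihood uses the standard 2-D normalization (2πσ²√|S̄|)⁻¹.

## Synthetic-data generator

`simulate` reproduces the in-silico migration experiments: N cells seeded
i.i.d. uniform in a centred 40×40 square, confined to 50×50 by hard walls,
integrated with Euler–Maruyama steps of h = 1 s (effectively continuous
relative to the dynamics, whose fastest curvature rates are ~5e−3 s⁻¹) and
observed every 5–60 minutes. The fine-step integrator deliberately does
*not* use the higher-order scheme, so the data-generating process is
independent of the inference approximation being tested. Walls are
implemented as reflections (coordinates folded back into the box), chosen
over clamping because reflection preserves interior Brownian statistics
and is isolated in one function (`_reflect`) should clamping be wanted.
The population size is constant — no division or death. One seeded
generator drives each run, with the seeding and dynamics streams split
from the config seed, and noise drawn as an N×2 block per step in fixed
particle order: identical config + seed gives bit-identical output.

Presets (`exp0`–`exp4`): exp0 has D_e = 4e−4, a = 4, σ = 1e−2, N = 100;
exp1–exp4 have D_e = 2.1e−4, a = 3.5, σ = e^(−9/2) ≈ 0.011109 and
N = 64, 128, 256, 512; all default to two simulated days. Durations, N and
interaction parameters are overridable, and scaled-down runs are
first-class.

What the generator does not emulate about real microscopy data:
measurement noise on positions, frame-to-frame tracking errors, cell
division/death and heterogeneous interaction strengths. Passing tests
therefore demonstrate correctness of the estimators under the stated SDE
model, not robustness to those effects.

## Evaluation

Per-method accuracy on one dataset is the root-sum-square mode deviation
`E = √Σ_i (σ − σ̂_i)²`; the package reports `delta = E_msd − E_hom`
(positive when the interaction-aware method is closer). Mode histograms on
the natural-log scale are smoothed with a Gaussian kernel of fixed
bandwidth N^(−5/8) (optimal-rate bandwidth in the population size, applied
identically to both methods), evaluated directly on a grid. The
density × resolution comparison grid simulates one dataset per cell with
per-cell seeds derived from a master seed, and records full provenance.

## Problem sizes and numerical choices

The test suite and the acceptance script use scaled-down designs chosen to
exercise the same regimes as the full two-day experiments: recovery runs
use N = 128 (or 100) cells for 4 simulated hours at 5-minute sampling
(K = 48), and the equilibrated-crowding comparison uses 32 hours
(K = 384). Monte-Carlo moment checks use 1e5 draws with 3-standard-error
bands; the χ² sampling-distribution check uses 500 replicates of K = 20
Brownian increments. Pair interactions are summed exactly (O(N²), no
cutoff) in all shipped runs; an optional cutoff radius exists for larger
systems. Pairs closer than 1e−8 cell diameters raise a degenerate-geometry
error — gradients diverge there and the experiments never produce such
configurations.

## Known limitations

The higher-order density linearizes the drift across the observation gap.
Its accuracy is governed by |λ|Δt, where λ ranges over the eigenvalues of
the drift Jacobian. In crowded configurations a cell bound in the Morse
well of 1–3 neighbours has |λ| ≈ 2·D_e·a²·(number of neighbours) ≈
2.6e−3–8e−3 s⁻¹, so at 5-minute sampling |λ|Δt ≈ 0.8–2.4: outside the
small-|λ|Δt regime. The result is a systematic *over*-estimate of σ for
clustered cells — roughly +8–10% of the population-mean posterior mode at
5-minute sampling under the exp2/exp3 conditions, vanishing as the
sampling interval shrinks (the population mean is within Monte-Carlo error
of the truth at 5-second sampling). The MSD route errs in the opposite
direction and its bias grows as the population clusters (from about −4%
shortly after uniform seeding to −11% once equilibrated), so the
interaction-aware method wins on the error sum E once the population has
equilibrated (demonstrated at 32 h in the suite), while at short times
after seeding MSD can still be the better-calibrated estimator. Remedies
that keep conjugacy are limited: the expansion used here is the highest
order at which σ appears linearly enough for the Gamma conjugacy, so
further improvement requires propagating moment ODEs across the gap at the
cost of the closed form.
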