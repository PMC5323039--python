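# Methods

This note documents the models behind `poreflux`, the numerical choices
that matter, what the synthetic-data scenarios do and do not emulate, and
the known limitations.  Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Units and constants

Lengths in Å, times in ps, energies in kcal/mol, temperatures in K,
charges in elementary charges.  k_B = 1.987204×10⁻³ kcal/(mol·K).  The
conductance conversion constant e²/(kcal·mol⁻¹·ps) → pS is derived from
CODATA values at import; the "SI path" of the conductance calculation
re-derives γ entirely in SI units from the same thermal energy and must
agree with the internal path to 10⁻¹⁰ relative (tested).

## Brownian engine

Overdamped Langevin dynamics by first-order Euler–Maruyama,

x ← x + (D₀/k_BT)·F(x)·dt + √(2·D₀·dt)·η,

whose stationary law is the Boltzmann distribution of the supplied
potential up to O(θ·dt) corrections with θ = βD₀·U″ the local relaxation
rate.  Step sizes are chosen per study so that θ·dt ≲ 0.03 and so that
the per-step noise displacement √(2D₀dt) is at least ~7× smaller than the
narrowest potential feature (a switching shell, a restraint boundary).
Every potential term returns the exact negative gradient of its energy;
the suite verifies this by central finite differences (relative error
< 10⁻⁵ at 10⁻⁴ Å steps) for every term type.  One seeded PCG64 generator
drives each system; per-walker seeds are `seed + walker_index`.  Identical
(seed, configuration) reproduces trajectories bit-for-bit.

The engine deliberately omits inertia, hydrodynamics, explicit solvent
forces, and pair interactions: the estimators under test assume only
diffusive dynamics in a potential, and every added ingredient would blur
the analytic oracles.

## Density collective variable

The wetting order parameter is ρ = Σᵢ ξ(Xᵢ)/V over a soft cylinder of
nominal radius R and half-length Z with switching shells ΔR, ΔZ.  The
switching function

χ_S(σ) = (b²−σ²)²(b²+2σ²−3a²)/(b²−a²)³,  a = S−ΔS/2, b = S+ΔS/2,

is a smoothstep in σ²: χ(a)=1, χ(b)=0, with dχ/dσ = 12σ(b²−σ²)(a²−σ²)/(b²−a²)³
vanishing at both shell edges.  The effective volume factorises; the
radial factor has the exact closed form π(R²+ΔR²/4) and the axial shell
integral is evaluated after the substitution σ = a + ΔS·x, which keeps the
coefficients O(1) for arbitrarily thin shells (the naive polynomial
antiderivative cancels catastrophically as ΔS → 0).

Gradients are analytic and non-zero only inside the shells.  By default
the gradient is taken at fixed frame — reference particles feel no
counter-force from the bias, matching common practice — and an exact mode
adds the chain-rule terms through the anchored origin and axis, restoring
Σᵢ ∂ρ/∂xᵢ = 0 (tested against finite differences).  The frame's origin is
the centroid of a middle reference group; its axis the unit vector
between two distal group centroids, so ρ is invariant under rigid motions
applied jointly to particles and references (tested).

Neighbor lists include everything within the outer boundary plus a margin
(default 4 Å, refresh every 200 steps; the metadynamics driver uses a
50-step stride).  Because the evaluation sums sequentially in particle
order, neighbor-list and all-particle evaluations agree exactly, not just
approximately.  An optional numba kernel accelerates the evaluation
~5-fold; the pure-numpy path is mathematically identical and used when
numba is absent.

## Multiple-walker metadynamics

Walkers advance independently between deposit boundaries (4 ps), then
deposit Gaussians of fixed width (0.0005 Å⁻³) into one shared bias in
walker order; all walkers feel the updated bias in the next interval.
Gaussian heights follow h(t) = max(floor, h₀·(floor/h₀)^(t/t_decay)) —
a geometric decay reaching the floor exactly at t_decay and holding it.
Defaults: h₀ = 0.035, floor = 0.0035 kcal/mol.  The decay law itself is a
design choice; only its endpoint is canonical.

The bias is stored both as the deposit history and as a dense grid
(resolution = width/5, auto-expanding) for O(1) evaluation.  The free
energy is the negative *time average* of the bias over [t₀, T]; because a
deposit made at tᵢ contributes to U_b for all t ≥ tᵢ, the average is
computed exactly from the history with per-deposit weights
(T − max(tᵢ, t₀))/(T − t₀).  The error band is |F₁ − F₂| from the two
halves of the averaging window.  Caveat: the two halves share all bias
accumulated before t₀, so the pointwise band under-reports slowly-varying
error and has structural zeros wherever the half-profiles cross; when the
band is used as a tolerance it is therefore floored at its length-average
(the same convention as the ABF error summary).

Optional harmonic walls on the CV ((k/2)(ρ−wall)² outside [lo, hi])
restrict sampling to the range of interest without altering F between the
walls — without them the walkers spend most of their corrective sampling
far outside the range being measured.

## Hydration free energy vs Poisson statistics

For a non-interacting bath at bulk density n, the occupancy N of any
sub-volume is Poisson with λ = n·V, so the hydration free energy is
F(N) = −k_BT·ln(λᴺe^{−λ}/N!) — an exact oracle for the entire
density-CV + metadynamics stack.  The validation study uses a cylinder
with R = 7.8 Å, Z = 11.7 Å and thin shells (0.5 Å), V ≈ 4480 Å³, with n
chosen so λ = 20, eight walkers of 16 ns each (heights decaying over
4 ns; averaging over the final 11 ns), and walls at λ−3.5√λ and λ+4√λ.
The comparison covers integer occupancies in λ ± 3√λ with the free
additive constant chosen by Chebyshev alignment against the tolerance.

Two idealization gaps are handled explicitly:

* **Fixed particle counts are binomial, not Poisson.**  A closed box with
  M particles gives occupancy variance λ(1−V/V_box), and per-walker fixed
  counts add a seed-dependent error to the distribution tails that the
  half-split band cannot see.  The study therefore emulates an *open*
  reservoir: walker counts are drawn from Poisson at construction, and a
  grand-canonical move periodically redraws the particle count outside a
  safe zone from its exact Poisson marginal (uniform insertions and
  deletions far from the region — exact for an ideal gas, since the
  outside configuration is an independent uniform Poisson process and the
  bias depends only on the region's interior).
* **Soft counting is slightly sub-Poisson.**  Σξ weights shell particles
  fractionally, so its variance is n∫ξ²dX < λ.  With 0.5 Å shells the
  exact law (computable by direct Monte Carlo) deviates from the Poisson
  formula by ≲ 0.04 kcal/mol except at the extreme low-occupancy edge
  (≈ +0.1 kcal/mol at N = 7).  This is a property of the comparison, not
  of the sampler, and bounds how closely the Poisson formula can ever be
  matched.

These run lengths are ~8× shorter than the all-atom protocol the method
derives from (120–140 ns per walker); passing this study demonstrates
correctness of the machinery on a bath with known statistics, not the
convergence of any real pore's free energy.

## Adaptive biasing force

Bins of 0.2 Å accumulate instantaneous systematic z-forces on the tagged
particle (restraint terms excluded); the applied bias is the negative
running bin mean ramped by min(count/1000, 1).  In the overdamped engine
the systematic force on z *is* the mean-force estimand, so binned means
converge rapidly; the residual error is within-bin discretisation plus
trapezoidal integration (both ≪ 0.01 kcal/mol at 0.2 Å bins for smooth
potentials).  The protocol mirrors the two-sided convention: two runs
started in opposite wells, error band from their profile difference,
grids merged by pooling and refined by a third run.  The PMF reporting
range is trimmed to bins with a full ramp; it is anchored either to a
bulk region (outermost 10 Å, default) or to min G = 0 for well-type
potentials.

## Position-dependent diffusion

D(z) = var(z)/τ(z) per window, with τ = ∫₀^cutoff C(t)dt/C(0) and C the
biased (1/N-normalised) autocovariance via FFT.  The biased normalisation
keeps the long-lag tail from destabilising the integral; a plateau flag
reports whether the running integral is converged over the last 20% of
lags.  For an Ornstein–Uhlenbeck window (harmonic spring k), var = k_BT/k
and τ = k_BT/(D₀k), so var/τ = D₀ identically — the estimator's central
exactness property, tested at D₀ ∈ {0.1, 0.2, 0.5} Å²/ps.

The integration cutoff trades truncation bias against accumulated tail
noise: the default (100 ps) suits correlation times of tens of ps; the OU
validation studies use 20 ps ≈ 7–17 τ, where per-window scatter is ±4%
rather than the ±20% found when integrating a 3-ps-correlation window out
to 100 ps.  Profiles are natural cubic splines through the window
estimates (the boundary condition is a choice; windows outside the data
range are never extrapolated in the studies), with per-window half-split
error bars.  Sampling a window at 0.02 ps spacing, first-order
integrator bias in D is (1+θdt) with θdt ≤ 0.01 for the studied springs.

## Conductance model

γ = q²CS/(k_BT)·[∫_{Z1}^{Z2} e^{G(z)/k_BT}/D(z) dz]⁻¹, trapezoidal on the
union grid of the two (linearly interpolated) profiles.  G must be
bulk-anchored (warned if the range-edge mean exceeds 0.5 kcal/mol) and
D positive (error otherwise).  The effective cross-section defaults to
S = πr² of the confinement radius (π·8² ≈ 201 Å², π·14² ≈ 616 Å²); an
explicit S overrides it.  Error bands re-evaluate γ at G ± err
(worst-case), consistent with difference-of-halves uncertainties, rather
than assuming Gaussian errors.  Selectivity is the pointwise PMF
difference on the overlap grid with quadrature-combined errors.

## Scenario realism

The scenarios reproduce the *statistical structure* each estimator
assumes — OU fluctuations in restrained windows, barrier crossing in a
confined channel, Poisson occupancy of a sub-volume, Boltzmann
partitioning of two species — and nothing else.  They contain no solvent
structure, no electrostatics, no protein flexibility, no
ion–water coupling.  Passing the studies certifies the estimators and
their implementations; it says nothing about force fields or sampling
adequacy on real systems, where the same tools face rugged landscapes,
correlated solvent dynamics and far longer relaxation times.

## Degenerate inputs and tie-breaks

Particles exactly on a switching boundary get ξ from the closed branch
(χ = 1 inside, 0 outside — the piecewise definition is continuous there).
Radial gradients at r → 0 are zero (the switching derivative vanishes
strictly inside the inner radius).  Empty ABF bins inside the reporting
range raise; out-of-range ABF samples are counted but ignored.  Constant
window series raise on τ estimation (flagged degenerate in C(t)).
Profiles require strictly increasing grids; interpolation never
extrapolates.

## Known limitations

* First-order integrator: stationary distributions carry O(dt) bias;
  studies budget for it (documented per study above) rather than using a
  higher-order scheme.
* The half-split band of a quasi-static metadynamics bias underestimates
  slow systematic error; treat it as a lower bound on uncertainty.
* The grand-canonical move is exact only for non-interacting particles;
  it must not be combined with interacting baths.
* Multi-dimensional CVs, replica exchange, reweighting estimators,
  Poisson–Nernst–Planck or multi-ion conduction are out of scope.
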