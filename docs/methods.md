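# Methods

## Model

`gutfix` models the bulk of the colon lumen as a one-dimensional segment of
length L (cm) and cross-section S (cm²) through which digesta flows with
constant velocity v (cm/h) while peristaltic mixing acts as an effective
diffusion D (cm²/h).  Three concentration fields live on this segment: food
F (mM), wild-type bacteria B, and neutral-mutant bacteria M (both
bacteria/cm³).  Bacteria divide at the Monod rate

    rho(F) = r F / (k + F),

consuming food with yield alpha (bacteria produced per mM consumed):

    dF/dt = D F'' − v F' − (r/alpha)(B+M) F/(k+F)
    dB/dt = D B'' − v B' + rho(F) B
    dM/dt = D M'' − v M' + rho(F) M.

At the entrance (x=0) the *total* flux of food is prescribed, v·Fin with
Fin = vFin/v, and the bacterial fluxes are zero (nutrients flow in, bacteria
do not).  At the exit (x=L) the diffusive flux vanishes and material leaves
advectively at v·c.  With these units S·∫B dx is a genuine bacterial count,
which the population-size analysis relies on.

Three dimensionless groups fix the stationary state: the Péclet number vL/D,
the growth number rL/v (divisions available per transit), and the saturation
k/Fin.  Two parameter sets sharing these groups have identical steady
profiles after rescaling x by L, F by Fin, and B by alpha·Fin; the
stochastic module exploits this to shrink populations without changing the
physics.

Reference parameter values used throughout the package and its tests:
r = 0.42 1/h, k = 0.1 mM, vFin = 1 mM·cm/h, alpha = 6.13×10⁸ bacteria/mM,
L = 6 cm, S = 1 cm².  The "benchmark" transport point is (v, D) =
(0.5, 0.2); the "active-population" point is (0.181, 0.02), chosen close to
the diffusive washout line so that concentration profiles are strongly
spatial.

## Regimes and washout

Bacteria persist only between two analytic limits, both asymptotic:

* diffusive washout when D < v²(k/Fin + 1)/(4r) — the classic pulled-front
  criterion with leading-edge growth rate r/(k/Fin+1);
* convective washout when v > rL/(k/Fin + 1) — transit faster than
  replication.

The spatial-dependence metric [F(0) − F(L)]/Fin classifies persistent states:
above 0.9 the profiles are called strongly spatial (the threshold used to
filter the plateau analysis), near 0 the gut behaves like a chemostat.
Boundary values F(0), F(L) are extrapolated from ghost values consistent with
the imposed face fluxes, not read off raw cell centers.

## Discretization and steady states

Space is discretized by a cell-centered finite volume on a uniform grid
(default 600 cells for L = 6 cm, dx = 0.01 cm).  Diffusion uses two-point
central fluxes.  Advection defaults to first-order upwind, which is
unconditionally positive and — deliberately — is the exact mean field of the
stochastic simulator's hop rates.  A second-order central advective flux is
available (`scheme="central"`, valid for cell Péclet v·dx/D < 2) and is what
the grid-refinement verification uses: with it, doubling the resolution moves
the benchmark steady profile by < 0.1% in sup-norm, versus ~2% for upwind.

Because every interior flux appears once with each sign, the discrete steady
state satisfies the integral mass balance v·alpha·Fin =
v·(alpha·F(L) + B(L) + M(L)) to round-off at any resolution.

**A numerical sensitivity worth knowing about.**  The active-population
point (v = 0.181, D = 0.02) sits 0.07% above the exact diffusive washout
threshold (d_crit = 0.019854).  At that margin the fate of the *discrete*
front depends on the scheme's O(dx) numerical diffusion: the upwind front
persists at 600 cells (adding v·dx/2 ≈ 9×10⁻⁴ cm²/h of diffusion), while the
second-order front washes out.  Published phase-diagram numerics in this
regime behave the same way — reported persistent velocities extend slightly
beyond the asymptotic line.  Package policy: near-critical persistence is
decided by long-time integration of the production (upwind) scheme, and the
washout-line comparison tolerates disagreement within ±20% of the analytic
lines.

Time integration is LSODA (stiffness-switching, banded Jacobian of width 3
via per-cell interleaving of F, B, M) with relative tolerance 10⁻⁸ and
per-species absolute tolerances; the mutant field gets its own floor because
it can sit nine decades below B.  Steady states are found by integrating in
expanding chunks and finishing with a damped Newton solve on the (F, B)
subsystem (analytic sparse Jacobian).  Newton results are accepted only when
they land near the integrated trajectory, so the solver cannot jump from a
slowly growing or decaying transient onto the wrong root (e.g. collapsing a
young population onto the extinct solution).  The converged residual —
max |dc/dt|/(|c| + 10⁻³·scale) — is typically 10⁻¹²–10⁻¹³/h, far below the
acceptance tolerance of 10⁻⁸/h.  The fallback horizon is 4000 h: 500 h
suffices visually at the benchmark point, but near-critical fronts creep for
a few thousand hours at this residual tolerance.  Washout is declared when
max B < 10⁻⁶·alpha·Fin.

## Neutral-mutant fate

A mutant pulse places NM mutants in a slab of width dx (one grid cell by
default, wider for convergence checks) centered at xM, so that S·∫M dx = NM
exactly; it must be dilute (M₀ < 10⁻³·B(xM)).  Because M obeys the same
linear equation as B once F has relaxed, M(x)/B(x) converges to a constant C
— the fixation probability of that introduction.  Two independent routes
compute it:

* **direct**: integrate the nonlinear system until the coefficient of
  variation of M/B over populated cells (B > 10⁻⁶·alpha·Fin) falls below
  10⁻³ and the mean stops drifting;
* **adjoint**: freeze F at F*, form the tridiagonal mutant operator
  𝓛 = T + diag(rho), and take its left null vector φ (B* is the right null
  vector).  φ·M is conserved, so C(xM) = NM·φ(xM) / (S·dx·Σφ·B*) for every
  introduction cell at once.

𝓛 has constant positive off-diagonals, so a similarity transform with the
geometric diagonal (qr/ql)^(i/2) makes it symmetric with off-diagonal
√(qr·ql); the spectrum comes from `scipy.linalg.eigh_tridiagonal` and the
left null vector is recovered in log space (no overflow at high Péclet).
The two routes agree to ~10⁻¹⁰ relative — they share the discretization, so
this validates the linear-algebra pipeline rather than the grid; grid
adequacy is established separately by refinement.

Averaging C over where mutants actually arise — proportional to the local
reproduction density R = B·rho — gives the overall fixation probability
F̄ = ∫R·C dx / ∫R dx.  The active population NA counts bacteria upstream of
x*, where the monotone food profile crosses k (linear interpolation between
cell centers; if F never crosses k, activity is spatially uniform and
NA = NT).  In the strongly spatial regime F̄ ≈ NM/NA; in flat regimes
F̄ ≈ NM/NT.  All fixation quantities are linear in NM, and the default
NM = 1 bacterium keeps them interpretable as per-organism probabilities.

## Stochastic validation

The individual-based simulator puts integer bacteria in compartments
(default 40 for L = 6 cm).  Per capita, an individual divides with
propensity rho(F_i), hops downstream with rate v/dx + D/dx², upstream with
D/dx², and exits absorbing through the last compartment at v/dx; these rates
make the ensemble mean *identical* to the upwind finite-volume scheme, so
mean-field comparisons carry no discretization mismatch.  Time advances by
tau-leaps capped at 0.2 expected events per individual; hops are binomial
(movers can never exceed occupancy), divisions binomial with probability
rho·tau.  Food is by default a deterministic per-compartment field advanced
with the same transport stencil and debited by the births that actually
occurred (so food consumed equals births/alpha identically); it can be
frozen (`fixed`), which is what closed-system neutrality checks use, or
carried as integer quanta of 1/(alpha·S·dx) mM (`stochastic_units`).

Populations are scaled into the tractable 10²–10⁶ range by reducing alpha —
the dimensionless groups, and hence the fixation curve, are untouched.  All
replicates advance in lockstep as (replicates × compartments) arrays drawn
from a single seeded `numpy` Generator: runs are bit-reproducible for a
given seed and ensemble size, and the vectorization is what makes 1000
replicates a minute-scale computation.

The fixation estimator is the replicate mean of the final mutant fraction
M/(M+B).  For dilute neutral mutants E[M] follows the deterministic linear
dynamics exactly (the tau-leap mean preserves the adjoint invariant φ·E[M]
step by step), so the estimator is unbiased at any horizon once the
deterministic transient has decayed.  Two practical points shape the runs:

* **Horizon.**  The mutant operator is non-normal: a localized pulse can
  overshoot its plateau by orders of magnitude long after the spectral gap
  suggests.  The observation horizon is therefore computed from the exact
  linear transient (full eigendecomposition on the simulation grid): the
  first time after which the mean mutant count stays within 2% of its
  plateau, times a 1.2 safety factor.
* **Where validation is statistically feasible.**  The estimator's relative
  error is ~1/√(p·N) with p the probability that the lineage is still alive
  at the horizon.  Downstream introductions have plateau expectations far
  below one individual, so p collapses and no desk-scale ensemble resolves
  them; validation positions are chosen upstream, where the plateau exceeds
  about one individual (C·NT ≳ 1) and 1000 replicates give sub-3-SE
  agreement.  The upstream-vs-downstream ordering is still checked
  qualitatively at larger separations.

Replicates are also classified established (lineage alive at the horizon)
versus extinct, with a binomial standard error on that fraction.

## What the synthetic conditions do and do not show

All inputs are parameter values; there are no external datasets.  The tests
therefore demonstrate internal consistency of the model and its analysis
layer at the reference parameter ranges — conservation, phase boundaries,
the adjoint/direct oracle pair, the active-population law, and
deterministic–stochastic agreement — under the model's own idealizations:
constant v and D, a single food source, constant inflow, no mucus or crypt
reservoirs, radial uniformity, and neutral mutants only.  Agreement here
says nothing about, e.g., time-varying meals or multi-species ecology, which
the model does not represent.

## Problem sizes and defaults

| quantity | default | note |
| --- | --- | --- |
| grid cells (deterministic) | 600 | dx = 0.01 cm; phase-diagram scans use 300 |
| steady-state residual tolerance | 10⁻⁸ /h | Newton polish reaches ~10⁻¹²/h |
| integrator rtol | 10⁻⁸ | per-species atol, mutant scaled separately |
| steady-state horizon | 4000 h | Newton usually ends runs by ~100–1600 h |
| washout threshold | 10⁻⁶·alpha·Fin | on max B |
| stochastic compartments | 40 | dx = 0.15 cm |
| stochastic population | ~3000 | via scaled alpha; window 10²–10⁶ |
| replicates per estimate | ≥ 1000 | acceptance runs use exactly 1000 |
| tau-leap cap | 0.2 events/individual | also bounds the food CFL |
| strongly-spatial threshold | 0.9 | on [F(0)−F(L)]/Fin |

## Known limitations

* First-order upwind is the production scheme; quantities tied to sharp
  front *positions* carry O(dx) bias.  All headline comparisons are
  internal-consistency relations (both sides computed on the same scheme),
  which is why they hold to much better than the scheme's absolute accuracy.
* Near the washout lines, persistence of the discrete system is
  scheme-dependent (see above); the analytic lines are asymptotic and the
  package treats a ±20% band around them as undecided.
* The stochastic validation estimates establishment-stage fixation; the
  final drift to absorption (timescale proportional to population size) is
  deliberately not simulated, consistent with the two-timescale argument the
  analysis rests on.
* Fixation times and non-neutral mutants are out of scope.
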