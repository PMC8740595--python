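# gutfix

Neutral-mutant fixation in a flowing, food-limited gut.

Most bacteria in the human body live in the colon lumen, carried passively
by flow, mixed by peristalsis, and fed by whatever nutrients survive the
small intestine.  `gutfix` asks what that environment does to the fate of a
*neutral* mutation: in a well-mixed population of size N_T a neutral mutant
fixes with probability 1/N_T, but the gut is neither well mixed nor
uniformly fed.  The package implements a minimal spatial model of the colon
lumen and the full analysis chain from its steady states to fixation
probabilities — including the result that, when food and bacterial profiles
are strongly spatial, fixation is governed by a much smaller **active
population** N_A (the bacteria upstream of the point x\* where food falls to
the Monod constant), so neutral diversity is enhanced:

    F  =  N_M / N_A   ≫   N_M / N_T .

## Model

Food F, wild-type B, and mutant M concentrations on x ∈ [0, L] obey
advection–diffusion–reaction equations with Monod growth,

    ∂F/∂t = D ∂²F/∂x² − v ∂F/∂x − (r/α)(B+M) F/(k+F)
    ∂B/∂t = D ∂²B/∂x² − v ∂B/∂x + r B F/(k+F)
    ∂M/∂t = D ∂²M/∂x² − v ∂M/∂x + r M F/(k+F)

with prescribed food influx v·F_in at the entrance, no bacterial inflow, and
free advective outflow at the exit.  The package provides:

* a conservative finite-volume solver with steady-state detection (Newton
  polish to round-off residuals), washout classification against the two
  analytic limits D = v²(k/F_in+1)/(4r) and v = rL/(k/F_in+1), and the
  spatial-dependence metric [F(0) − F(L)]/F_in;
* the mutant-fate layer: localized pulses, the position-resolved fixation
  probability C(x_M) computed both by direct integration and by the adjoint
  zero mode of the linearized mutant dynamics, reproduction density
  R = B·ρ, overall fixation ∫RC/∫R, and the population sizes N_T, N_A, x\*;
* (v, D) sweep pipelines behind the phase-diagram, fixation-vs-N_T, and
  fixation-vs-N_A analyses;
* a reduced-scale individual-based simulator (compartment hops + divisions,
  exact mean-field counterpart of the deterministic scheme) that validates
  the deterministic fixation probabilities by replicate ensembles.

## Worked example

```python
from gutfix import make_parameters, solve_steady_state, analyze_fixation

params = make_parameters(dict(
    v=0.5, D=0.2, r=0.42, k=0.1, vFin=1.0, alpha=6.13e8, L=6.0, S=1.0,
))
steady = solve_steady_state(params, n_cells=600)
report = analyze_fixation(steady, NM=1.0)
print(f"spatial dependence [F(0)-F(L)]/Fin : {report.spatial_dependence:.3f}")
print(f"total population NT               : {report.NT:.3e}")
print(f"active population NA (x* = {report.x_star:.2f} cm): {report.NA:.3e}")
print(f"overall fixation probability      : {report.overall_fixation:.3e}")
print(f"well-mixed expectation NM/NT      : {1/report.NT:.3e}")
print(f"active-population prediction NM/NA: {1/report.NA:.3e}")
```

prints

```
spatial dependence [F(0)-F(L)]/Fin : 0.986
total population NT               : 4.532e+09
active population NA (x* = 3.56 cm): 1.552e+09
overall fixation probability      : 6.139e-10
well-mixed expectation NM/NT      : 2.207e-10
active-population prediction NM/NA: 6.443e-10
```

At these flow/mixing values the food profile is strongly spatial (metric
0.986): food is abundant near the entrance and exhausted by x\* = 3.56 cm,
so only the 1.55×10⁹ bacteria upstream of x\* divide appreciably.  A single
neutral mutant fixes with probability 6.1×10⁻¹⁰ — within 5% of NM/N_A and
2.8× the well-mixed expectation NM/N_T.

The same analyses are scriptable from the shell:

```
gutfix steady        --v 0.5 --D 0.2 --out-dir out/
gutfix regime        --v 0.181 --D 0.02
gutfix mutant-fate   --xm 1.0 --out-dir out/
gutfix sweep         --d 0.02 --v-min 0.15 --v-max 0.183 --out-dir out/
gutfix stochastic    --xm 0.225 --xm 0.825 --replicates 1000 --seed 1 --out-dir out/
gutfix figure fig1c  --out-dir out/
```

Every command accepts `--config file.yaml` (flat map of the eight physical
parameters plus numerics) with per-flag overrides, writes tidy CSV/JSON, and
records a manifest with checksums so deterministic runs reproduce
bit-for-bit.

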