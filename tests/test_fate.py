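"""Mutant pulses, fixation curves, and population-size analysis."""

import numpy as np
import pytest

from gutfix import (
    MutantPulse,
    PulseError,
    WashoutError,
    active_population,
    analyze_fixation,
    fixation_curve_adjoint,
    introduce_mutant,
    mutant_steady_ratio,
    overall_fixation_probability,
    predicted_fixation,
    reproduction_density,
    reproductions_per_time,
    total_population,
)
from gutfix.fate import mutant_operator_spectrum


class TestIntroduceMutant:
    def test_single_cell_concentration(self, bench_steady_coarse):
        g = bench_steady_coarse.grid
        state = introduce_mutant(bench_steady_coarse, MutantPulse(xM=3.0, NM=1.0))
        nz = np.nonzero(state.M)[0]
        assert nz.size <= 2
        # S * integral(M dx) == NM at machine precision
        total = bench_steady_coarse.params.S * g.dx * state.M.sum()
        assert total == pytest.approx(1.0, rel=1e-14)

    def test_wider_pulse_preserves_total(self, bench_steady_coarse):
        g = bench_steady_coarse.grid
        state = introduce_mutant(
            bench_steady_coarse, MutantPulse(xM=3.0, NM=5.0, dx_pulse=10 * g.dx)
        )
        total = bench_steady_coarse.params.S * g.dx * state.M.sum()
        assert total == pytest.approx(5.0, rel=1e-14)

    def test_position_outside_domain_rejected(self, bench_steady_coarse):
        with pytest.raises(PulseError):
            introduce_mutant(bench_steady_coarse, MutantPulse(xM=7.0, NM=1.0))

    def test_non_dilute_pulse_rejected(self, bench_steady_coarse):
        # enough mutants to rival the local wild-type concentration
        with pytest.raises(PulseError, match="dilute"):
            introduce_mutant(bench_steady_coarse, MutantPulse(xM=3.0, NM=1e8))

    def test_nonpositive_count_rejected(self):
        with pytest.raises(PulseError):
            MutantPulse(xM=1.0, NM=0.0)


class TestFixationCurve:
    def test_proportional_ic_returns_its_constant(self, bench_steady_coarse):
        """M0 = c*B* is already the invariant direction: C = c immediately."""
        from gutfix.parameters import FieldState

        p, g = bench_steady_coarse.params, bench_steady_coarse.grid
        c = 1e-7
        state = FieldState(
            0.0,
            bench_steady_coarse.state.F.copy(),
            bench_steady_coarse.state.B.copy(),
            c * bench_steady_coarse.state.B,
        )
        got, cv = mutant_steady_ratio(state, p, g, return_cv=True)
        assert got == pytest.approx(c, rel=1e-6)
        assert cv < 1e-6

    def test_adjoint_reproduces_proportional_functional(self, bench_steady_coarse):
        """sum(phi * cB*)/sum(phi * B*) = c is exact for the adjoint curve."""
        phi_curve = fixation_curve_adjoint(bench_steady_coarse, NM=1.0)
        g = bench_steady_coarse.grid
        p = bench_steady_coarse.params
        B = bench_steady_coarse.state.B
        c = 3.7e-9
        # C is linear in the initial condition: a proportional IC integrates
        # to c through the same quadrature
        weights = phi_curve * p.S * g.dx  # = phi / sum(phi B*) normalized
        assert float(weights @ (c * B)) == pytest.approx(c, rel=1e-12)

    def test_upstream_fixes_more_than_downstream(self, bench_steady_coarse):
        C = fixation_curve_adjoint(bench_steady_coarse, NM=1.0)
        assert np.all(np.diff(C) < 0)
        assert C[0] / C[-1] > 100

    def test_linear_in_nm(self, bench_steady_coarse):
        C1 = fixation_curve_adjoint(bench_steady_coarse, NM=1.0)
        C2 = fixation_curve_adjoint(bench_steady_coarse, NM=2.0)
        assert np.allclose(C2, 2 * C1, rtol=1e-12)

    def test_direct_doubling_nm_doubles_ratio(self, bench_steady_coarse):
        p, g = bench_steady_coarse.params, bench_steady_coarse.grid
        c1 = mutant_steady_ratio(
            introduce_mutant(bench_steady_coarse, MutantPulse(2.0, 1.0)), p, g
        )
        c2 = mutant_steady_ratio(
            introduce_mutant(bench_steady_coarse, MutantPulse(2.0, 2.0)), p, g
        )
        assert c2 / c1 == pytest.approx(2.0, rel=1e-4)

    def test_adjoint_matches_direct_integration(self, bench_steady_coarse):
        """The module's core oracle at unit-test scale: one position."""
        p, g = bench_steady_coarse.params, bench_steady_coarse.grid
        C = fixation_curve_adjoint(bench_steady_coarse, NM=1.0)
        xm = g.cell_centers[60]
        direct = mutant_steady_ratio(
            introduce_mutant(bench_steady_coarse, MutantPulse(xm, 1.0)), p, g
        )
        assert direct == pytest.approx(C[60], rel=0.02)

    def test_flat_regime_curve_nearly_constant(self, bench_params):
        """Where food profiles are flat (spatial dependence < 0.05) the
        introduction position no longer matters."""
        from gutfix import solve_steady_state
        from gutfix.solver import spatial_dependence

        s = solve_steady_state(bench_params.replace(D=20.0, v=0.15), n_cells=200)
        assert spatial_dependence(s) < 0.05
        C = fixation_curve_adjoint(s, NM=1.0)
        assert C.max() / C.min() - 1 < 0.05

    def test_washout_state_rejected(self, bench_params):
        from gutfix import solve_steady_state

        washed = solve_steady_state(bench_params.replace(D=0.1), n_cells=150)
        with pytest.raises(WashoutError):
            fixation_curve_adjoint(washed)

    def test_spectrum_top_eigenvalue_is_zero(self, bench_steady_coarse):
        lam = mutant_operator_spectrum(bench_steady_coarse, k=2)
        assert abs(lam[0]) < 1e-8
        assert lam[1] < -0.01


class TestReproductionDensity:
    def test_zero_population_zero_density(self, bench_params):
        from gutfix import solve_steady_state

        washed = solve_steady_state(bench_params.replace(D=0.1), n_cells=150)
        assert np.all(reproduction_density(washed) < 1e-3)

    def test_interior_maximum_in_spatial_regime(self, bench_steady_coarse):
        R = reproduction_density(bench_steady_coarse)
        j = int(np.argmax(R))
        n = R.size
        assert 0.05 * n < j < 0.95 * n

    def test_flat_regime_density_uniform(self, bench_params):
        """Near the convective washout limit bacteria are sparse, food stays
        near Fin, and reproduction is uniform along the gut."""
        from gutfix import solve_steady_state

        s = solve_steady_state(bench_params.replace(D=20.0, v=1.5), n_cells=200)
        R = reproduction_density(s)
        assert R.max() / R.min() - 1 < 0.10


class TestOverallFixation:
    def test_constant_curve_passes_through(self, bench_steady_coarse):
        g = bench_steady_coarse.grid
        R = reproduction_density(bench_steady_coarse)
        C = np.full(g.n_cells, 0.42)
        assert overall_fixation_probability(C, R, g) == pytest.approx(0.42)

    def test_point_mass_weights(self, bench_steady_coarse):
        g = bench_steady_coarse.grid
        C = np.linspace(1.0, 2.0, g.n_cells)
        R = np.zeros(g.n_cells)
        R[17] = 5.0
        assert overall_fixation_probability(C, R, g) == pytest.approx(C[17])

    def test_bounded_by_curve_extremes(self, bench_steady_coarse):
        g = bench_steady_coarse.grid
        C = fixation_curve_adjoint(bench_steady_coarse)
        R = reproduction_density(bench_steady_coarse)
        f = overall_fixation_probability(C, R, g)
        assert C.min() <= f <= C.max()

    def test_zero_reproduction_rejected(self, bench_steady_coarse):
        g = bench_steady_coarse.grid
        with pytest.raises(WashoutError):
            overall_fixation_probability(
                np.ones(g.n_cells), np.zeros(g.n_cells), g
            )


class TestPopulations:
    def test_total_population_is_a_count(self, bench_steady_coarse):
        p = bench_steady_coarse.params
        nt = total_population(bench_steady_coarse)
        # bounded by a gut full of fully-converted food
        assert 0 < nt < p.alpha * p.Fin * p.L * p.S

    def test_active_below_total(self, bench_steady_coarse):
        na, x_star = active_population(bench_steady_coarse)
        assert 0 < na <= total_population(bench_steady_coarse)
        assert 0 < x_star <= bench_steady_coarse.grid.L

    def test_weak_gradient_all_active(self, bench_params):
        """If food never crosses k the whole population counts as active."""
        from gutfix import solve_steady_state

        # short gut, fast flow: food stays near Fin > k everywhere
        p = bench_params.replace(L=1.0, v=1.0, D=1.0)
        s = solve_steady_state(p, n_cells=100)
        na, x_star = active_population(s)
        assert na == pytest.approx(total_population(s))
        assert x_star == p.L

    def test_active_boundary_concentration_identity(self, bench_steady_coarse):
        """B(x*) = alpha*Fin*(1 - k/Fin): all food upstream of x* has become
        bacteria, up to the residual concentration k."""
        p = bench_steady_coarse.params
        na, x_star = active_population(bench_steady_coarse)
        b_at = np.interp(
            x_star,
            bench_steady_coarse.grid.cell_centers,
            bench_steady_coarse.state.B,
        )
        expected = p.alpha * p.Fin * (1 - p.k / p.Fin)
        assert b_at == pytest.approx(expected, rel=0.05)

    def test_reproduction_rate_totals(self, bench_steady_coarse):
        """NR ~ r*NA (active bacteria divide near full speed) and
        NR ~ alpha*v*(Fin - F(L)) (food bookkeeping at steady state)."""
        p = bench_steady_coarse.params
        nr = reproductions_per_time(bench_steady_coarse)
        na, _ = active_population(bench_steady_coarse)
        assert nr == pytest.approx(p.r * na, rel=0.15)
        food_in_minus_out = p.alpha * p.v * (p.Fin - bench_steady_coarse.state.F[-1])
        assert nr == pytest.approx(food_in_minus_out, rel=0.03)

    def test_predicted_fixation_examples(self):
        assert predicted_fixation(3.0, 3.0) == 1.0
        assert predicted_fixation(1.0, 100.0) == pytest.approx(0.01)
        with pytest.raises(WashoutError):
            predicted_fixation(1.0, 0.0)


class TestAnalyzeFixation:
    def test_report_consistency(self, bench_steady_coarse):
        rep = analyze_fixation(bench_steady_coarse, NM=1.0)
        assert 0 < rep.overall_fixation < 1
        assert rep.NA <= rep.NT
        assert rep.regime == "persistent_spatial"
        # spatial structure never suppresses fixation below the well-mixed
        # baseline NM/NT
        assert rep.overall_fixation >= (rep.NM / rep.NT) * (1 - 1e-9)

    def test_spatial_beats_well_mixed(self, bench_steady_coarse):
        rep = analyze_fixation(bench_steady_coarse, NM=1.0)
        assert rep.overall_fixation > 2 * rep.NM / rep.NT
        assert rep.overall_fixation == pytest.approx(rep.NM / rep.NA, rel=0.15)
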