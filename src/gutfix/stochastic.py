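"""Individual-based stochastic counterpart of the PDE model.

Bacteria are simulated as integer counts in compartments along the gut.  Each
individual divides with the local Monod propensity r F/(k+F), hops downstream
with rate v/dx + D/dx^2 and upstream with rate D/dx^2, and leaves the system
through the last compartment (advective outflow; no entry upstream).  These
rates are chosen so the compartment master equation's *mean* obeys exactly the
upwind finite-volume discretization used by the deterministic solver: the
mean-field comparison is an identity, not an approximation.

Food is, by default, a deterministic per-compartment field advanced between
stochastic steps and debited by the births that actually occurred (hybrid
tau-leaping); it can also be frozen ('fixed', useful for closed-system neutral
checks) or treated as integer quanta ('stochastic_units').

Population scale is set by reducing the yield alpha while leaving
(vL/D, rL/v, k/Fin) untouched: the dimensionless steady state, and hence the
shape-dependent fixation curve, is unchanged, but total populations of
10^2-10^6 individuals make drift observable in a desk-scale simulation.

The fixation-probability estimator is the replicate mean of the final mutant
fraction M/(M+B): for dilute neutral mutants the dynamics of M is linear, so
this mean follows the deterministic equation and converges to the
deterministic plateau ratio C.  (The tau-leap update preserves the adjoint
invariant phi . E[M] exactly, so the estimator carries no step-size bias.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import GutParameters, SpatialGrid, build_grid
from .solver import SteadyState, hop_rates, solve_steady_state
from .fate import (
    MutantPulse,
    PulseError,
    WashoutError,
    fixation_curve_adjoint,
    mutant_operator_spectrum,
    total_population,
)

__all__ = [
    "StochasticConfig",
    "ReplicateOutcome",
    "StochasticResult",
    "StochasticEngine",
    "scale_alpha_to_population",
    "run_stochastic",
    "compare_to_deterministic",
]

FOOD_TREATMENTS = ("deterministic_field", "stochastic_units", "fixed")


@dataclass(frozen=True)
class StochasticConfig:
    """Controls for the reduced-scale stochastic runs."""

    alpha_scaled: float  # reduced yield setting the population scale
    n_replicates: int = 1000
    seed: int = 0
    n_compartments: int = 40
    t_burn: float = 30.0  # h of wild-type-only equilibration before the pulse
    t_obs: float | None = None  # h after the pulse; None -> 6 / spectral gap
    food_treatment: str = "deterministic_field"
    rate_cap: float = 0.2  # max per-capita event probability per tau-leap
    max_population: float = 2e7  # hard cap guarding runaway configurations

    def __post_init__(self) -> None:
        if self.food_treatment not in FOOD_TREATMENTS:
            raise ValueError(
                f"food_treatment must be one of {FOOD_TREATMENTS}, "
                f"got {self.food_treatment!r}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ReplicateOutcome:
    """Fate of one replicate's mutant lineage at the horizon."""

    fixed: bool  # lineage alive at the horizon (reached the coexistence plateau)
    extinct: bool
    final_ratio: float  # M / (M + B), total over the gut
    t_final: float


@dataclass
class StochasticResult:
    """Ensemble estimate of the fixation probability at one pulse position."""

    xM: float
    estimate: float  # mean final mutant fraction ~ fixation probability
    se: float  # standard error of that mean
    established_fraction: float
    established_se: float  # binomial SE of the established fraction
    n_replicates: int
    t_obs: float
    C_det: float  # deterministic plateau ratio on the same grid
    outcomes: list[ReplicateOutcome] = field(repr=False)

    @property
    def z(self) -> float:
        """Discrepancy from the deterministic prediction in SE units."""
        return (self.estimate - self.C_det) / self.se if self.se > 0 else np.inf


def scale_alpha_to_population(
    params: GutParameters, target_NT: float, n_compartments: int = 40
) -> float:
    """Yield alpha that puts the steady-state population near ``target_NT``.

    NT is proportional to alpha at fixed dimensionless groups, so one
    deterministic solve at the original alpha fixes the scaling.
    """
    steady = solve_steady_state(params, n_cells=max(n_compartments, 100))
    if steady.washed_out:
        raise WashoutError("cannot scale population in a washout regime")
    nt = total_population(steady)
    return params.alpha * target_NT / nt


class StochasticEngine:
    """Vectorized tau-leaping over an ensemble of replicates.

    All replicates advance in lockstep as (n_replicates, n_compartments)
    integer arrays, driven by one seeded Generator; runs are bit-reproducible
    for a given seed, replicate count, and horizon.
    """

    def __init__(self, params: GutParameters, config: StochasticConfig):
        self.config = config
        self.params = params.replace(alpha=config.alpha_scaled)
        self.grid: SpatialGrid = build_grid(self.params, config.n_compartments)
        # upwind throughout: the compartment hop rates ARE this scheme
        self.steady: SteadyState = solve_steady_state(
            self.params, grid=self.grid, scheme="upwind"
        )
        if self.steady.washed_out:
            raise WashoutError(
                "parameters are in a washout regime at the scaled yield"
            )
        self.expected_NT = total_population(self.steady)
        if not 1e2 <= self.expected_NT <= 1e6:
            raise ValueError(
                f"expected steady population {self.expected_NT:.3g} outside "
                "the tractable window [1e2, 1e6]; adjust alpha_scaled"
            )
        n = self.grid.n_cells
        dx = self.grid.dx
        qr, ql = hop_rates(self.params, self.grid, "upwind")
        self.qr, self.ql = qr, ql
        # per-cell hop rates; entrance face is closed, exit is advective only
        self.rate_left = np.full(n, ql)
        self.rate_left[0] = 0.0
        self.rate_right = np.full(n, qr)
        self.rate_right[-1] = self.params.v / dx
        per_capita = float(np.max(self.rate_left + self.rate_right) + self.params.r)
        self.tau = config.rate_cap / per_capita
        self.food_unit = 1.0 / (self.params.alpha * self.params.S * dx)

    # -- stepping -----------------------------------------------------------

    def _hop(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One tau-leap of hopping for integer counts X, shape (reps, n)."""
        p_move = np.minimum((self.rate_left + self.rate_right) * self.tau, 0.95)
        movers = rng.binomial(X, p_move[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_right = np.where(
                self.rate_left + self.rate_right > 0,
                self.rate_right / (self.rate_left + self.rate_right),
                0.0,
            )
        right = rng.binomial(movers, frac_right[None, :])
        left = movers - right
        out = X - movers
        out[:, 1:] += right[:, :-1]  # right-movers from the last cell exit
        out[:, :-1] += left[:, 1:]
        return out

    def _food_transport(self, F: np.ndarray) -> np.ndarray:
        """Upwind FV transport of the deterministic food field (reps, n)."""
        qr, ql = self.qr, self.ql
        dF = np.empty_like(F)
        dF[:, 0] = -qr * F[:, 0] + ql * F[:, 1]
        dF[:, 1:-1] = qr * F[:, :-2] - (qr + ql) * F[:, 1:-1] + ql * F[:, 2:]
        dF[:, -1] = qr * F[:, -2] - qr * F[:, -1]
        dF[:, 0] += self.params.vFin / self.grid.dx
        return dF

    def step(self, B, M, F, rng: np.random.Generator):
        """Advance (B, M, F) by one tau-leap; returns updated arrays."""
        p = self.params
        if self.config.food_treatment == "stochastic_units":
            conc = F * self.food_unit
        else:
            conc = F
        rho = p.r * conc / (p.k + conc)
        prob_div = rho * self.tau
        births_B = rng.binomial(B, prob_div)
        births_M = rng.binomial(M, prob_div)
        B = self._hop(B, rng) + births_B
        M = self._hop(M, rng) + births_M
        births = births_B + births_M
        treatment = self.config.food_treatment
        if treatment == "deterministic_field":
            # transport explicitly; debit the births that actually happened
            F = F + self.tau * self._food_transport(F)
            F -= births * (1.0 / (p.alpha * p.S * self.grid.dx))
            np.clip(F, 0.0, None, out=F)
        elif treatment == "stochastic_units":
            F = self._hop(F, rng)
            inflow = rng.poisson(
                p.vFin * p.alpha * p.S * self.tau, size=F.shape[0]
            )
            F[:, 0] += inflow
            F -= np.minimum(births, F)
        return B, M, F

    # -- initial conditions -------------------------------------------------

    def initial_fields(self, n_replicates: int):
        """Replicated integer wild type and food at the deterministic steady."""
        counts = np.rint(
            self.steady.state.B * self.params.S * self.grid.dx
        ).astype(np.int64)
        B = np.tile(counts, (n_replicates, 1))
        if self.config.food_treatment == "stochastic_units":
            F = np.tile(
                np.rint(self.steady.state.F / self.food_unit).astype(np.int64),
                (n_replicates, 1),
            )
        else:
            F = np.tile(self.steady.state.F, (n_replicates, 1))
        M = np.zeros_like(B)
        return B, M, F

    def run(self, B, M, F, t: float, rng: np.random.Generator):
        """Advance the ensemble for a duration ``t``."""
        cap = self.config.max_population
        for _ in range(int(np.ceil(t / self.tau))):
            B, M, F = self.step(B, M, F, rng)
            if B.sum() + M.sum() > cap * B.shape[0]:
                raise ValueError(
                    "population exceeded the hard cap; alpha_scaled too large"
                )
        return B, M, F

    # -- deterministic reference -------------------------------------------

    def deterministic_curve(self, NM: float = 1.0) -> np.ndarray:
        """Adjoint fixation curve C(x) on the engine's own grid and yield."""
        return fixation_curve_adjoint(self.steady, NM=NM)

    def relaxation_time(self) -> float:
        """1 / spectral gap of the mutant operator (h)."""
        lam = mutant_operator_spectrum(self.steady, k=2)
        gap = -float(lam[1])
        return 1.0 / gap if gap > 1e-6 else 1e6

    def transient_horizon(self, cell: int, tol: float = 0.02) -> float:
        """Time until the mean mutant fraction is within ``tol`` of its plateau.

        The mutant operator is non-normal (advection), so a localized pulse
        can overshoot its plateau by orders of magnitude long after the
        spectral gap suggests; this propagates the deterministic linear
        dynamics exactly (full eigendecomposition, n <= 100) and returns the
        first time after which the relative deviation stays below ``tol``.
        """
        from scipy.linalg import eigh_tridiagonal

        from .fate import _symmetrized_operator

        diag, off, qr, ql = _symmetrized_operator(self.steady)
        n = diag.size
        lam, psi = eigh_tridiagonal(diag, off)
        logd = 0.5 * np.arange(n) * np.log(qr / ql)
        d = np.exp(logd - logd.max())
        M0 = np.zeros(n)  # one mutant, as a per-cell count
        M0[cell] = 1.0
        u0 = psi.T @ (M0 / d)
        B = self.steady.state.B
        # plateau count: C * NT, with NT = S dx sum(B)
        plateau = float(
            self.deterministic_curve(NM=1.0)[cell]
            * (self.params.S * self.grid.dx)
            * B.sum()
        )
        times = np.linspace(2.0, 2000.0, 500)
        m_tot = (d[:, None] * (psi @ (u0[:, None] * np.exp(lam[:, None] * times)))).sum(
            axis=0
        )
        dev = np.abs(m_tot / plateau - 1.0)
        bad = np.nonzero(dev > tol)[0]
        t_star = times[bad[-1] + 1] if bad.size and bad[-1] + 1 < times.size else times[0]
        return float(min(1.2 * t_star, 2000.0))


def run_stochastic(
    params: GutParameters,
    config: StochasticConfig,
    pulse: MutantPulse,
) -> StochasticResult:
    """Estimate the fixation probability of a pulse by replicate simulation.

    ``pulse.NM`` mutant individuals are added to the compartment containing
    ``pulse.xM`` after a wild-type burn-in; the ensemble then runs for
    ``t_obs`` (default: six relaxation times of the mutant operator, after
    which the deterministic transient has decayed by e^-6).
    """
    nm = pulse.NM
    if abs(nm - round(nm)) > 1e-9 or nm < 1:
        raise PulseError("stochastic runs need an integer NM >= 1")
    nm = int(round(nm))
    engine = StochasticEngine(params, config)
    cell = engine.grid.locate(pulse.xM)
    c_cell = float(engine.deterministic_curve(NM=nm)[cell])
    t_obs = config.t_obs
    if t_obs is None:
        t_obs = engine.transient_horizon(cell)
    rng = np.random.default_rng(config.seed)
    B, M, F = engine.initial_fields(config.n_replicates)
    B, M, F = engine.run(B, M, F, config.t_burn, rng)
    M[:, cell] += nm
    B, M, F = engine.run(B, M, F, t_obs, rng)
    m_tot = M.sum(axis=1).astype(float)
    b_tot = B.sum(axis=1).astype(float)
    ratio = np.where(m_tot + b_tot > 0, m_tot / np.maximum(m_tot + b_tot, 1), 0.0)
    estimate = float(ratio.mean())
    se = float(ratio.std(ddof=1) / np.sqrt(config.n_replicates))
    alive = m_tot > 0
    p_est = float(alive.mean())
    outcomes = [
        ReplicateOutcome(
            fixed=bool(a), extinct=not bool(a), final_ratio=float(x), t_final=t_obs
        )
        for a, x in zip(alive, ratio)
    ]
    return StochasticResult(
        xM=pulse.xM,
        estimate=estimate,
        se=se,
        established_fraction=p_est,
        established_se=float(
            np.sqrt(p_est * (1 - p_est) / config.n_replicates)
        ),
        n_replicates=config.n_replicates,
        t_obs=t_obs,
        C_det=c_cell,
        outcomes=outcomes,
    )


def compare_to_deterministic(
    results: list[StochasticResult], z_threshold: float = 3.0
) -> pd.DataFrame:
    """Tabulate stochastic estimates against the deterministic plateau ratios.

    One row per introduction position with the estimate, its SE, the
    deterministic C, the z-score, and a pass flag at ``z_threshold`` SE.
    """
    if not results:
        raise ValueError("no stochastic results to compare")
    rows = [
        {
            "xM": res.xM,
            "estimate": res.estimate,
            "se": res.se,
            "C_det": res.C_det,
            "z": res.z,
            "ok": abs(res.z) <= z_threshold,
            "n_replicates": res.n_replicates,
        }
        for res in results
    ]
    return pd.DataFrame(rows)
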