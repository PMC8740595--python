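"""Mutant introduction, fixation probabilities, and population-size analysis.

A neutral mutant obeys the same equation as the wild type, so once food has
relaxed back to F* the mutant profile converges to a multiple of the wild-type
profile: M(x)/B(x) -> C, a constant.  Because genetic drift in the linear
dilute regime averages to the deterministic dynamics, that constant *is* the
fixation probability of the introduced lineage.

Two independent routes compute C:

* the *direct* route integrates the full nonlinear system after a localized
  mutant pulse until M/B flattens;
* the *adjoint* route freezes food at F*, builds the linear mutant operator
  L = T + diag(rho), and uses its left null vector phi (the conserved linear
  functional of the dynamics): C(xM) = NM phi(xM) / (S dx sum(phi B*)).

The adjoint route yields the whole curve C(xM) from one eigen-solve and is the
default; the direct route serves as its oracle in tests.

Fixation averaged over where mutants actually arise (proportional to the local
reproduction density R = B rho) gives the overall fixation probability

    Fbar = int R C dx / int R dx ,

and the active population NA (bacteria upstream of x*, where F crosses the
Monod constant k) is the effective population size: Fbar ~ NM/NA in the
strongly spatial regime, vs. NM/NT in a well-mixed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh_tridiagonal

from .parameters import FieldState, GutParameters, SpatialGrid, build_grid
from .solver import (
    SteadyState,
    hop_rates,
    integrate,
    reproduction_rate,
    solve_steady_state,
    spatial_dependence,
    WASHOUT_FRACTION,
)

__all__ = [
    "PulseError",
    "WashoutError",
    "MutantPulse",
    "FixationReport",
    "introduce_mutant",
    "mutant_steady_ratio",
    "mutant_operator_spectrum",
    "fixation_curve_adjoint",
    "reproduction_density",
    "overall_fixation_probability",
    "total_population",
    "active_population",
    "reproductions_per_time",
    "predicted_fixation",
    "analyze_fixation",
    "sweep_fixation_vs_population",
]


class PulseError(ValueError):
    """Invalid mutant introduction."""


class WashoutError(RuntimeError):
    """Operation undefined on an extinct population."""


#: M/B is ill-conditioned where B ~ 0; cells below this fraction of alpha*Fin
#: are excluded from ratio statistics.
B_RATIO_FLOOR = 1e-6


@dataclass(frozen=True)
class MutantPulse:
    """A localized mutant introduction.

    ``NM`` mutants are spread over a slab of width ``dx_pulse`` (one grid cell
    by default) centered on ``xM``, giving local concentration
    M0 = NM/(S*dx_pulse).  The pulse must be dilute: M0 << B(xM).
    """

    xM: float
    NM: float
    dx_pulse: float | None = None  # None -> one grid cell

    def __post_init__(self) -> None:
        if self.NM <= 0:
            raise PulseError(f"NM must be positive, got {self.NM}")
        if self.dx_pulse is not None and self.dx_pulse <= 0:
            raise PulseError("dx_pulse must be positive")


def introduce_mutant(
    steady: SteadyState, pulse: MutantPulse, grid: SpatialGrid | None = None
) -> FieldState:
    """Superpose a mutant pulse on a converged mutant-free steady state.

    The resulting state has F = F*, B = B*, and M covering the cells under the
    pulse such that S * integral(M dx) = NM exactly.
    """
    grid = grid or steady.grid
    params = steady.params
    if not 0.0 < pulse.xM < grid.L:
        raise PulseError(f"xM={pulse.xM} outside (0, {grid.L})")
    width = pulse.dx_pulse if pulse.dx_pulse is not None else grid.dx
    m0 = pulse.NM / (params.S * width)
    lo = pulse.xM - width / 2.0
    hi = pulse.xM + width / 2.0
    edges = np.arange(grid.n_cells + 1) * grid.dx
    # overlap of [lo, hi] with each cell, as a fraction of the pulse width
    overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
    if not np.isclose(overlap.sum(), width):
        raise PulseError("pulse extends outside the domain")
    M = m0 * (overlap / grid.dx)  # S * sum(M) * dx == NM exactly
    b_local = float(np.interp(pulse.xM, grid.cell_centers, steady.state.B))
    if m0 >= 1e-3 * b_local:
        raise PulseError(
            f"pulse not dilute: M0={m0:.3g} vs B(xM)={b_local:.3g}; "
            "reduce NM or move xM into the populated region"
        )
    return FieldState(steady.state.t, steady.state.F.copy(), steady.state.B.copy(), M)


def _ratio_stats(
    state: FieldState, params: GutParameters
) -> tuple[float, float]:
    """(mean, CV) of M/B over well-populated cells."""
    mask = state.B > B_RATIO_FLOOR * params.alpha * params.Fin
    if not np.any(mask):
        raise WashoutError("no populated cells: cannot form M/B ratio")
    ratio = state.M[mask] / state.B[mask]
    mean = float(ratio.mean())
    cv = float(ratio.std() / mean) if mean > 0 else np.inf
    return mean, cv


def mutant_steady_ratio(
    initial: FieldState,
    params: GutParameters,
    grid: SpatialGrid,
    cv_tol: float = 1e-3,
    t_max: float = 20000.0,
    return_cv: bool = False,
    scheme: str = "upwind",
):
    """Direct route: integrate the nonlinear system until M/B is flat.

    Returns the constant C (the per-introduction fixation probability), or
    ``(C, cv)`` with ``return_cv=True``.  Raises if the ratio has not
    flattened to ``cv_tol`` by ``t_max``.
    """
    mean0, _ = _ratio_stats(initial, params)
    m_scale = float(initial.M.max())
    state = initial.copy()
    t_chunk, prev_mean = 100.0, mean0
    while state.t < t_max:
        t_next = min(state.t + t_chunk, t_max)
        state = integrate(state, params, grid, t_next, m_scale=m_scale, scheme=scheme)
        mean, cv = _ratio_stats(state, params)
        drift = abs(mean - prev_mean) / mean if mean > 0 else np.inf
        if cv < cv_tol and drift < 1e-5:
            return (mean, cv) if return_cv else mean
        prev_mean = mean
        t_chunk = min(2.0 * t_chunk, 3200.0)
    raise WashoutError(
        f"M/B did not flatten by t={t_max} h (cv={cv:.3g}); "
        "the run may be near washout or under-resolved"
    )


def _symmetrized_operator(
    steady: SteadyState,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Diagonal + off-diagonal of the symmetrized mutant operator.

    The mutant operator L = T + diag(rho(F*)) is tridiagonal with constant
    positive couplings (sub = qr, super = ql), so the similarity transform
    with the geometric diagonal d_i = (qr/ql)^(i/2) makes it symmetric with
    off-diagonal sqrt(qr*ql).  Returns (diag, offdiag, qr, ql).
    """
    params, grid = steady.params, steady.grid
    qr, ql = hop_rates(params, grid, steady.scheme)
    rho = reproduction_rate(steady.state.F, params)
    n = grid.n_cells
    diag = -(qr + ql) + rho
    diag = np.asarray(diag, dtype=float)
    diag[0] = -qr + rho[0]
    diag[-1] = -qr + rho[-1]
    off = np.full(n - 1, np.sqrt(qr * ql))
    return diag, off, qr, ql


def mutant_operator_spectrum(steady: SteadyState, k: int = 2) -> np.ndarray:
    """Largest ``k`` eigenvalues of the linear mutant operator (1/h).

    At a converged persistent steady state the top eigenvalue is ~0 (the
    conserved neutral direction, eigenvector B*); the gap to the next one is
    the relaxation rate of the mutant profile toward proportionality.
    """
    diag, off, _, _ = _symmetrized_operator(steady)
    n = diag.size
    vals = eigh_tridiagonal(
        diag, off, select="i", select_range=(n - k, n - 1), eigvals_only=True
    )
    return vals[::-1]


def fixation_curve_adjoint(
    steady: SteadyState,
    params: GutParameters | None = None,
    grid: SpatialGrid | None = None,
    NM: float = 1.0,
) -> np.ndarray:
    """Adjoint route: fixation probability C(xM) for every cell at once.

    Solves for the left null vector phi of the frozen-food mutant operator
    (whose right null vector is B*) and normalizes the conserved functional so
    that a pulse of NM mutants in cell j yields
    C_j = NM * phi_j / (S * dx * sum_i phi_i B*_i).
    """
    params = params or steady.params
    grid = grid or steady.grid
    if steady.washed_out:
        raise WashoutError("no fixation curve in a washout regime")
    diag, off, qr, ql = _symmetrized_operator(steady)
    n = diag.size
    vals, vecs = eigh_tridiagonal(
        diag, off, select="i", select_range=(n - 2, n - 1)
    )
    lam0, lam1 = vals[-1], vals[-2]
    if lam0 - lam1 < 1e-8:
        raise RuntimeError(
            f"near-degenerate mutant operator (gap {lam0 - lam1:.3g}/h); "
            "refine the grid"
        )
    psi = vecs[:, -1]
    # Left null vector: phi_i = psi_i * (ql/qr)^(i/2); do it in log space so
    # high-Peclet geometric factors cannot overflow.
    log_d = 0.5 * np.arange(n) * np.log(qr / ql)
    log_phi = np.log(np.abs(psi) + 1e-300) - log_d
    phi = np.sign(psi) * np.exp(log_phi - log_phi.max())
    if phi.sum() < 0:
        phi = -phi
    if np.any(phi < -1e-10 * np.max(np.abs(phi))):
        raise RuntimeError("adjoint zero mode is not sign-definite; refine grid")
    phi = np.maximum(phi, 0.0)
    norm = params.S * grid.dx * float(phi @ steady.state.B)
    return NM * phi / norm


def reproduction_density(
    steady: SteadyState, params: GutParameters | None = None
) -> np.ndarray:
    """R(x) = B(x) rho(x): reproduction events per unit volume and time.

    Mutants arising from replication errors appear proportionally to R; in
    the strongly spatial regime R is small at both ends (no bacteria upstream,
    no food downstream) and peaks in between.
    """
    params = params or steady.params
    return steady.state.B * reproduction_rate(steady.state.F, params)


def overall_fixation_probability(
    ratio_curve: np.ndarray, R_curve: np.ndarray, grid: SpatialGrid
) -> float:
    """Reproduction-weighted average fixation: int(R C)dx / int(R)dx."""
    ratio_curve = np.asarray(ratio_curve, dtype=float)
    R_curve = np.asarray(R_curve, dtype=float)
    if ratio_curve.shape != R_curve.shape or ratio_curve.size != grid.n_cells:
        raise ValueError("curves must share the solver grid")
    total = float(R_curve.sum())
    if total <= 0.0:
        raise WashoutError("zero total reproduction: fixation undefined")
    return float((R_curve * ratio_curve).sum() / total)


def total_population(steady: SteadyState, params: GutParameters | None = None) -> float:
    """Total bacterial count NT = S * integral(B + M) dx."""
    params = params or steady.params
    return params.S * steady.grid.dx * float((steady.state.B + steady.state.M).sum())


def active_population(
    steady: SteadyState,
    params: GutParameters | None = None,
    grid: SpatialGrid | None = None,
) -> tuple[float, float]:
    """Active population NA and its boundary x*.

    x* is where the (monotone decreasing) food profile crosses the Monod
    constant k, located by linear interpolation between cell centers;
    NA = S * integral_0^x* B dx counts the bacteria that still see enough food
    to divide at a substantial rate.  If F never crosses k — either F > k
    everywhere (weak gradients) or F < k everywhere (uniformly food-limited,
    as in a slow chemostat) — activity is spatially uniform and NA = NT.
    """
    params = params or steady.params
    grid = grid or steady.grid
    F, B = steady.state.F, steady.state.B
    drops = np.diff(F)
    if np.any(drops > 1e-9 * params.Fin):
        raise RuntimeError("food profile is not monotone decreasing")
    if F.min() >= params.k or F.max() < params.k:
        return total_population(steady, params), grid.L
    j = int(np.argmax(F < params.k))  # first cell below k
    if j == 0:
        from .solver import boundary_values

        f0, _ = boundary_values(F, params, grid, params.vFin)
        x_lo, x_hi = 0.0, grid.cell_centers[0]
        frac = (f0 - params.k) / (f0 - F[0])
    else:
        x_lo, x_hi = grid.cell_centers[j - 1], grid.cell_centers[j]
        frac = (F[j - 1] - params.k) / (F[j - 1] - F[j])
    x_star = float(x_lo + frac * (x_hi - x_lo))
    # FV integral of B up to x_star: whole cells plus a fractional cell
    edges = np.arange(grid.n_cells + 1) * grid.dx
    weights = np.clip((x_star - edges[:-1]) / grid.dx, 0.0, 1.0)
    na = params.S * grid.dx * float((weights * B).sum())
    return na, x_star


def reproductions_per_time(
    steady: SteadyState, params: GutParameters | None = None
) -> float:
    """NR = S * integral(B rho) dx: total reproductions per hour."""
    params = params or steady.params
    return params.S * steady.grid.dx * float(reproduction_density(steady, params).sum())


def predicted_fixation(NM: float, NA: float) -> float:
    """Effective-population prediction NM/NA for the overall fixation."""
    if NA <= 0:
        raise WashoutError("active population is zero")
    return NM / NA


@dataclass
class FixationReport:
    """Everything the fixation analysis derives from one steady state."""

    ratio_curve: np.ndarray  # C(xM) per cell
    R_curve: np.ndarray  # B*rho per cell
    overall_fixation: float
    NT: float
    NA: float
    x_star: float
    NR: float
    NM: float
    spatial_dependence: float
    regime: str


def analyze_fixation(
    steady: SteadyState, NM: float = 1.0, spatial_threshold: float = 0.9
) -> FixationReport:
    """Run the full fixation pipeline on a converged steady state."""
    params, grid = steady.params, steady.grid
    ratio = fixation_curve_adjoint(steady, NM=NM)
    R = reproduction_density(steady)
    sd = spatial_dependence(steady)
    na, x_star = active_population(steady)
    return FixationReport(
        ratio_curve=ratio,
        R_curve=R,
        overall_fixation=overall_fixation_probability(ratio, R, grid),
        NT=total_population(steady),
        NA=na,
        x_star=x_star,
        NR=reproductions_per_time(steady),
        NM=NM,
        spatial_dependence=sd,
        regime="persistent_spatial" if sd > spatial_threshold else "persistent_mixed",
    )


def sweep_fixation_vs_population(
    params_base: GutParameters,
    D_list,
    v_lists,
    NM: float = 1.0,
    n_cells: int = 600,
) -> pd.DataFrame:
    """Fixation vs. population size across a (v, D) sweep at fixed vFin.

    For each D in ``D_list`` the matching entry of ``v_lists`` gives the
    velocities to scan (food inflow vFin is a property of ``params_base`` and
    held constant, so Fin = vFin/v varies with v, as in the phase-diagram
    analyses).  Washout points are flagged, never silently dropped.

    Returns a tidy frame with one row per (v, D):
    v, D, washed_out, spatial_dependence, NT, NA, x_star, fixation, NR.
    """
    rows = []
    v_lists = list(v_lists)
    if len(v_lists) != len(list(D_list)):
        raise ValueError("need one v-list per D value")
    for D, vs in zip(D_list, v_lists):
        for v in vs:
            p = params_base.replace(v=float(v), D=float(D))
            steady = solve_steady_state(p, n_cells=n_cells)
            row = {
                "v": float(v),
                "D": float(D),
                "washed_out": steady.washed_out,
                "converged": steady.converged,
            }
            if steady.washed_out:
                row.update(
                    spatial_dependence=np.nan,
                    NT=0.0,
                    NA=0.0,
                    x_star=np.nan,
                    fixation=np.nan,
                    NR=0.0,
                )
            else:
                rep = analyze_fixation(steady, NM=NM)
                row.update(
                    spatial_dependence=rep.spatial_dependence,
                    NT=rep.NT,
                    NA=rep.NA,
                    x_star=rep.x_star,
                    fixation=rep.overall_fixation,
                    NR=rep.NR,
                )
            rows.append(row)
    return pd.DataFrame(rows)
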