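"""Physical parameters, spatial grid, field containers, and dimensionless groups.

Units are fixed package-wide: lengths in cm, time in h, food concentration in
mM, bacterial concentration in bacteria/cm^3.  With the cross-section area S in
cm^2, ``S * integral(B dx)`` is then a genuine bacterial count, which is what
the population-size and fixation analyses rely on.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from numbers import Real

import numpy as np

__all__ = [
    "ConfigurationError",
    "ResolutionError",
    "GutParameters",
    "SpatialGrid",
    "FieldState",
    "DimensionlessParams",
    "PHYSICAL_KEYS",
    "make_parameters",
    "build_grid",
    "nondimensionalize",
]


class ConfigurationError(ValueError):
    """Invalid or incomplete physical configuration."""


class ResolutionError(ValueError):
    """Spatial resolution too coarse for the requested computation."""


#: The eight physical parameters every model run needs, with their units.
PHYSICAL_KEYS: dict[str, str] = {
    "v": "flow velocity (cm/h)",
    "D": "effective diffusion coefficient (cm^2/h)",
    "r": "maximal growth rate (1/h)",
    "k": "Monod constant (mM)",
    "vFin": "food inflow rate at the entrance (mM*cm/h)",
    "alpha": "yield, bacteria produced per unit food (bacteria/cm^3 per mM)",
    "L": "gut segment length (cm)",
    "S": "cross-section area (cm^2)",
}


@dataclass(frozen=True)
class GutParameters:
    """Physical constants of the one-dimensional gut model.

    The gut is a tube of length ``L`` and section ``S`` with constant flow
    velocity ``v`` and effective diffusion ``D`` (mixing).  Food enters at
    x=0 at rate ``vFin`` (so the incoming food concentration is
    ``Fin = vFin / v``); bacteria grow at Monod rate ``r*F/(k+F)`` and convert
    food to biomass with yield ``alpha``.
    """

    v: float
    D: float
    r: float
    k: float
    vFin: float
    alpha: float
    L: float
    S: float

    def __post_init__(self) -> None:
        for name in PHYSICAL_KEYS:
            value = getattr(self, name)
            if not isinstance(value, Real) or isinstance(value, bool):
                raise ConfigurationError(
                    f"parameter {name!r} must be a number, got {value!r}"
                )
            value = float(value)
            if not np.isfinite(value) or value <= 0.0:
                raise ConfigurationError(
                    f"parameter {name!r} must be strictly positive and finite, "
                    f"got {value!r}"
                )
            object.__setattr__(self, name, value)

    @property
    def Fin(self) -> float:
        """Incoming food concentration Fin = vFin / v (mM)."""
        return self.vFin / self.v

    def replace(self, **changes: float) -> "GutParameters":
        """Return a copy with the given parameters replaced."""
        values = {name: getattr(self, name) for name in PHYSICAL_KEYS}
        values.update(changes)
        return GutParameters(**values)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PHYSICAL_KEYS}


def make_parameters(config: Mapping[str, object]) -> GutParameters:
    """Validate a flat key-value map into :class:`GutParameters`.

    All eight physical keys must be present, numeric, and strictly positive;
    unknown keys are rejected so typos cannot silently fall back to defaults.
    """
    unknown = sorted(set(config) - set(PHYSICAL_KEYS))
    if unknown:
        raise ConfigurationError(f"unknown parameter keys: {', '.join(unknown)}")
    missing = sorted(set(PHYSICAL_KEYS) - set(config))
    if missing:
        raise ConfigurationError(f"missing parameter keys: {', '.join(missing)}")
    return GutParameters(**{k: config[k] for k in PHYSICAL_KEYS})


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform cell-centered finite-volume grid covering [0, L]."""

    n_cells: int
    dx: float
    cell_centers: np.ndarray = field(repr=False)
    L: float

    def locate(self, x: float) -> int:
        """Index of the cell whose interval [i*dx, (i+1)*dx) contains x."""
        if not 0.0 < x < self.L:
            raise ValueError(f"position x={x} outside (0, {self.L})")
        return min(int(x / self.dx), self.n_cells - 1)


def build_grid(params: GutParameters, n_cells: int) -> SpatialGrid:
    """Build a uniform cell-centered grid with ``n_cells`` cells on [0, L]."""
    if not isinstance(n_cells, (int, np.integer)) or n_cells < 10:
        raise ResolutionError(f"n_cells must be an integer >= 10, got {n_cells!r}")
    n_cells = int(n_cells)
    dx = params.L / n_cells
    centers = (np.arange(n_cells) + 0.5) * dx
    return SpatialGrid(n_cells=n_cells, dx=dx, cell_centers=centers, L=params.L)


@dataclass
class FieldState:
    """Concentration profiles of food F, wild type B, and mutant M at time t.

    F is in mM; B and M in bacteria/cm^3.  All arrays live on the same
    cell-centered grid and are elementwise non-negative.
    """

    t: float
    F: np.ndarray
    B: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        n = self.F.shape
        if self.B.shape != n or self.M.shape != n or self.F.ndim != 1:
            raise ValueError("F, B, M must be 1-d arrays of equal length")
        for name in ("F", "B", "M"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if arr.min(initial=0.0) < 0.0:
                raise ValueError(f"{name} contains negative concentrations")

    @property
    def n_cells(self) -> int:
        return self.F.size

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.F.copy(), self.B.copy(), self.M.copy())


@dataclass(frozen=True)
class DimensionlessParams:
    """The three dimensionless groups that fix the stationary state.

    * ``peclet`` = vL/D: advective vs. diffusive transport over the gut length.
    * ``growth_number`` = rL/v: divisions available during one transit.
    * ``saturation`` = k/Fin: Monod constant relative to incoming food.

    Two parameter sets sharing these three numbers have identical steady
    profiles once x is rescaled by L, F by Fin, and B, M by alpha*Fin.
    """

    peclet: float
    growth_number: float
    saturation: float

    def __post_init__(self) -> None:
        for name in ("peclet", "growth_number", "saturation"):
            value = float(getattr(self, name))
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be positive and finite")
            object.__setattr__(self, name, value)

    def to_parameters(
        self,
        L: float = 1.0,
        Fin: float = 1.0,
        r: float = 1.0,
        alpha: float = 1.0,
        S: float = 1.0,
    ) -> GutParameters:
        """Reconstruct a concrete parameter set with the chosen scales."""
        v = r * L / self.growth_number
        return GutParameters(
            v=v,
            D=v * L / self.peclet,
            r=r,
            k=self.saturation * Fin,
            vFin=v * Fin,
            alpha=alpha,
            L=L,
            S=S,
        )


def nondimensionalize(params: GutParameters) -> DimensionlessParams:
    """Return (vL/D, rL/v, k/Fin) for a parameter set."""
    return DimensionlessParams(
        peclet=params.v * params.L / params.D,
        growth_number=params.r * params.L / params.v,
        saturation=params.k / params.Fin,
    )
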