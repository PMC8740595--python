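"""Data pipelines behind the headline analyses.

Each pipeline emits the tidy CSV underlying one figure-style analysis:

* ``fig1b`` - steady concentration profiles F, B, rho at the benchmark
  spatially-structured parameter point;
* ``fig1c`` - heat-map grid of the spatial-dependence metric over (v, D)
  with the two analytic washout lines;
* ``fig2``  - fixation probability C, reproduction density R, and their
  product vs. the mutant introduction position;
* ``fig3``  - overall fixation vs. total population NT across a (v, D)
  sweep at constant food inflow;
* ``fig4``  - fixation vs. active population NA in the strongly spatial
  regime (rows filtered to spatial dependence > 0.9), against NM/NA.

Plotting is deliberately left out: the CSV is the contract.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fate import analyze_fixation, sweep_fixation_vs_population
from .io import write_profile
from .parameters import GutParameters
from .solver import (
    reproduction_rate,
    solve_steady_state,
    spatial_dependence,
    washout_thresholds,
)

__all__ = ["FIGURES", "figure_pipeline"]

#: Benchmark parameter point with strong spatial structure (profiles figure).
BENCHMARK = dict(v=0.5, D=0.2, k=0.1, r=0.42, vFin=1.0, alpha=6.13e8, L=6.0, S=1.0)
#: Strongly spatial, near-washout point used for the active-population figure.
ACTIVE_POP_POINT = dict(v=0.181, D=0.02)


def _fig1b(params: GutParameters, out_dir: Path, n_cells: int) -> list[Path]:
    steady = solve_steady_state(params, n_cells=n_cells)
    rho = reproduction_rate(steady.state.F, params)
    out = out_dir / "fig1b_profiles.csv"
    write_profile(
        out,
        steady.state,
        steady.grid.cell_centers,
        extra={"rho": rho},
        header_comment=(
            f"steady profiles, v={params.v} cm/h, D={params.D} cm^2/h; "
            f"residual={steady.residual:.3g}/h"
        ),
    )
    return [out]


def _fig1c(
    params: GutParameters, out_dir: Path, n_cells: int, n_v: int = 12, n_d: int = 12
) -> list[Path]:
    vs = np.geomspace(0.05, 2.4, n_v)
    ds = np.geomspace(0.02, 20.0, n_d)
    rows = []
    for v in vs:
        for d in ds:
            p = params.replace(v=float(v), D=float(d))
            d_crit, v_crit = washout_thresholds(p)
            steady = solve_steady_state(p, n_cells=min(n_cells, 300), t_max=500.0)
            rows.append(
                {
                    "v": v,
                    "D": d,
                    "washed_out": steady.washed_out,
                    "spatial_dependence": (
                        np.nan
                        if steady.washed_out
                        else spatial_dependence(steady, p)
                    ),
                    "d_crit": d_crit,
                    "v_crit": v_crit,
                }
            )
    out = out_dir / "fig1c_phase_diagram.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return [out]


def _fig2(params: GutParameters, out_dir: Path, n_cells: int, NM: float = 1.0) -> list[Path]:
    steady = solve_steady_state(params, n_cells=n_cells)
    rep = analyze_fixation(steady, NM=NM)
    df = pd.DataFrame(
        {
            "xM": steady.grid.cell_centers,
            "C": rep.ratio_curve,
            "R": rep.R_curve,
            "RC": rep.ratio_curve * rep.R_curve,
        }
    )
    out = out_dir / "fig2_fixation_vs_position.csv"
    df.to_csv(out, index=False)
    return [out]


def _fig3(
    params: GutParameters, out_dir: Path, n_cells: int, NM: float = 1.0
) -> list[Path]:
    # One velocity scan per diffusion coefficient, constant vFin throughout.
    sweeps = {
        0.02: np.linspace(0.15, 0.183, 6),
        0.2: np.linspace(0.3, 1.0, 5),
        2.0: np.linspace(0.3, 2.0, 5),
        20.0: np.linspace(0.1, 1.5, 5),
    }
    df = sweep_fixation_vs_population(
        params,
        list(sweeps),
        [list(v) for v in sweeps.values()],
        NM=NM,
        n_cells=n_cells,
    )
    out = out_dir / "fig3_fixation_vs_population.csv"
    df.to_csv(out, index=False)
    return [out]


def _fig4(
    params: GutParameters, out_dir: Path, n_cells: int, NM: float = 1.0
) -> list[Path]:
    p = params.replace(**ACTIVE_POP_POINT)
    df = sweep_fixation_vs_population(
        p, [p.D], [list(np.linspace(0.15, 0.183, 8))], NM=NM, n_cells=n_cells
    )
    kept = df[(~df.washed_out) & (df.spatial_dependence > 0.9)].copy()
    kept["predicted_fixation"] = NM / kept["NA"]
    out = out_dir / "fig4_fixation_vs_active_population.csv"
    kept.to_csv(out, index=False)
    return [out]


FIGURES = {
    "fig1b": _fig1b,
    "fig1c": _fig1c,
    "fig2": _fig2,
    "fig3": _fig3,
    "fig4": _fig4,
}


def figure_pipeline(
    name: str, params: GutParameters, out_dir: str | Path, n_cells: int = 600
) -> list[Path]:
    """Run one named pipeline, returning the paths it wrote."""
    if name not in FIGURES:
        raise ValueError(f"unknown figure {name!r}; choose from {sorted(FIGURES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return FIGURES[name](params, out_dir, n_cells)
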