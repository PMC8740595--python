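"""Configuration files, profile tables, and run manifests.

Profiles travel as tidy CSV/TSV (columns x, F, B, M on a uniform grid) so
every intermediate is human-inspectable; scalar outputs and provenance go in
JSON sidecars.  Each CLI run writes a manifest recording the fully resolved
configuration, numerics, package version, and checksums of its outputs, so a
deterministic run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .parameters import (
    ConfigurationError,
    FieldState,
    GutParameters,
    PHYSICAL_KEYS,
    make_parameters,
)

__all__ = [
    "ProfileFormatError",
    "NUMERIC_KEYS",
    "load_config",
    "read_profile",
    "write_profile",
    "RunManifest",
]


class ProfileFormatError(ValueError):
    """A profile table violates the expected layout."""


#: Recognized non-physical configuration keys and their defaults.
NUMERIC_KEYS: dict[str, object] = {
    "n_cells": None,  # None -> CLI flag or package default
    "t_max": None,  # solver default
    "steady_tol": None,
    "seed": 0,
}


def load_config(path: str | Path) -> tuple[GutParameters, dict[str, object]]:
    """Read a YAML/JSON config into parameters plus numerics options.

    The file is a flat map of the eight physical parameters with optional
    numerics keys (n_cells, t_max, steady_tol, seed).  Anything else is
    rejected.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a flat mapping")
    numerics = dict(NUMERIC_KEYS)
    physical = {}
    for key, value in raw.items():
        if isinstance(value, str):
            # YAML 1.1 reads '6.13e8' (no sign) as a string; be forgiving
            try:
                value = float(value)
            except ValueError:
                pass
        if key in NUMERIC_KEYS:
            numerics[key] = value
        else:
            physical[key] = value
    return make_parameters(physical), numerics


def read_profile(path: str | Path) -> FieldState:
    """Read a concentration profile table into a :class:`FieldState`.

    Expects CSV or TSV with header columns x, F, B and optionally M
    (defaulting to zero); x must be strictly increasing and uniformly spaced
    (relative tolerance 1e-6).  Lines starting with '#' are comments.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = {"x", "F", "B"} - set(df.columns)
    if missing:
        raise ProfileFormatError(f"{path}: missing columns {sorted(missing)}")
    if "M" not in df.columns:
        df["M"] = 0.0
    x = df["x"].to_numpy(dtype=float)
    if x.size < 2 or np.any(np.diff(x) <= 0):
        raise ProfileFormatError(f"{path}: x must be strictly increasing")
    dx = np.diff(x)
    if np.max(np.abs(dx - dx[0])) > 1e-6 * dx[0]:
        j = int(np.argmax(np.abs(dx - dx[0]))) + 2  # 1-based data line
        raise ProfileFormatError(f"{path}: non-uniform spacing at data line {j}")
    for col in ("F", "B", "M"):
        vals = df[col].to_numpy(dtype=float)
        neg = np.nonzero(vals < 0)[0]
        if neg.size:
            raise ProfileFormatError(
                f"{path}: negative {col} at data line {int(neg[0]) + 1}"
            )
    return FieldState(
        t=0.0,
        F=df["F"].to_numpy(dtype=float),
        B=df["B"].to_numpy(dtype=float),
        M=df["M"].to_numpy(dtype=float),
    )


def write_profile(
    path: str | Path,
    state: FieldState,
    cell_centers: np.ndarray,
    extra: dict[str, np.ndarray] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a profile as tidy CSV with an explanatory header comment."""
    path = Path(path)
    data = {"x": cell_centers, "F": state.F, "B": state.B, "M": state.M}
    if extra:
        data.update(extra)
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write("# x (cm), F (mM), B and M (bacteria/cm^3)\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    parameters: dict[str, float]
    numerics: dict[str, object]
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    outputs: list[dict[str, str]] = field(default_factory=list)

    def record_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs.append({"path": str(path), "sha256": _checksum(path)})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
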