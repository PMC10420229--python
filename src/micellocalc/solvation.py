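"""Solvent-water partition coefficients from solvation free energies.

The transfer free energy of a solute from water into a bulk solvent is the
difference of its standard solvation free energies,
``ddG = dG_solv - dG_water`` (kcal/mol), and the corresponding partition
coefficient is ``logP = -ddG / (R T ln 10)``.  At 298.15 K the denominator
R*T*ln10 is 1.36425 kcal/mol, so 1.36 kcal/mol of transfer free energy is
one logP unit.

Solvation energies are consumed as tables (e.g. exported from a continuum-
solvation quantum-chemistry workflow); computing them is outside this
package's scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalConstants",
    "transfer_energy",
    "logp_from_transfer",
    "logp_matrix",
    "load_solvation_table",
    "read_per_solvent_export",
]

R_GAS_KCAL = 1.98720e-3  # molar gas constant, kcal/(mol K)
KJ_PER_KCAL = 4.184

WATER = "water"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant and temperature entering the logP conversion."""

    r_gas: float = R_GAS_KCAL  # kcal/(mol K)
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError(f"temperature must be positive, got {self.temperature}")

    @property
    def rt_ln10(self) -> float:
        """R*T*ln(10) in kcal/mol — one logP unit of transfer free energy."""
        return self.r_gas * self.temperature * math.log(10.0)


def transfer_energy(dg_solv: float, dg_water: float) -> float:
    """Water-to-solvent transfer free energy, kcal/mol; NaN propagates."""
    return dg_solv - dg_water


def logp_from_transfer(ddg: float, constants: PhysicalConstants = PhysicalConstants()) -> float:
    """logP = -ddG / (R T ln 10); negative transfer energy favours the solvent."""
    return -ddg / constants.rt_ln10


def load_solvation_table(
    path: str | Path, energy_unit: str = "kcal/mol"
) -> pd.DataFrame:
    """Read a wide solvation-energy CSV: compound column then one column per
    solvent (a ``water`` column is required downstream).  Energies are stored
    in kcal/mol; ``energy_unit="kJ/mol"`` converts on input.
    """
    df = pd.read_csv(path, index_col=0)
    df.index.name = "compound"
    df = df.astype(float)
    if energy_unit == "kJ/mol":
        df = df / KJ_PER_KCAL
    elif energy_unit != "kcal/mol":
        raise ConfigurationError(f"unknown energy unit {energy_unit!r}")
    return df


def read_per_solvent_export(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Assemble a solvation table from per-solvent two-column (compound, dG)
    CSV exports, keyed by solvent name."""
    cols = {}
    for solvent, path in paths.items():
        two = pd.read_csv(path, index_col=0)
        if two.shape[1] != 1:
            raise ConfigurationError(f"{path}: expected exactly one energy column")
        cols[solvent] = two.iloc[:, 0].astype(float)
    return pd.DataFrame(cols)


def logp_matrix(
    solvation: pd.DataFrame,
    constants: PhysicalConstants = PhysicalConstants(),
    water_column: str = WATER,
) -> pd.DataFrame:
    """Solvent/water logP matrix from a compounds x solvents energy table.

    Each non-water solvent column yields one output column named
    ``"<solvent>/water"``; an entry is missing wherever either solvation
    energy is missing.
    """
    matches = [c for c in solvation.columns if c == water_column]
    if len(matches) != 1:
        raise ConfigurationError(
            f"need exactly one {water_column!r} column, found {len(matches)}"
        )
    dg_wat = solvation[water_column]
    out = {}
    for solvent in solvation.columns:
        if solvent == water_column:
            continue
        ddg = solvation[solvent] - dg_wat
        out[f"{solvent}/water"] = -ddg / constants.rt_ln10
    result = pd.DataFrame(out, index=solvation.index)
    result.index.name = "compound"
    return result


def solvation_from_logp(
    logp: pd.DataFrame,
    dg_water: pd.Series,
    constants: PhysicalConstants = PhysicalConstants(),
) -> pd.DataFrame:
    """Inverse of :func:`logp_matrix`: build a solvation table whose
    logp_matrix reproduces ``logp`` exactly.  Column names in ``logp`` may
    carry the ``/water`` suffix; it is stripped.

    Used by the simulator; exact to floating-point round-off.
    """
    table = {WATER: dg_water.astype(float)}
    for col in logp.columns:
        solvent = col.removesuffix("/water")
        ddg = -logp[col] * constants.rt_ln10
        table[solvent] = dg_water + ddg
    out = pd.DataFrame(table, index=logp.index)
    out.index.name = "compound"
    return out
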