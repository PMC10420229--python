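"""Compound structures, partition tables, and the micelle parameter registry.

The package's central container for partition data is a pandas DataFrame
indexed by compound name with one column per partition system (micelle or
``solvent/water`` pair).  Missing measurements are NaN; on disk they are
written as ``-`` so that a round-trip through CSV preserves them
distinguishably from numeric zeros.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "Compound",
    "CompoundSet",
    "MicelleSystem",
    "load_compound_table",
    "load_partition_table",
    "write_partition_table",
    "micelle_registry",
    "bundled_compounds",
    "bundled_partition_table",
    "bundled_reference_calibrations",
]

RDLogger.DisableLog("rdApp.*")

MISSING_MARKER = "-"


class FormatError(ValueError):
    """A file does not have the expected layout."""


class ValidationError(ValueError):
    """A file parsed but its content violates an invariant."""


@dataclass(frozen=True)
class Compound:
    """A named chemical structure.

    Parameters
    ----------
    name : unique identifier (case-insensitively unique within a set)
    smiles : structure in SMILES notation; must parse under RDKit's
        default (Daylight-like) aromaticity model
    tags : optional free-text class labels, e.g. ``("urea herbicide",)``
    """

    name: str
    smiles: str
    tags: tuple[str, ...] = ()

    @property
    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValidationError(f"unparsable SMILES for {self.name!r}: {self.smiles!r}")
        return mol


@dataclass
class CompoundSet:
    """An ordered collection of compounds; iteration follows input order."""

    compounds: list[Compound] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.compounds:
            key = c.name.casefold()
            if key in seen:
                raise ValidationError(f"duplicate compound name {c.name!r}")
            seen.add(key)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def __getitem__(self, name: str) -> Compound:
        key = name.casefold()
        for c in self.compounds:
            if c.name.casefold() == key:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
        except KeyError:
            return False
        return True

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def subset(self, names: list[str]) -> "CompoundSet":
        """Sub-collection in this set's order, restricted to ``names``."""
        wanted = {n.casefold() for n in names}
        return CompoundSet([c for c in self.compounds if c.name.casefold() in wanted])


@dataclass(frozen=True)
class MicelleSystem:
    """Surfactant constants parameterising the micellar phase ratio.

    The phase ratio of a micellar pseudo-stationary phase is
    ``phi = molar_volume * (c_total - cmc)``: only surfactant above the
    critical micellar concentration contributes micellar volume.

    Parameters
    ----------
    name : system label, e.g. ``"SC"``
    c_total : total surfactant concentration (mol/L)
    cmc : critical micellar concentration (mol/L)
    molar_volume : partial molar volume of micellised surfactant (L/mol)
    """

    name: str
    c_total: float
    cmc: float
    molar_volume: float

    def __post_init__(self) -> None:
        if not (self.c_total > self.cmc >= 0.0):
            raise ValidationError(
                f"{self.name}: need c_total > cmc >= 0, got "
                f"c_total={self.c_total}, cmc={self.cmc}"
            )
        phi = self.phase_ratio
        if not (0.0 < phi < 1.0):
            raise ValidationError(
                f"{self.name}: phase ratio {phi:.4g} outside (0, 1)"
            )

    @property
    def phase_ratio(self) -> float:
        """phi = molar_volume * (c_total - cmc), dimensionless."""
        return self.molar_volume * (self.c_total - self.cmc)


# Surfactant constants for the three measured systems: concentrations of the
# MEKC runs (80/40/20 mM in phosphate buffer, pH 7, 25 degC), CMCs measured in
# the same buffer, and literature partial molar volumes.
_DEFAULT_REGISTRY = (
    MicelleSystem("SC", c_total=0.080, cmc=0.0124, molar_volume=0.317),
    MicelleSystem("LPFOS", c_total=0.040, cmc=0.00327, molar_volume=0.285),
    MicelleSystem("HTAB", c_total=0.020, cmc=0.00034, molar_volume=0.324),
)


def micelle_registry(
    overrides: dict[str, dict[str, float]] | None = None,
    concentration_unit: str = "mol/L",
) -> dict[str, MicelleSystem]:
    """Registry of micellar systems, keyed by name.

    By default contains sodium cholate (SC), lithium perfluorooctane-
    sulfonate (LPFOS) and hexadecyltrimethylammonium bromide (HTAB).
    Additional systems, or replacements, are supplied via ``overrides``
    mapping name -> {c_total, cmc, molar_volume}.  ``concentration_unit``
    ("mol/L" or "mmol/L") applies to override concentrations only; the
    registry is stored in mol/L internally.
    """
    scale = {"mol/L": 1.0, "M": 1.0, "mmol/L": 1e-3, "mM": 1e-3}.get(concentration_unit)
    if scale is None:
        raise ValueError(f"unknown concentration unit {concentration_unit!r}")
    registry = {m.name: m for m in _DEFAULT_REGISTRY}
    for name, params in (overrides or {}).items():
        registry[name] = MicelleSystem(
            name,
            c_total=float(params["c_total"]) * scale,
            cmc=float(params["cmc"]) * scale,
            molar_volume=float(params["molar_volume"]),
        )
    return registry


def load_compound_table(path: str | Path) -> CompoundSet:
    """Read a compound CSV with columns ``name``, ``smiles`` (``tags`` optional).

    Every SMILES is parsed eagerly so malformed rows fail here, with the
    offending row named, rather than deep inside a downstream stage.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"name", "smiles"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    compounds = []
    for i, row in df.iterrows():
        name = str(row["name"]).strip()
        smiles = str(row["smiles"]).strip()
        if Chem.MolFromSmiles(smiles) is None:
            raise ValidationError(f"{path} row {i + 2}: unparsable SMILES {smiles!r} for {name!r}")
        tags_raw = row.get("tags")
        tags = tuple(t.strip() for t in str(tags_raw).split(";")) if pd.notna(tags_raw) else ()
        compounds.append(Compound(name, smiles, tags))
    return CompoundSet(compounds)


def load_partition_table(path: str | Path) -> pd.DataFrame:
    """Read a logP matrix CSV: first column compound names, then one column
    per system.  ``-`` or an empty cell marks a missing measurement (NaN).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise FormatError(f"{path}: expected a compound column plus >=1 system column")
    df = df.set_index(df.columns[0])
    df.index.name = "compound"
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for name, cell in df[col].items():
            cell = cell.strip()
            if cell in ("", MISSING_MARKER):
                out.loc[name, col] = np.nan
            else:
                try:
                    out.loc[name, col] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at (compound={name!r}, system={col!r})"
                    ) from None
    return out


def write_partition_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a logP matrix; NaN cells become ``-`` so load/write round-trips."""
    out = table.map(lambda v: MISSING_MARKER if pd.isna(v) else format(v, "g"))
    out.to_csv(path, index_label="compound")


def _data_path(filename: str) -> Path:
    return Path(importlib.resources.files("micellocalc").joinpath("data", filename))


def bundled_compounds() -> CompoundSet:
    """The 63 measured compounds with curated SMILES and class tags."""
    return load_compound_table(_data_path("compounds.csv"))


def bundled_partition_table() -> pd.DataFrame:
    """The experimental micelle-water logP table (63 compounds x SC/HTAB/LPFOS).

    Five HTAB entries are missing in the source data and load as NaN.
    """
    return load_partition_table(_data_path("experimental_logp.csv"))


def bundled_reference_calibrations() -> pd.DataFrame:
    """Published micelle-vs-alcohol linear calibrations (slope, intercept,
    R^2, MAE).  Shipped as reference values; not recomputed by this package
    because the underlying solvation energies are not public.
    """
    return pd.read_csv(_data_path("reference_calibrations.csv"))
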