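"""Surrogate-solvent identification.

A bulk solvent is a useful surrogate for a micellar phase when the
solvent/water logP of a compound set correlates strongly with the
micelle-water logP measured in that micelle.  This module computes the
pairwise Pearson correlation structure between experimental (micellar) and
computed (solvent/water) logP columns, applies the substructure filter that
removes compounds partitioning anomalously in cationic HTAB micelles
(aromatic-ring nitrogen or a urea group), and fits per-(micelle, solvent)
linear calibrations y_micelle = a * x_solvent + b with the usual error
metrics (R^2, MAE, MSE, RMSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .compounds import CompoundSet

__all__ = [
    "CorrelationMatrix",
    "FilterResult",
    "CalibrationModel",
    "correlation_matrix",
    "nset_filter",
    "fit_calibration",
    "calibrate_all",
    "predict_micellar_logp",
    "best_micelle",
    "rank_surrogates",
]

# Exclusion rule: nitrogen inside an aromatic ring, or the urea (carbamide)
# fragment N-C(=O)-N.  [NX3] keeps the rule away from plain amides: benzamide
# has only one nitrogen flanking the carbonyl and must be retained.
AROMATIC_N_SMARTS = "[n]"
UREA_SMARTS = "[NX3][CX3](=O)[NX3]"

_AROMATIC_N = Chem.MolFromSmarts(AROMATIC_N_SMARTS)
_UREA = Chem.MolFromSmarts(UREA_SMARTS)


class InsufficientDataError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations between logP columns.

    ``r`` is symmetric with unit diagonal (where defined); ``n_pairs`` holds
    the number of jointly observed compounds behind each cell.  Columns in
    ``experimental`` are the measured micellar systems; all others are
    computed solvent/water surrogate candidates.
    """

    r: pd.DataFrame
    n_pairs: pd.DataFrame
    experimental: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)


def correlation_matrix(
    experimental: pd.DataFrame,
    *computed: pd.DataFrame,
    min_pairs: int = 2,
) -> CorrelationMatrix:
    """Correlate every logP column with every other.

    The experimental table's columns come first in the output ordering, then
    the computed tables' columns in the order given.  Correlations use
    pairwise-complete observations; a cell whose pair count falls below
    ``min_pairs`` is reported missing, as is any pair involving a
    zero-variance column (with a warning).
    """
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    joined = experimental.copy()
    for tab in computed:
        joined = joined.join(tab, how="outer")
    if joined.columns.duplicated().any():
        dupes = joined.columns[joined.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column labels across tables: {dupes}")

    notna = joined.notna().astype(int)
    n_pairs = pd.DataFrame(
        notna.T.values @ notna.values, index=joined.columns, columns=joined.columns
    )
    r = joined.corr(method="pearson", min_periods=min_pairs)

    for col in joined.columns:
        series = joined[col].dropna()
        if len(series) >= min_pairs and float(np.var(series.values)) == 0.0:
            warnings.warn(f"column {col!r} has zero variance; correlations undefined")
            r.loc[col, :] = np.nan
            r.loc[:, col] = np.nan
    # unit diagonal wherever at least min_pairs observations exist
    for col in joined.columns:
        if n_pairs.loc[col, col] >= min_pairs:
            r.loc[col, col] = 1.0
    return CorrelationMatrix(r=r, n_pairs=n_pairs, experimental=list(experimental.columns))


@dataclass
class FilterResult:
    """Partition of a compound set by the aromatic-N / urea exclusion rule."""

    retained: CompoundSet
    excluded: CompoundSet
    reasons: dict[str, tuple[str, ...]]

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "compound": c.name,
                "excluded": c.name in {e.name for e in self.excluded},
                "reasons": ";".join(self.reasons.get(c.name, ())),
            }
            for c in list(self.retained) + list(self.excluded)
        ]
        return pd.DataFrame(rows).set_index("compound")


def nset_filter(compounds: CompoundSet) -> FilterResult:
    """Split a compound set into retained and excluded ("N set") members.

    A compound is excluded iff its structure contains a nitrogen atom that is
    a member of an aromatic ring (SMARTS ``[n]``) or the urea substructure
    (SMARTS ``[NX3][CX3](=O)[NX3]``).  Both reasons are recorded when both
    apply.  Idempotent: filtering the retained set excludes nothing further.
    """
    retained, excluded, reasons = [], [], {}
    for compound in compounds:
        mol = compound.mol  # raises on unparsable SMILES
        why = []
        if mol.HasSubstructMatch(_AROMATIC_N):
            why.append("aromatic-N")
        if mol.HasSubstructMatch(_UREA):
            why.append("urea")
        if why:
            excluded.append(compound)
            reasons[compound.name] = tuple(why)
        else:
            retained.append(compound)
    return FilterResult(CompoundSet(retained), CompoundSet(excluded), reasons)


@dataclass(frozen=True)
class CalibrationModel:
    """Ordinary-least-squares line mapping solvent/water logP to micellar logP.

    ``r2`` is the squared Pearson correlation of the fitted pairs, which for
    a simple linear regression with intercept equals the OLS coefficient of
    determination.  ``slope_stderr``/``intercept_stderr`` are the usual OLS
    standard errors, enabling t-based confidence intervals.
    """

    micelle: str
    solvent: str
    slope: float
    intercept: float
    r2: float
    mae: float
    mse: float
    rmse: float
    n: int
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t distribution, n-2 df)."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - tcrit * self.slope_stderr, self.slope + tcrit * self.slope_stderr)

    def intercept_ci(self, level: float = 0.95) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (
            self.intercept - tcrit * self.intercept_stderr,
            self.intercept + tcrit * self.intercept_stderr,
        )


def fit_calibration(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    micelle: str = "",
    solvent: str = "",
    min_n: int = 3,
) -> CalibrationModel:
    """Fit y = slope*x + intercept by OLS on listwise-complete pairs.

    Pairs with a missing value on either side are dropped.  Requires at
    least ``min_n`` complete pairs and nonzero variance in x.
    """
    x = pd.Series(np.asarray(x, dtype=float)) if not isinstance(x, pd.Series) else x
    y = pd.Series(np.asarray(y, dtype=float)) if not isinstance(y, pd.Series) else y
    df = pd.concat({"x": x, "y": y}, axis=1).dropna()
    n = len(df)
    if n < min_n:
        raise InsufficientDataError(f"need >= {min_n} complete pairs, got {n}")
    xv, yv = df["x"].values, df["y"].values
    if float(np.ptp(xv)) == 0.0:
        raise DegenerateFitError("zero variance in x; slope undefined")
    if float(np.ptp(yv)) == 0.0:
        # constant response: flat line, no explained variance
        res_zero = yv - yv.mean()
        return CalibrationModel(
            micelle, solvent, 0.0, float(yv.mean()), 0.0,
            float(np.mean(np.abs(res_zero))), float(np.mean(res_zero**2)),
            float(np.sqrt(np.mean(res_zero**2))), n, 0.0, 0.0,
        )
    fit = stats.linregress(xv, yv)
    resid = yv - (fit.slope * xv + fit.intercept)
    mse = float(np.mean(resid**2))
    return CalibrationModel(
        micelle=micelle,
        solvent=solvent,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        mae=float(np.mean(np.abs(resid))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        n=n,
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
    )


def calibrate_all(
    micellar: pd.DataFrame, computed: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Fit one calibration per (micelle column, solvent column) pair.

    Returns a tidy table with slope/intercept/R^2/MAE/MSE/RMSE/n per pair;
    pairs with too few complete observations are silently omitted.
    """
    joined_index = micellar.index.intersection(computed.index)
    rows = []
    for mic in micellar.columns:
        for sol in computed.columns:
            try:
                m = fit_calibration(
                    computed.loc[joined_index, sol],
                    micellar.loc[joined_index, mic],
                    micelle=mic,
                    solvent=sol,
                    min_n=min_n,
                )
            except (InsufficientDataError, DegenerateFitError):
                continue
            rows.append(
                {
                    "micelle": m.micelle, "solvent": m.solvent, "slope": m.slope,
                    "intercept": m.intercept, "r2": m.r2, "mae": m.mae,
                    "mse": m.mse, "rmse": m.rmse, "n": m.n,
                }
            )
    return pd.DataFrame(rows)


def predict_micellar_logp(model: CalibrationModel, x: float | np.ndarray) -> float | np.ndarray:
    """Micellar logP predicted from a solvent/water logP."""
    return model.slope * x + model.intercept


def best_micelle(models: list[CalibrationModel], x: float) -> CalibrationModel:
    """The model predicting the highest micellar logP at x — i.e. the
    micellar system expected to solubilise the compound best."""
    return max(models, key=lambda m: predict_micellar_logp(m, x))


def rank_surrogates(cm: CorrelationMatrix, micelle: str) -> list[tuple[str, float]]:
    """Candidate surrogate solvents for a micelle, best first.

    Non-experimental columns sorted by descending Pearson r against the
    micelle column; ties broken alphabetically; missing correlations sort
    last.
    """
    if micelle not in cm.r.columns:
        raise KeyError(f"unknown micelle label {micelle!r}")
    candidates = [c for c in cm.r.columns if c not in cm.experimental]
    rs = [(sol, float(cm.r.loc[micelle, sol])) for sol in candidates]
    return sorted(rs, key=lambda t: (np.isnan(t[1]), -(t[1] if not np.isnan(t[1]) else -np.inf), t[0]))
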