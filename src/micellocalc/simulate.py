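"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the three data domains of the pipeline:

* retention records — a ground-truth micellar logP table is pushed through
  the exact inverse of the MEKC retention model and Gaussian noise is added
  on the *time* axis, where the measurement noise physically lives; each
  compound is emitted in triplicate, matching laboratory practice;
* solvation-energy panels — solvent/water logP values are generated from
  planted linear micelle<->solvent calibrations plus Gaussian residuals and
  converted back to free energies, so that refitting the calibration
  recovers the planted slope and intercept;
* descriptor matrices — Gaussian blobs with chosen sizes and separation,
  the planted labels returned alongside for recovery tests.

All generators are pure functions of (spec, seed): repeated calls with the
same arguments are bit-identical.

Defaults mirror the measured study conditions: 63 compounds, micellar logP
spanning [0.19, 3.71] (the observed extremes), triplicate injections,
retention noise 0.05 min on markers near t_0 = 2 and t_m = 10 min,
calibration slope 0.47 / intercept 0.55 with residual sd 0.5 logP units,
and a three-group 45/13/5 structure in an 85-descriptor space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compounds import MicelleSystem
from .mekc import RetentionRecord, retention_factor_from_logp, retention_time_from_factor
from .solvation import PhysicalConstants, solvation_from_logp

__all__ = [
    "SyntheticSpec",
    "BlobSpec",
    "simulate_partition_truth",
    "simulate_retention",
    "simulate_solvation",
    "simulate_descriptors",
]


@dataclass(frozen=True)
class BlobSpec:
    """Planted cluster structure: group sizes, separation (in within-blob
    sd units), and descriptor-space dimension."""

    sizes: tuple[int, ...] = (45, 13, 5)
    separation: float = 10.0
    dimension: int = 85

    def __post_init__(self) -> None:
        if self.separation < 0 or any(s <= 0 for s in self.sizes):
            raise ValueError("blob sizes must be positive and separation >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    true_logp_range is the uniform support of the planted micellar logP;
    calibration maps (micelle, solvent) -> (slope, intercept) for the
    solvation generator; residual_sd is the calibration scatter in logP
    units; retention_noise_sd is in minutes.
    """

    n_compounds: int = 63
    seed: int = 0
    true_logp_range: tuple[float, float] = (0.19, 3.71)
    retention_noise_sd: float = 0.05
    calibration: dict = field(
        default_factory=lambda: {("SC", "propan-1-ol"): (0.47, 0.55)}
    )
    residual_sd: float = 0.5
    blob_spec: BlobSpec = BlobSpec()

    def __post_init__(self) -> None:
        if self.retention_noise_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be >= 0")


def _compound_names(n: int) -> list[str]:
    return [f"cpd{i + 1:03d}" for i in range(n)]


def simulate_partition_truth(
    spec: SyntheticSpec, systems: list[str] = ("SC", "LPFOS", "HTAB")
) -> pd.DataFrame:
    """Ground-truth micellar logP drawn uniformly over the spec's range."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.true_logp_range
    values = rng.uniform(lo, hi, size=(spec.n_compounds, len(systems)))
    table = pd.DataFrame(values, index=_compound_names(spec.n_compounds), columns=list(systems))
    table.index.name = "compound"
    return table


def simulate_retention(
    truth: pd.DataFrame,
    registry: dict[str, MicelleSystem],
    t_0: float = 2.0,
    t_m: float = 10.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
) -> list[RetentionRecord]:
    """Noisy retention records implied by a ground-truth logP table.

    The noise-free analyte time comes from the exact inverse retention
    model; Gaussian noise of sd ``noise_sd`` minutes is added and the result
    clipped into the open interval (t_0, t_m) — times at or beyond the
    markers are not physically observable for a partitioning analyte.
    """
    rng = np.random.default_rng(seed)
    eps = 1e-9 * (t_m - t_0)
    records = []
    n_clipped = 0
    for compound in truth.index:
        for system in truth.columns:
            logp = truth.loc[compound, system]
            if pd.isna(logp):
                continue
            k = retention_factor_from_logp(float(logp), registry[system])
            t_clean = retention_time_from_factor(k, t_0, t_m)
            for _ in range(n_replicates):
                t_r = t_clean + rng.normal(0.0, noise_sd) if noise_sd > 0 else t_clean
                if not t_0 + eps <= t_r <= t_m - eps:
                    n_clipped += 1
                    t_r = min(max(t_r, t_0 + eps), t_m - eps)
                records.append(RetentionRecord(compound, system, t_r, t_0, t_m))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} simulated time(s) into ({t_0}, {t_m})")
    return records


def simulate_solvation(
    truth: pd.DataFrame,
    calibration: dict[tuple[str, str], tuple[float, float]],
    residual_sd: float = 0.5,
    constants: PhysicalConstants = PhysicalConstants(),
    seed: int = 0,
    dg_water_range: tuple[float, float] = (-15.0, -2.0),
) -> pd.DataFrame:
    """Solvation-energy panel consistent with planted linear calibrations.

    For each (micelle, solvent) pair with planted slope a and intercept b,
    solvent/water logP values x are drawn conditionally on the true micellar
    logP y so that the *forward* regression of y on x has slope a, intercept
    b, and residual standard deviation ``residual_sd``.  Simply inverting
    the line and adding noise to x would attenuate the recovered slope
    (classical errors-in-x bias); instead x follows the inverse-regression
    line x = c (y - mean(y)) + (mean(y) - b)/a + noise with

        c = (1 - residual_sd^2 / var(y)) / a,
        var(noise) = c var(y) (1 - a c) / a,

    which makes y = a x + b + residual the best linear predictor with the
    planted coefficients.  At residual_sd = 0 this reduces to the exact
    inversion x = (y - b)/a.  Requires residual_sd^2 < var(y) — otherwise
    the planted calibration would explain none of the variance.

    Water solvation energies are drawn uniformly from ``dg_water_range``
    (kcal/mol); each solvent energy is water plus the transfer energy
    implied by x.
    """
    rng = np.random.default_rng(seed)
    logp_cols = {}
    for (micelle, solvent), (slope, intercept) in calibration.items():
        if slope == 0:
            raise ValueError(f"({micelle}, {solvent}): slope must be nonzero")
        y = truth[micelle].astype(float)
        if residual_sd == 0:
            logp_cols[solvent] = (y - intercept) / slope
            continue
        var_y = float(np.var(y.dropna(), ddof=0))
        if residual_sd**2 >= var_y:
            raise ValueError(
                f"({micelle}, {solvent}): residual_sd^2 = {residual_sd**2:.3g} must be "
                f"smaller than var(truth logP) = {var_y:.3g}"
            )
        mu_y = float(np.mean(y.dropna()))
        c = (1.0 - residual_sd**2 / var_y) / slope
        tau = np.sqrt(c * var_y * (1.0 - slope * c) / slope)
        x_mu = (mu_y - intercept) / slope
        logp_cols[solvent] = c * (y - mu_y) + x_mu + rng.normal(0.0, tau, size=len(y))
    logp = pd.DataFrame(logp_cols, index=truth.index)
    dg_water = pd.Series(
        rng.uniform(*dg_water_range, size=len(truth)), index=truth.index, name="water"
    )
    return solvation_from_logp(logp, dg_water, constants)


def simulate_descriptors(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Descriptor matrix of Gaussian blobs plus the hidden truth labels.

    Blob centres are drawn on a sphere of radius ``separation`` (in
    within-blob sd units, sd = 1) around the origin, so the pairwise
    centre distances are of order the stated separation.
    """
    blob = spec.blob_spec
    if sum(blob.sizes) != spec.n_compounds:
        raise ValueError(
            f"blob sizes {blob.sizes} sum to {sum(blob.sizes)}, "
            f"but n_compounds = {spec.n_compounds}"
        )
    rng = np.random.default_rng(spec.seed)
    k, p = len(blob.sizes), blob.dimension
    directions = rng.normal(size=(k, p))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    centers = blob.separation * directions
    rows, labels = [], []
    for j, size in enumerate(blob.sizes):
        rows.append(centers[j] + rng.normal(size=(size, p)))
        labels.extend([j + 1] * size)
    matrix = pd.DataFrame(
        np.vstack(rows),
        index=_compound_names(spec.n_compounds),
        columns=[f"d{i + 1:03d}" for i in range(p)],
    )
    matrix.index.name = "compound"
    truth = pd.Series(labels, index=matrix.index, name="cluster")
    return matrix, truth
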