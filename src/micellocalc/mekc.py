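"""The MEKC retention model.

In micellar electrokinetic chromatography a neutral analyte migrates
between the electro-osmotic-flow marker (time ``t_0``, fully aqueous) and
the micellar marker (time ``t_m``, fully micelle-bound).  Its retention
factor is

    k = (t_R - t_0) / (t_0 * (1 - t_R / t_m))

and k is tied to the micelle-water partition coefficient P through the
phase ratio phi = v * (C_T - CMC) of the surfactant system:

    k = P * phi / (1 - phi)        i.e.   logP = log10 k + log10((1-phi)/phi)

Both directions are implemented: forward (measured times -> logP) for
analysis, inverse (logP -> times) for simulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import MicelleSystem

__all__ = [
    "RetentionRecord",
    "retention_factor",
    "logp_from_retention",
    "retention_factor_from_logp",
    "retention_time_from_factor",
    "convert_table",
]

logger = logging.getLogger(__name__)


class RetentionDomainError(ValueError):
    """Retention times outside the physically meaningful window."""


@dataclass(frozen=True)
class RetentionRecord:
    """One electropherogram measurement: analyte and marker times, in minutes."""

    compound: str
    system: str
    t_r: float
    t_0: float
    t_m: float

    def __post_init__(self) -> None:
        if not self.t_0 > 0:
            raise RetentionDomainError(f"t_0 must be positive, got {self.t_0}")
        if not self.t_0 < self.t_m:
            raise RetentionDomainError(f"need t_0 < t_m, got t_0={self.t_0}, t_m={self.t_m}")


def retention_factor(rec: RetentionRecord) -> float:
    """Retention factor k from (t_R, t_0, t_m).

    k = 0 when the analyte co-migrates with the EOF marker; k diverges as
    t_R approaches the micellar marker, so t_R >= t_m is a domain error.
    """
    if rec.t_r < rec.t_0:
        raise RetentionDomainError(
            f"{rec.compound}: t_r={rec.t_r} precedes EOF marker t_0={rec.t_0}"
        )
    if rec.t_r >= rec.t_m:
        raise RetentionDomainError(
            f"{rec.compound}: analyte co-elutes with or after micellar marker "
            f"(t_r={rec.t_r}, t_m={rec.t_m})"
        )
    return (rec.t_r - rec.t_0) / (rec.t_0 * (1.0 - rec.t_r / rec.t_m))


def logp_from_retention(k: float, system: MicelleSystem) -> float:
    """Micelle-water logP from a retention factor.

    logP = log10(k) + log10((1 - phi) / phi) with phi the phase ratio.
    """
    if k <= 0:
        raise RetentionDomainError(f"retention factor must be positive, got {k}")
    phi = system.phase_ratio
    return float(np.log10(k) + np.log10((1.0 - phi) / phi))


def retention_factor_from_logp(logp: float, system: MicelleSystem) -> float:
    """Exact inverse of :func:`logp_from_retention`: k = 10**logP * phi/(1-phi)."""
    phi = system.phase_ratio
    return float(10.0**logp * phi / (1.0 - phi))


def retention_time_from_factor(k: float, t_0: float, t_m: float) -> float:
    """Analyte migration time implied by retention factor k and the markers.

    t_R = t_0 (1 + k) / (1 + k t_0 / t_m); lies in [t_0, t_m) for k >= 0 and
    approaches t_m from below as k grows.
    """
    if k < 0:
        raise RetentionDomainError(f"retention factor must be >= 0, got {k}")
    if not 0 < t_0 < t_m:
        raise RetentionDomainError(f"need 0 < t_0 < t_m, got t_0={t_0}, t_m={t_m}")
    return t_0 * (1.0 + k) / (1.0 + k * t_0 / t_m)


def convert_table(
    records: list[RetentionRecord] | pd.DataFrame,
    registry: dict[str, MicelleSystem],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert retention records to a compounds x systems logP table.

    Replicates of the same (compound, system) pair are averaged on the logP
    scale; the second returned table holds the replicate standard deviation
    (ddof=1; NaN for a single replicate).  Records whose analyte time sits at
    a boundary (t_r = t_0, giving k = 0, or t_r >= t_m) produce a missing
    entry with a logged warning rather than aborting the batch.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            RetentionRecord(
                str(r["compound"]), str(r["system"]),
                float(r["t_r"]), float(r["t_0"]), float(r["t_m"]),
            )
            for _, r in records.iterrows()
        ]
    values: dict[tuple[str, str], list[float]] = {}
    order_c: list[str] = []
    order_s: list[str] = []
    for rec in records:
        if rec.system not in registry:
            raise KeyError(f"unknown micellar system {rec.system!r}")
        if rec.compound not in order_c:
            order_c.append(rec.compound)
        if rec.system not in order_s:
            order_s.append(rec.system)
        key = (rec.compound, rec.system)
        try:
            k = retention_factor(rec)
            if k == 0.0:
                raise RetentionDomainError("k = 0 (analyte at EOF marker)")
            logp = logp_from_retention(k, registry[rec.system])
        except RetentionDomainError as err:
            warnings.warn(
                f"dropping record ({rec.compound}, {rec.system}): {err}",
                stacklevel=2,
            )
            values.setdefault(key, [])
            continue
        values.setdefault(key, []).append(logp)

    mean = pd.DataFrame(np.nan, index=order_c, columns=order_s)
    sd = pd.DataFrame(np.nan, index=order_c, columns=order_s)
    mean.index.name = sd.index.name = "compound"
    for (comp, sys_name), logps in values.items():
        if logps:
            mean.loc[comp, sys_name] = float(np.mean(logps))
            if len(logps) > 1:
                sd.loc[comp, sys_name] = float(np.std(logps, ddof=1))
    return mean, sd
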