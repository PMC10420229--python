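"""End-to-end analysis: experimental table -> correlations -> filter ->
calibrations -> clustering / PCA / SVM, driven by a single config.

Every random operation's seed is explicit in the config echo written to the
run manifest, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compounds import (
    bundled_compounds,
    bundled_partition_table,
    bundled_reference_calibrations,
    load_compound_table,
    load_partition_table,
    micelle_registry,
)
from .matching import calibrate_all, correlation_matrix, nset_filter
from .ml import (
    cluster_profile,
    descriptor_extremes,
    kmeans_cluster,
    pca,
    rdkit_descriptor_matrix,
    standardize,
    svm_regress,
)
from .simulate import simulate_solvation
from .solvation import PhysicalConstants, load_solvation_table, logp_matrix

__all__ = ["RunConfig", "run_full_analysis", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Configuration for a full analysis run.

    ``compounds``/``partition`` default to the bundled experimental data.
    ``solvation`` is a path to a solvation-energy CSV or the literal string
    ``"simulate"`` to generate a panel from the planted reference
    calibrations (useful for smoke runs and for exercising the pipeline
    without quantum-chemistry output).
    """

    output_dir: str = "micellocalc_out"
    seed: int = 0
    temperature: float = 298.15
    compounds: str | None = None
    partition: str | None = None
    solvation: str | None = "simulate"
    residual_sd: float = 0.5
    registry_overrides: dict = field(default_factory=dict)
    min_pairs: int = 5
    apply_filter: bool = True
    k_clusters: int = 3
    n_restarts: int = 25
    pca_components: int = 3
    svm_micelles: tuple[str, ...] = ("SC", "LPFOS", "HTAB")
    svm_test_fraction: float = 0.15
    svm_folds: int = 10
    descriptors: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"[config] unknown config key(s): {sorted(unknown)}")
        if "svm_micelles" in raw:
            raw["svm_micelles"] = tuple(raw["svm_micelles"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"[{name}] {err}") from err
        return wrapper
    return deco


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``cfg.output_dir``.

    Returns the manifest dictionary.  On stage failure the manifest is still
    written with ``"complete": false`` and the failing stage recorded, then
    the error re-raised.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "micellocalc",
        "version": __version__,
        "config": asdict(cfg),
        "complete": False,
        "outputs": [],
    }

    def emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, **kwargs)
        manifest["outputs"].append(name)

    try:
        constants = PhysicalConstants(temperature=cfg.temperature)
        registry = micelle_registry(cfg.registry_overrides or None)

        compounds = _load_compounds(cfg)
        experimental = _load_partition(cfg)
        manifest["n_compounds"] = len(compounds)
        manifest["n_measured"] = int(experimental.notna().sum().sum())

        computed = _computed_logp(cfg, experimental, constants)
        emit(computed, "computed_logp.csv")

        cm_all = _correlations(experimental, computed, cfg.min_pairs)
        emit(cm_all.r, "correlation_all.csv")
        emit(cm_all.n_pairs, "correlation_all_npairs.csv")

        fr = _filter(compounds)
        emit(fr.report(), "filter_report.csv")
        manifest["n_excluded"] = len(fr.excluded)
        if cfg.apply_filter:
            kept = fr.retained.names
            cm_f = _correlations(
                experimental.loc[experimental.index.intersection(kept)],
                computed.loc[computed.index.intersection(kept)],
                cfg.min_pairs,
            )
            emit(cm_f.r, "correlation_filtered.csv")

        cal = _calibrations(experimental, computed)
        emit(cal, "calibrations.csv", index=False)
        emit(bundled_reference_calibrations(), "reference_calibrations.csv", index=False)

        dm = _descriptors(cfg, compounds)
        z = standardize(dm)
        emit(dm, "descriptors.csv")
        cr = kmeans_cluster(z, k=cfg.k_clusters, seed=cfg.seed, n_restarts=cfg.n_restarts)
        emit(cr.labels.to_frame(), "clusters.csv")
        profile = cluster_profile(cr, z)
        emit(profile, "cluster_profile.csv")
        emit(descriptor_extremes(profile), "cluster_extremes.csv")
        manifest["cluster_sizes"] = cr.sizes.tolist()

        pr = pca(z, m=cfg.pca_components)
        emit(pr.loadings, "pca_loadings.csv")
        emit(pr.scores, "pca_scores.csv")
        ratios = pd.DataFrame(
            {"explained_variance_ratio": pr.explained_variance_ratio},
            index=pd.RangeIndex(1, len(pr.explained_variance_ratio) + 1, name="component"),
        )
        emit(ratios, "pca_variance.csv")
        manifest["pca_top3_variance"] = float(pr.explained_variance_ratio[: cfg.pca_components].sum())

        svm_rows = []
        for micelle in cfg.svm_micelles:
            if micelle not in experimental.columns:
                continue
            rep = _svm(dm, experimental[micelle], micelle, cfg)
            svm_rows.append(
                {
                    "micelle": rep.micelle, "r2_test": rep.r2_test,
                    "rmse_test": rep.rmse_test, "mae_test": rep.mae_test,
                    "n_train": rep.n_train, "n_test": rep.n_test,
                    "best_hyperparameters": json.dumps(rep.best_hyperparameters),
                }
            )
        emit(pd.DataFrame(svm_rows), "svm_report.csv", index=False)

        manifest["complete"] = True
    except Exception as err:
        manifest["error"] = str(err)
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@_stage("compounds")
def _load_compounds(cfg: RunConfig):
    return load_compound_table(cfg.compounds) if cfg.compounds else bundled_compounds()


@_stage("partition")
def _load_partition(cfg: RunConfig):
    return load_partition_table(cfg.partition) if cfg.partition else bundled_partition_table()


@_stage("solvation")
def _computed_logp(cfg: RunConfig, experimental: pd.DataFrame, constants: PhysicalConstants):
    if cfg.solvation == "simulate":
        ref = bundled_reference_calibrations()
        ref = ref[ref["filter"] == "all"]
        calibration = {
            (row["micelle"], row["solvent"]): (row["slope"], row["intercept"])
            for _, row in ref.iterrows()
            if row["micelle"] in experimental.columns
        }
        # one planted calibration per solvent suffices for generation
        per_solvent = {}
        for (mic, sol), ab in calibration.items():
            per_solvent.setdefault(sol, ((mic, sol), ab))
        calibration = {key: ab for key, ab in per_solvent.values()}
        truth = experimental.dropna()
        solvation = simulate_solvation(
            truth, calibration, residual_sd=cfg.residual_sd,
            constants=constants, seed=cfg.seed,
        )
    elif cfg.solvation:
        solvation = load_solvation_table(cfg.solvation)
    else:
        raise PipelineError("[solvation] no solvation input configured")
    return logp_matrix(solvation, constants)


@_stage("correlation")
def _correlations(experimental, computed, min_pairs):
    return correlation_matrix(experimental, computed, min_pairs=min_pairs)


@_stage("filter")
def _filter(compounds):
    return nset_filter(compounds)


@_stage("calibration")
def _calibrations(experimental, computed):
    return calibrate_all(experimental, computed)


@_stage("descriptors")
def _descriptors(cfg: RunConfig, compounds):
    if cfg.descriptors:
        df = pd.read_csv(cfg.descriptors, index_col=0)
        return df.astype(float)
    return rdkit_descriptor_matrix(compounds)


@_stage("svm")
def _svm(dm, y, micelle, cfg: RunConfig):
    return svm_regress(
        dm, y, micelle=micelle, seed=cfg.seed,
        test_fraction=cfg.svm_test_fraction, cv_folds=cfg.svm_folds,
    )
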