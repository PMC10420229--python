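"""Descriptor-space analysis: standardization, k-means, PCA, SVM regression.

The workflow operates on any compounds x descriptors matrix (a pandas
DataFrame indexed by compound name).  Columns are z-transformed before
clustering and PCA so that descriptors with large numeric ranges do not
dominate the Euclidean geometry; PCA follows the correlation-matrix
convention (total variance = number of descriptors).

A descriptor generator built on RDKit is provided (constitutional counts,
topological indices, and the VSA descriptor families that sum van der Waals
surface-area contributions binned by an atomic property).  Any external
descriptor CSV with the same layout is accepted interchangeably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .compounds import CompoundSet

__all__ = [
    "ClusterResult",
    "PCAResult",
    "SVMReport",
    "standardize",
    "kmeans_cluster",
    "pca",
    "cluster_profile",
    "descriptor_extremes",
    "svm_regress",
    "rdkit_descriptor_matrix",
    "DEFAULT_SVM_GRID",
]


class DegenerateInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


def standardize(dm: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-transform: mean 0, sample (ddof=1) standard deviation 1.

    Zero-variance columns carry no information for a correlation-convention
    analysis and are dropped with a warning; if every column is constant the
    input is degenerate.
    """
    values = dm.astype(float)
    sd = values.std(ddof=1)
    constant = sd == 0.0
    if constant.all():
        raise DegenerateInputError("all descriptor columns are constant")
    if constant.any():
        dropped = list(values.columns[constant])
        warnings.warn(f"dropping {len(dropped)} zero-variance column(s): {dropped[:5]}...")
        values = values.loc[:, ~constant]
        sd = sd[~constant]
    return (values - values.mean()) / sd


@dataclass
class ClusterResult:
    """k-means partition: labels in 1..k, centroids in standardized space."""

    labels: pd.Series
    centroids: pd.DataFrame
    within_ss: float
    sizes: pd.Series


def kmeans_cluster(
    dm: pd.DataFrame, k: int, seed: int, n_restarts: int = 25
) -> ClusterResult:
    """Partition compounds into k groups minimising within-cluster squared
    Euclidean distance, best of ``n_restarts`` k-means++ initialisations.

    Deterministic given (data, k, seed, n_restarts).  Expects a standardized
    matrix; cluster indices are 1-based and sorted by decreasing size so the
    labelling is stable across runs.
    """
    n = len(dm)
    if k > n:
        raise ValueError(f"k={k} exceeds number of compounds n={n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(dm.values)
    # relabel clusters by decreasing size (ties: by first occurrence)
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], list(raw).index(c)))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=dm.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=dm.columns,
    )
    sizes = labels.value_counts().sort_index()
    return ClusterResult(labels=labels, centroids=centroids,
                         within_ss=float(km.inertia_), sizes=sizes)


@dataclass
class PCAResult:
    """Principal components of a standardized descriptor matrix.

    ``explained_variance_ratio`` covers all computable components (its sum
    is 1); ``loadings`` (descriptors x m) and ``scores`` (compounds x m) are
    truncated to the m requested components.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_components = self.loadings.shape[1]


def pca(dm: pd.DataFrame, m: int) -> PCAResult:
    """PCA on a standardized matrix — eigendecomposition of the correlation
    matrix, components ordered by decreasing eigenvalue."""
    n, p = dm.shape
    max_m = min(n, p)
    if not 1 <= m <= max_m:
        raise ValueError(f"m must be in [1, {max_m}], got {m}")
    model = PCA(n_components=max_m, svd_solver="full")
    scores_full = model.fit_transform(dm.values)
    comp_names = [f"PC{i + 1}" for i in range(m)]
    loadings = pd.DataFrame(model.components_[:m].T, index=dm.columns, columns=comp_names)
    scores = pd.DataFrame(scores_full[:, :m], index=dm.index, columns=comp_names)
    return PCAResult(loadings=loadings, scores=scores,
                     explained_variance_ratio=model.explained_variance_ratio_)


def cluster_profile(cr: ClusterResult, dm: pd.DataFrame) -> pd.DataFrame:
    """Within-cluster descriptor means (k x p, standardized units).

    Because columns of a standardized matrix average to zero, the
    size-weighted average of profile rows is the zero vector — each cluster's
    profile shows how it deviates from the pooled compound population.
    """
    if not cr.labels.index.equals(dm.index):
        raise ValueError("cluster labels do not align with descriptor matrix rows")
    return dm.groupby(cr.labels).mean()


def descriptor_extremes(profile: pd.DataFrame) -> pd.DataFrame:
    """For each descriptor, which cluster sits highest and lowest.

    This is the reading used to characterise clusters ("maximal levels for
    descriptors X, Y" etc.) from a profile matrix.
    """
    return pd.DataFrame(
        {"max_cluster": profile.idxmax(), "min_cluster": profile.idxmin()}
    )


DEFAULT_SVM_GRID = {
    "C": [0.1, 1.0, 10.0, 100.0],
    "epsilon": [0.01, 0.1, 0.5],
    "gamma_scale_factor": [0.1, 1.0, 10.0],
}


@dataclass
class SVMReport:
    """Held-out evaluation of an SVM regression on selected descriptors.

    Metrics are computed exclusively on compounds never seen during training
    or hyperparameter search.
    """

    micelle: str
    selected_descriptors: list[str]
    best_hyperparameters: dict
    r2_test: float
    rmse_test: float
    mae_test: float
    n_train: int
    n_test: int
    test_compounds: list[str]


def svm_regress(
    dm: pd.DataFrame,
    y: pd.Series,
    selected: list[str] | None = None,
    seed: int = 0,
    micelle: str = "",
    test_fraction: float = 0.15,
    cv_folds: int = 10,
    grid: dict | None = None,
) -> SVMReport:
    """RBF-kernel support-vector regression with seeded split and grid search.

    The complete rows are split into training (1 - ``test_fraction``) and
    test sets by a seeded shuffle; hyperparameters (C, epsilon, gamma) are
    chosen by ``cv_folds``-fold cross-validated grid search on the training
    split only, with features standardized using training statistics.  The
    gamma grid is expressed as multiples of the scale heuristic
    1 / (p * var(X_train_scaled)).

    Rows are ordered by compound name before the shuffle, so the split —
    and hence every reported metric — depends only on the set of compounds
    and the seed, not on input row order.
    """
    selected = list(selected) if selected is not None else list(dm.columns)
    unknown = set(selected) - set(dm.columns)
    if unknown:
        raise KeyError(f"selected descriptors not in matrix: {sorted(unknown)}")
    data = dm.loc[:, selected].join(y.rename("__y__"), how="inner").dropna()
    data = data.sort_index()
    if len(data) < 20:
        raise InsufficientDataError(f"need >= 20 complete rows, got {len(data)}")

    X = data[selected].values
    yv = data["__y__"].values
    idx_train, idx_test = train_test_split(
        np.arange(len(data)), test_size=test_fraction, random_state=seed, shuffle=True
    )
    scaler = StandardScaler().fit(X[idx_train])
    Xtr = scaler.transform(X[idx_train])
    Xte = scaler.transform(X[idx_test])

    grid = dict(grid or DEFAULT_SVM_GRID)
    scale_gamma = 1.0 / (Xtr.shape[1] * Xtr.var()) if Xtr.var() > 0 else 1.0
    param_grid = {
        "C": grid.get("C", DEFAULT_SVM_GRID["C"]),
        "epsilon": grid.get("epsilon", DEFAULT_SVM_GRID["epsilon"]),
        "gamma": [f * scale_gamma for f in grid.get("gamma_scale_factor", [1.0])],
    }
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(SVR(kernel="rbf"), param_grid, cv=cv, scoring="neg_mean_squared_error")
    search.fit(Xtr, yv[idx_train])
    pred = search.best_estimator_.predict(Xte)
    return SVMReport(
        micelle=micelle,
        selected_descriptors=selected,
        best_hyperparameters=dict(search.best_params_),
        r2_test=float(r2_score(yv[idx_test], pred)),
        rmse_test=float(np.sqrt(mean_squared_error(yv[idx_test], pred))),
        mae_test=float(mean_absolute_error(yv[idx_test], pred)),
        n_train=len(idx_train),
        n_test=len(idx_test),
        test_compounds=list(data.index[idx_test]),
    )


def rdkit_descriptor_matrix(compounds: CompoundSet) -> pd.DataFrame:
    """Open descriptor set: constitutional counts, topological indices, and
    the VSA families (surface-area sums binned by logP contribution, molar
    refractivity, or partial charge).

    A stand-in descriptor space for workflows whose original descriptors
    came from commercial software; the analysis methods accept any matrix
    with the same compounds x descriptors layout.
    """
    rows = {}
    for compound in compounds:
        mol = compound.mol
        desc: dict[str, float] = {
            "MolWt": Descriptors.MolWt(mol),
            "HeavyAtomCount": Descriptors.HeavyAtomCount(mol),
            "RingCount": rdMolDescriptors.CalcNumRings(mol),
            "AromaticRings": rdMolDescriptors.CalcNumAromaticRings(mol),
            "RotatableBonds": Lipinski.NumRotatableBonds(mol),
            "HBondDonors": Lipinski.NumHDonors(mol),
            "HBondAcceptors": Lipinski.NumHAcceptors(mol),
            "TPSA": rdMolDescriptors.CalcTPSA(mol),
            "MolLogP": Crippen.MolLogP(mol),
            "MolMR": Crippen.MolMR(mol),
            "FractionCSP3": rdMolDescriptors.CalcFractionCSP3(mol),
            "Chi0v": rdMolDescriptors.CalcChi0v(mol),
            "Chi1v": rdMolDescriptors.CalcChi1v(mol),
            "Chi2v": rdMolDescriptors.CalcChi2v(mol),
            "Chi3v": rdMolDescriptors.CalcChi3v(mol),
            "Kappa1": rdMolDescriptors.CalcKappa1(mol),
            "Kappa2": rdMolDescriptors.CalcKappa2(mol),
            "HallKierAlpha": rdMolDescriptors.CalcHallKierAlpha(mol),
            "BalabanJ": Descriptors.BalabanJ(mol),
            "BertzCT": Descriptors.BertzCT(mol),
            "LabuteASA": rdMolDescriptors.CalcLabuteASA(mol),
        }
        for name, count in _element_fractions(mol).items():
            desc[name] = count
        for i, v in enumerate(rdMolDescriptors.SlogP_VSA_(mol), start=1):
            desc[f"SlogP_VSA{i}"] = v
        for i, v in enumerate(rdMolDescriptors.SMR_VSA_(mol), start=1):
            desc[f"SMR_VSA{i}"] = v
        for i, v in enumerate(rdMolDescriptors.PEOE_VSA_(mol), start=1):
            desc[f"PEOE_VSA{i}"] = v
        rows[compound.name] = desc
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "compound"
    return out


def _element_fractions(mol) -> dict[str, float]:
    """Percent of heavy atoms that are C, N, O, halogen (constitutional)."""
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    n_heavy = max(len(symbols), 1)
    halogens = {"F", "Cl", "Br", "I"}
    return {
        "C_pct": 100.0 * sum(s == "C" for s in symbols) / n_heavy,
        "N_pct": 100.0 * sum(s == "N" for s in symbols) / n_heavy,
        "O_pct": 100.0 * sum(s == "O" for s in symbols) / n_heavy,
        "Hal_pct": 100.0 * sum(s in halogens for s in symbols) / n_heavy,
    }
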