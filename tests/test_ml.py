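"""Standardization, k-means, PCA, cluster profiles, SVM regression."""

import numpy as np
import pandas as pd
import pytest

from micellocalc import (
    BlobSpec,
    SyntheticSpec,
    cluster_profile,
    descriptor_extremes,
    kmeans_cluster,
    pca,
    rdkit_descriptor_matrix,
    simulate_descriptors,
    standardize,
    svm_regress,
)
from micellocalc.ml import DegenerateInputError, InsufficientDataError


def frame(values, prefix="d"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"c{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


@pytest.fixture(scope="module")
def blobs():
    spec = SyntheticSpec(n_compounds=63, seed=9, blob_spec=BlobSpec((45, 13, 5), 10.0, 85))
    return simulate_descriptors(spec)


class TestStandardize:
    def test_column_123(self):
        z = standardize(frame([[1.0], [2.0], [3.0]]))
        assert np.allclose(z.values.ravel(), [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one_and_idempotence(self):
        rng = np.random.default_rng(2)
        z = standardize(frame(rng.normal(3, 7, size=(50, 4))))
        assert np.all(np.abs(z.mean().values) < 1e-12)
        assert np.allclose(z.std(ddof=1).values, 1.0)
        assert np.allclose(standardize(z).values, z.values, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        data = frame(np.column_stack([np.arange(5.0), np.ones(5)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            z = standardize(data)
        assert list(z.columns) == ["d0"]

    def test_all_constant_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            standardize(frame(np.ones((5, 3))))


class TestKMeans:
    def test_single_cluster_within_ss_is_total_ss(self):
        rng = np.random.default_rng(4)
        z = standardize(frame(rng.normal(size=(30, 5))))
        result = kmeans_cluster(z, k=1, seed=0)
        total_ss = float(((z - z.mean()) ** 2).sum().sum())
        assert result.within_ss == pytest.approx(total_ss)
        assert result.sizes.tolist() == [30]

    def test_planted_blobs_recovered(self, blobs):
        dm, truth = blobs
        result = kmeans_cluster(standardize(dm), k=3, seed=0)
        assert sorted(result.sizes.tolist()) == sorted(truth.value_counts().tolist())
        # exact recovery up to label permutation
        joint = pd.crosstab(result.labels, truth)
        assert (joint.values > 0).sum() == 3

    def test_each_point_own_cluster_gives_zero_within_ss(self):
        rng = np.random.default_rng(6)
        z = standardize(frame(rng.normal(size=(6, 3))))
        assert kmeans_cluster(z, k=6, seed=0).within_ss == pytest.approx(0.0, abs=1e-20)

    def test_k_exceeding_n_rejected(self):
        z = standardize(frame(np.random.default_rng(0).normal(size=(4, 2))))
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(z, k=5, seed=0)

    def test_within_ss_nonincreasing_in_k(self, blobs):
        dm, _ = blobs
        z = standardize(dm)
        ws = [kmeans_cluster(z, k=k, seed=0).within_ss for k in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(ws, ws[1:]))

    def test_deterministic_given_seed(self, blobs):
        dm, _ = blobs
        z = standardize(dm)
        a = kmeans_cluster(z, k=3, seed=7)
        b = kmeans_cluster(z, k=3, seed=7)
        assert a.labels.equals(b.labels)
        assert a.within_ss == b.within_ss


class TestPCA:
    def test_collinear_columns_give_single_component(self):
        x = np.arange(20, dtype=float)
        z = standardize(frame(np.column_stack([x, 2 * x])))
        result = pca(z, m=1)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one_and_nonincreasing(self, blobs):
        dm, _ = blobs
        result = pca(standardize(dm), m=3)
        ratios = result.explained_variance_ratio
        assert ratios.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(ratios) <= 1e-12)

    def test_loadings_orthonormal(self, blobs):
        dm, _ = blobs
        L = pca(standardize(dm), m=3).loadings.values
        assert np.allclose(L.T @ L, np.eye(3), atol=1e-10)

    def test_identity_covariance_ratios_near_uniform(self):
        rng = np.random.default_rng(8)
        p = 5
        z = standardize(frame(rng.normal(size=(20_000, p))))
        ratios = pca(z, m=p).explained_variance_ratio
        assert np.allclose(ratios, 1.0 / p, atol=0.01)

    def test_out_of_range_m_rejected(self):
        z = standardize(frame(np.random.default_rng(0).normal(size=(10, 4))))
        with pytest.raises(ValueError):
            pca(z, m=5)


class TestClusterProfile:
    def test_single_cluster_profile_is_zero(self):
        rng = np.random.default_rng(10)
        z = standardize(frame(rng.normal(size=(15, 4))))
        result = kmeans_cluster(z, k=1, seed=0)
        profile = cluster_profile(result, z)
        assert np.allclose(profile.values, 0.0, atol=1e-12)

    def test_size_weighted_profile_average_is_zero(self, blobs):
        dm, _ = blobs
        z = standardize(dm)
        result = kmeans_cluster(z, k=3, seed=0)
        profile = cluster_profile(result, z)
        weighted = (profile.values * result.sizes.values[:, None]).sum(axis=0) / len(z)
        assert np.allclose(weighted, 0.0, atol=1e-10)

    def test_profiles_near_blob_centers(self, blobs):
        dm, truth = blobs
        result = kmeans_cluster(standardize(dm), k=3, seed=0)
        profile = cluster_profile(result, standardize(dm))
        true_profile = standardize(dm).groupby(truth).mean()
        # same partition -> same means, whatever the label permutation
        got = np.sort(profile.values, axis=0)
        want = np.sort(true_profile.values, axis=0)
        assert np.allclose(got, want, atol=1e-8)

    def test_extremes_report(self, blobs):
        dm, _ = blobs
        z = standardize(dm)
        profile = cluster_profile(kmeans_cluster(z, k=3, seed=0), z)
        ext = descriptor_extremes(profile)
        assert set(ext.columns) == {"max_cluster", "min_cluster"}
        assert (ext["max_cluster"] != ext["min_cluster"]).all()


class TestSVM:
    def test_noiseless_linear_response_recovered(self):
        rng = np.random.default_rng(12)
        dm = frame(rng.normal(size=(80, 6)))
        y = pd.Series(2.0 * dm["d2"].values + 1.0, index=dm.index)
        report = svm_regress(dm, y, selected=["d2"], seed=0)
        assert report.r2_test >= 0.99

    def test_metrics_only_on_held_out_split(self):
        rng = np.random.default_rng(13)
        dm = frame(rng.normal(size=(40, 3)))
        y = pd.Series(dm["d0"].values + 0.1 * rng.normal(size=40), index=dm.index)
        report = svm_regress(dm, y, seed=1)
        assert report.n_test == 6  # 15% of 40
        assert report.n_train + report.n_test == 40
        assert len(report.test_compounds) == report.n_test

    def test_row_order_invariance(self):
        rng = np.random.default_rng(14)
        dm = frame(rng.normal(size=(30, 4)))
        y = pd.Series(dm["d1"].values + 0.2 * rng.normal(size=30), index=dm.index)
        a = svm_regress(dm, y, seed=3)
        perm = rng.permutation(len(dm))
        b = svm_regress(dm.iloc[perm], y.iloc[perm], seed=3)
        assert a.r2_test == b.r2_test
        assert a.test_compounds == b.test_compounds

    def test_too_few_rows_rejected(self):
        dm = frame(np.random.default_rng(0).normal(size=(10, 2)))
        y = pd.Series(np.arange(10.0), index=dm.index)
        with pytest.raises(InsufficientDataError):
            svm_regress(dm, y, seed=0)

    def test_unknown_descriptor_rejected(self):
        dm = frame(np.random.default_rng(0).normal(size=(25, 2)))
        y = pd.Series(np.arange(25.0), index=dm.index)
        with pytest.raises(KeyError):
            svm_regress(dm, y, selected=["nope"], seed=0)


class TestDescriptorGenerator:
    def test_bundled_compounds_descriptor_matrix(self, compounds):
        dm = rdkit_descriptor_matrix(compounds)
        assert dm.shape[0] == 63
        assert dm.shape[1] >= 40
        assert dm.notna().all().all()
        assert dm.loc["Phenol", "HeavyAtomCount"] == 7
        assert dm.loc["Pyrimidine", "N_pct"] == pytest.approx(100.0 * 2 / 6)
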