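"""Correlation structure, the aromatic-N/urea filter, and calibrations."""

import numpy as np
import pandas as pd
import pytest

from micellocalc import (
    CompoundSet,
    correlation_matrix,
    fit_calibration,
    best_micelle,
    nset_filter,
    predict_micellar_logp,
    rank_surrogates,
)
from micellocalc.compounds import Compound
from micellocalc.matching import DegenerateFitError, InsufficientDataError

from conftest import pearson_oracle


def table(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"c{i}" for i in range(n)])


class TestCorrelationMatrix:
    def test_self_correlation_and_affine_invariance(self):
        x = np.arange(10, dtype=float)
        cm = correlation_matrix(table(a=x), table(b=2 * x + 1, c=-x))
        assert cm.r.loc["a", "a"] == 1.0
        assert cm.r.loc["a", "b"] == pytest.approx(1.0)
        assert cm.r.loc["a", "c"] == pytest.approx(-1.0)
        assert cm.experimental == ["a"]

    def test_pairwise_complete_matches_oracle_on_fixture(self, experimental_table):
        cm = correlation_matrix(experimental_table)
        for a in experimental_table.columns:
            for b in experimental_table.columns:
                expected = pearson_oracle(
                    experimental_table[a].values, experimental_table[b].values
                )
                assert cm.r.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_n_pairs_counts_joint_observations(self, experimental_table):
        cm = correlation_matrix(experimental_table)
        assert cm.n_pairs.loc["SC", "SC"] == 63
        assert cm.n_pairs.loc["SC", "HTAB"] == 58  # five missing HTAB entries

    def test_min_pairs_masks_sparse_cells(self):
        a = pd.Series([1.0, 2.0, 3.0, np.nan, np.nan], index=list("vwxyz"))
        b = pd.Series([np.nan, np.nan, 1.0, 2.0, 3.0], index=list("vwxyz"))
        cm = correlation_matrix(a.to_frame("a"), b.to_frame("b"), min_pairs=2)
        assert np.isnan(cm.r.loc["a", "b"])  # only one joint observation

    def test_zero_variance_column_warns_and_is_missing(self):
        with pytest.warns(UserWarning, match="zero variance"):
            cm = correlation_matrix(table(a=np.arange(5.0)), table(b=np.ones(5)))
        assert np.isnan(cm.r.loc["a", "b"])

    def test_symmetry(self, experimental_table):
        cm = correlation_matrix(experimental_table)
        assert np.allclose(cm.r.values, cm.r.values.T, equal_nan=True)


PANEL_EXCLUDED = {
    "Pyrimidine": "aromatic-N",
    "Pyrrole": "aromatic-N",
    "Quinoline": "aromatic-N",
    "Caffeine": "aromatic-N",
    "Atrazine": "aromatic-N",
    "Propazine": "aromatic-N",
    "Diuron": "urea",
    "Isoproturon": "urea",
    "Linuron": "urea",
    "Metobromuron": "urea",
    "Monuron": "urea",
    "Metoxuron": "urea",
    "Phenylurea": "urea",
    "Fluometuron": "urea",
}
PANEL_RETAINED = [
    "Aniline",
    "Benzamide",
    "N-Phenylacetamide",
    "2-Nitroaniline",
    "3-Nitroaniline",
    "4-Nitroaniline",
]


class TestNsetFilter:
    def test_hand_labeled_panel(self, compounds):
        result = nset_filter(compounds)
        excluded = {c.name for c in result.excluded}
        assert excluded == set(PANEL_EXCLUDED)
        for name, reason in PANEL_EXCLUDED.items():
            assert reason in result.reasons[name]
        for name in PANEL_RETAINED:
            assert name in result.retained

    def test_partition_is_exact_and_disjoint(self, compounds):
        result = nset_filter(compounds)
        names = {c.name for c in result.retained} | {c.name for c in result.excluded}
        assert names == set(compounds.names)
        assert len(result.retained) + len(result.excluded) == len(compounds)

    def test_idempotent(self, compounds):
        once = nset_filter(compounds)
        twice = nset_filter(once.retained)
        assert len(twice.excluded) == 0
        assert twice.retained.names == once.retained.names

    def test_exocyclic_nitrogen_not_excluded(self):
        cs = CompoundSet(
            [Compound("aniline", "Nc1ccccc1"), Compound("benzamide", "NC(=O)c1ccccc1")]
        )
        result = nset_filter(cs)
        assert len(result.excluded) == 0


class TestCalibration:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 5, 10)
        m = fit_calibration(x, 0.5 * x + 1.0)
        assert m.slope == pytest.approx(0.5)
        assert m.intercept == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)
        assert m.mae == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(m.mse), abs=1e-12)

    def test_constant_response(self):
        m = fit_calibration(np.arange(5.0), np.full(5, 2.0))
        assert m.slope == 0.0
        assert m.r2 == 0.0

    def test_two_point_closed_form(self):
        m = fit_calibration(np.array([1.0, 3.0]), np.array([2.0, 8.0]), min_n=2)
        assert m.slope == pytest.approx(3.0)  # dy/dx
        assert m.intercept == pytest.approx(-1.0)

    def test_listwise_deletion(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0])
        y = pd.Series([1.0, 2.0, 3.0, np.nan, 5.0])
        m = fit_calibration(x, y)
        assert m.n == 3

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(DegenerateFitError):
            fit_calibration(np.ones(5), np.arange(5.0))

    def test_mae_converges_to_gaussian_identity(self):
        # for Gaussian residuals with sd sigma, E|resid| = sigma*sqrt(2/pi)
        rng = np.random.default_rng(0)
        n, sigma = 10_000, 0.5
        x = rng.uniform(0, 5, n)
        y = 0.47 * x + 0.55 + rng.normal(0, sigma, n)
        m = fit_calibration(x, y)
        assert m.mae == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.05)

    def test_monte_carlo_slope_ci_coverage(self):
        # OLS slope CI is exact under Gaussian errors: ~95% coverage
        rng = np.random.default_rng(1)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.uniform(0, 5, 63)
            y = 0.47 * x + 0.55 + rng.normal(0, 0.5, 63)
            lo, hi = fit_calibration(x, y).slope_ci()
            hits += lo <= 0.47 <= hi
        assert hits / reps >= 0.90


class TestPredictionAndRanking:
    def test_published_sc_model_prediction(self):
        m = fit_calibration(np.array([0.0, 1.0, 2.0]), np.array([0.55, 1.02, 1.49]))
        assert m.slope == pytest.approx(0.47)
        assert predict_micellar_logp(m, 3.0) == pytest.approx(1.96)
        assert predict_micellar_logp(m, 0.0) == pytest.approx(m.intercept)

    def test_best_micelle_is_argmax(self):
        x = np.arange(4.0)
        models = [
            fit_calibration(x, 0.47 * x + 0.55, micelle="SC"),
            fit_calibration(x, 0.23 * x + 1.80, micelle="HTAB"),
        ]
        assert best_micelle(models, 10.0).micelle == "SC"
        assert best_micelle(models, 0.0).micelle == "HTAB"

    def test_rank_surrogates_orders_by_r_then_alphabetically(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        exp = pd.DataFrame({"SC": y}, index=[f"c{i}" for i in range(30)])
        comp = pd.DataFrame(
            {
                "good": y + 0.1 * rng.normal(size=30),
                "bad": rng.normal(size=30),
                "tie_b": y,
                "tie_a": y,
            },
            index=exp.index,
        )
        cm = correlation_matrix(exp, comp)
        ranking = rank_surrogates(cm, "SC")
        names = [s for s, _ in ranking]
        assert set(names) == {"good", "bad", "tie_a", "tie_b"}
        assert names.index("tie_a") < names.index("tie_b")  # tie broken alphabetically
        assert names[-1] == "bad"
        with pytest.raises(KeyError):
            rank_surrogates(cm, "nope")
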