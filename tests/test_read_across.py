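import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qsarws.errors import NoAnalogueError, QsarError, SchemaError
from qsarws.read_across import (
    RAConfig,
    ReadAcrossModel,
    autoscale,
    fit_qrasar,
    optimize_ra_hyperparameters,
    ra_predict,
    rasar_features,
    similarities,
)
from qsarws.regression import fit_ols
from tests.conftest import make_table


@pytest.fixture()
def train_table(rng):
    X = rng.normal(size=(30, 3))
    y = X @ np.array([1.0, -0.5, 2.0]) + 5.0
    return make_table(X, y)


class TestAutoscale:
    def test_training_columns_standardized(self, rng):
        X = rng.normal(loc=3, scale=2, size=(40, 4))
        Z, _, _ = autoscale(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_query_at_training_mean_is_zero_row(self, rng):
        X = rng.normal(size=(20, 3))
        _, Zq, _ = autoscale(X, X.mean(axis=0))
        assert np.allclose(Zq, 0, atol=1e-12)

    def test_round_trip(self, rng):
        X = rng.normal(size=(20, 3))
        Z, _, params = autoscale(X)
        back = Z * params["sd"] + params["mean"]
        assert np.allclose(back, X[:, params["columns"]], atol=1e-12)

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 4.0
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, _, params = autoscale(X)
        assert Z.shape[1] == 2 and list(params["columns"]) == [0, 2]

    def test_all_constant_raises(self):
        with pytest.raises(QsarError):
            autoscale(np.ones((10, 2)))


class TestSimilarities:
    def test_identical_query_is_one_under_all_kernels(self, rng):
        Z = rng.normal(size=(10, 3))
        for kernel in ("ED", "GK", "LK"):
            s = similarities(Z, Z[4], RAConfig(similarity=kernel))
            assert s[4] == pytest.approx(1.0)
            assert (s <= 1.0).all() and (s > 0).all()

    def test_gaussian_at_sigma_root_two(self):
        Z = np.array([[0.0, 0.0], [np.sqrt(2.0), 0.0]])
        s = similarities(Z, Z[0], RAConfig(similarity="GK", sigma=1.0))
        assert s[1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_ed_strictly_decreasing_in_distance(self):
        Z = np.array([[float(i), 0.0] for i in range(6)])
        s = similarities(Z, Z[0], RAConfig(similarity="ED"))
        assert (np.diff(s) < 0).all()

    def test_dimension_mismatch(self, rng):
        with pytest.raises(SchemaError):
            similarities(rng.normal(size=(5, 3)), rng.normal(size=2), RAConfig())

    def test_ed_and_gk_share_neighbor_ranking(self, rng):
        Z = rng.normal(size=(25, 4))
        q = rng.normal(size=4)
        s_ed = similarities(Z, q, RAConfig(similarity="ED"))
        s_gk = similarities(Z, q, RAConfig(similarity="GK"))
        assert np.array_equal(np.argsort(-s_ed), np.argsort(-s_gk))


class TestRaPredict:
    def test_duplicate_of_training_compound(self, train_table):
        q = train_table.descriptors.iloc[7].to_numpy()
        pred, info = ra_predict(train_table, q, RAConfig(n_neighbors=1))
        assert pred == pytest.approx(train_table.pic50.iloc[7])
        assert info["neighbor_ids"] == [train_table.ids[7]]

    def test_two_equidistant_neighbors_average(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 5.0], [0.0, -5.0]])
        y = np.array([2.0, 4.0, 9.0, 9.0])
        table = make_table(X, y)
        pred, _ = ra_predict(
            table, np.array([0.0, 0.0]), RAConfig(n_neighbors=2)
        )
        assert pred == pytest.approx(3.0)

    @given(st.integers(min_value=1, max_value=10), st.integers(0, 1000))
    def test_prediction_is_convex_combination(self, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15) * 3 + 5
        table = make_table(X, y)
        model = ReadAcrossModel(table, config=RAConfig(n_neighbors=k))
        info = model.predict_one(rng.normal(size=3))
        lo, hi = info["neighbor_responses"].min(), info["neighbor_responses"].max()
        assert lo - 1e-12 <= info["prediction"] <= hi + 1e-12

    def test_many_neighbors_uniform_similarity_approaches_mean(self):
        # all training compounds equidistant from the origin query
        theta = np.linspace(0, 2 * np.pi, 13)[:-1]
        X = np.column_stack([np.cos(theta), np.sin(theta)])
        y = np.arange(12.0)
        table = make_table(X, y)
        pred, _ = ra_predict(table, np.zeros(2), RAConfig(n_neighbors=12))
        assert pred == pytest.approx(y.mean())

    def test_no_eligible_neighbor_raises(self, train_table):
        cfg = RAConfig(distance_threshold=1e-9, similarity_threshold=0.999999)
        model = ReadAcrossModel(train_table, config=cfg)
        with pytest.raises(NoAnalogueError):
            model.predict_one(np.full(3, 100.0))

    def test_exclude_self(self, train_table):
        model = ReadAcrossModel(train_table, config=RAConfig(n_neighbors=1))
        q = train_table.descriptors.iloc[0].to_numpy()
        info = model.predict_one(q, exclude_id=train_table.ids[0])
        assert train_table.ids[0] not in info["neighbor_ids"]


class TestRasarFeatures:
    def test_duplicate_query_features(self, train_table):
        queries = train_table.subset(train_table.ids[:3])
        feats = rasar_features(train_table, queries)
        # with itself in the pool at similarity 1 and n_neighbors 1 the ED
        # prediction equals the response; default 6 neighbours only approximates,
        # so check the dedicated single-neighbour configuration
        cfgs = {k: RAConfig(similarity=k, n_neighbors=1) for k in ("ED", "GK", "LK")}
        f1 = rasar_features(train_table, queries, configs=cfgs)
        for cid in queries.ids:
            assert f1.loc[cid, "RA_ED"] == pytest.approx(train_table.pic50.loc[cid])
        assert set(feats.columns) >= {
            "RA_ED",
            "RA_GK",
            "RA_LK",
            "mean_similarity",
            "sd_similarity",
            "sd_neighbor_response",
            "neighbor_ids",
        }

    def test_sd_neighbor_response_hand_checked_on_toy(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [10.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0, 50.0])
        table = make_table(X, y)
        cfgs = {k: RAConfig(similarity=k, n_neighbors=3) for k in ("ED", "GK", "LK")}
        feats = rasar_features(table, table.subset([table.ids[0]]), configs=cfgs)
        # nearest three responses to compound 0 are (1, 2, 3)
        assert feats.iloc[0]["sd_neighbor_response"] == pytest.approx(
            np.std([1.0, 2.0, 3.0], ddof=1)
        )


class TestHyperparameterSearch:
    def test_single_config_grid(self, train_table):
        cfg = RAConfig(n_neighbors=3)
        best, table = optimize_ra_hyperparameters(train_table, [cfg], seed=0)
        assert best is cfg and len(table) == 1

    def test_matches_exhaustive_oracle(self, train_table):
        grid = [RAConfig(n_neighbors=k) for k in (1, 2, 4, 8)]
        best, table = optimize_ra_hyperparameters(train_table, grid, seed=3)
        assert best.n_neighbors == int(
            table.loc[table["subtest_rmse"].idxmin(), "n_neighbors"]
        )

    def test_seed_reproducible(self, train_table):
        grid = [RAConfig(n_neighbors=k) for k in (2, 5)]
        b1, t1 = optimize_ra_hyperparameters(train_table, grid, seed=9)
        b2, t2 = optimize_ra_hyperparameters(train_table, grid, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        assert b1 is b2


class TestFitQrasar:
    def test_model_equals_manual_feature_fit(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + rng.normal(0, 0.2, 40)
        train = make_table(X, y)
        res = fit_qrasar(
            train,
            feature_descriptors=["x0"],
            lmo_iterations=10,
            yscr_iterations=10,
        )
        feats = rasar_features(train, train, leave_out_self=True)
        manual = fit_ols(
            pd.concat([feats[["RA_ED"]], train.descriptors[["x0"]]], axis=1),
            y,
        )
        assert np.allclose(res.model.coefficients, manual.coefficients, atol=1e-12)
        assert res.model.intercept == pytest.approx(manual.intercept, abs=1e-12)
        assert res.model.descriptor_names == ["RA_ED", "x0"]

    def test_planted_feature_relation_recovered(self, rng):
        # build a response that is an exact linear function of the RA_ED
        # feature and one descriptor, then confirm the OLS stage recovers it
        X = rng.normal(size=(50, 3))
        y0 = X @ np.array([1.0, -1.0, 0.5])
        train0 = make_table(X, y0)
        feats = rasar_features(train0, train0, leave_out_self=True)
        y2 = 0.9 * feats["RA_ED"].to_numpy() + 0.3 * X[:, 0] - 1.1
        model = fit_ols(
            pd.concat([feats[["RA_ED"]], train0.descriptors[["x0"]]], axis=1), y2
        )
        assert np.allclose(model.coefficients, [0.9, 0.3], atol=1e-10)
        assert model.intercept == pytest.approx(-1.1, abs=1e-10)

    def test_qrasar_produces_fewer_or_equal_response_outliers(self, rng):
        """Read-across features absorb local response structure, so the
        hybrid model should not flag more response outliers than the
        structural model on matched data."""
        from qsarws.ad import standardized_residuals

        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = r.normal(size=(120, 4))
            y = X @ np.array([2.0, -1.0, 0.0, 0.0]) + r.normal(0, 1.0, 120)
            y[:4] += r.choice([-4.0, 4.0], size=4)  # planted cliffs
            train = make_table(X, y)
            qsar = fit_ols(train.descriptors, y)
            _, flags_qsar = standardized_residuals(qsar, train.descriptors, y)
            res = fit_qrasar(
                train,
                feature_descriptors=["x0", "x1"],
                lmo_iterations=1,
                yscr_iterations=1,
            )
            feats = pd.concat(
                [res.train_features[["RA_ED"]], train.descriptors[["x0", "x1"]]],
                axis=1,
            )
            _, flags_qr = standardized_residuals(res.model, feats, y)
            if flags_qr.sum() <= flags_qsar.sum():
                wins += 1
        assert wins >= n_seeds / 2
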