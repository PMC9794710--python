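"""Validation battery: fitting/CV/external statistics, scrambling, leverage."""

import math

import numpy as np
import pytest

from chalqsar.errors import SizeError
from chalqsar.mlr import DataTable, MLRModel, design_matrix, fit_mlr, predict
from chalqsar.simulate import QsarSimSpec, gen_qsar
from chalqsar.validation import (
    applicability_domain,
    external_stats,
    fit_stats,
    gt_check,
    loo_predictions,
    q2_lmo,
    q2_loo,
    y_scramble,
)


def _table(X, y, names=None, ids=None):
    X = np.asarray(X, float)
    names = tuple(names or (f"x{j+1}" for j in range(X.shape[1])))
    ids = tuple(ids or (f"r{i}" for i in range(len(y))))
    return DataTable(ids=ids, X=X, y=np.asarray(y, float), descriptor_names=names)


# Six-point hand dataset used for the spreadsheet-style brute-force checks.
HAND_X = np.array([[0.1, 2.0], [0.4, 1.0], [0.9, 3.0], [1.3, 0.5], [1.8, 2.5], [2.2, 1.5]])
HAND_Y = np.array([1.0, 1.3, 2.6, 2.2, 3.9, 4.1])


def brute_force_fit_stats(X, y):
    """Spreadsheet-style statistics via explicit sums, no shared code."""
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    yhat = A @ beta
    rss = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
    ybar = sum(y) / n
    tss = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1 - rss / tss
    hbar = sum(yhat) / n
    ccc = (
        2 * sum((yh - hbar) * (yi - ybar) for yh, yi in zip(yhat, y))
        / (sum((yh - hbar) ** 2 for yh in yhat) + tss + n * (hbar - ybar) ** 2)
    )
    return {
        "r2": r2,
        "r2_adj": 1 - (1 - r2) * (n - 1) / (n - p - 1),
        "rmse": math.sqrt(rss / n),
        "mae": sum(abs(yi - yh) for yi, yh in zip(y, yhat)) / n,
        "rss": rss,
        "ccc": ccc,
        "s": math.sqrt(rss / (n - p - 1)),
        "f": (r2 / p) / ((1 - r2) / (n - p - 1)),
        "yhat": yhat,
    }


class TestFitStats:
    def test_perfect_fit(self):
        x = np.arange(6.0)
        table = _table(x[:, None], 3 * x - 1)
        stats = fit_stats(fit_mlr(table), table)
        assert stats.r2_tr == pytest.approx(1.0, abs=1e-12)
        assert stats.rmse_tr == pytest.approx(0.0, abs=1e-10)
        assert stats.ccc_tr == pytest.approx(1.0, abs=1e-12)

    def test_hand_dataset_brute_force(self):
        table = _table(HAND_X, HAND_Y)
        stats = fit_stats(fit_mlr(table), table)
        oracle = brute_force_fit_stats(HAND_X, HAND_Y)
        assert stats.r2_tr == pytest.approx(oracle["r2"], abs=1e-10)
        assert stats.r2_adj == pytest.approx(oracle["r2_adj"], abs=1e-10)
        assert stats.rmse_tr == pytest.approx(oracle["rmse"], abs=1e-10)
        assert stats.mae_tr == pytest.approx(oracle["mae"], abs=1e-10)
        assert stats.rss_tr == pytest.approx(oracle["rss"], abs=1e-10)
        assert stats.ccc_tr == pytest.approx(oracle["ccc"], abs=1e-10)
        assert stats.s == pytest.approx(oracle["s"], abs=1e-10)
        assert stats.f == pytest.approx(oracle["f"], abs=1e-8)

    def test_duplicated_column_kxx_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        table = _table(np.column_stack([x, x]), rng.normal(size=12))
        # correlation 1 between the two columns -> eigenvalues (2, 0) -> K = 1
        stats = fit_stats(MLRModel(0.0, {"x1": 1.0, "x2": 0.0}, table.ids, 1.0), table)
        assert stats.kxx == pytest.approx(1.0, abs=1e-6)

    def test_near_orthogonal_columns_low_kxx(self):
        rng = np.random.default_rng(1)
        table = _table(rng.normal(size=(500, 3)), rng.normal(size=500))
        stats = fit_stats(fit_mlr(table), table)
        assert stats.kxx < 0.1

    def test_too_few_rows(self):
        table = _table(np.arange(3.0)[:, None], np.arange(3.0))
        model = fit_mlr(table)
        with pytest.raises(SizeError):
            fit_stats(model, _table(np.arange(2.0)[:, None], np.arange(2.0)))


class TestLOO:
    def test_perfect_data_q2_one(self):
        x = np.arange(8.0)
        table = _table(x[:, None], 2 * x + 3)
        assert q2_loo(table, ("x1",)).q2_loo == pytest.approx(1.0, abs=1e-10)

    def test_shortcut_equals_explicit_refitting(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, p = int(rng.integers(8, 20)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            table = _table(X, y)
            shortcut = loo_predictions(table, table.descriptor_names)
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                beta = np.linalg.lstsq(
                    np.column_stack([np.ones(n - 1), X[mask]]), y[mask], rcond=None
                )[0]
                explicit = beta[0] + X[i] @ beta[1:]
                assert shortcut[i] == pytest.approx(explicit, abs=1e-10)

    def test_pure_noise_q2_negative(self):
        negative = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            table = _table(rng.normal(size=(15, 3)), rng.normal(size=15))
            if q2_loo(table, table.descriptor_names).q2_loo < 0:
                negative += 1
        assert negative >= 180

    def test_q2_below_r2(self, fixture_table):
        from chalqsar.descriptors import MODEL_DESCRIPTORS

        model = fit_mlr(fixture_table, MODEL_DESCRIPTORS)
        stats = fit_stats(model, fixture_table)
        cv = q2_loo(fixture_table, MODEL_DESCRIPTORS)
        assert cv.q2_loo < stats.r2_tr
        assert cv.press_cv >= stats.rss_tr


class TestLMO:
    def test_perfect_data(self):
        x = np.arange(12.0)
        table = _table(x[:, None], 0.5 * x - 2)
        assert q2_lmo(table, ("x1",), 0.3, 100, seed=0) == pytest.approx(1.0, abs=1e-10)

    def test_deterministic(self):
        table = gen_qsar(QsarSimSpec(n=15, p=3, sigma=0.3, seed=2))
        a = q2_lmo(table, table.descriptor_names, 0.3, 100, seed=9)
        b = q2_lmo(table, table.descriptor_names, 0.3, 100, seed=9)
        assert a == b


class TestYScramble:
    def test_destroys_signal(self):
        table = gen_qsar(QsarSimSpec(n=15, p=3, sigma=0.2, seed=1))
        model = fit_mlr(table)
        unscrambled = fit_stats(model, table).r2_tr
        scramble = y_scramble(table, table.descriptor_names, 200, seed=0)
        assert scramble.q2_yscr_mean < 0.0
        assert scramble.r2_yscr_mean < unscrambled
        assert len(scramble.r2_values) == 200

    def test_deterministic(self):
        table = gen_qsar(QsarSimSpec(seed=3))
        a = y_scramble(table, table.descriptor_names, 100, seed=5)
        b = y_scramble(table, table.descriptor_names, 100, seed=5)
        assert np.array_equal(a.r2_values, b.r2_values)


class TestExternalStats:
    def _tables(self):
        train = _table(HAND_X, HAND_Y)
        X_test = np.array([[0.2, 1.2], [0.8, 2.2], [1.6, 0.8], [2.0, 2.8]])
        y_test = np.array([1.1, 2.3, 2.9, 4.4])
        test = _table(X_test, y_test, ids=("t0", "t1", "t2", "t3"))
        return train, test

    def test_identity_predictions(self):
        # model reproducing y exactly: single descriptor equal to the response
        y = np.array([1.0, 2.0, 3.0, 4.0])
        test = _table(y[:, None], y, names=("x1",), ids=("a", "b", "c", "d"))
        train = _table(np.array([[0.0], [5.0], [6.0]]), np.array([0.0, 5.0, 6.0]))
        model = MLRModel(0.0, {"x1": 1.0}, train.ids, 0.1)
        ext = external_stats(model, test, train)
        assert ext.q2_f1 == ext.q2_f2 == pytest.approx(1.0, abs=1e-12)
        assert ext.k == pytest.approx(1.0) and ext.k_prime == pytest.approx(1.0)
        assert ext.angle_from_diagonal_deg == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_q2f2_hand_value(self):
        # yhat = y + 0.5 on y = 1..4: PRESS = 1, Σ(y-ȳ)² = 5 -> Q²F2 = 0.8
        y = np.array([1.0, 2.0, 3.0, 4.0])
        test = _table(y[:, None], y, names=("x1",), ids=("a", "b", "c", "d"))
        train = _table(np.array([[0.0], [5.0], [6.0]]), np.array([0.0, 5.0, 6.0]))
        model = MLRModel(0.5, {"x1": 1.0}, train.ids, 0.1)
        ext = external_stats(model, test, train)
        assert ext.q2_f2 == pytest.approx(0.8, abs=1e-12)

    def test_hand_dataset_brute_force(self):
        train, test = self._tables()
        model = fit_mlr(train)
        ext = external_stats(model, test, train)
        yhat = predict(model, test)
        y = test.y
        press = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
        assert ext.press_ext == pytest.approx(press, abs=1e-10)
        assert ext.q2_f1 == pytest.approx(
            1 - press / sum((yi - train.y.mean()) ** 2 for yi in y), abs=1e-10
        )
        assert ext.q2_f3 == pytest.approx(
            1 - (press / 4) / (sum((t - train.y.mean()) ** 2 for t in train.y) / 6), abs=1e-10
        )
        k = sum(y * yhat) / sum(yhat**2)
        assert ext.k == pytest.approx(k, abs=1e-12)
        r2o = 1 - sum((y - k * yhat) ** 2) / sum((y - y.mean()) ** 2)
        assert ext.r2o == pytest.approx(r2o, abs=1e-10)
        r2 = np.corrcoef(y, yhat)[0, 1] ** 2
        assert ext.r2m == pytest.approx(r2 * (1 - math.sqrt(max(r2 - r2o, 0))), abs=1e-10)

    def test_requires_three_rows(self):
        train, test = self._tables()
        model = fit_mlr(train)
        tiny = _table(test.X[:2], test.y[:2], ids=("t0", "t1"))
        with pytest.raises(SizeError):
            external_stats(model, tiny, train)


class TestGTCheck:
    def _ideal(self):
        from chalqsar.validation import CVStats, ExternalStats, FitStats

        fit = FitStats(1.0, 1.0, 0.0, 0.2, 0.3, 0.0, 0.0, 0.0, 1.0, 0.0, 1e9)
        # q2_loo strictly below r2_tr in both the ideal and degraded variants
        cv = CVStats(0.52, 0.1, 0.05, 0.1, 1.0, q2_lmo=0.8)
        ext = ExternalStats(0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        return fit, cv, ext

    def test_ideal_all_pass(self):
        report = gt_check(*self._ideal())
        assert report["all_pass"]["passed"]

    def test_single_criterion_isolation(self):
        from dataclasses import replace

        fit, cv, ext = self._ideal()
        report = gt_check(replace(fit, r2_tr=0.55), cv, ext)
        failed = [k for k, v in report.items() if not v["passed"]]
        assert failed == ["r2_tr >= 0.6", "all_pass"]


class TestApplicabilityDomain:
    def test_leverages_sum_to_p_plus_one(self):
        table = gen_qsar(QsarSimSpec(n=15, p=3, sigma=0.3, seed=4))
        model = fit_mlr(table)
        report = applicability_domain(model, table)
        assert sum(report.leverages.values()) == pytest.approx(4.0, abs=1e-8)
        assert report.h_star == pytest.approx(3 * 4 / 15)

    def test_duplicated_row_leverage_halves(self):
        X = np.array([[0.0], [1.0], [1.0]])
        y = np.array([0.0, 1.0, 1.0])
        table = _table(X, y, ids=("a", "b", "b2"))
        model = MLRModel(0.0, {"x1": 1.0}, table.ids, 1.0)
        report = applicability_domain(model, table)
        assert report.leverages["a"] == pytest.approx(1.0, abs=1e-10)
        assert report.leverages["b"] == pytest.approx(0.5, abs=1e-10)

    def test_centroid_query_minimum_leverage(self):
        table = gen_qsar(QsarSimSpec(n=12, p=2, beta=(0, 1, 1), sigma=0.1, seed=6))
        model = fit_mlr(table)
        centroid = table.X.mean(axis=0)
        query = _table(centroid[None, :], [0.0], names=table.descriptor_names, ids=("q",))
        report = applicability_domain(model, table, query)
        assert report.leverages["q"] == pytest.approx(1.0 / table.n, abs=1e-10)
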