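"""Cleaning-rule checks: ln(1+x) transform, 5 s.d. outlier masking, the
2.5% missingness filter, and OLS residualisation."""

import numpy as np
import pandas as pd
import pytest

from bridgenet.preprocess import (
    DomainError,
    filter_missingness,
    log_transform,
    mask_outliers,
    percent_reduction,
    residualize,
)
from bridgenet.variables import (
    CATEGORICAL,
    CONTINUOUS,
    CollinearityError,
    CovariateTable,
    MixedDataMatrix,
    VariableSpec,
)


def _matrix(cols: dict[str, np.ndarray], kinds: dict[str, str] | None = None):
    kinds = kinds or {}
    specs = []
    for k, name in enumerate(cols):
        kind = kinds.get(name, CONTINUOUS)
        group = "somatic" if kind == CATEGORICAL else "panel"
        specs.append(VariableSpec(name, kind, 4 if kind == CATEGORICAL else 0,
                                  group, k))
    return MixedDataMatrix(np.column_stack(list(cols.values())), specs)


def _covariates(n, **overrides):
    rng = np.random.default_rng(0)
    base = dict(sex=rng.binomial(1, 0.5, n), age=rng.normal(40, 10, n),
                batch=rng.binomial(1, 0.5, n), bmi=rng.normal(25, 4, n),
                smoking=rng.binomial(1, 0.4, n), ad_use=rng.binomial(1, 0.2, n),
                statin_use=rng.binomial(1, 0.1, n))
    base.update(overrides)
    return CovariateTable(pd.DataFrame({k: np.asarray(v, float) for k, v in base.items()}))


class TestLogTransform:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.0), (np.e - 1, 1.0), (1.0, np.log(2)), (3.0, np.log(4))],
    )
    def test_known_values(self, x, expected):
        assert log_transform(np.array([x]))[0] == pytest.approx(expected)

    def test_column_example(self):
        np.testing.assert_allclose(
            log_transform(np.array([0.0, 1.0, 3.0])),
            [0.0, np.log(2), np.log(4)],
        )

    def test_preserves_missing(self):
        out = log_transform(np.array([0.0, np.nan, 1.0]))
        assert np.isnan(out[1]) and out[0] == 0.0

    def test_domain_error_below_minus_one(self):
        with pytest.raises(DomainError, match="met_x"):
            log_transform(np.array([0.0, -1.5]), name="met_x")


class TestMaskOutliers:
    def test_constant_column_unchanged(self):
        x = np.full(20, 3.0)
        np.testing.assert_array_equal(mask_outliers(x), x)

    def test_single_extreme_value_masked(self):
        rng = np.random.default_rng(1)
        x = np.append(rng.standard_normal(100), 50.0)
        # oracle: mean/sd computed including the outlier still leave 50
        # beyond 5 s.d. while all N(0,1) draws stay inside
        mean, sd = x.mean(), x.std()
        assert abs(50.0 - mean) > 5 * sd
        assert np.all(np.abs(x[:100] - mean) <= 5 * sd)
        out = mask_outliers(x)
        assert np.isnan(out[100]) and not np.isnan(out[:100]).any()

    def test_tight_column_is_identity(self):
        x = np.linspace(-1, 1, 50)
        np.testing.assert_array_equal(mask_outliers(x), x)


class TestFilterMissingness:
    def test_complete_data_identity(self):
        data = _matrix({"m0": np.arange(5.0), "m1": np.ones(5)})
        out, report = filter_missingness(data)
        np.testing.assert_array_equal(out.values, data.values)
        assert report.dropped_columns == [] and report.dropped_rows == 0

    def test_leaky_column_dropped_rows_kept(self):
        m0 = np.arange(10.0)
        m0[[1, 4, 7]] = np.nan                     # 30% > 2.5%
        data = _matrix({"m0": m0, "m1": np.ones(10)})
        out, report = filter_missingness(data)
        assert report.dropped_columns == ["m0"]
        assert out.n == 10 and out.names == ["m1"]

    def test_sparse_column_kept_rows_dropped(self):
        m0 = np.zeros(1000)
        m0[:20] = np.nan                           # 2.0% <= 2.5%
        data = _matrix({"m0": m0, "m1": np.ones(1000)})
        out, report = filter_missingness(data)
        assert report.dropped_columns == []
        assert report.dropped_rows == 20
        assert out.n == 980

    def test_counts_reconcile(self):
        rng = np.random.default_rng(2)
        m0 = rng.standard_normal(200)
        m0[rng.random(200) < 0.01] = np.nan
        data = _matrix({"m0": m0, "s0": rng.integers(0, 4, 200).astype(float)},
                       kinds={"s0": CATEGORICAL})
        out, report = filter_missingness(data)
        assert report.n_before - report.dropped_rows == report.n_after == out.n

    def test_symptom_missing_drops_row_not_column(self):
        s0 = np.array([0.0, 1, np.nan, 2, 3, 0, 1, 2, 3, 0])  # 10% missing
        data = _matrix({"s0": s0, "m0": np.ones(10)}, kinds={"s0": CATEGORICAL})
        out, report = filter_missingness(data)
        assert report.dropped_columns == []                   # not a metabolite
        assert out.n == 9


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self):
        cov = _covariates(50)
        m = 2 * cov.frame["age"].to_numpy() + 1
        data = _matrix({"m0": m})
        out = residualize(data, cov)
        np.testing.assert_allclose(out.values[:, 0], 0.0, atol=1e-9)

    def test_orthogonal_covariates_center_only(self):
        n = 400
        rng = np.random.default_rng(3)
        y = rng.standard_normal(n) + 5
        cov = _covariates(n, sex=np.zeros(n), age=np.zeros(n), batch=np.zeros(n))
        # constant covariates are collinear with the intercept; orthogonalise
        cov.frame["sex"] = rng.binomial(1, 0.5, n)
        cov.frame["age"] = rng.standard_normal(n)
        cov.frame["batch"] = rng.binomial(1, 0.5, n)
        data = _matrix({"m0": y})
        out = residualize(data, cov)
        assert out.values[:, 0].mean() == pytest.approx(0.0, abs=1e-9)
        # independent covariates barely change the column beyond centering
        assert np.corrcoef(out.values[:, 0], y - y.mean())[0, 1] > 0.99

    def test_projection_idempotent(self):
        n = 300
        cov = _covariates(n)
        rng = np.random.default_rng(4)
        data = _matrix({"m0": rng.standard_normal(n) + cov.frame["age"].to_numpy()})
        once = residualize(data, cov)
        twice = residualize(once, cov)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_symptom_columns_untouched(self):
        n = 100
        cov = _covariates(n)
        rng = np.random.default_rng(5)
        s = rng.integers(0, 4, n).astype(float)
        data = _matrix({"s0": s, "m0": rng.standard_normal(n)},
                       kinds={"s0": CATEGORICAL})
        out = residualize(data, cov)
        np.testing.assert_array_equal(out.values[:, 0], s)

    def test_collinear_design_rejected(self):
        cov = _covariates(50, batch=np.zeros(50))   # constant = intercept
        data = _matrix({"m0": np.arange(50.0)})
        with pytest.raises(CollinearityError):
            residualize(data, cov)


def test_percent_reduction_examples():
    assert percent_reduction(2981, 2498) == pytest.approx(16.2, abs=0.05)
    assert percent_reduction(2256, 1745) == pytest.approx(22.7, abs=0.05)
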