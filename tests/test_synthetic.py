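"""Generator checks: sampler marginals against closed-form Gaussian
oracles, covariate confounding, missingness injection, determinism."""

import numpy as np
import pytest

from bridgenet.synthetic import (
    CovariateModel,
    PairwiseMixedModel,
    apply_covariates,
    demo_model,
    gibbs_sample,
    inject_missing,
    model_from_yaml,
    model_to_yaml,
)
from bridgenet.variables import (
    CATEGORICAL,
    CONTINUOUS,
    ParameterError,
    SpecificationError,
    VariableSpec,
)


def _cont_specs(p):
    return [VariableSpec(f"x{i}", CONTINUOUS, 0, "panel", i) for i in range(p)]


def _pairwise_model(couplings=None, p=2, variances=None):
    specs = _cont_specs(p)
    m = PairwiseMixedModel(
        node_specs=specs,
        couplings={k: np.asarray(v, float) for k, v in (couplings or {}).items()},
        variances=variances or {},
    )
    m.validate()
    return m


class TestGibbsSampler:
    def test_empty_graph_gives_independent_columns(self):
        d = gibbs_sample(_pairwise_model(p=2), n=5000, seed=1)
        r = np.corrcoef(d.values.T)[0, 1]
        assert abs(r) < 0.05

    def test_uniform_categorical_marginal_under_equal_thresholds(self):
        specs = [VariableSpec("s", CATEGORICAL, 4, "somatic", 0)]
        m = PairwiseMixedModel(node_specs=specs)
        d = gibbs_sample(m, n=8000, seed=2)
        freqs = [np.mean(d.values[:, 0] == l) for l in range(4)]
        assert all(abs(f - 0.25) < 0.03 for f in freqs)

    def test_bivariate_correlation_matches_precision_oracle(self):
        # coupling c=0.4, unit conditional variances -> precision
        # [[1,-0.4],[-0.4,1]]; invert analytically for the expected corr
        c = 0.4
        prec = np.array([[1.0, -c], [-c, 1.0]])
        cov = np.linalg.inv(prec)
        expected = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        d = gibbs_sample(_pairwise_model({("x0", "x1"): c}), n=10000, seed=3)
        r = np.corrcoef(d.values.T)[0, 1]
        assert r == pytest.approx(expected, abs=0.03)

    def test_gaussian_submodel_matches_analytic_covariance(self):
        coup = {("x0", "x1"): 0.3, ("x1", "x2"): -0.25, ("x0", "x3"): 0.2}
        m = _pairwise_model(coup, p=4)
        expected = np.linalg.inv(m.continuous_precision())
        d = gibbs_sample(m, n=20000, seed=4)
        emp = np.cov(d.values.T)
        assert np.allclose(emp, expected, atol=0.06)

    def test_null_association_shrinks_with_n(self):
        m = _pairwise_model(p=2)
        r500 = abs(np.corrcoef(gibbs_sample(m, 500, seed=5).values.T)[0, 1])
        r5000 = abs(np.corrcoef(gibbs_sample(m, 5000, seed=5).values.T)[0, 1])
        assert r500 < 0.15 and r5000 < 0.05

    def test_deterministic_under_seed(self):
        m = demo_model()
        a = gibbs_sample(m, 100, burn_in=50, seed=11)
        b = gibbs_sample(m, 100, burn_in=50, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ParameterError):
            _pairwise_model(p=2, variances={"x0": 0.0})

    def test_indefinite_precision_rejected(self):
        with pytest.raises(ParameterError):
            _pairwise_model({("x0", "x1"): 1.5}, p=2)

    def test_coupling_blocks_symmetric_storage(self):
        specs = [VariableSpec("s", CATEGORICAL, 3, "somatic", 0),
                 VariableSpec("m", CONTINUOUS, 0, "panel", 1)]
        blk = np.array([0.0, 0.2, 0.4])
        model = PairwiseMixedModel(node_specs=specs, couplings={("m", "s"): blk})
        np.testing.assert_array_equal(model.block("s", "m"), blk)
        np.testing.assert_array_equal(model.block("m", "s"), blk)


class TestApplyCovariates:
    def test_empty_effects_is_identity(self):
        d = gibbs_sample(_pairwise_model(p=2), n=200, seed=6)
        out, table = apply_covariates(d, CovariateModel(), seed=7)
        np.testing.assert_array_equal(out.values, d.values)
        assert table.n == 200

    def test_batch_shift_moves_group_means(self):
        d = gibbs_sample(_pairwise_model(p=2), n=4000, seed=8)
        cm = CovariateModel(effects={"batch": [("x0", 0.5)]})
        out, table = apply_covariates(d, cm, seed=9)
        batch = table.frame["batch"].to_numpy()
        diff = out.values[batch == 1, 0].mean() - out.values[batch == 0, 0].mean()
        assert diff == pytest.approx(0.5, abs=0.1)

    def test_confounder_induces_marginal_not_partial_association(self):
        # BMI-like effect on one metabolite and one symptom latent score,
        # zero direct coupling: marginal association positive, association
        # conditional on BMI ~ 0 (partial-correlation oracle)
        specs = [VariableSpec("s", CATEGORICAL, 4, "somatic", 0),
                 VariableSpec("m", CONTINUOUS, 0, "panel", 1)]
        model = PairwiseMixedModel(
            node_specs=specs, thresholds={"s": np.zeros(4)})
        d = gibbs_sample(model, n=6000, seed=10)
        cm = CovariateModel(effects={"bmi": [("s", 0.8), ("m", 0.8)]})
        out, table = apply_covariates(d, cm, seed=11)
        s, m = out.values[:, 0], out.values[:, 1]
        z = table.frame["bmi"].to_numpy()
        marginal = np.corrcoef(s, m)[0, 1]
        rs = s - np.polyval(np.polyfit(z, s, 1), z)
        rm = m - np.polyval(np.polyfit(z, m, 1), z)
        partial = np.corrcoef(rs, rm)[0, 1]
        assert marginal > 0.1
        assert abs(partial) < 0.05

    def test_unknown_target_rejected(self):
        d = gibbs_sample(_pairwise_model(p=2), n=50, seed=12)
        with pytest.raises(SpecificationError):
            apply_covariates(d, CovariateModel(effects={"bmi": [("nope", 1.0)]}), 0)


class TestInjectMissing:
    def test_zero_rates_leave_data_complete(self):
        d = gibbs_sample(_pairwise_model(p=2), n=300, seed=13)
        out = inject_missing(d, {"x0": 0.0}, seed=14)
        assert not np.isnan(out.values).any()

    def test_missing_count_within_binomial_bounds(self):
        d = gibbs_sample(_pairwise_model(p=2), n=1000, seed=15)
        out = inject_missing(d, {"x0": 0.3}, seed=16)
        count = int(np.isnan(out.values[:, 0]).sum())
        assert 250 <= count <= 350          # +-3.4 binomial s.d.

    def test_same_seed_same_mask(self):
        d = gibbs_sample(_pairwise_model(p=3), n=500, seed=17)
        a = inject_missing(d, {"x0": 0.2, "x2": 0.1}, seed=18)
        b = inject_missing(d, {"x0": 0.2, "x2": 0.1}, seed=18)
        np.testing.assert_array_equal(np.isnan(a.values), np.isnan(b.values))

    def test_rate_one_rejected(self):
        d = gibbs_sample(_pairwise_model(p=2), n=10, seed=19)
        with pytest.raises(ParameterError):
            inject_missing(d, {"x0": 1.0}, seed=20)


def test_ground_truth_yaml_round_trip():
    model = demo_model()
    clone = model_from_yaml(model_to_yaml(model))
    assert [s.name for s in clone.node_specs] == [s.name for s in model.node_specs]
    assert set(clone.couplings) == set(model.couplings)
    for key, blk in model.couplings.items():
        np.testing.assert_allclose(clone.couplings[key], blk)
    assert clone.bridge_set == model.bridge_set
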