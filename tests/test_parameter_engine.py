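import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
import paapcea as p
from paapcea.parameter_engine import (
    DistributionSpec,
    EstimationError,
    estimate_branch_payoffs,
    estimate_branch_probabilities,
    resolve_missing_branches,
)


class TestAnnualize:
    @pytest.mark.parametrize("value, days, expected", [
        (100.0, 365.0, 100.0),
        (50.0, 182.5, 100.0),
        (123.4, 100.0, 450.41),
    ])
    def test_values(self, value, days, expected):
        assert p.annualize(value, days) == pytest.approx(expected)

    @given(value=st.floats(0, 1e6), days=st.floats(1, 366),
           scale=st.floats(0.1, 10))
    def test_linear_in_value_inverse_in_exposure(self, value, days, scale):
        assert p.annualize(scale * value, days) == pytest.approx(
            scale * p.annualize(value, days), rel=1e-12)

    def test_rejects_nonpositive_exposure(self):
        with pytest.raises(ValueError):
            p.annualize(10.0, 0.0)


class TestMomentMatching:
    def test_beta_uniform_closed_form(self):
        a, b = p.beta_from_moments(0.5, 0.288675)
        assert (a, b) == (pytest.approx(1.0, rel=1e-4),
                          pytest.approx(1.0, rel=1e-4))

    def test_beta_test_uptake(self):
        # nu = 0.910*0.090/0.082^2 - 1 = 11.180
        a, b = p.beta_from_moments(0.910, 0.082)
        assert a == pytest.approx(10.174, abs=5e-3)
        assert b == pytest.approx(1.006, abs=5e-3)

    @given(mean=st.floats(0.01, 0.99), frac=st.floats(0.05, 0.95))
    def test_beta_round_trip_exact_moments(self, mean, frac):
        sd = frac * math.sqrt(mean * (1 - mean))
        a, b = p.beta_from_moments(mean, sd)
        assert a / (a + b) == pytest.approx(mean, rel=1e-10)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-10)

    def test_beta_infeasible_moments(self):
        with pytest.raises(ValueError, match="infeasible"):
            p.beta_from_moments(0.9, 0.5)

    def test_lognormal_standard_closed_form(self):
        mean = math.exp(0.5)
        sd = mean * math.sqrt(math.e - 1)
        mu, sigma = p.lognormal_from_moments(mean, sd)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, rel=1e-12)

    def test_lognormal_cost_payoff(self):
        mu, sigma = p.lognormal_from_moments(1176.55, 1587.10)
        assert mu == pytest.approx(6.5520, abs=1e-4)
        assert sigma == pytest.approx(1.0182, abs=1e-4)

    @given(mean=st.floats(1.0, 1e5), cv=st.floats(0.05, 3.0))
    def test_lognormal_round_trip_exact_moments(self, mean, cv):
        sd = cv * mean
        mu, sigma = p.lognormal_from_moments(mean, sd)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-10)
        implied_var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert math.sqrt(implied_var) == pytest.approx(sd, rel=1e-10)

    @pytest.mark.parametrize("mean, sd", [(0.0, 1.0), (-5.0, 1.0), (10.0, 0.0)])
    def test_lognormal_rejects_degenerate(self, mean, sd):
        with pytest.raises(ValueError):
            p.lognormal_from_moments(mean, sd)

    def test_sampled_moments_match(self):
        rng = np.random.default_rng(5)
        spec = DistributionSpec("beta", 0.910, 0.082)
        x = spec.sample(10**6, rng)
        assert x.mean() == pytest.approx(0.910, abs=4 * 0.082 / 1000)
        assert x.std() == pytest.approx(0.082, rel=0.02)
        spec = DistributionSpec("lognormal", 1176.55, 1587.10)
        y = spec.sample(10**6, rng)
        assert y.mean() == pytest.approx(1176.55, abs=4 * 1587.10 / 1000)


class TestDistributionSpec:
    def test_fixed_ignores_uncertainty(self):
        spec = DistributionSpec("fixed", 0.3, 0.0)
        assert spec.is_fixed
        assert np.unique(spec.sample(10, np.random.default_rng(0))).size == 1

    def test_boundary_beta_is_structural(self):
        assert DistributionSpec("beta", 1.0, 0.0).is_fixed
        assert DistributionSpec("beta", 0.0, 0.0).is_fixed

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            DistributionSpec("gamma", 1.0, 1.0)


class TestProbabilityEstimation:
    def test_hand_count(self, hand_table):
        table = hand_table(
            [{"tested": i < 9,
              "test_result": "negative" if i < 9 else "not_applicable",
              "delabelled": i < 9, "branch":
                  "neg_nolabel_no_tf" if i < 9 else "no_test_no_tf"}
             for i in range(10)]
            + [{"arm": "usual_care", "tested": False,
                "test_result": "not_applicable", "delabelled": False,
                "branch": "no_test_no_tf"} for _ in range(5)])
        params = estimate_branch_probabilities(table)
        assert params["paap"].probabilities["p_test"].mean == pytest.approx(0.9)

    def test_all_tested_is_boundary_fixed(self, hand_table):
        table = hand_table(
            [{"tested": True} for _ in range(4)]
            + [{"arm": "usual_care", "tested": True} for _ in range(4)])
        spec = estimate_branch_probabilities(table)["paap"].probabilities["p_test"]
        assert spec.mean == 1.0 and spec.is_fixed

    def test_empty_arm_raises(self, hand_table):
        table = hand_table([{"arm": "paap"}])
        with pytest.raises(EstimationError):
            estimate_branch_probabilities(table)

    def test_se_option_smaller_than_sample_sd(self, medium_table):
        sd = estimate_branch_probabilities(medium_table, "sample_sd")
        se = estimate_branch_probabilities(medium_table, "se")
        assert (se["paap"].probabilities["p_test"].sd
                < sd["paap"].probabilities["p_test"].sd)


class TestPayoffEstimation:
    def test_single_member_branch_degenerate(self, hand_table):
        table = hand_table(
            [{"branch": "neg_nolabel_no_tf"},
             {"arm": "usual_care", "tested": False,
              "test_result": "not_applicable", "delabelled": False,
              "branch": "no_test_no_tf"}],
            years=[{"pid": "p000", "cost_total": 1234.5, "utility": 0.7},
                   {"pid": "p001", "cost_total": 99.0, "utility": 0.6}])
        params = estimate_branch_payoffs(table)
        ap = params["paap"]
        assert ap.costs["neg_nolabel_no_tf"].mean == pytest.approx(1234.5)
        assert ap.costs["neg_nolabel_no_tf"].sd == 0.0
        assert ap.provenance[("cost", "neg_nolabel_no_tf")] == \
            "degenerate-single-member"

    def test_reference_branch_mean_round_trips(self, hand_table):
        # two members straddling the reference mean 1176.55
        table = hand_table(
            [{"branch": "pos_label_no_tf", "test_result": "positive",
              "delabelled": False},
             {"branch": "pos_label_no_tf", "test_result": "positive",
              "delabelled": False},
             {"arm": "usual_care", "tested": False,
              "test_result": "not_applicable", "delabelled": False,
              "branch": "no_test_no_tf"}],
            years=[{"pid": "p000", "cost_total": 1000.0, "utility": 0.8},
                   {"pid": "p001", "cost_total": 1353.10, "utility": 0.8},
                   {"pid": "p002", "cost_total": 50.0, "utility": 0.9}])
        params = estimate_branch_payoffs(table)
        spec = params["paap"].costs["pos_label_no_tf"]
        assert spec.mean == pytest.approx(1176.55)

    def test_annualisation_applied_before_averaging(self, hand_table):
        table = hand_table(
            [{}, {"arm": "usual_care", "tested": False,
                  "test_result": "not_applicable", "delabelled": False,
                  "branch": "no_test_no_tf"}],
            years=[{"pid": "p000", "cost_total": 100.0,
                    "exposure_days": 182.5, "utility": 0.8},
                   {"pid": "p001", "cost_total": 10.0, "utility": 0.8}])
        params = estimate_branch_payoffs(table)
        assert params["paap"].costs["neg_nolabel_no_tf"].mean == \
            pytest.approx(200.0)


class TestMissingBranchSubstitution:
    def test_bundled_substitution_value(self, reference_params):
        uc = reference_params["usual_care"]
        assert uc.qalys["pos_label_no_tf"].mean == pytest.approx(0.980)
        assert uc.qalys["pos_label_no_tf"].sd == 0.0
        assert uc.provenance[("qaly", "pos_label_no_tf")] == "substituted"
        assert uc.costs["pos_label_no_tf"].mean == pytest.approx(839.63)

    def test_identity_when_nothing_missing(self, medium_table):
        params = estimate_branch_payoffs(medium_table)
        before = {b: s.mean for b, s in params["paap"].costs.items()
                  if s is not None}
        resolved = resolve_missing_branches(params)
        for b, m in before.items():
            assert resolved["paap"].costs[b].mean == m

    def test_engineered_empty_branch_takes_donor_value(self, hand_table):
        # PAAP has no pos_label_no_tf member; usual care does
        table = hand_table(
            [{"branch": "neg_nolabel_no_tf"},
             {"arm": "usual_care", "tested": True, "test_result": "positive",
              "delabelled": False, "branch": "pos_label_no_tf"},
             {"arm": "usual_care", "tested": False,
              "test_result": "not_applicable", "delabelled": False,
              "branch": "no_test_no_tf"}],
            years=[{"pid": "p000", "cost_total": 10.0, "utility": 0.8},
                   {"pid": "p001", "cost_total": 777.0, "utility": 0.66},
                   {"pid": "p002", "cost_total": 20.0, "utility": 0.9}])
        params = resolve_missing_branches(estimate_branch_payoffs(table))
        ap = params["paap"]
        # QALY donor: same branch, other arm (direct lookup oracle)
        assert ap.qalys["pos_label_no_tf"].mean == pytest.approx(0.66)
        assert ap.provenance[("qaly", "pos_label_no_tf")] == "substituted"

    def test_unresolvable_branch_raises(self, hand_table):
        table = hand_table(
            [{"branch": "neg_nolabel_no_tf"},
             {"arm": "usual_care", "branch": "neg_nolabel_no_tf"}],
            years=[{"pid": "p000", "cost_total": 1.0, "utility": 0.5},
                   {"pid": "p001", "cost_total": 1.0, "utility": 0.5}])
        params = estimate_branch_payoffs(table)
        # strip the fallback candidates to simulate a dead end
        params["paap"].substitutions = {
            k: {"candidates": [{"arm": "paap", "branch": "pos_label_tf"}]}
            for k in params["paap"].substitutions}
        with pytest.raises(EstimationError):
            resolve_missing_branches(params)


class TestCostRegression:
    def test_constant_costs_give_unit_multipliers(self, hand_table):
        table = hand_table(
            [{"delabelled": True}, {"delabelled": False},
             {"arm": "usual_care", "tested": False,
              "test_result": "not_applicable", "delabelled": False,
              "branch": "no_test_no_tf", "treatment_failure": True}],
            years=[{"pid": f"p{i:03d}", "year": y, "cost_total": 500.0,
                    "utility": 0.8}
                   for i in range(3) for y in (1, 2, 3)])
        reg = p.fit_post_year1_cost_model(table)
        assert reg.baseline == pytest.approx(500.0)
        assert reg.no_label_multiplier == pytest.approx(1.0)
        assert reg.tf_multiplier == pytest.approx(1.0)

    def test_no_later_records_raises(self, hand_table):
        with pytest.raises(EstimationError):
            p.fit_post_year1_cost_model(hand_table([{}]))

    def test_predict_composes_multipliers(self):
        reg = p.CostRegression(1000.0, 0.9, 1.5)
        assert reg.predict(label=True, tf=False) == 1000.0
        assert reg.predict(label=False, tf=True) == pytest.approx(1350.0)


class TestSerialization:
    def test_round_trip(self, medium_table, tmp_path):
        params = p.estimate_params(medium_table)
        path = tmp_path / "params.yaml"
        p.save_params(params, path)
        loaded = p.load_params(path)
        for arm in ("paap", "usual_care"):
            for name, spec in params[arm].probabilities.items():
                assert loaded[arm].probabilities[name].mean == \
                    pytest.approx(spec.mean)
            for b, spec in params[arm].costs.items():
                assert loaded[arm].costs[b].mean == pytest.approx(spec.mean)

    def test_reference_file_loads_resolved(self, reference_params):
        assert reference_params.is_resolved()
        assert reference_params["paap"].n == 401
        assert reference_params["usual_care"].n == 410
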