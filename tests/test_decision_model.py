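import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import paapcea as p
from paapcea.decision_model import BRANCH_STATES, end_of_year1_states
from paapcea.parameter_engine import (
    ArmParams,
    BranchParams,
    DistributionSpec,
    TERMINAL_BRANCHES,
)


def build_params(prob_overrides=None, cost=100.0, qaly=0.8):
    """Minimal two-arm parameter set with uniform payoffs."""
    arms = {}
    for arm in ("paap", "usual_care"):
        probs = {"p_test": 0.5, "p_positive": 0.5, "p_delabel_pos": 0.0,
                 "p_delabel_neg": 0.5, "tf_pos_label": 0.5,
                 "tf_neg_label": 0.5, "tf_neg_nolabel": 0.5,
                 "tf_no_test": 0.5}
        probs.update((prob_overrides or {}).get(arm, {}))
        arms[arm] = ArmParams(
            probabilities={k: DistributionSpec("fixed", v)
                           for k, v in probs.items()},
            costs={b: DistributionSpec("fixed", cost)
                   for b in TERMINAL_BRANCHES},
            qalys={b: DistributionSpec("fixed", qaly)
                   for b in TERMINAL_BRANCHES},
        )
    return BranchParams(arms=arms)


prob_floats = st.floats(0.0, 1.0)


class TestPathEnumeration:
    def test_reference_paap_probabilities(self, reference_params):
        probs = dict(p.enumerate_paths(reference_params, "paap"))
        # hand multiplication: 0.910*0.918*0.973*0.911
        assert probs["neg_nolabel_no_tf"] == pytest.approx(0.74048, abs=1e-5)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_reference_usual_care_probabilities(self, reference_params):
        probs = dict(p.enumerate_paths(reference_params, "usual_care"))
        assert probs["no_test_tf"] + probs["no_test_no_tf"] == \
            pytest.approx(0.988, abs=1e-12)
        assert probs["no_test_tf"] == pytest.approx(0.11263, abs=1e-5)

    def test_degenerate_probabilities_single_path(self):
        params = build_params({"paap": {"p_test": 1.0, "p_positive": 0.0,
                                        "p_delabel_neg": 1.0,
                                        "tf_neg_nolabel": 1.0}})
        probs = dict(p.enumerate_paths(params, "paap"))
        assert probs["neg_nolabel_tf"] == pytest.approx(1.0)
        assert sum(v for k, v in probs.items() if k != "neg_nolabel_tf") == 0.0

    @given(ps=st.lists(prob_floats, min_size=8, max_size=8))
    def test_conservation_over_random_parameters(self, ps):
        names = ["p_test", "p_positive", "p_delabel_pos", "p_delabel_neg",
                 "tf_pos_label", "tf_neg_label", "tf_neg_nolabel",
                 "tf_no_test"]
        params = build_params({"paap": dict(zip(names, ps))})
        total = sum(pr for _, pr in p.enumerate_paths(params, "paap"))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestYear1Payoffs:
    def test_reference_values_match_enumeration_oracle(self, reference_params,
                                                       econ):
        # independent oracle: explicit loop over the eight payoff branches
        for arm, exp_cost, exp_qaly in [("paap", 1390.1, 0.8704),
                                        ("usual_care", 1297.8, 0.8400)]:
            ap = reference_params[arm]
            probs = dict(p.enumerate_paths(reference_params, arm))
            oracle_cost = sum(probs[b] * ap.costs[b].mean
                              for b in TERMINAL_BRANCHES)
            oracle_qaly = sum(probs[b] * ap.qalys[b].mean
                              for b in TERMINAL_BRANCHES)
            cost, qaly = p.expected_year1_payoffs(reference_params, arm, econ)
            assert cost == pytest.approx(oracle_cost, rel=1e-12)
            assert qaly == pytest.approx(oracle_qaly, rel=1e-12)
            assert cost == pytest.approx(exp_cost, abs=0.1)
            assert qaly == pytest.approx(exp_qaly, abs=1e-4)

    def test_exposure_fraction_scales_payoffs(self, reference_params):
        full = p.expected_year1_payoffs(reference_params, "paap",
                                        p.EconConfig())
        half = p.expected_year1_payoffs(
            reference_params, "paap",
            p.EconConfig(year1_exposure_fraction=0.5))
        assert half[0] == pytest.approx(full[0] / 2)
        assert half[1] == pytest.approx(full[1] / 2)

    def test_degenerate_path_returns_branch_payoff(self):
        params = build_params({"paap": {"p_test": 0.0, "tf_no_test": 1.0}},
                              cost=321.0, qaly=0.77)
        cost, qaly = p.expected_year1_payoffs(params, "paap", p.EconConfig())
        assert cost == pytest.approx(321.0)
        assert qaly == pytest.approx(0.77)


class TestEndOfYear1States:
    def test_reference_no_label_mass(self, reference_params):
        s = end_of_year1_states(reference_params, "paap")
        assert s.p_no_label() == pytest.approx(0.910 * 0.918 * 0.973,
                                               abs=1e-12)
        s = end_of_year1_states(reference_params, "usual_care")
        assert s.p_no_label() == pytest.approx(0.0096, abs=1e-12)

    def test_mass_concentrates_when_all_delabelled(self):
        params = build_params({"paap": {"p_test": 1.0, "p_positive": 0.0,
                                        "p_delabel_neg": 1.0,
                                        "tf_neg_nolabel": 0.0}})
        s = end_of_year1_states(params, "paap")
        assert s.probs[(False, False)] == pytest.approx(1.0)


class TestAnnuityFactor:
    def test_zero_rate_counts_years(self):
        assert p.annuity_factor(0.0, 2, 5) == pytest.approx(4.0)

    def test_reference_rate_direct_sum(self):
        direct = sum(1.035 ** -(t - 1) for t in range(2, 6))
        assert p.annuity_factor(0.035, 2, 5) == pytest.approx(direct,
                                                              abs=1e-12)
        assert p.annuity_factor(0.035, 2, 5) == pytest.approx(3.673080,
                                                              abs=1e-6)

    def test_single_year(self):
        assert p.annuity_factor(0.035, 2, 2) == pytest.approx(0.966184,
                                                              abs=1e-6)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            p.annuity_factor(0.035, 1, 5)


class TestExtrapolation:
    def test_constant_qaly_times_annuity(self, reference_params, cost_reg):
        config = p.EconConfig()
        traj = p.extrapolate(reference_params, "paap", cost_reg, config)
        years2to5 = traj.discounted_qaly_total - traj.year1_qaly
        assert years2to5 == pytest.approx(
            traj.year1_qaly * p.annuity_factor(0.035, 2, 5), rel=1e-12)

    def test_published_qaly_row_closes(self):
        # annual QALY 0.422 over discounted years 2-5 reproduces the printed
        # usual-care 1.549 within rounding of the printed inputs
        assert 0.422 * p.annuity_factor(0.035, 2, 5) == pytest.approx(
            1.549, rel=1e-3)

    def test_unit_multipliers_give_flat_baseline(self, reference_params):
        reg = p.CostRegression(700.0, 1.0, 1.0)
        traj = p.extrapolate(reference_params, "paap", reg, p.EconConfig())
        assert traj.discounted_cost_total - traj.year1_cost == pytest.approx(
            700.0 * p.annuity_factor(0.035, 2, 5), rel=1e-12)

    def test_zero_discount_adds_plain_years(self, reference_params):
        reg = p.CostRegression(500.0, 1.0, 1.0)
        config = p.EconConfig(discount_rate=0.0)
        traj = p.extrapolate(reference_params, "paap", reg, config)
        assert traj.discounted_cost_total - traj.year1_cost == \
            pytest.approx(2000.0)

    def test_trajectory_identity(self, reference_params, cost_reg, econ):
        traj = p.extrapolate(reference_params, "usual_care", cost_reg, econ)
        weights = [(1 + econ.discount_rate) ** -(t - 1) for t in range(2, 6)]
        manual = traj.year1_cost + float(
            np.dot(weights, traj.annual_costs))
        assert traj.discounted_cost_total == pytest.approx(manual, rel=1e-12)
        assert all(0 <= q <= 1 for q in traj.annual_qalys)


class TestMarkovRelabelling:
    def test_rate_zero_equals_extrapolate(self, reference_params, cost_reg,
                                          econ):
        a = p.extrapolate(reference_params, "paap", cost_reg, econ)
        b = p.markov_relabel(reference_params, "paap", cost_reg, 0.0, econ)
        assert b.discounted_cost_total == pytest.approx(
            a.discounted_cost_total, abs=1e-10)
        assert b.discounted_qaly_total == pytest.approx(
            a.discounted_qaly_total, abs=1e-10)

    def test_rate_one_hand_chain_oracle(self, reference_params, cost_reg):
        config = p.EconConfig()
        traj = p.markov_relabel(reference_params, "paap", cost_reg, 1.0,
                                config)
        # hand-run chain: from year 2 every de-labelled patient is labelled
        probs = dict(p.enumerate_paths(reference_params, "paap"))
        ap = reference_params["paap"]
        cost_y = sum(pr * cost_reg.predict(True, BRANCH_STATES[b][1])
                     for b, pr in probs.items())
        qaly_y = 0.0
        for b, pr in probs.items():
            label, tf = BRANCH_STATES[b]
            if label:
                q = ap.qalys[b].mean
            else:
                counterpart = b.replace("nolabel", "label")
                q = ap.qalys[counterpart].mean
            qaly_y += pr * q
        assert traj.annual_costs == pytest.approx([cost_y] * 4, rel=1e-12)
        assert traj.annual_qalys == pytest.approx([qaly_y] * 4, rel=1e-12)

    def test_relabelling_monotonically_erodes_paap_advantage(
            self, reference_params, cost_reg, econ):
        deltas = []
        for rate in (0.0, 0.2, 0.5, 0.8, 1.0):
            t = {arm: p.markov_relabel(reference_params, arm, cost_reg, rate,
                                       econ)
                 for arm in ("paap", "usual_care")}
            deltas.append((
                t["paap"].discounted_cost_total
                - t["usual_care"].discounted_cost_total,
                t["paap"].discounted_qaly_total
                - t["usual_care"].discounted_qaly_total))
        dcs, dqs = zip(*deltas)
        assert all(a < b for a, b in zip(dcs, dcs[1:]))
        assert all(a > b for a, b in zip(dqs, dqs[1:]))

    def test_six_month_rate_conversion(self):
        assert p.annual_from_6month_rate(0.066) == pytest.approx(0.12764,
                                                                 abs=1e-5)
        assert p.annual_from_6month_rate(0.0) == 0.0
        assert p.annual_from_6month_rate(1.0) == 1.0

    def test_invalid_rate_rejected(self, reference_params, cost_reg, econ):
        with pytest.raises(ValueError):
            p.markov_relabel(reference_params, "paap", cost_reg, 1.5, econ)


class TestRelabelThresholds:
    def test_cost_neutral_root_is_a_root(self, reference_params, cost_reg,
                                         econ):
        res = p.relabel_thresholds(reference_params, cost_reg, econ)
        assert res.cost_neutral_rate is not None
        t = {arm: p.markov_relabel(reference_params, arm, cost_reg,
                                   res.cost_neutral_rate, econ)
             for arm in ("paap", "usual_care")}
        dc = (t["paap"].discounted_cost_total
              - t["usual_care"].discounted_cost_total)
        assert abs(dc) < 0.05

    def test_no_crossing_reported_not_raised(self, reference_params,
                                             cost_reg, econ):
        res = p.relabel_thresholds(reference_params, cost_reg, econ,
                                   wtp=1e9)
        # at an enormous threshold the positive QALY gain keeps INMB > 0
        assert res.inmb_zero_rate is None
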