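"""Decision-tree model of penicillin allergy assessment and 5-year extrapolation.

The tree follows each strategy arm through four chance nodes: receive an
allergy test or not; test result (a *positive* result indicates the patient
is penicillin allergic); removal of the penicillin allergy label (PAL),
conditional on the result; and treatment failure during the first year,
conditional on (result, label) context.  Terminal branches carry first-year
cost and annual QALY payoffs.

Beyond year 1, annual QALYs are held constant at their year-1 value while
annual costs are predicted from a regression on 12-month label status and
year-1 treatment-failure status.  An optional two-state Markov chain
(no-label -> label, absorbing) relabels de-labelled patients during years
2..horizon at a constant annual rate.

All evaluation routines are written over a flat mapping of parameter values
that may hold scalars (deterministic run) or aligned arrays (one entry per
probabilistic-sensitivity draw), so the deterministic model and the PSA share
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .parameter_engine import (
    ARMS,
    TERMINAL_BRANCHES,
    BranchParams,
    CostRegression,
)

__all__ = [
    "EconConfig",
    "StateDistribution",
    "ArmTrajectory",
    "TREE_PATHS",
    "BRANCH_STATES",
    "enumerate_paths",
    "path_probabilities",
    "expected_year1_payoffs",
    "end_of_year1_states",
    "annuity_factor",
    "extrapolate",
    "markov_relabel",
    "relabel_thresholds",
    "annual_from_6month_rate",
    "arm_values",
    "evaluate_arm",
]


@dataclass(frozen=True)
class EconConfig:
    """Economic evaluation settings.

    ``year1_exposure_fraction`` scales the tree's expected year-1 payoffs
    (both costs and QALYs); the constant annual QALY carried into years
    2..horizon is the scaled year-1 value.  Year 1 is undiscounted; year t>=2
    is discounted by (1+d)^-(t-1).
    """

    discount_rate: float = 0.035
    horizon_years: int = 5
    wtp_grid: tuple = tuple(range(0, 50_001, 1_000))
    year1_exposure_fraction: float = 1.0
    psa_draws: int = 10_000
    seed: int = 20230

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if len(self.wtp_grid) == 0 or list(self.wtp_grid) != sorted(self.wtp_grid):
            raise ValueError("wtp_grid must be non-empty and ascending")
        if not 0 < self.year1_exposure_fraction <= 1:
            raise ValueError("year1_exposure_fraction must be in (0, 1]")


#: Symbolic tree: branch id -> sequence of (probability name, complement?)
#: edge factors.  The path probability is the product of factors, taking
#: 1 - p where complement is True.
TREE_PATHS = {
    "pos_label_tf": (("p_test", False), ("p_positive", False),
                     ("p_delabel_pos", True), ("tf_pos_label", False)),
    "pos_label_no_tf": (("p_test", False), ("p_positive", False),
                        ("p_delabel_pos", True), ("tf_pos_label", True)),
    "pos_nolabel_tf": (("p_test", False), ("p_positive", False),
                       ("p_delabel_pos", False), ("tf_pos_nolabel", False)),
    "pos_nolabel_no_tf": (("p_test", False), ("p_positive", False),
                          ("p_delabel_pos", False), ("tf_pos_nolabel", True)),
    "neg_label_tf": (("p_test", False), ("p_positive", True),
                     ("p_delabel_neg", True), ("tf_neg_label", False)),
    "neg_label_no_tf": (("p_test", False), ("p_positive", True),
                        ("p_delabel_neg", True), ("tf_neg_label", True)),
    "neg_nolabel_tf": (("p_test", False), ("p_positive", True),
                       ("p_delabel_neg", False), ("tf_neg_nolabel", False)),
    "neg_nolabel_no_tf": (("p_test", False), ("p_positive", True),
                          ("p_delabel_neg", False), ("tf_neg_nolabel", True)),
    "no_test_tf": (("p_test", True), ("tf_no_test", False)),
    "no_test_no_tf": (("p_test", True), ("tf_no_test", True)),
}

#: Branch -> (has PAL at 12 months, treatment failure in year 1).
BRANCH_STATES = {
    "pos_label_tf": (True, True),
    "pos_label_no_tf": (True, False),
    "pos_nolabel_tf": (False, True),
    "pos_nolabel_no_tf": (False, False),
    "neg_label_tf": (True, True),
    "neg_label_no_tf": (True, False),
    "neg_nolabel_tf": (False, True),
    "neg_nolabel_no_tf": (False, False),
    "no_test_tf": (True, True),
    "no_test_no_tf": (True, False),
}


def arm_values(params: BranchParams, arm: str) -> dict:
    """Flatten one arm's parameter means into an evaluation mapping."""
    ap = params[arm]
    if ap.missing_branches():
        raise ValueError(
            f"arm {arm!r} has unresolved branches: {ap.missing_branches()}")
    values = {name: spec.mean for name, spec in ap.probabilities.items()}
    for b in TERMINAL_BRANCHES:
        values[f"cost_{b}"] = ap.costs[b].mean
        values[f"qaly_{b}"] = ap.qalys[b].mean
    return values


def path_probabilities(values: dict) -> dict:
    """Per-branch path probability from an evaluation mapping.

    Works element-wise when the mapping holds arrays of draws.
    """
    probs = {}
    for branch, factors in TREE_PATHS.items():
        p = 1.0
        for name, complement in factors:
            v = values[name]
            p = p * (1.0 - v if complement else v)
        probs[branch] = p
    return probs


def enumerate_paths(params: BranchParams, arm: str) -> list[tuple[str, float]]:
    """All terminal branches with their path probabilities at parameter means."""
    probs = path_probabilities(arm_values(params, arm))
    return [(b, float(p)) for b, p in probs.items()]


def expected_year1_payoffs(
    params: BranchParams, arm: str, config: EconConfig
) -> tuple[float, float]:
    """Probability-weighted year-1 (cost, QALY), scaled by the exposure fraction."""
    values = arm_values(params, arm)
    probs = path_probabilities(values)
    f = config.year1_exposure_fraction
    cost = sum(p * values.get(f"cost_{b}", 0.0) for b, p in probs.items())
    qaly = sum(p * values.get(f"qaly_{b}", 0.0) for b, p in probs.items())
    return f * cost, f * qaly


@dataclass(frozen=True)
class StateDistribution:
    """End-of-year-1 state probabilities {(label, tf): p}; sums to 1."""

    probs: dict

    def __post_init__(self):
        total = sum(self.probs.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"state probabilities sum to {total}, not 1")
        if any(p < -1e-12 for p in self.probs.values()):
            raise ValueError("negative state probability")

    def p_no_label(self) -> float:
        return sum(p for (label, _), p in self.probs.items() if not label)


def end_of_year1_states(params: BranchParams, arm: str) -> StateDistribution:
    """Aggregate path probabilities by (label, treatment-failure) status."""
    probs = path_probabilities(arm_values(params, arm))
    states = {(lab, tf): 0.0 for lab in (True, False) for tf in (True, False)}
    for branch, p in probs.items():
        states[BRANCH_STATES[branch]] += p
    return StateDistribution(probs=states)


def annuity_factor(rate: float, first_year: int, last_year: int) -> float:
    """Sum of discount weights (1+rate)^-(t-1) for t = first..last (each >= 2)."""
    if not 2 <= first_year <= last_year:
        raise ValueError("require 2 <= first_year <= last_year")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return float(sum((1 + rate) ** -(t - 1)
                     for t in range(first_year, last_year + 1)))


@dataclass
class ArmTrajectory:
    """Per-year expected costs and QALYs for one arm over the horizon.

    ``annual_costs`` / ``annual_qalys`` are undiscounted values for years
    2..horizon; discounted totals include the undiscounted year-1 value.
    """

    year1_cost: float
    year1_qaly: float
    annual_costs: np.ndarray
    annual_qalys: np.ndarray
    discount_rate: float
    discounted_cost_total: float = field(init=False)
    discounted_qaly_total: float = field(init=False)

    def __post_init__(self):
        weights = np.array(
            [(1 + self.discount_rate) ** -(t - 1)
             for t in range(2, 2 + len(self.annual_costs))])
        self.discounted_cost_total = float(
            self.year1_cost + (weights * self.annual_costs).sum())
        self.discounted_qaly_total = float(
            self.year1_qaly + (weights * self.annual_qalys).sum())


def _relabel_masses(probs: dict, rate: float, year: int):
    """Split each branch's mass into (still de-labelled, relabelled) at year t.

    De-labelled mass decays by (1-rate) at the start of each year from year 2
    on; the label state is absorbing.  Branches whose members keep their
    label throughout contribute (full mass, 0).
    """
    retained = (1.0 - rate) ** (year - 1)
    stay, moved = {}, {}
    for branch, p in probs.items():
        label, _ = BRANCH_STATES[branch]
        if label:
            stay[branch], moved[branch] = p, 0.0
        else:
            stay[branch] = p * retained
            moved[branch] = p * (1.0 - retained)
    return stay, moved


def evaluate_arm(
    values: dict,
    reg: CostRegression,
    config: EconConfig,
    relabel_rate: float = 0.0,
):
    """Core model evaluation over an evaluation mapping (scalars or draws).

    Returns a dict with year-1 payoffs, per-year annual values and the
    discounted 5-year totals; every entry is a scalar or an array aligned
    with the input draws.
    """
    if not 0.0 <= relabel_rate <= 1.0:
        raise ValueError("relabel rate must lie in [0, 1]")
    probs = path_probabilities(values)
    f = config.year1_exposure_fraction
    cost1 = f * sum(p * values.get(f"cost_{b}", 0.0) for b, p in probs.items())
    qaly1 = f * sum(p * values.get(f"qaly_{b}", 0.0) for b, p in probs.items())

    annual_costs, annual_qalys = [], []
    cost_total = cost1
    qaly_total = qaly1
    for year in range(2, config.horizon_years + 1):
        stay, moved = _relabel_masses(probs, relabel_rate, year)
        cost_t = 0.0
        qaly_t = 0.0
        for branch in TREE_PATHS:
            label, tf = BRANCH_STATES[branch]
            q_branch = values.get(f"qaly_{branch}", 0.0)
            # a relabelled patient takes on the labelled counterpart of
            # their branch (same test result and TF status); where that
            # branch is a structural zero, the arm's untested profile
            q_counterpart = values.get(
                f"qaly_{branch.replace('nolabel', 'label')}", 0.0)
            q_untested = values.get(
                "qaly_no_test_tf" if tf else "qaly_no_test_no_tf", 0.0)
            q_relabel = np.where(np.asarray(q_counterpart) > 0,
                                 q_counterpart, q_untested)
            cost_t = cost_t + stay[branch] * reg.predict(label, tf, year)
            cost_t = cost_t + moved[branch] * reg.predict(True, tf, year)
            qaly_t = qaly_t + f * (stay[branch] * q_branch
                                   + moved[branch] * q_relabel)
        weight = (1 + config.discount_rate) ** -(year - 1)
        annual_costs.append(cost_t)
        annual_qalys.append(qaly_t)
        cost_total = cost_total + weight * cost_t
        qaly_total = qaly_total + weight * qaly_t
    return {
        "year1_cost": cost1,
        "year1_qaly": qaly1,
        "annual_costs": annual_costs,
        "annual_qalys": annual_qalys,
        "discounted_cost_total": cost_total,
        "discounted_qaly_total": qaly_total,
    }


def extrapolate(
    params: BranchParams,
    arm: str,
    reg: CostRegression,
    config: EconConfig,
) -> ArmTrajectory:
    """Extrapolate one arm to the horizon with no relabelling.

    Annual costs for years 2..horizon come from the (label, TF) state mix
    fixed at its end-of-year-1 value; annual QALYs are constant at the
    year-1 value.
    """
    states = end_of_year1_states(params, arm)
    cost1, qaly1 = expected_year1_payoffs(params, arm, config)
    years = range(2, config.horizon_years + 1)
    annual_costs = np.array(
        [sum(p * reg.predict(label, tf, year)
             for (label, tf), p in states.probs.items())
         for year in years])
    annual_qalys = np.full(len(annual_costs), qaly1)
    return ArmTrajectory(cost1, qaly1, annual_costs, annual_qalys,
                         config.discount_rate)


def markov_relabel(
    params: BranchParams,
    arm: str,
    reg: CostRegression,
    annual_relabel_rate: float,
    config: EconConfig,
) -> ArmTrajectory:
    """Extrapolate with an absorbing no-label -> label chain in years 2..horizon.

    Each year, de-labelled patients are relabelled with the given annual
    probability; on relabelling, their annual cost reverts to the labelled
    prediction and their annual QALY to the untested branch mean of their
    arm (matched on treatment-failure status).  Rate 0 reproduces
    :func:`extrapolate`.
    """
    out = evaluate_arm(arm_values(params, arm), reg, config,
                       relabel_rate=annual_relabel_rate)
    return ArmTrajectory(
        out["year1_cost"], out["year1_qaly"],
        np.array(out["annual_costs"], dtype=float),
        np.array(out["annual_qalys"], dtype=float),
        config.discount_rate)


def annual_from_6month_rate(rate_6m: float) -> float:
    """Convert a 6-month relabelling probability to an annual one."""
    if not 0 <= rate_6m <= 1:
        raise ValueError("6-month rate must lie in [0, 1]")
    return 1.0 - (1.0 - rate_6m) ** 2


@dataclass(frozen=True)
class ThresholdResult:
    """Relabelling-rate roots; ``None`` where no sign change exists in [0, 1]."""

    cost_neutral_rate: float | None
    inmb_zero_rate: float | None
    wtp: float


def relabel_thresholds(
    params: BranchParams,
    reg: CostRegression,
    config: EconConfig,
    wtp: float = 20_000.0,
    xtol: float = 1e-6,
) -> ThresholdResult:
    """Annual relabelling rates at which PAAP stops saving costs / INMB hits 0.

    The chain is applied to both arms.  Roots are found by bisection on
    [0, 1]; absence of a sign change is reported, not raised.
    """

    def deltas(rate: float) -> tuple[float, float]:
        t = {a: markov_relabel(params, a, reg, rate, config) for a in ARMS}
        dc = (t["paap"].discounted_cost_total
              - t["usual_care"].discounted_cost_total)
        dq = (t["paap"].discounted_qaly_total
              - t["usual_care"].discounted_qaly_total)
        return dc, dq

    def solve(fn) -> float | None:
        lo, hi = fn(0.0), fn(1.0)
        if lo == 0.0:
            return 0.0
        if np.sign(lo) == np.sign(hi):
            return None
        return float(optimize.brentq(fn, 0.0, 1.0, xtol=xtol, maxiter=100))

    cost_root = solve(lambda r: deltas(r)[0])
    inmb_root = solve(lambda r: (lambda dc, dq: wtp * dq - dc)(*deltas(r)))
    return ThresholdResult(cost_neutral_rate=cost_root,
                           inmb_zero_rate=inmb_root, wtp=wtp)
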