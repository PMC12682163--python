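"""Value-of-information analysis.

Quantifies the expected payoff of further research on top of a completed
probabilistic sensitivity analysis: EVPI (perfect information on everything),
per-parameter EVPPI via flexible one-dimensional regression, EVSI for a
hypothetical follow-on two-arm trial via regression on simulated trial
summary statistics, linear trial cost/duration models, population scaling
over a multi-year eligible cohort, and expected-net-benefit-of-sampling
(ENBS) optimisation over candidate sample sizes.

With only two strategies the net-benefit framework reduces to the
incremental net benefit INB: for any information structure X,

    value of X = E[max(E[INB | X], 0)] - max(E[INB], 0)

with X the parameter itself (EVPPI), the trial summary statistic (EVSI), or
INB itself (EVPI).  Conditional expectations are estimated by regression on
the PSA draws, the accepted desk-scale approach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures

from . import reference
from .cea_engine import PSADraws, inmb
from .decision_model import BRANCH_STATES, path_probabilities

__all__ = [
    "TrialDesign",
    "PopulationModel",
    "evpi",
    "evppi_single",
    "evppi_ranking",
    "evppi_summary",
    "evsi",
    "trial_cost",
    "trial_duration",
    "population_value",
    "enbs_optimize",
    "sample_size_two_proportions",
    "default_trial_design",
]


def _fit_line(points):
    (x1, y1), (x2, y2) = points
    slope = (y2 - y1) / (x2 - x1)
    return y1 - slope * x1, slope


_COST_INTERCEPT, _COST_SLOPE = _fit_line(reference.TRIAL_COST_ANCHORS)
_DUR_INTERCEPT, _DUR_SLOPE = _fit_line(reference.TRIAL_DURATION_ANCHORS)


@dataclass(frozen=True)
class TrialDesign:
    """A candidate follow-on two-arm trial.

    ``endpoints`` is 'clinical' (per-arm treatment-failure counts only) or
    'full' (additionally per-arm mean cost and mean utility).  Cost and
    duration are linear in n; the defaults are calibrated to the published
    (769 participants, 1.76M GBP, 30 months) and (1267, 2.37M, 46) anchors.
    The residual SDs describe individual-level noise of the cost and utility
    endpoints around their arm means.
    """

    n_participants: int = 1267
    allocation: float = 0.5
    endpoints: str = "clinical"
    cost_fixed: float = _COST_INTERCEPT
    cost_per_participant: float = _COST_SLOPE
    months_fixed: float = _DUR_INTERCEPT
    months_per_participant: float = _DUR_SLOPE
    residual_cost_sd: float = 2900.0
    residual_utility_sd: float = 0.27

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if not 0 < self.allocation < 1:
            raise ValueError("allocation must be in (0, 1)")
        if self.endpoints not in ("clinical", "full"):
            raise ValueError("endpoints must be 'clinical' or 'full'")
        if min(self.cost_fixed, self.cost_per_participant) < 0:
            raise ValueError("trial costs must be >= 0")

    def with_n(self, n: int) -> "TrialDesign":
        from dataclasses import replace

        return replace(self, n_participants=int(n))


@dataclass(frozen=True)
class PopulationModel:
    """Eligible population over the decision horizon, accrued uniformly."""

    total: float = float(reference.VOI_ANCHORS["eligible_population_10y"])
    horizon_years: int = 10
    discount_rate: float = 0.035

    def __post_init__(self):
        if self.total < 0 or self.horizon_years < 1:
            raise ValueError("invalid population model")


def _information_value(inb: np.ndarray, conditional_mean: np.ndarray) -> float:
    value = float(np.maximum(conditional_mean, 0.0).mean()
                  - max(float(inb.mean()), 0.0))
    return max(value, 0.0)


def evpi(draws: PSADraws, wtp: float) -> float:
    """Per-patient expected value of perfect information at threshold wtp."""
    if draws.n_draws == 0:
        raise ValueError("no PSA draws")
    inb = inmb(draws.delta_cost, draws.delta_qaly, wtp)
    return _information_value(inb, inb)


def _poly_regress(inb: np.ndarray, X: np.ndarray, degree: int) -> np.ndarray:
    # z-score before expansion: polynomial terms of raw GBP-scale and
    # probability-scale columns otherwise make the design ill-conditioned
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    feats = PolynomialFeatures(degree=degree, include_bias=False)
    model = LinearRegression()
    model.fit(feats.fit_transform(Z), inb)
    return model.predict(feats.transform(Z))


def evppi_single(
    draws: PSADraws, parameter_id: str, wtp: float, degree: int = 3
) -> float:
    """Per-patient EVPPI of one parameter by basis-expansion regression.

    The incremental net benefit is regressed on a polynomial basis of the
    parameter's draws; the fitted values estimate E[INB | parameter].  A
    parameter that does not vary has EVPPI 0.  The result is clipped to
    [0, EVPI].
    """
    x = draws.parameters[parameter_id].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        return 0.0
    inb = inmb(draws.delta_cost, draws.delta_qaly, wtp)
    fitted = _poly_regress(inb, x[:, None], degree)
    return min(_information_value(inb, fitted), evpi(draws, wtp))


def evppi_ranking(
    draws: PSADraws, wtp: float, degree: int = 3, top: int | None = None
) -> pd.DataFrame:
    """EVPPI for every varying parameter, sorted descending."""
    rows = []
    for col in draws.parameters.columns:
        if np.ptp(draws.parameters[col].to_numpy()) == 0.0:
            continue
        rows.append({"parameter": col,
                     "evppi": evppi_single(draws, col, wtp, degree)})
    out = pd.DataFrame(rows).sort_values(
        "evppi", ascending=False, ignore_index=True)
    return out.head(top) if top else out


def _arm_param_values(draws: PSADraws, arm: str) -> dict:
    prefix = f"{arm}:"
    return {c[len(prefix):]: draws.parameters[c].to_numpy()
            for c in draws.parameters.columns if c.startswith(prefix)}


def _true_summary_means(draws: PSADraws) -> np.ndarray:
    """Per-draw expectations of the trial summary statistics.

    Columns: difference in overall first-year treatment-failure probability,
    difference in expected year-1 cost, difference in expected year-1
    utility (PAAP minus usual care).
    """
    cols = []
    tf_probs = {}
    for arm in ("paap", "usual_care"):
        values = _arm_param_values(draws, arm)
        probs = path_probabilities(values)
        tf_probs[arm] = sum(p for b, p in probs.items()
                            if BRANCH_STATES[b][1])
    cols.append(tf_probs["paap"] - tf_probs["usual_care"])
    res = draws.results
    cols.append((res["year1_cost_paap"] - res["year1_cost_usual_care"])
                .to_numpy())
    cols.append((res["year1_qaly_paap"] - res["year1_qaly_usual_care"])
                .to_numpy())
    return np.column_stack(cols)


def evppi_summary(draws: PSADraws, wtp: float, endpoints: str = "clinical",
                  degree: int = 2) -> float:
    """EVPPI of the parameter set a follow-on trial would inform.

    This is the large-sample limit of :func:`evsi`: the value of knowing the
    true arm-level treatment-failure difference (clinical) plus the true
    year-1 cost and utility differences (full).
    """
    means = _true_summary_means(draws)
    X = means[:, :1] if endpoints == "clinical" else means
    inb = inmb(draws.delta_cost, draws.delta_qaly, wtp)
    fitted = _poly_regress(inb, X, degree)
    return min(_information_value(inb, fitted), evpi(draws, wtp))


def evsi(
    draws: PSADraws,
    design: TrialDesign,
    wtp: float,
    seed: int = 0,
    degree: int = 2,
) -> float:
    """Per-patient expected value of sample information for one trial design.

    For each PSA draw, a hypothetical trial outcome is simulated conditional
    on that draw's parameters: per-arm treatment-failure counts (binomial)
    and, for full endpoints, noisy per-arm mean cost and utility.  The
    incremental net benefit is regressed on the summary statistics; the
    fitted values estimate E[INB | trial data], giving the EVSI by the
    positive-part identity.  EVSI(0) = 0 and EVSI(n) approaches the EVPPI of
    the informed summary set as n grows.
    """
    if design.n_participants == 0:
        return 0.0
    rng = np.random.default_rng([seed, design.n_participants])
    n_paap = max(int(round(design.n_participants * design.allocation)), 1)
    n_uc = max(design.n_participants - n_paap, 1)
    means = _true_summary_means(draws)

    tf_probs = {}
    for arm in ("paap", "usual_care"):
        values = _arm_param_values(draws, arm)
        probs = path_probabilities(values)
        tf_probs[arm] = np.clip(
            sum(p for b, p in probs.items() if BRANCH_STATES[b][1]), 0, 1)
    x_paap = rng.binomial(n_paap, tf_probs["paap"]) / n_paap
    x_uc = rng.binomial(n_uc, tf_probs["usual_care"]) / n_uc
    summaries = [x_paap - x_uc]
    if design.endpoints == "full":
        summaries.append(means[:, 1]
                         + rng.normal(0.0, design.residual_cost_sd
                                      * np.sqrt(1 / n_paap + 1 / n_uc),
                                      draws.n_draws))
        summaries.append(means[:, 2]
                         + rng.normal(0.0, design.residual_utility_sd
                                      * np.sqrt(1 / n_paap + 1 / n_uc),
                                      draws.n_draws))
    X = np.column_stack(summaries)
    inb = inmb(draws.delta_cost, draws.delta_qaly, wtp)
    fitted = _poly_regress(inb, X, degree)
    return min(_information_value(inb, fitted), evpi(draws, wtp))


def trial_cost(design: TrialDesign, n: int | None = None) -> float:
    """Total cost (GBP) of running the trial: fixed + per-participant * n."""
    n = design.n_participants if n is None else n
    if n < 0:
        raise ValueError("n must be >= 0")
    return design.cost_fixed + design.cost_per_participant * n


def trial_duration(design: TrialDesign, n: int | None = None) -> float:
    """Months to complete the trial: fixed + months-per-participant * n."""
    n = design.n_participants if n is None else n
    if n < 0:
        raise ValueError("n must be >= 0")
    return design.months_fixed + design.months_per_participant * n


def population_value(per_patient: float, pop: PopulationModel) -> float:
    """Scale a per-patient information value to the eligible population.

    Uniform annual cohorts of total/horizon accrue from year 1, discounted
    with the same (1+d)^-(t-1) convention as the model.
    """
    cohort = pop.total / pop.horizon_years
    weights = sum((1 + pop.discount_rate) ** -(t - 1)
                  for t in range(1, pop.horizon_years + 1))
    return per_patient * cohort * weights


def enbs_optimize(
    draws: PSADraws,
    design: TrialDesign,
    pop: PopulationModel,
    wtp: float,
    n_grid=None,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Expected net benefit of sampling over a grid of trial sizes.

    ENBS(n) = population_value(EVSI(n)) - trial_cost(n).  Returns the argmax
    and the full curve; if ENBS is negative everywhere the optimum is n = 0
    (do not run the trial).
    """
    n_grid = list(n_grid) if n_grid is not None else list(range(50, 2001, 50))
    rows = []
    for n in n_grid:
        per_patient = evsi(draws, design.with_n(n), wtp, seed=seed)
        rows.append({
            "n": n,
            "evsi_per_patient": per_patient,
            "population_evsi": population_value(per_patient, pop),
            "trial_cost": trial_cost(design, n),
        })
    curve = pd.DataFrame(rows)
    curve["enbs"] = curve["population_evsi"] - curve["trial_cost"]
    if (curve["enbs"] <= 0).all():
        return 0, curve
    return int(curve.loc[curve["enbs"].idxmax(), "n"]), curve


def sample_size_two_proportions(
    p1: float, p2: float, power: float = 0.9, alpha: float = 0.05
) -> int:
    """Per-arm n to detect p1 vs p2, normal approximation, two-sided alpha."""
    for name, v in (("p1", p1), ("p2", p2)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = ((z_a + z_b) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2))
         / (p1 - p2) ** 2)
    return int(np.ceil(n))


def default_trial_design(**overrides) -> TrialDesign:
    return TrialDesign(**overrides)
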