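"""Model-parameter estimation and distribution handling.

The decision model is driven by a set of per-arm parameters: branch
probabilities of the allergy-testing decision tree, first-year cost payoffs
and annual QALY payoffs for each terminal branch, and a post-year-1 annual
cost regression used for extrapolation.  Each uncertain parameter is stored
as a :class:`DistributionSpec` — a (family, mean, sd) triple on the natural
scale — and converted to a sampling distribution by method-of-moments when
the probabilistic sensitivity analysis draws from it.

Parameters can either be loaded from a bundled reference file (the published
ALABAMA trial estimates) or re-estimated from individual-level trial data
produced by :mod:`paapcea.synthetic_trial`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

__all__ = [
    "ARMS",
    "TERMINAL_BRANCHES",
    "TF_CONTEXTS",
    "DistributionSpec",
    "ArmParams",
    "BranchParams",
    "CostRegression",
    "EstimationError",
    "annualize",
    "beta_from_moments",
    "lognormal_from_moments",
    "estimate_branch_probabilities",
    "estimate_branch_payoffs",
    "estimate_params",
    "resolve_missing_branches",
    "fit_post_year1_cost_model",
    "load_params",
    "save_params",
    "load_reference_params",
    "default_cost_regression",
]

ARMS = ("paap", "usual_care")

#: Terminal branches of the decision tree carrying a payoff row.  The
#: positive-and-delabelled pair exists in the tree but has structural
#: probability zero (allergy labels are never removed after a positive test).
TERMINAL_BRANCHES = (
    "pos_label_tf",
    "pos_label_no_tf",
    "neg_label_tf",
    "neg_label_no_tf",
    "neg_nolabel_tf",
    "neg_nolabel_no_tf",
    "no_test_tf",
    "no_test_no_tf",
)

STRUCTURAL_ZERO_BRANCHES = ("pos_nolabel_tf", "pos_nolabel_no_tf")

#: Contexts on which the first-year treatment-failure probability is
#: conditioned: (test result, label status at 12 months) or no test.
TF_CONTEXTS = ("pos_label", "neg_label", "neg_nolabel", "no_test")

PROBABILITY_NAMES = (
    "p_test",
    "p_positive",
    "p_delabel_pos",
    "p_delabel_neg",
    "tf_pos_label",
    "tf_neg_label",
    "tf_neg_nolabel",
    "tf_no_test",
    "tf_pos_nolabel",
)


class EstimationError(ValueError):
    """Raised when parameters cannot be estimated from the data provided."""


def annualize(value, exposure_days):
    """Scale a cost observed over a partial year to a full-year equivalent.

    ``value * 365 / exposure_days`` — the censoring adjustment applied to all
    observed annual costs before they enter estimation.
    """
    exposure = np.asarray(exposure_days, dtype=float)
    if np.any(exposure <= 0) or np.any(exposure > 366):
        raise ValueError("exposure_days must lie in (0, 366]")
    return np.asarray(value, dtype=float) * 365.0 / exposure


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta parameters (alpha, beta) for a given mean/sd.

    alpha = mean*nu, beta = (1-mean)*nu with nu = mean(1-mean)/sd^2 - 1.
    The resulting Beta(alpha, beta) has exactly the requested moments.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mean}")
    if sd <= 0.0:
        raise ValueError("sd must be positive; use family='fixed' for sd=0")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments for beta: sd^2={sd * sd:.6g} >= "
            f"mean(1-mean)={mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments lognormal parameters (mu, sigma) on the log scale.

    sigma^2 = ln(1 + sd^2/mean^2); mu = ln(mean) - sigma^2/2, so that
    exp(mu + sigma^2/2) equals ``mean`` exactly.
    """
    if mean <= 0.0:
        raise ValueError(f"lognormal mean must be positive, got {mean}")
    if sd <= 0.0:
        raise ValueError("sd must be positive; use family='fixed' for sd=0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain model parameter: (family, mean, sd) on the natural scale.

    family 'beta' for probabilities and utilities, 'lognormal' for costs,
    'fixed' for structural constants (sd is ignored and the parameter is
    excluded from probabilistic analysis).
    """

    family: str
    mean: float
    sd: float = 0.0

    def __post_init__(self):
        if self.family not in ("beta", "lognormal", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "beta":
            if not 0.0 <= self.mean <= 1.0:
                raise ValueError(f"beta mean {self.mean} outside [0,1]")
            if self.sd > 0 and self.sd**2 >= self.mean * (1 - self.mean):
                raise ValueError(
                    f"beta sd {self.sd} infeasible for mean {self.mean}"
                )
        if self.family == "lognormal" and self.mean < 0:
            raise ValueError(f"lognormal mean {self.mean} negative")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def is_fixed(self) -> bool:
        """Structural constants and boundary/degenerate values do not vary."""
        return (
            self.family == "fixed"
            or self.sd == 0.0
            or (self.family == "beta" and self.mean in (0.0, 1.0))
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.is_fixed:
            return np.full(n, self.mean)
        if self.family == "beta":
            a, b = beta_from_moments(self.mean, self.sd)
            return rng.beta(a, b, size=n)
        mu, sigma = lognormal_from_moments(self.mean, self.sd)
        return rng.lognormal(mu, sigma, size=n)


def _spec_or_fixed(family: str, mean: float, sd: float) -> DistributionSpec:
    """Build a spec, demoting zero-sd or boundary values to 'fixed'."""
    if sd == 0.0 or (family == "beta" and mean in (0.0, 1.0)):
        return DistributionSpec("fixed", mean, 0.0)
    return DistributionSpec(family, mean, sd)


@dataclass
class ArmParams:
    """Full parameter set for one strategy arm.

    ``costs`` / ``qalys`` entries may be ``None`` for tree branches with no
    observed members; such branches must appear in ``substitutions`` and are
    filled by :func:`resolve_missing_branches` before the model runs.
    """

    n: int | None = None
    probabilities: dict[str, DistributionSpec] = field(default_factory=dict)
    costs: dict[str, DistributionSpec | None] = field(default_factory=dict)
    qalys: dict[str, DistributionSpec | None] = field(default_factory=dict)
    #: ("cost"|"qaly", branch) -> substitution source: {"value": x} for an
    #: externally supplied number, {"arm": a, "branch": b} for a donor branch.
    substitutions: dict = field(default_factory=dict)
    #: ("cost"|"qaly", branch) -> provenance note ("observed", "substituted",
    #: "degenerate-single-member", ...)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probabilities.setdefault(
            "tf_pos_nolabel", DistributionSpec("fixed", 0.0)
        )

    def missing_branches(self) -> list[tuple[str, str]]:
        out = [("cost", b) for b, s in self.costs.items() if s is None]
        out += [("qaly", b) for b, s in self.qalys.items() if s is None]
        return out


@dataclass
class BranchParams:
    """Parameters for both arms plus shared metadata."""

    arms: dict[str, ArmParams]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, arm: str) -> ArmParams:
        return self.arms[arm]

    def is_resolved(self) -> bool:
        return all(not a.missing_branches() for a in self.arms.values())

    def iter_uncertain(self):
        """Yield (arm, kind, name, spec) for every non-fixed parameter."""
        for arm, ap in self.arms.items():
            for name, spec in ap.probabilities.items():
                if not spec.is_fixed:
                    yield arm, "prob", name, spec
            for branch, spec in ap.costs.items():
                if spec is not None and not spec.is_fixed:
                    yield arm, "cost", branch, spec
            for branch, spec in ap.qalys.items():
                if spec is not None and not spec.is_fixed:
                    yield arm, "qaly", branch, spec


@dataclass(frozen=True)
class CostRegression:
    """Post-year-1 annual cost model used for years 2..horizon.

    Annual cost = baseline * no_label_multiplier^(1 - label)
                * tf_multiplier^tf * year_drift^(year - 2)

    where ``label`` is penicillin-allergy-label status at 12 months and
    ``tf`` is treatment failure during year 1.  ``no_label_multiplier`` < 1
    encodes the observed saving from de-labelling; ``tf_multiplier`` > 1 the
    excess cost of early treatment failure.
    """

    baseline: float
    no_label_multiplier: float
    tf_multiplier: float
    year_drift: float = 1.0

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline annual cost must be positive")
        if min(self.no_label_multiplier, self.tf_multiplier, self.year_drift) <= 0:
            raise ValueError("multipliers must be positive")

    def predict(self, label: bool, tf: bool, year: int = 2) -> float:
        cost = self.baseline
        if not label:
            cost *= self.no_label_multiplier
        if tf:
            cost *= self.tf_multiplier
        return cost * self.year_drift ** (year - 2)


def default_cost_regression() -> CostRegression:
    """Reference post-year-1 cost model.

    Baseline 1450 GBP/year is calibrated so the usual-care state mix
    reproduces the observed second-year mean annual cost (~1519 GBP);
    de-labelled participants incur 8% lower and treatment-failure
    participants 42% higher annual costs, the midpoints of the observed
    6-11% and 39-46% effect bands.
    """
    return CostRegression(baseline=1450.0, no_label_multiplier=0.92,
                          tf_multiplier=1.42)


# ---------------------------------------------------------------------------
# Estimation from individual-level data
# ---------------------------------------------------------------------------


def _indicator_spec(flags: pd.Series, uncertainty: str) -> DistributionSpec:
    """Beta spec for a conditional proportion from a 0/1 indicator series."""
    n = len(flags)
    if n == 0:
        raise EstimationError("empty parent set for probability estimate")
    p = float(flags.mean())
    if p in (0.0, 1.0):
        return DistributionSpec("fixed", p, 0.0)
    if uncertainty == "se":
        sd = math.sqrt(p * (1 - p) / n)
    else:  # sample SD of the Bernoulli indicator
        sd = float(flags.std(ddof=1))
    sd = min(sd, math.sqrt(p * (1 - p)) * (1 - 1e-9))
    return DistributionSpec("beta", p, sd)


def estimate_branch_probabilities(
    table, uncertainty: str = "sample_sd"
) -> BranchParams:
    """Estimate tree branch probabilities as conditional sample proportions.

    ``uncertainty`` selects what is recorded as the sd: the sample SD of
    the branch indicator (default, matching the convention of the reference
    parameter table) or the binomial standard error ``sqrt(p(1-p)/n)``.
    """
    if uncertainty not in ("sample_sd", "se"):
        raise ValueError("uncertainty must be 'sample_sd' or 'se'")
    df = table.participants
    arms = {}
    for arm in ARMS:
        sub = df[df["arm"] == arm]
        if sub.empty:
            raise EstimationError(f"no participants in arm {arm!r}")
        tested = sub[sub["tested"]]
        pos = tested[tested["test_result"] == "positive"]
        neg = tested[tested["test_result"] == "negative"]
        untested = sub[~sub["tested"]]
        probs = {"p_test": _indicator_spec(sub["tested"].astype(float),
                                           uncertainty)}
        probs["p_positive"] = (
            _indicator_spec((tested["test_result"] == "positive").astype(float),
                            uncertainty)
            if len(tested) else DistributionSpec("fixed", 0.0)
        )
        probs["p_delabel_pos"] = (
            _indicator_spec(pos["delabelled"].astype(float), uncertainty)
            if len(pos) else DistributionSpec("fixed", 0.0)
        )
        probs["p_delabel_neg"] = (
            _indicator_spec(neg["delabelled"].astype(float), uncertainty)
            if len(neg) else DistributionSpec("fixed", 0.0)
        )
        ctx_sets = {
            "pos_label": pos[~pos["delabelled"]],
            "neg_label": neg[~neg["delabelled"]],
            "neg_nolabel": neg[neg["delabelled"]],
            "no_test": untested,
        }
        for ctx, members in ctx_sets.items():
            probs[f"tf_{ctx}"] = (
                _indicator_spec(members["treatment_failure"].astype(float),
                                uncertainty)
                if len(members) else DistributionSpec("fixed", 0.0)
            )
        arms[arm] = ArmParams(n=len(sub), probabilities=probs)
    return BranchParams(arms=arms, meta={"uncertainty": uncertainty})


def _payoff_specs(values: np.ndarray, family: str):
    """(spec, provenance) for a branch payoff sample; None if no members."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return None, "missing"
    mean = float(values.mean())
    if values.size == 1:
        return DistributionSpec("fixed", mean, 0.0), "degenerate-single-member"
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        return DistributionSpec("fixed", mean, 0.0), "observed"
    if family == "beta":
        if mean in (0.0, 1.0):
            return DistributionSpec("fixed", mean, 0.0), "observed"
        sd = min(sd, math.sqrt(mean * (1 - mean)) * (1 - 1e-9))
    if family == "lognormal" and mean == 0.0:
        return DistributionSpec("fixed", 0.0, 0.0), "observed"
    return DistributionSpec(family, mean, sd), "observed"


def estimate_branch_payoffs(
    table, params: BranchParams | None = None, uncertainty: str = "sample_sd"
) -> BranchParams:
    """Estimate per-branch first-year cost and annual QALY payoffs.

    First-year costs are annualised to the participant's year-1 exposure
    window before averaging.  Branches with no observed members are left as
    ``None`` with a default substitution source: the corresponding branch of
    the other arm for QALYs, and the same arm's no-test branch (matched on
    treatment-failure status) for costs.
    """
    if params is None:
        params = estimate_branch_probabilities(table, uncertainty)
    df = table.participants
    y1 = table.years[table.years["year"] == 1]
    y1 = y1.set_index("pid")
    for arm in ARMS:
        ap = params[arm]
        sub = df[df["arm"] == arm]
        annual_cost = pd.Series(
            annualize(y1.loc[sub["pid"], "cost_total"].to_numpy(),
                      y1.loc[sub["pid"], "exposure_days"].to_numpy()),
            index=sub["pid"],
        )
        other = ARMS[1 - ARMS.index(arm)]
        for branch in TERMINAL_BRANCHES:
            members = sub[sub["branch"] == branch]
            cost_spec, cost_src = _payoff_specs(
                annual_cost.loc[members["pid"]].to_numpy(), "lognormal")
            qaly_spec, qaly_src = _payoff_specs(
                y1.loc[members["pid"], "utility"].to_numpy(), "beta")
            ap.costs[branch] = cost_spec
            ap.qalys[branch] = qaly_spec
            ap.provenance[("cost", branch)] = cost_src
            ap.provenance[("qaly", branch)] = qaly_src
            tf_branch = ("no_test_tf" if branch.endswith("_tf")
                         and not branch.endswith("no_tf") else "no_test_no_tf")
            last_resort = [{"arm": arm, "branch": "no_test_no_tf"},
                           {"arm": other, "branch": "no_test_no_tf"}]
            if cost_spec is None:
                ap.substitutions[("cost", branch)] = {"candidates": [
                    {"arm": arm, "branch": tf_branch},
                    {"arm": other, "branch": branch},
                    {"arm": other, "branch": tf_branch},
                ] + last_resort}
            if qaly_spec is None:
                ap.substitutions[("qaly", branch)] = {"candidates": [
                    {"arm": other, "branch": branch},
                    {"arm": arm, "branch": tf_branch},
                    {"arm": other, "branch": tf_branch},
                ] + last_resort}
    return params


def estimate_params(table, uncertainty: str = "sample_sd") -> BranchParams:
    """Complete resolved parameter set estimated from individual-level data."""
    params = estimate_branch_payoffs(table, uncertainty=uncertainty)
    return resolve_missing_branches(params)


def resolve_missing_branches(params: BranchParams) -> BranchParams:
    """Fill every unobserved branch payoff from its substitution source.

    Substituted payoffs enter the model as fixed values (sd 0) and are marked
    in the provenance map.  A branch that is empty everywhere, with no
    externally supplied value, is unresolvable.
    """
    kind_map = {"cost": "costs", "qaly": "qalys"}
    for arm, ap in params.arms.items():
        for kind, branch in ap.missing_branches():
            source = ap.substitutions.get((kind, branch))
            if source is None:
                raise EstimationError(
                    f"branch {branch!r} ({kind}) empty in arm {arm!r} with no "
                    "substitution source")
            if "value" in source:
                value = float(source["value"])
            else:
                candidates = source.get("candidates", [source])
                value = None
                for cand in candidates:
                    donor = getattr(params[cand["arm"]],
                                    kind_map[kind]).get(cand["branch"])
                    if donor is not None:
                        value = donor.mean
                        break
                if value is None:
                    raise EstimationError(
                        f"no substitution donor for {arm}/{branch} ({kind}) "
                        "has an observed value")
            getattr(ap, kind_map[kind])[branch] = DistributionSpec(
                "fixed", value, 0.0)
            ap.provenance[(kind, branch)] = "substituted"
    return params


def fit_post_year1_cost_model(table) -> CostRegression:
    """Fit the multiplicative annual cost model on year-2+ records.

    Gamma GLM with log link of annualised annual cost on indicators for
    no-label (de-labelled at 12 months) and year-1 treatment failure; zero
    costs are offset by half the smallest positive observed cost, the usual
    device for log-link models of skewed cost data.
    """
    later = table.years[table.years["year"] >= 2]
    if later.empty:
        raise EstimationError("no post-year-1 cost records")
    df = later.merge(
        table.participants[["pid", "delabelled", "treatment_failure"]],
        on="pid")
    y = annualize(df["cost_total"].to_numpy(), df["exposure_days"].to_numpy())
    positive = y[y > 0]
    if positive.size == 0:
        raise EstimationError("all post-year-1 costs are zero")
    y = np.where(y <= 0, positive.min() * 0.5, y)
    if np.ptp(y) == 0.0:
        # degenerate data: constant cost, no estimable effects
        return CostRegression(float(y[0]), 1.0, 1.0)
    X = sm.add_constant(
        df[["delabelled", "treatment_failure"]].astype(float).to_numpy())
    fit = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
    b0, b_nolabel, b_tf = fit.params
    return CostRegression(
        baseline=float(np.exp(b0)),
        no_label_multiplier=float(np.exp(b_nolabel)),
        tf_multiplier=float(np.exp(b_tf)),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PROB_LABELS = {
    "p_test": "receive_test",
    "p_positive": "test_positive",
    "p_delabel_pos": "pal_removed_after_positive_test",
    "p_delabel_neg": "pal_removed_after_negative_test",
    "tf_pos_label": "tf_after_test_positive_pal_not_removed",
    "tf_neg_label": "tf_after_test_negative_pal_not_removed",
    "tf_neg_nolabel": "tf_after_test_negative_pal_removed",
    "tf_no_test": "tf_with_no_test",
}
_LABEL_PROBS = {v: k for k, v in _PROB_LABELS.items()}


def _spec_to_obj(spec: DistributionSpec | None):
    if spec is None:
        return None
    return {"family": spec.family, "mean": float(spec.mean),
            "sd": float(spec.sd)}


def _obj_to_spec(obj) -> DistributionSpec | None:
    if obj is None:
        return None
    return _spec_or_fixed(obj.get("family", "fixed"),
                          float(obj["mean"]), float(obj.get("sd", 0.0)))


def save_params(params: BranchParams, path) -> None:
    doc = {"schema": 1, "meta": params.meta, "arms": {}}
    for arm, ap in params.arms.items():
        doc["arms"][arm] = {
            "n": ap.n,
            "event_probabilities": {
                _PROB_LABELS.get(k, k): _spec_to_obj(v)
                for k, v in ap.probabilities.items() if k != "tf_pos_nolabel"
            },
            "first_year_costs": {b: _spec_to_obj(ap.costs.get(b))
                                 for b in TERMINAL_BRANCHES},
            "annual_qalys": {b: _spec_to_obj(ap.qalys.get(b))
                             for b in TERMINAL_BRANCHES},
            "substitutions": {
                f"{kind}:{branch}": src
                for (kind, branch), src in ap.substitutions.items()
            },
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> BranchParams:
    """Load a parameter file and resolve substitutions."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema") != 1:
        raise ValueError(f"unsupported parameter file schema: {doc.get('schema')}")
    arms = {}
    for arm, obj in doc["arms"].items():
        probs = {_LABEL_PROBS.get(k, k): _obj_to_spec(v)
                 for k, v in obj["event_probabilities"].items()}
        ap = ArmParams(
            n=obj.get("n"),
            probabilities=probs,
            costs={b: _obj_to_spec(obj["first_year_costs"].get(b))
                   for b in TERMINAL_BRANCHES},
            qalys={b: _obj_to_spec(obj["annual_qalys"].get(b))
                   for b in TERMINAL_BRANCHES},
        )
        for key, src in (obj.get("substitutions") or {}).items():
            kind, branch = key.split(":", 1)
            ap.substitutions[(kind, branch)] = src
        arms[arm] = ap
    params = BranchParams(arms=arms, meta=doc.get("meta", {}))
    return resolve_missing_branches(params)


def load_reference_params() -> BranchParams:
    """The bundled reference parameter set (published ALABAMA estimates)."""
    from importlib.resources import files

    path = files("paapcea").joinpath("data", "reference_parameters.yaml")
    return load_params(str(path))
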