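"""Synthetic two-arm allergy-testing trial data.

Generates individual-level participant records with the statistical
structure the economic model assumes: branch membership drawn from the
decision tree's conditional probabilities, right-skewed annual costs built
from Gamma-distributed service components, annual utilities in [0, 1],
post-year-1 costs driven by 12-month label and treatment-failure status,
and administrative censoring with exposure-time weighting.  The default
configuration reproduces the ALABAMA trial's published arm sizes, branch
probabilities, payoff means and observed cost composition, so parameters
re-estimated from a large generated cohort recover the reference values.

Two tables describe a cohort: one row per participant (arm, testing and
label status, covariates) and one row per participant-year (exposure days,
component and total costs, annual utility).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .parameter_engine import ARMS, TERMINAL_BRANCHES, TF_CONTEXTS

__all__ = [
    "GeneratorConfig",
    "ParticipantTable",
    "EmptyArmError",
    "default_config",
    "generate_trial",
    "apply_censoring",
    "as_treated_reassign",
    "summarize_arm",
]

COST_COMPONENTS = (
    "test",
    "primary_care_consultations",
    "primary_care_medications",
    "hospital_admissions",
    "outpatient_visits",
    "emergency",
)

_BRANCH_CONTEXT = {
    "pos_label_tf": "pos_label", "pos_label_no_tf": "pos_label",
    "neg_label_tf": "neg_label", "neg_label_no_tf": "neg_label",
    "neg_nolabel_tf": "neg_nolabel", "neg_nolabel_no_tf": "neg_nolabel",
    "no_test_tf": "no_test", "no_test_no_tf": "no_test",
}


class EmptyArmError(ValueError):
    """Raised when a summary or estimate is requested for an empty arm."""


def _check_prob(name, value):
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class GeneratorConfig:
    """Truth values and noise models for the synthetic cohort.

    Probabilities, payoff means and cost composition default to the
    published ALABAMA estimates; the post-year-1 cost process applies a
    0.92 multiplier for de-labelled and 1.42 for treatment-failure
    participants to a common annual baseline.  ``age_qaly_interaction``
    optionally adds a utility benefit of de-labelling for participants
    aged 65+, the only built-in covariate-outcome link.
    """

    n_per_arm: dict = field(
        default_factory=lambda: {"paap": 401, "usual_care": 410})
    p_test: dict = field(
        default_factory=lambda: {"paap": 0.910, "usual_care": 0.012})
    p_positive: dict = field(
        default_factory=lambda: {"paap": 0.082, "usual_care": 0.200})
    p_delabel_pos: dict = field(
        default_factory=lambda: {"paap": 0.0, "usual_care": 0.0})
    p_delabel_neg: dict = field(
        default_factory=lambda: {"paap": 0.973, "usual_care": 1.000})
    #: arm -> context -> first-year treatment-failure probability
    tf_probs: dict = field(default_factory=lambda: {
        "paap": {"pos_label": 0.033, "neg_label": 0.111,
                 "neg_nolabel": 0.089, "no_test": 0.083},
        "usual_care": {"pos_label": 0.0, "neg_label": 0.0,
                       "neg_nolabel": 0.0, "no_test": 0.114},
    })
    #: arm -> branch -> mean first-year total cost (GBP)
    branch_cost_means: dict = field(default_factory=lambda: {
        "paap": {"pos_label_tf": 510.23, "pos_label_no_tf": 1176.55,
                 "neg_label_tf": 3565.61, "neg_label_no_tf": 501.37,
                 "neg_nolabel_tf": 1868.20, "neg_nolabel_no_tf": 1481.03,
                 "no_test_tf": 432.47, "no_test_no_tf": 604.89},
        "usual_care": {"pos_label_tf": 839.63, "pos_label_no_tf": 839.63,
                       "neg_label_tf": 409.14, "neg_label_no_tf": 409.14,
                       "neg_nolabel_tf": 409.14, "neg_nolabel_no_tf": 409.14,
                       "no_test_tf": 2077.52, "no_test_no_tf": 1208.45},
    })
    #: arm -> branch -> mean annual utility
    branch_qaly_means: dict = field(default_factory=lambda: {
        "paap": {"pos_label_tf": 0.924, "pos_label_no_tf": 0.828,
                 "neg_label_tf": 0.776, "neg_label_no_tf": 0.837,
                 "neg_nolabel_tf": 0.808, "neg_nolabel_no_tf": 0.880,
                 "no_test_tf": 0.689, "no_test_no_tf": 0.902},
        "usual_care": {"pos_label_tf": 0.924, "pos_label_no_tf": 0.980,
                       "neg_label_tf": 0.776, "neg_label_no_tf": 0.837,
                       "neg_nolabel_tf": 0.888, "neg_nolabel_no_tf": 0.888,
                       "no_test_tf": 0.755, "no_test_no_tf": 0.850},
    })
    #: arm -> branch -> utility SD (Beta noise; 0 means constant)
    branch_qaly_sds: dict = field(default_factory=lambda: {
        "paap": {"pos_label_tf": 0.05, "pos_label_no_tf": 0.226,
                 "neg_label_tf": 0.05, "neg_label_no_tf": 0.132,
                 "neg_nolabel_tf": 0.146, "neg_nolabel_no_tf": 0.137,
                 "no_test_tf": 0.060, "no_test_no_tf": 0.082},
        "usual_care": {"pos_label_tf": 0.05, "pos_label_no_tf": 0.014,
                       "neg_label_tf": 0.05, "neg_label_no_tf": 0.132,
                       "neg_nolabel_tf": 0.091, "neg_nolabel_no_tf": 0.091,
                       "no_test_tf": 0.249, "no_test_no_tf": 0.175},
    })
    #: arm -> component -> (annual mean over the whole arm, SD); the test
    #: component is drawn only for tested participants.
    cost_components: dict = field(default_factory=lambda: {
        arm: dict(reference.FIRST_YEAR_COST_COMPONENTS[arm])
        for arm in ARMS})
    cost_component_cv: float = 3.0
    #: per-test cost conditional on being tested (GBP)
    test_cost_mean: dict = field(
        default_factory=lambda: {"paap": 186.0, "usual_care": 127.0})
    test_cost_sd: float = 40.0
    #: post-year-1 annual cost process
    annual_cost_baseline: float = 1450.0
    no_label_cost_multiplier: float = 0.92
    tf_cost_multiplier: float = 1.42
    annual_cost_cv: float = 2.0
    #: administrative censoring: fraction of participants censored at a day
    #: drawn uniformly over [censor_start_day, censor_start_day + window)
    censor_fraction: float = 0.3
    censor_start_day: int = 365
    censor_window_days: int = 1095
    #: covariates
    age_mean: float = 54.0
    age_sd: float = 16.0
    p_female: float = 0.72
    qof_rate: float = 1.8
    abx_rate: float = 1.9
    age_qaly_interaction: float = 0.0
    horizon_years: int = 5
    seed: int = 20230

    def validate(self) -> None:
        for arm in ARMS:
            if self.n_per_arm[arm] < 0:
                raise ValueError("n_per_arm must be >= 0")
            for name in ("p_test", "p_positive", "p_delabel_pos",
                         "p_delabel_neg"):
                _check_prob(f"{name}[{arm}]", getattr(self, name)[arm])
            for ctx in TF_CONTEXTS:
                _check_prob(f"tf_probs[{arm}][{ctx}]",
                            self.tf_probs[arm][ctx])
            for b in TERMINAL_BRANCHES:
                if self.branch_cost_means[arm][b] < 0:
                    raise ValueError("cost means must be >= 0")
                _check_prob(f"branch_qaly_means[{arm}][{b}]",
                            self.branch_qaly_means[arm][b])
        _check_prob("censor_fraction", self.censor_fraction)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


@dataclass
class ParticipantTable:
    """A generated cohort: participant-level and participant-year tables."""

    participants: pd.DataFrame
    years: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.participants["pid"].duplicated().any():
            raise ValueError("participant ids must be unique")

    def subset(self, mask) -> "ParticipantTable":
        part = self.participants[np.asarray(mask)].reset_index(drop=True)
        keep = self.years["pid"].isin(part["pid"])
        return ParticipantTable(part, self.years[keep].reset_index(drop=True),
                                dict(self.meta))

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(directory / "participants.csv", index=False)
        self.years.to_csv(directory / "participant_years.csv", index=False)
        (directory / "meta.json").write_text(
            json.dumps(self.meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "ParticipantTable":
        directory = Path(directory)
        return cls(
            participants=pd.read_csv(
                directory / "participants.csv",
                dtype={"pid": str, "arm": str, "test_result": str,
                       "gender": str, "branch": str}),
            years=pd.read_csv(directory / "participant_years.csv",
                              dtype={"pid": str}),
            meta=json.loads((directory / "meta.json").read_text()),
        )


def _gamma_draw(mean, sd, rng: np.random.Generator) -> np.ndarray:
    """Element-wise Gamma draw matched to (mean, sd); degenerate cases pass through."""
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)
    out = np.array(mean, copy=True)
    ok = (mean > 0) & (sd > 0)
    if ok.any():
        shape = (mean[ok] / sd[ok]) ** 2
        scale = sd[ok] ** 2 / mean[ok]
        out[ok] = rng.gamma(shape, scale)
    return out


def _beta_draw(mean, sd, rng: np.random.Generator) -> np.ndarray:
    """Element-wise Beta draw matched to (mean, sd), clipped to feasibility."""
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape).copy()
    out = np.array(mean, copy=True)
    interior = (mean > 0) & (mean < 1)
    cap = np.sqrt(np.where(interior, mean * (1 - mean), 1.0)) * 0.999
    sd = np.minimum(sd, cap)
    ok = interior & (sd > 0)
    if ok.any():
        nu = mean[ok] * (1 - mean[ok]) / sd[ok] ** 2 - 1
        out[ok] = rng.beta(mean[ok] * nu, (1 - mean[ok]) * nu)
    return out


def _generate_arm(arm: str, config: GeneratorConfig,
                  rng: np.random.Generator):
    n = config.n_per_arm[arm]
    pid = np.array([f"{arm}_{i:06d}" for i in range(n)])
    tested = rng.random(n) < config.p_test[arm]
    positive = tested & (rng.random(n) < config.p_positive[arm])
    p_delabel = np.where(positive, config.p_delabel_pos[arm],
                         config.p_delabel_neg[arm])
    delabelled = tested & (rng.random(n) < p_delabel)
    test_result = np.where(tested,
                           np.where(positive, "positive", "negative"),
                           "not_applicable")
    context = np.where(
        ~tested, "no_test",
        np.where(positive, "pos_label",
                 np.where(delabelled, "neg_nolabel", "neg_label")))
    tf_p = pd.Series(context).map(config.tf_probs[arm]).to_numpy(dtype=float)
    tf = rng.random(n) < tf_p
    branch = np.char.add(context.astype(str),
                         np.where(tf, "_tf", "_no_tf"))

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 95)
    gender = np.where(rng.random(n) < config.p_female, "female", "male")
    qof = rng.poisson(config.qof_rate, n)
    abx = rng.poisson(config.abx_rate, n)

    participants = pd.DataFrame({
        "pid": pid, "arm": arm, "tested": tested, "test_result": test_result,
        "delabelled": delabelled, "treatment_failure": tf, "branch": branch,
        "age": np.round(age, 1), "gender": gender,
        "qof_count": qof, "abx_count": abx,
    })

    # --- year 1 costs: scaled service components + test cost if tested ----
    comp_means = config.cost_components[arm]
    base_total = sum(v for k, v in comp_means.items() if k != "test")
    target = pd.Series(branch).map(
        config.branch_cost_means[arm]).to_numpy(dtype=float)
    test_cost = np.where(
        tested,
        _gamma_draw(np.where(tested, config.test_cost_mean[arm], 0.0),
                    config.test_cost_sd, rng),
        0.0)
    scale = np.maximum(
        (target - tested * config.test_cost_mean[arm]) / base_total, 0.02)
    comp_cols = {"cost_test": test_cost}
    for comp in COST_COMPONENTS[1:]:
        m = comp_means[comp] * scale
        comp_cols[f"cost_{comp}"] = _gamma_draw(
            m, config.cost_component_cv * m, rng)
    y1_total = np.sum([comp_cols[f"cost_{c}"] for c in COST_COMPONENTS],
                      axis=0)

    # --- year 1 utility, optionally shifted for de-labelled elders --------
    q_mean = pd.Series(branch).map(
        config.branch_qaly_means[arm]).to_numpy(dtype=float)
    q_sd = pd.Series(branch).map(
        config.branch_qaly_sds[arm]).to_numpy(dtype=float)
    utility1 = _beta_draw(q_mean, q_sd, rng)
    if config.age_qaly_interaction:
        utility1 = np.clip(
            utility1 + config.age_qaly_interaction * (age >= 65) * delabelled,
            0.0, 1.0)

    # --- years 2..horizon: label/TF-driven annual cost process ------------
    rows = [pd.DataFrame({
        "pid": pid, "year": 1, "exposure_days": 365.0,
        **{k: np.round(v, 2) for k, v in comp_cols.items()},
        "cost_total": np.round(y1_total, 2),
        "utility": np.round(utility1, 4),
    })]
    rows[0]["cost_total"] = rows[0][
        [f"cost_{c}" for c in COST_COMPONENTS]].sum(axis=1)
    mu = (config.annual_cost_baseline
          * np.where(delabelled, config.no_label_cost_multiplier, 1.0)
          * np.where(tf, config.tf_cost_multiplier, 1.0))
    shares = reference.SECOND_YEAR_COST_COMPONENTS[arm]
    share_total = sum(shares.values())
    for year in range(2, config.horizon_years + 1):
        total = _gamma_draw(mu, config.annual_cost_cv * mu, rng)
        cols = {"cost_test": np.zeros(n)}
        for comp in COST_COMPONENTS[1:]:
            cols[f"cost_{comp}"] = np.round(
                total * shares[comp] / share_total, 2)
        frame = pd.DataFrame({
            "pid": pid, "year": year, "exposure_days": 365.0, **cols,
            "utility": np.round(utility1, 4),
        })
        frame["cost_total"] = frame[
            [f"cost_{c}" for c in COST_COMPONENTS]].sum(axis=1)
        frame["utility"] = np.round(utility1, 4)
        rows.append(frame)
    years = pd.concat(rows, ignore_index=True)
    order = ["pid", "year", "exposure_days",
             *[f"cost_{c}" for c in COST_COMPONENTS], "cost_total", "utility"]
    return participants, years[order]


def generate_trial(config: GeneratorConfig | None = None) -> ParticipantTable:
    """Generate a complete uncensored cohort; reproducible given the seed."""
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    parts, years = [], []
    for arm in ARMS:
        if config.n_per_arm[arm] == 0:
            continue
        p, y = _generate_arm(arm, config, rng)
        parts.append(p)
        years.append(y)
    if parts:
        participants = pd.concat(parts, ignore_index=True)
        year_table = pd.concat(years, ignore_index=True)
    else:
        participants = pd.DataFrame(
            columns=["pid", "arm", "tested", "test_result", "delabelled",
                     "treatment_failure", "branch", "age", "gender",
                     "qof_count", "abx_count"])
        year_table = pd.DataFrame(
            columns=["pid", "year", "exposure_days",
                     *[f"cost_{c}" for c in COST_COMPONENTS],
                     "cost_total", "utility"])
    meta = {"seed": config.seed, "config_hash": config.hash(),
            "n_per_arm": dict(config.n_per_arm), "censored": False}
    return ParticipantTable(participants, year_table, meta)


def apply_censoring(
    table: ParticipantTable, config: GeneratorConfig
) -> ParticipantTable:
    """Administratively censor a fraction of participants.

    Each censored participant gets a censor day drawn uniformly over the
    configured window; the year containing that day keeps a shortened
    exposure window with costs scaled proportionally (uniform daily cost
    within the year), and later years are dropped.
    """
    config.validate()
    if config.censor_fraction == 0.0 or table.participants.empty:
        out = ParticipantTable(table.participants.copy(),
                               table.years.copy(), dict(table.meta))
        out.meta["censored"] = True
        return out
    rng = np.random.default_rng([config.seed, 7])
    pids = table.participants["pid"].to_numpy()
    censored = rng.random(len(pids)) < config.censor_fraction
    day = np.floor(config.censor_start_day
                   + rng.random(len(pids)) * config.censor_window_days)
    censor_day = pd.Series(np.where(censored, day, np.inf), index=pids)

    years = table.years.copy()
    cd = censor_day.loc[years["pid"]].to_numpy()
    year_start = (years["year"].to_numpy() - 1) * 365.0
    keep = year_start < cd
    years = years[keep].reset_index(drop=True)
    cd = cd[keep]
    year_start = year_start[keep]
    exposure = np.minimum(cd - year_start, 365.0)
    exposure = np.maximum(exposure, 1.0)
    frac = exposure / 365.0
    cost_cols = [c for c in years.columns if c.startswith("cost")]
    years[cost_cols] = years[cost_cols].mul(frac, axis=0).round(2)
    years["cost_total"] = years[
        [f"cost_{c}" for c in COST_COMPONENTS]].sum(axis=1)
    years["exposure_days"] = exposure
    meta = dict(table.meta)
    meta["censored"] = True
    return ParticipantTable(table.participants.copy(), years, meta)


def as_treated_reassign(table: ParticipantTable) -> ParticipantTable:
    """Move untested PAAP participants to the usual-care arm.

    Only the ``arm`` field changes; cohort size and every other field are
    preserved.
    """
    participants = table.participants.copy()
    mask = (participants["arm"] == "paap") & (~participants["tested"])
    participants.loc[mask, "arm"] = "usual_care"
    meta = dict(table.meta)
    meta["as_treated"] = True
    return ParticipantTable(participants, table.years.copy(), meta)


def summarize_arm(table: ParticipantTable, arm: str) -> pd.DataFrame:
    """Per-year mean/SD of annualised component costs and utilities.

    Costs are annualised to each record's exposure window before averaging,
    mirroring the censoring adjustment used for estimation.
    """
    from .parameter_engine import annualize

    sub = table.participants[table.participants["arm"] == arm]
    if sub.empty:
        raise EmptyArmError(f"arm {arm!r} has no participants")
    years = table.years[table.years["pid"].isin(sub["pid"])].copy()
    cost_cols = [f"cost_{c}" for c in COST_COMPONENTS] + ["cost_total"]
    for col in cost_cols:
        years[col] = annualize(years[col].to_numpy(),
                               years["exposure_days"].to_numpy())
    agg = years.groupby("year")[cost_cols + ["utility"]].agg(["mean", "std"])
    agg.columns = [f"{q}_{stat}" for q, stat in agg.columns]
    std_cols = [c for c in agg.columns if c.endswith("_std")]
    agg[std_cols] = agg[std_cols].fillna(0.0)  # single-member groups
    agg["n"] = years.groupby("year")["pid"].count()
    return agg
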