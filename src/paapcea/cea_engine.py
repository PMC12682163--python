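"""Deterministic and probabilistic cost-effectiveness comparison.

Two strategies (PAAP vs usual care) are compared on discounted 5-year costs
and QALYs: incremental cost-effectiveness ratio with the usual dominance
conventions, incremental net monetary benefit INMB(lambda) = lambda*dQ - dC,
Monte-Carlo probabilistic sensitivity analysis (PSA) with independent
method-of-moments draws per parameter, cost-effectiveness acceptability
curves, cost-effectiveness plane summaries, and subgroup re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision_model import ARMS, EconConfig, arm_values, evaluate_arm
from .parameter_engine import BranchParams, CostRegression

__all__ = [
    "ICERResult",
    "CEAResult",
    "PSADraws",
    "PSASummary",
    "CEACCurve",
    "icer",
    "inmb",
    "deterministic_cea",
    "sample_parameters",
    "run_psa",
    "ceac",
    "subgroup_cea",
    "DEFAULT_SUBGROUP_SPLITS",
]


@dataclass(frozen=True)
class ICERResult:
    """ICER value with its dominance classification.

    ``dominant`` (saves costs, gains QALYs) and ``dominated`` (costs more,
    loses QALYs) carry no ratio.  South-west ratios are reported positive and
    read as the cost saving per QALY lost; ``undefined`` flags dQ = 0.
    """

    value: float | None
    dominance_class: str  # dominant | dominated | north_east | south_west | undefined


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Classify an incremental (cost, QALY) pair and compute the ratio."""
    if delta_qaly == 0.0:
        return ICERResult(None, "undefined")
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return ICERResult(None, "dominant")
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return ICERResult(None, "dominated")
    quadrant = "north_east" if delta_qaly > 0.0 else "south_west"
    return ICERResult(float(delta_cost / delta_qaly), quadrant)


def inmb(delta_cost, delta_qaly, wtp):
    """Incremental net monetary benefit lambda*dQ - dC."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


@dataclass
class CEAResult:
    """Incremental comparison of PAAP against usual care."""

    delta_cost: float
    delta_qaly: float
    icer: ICERResult
    inmb: dict  # wtp -> INMB
    arm_totals: dict = field(default_factory=dict)  # arm -> (cost, qaly)
    n: int | None = None

    @classmethod
    def from_deltas(cls, delta_cost, delta_qaly, wtp_grid, **kw):
        return cls(
            delta_cost=float(delta_cost),
            delta_qaly=float(delta_qaly),
            icer=icer(delta_cost, delta_qaly),
            inmb={w: float(inmb(delta_cost, delta_qaly, w)) for w in wtp_grid},
            **kw,
        )


def deterministic_cea(
    params: BranchParams,
    reg: CostRegression,
    config: EconConfig,
    relabel_rate: float = 0.0,
) -> CEAResult:
    """Run the model at parameter means and assemble the incremental result."""
    totals = {}
    for arm in ARMS:
        out = evaluate_arm(arm_values(params, arm), reg, config,
                           relabel_rate=relabel_rate)
        totals[arm] = (out["discounted_cost_total"],
                       out["discounted_qaly_total"])
    dc = totals["paap"][0] - totals["usual_care"][0]
    dq = totals["paap"][1] - totals["usual_care"][1]
    n = sum(a.n or 0 for a in params.arms.values()) or None
    return CEAResult.from_deltas(dc, dq, config.wtp_grid,
                                 arm_totals=totals, n=n)


def sample_parameters(
    params: BranchParams, n_draws: int, seed: int | np.random.Generator
) -> dict:
    """Independent PSA draws for every uncertain parameter.

    Returns {arm: evaluation mapping of arrays}; fixed parameters appear as
    constant arrays so the mapping can drive :func:`evaluate_arm` directly.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sampled = {}
    for arm in ARMS:
        ap = params[arm]
        values = {name: spec.sample(n_draws, rng)
                  for name, spec in ap.probabilities.items()}
        for branch, spec in ap.costs.items():
            values[f"cost_{branch}"] = spec.sample(n_draws, rng)
        for branch, spec in ap.qalys.items():
            values[f"qaly_{branch}"] = spec.sample(n_draws, rng)
        sampled[arm] = values
    return sampled


@dataclass
class PSADraws:
    """Per-draw strategy payoffs and sampled parameters."""

    results: pd.DataFrame  # cost/qaly per arm, delta_cost, delta_qaly
    parameters: pd.DataFrame  # one column per sampled parameter ("arm:name")
    seed: int
    n_draws: int

    @property
    def delta_cost(self) -> np.ndarray:
        return self.results["delta_cost"].to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.results["delta_qaly"].to_numpy()


@dataclass
class PSASummary:
    mean_delta_cost: float
    mean_delta_qaly: float
    icer: ICERResult
    inmb: dict  # wtp -> INMB of the means
    p_cost_effective: dict  # wtp -> P(INMB > 0)
    p_cost_saving: float
    n_draws: int
    n_failed: int = 0


def run_psa(
    params: BranchParams,
    reg: CostRegression,
    config: EconConfig,
    relabel_rate: float = 0.0,
    thresholds: tuple = (20_000.0, 30_000.0),
) -> tuple[PSADraws, PSASummary]:
    """Propagate parameter uncertainty through the full 5-year model.

    Every non-fixed parameter is drawn from its method-of-moments
    distribution; each draw is evaluated through the decision tree and
    extrapolation for both arms (vectorised over draws).
    """
    n = config.psa_draws
    sampled = sample_parameters(params, n, config.seed)
    cols = {}
    for arm in ARMS:
        out = evaluate_arm(sampled[arm], reg, config, relabel_rate=relabel_rate)
        cols[f"cost_{arm}"] = np.broadcast_to(
            out["discounted_cost_total"], (n,)).astype(float)
        cols[f"qaly_{arm}"] = np.broadcast_to(
            out["discounted_qaly_total"], (n,)).astype(float)
        cols[f"year1_cost_{arm}"] = np.broadcast_to(
            out["year1_cost"], (n,)).astype(float)
        cols[f"year1_qaly_{arm}"] = np.broadcast_to(
            out["year1_qaly"], (n,)).astype(float)
    results = pd.DataFrame(cols)
    results["delta_cost"] = results["cost_paap"] - results["cost_usual_care"]
    results["delta_qaly"] = results["qaly_paap"] - results["qaly_usual_care"]
    parameters = pd.DataFrame(
        {f"{arm}:{name}": np.broadcast_to(v, (n,))
         for arm in ARMS for name, v in sampled[arm].items()})
    draws = PSADraws(results=results, parameters=parameters,
                     seed=config.seed, n_draws=n)
    dc, dq = draws.delta_cost, draws.delta_qaly
    mean_dc, mean_dq = float(dc.mean()), float(dq.mean())
    summary = PSASummary(
        mean_delta_cost=mean_dc,
        mean_delta_qaly=mean_dq,
        icer=icer(mean_dc, mean_dq),
        inmb={w: float(inmb(mean_dc, mean_dq, w)) for w in thresholds},
        p_cost_effective={w: float((inmb(dc, dq, w) > 0).mean())
                          for w in thresholds},
        p_cost_saving=float((dc < 0).mean()),
        n_draws=n,
    )
    return draws, summary


@dataclass
class CEACCurve:
    """P(cost-effective) over the willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray
    p_cost_saving: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp,
                             "p_cost_effective": self.probability})


def ceac(draws: PSADraws, wtp_grid) -> CEACCurve:
    """Fraction of draws with positive net benefit at each threshold.

    At lambda = 0 this is the probability of cost saving; ties at exactly
    zero net benefit count as not cost-effective.
    """
    if draws.n_draws == 0:
        raise ValueError("no PSA draws")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    dc = draws.delta_cost[:, None]
    dq = draws.delta_qaly[:, None]
    prob = (wtp[None, :] * dq - dc > 0).mean(axis=0)
    return CEACCurve(wtp=wtp, probability=prob,
                     p_cost_saving=float((draws.delta_cost < 0).mean()))


#: Published subgroup splits: name -> callable(participants df) -> bool mask.
DEFAULT_SUBGROUP_SPLITS = {
    "age_lt_65": lambda df: df["age"] < 65,
    "age_ge_65": lambda df: df["age"] >= 65,
    "female": lambda df: df["gender"] == "female",
    "male": lambda df: df["gender"] == "male",
    "qof_lt_2": lambda df: df["qof_count"] < 2,
    "qof_ge_2": lambda df: df["qof_count"] >= 2,
    "abx_lt_2": lambda df: df["abx_count"] < 2,
    "abx_ge_2": lambda df: df["abx_count"] >= 2,
}


def subgroup_cea(
    table,
    config: EconConfig,
    splits: dict | None = None,
    reg: CostRegression | None = None,
    run_probabilistic: bool = False,
    min_n: int = 30,
) -> dict:
    """Re-run estimation and the model within each participant stratum.

    Parameters are re-estimated from the stratum's individual-level data;
    the post-year-1 cost regression is refitted per stratum unless a shared
    one is supplied.  Strata below ``min_n`` per arm are flagged
    (``"small_stratum"``) but still analysed.
    """
    from .parameter_engine import estimate_params, fit_post_year1_cost_model

    splits = DEFAULT_SUBGROUP_SPLITS if splits is None else splits
    out = {}
    for name, mask_fn in splits.items():
        sub = table.subset(mask_fn(table.participants))
        arm_ns = sub.participants["arm"].value_counts()
        entry = {"n": int(len(sub.participants)),
                 "flags": [],
                 "result": None}
        if any(arm_ns.get(a, 0) == 0 for a in ARMS):
            entry["flags"].append("empty_arm")
            out[name] = entry
            continue
        if any(arm_ns.get(a, 0) < min_n for a in ARMS):
            entry["flags"].append("small_stratum")
        sub_params = estimate_params(sub)
        sub_reg = reg if reg is not None else fit_post_year1_cost_model(sub)
        entry["result"] = deterministic_cea(sub_params, sub_reg, config)
        if run_probabilistic:
            _, entry["psa_summary"] = run_psa(sub_params, sub_reg, config)
        out[name] = entry
    return out
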