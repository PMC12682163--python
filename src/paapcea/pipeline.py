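"""Configuration-driven end-to-end runs with file-based outputs.

A run takes parameters either from a structured parameter file
(``from_table``), from the bundled synthetic-trial generator
(``from_synthetic``), or from individual-level CSV data (``from_csv``),
then executes: deterministic CEA -> PSA -> CEAC/CE-plane -> scenario
sensitivity analyses -> subgroups (when individual data exist) -> VOI.
Every artifact is a CSV/JSON/YAML file stamped with the seed and a config
hash, and reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import reference
from .cea_engine import (
    CEAResult,
    ceac,
    deterministic_cea,
    run_psa,
    subgroup_cea,
)
from .decision_model import (
    EconConfig,
    annual_from_6month_rate,
    relabel_thresholds,
)
from .parameter_engine import (
    BranchParams,
    estimate_params,
    fit_post_year1_cost_model,
    default_cost_regression,
    load_params,
    load_reference_params,
    save_params,
)
from .synthetic_trial import (
    GeneratorConfig,
    ParticipantTable,
    apply_censoring,
    as_treated_reassign,
    generate_trial,
)
from . import voi_engine

log = logging.getLogger("paapcea")

_MODES = ("from_table", "from_synthetic", "from_csv")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; unknown keys are errors."""

    mode: str = "from_table"
    out_dir: str = "paapcea_run"
    params_file: str | None = None  # from_table: None -> bundled reference
    data_dir: str | None = None  # from_csv: ParticipantTable directory
    seed: int = 20230
    psa_draws: int = 10_000
    discount_rate: float = 0.035
    horizon_years: int = 5
    year1_exposure_fraction: float = 1.0
    n_per_arm: dict | None = None  # from_synthetic override
    relabel_rate_6m: float | None = None  # Markov relabelling scenario
    as_treated: bool = False  # individual-data modes only
    test_unit_cost: float | None = None  # alternative PAAP delivery cost
    subgroups: bool = False
    run_voi: bool = False
    voi_wtp: float = 20_000.0
    plots: bool = False

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.mode == "from_csv" and not self.data_dir:
            raise ValueError("from_csv mode requires data_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def econ(self) -> EconConfig:
        return EconConfig(
            discount_rate=self.discount_rate,
            horizon_years=self.horizon_years,
            year1_exposure_fraction=self.year1_exposure_fraction,
            psa_draws=self.psa_draws,
            seed=self.seed,
        )


#: Mean unit cost of the allergy test per tested PAAP participant implied by
#: the reference cost composition (169.52 observed over all participants at
#: 91% uptake).
BASE_TEST_UNIT_COST = 169.52 / 0.910


def with_test_unit_cost(params: BranchParams, unit_cost: float,
                        current: float = BASE_TEST_UNIT_COST) -> BranchParams:
    """Shift tested-branch cost payoffs of the PAAP arm to a new test price."""
    import copy

    from .parameter_engine import DistributionSpec

    out = copy.deepcopy(params)
    delta = unit_cost - current
    ap = out["paap"]
    for branch, spec in ap.costs.items():
        if branch.startswith("no_test"):
            continue
        mean = max(spec.mean + delta, 0.01)
        family = spec.family if spec.sd > 0 else "fixed"
        ap.costs[branch] = DistributionSpec(family, mean, spec.sd)
    return out


def _cea_row(name: str, res: CEAResult, psa_summary=None) -> dict:
    row = {
        "scenario": name,
        "delta_cost": res.delta_cost,
        "delta_qaly": res.delta_qaly,
        "icer": res.icer.value,
        "dominance": res.icer.dominance_class,
        "inmb_20000": res.inmb.get(20_000.0, res.inmb.get(20_000)),
        "inmb_30000": res.inmb.get(30_000.0, res.inmb.get(30_000)),
        "n": res.n,
    }
    if psa_summary is not None:
        row["p_ce_20000"] = psa_summary.p_cost_effective[20_000.0]
        row["p_ce_30000"] = psa_summary.p_cost_effective[30_000.0]
        row["p_cost_saving"] = psa_summary.p_cost_saving
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns {artifact name: path}."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.hash(),
             "mode": config.mode}
    artifacts: dict[str, Path] = {}
    econ = config.econ()
    wtp_grid = econ.wtp_grid

    # ---- stage 1: obtain parameters --------------------------------------
    log.info("stage=parameters mode=%s", config.mode)
    table: ParticipantTable | None = None
    if config.mode == "from_table":
        params = (load_params(config.params_file) if config.params_file
                  else load_reference_params())
        reg = default_cost_regression()
    else:
        if config.mode == "from_synthetic":
            gen = GeneratorConfig(seed=config.seed)
            if config.n_per_arm:
                gen.n_per_arm = dict(config.n_per_arm)
            table = apply_censoring(generate_trial(gen), gen)
        else:
            table = ParticipantTable.load(config.data_dir)
        if config.as_treated:
            table = as_treated_reassign(table)
        params = estimate_params(table)
        reg = fit_post_year1_cost_model(table)
    if config.test_unit_cost is not None:
        params = with_test_unit_cost(params, config.test_unit_cost)

    snap = out_dir / "parameter_snapshot.yaml"
    params.meta.update(stamp)
    save_params(params, snap)
    artifacts["parameter_snapshot"] = snap

    # ---- stage 2: deterministic CEA and PSA ------------------------------
    log.info("stage=cea")
    relabel_rate = (annual_from_6month_rate(config.relabel_rate_6m)
                    if config.relabel_rate_6m else 0.0)
    det = deterministic_cea(params, reg, econ, relabel_rate=relabel_rate)
    draws, psa_summary = run_psa(params, reg, econ,
                                 relabel_rate=relabel_rate)
    base_rows = [
        _cea_row("base_case", det),
        {**_cea_row("psa", CEAResult.from_deltas(
            psa_summary.mean_delta_cost, psa_summary.mean_delta_qaly,
            (20_000.0, 30_000.0), n=det.n), psa_summary=psa_summary)},
    ]
    cea_path = out_dir / "cea_summary.csv"
    pd.DataFrame(base_rows).to_csv(cea_path, index=False)
    artifacts["cea_summary"] = cea_path

    draws_path = out_dir / "psa_draws.csv"
    draws.results.round(6).to_csv(draws_path, index=False)
    artifacts["psa_draws"] = draws_path
    summary_path = out_dir / "psa_summary.json"
    summary_path.write_text(json.dumps({
        **stamp,
        "mean_delta_cost": psa_summary.mean_delta_cost,
        "mean_delta_qaly": psa_summary.mean_delta_qaly,
        "inmb": psa_summary.inmb,
        "p_cost_effective": psa_summary.p_cost_effective,
        "p_cost_saving": psa_summary.p_cost_saving,
        "n_draws": psa_summary.n_draws,
    }, indent=2, sort_keys=True))
    artifacts["psa_summary"] = summary_path

    curve = ceac(draws, wtp_grid)
    ceac_path = out_dir / "ceac.csv"
    curve.to_frame().to_csv(ceac_path, index=False)
    artifacts["ceac"] = ceac_path
    plane_path = out_dir / "ce_plane.csv"
    draws.results[["delta_cost", "delta_qaly"]].round(6).to_csv(
        plane_path, index=False)
    artifacts["ce_plane"] = plane_path
    if config.plots:
        artifacts.update(_write_plots(out_dir, draws, curve))

    # ---- stage 3: scenario sensitivity analyses --------------------------
    log.info("stage=sensitivity")
    sens_rows = []
    for unit_name, unit_cost in reference.UNIT_COST_SCENARIOS.items():
        alt = with_test_unit_cost(params, unit_cost)
        sens_rows.append(_cea_row(f"unit_cost_{unit_name}",
                                  deterministic_cea(alt, reg, econ)))
    palace_annual = annual_from_6month_rate(
        reference.VOI_ANCHORS["relabel_rate_6month_palace"])
    sens_rows.append(_cea_row(
        "relabel_palace_6m_constant",
        deterministic_cea(params, reg, econ, relabel_rate=palace_annual)))
    thresholds = relabel_thresholds(params, reg, econ, wtp=20_000.0)
    if table is not None:
        at_table = as_treated_reassign(table)
        at_params = estimate_params(at_table)
        at_reg = fit_post_year1_cost_model(at_table)
        sens_rows.append(_cea_row(
            "as_treated", deterministic_cea(at_params, at_reg, econ)))
    sens_path = out_dir / "sensitivity.csv"
    pd.DataFrame(sens_rows).to_csv(sens_path, index=False)
    artifacts["sensitivity"] = sens_path
    thr_path = out_dir / "relabel_thresholds.json"
    thr_path.write_text(json.dumps({
        **stamp,
        "cost_neutral_annual_rate": thresholds.cost_neutral_rate,
        "inmb_zero_annual_rate": thresholds.inmb_zero_rate,
        "wtp": thresholds.wtp,
    }, indent=2, sort_keys=True))
    artifacts["relabel_thresholds"] = thr_path

    # ---- stage 4: subgroups ----------------------------------------------
    if config.subgroups and table is not None:
        log.info("stage=subgroups")
        rows = []
        for name, entry in subgroup_cea(table, econ).items():
            if entry["result"] is None:
                rows.append({"scenario": name, "n": entry["n"],
                             "flags": ";".join(entry["flags"])})
                continue
            row = _cea_row(name, entry["result"])
            row["n"] = entry["n"]
            row["flags"] = ";".join(entry["flags"])
            rows.append(row)
        sub_path = out_dir / "subgroups.csv"
        pd.DataFrame(rows).to_csv(sub_path, index=False)
        artifacts["subgroups"] = sub_path

    # ---- stage 5: value of information -----------------------------------
    if config.run_voi:
        log.info("stage=voi")
        wtp = config.voi_wtp
        clinical = voi_engine.default_trial_design(endpoints="clinical")
        full = voi_engine.default_trial_design(endpoints="full")
        pop = voi_engine.PopulationModel(discount_rate=config.discount_rate)
        ranking = voi_engine.evppi_ranking(draws, wtp, top=10)
        evppi_path = out_dir / "evppi_ranking.csv"
        ranking.to_csv(evppi_path, index=False)
        artifacts["evppi_ranking"] = evppi_path
        evsi_clin = voi_engine.evsi(draws, clinical, wtp, seed=config.seed)
        evsi_full = voi_engine.evsi(draws, full, wtp, seed=config.seed)
        optimal_n, enbs_curve = voi_engine.enbs_optimize(
            draws, full, pop, wtp,
            n_grid=range(100, 2001, 100), seed=config.seed)
        enbs_path = out_dir / "enbs_curve.csv"
        enbs_curve.to_csv(enbs_path, index=False)
        artifacts["enbs_curve"] = enbs_path
        voi_path = out_dir / "voi_summary.json"
        voi_path.write_text(json.dumps({
            **stamp,
            "wtp": wtp,
            "evpi_per_patient": voi_engine.evpi(draws, wtp),
            "evsi_clinical_per_patient": evsi_clin,
            "evsi_full_per_patient": evsi_full,
            "trial_cost_at_design_n": voi_engine.trial_cost(full),
            "trial_duration_months_at_design_n":
                voi_engine.trial_duration(full),
            "population_evsi_full": voi_engine.population_value(evsi_full,
                                                                pop),
            "optimal_n": optimal_n,
        }, indent=2, sort_keys=True))
        artifacts["voi_summary"] = voi_path

    report = write_report(artifacts, out_dir, stamp)
    artifacts["report"] = report
    return {k: str(v) for k, v in artifacts.items()}


def _write_plots(out_dir: Path, draws, curve) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = {}
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(draws.delta_qaly, draws.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, lw=0.8, color="k")
    ax.axvline(0, lw=0.8, color="k")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP)")
    fig.tight_layout()
    path = out_dir / "ce_plane.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out["ce_plane_plot"] = path

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.wtp, curve.probability)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (GBP/QALY)")
    ax.set_ylabel("P(cost-effective)")
    fig.tight_layout()
    path = out_dir / "ceac.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out["ceac_plot"] = path
    return out


def write_report(artifacts: dict, out_dir: Path, stamp: dict) -> Path:
    """Human-readable markdown summary assembled from the run's artifacts."""
    out_dir = Path(out_dir)
    lines = ["# PAAP cost-effectiveness run", "",
             f"- mode: {stamp.get('mode')}",
             f"- seed: {stamp.get('seed')}",
             f"- config hash: {stamp.get('config_hash')}", ""]
    sections = [
        ("Incremental results", "cea_summary"),
        ("Sensitivity scenarios", "sensitivity"),
        ("Subgroups", "subgroups"),
    ]
    for title, key in sections:
        lines.append(f"## {title}")
        path = artifacts.get(key)
        if path is None or not Path(path).exists():
            lines.append("_absent_")
        else:
            df = pd.read_csv(path)
            lines.append(df.to_markdown(index=False, floatfmt=".3f"))
        lines.append("")
    for title, key in (("PSA summary", "psa_summary"),
                       ("Relabelling thresholds", "relabel_thresholds"),
                       ("Value of information", "voi_summary")):
        lines.append(f"## {title}")
        path = artifacts.get(key)
        if path is None or not Path(path).exists():
            lines.append("_absent_")
        else:
            lines.append("```json")
            lines.append(Path(path).read_text().strip())
            lines.append("```")
        lines.append("")
    report = out_dir / "report.md"
    report.write_text("\n".join(lines))
    return report
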