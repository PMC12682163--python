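import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import paapcea as p
from paapcea.synthetic_trial import COST_COMPONENTS, ParticipantTable

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_params():
    return p.load_reference_params()


@pytest.fixture(scope="session")
def econ():
    return p.EconConfig()


@pytest.fixture(scope="session")
def cost_reg():
    return p.default_cost_regression()


@pytest.fixture(scope="session")
def medium_table():
    """A mid-sized cohort shared by estimation tests (2,000 per arm)."""
    cfg = p.GeneratorConfig(
        seed=11, n_per_arm={"paap": 2000, "usual_care": 2000})
    return p.generate_trial(cfg)


def freeze_params(params):
    """Copy of a parameter set with every distribution fixed at its mean."""
    import copy

    from paapcea.parameter_engine import DistributionSpec

    out = copy.deepcopy(params)
    for ap in out.arms.values():
        for name, spec in ap.probabilities.items():
            ap.probabilities[name] = DistributionSpec("fixed", spec.mean)
        for b, spec in ap.costs.items():
            ap.costs[b] = DistributionSpec("fixed", spec.mean)
        for b, spec in ap.qalys.items():
            ap.qalys[b] = DistributionSpec("fixed", spec.mean)
    return out


@pytest.fixture(scope="session")
def frozen_params(reference_params):
    return freeze_params(reference_params)


def make_table(participants: list[dict], years: list[dict] | None = None):
    """Hand-built cohort: fill defaults so tests only state what matters."""
    part_defaults = dict(arm="paap", tested=True, test_result="negative",
                         delabelled=True, treatment_failure=False,
                         branch="neg_nolabel_no_tf", age=50.0,
                         gender="female", qof_count=1, abx_count=1)
    rows = []
    for i, spec in enumerate(participants):
        row = {**part_defaults, "pid": f"p{i:03d}", **spec}
        rows.append(row)
    part = pd.DataFrame(rows)
    if years is None:
        years = [{"pid": r["pid"]} for r in rows]
    year_defaults = {"year": 1, "exposure_days": 365.0,
                     **{f"cost_{c}": 0.0 for c in COST_COMPONENTS},
                     "cost_total": 0.0, "utility": 0.8}
    ydf = pd.DataFrame([{**year_defaults, **y} for y in years])
    return ParticipantTable(part, ydf, {"seed": 0, "config_hash": "manual"})


@pytest.fixture
def hand_table():
    return make_table
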