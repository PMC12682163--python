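"""Published reference numbers from the ALABAMA PAAP economic evaluation.

These are *inputs*, not results: observed resource-use/cost summaries, the
per-period cost and QALY totals, the headline incremental results, and the
follow-on-trial economics anchors.  They are used to cross-check the
arithmetic identities that tie the published tables together (net-benefit
linearity, period additivity, component totals, linear trial-cost model) and
to calibrate the synthetic-data generator.  All monetary values are GBP at
2022-23 prices.
"""

from __future__ import annotations

__all__ = [
    "FIRST_YEAR_COST_COMPONENTS",
    "SECOND_YEAR_COST_COMPONENTS",
    "PERIOD_TOTALS",
    "HEADLINE_ROWS",
    "SUBGROUP_ROWS",
    "TRIAL_COST_ANCHORS",
    "TRIAL_DURATION_ANCHORS",
    "VOI_ANCHORS",
    "first_year_total_cost",
]

#: Observed mean first-year cost per participant by component (GBP).
FIRST_YEAR_COST_COMPONENTS = {
    "paap": {
        "test": 169.52,
        "primary_care_consultations": 38.74,
        "primary_care_medications": 6.07,
        "hospital_admissions": 643.54,
        "outpatient_visits": 462.59,
        "emergency": 74.25,
    },
    "usual_care": {
        "test": 1.52,
        "primary_care_consultations": 47.25,
        "primary_care_medications": 8.87,
        "hospital_admissions": 748.12,
        "outpatient_visits": 475.51,
        "emergency": 89.72,
    },
}

#: Printed first-year totals the component means must add up to.
FIRST_YEAR_COST_TOTALS = {"paap": 1394.71, "usual_care": 1370.99}

#: Observed mean second-year annualised cost per participant by component.
SECOND_YEAR_COST_COMPONENTS = {
    "paap": {
        "primary_care_consultations": 39.59,
        "primary_care_medications": 8.30,
        "hospital_admissions": 848.79,
        "outpatient_visits": 581.54,
        "emergency": 59.11,
    },
    "usual_care": {
        "primary_care_consultations": 42.02,
        "primary_care_medications": 7.29,
        "hospital_admissions": 888.58,
        "outpatient_visits": 507.67,
        "emergency": 73.18,
    },
}

#: Modelled per-period totals (base case): costs year 1, discounted costs
#: years 2-5, QALYs year 1, discounted QALYs years 2-5, per arm and increment.
PERIOD_TOTALS = {
    "cost_year1": {"paap": 684.141, "usual_care": 630.854, "delta": 53.287},
    "cost_years2to5": {"paap": 1523.834, "usual_care": 1660.246,
                       "delta": -136.412},
    "qaly_year1": {"paap": 0.429, "usual_care": 0.422, "delta": 0.008},
    "qaly_years2to5": {"paap": 1.577, "usual_care": 1.549, "delta": 0.028},
}

#: Headline incremental results: (delta_cost, inmb at 20k, inmb at 30k).
HEADLINE_ROWS = {
    "base_case": {"delta_cost": -114.959, "inmb_20000": 563.834,
                  "inmb_30000": 788.272},
    "psa": {"delta_cost": -83.125, "delta_qaly": 0.036,
            "inmb_20000": 805.723, "inmb_30000": 1167.022},
    "as_treated": {"delta_cost": -435.792, "inmb_20000": -6572.997,
                   "inmb_30000": -10077.390},
}

#: Subgroup rows used for net-benefit linearity checks.
SUBGROUP_ROWS = {
    "female": {"n": 584, "delta_cost": -20.051, "inmb_20000": 967.089,
               "inmb_30000": 1440.607},
    "male": {"n": 227, "delta_cost": -264.00, "inmb_20000": -90.514,
             "inmb_30000": -267.771},
    "age_65_plus": {"n": 256, "delta_cost": -60.956, "inmb_20000": 2455.833,
                    "inmb_30000": 3653.272},
}

#: (n participants, total cost GBP) anchors for the follow-on-trial cost model.
TRIAL_COST_ANCHORS = ((769, 1.76e6), (1267, 2.37e6))

#: (n participants, months) anchors for the follow-on-trial duration model.
TRIAL_DURATION_ANCHORS = ((769, 30.0), (1267, 46.0))

#: Value-of-information anchors: per-patient EVSI of a clinical-outcomes-only
#: follow-on trial of 1267 participants, the eligible population over 10
#: years, and the gross population value of that information.
VOI_ANCHORS = {
    "evsi_clinical_per_patient": 249.15,
    "evsi_full_per_patient": 3097.0,
    "eligible_population_10y": 79877,
    "gross_population_value": 19.6e6,
    "relabel_rate_6month_palace": 0.066,
    "relabel_rate_annual_literature_max": 0.032,
}

#: Alternative unit costs for delivering the allergy test (GBP per test).
UNIT_COST_SCENARIOS = {
    "day_case_tariff": 368.0,
    "micro_cost_spt_oral_challenge": 234.0,
    "micro_cost_direct_oral_challenge": 155.0,
}


def first_year_total_cost(arm: str) -> float:
    """Sum of observed first-year component means for one arm (GBP)."""
    return sum(FIRST_YEAR_COST_COMPONENTS[arm].values())
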