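"""Published study inputs for the two districts.

This module holds, as plain Python data, the parameter tables of the
underlying CHW programme study: median travel/activity minutes and
share-of-time per activity (by district and site class), home-visit
composition frequencies, the cost-ingredient tables with their printed
annualized values, per-service home-visit time profiles and modelled
per-service hours per 100,000 population, and the duty-time parameters.
Everything downstream (the synthetic diary generator's defaults, the cost
models, the workforce reconstruction, the stipend scenarios) is
parameterized from here, so the whole pipeline runs with no external data.
"""

from __future__ import annotations

from .costing import CostIngredient, CostModel
from .diary import SiteClass
from .workforce import ServiceTimeProfile, UtilizationRecord, WorkforceParams

SEDIBENG = "Sedibeng"
UMZINYATHI = "uMzinyathi"
DISTRICTS = (SEDIBENG, UMZINYATHI)

PU = SiteClass.PERI_URBAN
RU = SiteClass.RURAL
DR = SiteClass.DEEP_RURAL

#: Site classes sampled in each district (uMzinyathi's "rural" sites are
#: deep-rural; Sedibeng's are farm settlements).
DISTRICT_SITES: dict[str, tuple[SiteClass, SiteClass]] = {
    SEDIBENG: (PU, RU),
    UMZINYATHI: (PU, DR),
}

#: CHWs sampled per cell: 111 in Sedibeng (68% peri-urban) and 110 in
#: uMzinyathi (77% deep-rural).
SAMPLED_CHWS: dict[tuple[str, SiteClass], int] = {
    (SEDIBENG, PU): 75,
    (SEDIBENG, RU): 36,
    (UMZINYATHI, PU): 25,
    (UMZINYATHI, DR): 85,
}

N_DIARY_DAYS = 10  # two consecutive working weeks

# ---------------------------------------------------------------------------
# Time use: median minutes (travel, activity) per activity, and the share of
# combined (travel + activity) time per activity, by district and site class.
# Sedibeng's three home-visit rows share one printed home-visit time share
# (66% peri-urban / 57% rural), split evenly here across the three rows.
# ---------------------------------------------------------------------------

# activity -> (travel_median, activity_median, share_of_time_percent)
TIME_USE: dict[tuple[str, SiteClass], dict[str, tuple[float, float, float]]] = {
    (SEDIBENG, PU): {
        "household_registration": (15, 19, 22.0),
        "household_screening": (15, 15, 22.0),
        "home_visit_other": (15, 20, 22.0),
        "facility_visit": (15, 25, 23.0),
        "support_group": (28, 10, 0.0),
        "creche_ecd": (20, 15, 0.0),
        "other_institution": (10, 10, 0.0),
        "health_day": (15, 20, 0.0),
        "school_health": (18, 53, 0.0),
        "meeting": (30, 330, 1.0),
        "other": (17, 24, 8.0),
    },
    (SEDIBENG, RU): {
        "household_registration": (15, 24, 19.0),
        "household_screening": (17, 23, 19.0),
        "home_visit_other": (15, 20, 19.0),
        "facility_visit": (30, 30, 29.0),
        "support_group": (16, 34, 1.0),
        "other_institution": (25, 10, 0.0),
        "health_day": (20, 15, 0.0),
        "school_health": (10, 21, 0.0),
        "meeting": (165, 225, 3.0),
        "other": (9, 30, 8.0),
    },
    (UMZINYATHI, PU): {
        "home_visit_other": (15, 40, 55.0),
        "facility_visit": (25, 120, 18.0),
        "phila_mtwana": (30, 360, 15.0),
        "creche_ecd": (27, 50, 1.0),
        "campaign": (20, 150, 2.0),
        "meeting": (20, 40, 3.0),
        "war_room": (30, 122, 2.0),
        "training": (35, 51, 2.0),
        "support_group": (30, 55, 1.0),
        "other": (16, 43, 1.0),
    },
    (UMZINYATHI, DR): {
        "home_visit_other": (20, 60, 49.0),
        "facility_visit": (30, 115, 13.0),
        "phila_mtwana": (30, 425, 16.0),
        "creche_ecd": (23, 73, 2.0),
        "campaign": (20, 235, 3.0),
        "meeting": (30, 100, 4.0),
        "war_room": (35, 188, 2.0),
        "training": (30, 120, 5.0),
        "support_group": (30, 95, 1.0),
        "other": (15, 40, 5.0),
    },
}

#: Broad activity groups used for the share-of-time table.
ACTIVITY_GROUPS: dict[str, str] = {
    "household_registration": "home_visits",
    "household_screening": "home_visits",
    "home_visit_other": "home_visits",
    "facility_visit": "facility",
    "support_group": "support_groups",
    "creche_ecd": "creche_ecd",
    "other_institution": "other_institution",
    "health_day": "health_days",
    "school_health": "school_health",
    "meeting": "meetings",
    "phila_mtwana": "phila_mtwana",
    "campaign": "campaigns",
    "war_room": "war_room",
    "training": "training",
    "other": "other",
}

#: Share of combined CHW time spent on home visits, by cell (percent).
HOME_VISIT_TIME_SHARE: dict[tuple[str, SiteClass], float] = {
    (SEDIBENG, PU): 66.0,
    (SEDIBENG, RU): 57.0,
    (UMZINYATHI, PU): 55.0,
    (UMZINYATHI, DR): 49.0,
}

# ---------------------------------------------------------------------------
# Home-visit composition.  Content rates are per-visit occurrence rates
# (codes co-occur within a visit, so columns sum to >1); condition and
# recipient columns are code-level proportions.
# ---------------------------------------------------------------------------

CONTENT_RATES: dict[tuple[str, SiteClass], dict[str, float]] = {
    (SEDIBENG, PU): {
        "screening": 0.40,
        "health_education": 0.30,
        "bring_medicines": 0.28,
        "tracing_defaulters": 0.04,
        "hbc": 0.03,
        "referral": 0.04,
        "dots": 0.03,
        "other": 0.04,
    },
    (SEDIBENG, RU): {
        "screening": 0.30,
        "health_education": 0.19,
        "bring_medicines": 0.18,
        "tracing_defaulters": 0.26,
        "hbc": 0.07,
        "referral": 0.03,
        "dots": 0.02,
        "other": 0.07,
    },
    (UMZINYATHI, PU): {
        "screening": 0.26,
        "health_education": 0.34,
        "bring_medicines": 0.12,
        "referral": 0.02,
        "child_health": 0.08,
        "hbc": 0.09,
        "tracing_defaulters": 0.05,
        "dots": 0.05,
        "other": 0.03,
    },
    (UMZINYATHI, DR): {
        "screening": 0.23,
        "health_education": 0.49,
        "bring_medicines": 0.07,
        "referral": 0.12,
        "child_health": 0.12,
        "hbc": 0.08,
        "tracing_defaulters": 0.06,
        "dots": 0.04,
        "other": 0.05,
    },
}

CONDITION_SHARES: dict[tuple[str, SiteClass], dict[str, float]] = {
    (SEDIBENG, PU): {
        "mother_child": 0.07,
        "hiv": 0.20,
        "tb": 0.20,
        "chronic": 0.45,
        "nutrition": 0.03,
        "fp": 0.12,
        "other": 0.05,
        "unknown": 0.04,
    },
    (SEDIBENG, RU): {
        "mother_child": 0.04,
        "hiv": 0.21,
        "tb": 0.38,
        "chronic": 0.26,
        "nutrition": 0.05,
        "fp": 0.08,
        "other": 0.05,
        "unknown": 0.03,
    },
    (UMZINYATHI, PU): {
        "mother_child": 0.13,
        "hiv": 0.11,
        "tb": 0.11,
        "chronic": 0.28,
        "nutrition": 0.14,
        "fp": 0.20,
        "other": 0.05,
        "unknown": 0.02,
    },
    (UMZINYATHI, DR): {
        "mother_child": 0.14,
        "hiv": 0.18,
        "tb": 0.14,
        "chronic": 0.19,
        "nutrition": 0.19,
        "fp": 0.23,
        "other": 0.10,
        "unknown": 0.01,
    },
}

RECIPIENT_SHARES: dict[tuple[str, SiteClass], dict[str, float]] = {
    (SEDIBENG, PU): {
        "pregnant": 0.04,
        "postnatal": 0.02,
        "infant": 0.02,
        "age1_5": 0.05,
        "age5_18": 0.05,
        "adult": 0.48,
        "elderly": 0.30,
        "family": 0.12,
        "community": 0.01,
        "unknown": 0.01,
    },
    (SEDIBENG, RU): {
        "pregnant": 0.02,
        "postnatal": 0.01,
        "infant": 0.01,
        "age1_5": 0.04,
        "age5_18": 0.10,
        "adult": 0.59,
        "elderly": 0.23,
        "family": 0.14,
        "community": 0.00,
        "unknown": 0.03,
    },
    (UMZINYATHI, PU): {
        "pregnant": 0.03,
        "postnatal": 0.03,
        "infant": 0.03,
        "age1_5": 0.09,
        "age5_18": 0.04,
        "adult": 0.49,
        "elderly": 0.07,
        "family": 0.12,
        "community": 0.05,
        "unknown": 0.04,
    },
    (UMZINYATHI, DR): {
        "pregnant": 0.06,
        "postnatal": 0.06,
        "infant": 0.04,
        "age1_5": 0.19,
        "age5_18": 0.11,
        "adult": 0.47,
        "elderly": 0.09,
        "family": 0.14,
        "community": 0.02,
        "unknown": 0.00,
    },
}

# ---------------------------------------------------------------------------
# Cost-ingredient tables.  `published_annual` carries the printed annualized
# district cost; unit-cost arithmetic reproduces it to within 2e-4 relative
# (a few printed unit costs are rounded).
# ---------------------------------------------------------------------------


def _ing(name, category, cost_class, unit_cost, quantity, life_years, share,
         published, stipend_role=None) -> CostIngredient:
    return CostIngredient(
        name=name,
        category=category,
        cost_class=cost_class,
        unit_cost=unit_cost,
        quantity=quantity,
        life_years=life_years,
        allocation_share=share,
        published_annual=published,
        stipend_role=stipend_role,
    )


_SEDIBENG_HEALTH_POSTS = (
    _ing("Infrastructure", "setup", "infrastructure", 490_000, 22, 15, 0.35, 251_533),
    _ing("Equipment: Health Post", "setup", "equipment", 39_200, 22, 15, 0.35, 20_123),
    _ing("Equipment: kits", "setup", "equipment", 2_495, 424, 2, 1.0, 528_940),
    _ing("Training: CHWs", "setup", "training", 6_000, 424, 5, 1.0, 508_800),
    _ing("Asst Dr", "recurrent", "salary", 426_000, 1, 1, 0.50, 213_000),
    _ing("Professional Nurses", "recurrent", "salary", 46_423, 22, 1, 0.55, 561_721),
    _ing("Staff Nurses", "recurrent", "salary", 251_244, 22, 1, 1.0, 5_527_375),
    _ing("CHW WBOTs", "recurrent", "salary", 30_000, 424, 1, 1.0, 12_720_000,
         stipend_role="chw"),
    _ing("Health Post Maintenance", "recurrent", "maintenance", 10_000, 22, 1, 1.0,
         220_000),
    _ing("Kit replenishment", "recurrent", "supplies", 250, 424, 1, 1.0, 106_000),
)

_SEDIBENG_FACILITIES = (
    _ing("Equipment: kits", "setup", "equipment", 2_495, 424, 2, 1.0, 528_940),
    _ing("Training CHWs", "setup", "training", 6_000, 424, 5, 1.0, 508_800),
    _ing("Asst Dr", "recurrent", "salary", 426_000, 1, 1, 0.50, 213_000),
    _ing("Professional Nurses", "recurrent", "salary", 46_423, 22, 1, 0.55, 561_718),
    _ing("Staff Nurses", "recurrent", "salary", 251_244, 22, 1, 1.0, 5_527_375),
    _ing("CHW WBOTs", "recurrent", "salary", 30_000, 424, 1, 1.0, 12_720_000,
         stipend_role="chw"),
    _ing("Kit replenishment", "recurrent", "supplies", 250, 424, 1, 1.0, 106_000),
)

_UMZINYATHI_MAIN = (
    _ing("Training/Supervision", "setup", "training", 2_000, 6, 5, 1.0, 2_400),
    _ing("Training CHWs", "setup", "training", 6_000, 481, 5, 1.0, 577_200),
    _ing("Car for community health facilitators", "setup", "transport",
         350_000, 6, 5, 1.0, 420_000),
    _ing("Kit", "setup", "equipment", 510, 481, 2, 1.0, 122_655),
    _ing("Jacket, umbrella and coolerbox", "setup", "equipment", 477, 481, 1, 1.0,
         229_466),
    _ing("District CHW co-ordinator", "recurrent", "salary", 426_000, 1, 1, 1.0,
         426_000),
    _ing("Community health facilitator", "recurrent", "salary", 177_660, 6, 1, 1.0,
         1_065_957),
    _ing("CHW supervisor", "recurrent", "salary", 27_600, 16, 1, 1.0, 441_600,
         stipend_role="supervisor"),
    _ing("CHW", "recurrent", "salary", 21_600, 481, 1, 1.0, 10_389_600,
         stipend_role="chw"),
    _ing("Kit replenishment", "recurrent", "supplies", 671, 481, 1, 1.0, 322_751),
    _ing("Transport supervisors", "recurrent", "transport", 101_839, 4, 1, 1.0,
         407_356),
)

USD_PER_ZAR_RATE = 14.3  # ZAR per USD

#: Monthly CHW stipends at the time of costing (ZAR).
CURRENT_STIPEND: dict[str, float] = {SEDIBENG: 2_500, UMZINYATHI: 1_800}
MINIMUM_WAGE_STIPEND = 3_500  # ZAR/month


def sedibeng_cost_model() -> CostModel:
    """Cost model for Sedibeng: 424 CHWs in each of two panels (health-post
    based and facility based teams), 8% overheads, PHC spend R1,200/capita."""
    return CostModel(
        district=SEDIBENG,
        panels={
            "health_posts": _SEDIBENG_HEALTH_POSTS,
            "facilities": _SEDIBENG_FACILITIES,
        },
        overhead_rate=0.08,
        population=935_831,
        n_chw={"health_posts": 424, "facilities": 424},
        phc_per_capita=1_200,
        exchange_rate=USD_PER_ZAR_RATE,
    )


def umzinyathi_cost_model() -> CostModel:
    """Cost model for uMzinyathi: one panel of 481 CHWs, no overhead
    mark-up, PHC spend R1,150/capita."""
    return CostModel(
        district=UMZINYATHI,
        panels={"main": _UMZINYATHI_MAIN},
        overhead_rate=0.0,
        population=513_974,
        n_chw={"main": 481},
        phc_per_capita=1_150,
        exchange_rate=USD_PER_ZAR_RATE,
    )


def cost_model(district: str) -> CostModel:
    if district == SEDIBENG:
        return sedibeng_cost_model()
    if district == UMZINYATHI:
        return umzinyathi_cost_model()
    raise KeyError(f"no bundled cost model for district {district!r}")


# ---------------------------------------------------------------------------
# Workforce-requirement inputs: per-service median minutes per home visit
# (combined travel + activity), modelled per-service hours per 100,000 total
# population at 70% coverage, and duty-time parameters.
# ---------------------------------------------------------------------------

SERVICE_TYPES = ("registration", "screening", "mother_under5", "hiv_tb",
                 "chronic", "other")

SERVICE_MINUTES: dict[tuple[str, SiteClass], dict[str, float]] = {
    (SEDIBENG, PU): {"registration": 35, "screening": 35, "mother_under5": 36,
                     "hiv_tb": 35, "chronic": 35, "other": 39},
    (SEDIBENG, RU): {"registration": 40, "screening": 40, "mother_under5": 40,
                     "hiv_tb": 35, "chronic": 45, "other": 50},
    (UMZINYATHI, PU): {"registration": 85, "screening": 35, "mother_under5": 71,
                       "hiv_tb": 61, "chronic": 72, "other": 110},
    (UMZINYATHI, DR): {"registration": 75, "screening": 90, "mother_under5": 110,
                       "hiv_tb": 90, "chronic": 89, "other": 120},
}

SERVICE_HOURS: dict[tuple[str, SiteClass], dict[str, float]] = {
    (SEDIBENG, PU): {"registration": 1_295, "screening": 1_295,
                     "mother_under5": 21_419, "hiv_tb": 18_579,
                     "chronic": 24_022, "other": 13},
    (SEDIBENG, RU): {"registration": 1_480, "screening": 1_480,
                     "mother_under5": 23_799, "hiv_tb": 18_579,
                     "chronic": 30_885, "other": 17},
    (UMZINYATHI, PU): {"registration": 5_441, "screening": 7_169,
                       "mother_under5": 23_339, "hiv_tb": 39_974,
                       "chronic": 44_589, "other": 38},
    (UMZINYATHI, DR): {"registration": 4_801, "screening": 18_434,
                       "mother_under5": 36_159, "hiv_tb": 58_978,
                       "chronic": 55_117, "other": 42},
}

#: 200 duty days/year; 6 duty hours/day in Sedibeng (30 h weeks) vs 8 in
#: uMzinyathi (40 h weeks); CHWs pair up in Sedibeng for security.
WORKFORCE_PARAMS: dict[tuple[str, SiteClass], WorkforceParams] = {
    (SEDIBENG, PU): WorkforceParams(200, 6, 0.66, 2),
    (SEDIBENG, RU): WorkforceParams(200, 6, 0.57, 2),
    (UMZINYATHI, PU): WorkforceParams(200, 8, 0.55, 1),
    (UMZINYATHI, DR): WorkforceParams(200, 8, 0.49, 1),
}


def service_time_profile(district: str, site_class: SiteClass) -> ServiceTimeProfile:
    key = (district, site_class)
    if key not in SERVICE_MINUTES:
        raise KeyError(f"no bundled time profile for {key}")
    return ServiceTimeProfile(
        district=district, site_class=site_class,
        minutes_per_visit=dict(SERVICE_MINUTES[key]),
    )


DEFAULT_COVERAGE = 0.70
HOUSEHOLDS_PER_CHW_BASE = 250  # government guideline for peri-urban areas

#: Illustrative utilization extracts shaped like the routine-information
#: pull: facility and home-visit headcounts with catchment populations,
#: chosen so the per-capita rates match the published rounded rates.
UTILIZATION_RECORDS: list[UtilizationRecord] = [
    UtilizationRecord(SEDIBENG, PU, clinic_headcount=200_000,
                      home_visit_headcount=100_000, population=100_000),
    UtilizationRecord(SEDIBENG, RU, clinic_headcount=170_000,
                      home_visit_headcount=40_000, population=100_000),
    UtilizationRecord(UMZINYATHI, PU, clinic_headcount=320_000,
                      home_visit_headcount=70_000, population=100_000),
    UtilizationRecord(UMZINYATHI, DR, clinic_headcount=310_000,
                      home_visit_headcount=40_000, population=100_000),
]
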