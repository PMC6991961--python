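"""Geography-specific CHW staffing requirements and utilization rates.

The requirement model follows workload-indicator logic: modelled home-visit
needs per 100,000 population (visits per service type at a target coverage)
are converted into hours using the observed median combined travel +
activity minutes per visit, summed, and divided by the hours one CHW has
available for home visits per year (duty days x duty hours x observed share
of time spent on home visits).  Where CHWs work in pairs the requirement is
multiplied by the team size.

Rounding conventions: CHW counts are reported rounded to integers (half
away from zero), but the relative requirement between site classes and the
derived households-per-CHW norm both use the *unrounded* requirement ratio
— the convention under which the published 33%/62% differences and the
169/96 household norms all reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .costing import round_half_away
from .diary import SiteClass, ValidationError


@dataclass(frozen=True)
class ServiceTimeProfile:
    """Median minutes per home visit (travel + activity) by service type."""

    district: str
    site_class: SiteClass
    minutes_per_visit: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.minutes_per_visit.values()):
            raise ValidationError("minutes per visit must be positive")


@dataclass(frozen=True)
class VisitNeeds:
    """Modelled home visits per 100,000 total population, per service type,
    at the stated coverage fraction (0.70 default)."""

    visits_per_100k: Mapping[str, float]
    coverage: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ValidationError("coverage must be in (0, 1]")
        if any(v < 0 for v in self.visits_per_100k.values()):
            raise ValidationError("visit counts must be non-negative")

    def at_coverage(self, coverage: float) -> "VisitNeeds":
        """Rescale the modelled visit counts to a different coverage."""
        factor = coverage / self.coverage
        return VisitNeeds(
            visits_per_100k={k: v * factor for k, v in self.visits_per_100k.items()},
            coverage=coverage,
        )


@dataclass(frozen=True)
class WorkforceParams:
    """Duty-time assumptions: days on duty per year, duty hours per day,
    share of duty time spent on home visits, CHWs per home visit."""

    days_per_year: float = 200
    hours_per_day: float = 8
    share_home_visits: float = 1.0
    chws_per_visit: int = 1

    def __post_init__(self) -> None:
        if min(self.days_per_year, self.hours_per_day, self.chws_per_visit) <= 0:
            raise ValidationError("workforce parameters must be positive")
        if not 0.0 < self.share_home_visits <= 1.0:
            raise ValidationError("share_home_visits must be in (0, 1]")


@dataclass
class WorkforceResult:
    """Derived requirement for one district x site-class scenario."""

    district: str
    site_class: SiteClass
    hours_by_service: dict[str, float]
    total_hours: float
    available_hours_per_chw: float
    chws_required_unrounded: float
    chws_required: int


@dataclass(frozen=True)
class RelativeRequirement:
    """Extra CHWs needed in the higher-need site class, relative to the
    reference class."""

    ratio_unrounded: float
    percent: int  # rounded to the whole percent reported


@dataclass(frozen=True)
class UtilizationRecord:
    """One routine-information extract: annual facility and home-visit
    headcounts for a catchment population."""

    district: str
    site_class: SiteClass
    clinic_headcount: float
    home_visit_headcount: float
    population: float

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError("population must be positive")


def derive_visit_needs(
    profile: ServiceTimeProfile,
    hours_by_service: Mapping[str, float],
    coverage: float = 0.70,
) -> VisitNeeds:
    """Back-derive visit counts from per-service hours: visits = h x 60 / min.

    Inverts the requirement construction so per-service hour tables are
    self-contained inputs when the upstream needs model is unavailable.
    """
    visits = {}
    for service, hours in hours_by_service.items():
        if service not in profile.minutes_per_visit:
            raise ValidationError(f"no visit time for service {service!r}")
        visits[service] = hours * 60.0 / profile.minutes_per_visit[service]
    return VisitNeeds(visits_per_100k=visits, coverage=coverage)


def required_hours(
    needs: VisitNeeds, profile: ServiceTimeProfile
) -> tuple[dict[str, float], float]:
    """Hours per 100,000 population per service and in total:
    hours(s) = visits(s) x minutes(s) / 60."""
    hours = {}
    for service, visits in needs.visits_per_100k.items():
        if service not in profile.minutes_per_visit:
            raise ValidationError(f"no visit time for service {service!r}")
        hours[service] = visits * profile.minutes_per_visit[service] / 60.0
    return hours, sum(hours.values())


def available_hours(params: WorkforceParams) -> float:
    """Hours one CHW has available for home visits per year."""
    return params.days_per_year * params.hours_per_day * params.share_home_visits


def chws_required(
    total_hours: float, available: float, chws_per_visit: int = 1
) -> tuple[float, int]:
    """CHWs required to deliver ``total_hours`` of home-visit work.

    Returns the unrounded value and the integer count (half away from zero).
    """
    if available <= 0:
        raise ValidationError("available hours must be positive")
    unrounded = total_hours / available * chws_per_visit
    return unrounded, int(round_half_away(unrounded))


def staffing_requirement(
    profile: ServiceTimeProfile, needs: VisitNeeds, params: WorkforceParams
) -> WorkforceResult:
    """Full requirement calculation for one district x site-class scenario."""
    hours, total = required_hours(needs, profile)
    avail = available_hours(params)
    unrounded, rounded = chws_required(total, avail, params.chws_per_visit)
    return WorkforceResult(
        district=profile.district,
        site_class=profile.site_class,
        hours_by_service=hours,
        total_hours=total,
        available_hours_per_chw=avail,
        chws_required_unrounded=unrounded,
        chws_required=rounded,
    )


def relative_requirement(
    result_ref: WorkforceResult, result_other: WorkforceResult
) -> RelativeRequirement:
    """Percent more CHWs required in ``result_other`` than the reference.

    Computed from the unrounded requirement ratio (the same ratio that
    drives the households-per-CHW norm), reported rounded to a whole
    percent.
    """
    if result_ref.chws_required_unrounded <= 0:
        raise ValidationError("reference requirement must be positive")
    ratio = result_other.chws_required_unrounded / result_ref.chws_required_unrounded
    return RelativeRequirement(
        ratio_unrounded=ratio,
        percent=int(round_half_away(100.0 * (ratio - 1.0))),
    )


def households_per_chw(base_households: float, unrounded_ratio: float) -> int:
    """Households one CHW should cover in a higher-need site class.

    The peri-urban guideline base is scaled down by the extra-requirement
    fraction: base x (1 - (ratio - 1)), using the unrounded ratio.
    """
    if base_households <= 0:
        raise ValidationError("base households must be positive")
    if unrounded_ratio < 1.0:
        raise ValidationError(
            "reference must be the lower-need site class (ratio >= 1)"
        )
    return int(round_half_away(base_households * (1.0 - (unrounded_ratio - 1.0))))


def utilization_rates(records: Sequence[UtilizationRecord]) -> pd.DataFrame:
    """Per-capita annual contact rates per record: clinic, home and total."""
    rows = []
    for r in records:
        clinic = r.clinic_headcount / r.population
        home = r.home_visit_headcount / r.population
        rows.append(
            {
                "district": r.district,
                "site_class": r.site_class.value,
                "clinic_per_capita": clinic,
                "home_visits_per_capita": home,
                "total_contacts_per_capita": clinic + home,
            }
        )
    return pd.DataFrame(rows)
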