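"""Workforce-requirement model: staffing arithmetic, relative requirements,
household norms and utilization rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chwplan as cp
from chwplan import reference as ref
from chwplan.workforce import (
    UtilizationRecord,
    VisitNeeds,
    WorkforceParams,
)

PU = cp.SiteClass.PERI_URBAN


def _requirements():
    out = {}
    for key, params in ref.WORKFORCE_PARAMS.items():
        profile = ref.service_time_profile(*key)
        needs = cp.derive_visit_needs(
            profile, ref.SERVICE_HOURS[key], ref.DEFAULT_COVERAGE
        )
        out[key] = cp.staffing_requirement(profile, needs, params)
    return out


@pytest.mark.parametrize(
    "days, hours, share, expected",
    [(200, 6, 0.66, 792), (200, 6, 0.57, 684), (200, 8, 0.55, 880),
     (200, 8, 0.49, 784), (200, 8, 1.0, 1600)],
)
def test_available_hours(days, hours, share, expected):
    params = WorkforceParams(days, hours, share, 1)
    assert cp.available_hours(params) == pytest.approx(expected)


@pytest.mark.parametrize(
    "total, avail, team, expected",
    [(66_623, 792, 2, 168), (173_530, 784, 1, 221), (792, 792, 1, 1)],
)
def test_chws_required(total, avail, team, expected):
    _, rounded = cp.chws_required(total, avail, team)
    assert rounded == expected


def test_full_reconstruction_of_requirements():
    """With the published per-service hours, duty parameters and team sizes
    the model returns exactly 168/223/137/221 CHWs per 100,000."""
    results = _requirements()
    expected = {
        (ref.SEDIBENG, PU): 168,
        (ref.SEDIBENG, cp.SiteClass.RURAL): 223,
        (ref.UMZINYATHI, PU): 137,
        (ref.UMZINYATHI, cp.SiteClass.DEEP_RURAL): 221,
    }
    for key, count in expected.items():
        assert results[key].chws_required == count
    # totals match the published per-100,000 hours within 1 hour
    assert results[(ref.SEDIBENG, PU)].total_hours == pytest.approx(66_623, abs=1)
    assert results[(ref.SEDIBENG, cp.SiteClass.RURAL)].total_hours == pytest.approx(
        76_240, abs=1
    )
    assert results[(ref.UMZINYATHI, PU)].total_hours == pytest.approx(120_549, abs=1)
    assert results[(ref.UMZINYATHI, cp.SiteClass.DEEP_RURAL)].total_hours == (
        pytest.approx(173_530, abs=1)
    )


def test_relative_requirements():
    results = _requirements()
    sed = cp.relative_requirement(
        results[(ref.SEDIBENG, PU)], results[(ref.SEDIBENG, cp.SiteClass.RURAL)]
    )
    umz = cp.relative_requirement(
        results[(ref.UMZINYATHI, PU)],
        results[(ref.UMZINYATHI, cp.SiteClass.DEEP_RURAL)],
    )
    assert sed.percent == 33
    assert umz.percent == 62
    identical = cp.relative_requirement(
        results[(ref.SEDIBENG, PU)], results[(ref.SEDIBENG, PU)]
    )
    assert identical.percent == 0


def test_households_per_chw():
    results = _requirements()
    sed = cp.relative_requirement(
        results[(ref.SEDIBENG, PU)], results[(ref.SEDIBENG, cp.SiteClass.RURAL)]
    )
    umz = cp.relative_requirement(
        results[(ref.UMZINYATHI, PU)],
        results[(ref.UMZINYATHI, cp.SiteClass.DEEP_RURAL)],
    )
    assert cp.households_per_chw(250, 1.0) == 250
    assert cp.households_per_chw(250, sed.ratio_unrounded) == 169
    assert cp.households_per_chw(250, umz.ratio_unrounded) == 96
    with pytest.raises(cp.ValidationError):
        cp.households_per_chw(250, 0.9)
    # strictly decreasing in the requirement ratio
    hh = [cp.households_per_chw(250, r) for r in (1.0, 1.2, 1.5, 1.9)]
    assert hh == sorted(hh, reverse=True) and len(set(hh)) == 4


@pytest.mark.parametrize(
    "hours, minutes, expected",
    [(1_295, 35, 2_220), (44_589, 72, pytest.approx(37_157.5)), (0, 60, 0)],
)
def test_derive_visit_needs(hours, minutes, expected):
    profile = cp.ServiceTimeProfile("d", PU, {"svc": minutes})
    needs = cp.derive_visit_needs(profile, {"svc": hours})
    assert needs.visits_per_100k["svc"] == expected


def test_needs_hours_round_trip():
    key = (ref.SEDIBENG, PU)
    profile = ref.service_time_profile(*key)
    needs = cp.derive_visit_needs(profile, ref.SERVICE_HOURS[key])
    hours, total = cp.required_hours(needs, profile)
    assert hours == pytest.approx(ref.SERVICE_HOURS[key])
    assert total == pytest.approx(sum(ref.SERVICE_HOURS[key].values()))


def test_required_hours_linearity():
    profile = cp.ServiceTimeProfile("d", PU, {"a": 60, "b": 30})
    needs = VisitNeeds({"a": 100, "b": 50})
    _, total = cp.required_hours(needs, profile)
    doubled = VisitNeeds({"a": 200, "b": 100})
    _, total2 = cp.required_hours(doubled, profile)
    assert total2 == pytest.approx(2 * total)
    assert total == pytest.approx(100 + 25)


def test_coverage_rescaling():
    needs = VisitNeeds({"a": 700}, coverage=0.7)
    full = needs.at_coverage(1.0)
    assert full.visits_per_100k["a"] == pytest.approx(1000)


def test_missing_service_raises():
    profile = cp.ServiceTimeProfile("d", PU, {"a": 60})
    with pytest.raises(cp.ValidationError, match="b"):
        cp.derive_visit_needs(profile, {"b": 10})
    with pytest.raises(cp.ValidationError, match="b"):
        cp.required_hours(VisitNeeds({"b": 10}), profile)


@given(
    total=st.floats(1, 1e6),
    extra=st.floats(0, 1e5),
    avail=st.floats(100, 2000),
    team=st.integers(1, 3),
)
def test_chws_required_monotonicity(total, extra, avail, team):
    """Non-decreasing in workload and team size, non-increasing in
    available hours."""
    base, _ = cp.chws_required(total, avail, team)
    more, _ = cp.chws_required(total + extra, avail, team)
    bigger_team, _ = cp.chws_required(total, avail, team + 1)
    more_hours, _ = cp.chws_required(total, avail * 1.5, team)
    assert more >= base
    assert bigger_team >= base
    assert more_hours <= base


def test_utilization_rates_additivity():
    rates = cp.utilization_rates(
        [UtilizationRecord("d", PU, 3_100, 400, 1_000)]
    )
    row = rates.iloc[0]
    assert row["clinic_per_capita"] == pytest.approx(3.1)
    assert row["home_visits_per_capita"] == pytest.approx(0.4)
    assert row["total_contacts_per_capita"] == pytest.approx(3.5)

    rng = np.random.default_rng(8)
    records = [
        UtilizationRecord("d", PU, rng.integers(0, 10_000),
                          rng.integers(0, 5_000), rng.integers(1, 10_000))
        for _ in range(25)
    ]
    table = cp.utilization_rates(records)
    assert np.allclose(
        table["total_contacts_per_capita"],
        table["clinic_per_capita"] + table["home_visits_per_capita"],
    )


def test_zero_headcounts_zero_rates():
    rates = cp.utilization_rates([UtilizationRecord("d", PU, 0, 0, 500)])
    assert rates.iloc[0]["total_contacts_per_capita"] == 0.0
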