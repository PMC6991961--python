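"""Time-use analytics and the three significance tests."""

import numpy as np
import pytest
from scipy import stats

import chwplan as cp
from chwplan import reference as ref
from chwplan.timeuse import (
    kruskal_wallis,
    median_difference_test,
    percent_longer,
    proportion_test,
)
from oracles import kruskal_wallis_oracle, small_kw_instances


def test_summarize_times_odd_count_median(tiny_dataset):
    out = cp.summarize_times(tiny_dataset)
    assert len(out) == 1
    assert out["median_activity"].iloc[0] == 50
    assert out["median_travel"].iloc[0] == 15
    assert out["n_episodes"].iloc[0] == 3


def test_summarize_times_identical_durations(tiny_dataset):
    entries = [
        cp.DiaryEntry(
            "c", "d", cp.SiteClass.RURAL, 1, "meeting",
            travel_minutes=7, activity_minutes=90,
        )
        for _ in range(4)
    ]
    out = cp.summarize_times(cp.DiaryDataset(entries=entries))
    assert out["median_activity"].iloc[0] == 90


def _two_entry_dataset(minutes_a, minutes_b, codes=("meeting", "training")):
    entries = [
        cp.DiaryEntry("c", "d", cp.SiteClass.PERI_URBAN, 1, code,
                      travel_minutes=0, activity_minutes=m)
        for m, code in zip((minutes_a, minutes_b), codes)
    ]
    return cp.DiaryDataset(entries=entries)


def test_share_of_time_normalization():
    ds = _two_entry_dataset(30, 70)
    one_group = cp.share_of_time(ds, {"meeting": "g", "training": "g"})
    assert one_group["share"].iloc[0] == pytest.approx(1.0)
    two_groups = cp.share_of_time(ds, {"meeting": "a", "training": "b"})
    shares = dict(zip(two_groups["activity_group"], two_groups["share"]))
    assert shares == {"a": pytest.approx(0.3), "b": pytest.approx(0.7)}


def test_share_of_time_errors():
    ds = _two_entry_dataset(30, 70)
    with pytest.raises(cp.ValidationError, match="training"):
        cp.share_of_time(ds, {"meeting": "g"})
    zero = _two_entry_dataset(0, 0)
    with pytest.raises(cp.ValidationError, match="zero combined"):
        cp.share_of_time(zero, {"meeting": "g", "training": "g"})


def test_shares_sum_to_one_per_cell(sed_pu_diaries, umz_dr_diaries):
    merged = cp.DiaryDataset(
        entries=sed_pu_diaries.entries + umz_dr_diaries.entries
    )
    shares = cp.share_of_time(merged, ref.ACTIVITY_GROUPS)
    sums = shares.groupby(["district", "site_class"])["share"].sum()
    assert np.allclose(sums, 1.0, atol=0.005)


@pytest.mark.parametrize(
    "district, site, expected",
    [(ref.SEDIBENG, cp.SiteClass.PERI_URBAN, 0.66),
     (ref.UMZINYATHI, cp.SiteClass.DEEP_RURAL, 0.49)],
)
def test_recovered_time_shares_match_study_values(district, site, expected):
    """Home-visit time share recovered within 2 points of the published 66%
    (Sedibeng peri-urban) and 49% (uMzinyathi deep-rural).

    Time shares are ratios of heavy-tailed sums, so this uses a larger
    simulated workforce (300 CHWs, ~24,000 episodes) to push the Monte
    Carlo error of the share well below the tolerance.
    """
    ds = cp.generate_diaries(cp.default_config(district, site, n_chws=300, seed=17))
    shares = cp.share_of_time(ds, ref.ACTIVITY_GROUPS)
    home = shares.loc[shares["activity_group"] == "home_visits", "share"].iloc[0]
    assert home == pytest.approx(expected, abs=0.02)


# -- median difference via 0.5-quantile regression ---------------------------


def test_median_difference_identical_groups():
    res = median_difference_test([10, 20, 30], [10, 20, 30], seed=1)
    assert res.estimate == 0
    assert res.p_value > 0.5


def test_median_difference_constant_shift_degenerate():
    res = median_difference_test([10, 10, 10], [20, 20, 20], seed=1)
    assert res.estimate == 10
    assert res.p_value == 1.0  # all-equal groups: estimate defined, p = 1
    assert res.ci_low <= res.estimate <= res.ci_high


def test_median_difference_detects_true_shift():
    rng = np.random.default_rng(1234)
    a = rng.normal(50, 10, 200)
    b = rng.normal(50, 10, 200) + 20
    res = median_difference_test(a, b, n_boot=1000, seed=99)
    assert res.estimate == pytest.approx(20, abs=3)
    assert res.p_value < 0.01
    assert res.ci_low <= res.estimate <= res.ci_high


def test_median_difference_matches_quantile_regression():
    """The group coefficient of a 0.5-quantile regression on an indicator
    equals the difference of group medians (odd counts: unique solution)."""
    from statsmodels.regression.quantile_regression import QuantReg

    rng = np.random.default_rng(7)
    a = np.sort(rng.integers(5, 200, size=51)).astype(float)
    b = np.sort(rng.integers(5, 200, size=75)).astype(float) + 0.5
    res = median_difference_test(a, b, n_boot=10, seed=0)
    y = np.concatenate([a, b])
    X = np.column_stack([np.ones_like(y), np.r_[np.zeros_like(a), np.ones_like(b)]])
    coef = QuantReg(y, X).fit(q=0.5).params[1]
    assert res.estimate == pytest.approx(coef, abs=1e-6)


def test_median_difference_requires_two_observations():
    with pytest.raises(cp.ValidationError):
        median_difference_test([1], [2, 3])


# -- Kruskal-Wallis -----------------------------------------------------------


def test_kruskal_identical_groups():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert res.H == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_kruskal_matches_rank_formula_oracle_on_three_groups():
    groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
    res = kruskal_wallis(groups)
    h, p = kruskal_wallis_oracle(groups)
    assert res.H == pytest.approx(h, abs=1e-12)
    assert res.p_value == pytest.approx(p, abs=1e-12)
    assert res.df == 2


def test_kruskal_all_identical_observations():
    res = kruskal_wallis([[5, 5], [5, 5, 5]])
    assert (res.H, res.p_value) == (0.0, 1.0)


def test_kruskal_two_groups_equals_ranksum():
    """For two tie-free groups, H equals the squared rank-sum z statistic
    and the chi-square p equals the two-sided normal p."""
    rng = np.random.default_rng(3)
    a = rng.permutation(np.arange(1, 30))[:12].astype(float)
    b = np.arange(100, 117).astype(float)
    res = kruskal_wallis([a, b])
    z, p = stats.ranksums(a, b)
    assert res.H == pytest.approx(z**2, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-10)


def test_kruskal_requires_two_nonempty_groups():
    with pytest.raises(cp.ValidationError):
        kruskal_wallis([[1, 2]])
    with pytest.raises(cp.ValidationError):
        kruskal_wallis([[1, 2], []])


# -- test of proportions ------------------------------------------------------


def test_proportion_equal_counts():
    res = proportion_test(50, 100, 50, 100)
    assert res.z == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_proportion_maximal_separation():
    assert proportion_test(0, 10, 10, 10).p_value < 0.001


@pytest.mark.parametrize(
    "x1, n1, x2, n2",
    [(30, 100, 45, 100), (1, 8, 7, 9), (12, 40, 12, 60), (0, 10, 3, 10)],
)
def test_proportion_z_squared_equals_chi_square(x1, n1, x2, n2):
    res = proportion_test(x1, n1, x2, n2)
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    chi2 = stats.chi2_contingency(table, correction=False)
    assert res.z**2 == pytest.approx(chi2.statistic, abs=1e-9)
    assert res.p_value == pytest.approx(chi2.pvalue, abs=1e-9)


def test_proportion_requires_positive_n():
    with pytest.raises(cp.ValidationError):
        proportion_test(0, 0, 1, 10)
    with pytest.raises(cp.ValidationError):
        proportion_test(5, 4, 1, 10)


# -- visit composition --------------------------------------------------------


def _visit(content=(), condition=(), recipients=("adult",)):
    return cp.DiaryEntry(
        "c", "d", cp.SiteClass.RURAL, 1, "home_visit_other",
        travel_minutes=10, activity_minutes=30,
        content_codes=content, condition_codes=condition,
        recipient_types=recipients,
    )


def test_content_is_per_visit_occurrence_rate():
    entries = [_visit(content=("screening",)) for _ in range(4)]
    entries += [_visit() for _ in range(6)]
    table = cp.visit_composition(cp.DiaryDataset(entries=entries), "content")
    assert table.loc[table["category"] == "screening", "proportion"].iloc[0] == 0.4


def test_condition_proportions_over_recorded_codes():
    entries = [_visit(condition=("hiv",)) for _ in range(5)]
    table = cp.visit_composition(cp.DiaryDataset(entries=entries), "condition")
    assert dict(zip(table["category"], table["proportion"])) == {"hiv": 1.0}


def test_composition_requires_home_visits():
    ds = _two_entry_dataset(10, 10)
    with pytest.raises(cp.ValidationError, match="home-visit"):
        cp.visit_composition(ds, "content")
    with pytest.raises(cp.ValidationError, match="dimension"):
        cp.visit_composition(ds, "colour")


def test_content_recovery_tracing_defaulters():
    """Synthetic Sedibeng rural diaries recover the 26% defaulter-tracing
    occurrence rate within 3 points."""
    ds = cp.generate_diaries(
        cp.default_config(ref.SEDIBENG, cp.SiteClass.RURAL, seed=404)
    )
    table = cp.visit_composition(ds, "content")
    rate = table.loc[table["category"] == "tracing_defaulters", "proportion"].iloc[0]
    assert rate == pytest.approx(0.26, abs=0.03)


# -- percent longer -----------------------------------------------------------


@pytest.mark.parametrize(
    "ref_median, other, expected",
    [(40, 60, 50.0), (25, 25, 0.0), (15, 20, pytest.approx(100 / 3))],
)
def test_percent_longer(ref_median, other, expected):
    assert percent_longer(ref_median, other) == expected


def test_percent_longer_zero_reference():
    with pytest.raises(cp.ValidationError):
        percent_longer(0, 10)
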