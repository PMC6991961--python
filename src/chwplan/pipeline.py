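"""End-to-end orchestration: one run configuration in, a directory of
report tables out.

``run_pipeline`` generates (or loads) diary data, runs the time-use
analytics and significance tests, reconstructs the cost, workforce,
household-norm and stipend-scenario tables from the bundled study inputs,
and writes everything as CSV reports plus a JSON manifest with input/output
digests.  Significant cells are encoded as a boolean column, never by
formatting.  The run is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .costing import district_summary, round_half_away, summarize_costs
from .diary import DiaryDataset, read_diaries, write_diaries
from .scenario import StipendScenario, apply_stipend
from .simulate import default_config, generate_diaries
from .timeuse import (
    kruskal_wallis,
    median_difference_test,
    proportion_test,
    share_of_time,
    summarize_times,
    visit_composition,
)
from .workforce import (
    derive_visit_needs,
    households_per_chw,
    relative_requirement,
    staffing_requirement,
    utilization_rates,
)

logger = logging.getLogger("chwplan")

REPORT_FILES = (
    "diaries.csv",
    "table1_time_use.csv",
    "table2_content.csv",
    "table3_conditions.csv",
    "table4_recipients.csv",
    "significance_tests.csv",
    "table5_costs_sedibeng.csv",
    "table6_costs_umzinyathi.csv",
    "table7_utilization.csv",
    "table8_workforce.csv",
    "table9_households.csv",
    "table10_stipend_scenarios.csv",
)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    alpha: float = 0.05
    n_boot: int = 1000
    n_days: int = reference.N_DIARY_DAYS
    #: CHWs per (district, site_class) cell; defaults to the study sample.
    n_chws: dict = field(default_factory=lambda: dict(reference.SAMPLED_CHWS))
    #: Optional pre-existing diary file (skips generation).
    diaries_path: Path | None = None
    new_stipend: float = reference.MINIMUM_WAGE_STIPEND

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _generate_all_diaries(config: RunConfig) -> DiaryDataset:
    cell_seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.n_chws)
    )
    entries = []
    for (district, site), seed in zip(sorted(config.n_chws), cell_seeds):
        gc = default_config(
            district, site, n_chws=config.n_chws[(district, site)],
            seed=int(seed) % (2**31),
        )
        ds = generate_diaries(gc)
        logger.info(
            "simulate: %s/%s -> %d episodes", district, site.value, len(ds)
        )
        entries.extend(ds.entries)
    return DiaryDataset(entries=entries, provenance=f"generated(seed={config.seed})")


def _time_use_reports(
    diaries: DiaryDataset, config: RunConfig, out: Path
) -> None:
    medians = summarize_times(diaries)
    shares = share_of_time(diaries, reference.ACTIVITY_GROUPS)
    medians["activity_group"] = medians["activity_code"].map(
        reference.ACTIVITY_GROUPS
    )
    table1 = medians.merge(
        shares.rename(columns={"share": "group_share"}),
        on=["district", "site_class", "activity_group"],
        how="left",
    )
    _write(table1, out / "table1_time_use.csv")
    for dimension, name in (
        ("content", "table2_content.csv"),
        ("condition", "table3_conditions.csv"),
        ("recipient", "table4_recipients.csv"),
    ):
        _write(visit_composition(diaries, dimension), out / name)


def _significance_report(
    diaries: DiaryDataset, config: RunConfig, out: Path
) -> None:
    """Site-class contrasts within each district: median-difference tests
    per activity and measure, an overall Kruskal-Wallis test per measure,
    and proportion tests on home-visit content occurrence."""
    df = diaries.to_frame()
    rows = []
    rng = np.random.default_rng(config.seed + 1)
    for district, ddf in df.groupby("district", sort=True):
        sites = sorted(ddf["site_class"].unique())
        if len(sites) != 2:
            continue
        ref_site, other_site = sites[::-1] if sites[0] != "peri_urban" else sites
        a_df = ddf[ddf["site_class"] == ref_site]
        b_df = ddf[ddf["site_class"] == other_site]
        for measure in ("travel_minutes", "activity_minutes"):
            groups = [g[measure].to_numpy() for _, g in ddf.groupby("site_class")]
            kw = kruskal_wallis(groups)
            rows.append(
                {
                    "district": district,
                    "test": "kruskal_wallis",
                    "measure": measure,
                    "activity_code": "all",
                    "estimate": kw.H,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": kw.p_value,
                    "significant": kw.p_value < config.alpha,
                }
            )
            for activity in sorted(set(a_df["activity_code"]) & set(b_df["activity_code"])):
                a = a_df.loc[a_df["activity_code"] == activity, measure].to_numpy()
                b = b_df.loc[b_df["activity_code"] == activity, measure].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    continue
                res = median_difference_test(
                    a, b, n_boot=config.n_boot, seed=int(rng.integers(2**31))
                )
                rows.append(
                    {
                        "district": district,
                        "test": "median_difference",
                        "measure": measure,
                        "activity_code": activity,
                        "estimate": res.estimate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "significant": res.p_value < config.alpha,
                    }
                )
        # content occurrence contrasts (test of proportions)
        content = visit_composition(diaries, "content")
        ccell = content[content["district"] == district]
        ref = ccell[ccell["site_class"] == ref_site].set_index("category")
        oth = ccell[ccell["site_class"] == other_site].set_index("category")
        for code in sorted(set(ref.index) & set(oth.index)):
            n1, n2 = int(ref.loc[code, "n"]), int(oth.loc[code, "n"])
            x1 = int(round(ref.loc[code, "proportion"] * n1))
            x2 = int(round(oth.loc[code, "proportion"] * n2))
            pt = proportion_test(x1, n1, x2, n2)
            rows.append(
                {
                    "district": district,
                    "test": "proportion",
                    "measure": "content:" + code,
                    "activity_code": "home_visits",
                    "estimate": pt.p2 - pt.p1,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": pt.p_value,
                    "significant": pt.p_value < config.alpha,
                }
            )
    _write(pd.DataFrame(rows), out / "significance_tests.csv")


def _cost_reports(out: Path) -> None:
    for district, name in (
        (reference.SEDIBENG, "table5_costs_sedibeng.csv"),
        (reference.UMZINYATHI, "table6_costs_umzinyathi.csv"),
    ):
        model = reference.cost_model(district)
        rows = []
        for panel in model.panels:
            s = summarize_costs(model, panel, use_published=True)
            for ln in s.lines:
                rows.append(
                    {
                        "panel": panel,
                        "line": ln.name,
                        "category": ln.category,
                        "cost_class": ln.cost_class,
                        "annual_cost": round_half_away(ln.annual_cost),
                        "annual_cost_per_chw": round_half_away(
                            ln.annual_cost / model.n_chw[panel]
                        ),
                    }
                )
            rows.append(
                {
                    "panel": panel,
                    "line": f"Overheads@{model.overhead_rate:.0%}",
                    "category": "",
                    "cost_class": "",
                    "annual_cost": round_half_away(s.overhead_amount),
                    "annual_cost_per_chw": round_half_away(
                        s.overhead_amount / model.n_chw[panel]
                    ),
                }
            )
            rows.append(
                {
                    "panel": panel,
                    "line": "Total",
                    "category": "",
                    "cost_class": "",
                    "annual_cost": round_half_away(s.total),
                    "annual_cost_per_chw": round_half_away(s.per_chw),
                }
            )
        d = district_summary(model, use_published=True)
        rows.append(
            {
                "panel": "combined",
                "line": "District total",
                "category": "",
                "cost_class": "",
                "annual_cost": round_half_away(d.total),
                "annual_cost_per_chw": round_half_away(d.per_chw),
            }
        )
        _write(pd.DataFrame(rows), out / name)
        logger.info(
            "cost: %s total R%.0f (%.1f%% of PHC per capita)",
            district, d.total, d.phc_share,
        )


def _workforce_reports(out: Path) -> pd.DataFrame:
    rows = []
    hh_rows = [
        {
            "district": "",
            "site_class": "peri_urban",
            "ratio_to_peri_urban": 1.0,
            "households_per_chw": reference.HOUSEHOLDS_PER_CHW_BASE,
        }
    ]
    for district in reference.DISTRICTS:
        results = {}
        for site in reference.DISTRICT_SITES[district]:
            key = (district, site)
            profile = reference.service_time_profile(district, site)
            needs = derive_visit_needs(
                profile, reference.SERVICE_HOURS[key], reference.DEFAULT_COVERAGE
            )
            res = staffing_requirement(
                profile, needs, reference.WORKFORCE_PARAMS[key]
            )
            results[site] = res
            rows.append(
                {
                    "district": district,
                    "site_class": site.value,
                    "total_hours_per_100k": round(res.total_hours, 1),
                    "share_home_visits": reference.WORKFORCE_PARAMS[key].share_home_visits,
                    "available_hours_per_chw": res.available_hours_per_chw,
                    "chws_per_visit": reference.WORKFORCE_PARAMS[key].chws_per_visit,
                    "chws_required": res.chws_required,
                    "chws_required_unrounded": round(res.chws_required_unrounded, 2),
                }
            )
        ref_site, other_site = reference.DISTRICT_SITES[district]
        rel = relative_requirement(results[ref_site], results[other_site])
        rows.append(
            {
                "district": district,
                "site_class": f"{other_site.value} vs {ref_site.value}",
                "total_hours_per_100k": np.nan,
                "share_home_visits": np.nan,
                "available_hours_per_chw": np.nan,
                "chws_per_visit": np.nan,
                "chws_required": np.nan,
                "chws_required_unrounded": np.nan,
                "pct_more_chws_required": rel.percent,
            }
        )
        hh_rows.append(
            {
                "district": district,
                "site_class": other_site.value,
                "ratio_to_peri_urban": round(rel.ratio_unrounded, 4),
                "households_per_chw": households_per_chw(
                    reference.HOUSEHOLDS_PER_CHW_BASE, rel.ratio_unrounded
                ),
            }
        )
    table8 = pd.DataFrame(rows)
    _write(table8, out / "table8_workforce.csv")
    _write(pd.DataFrame(hh_rows), out / "table9_households.csv")
    _write(utilization_rates(reference.UTILIZATION_RECORDS),
           out / "table7_utilization.csv")
    return table8


def _scenario_report(out: Path, new_stipend: float) -> None:
    rows = []
    for district in reference.DISTRICTS:
        model = reference.cost_model(district)
        scenario = StipendScenario(
            district=district,
            current_stipend=reference.CURRENT_STIPEND[district],
            new_stipend=new_stipend,
        )
        res = apply_stipend(model, scenario)
        rows.append(
            {
                "district": district,
                "current_stipend": scenario.current_stipend,
                "new_stipend": scenario.new_stipend,
                "pct_stipend_increase": round(res.pct_stipend_increase, 1),
                "baseline_total": round_half_away(res.baseline_total),
                "new_total": round_half_away(res.new_total),
                "pct_district_increase": round(res.pct_district_increase, 1),
                "per_capita_before": round_half_away(res.per_capita_before),
                "per_capita_after": round_half_away(res.per_capita_after),
                "per_capita_before_unrounded": res.per_capita_before,
                "per_capita_after_unrounded": res.per_capita_after,
                "phc_share_before_pct": round(res.phc_share_before, 1),
                "phc_share_after_pct": round(res.phc_share_after, 1),
            }
        )
    _write(pd.DataFrame(rows), out / "table10_stipend_scenarios.csv")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the report tables, manifest and log."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    if config.diaries_path is not None:
        diaries = read_diaries(config.diaries_path)
        logger.info(
            "diaries: read %d episodes (%d rejected) from %s",
            len(diaries), diaries.n_rejected, config.diaries_path,
        )
    else:
        diaries = _generate_all_diaries(config)
    write_diaries(diaries, out / "diaries.csv")
    logger.info("diaries: %d episodes in, %d out", len(diaries), len(diaries))

    _time_use_reports(diaries, config, out)
    _significance_report(diaries, config, out)
    _cost_reports(out)
    _workforce_reports(out)
    _scenario_report(out, config.new_stipend)

    from . import __version__

    manifest = {
        "package": "chwplan",
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_boot": config.n_boot,
        "n_episodes": len(diaries),
        "n_rejected": diaries.n_rejected,
        "files": {name: _sha256(out / name) for name in REPORT_FILES},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d reports in %s", len(REPORT_FILES), out)
    return out
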