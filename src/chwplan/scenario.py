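"""Stipend / minimum-wage sensitivity analysis.

Rescales the CHW stipend lines of a district cost model to a new monthly
stipend (the R3,500 national minimum wage by default), reapplies the
overhead rate to the incremented subtotal, and recomputes the district
expenditure, per-capita expenditure and PHC-expenditure share.  Supervisor
stipends below the new wage can optionally be raised too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .costing import CostModel, district_summary
from .diary import ValidationError

DEFAULT_NEW_STIPEND = 3_500.0  # ZAR/month national minimum wage


@dataclass(frozen=True)
class StipendScenario:
    district: str
    current_stipend: float  # ZAR/month
    new_stipend: float = DEFAULT_NEW_STIPEND
    raise_supervisors: bool = False

    def __post_init__(self) -> None:
        if self.current_stipend <= 0 or self.new_stipend <= 0:
            raise ValidationError("stipends must be positive")


@dataclass
class ScenarioResult:
    district: str
    pct_stipend_increase: float
    baseline_total: float
    new_total: float
    pct_district_increase: float
    per_capita_before: float
    per_capita_after: float
    phc_share_before: float
    phc_share_after: float


def apply_stipend(
    model: CostModel, scenario: StipendScenario, use_published: bool = True
) -> ScenarioResult:
    """Recompute district expenditure under a changed CHW stipend.

    CHW stipend lines (``stipend_role == 'chw'``) are replaced by
    12 x new_stipend x quantity; with ``raise_supervisors`` supervisor
    stipend lines below the new wage are raised the same way.  Overheads
    reapply to the new subtotal, so the increment is also marked up.
    """
    found_chw = False
    new_panels = {}
    for panel, ingredients in model.panels.items():
        new_lines = []
        for ing in ingredients:
            monthly = 12.0 * scenario.new_stipend
            if ing.stipend_role == "chw":
                found_chw = True
                ing = replace(ing, unit_cost=monthly, published_annual=None)
            elif (
                scenario.raise_supervisors
                and ing.stipend_role == "supervisor"
                and ing.unit_cost < monthly
            ):
                ing = replace(ing, unit_cost=monthly, published_annual=None)
            new_lines.append(ing)
        new_panels[panel] = tuple(new_lines)
    if not found_chw:
        raise ValidationError(
            f"no CHW stipend line found in cost model for {model.district}"
        )
    new_model = CostModel(
        district=model.district,
        panels=new_panels,
        overhead_rate=model.overhead_rate,
        population=model.population,
        n_chw=model.n_chw,
        phc_per_capita=model.phc_per_capita,
        exchange_rate=model.exchange_rate,
    )
    before = district_summary(model, use_published=use_published)
    after = district_summary(new_model, use_published=use_published)
    return ScenarioResult(
        district=model.district,
        pct_stipend_increase=100.0
        * (scenario.new_stipend / scenario.current_stipend - 1.0),
        baseline_total=before.total,
        new_total=after.total,
        pct_district_increase=100.0 * (after.total / before.total - 1.0),
        per_capita_before=before.per_capita,
        per_capita_after=after.per_capita,
        phc_share_before=before.phc_share,
        phc_share_after=after.phc_share,
    )
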