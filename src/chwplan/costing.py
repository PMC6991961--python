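"""Ingredient-based programme costing.

Each priced line item (ingredient) is annualized by straight-line
depreciation — unit cost x quantity x allocation share / life years — with
recurrent items carrying a life of one year.  Panel subtotals receive a
proportional overhead mark-up; district metrics (cost per capita, cost per
CHW, share of PHC expenditure per capita) combine all panels.

Ingredients may carry the published annualized figure alongside the unit
cost (source tables round some unit costs); ``use_published=True`` swaps the
published value in for exact reconstruction of the printed totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .diary import ValidationError

COST_CLASSES = (
    "infrastructure",
    "equipment",
    "training",
    "salary",
    "maintenance",
    "supplies",
    "transport",
)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for currency)."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor if ndigits else float(rounded)


@dataclass(frozen=True)
class CostIngredient:
    """One priced line item.

    ``category`` is ``setup`` (capital, annualized over ``life_years``) or
    ``recurrent`` (``life_years`` must be 1).  ``allocation_share`` is the
    fraction of the resource attributed to the programme (shared nurses,
    health posts).  ``published_annual`` optionally carries the source
    table's printed annualized district cost.  ``stipend_role`` tags stipend
    lines ("chw" or "supervisor") for scenario analysis.
    """

    name: str
    category: str
    cost_class: str
    unit_cost: float
    quantity: float
    life_years: float = 1.0
    allocation_share: float = 1.0
    published_annual: float | None = None
    stipend_role: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ("setup", "recurrent"):
            raise ValidationError(f"unknown cost category: {self.category!r}")
        if self.cost_class not in COST_CLASSES:
            raise ValidationError(f"unknown cost class: {self.cost_class!r}")
        if self.unit_cost < 0 or self.quantity < 0:
            raise ValidationError("unit_cost and quantity must be non-negative")
        if not 0.0 <= self.allocation_share <= 1.0:
            raise ValidationError("allocation_share must be in [0, 1]")
        if self.category == "recurrent" and self.life_years != 1:
            raise ValidationError("recurrent ingredients must have life_years == 1")


def annualize(ingredient: CostIngredient) -> float:
    """Annualized programme cost of one ingredient (currency/year)."""
    if ingredient.life_years <= 0:
        raise ValidationError(f"{ingredient.name}: life_years must be positive")
    return (
        ingredient.unit_cost
        * ingredient.quantity
        * ingredient.allocation_share
        / ingredient.life_years
    )


@dataclass
class CostModel:
    """A district's panels of ingredients plus its costing parameters."""

    district: str
    panels: Mapping[str, tuple[CostIngredient, ...]]
    overhead_rate: float
    population: int
    n_chw: Mapping[str, int]
    phc_per_capita: float
    exchange_rate: float = 14.3  # ZAR per USD

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError("population must be positive")
        if any(n <= 0 for n in self.n_chw.values()):
            raise ValidationError("n_chw must be positive")
        if not 0.0 <= self.overhead_rate < 1.0:
            raise ValidationError("overhead_rate must be in [0, 1)")
        self.panels = {k: tuple(v) for k, v in self.panels.items()}
        self.n_chw = dict(self.n_chw)

    @property
    def total_chws(self) -> int:
        return sum(self.n_chw.values())


@dataclass(frozen=True)
class CostLine:
    name: str
    category: str
    cost_class: str
    annual_cost: float


@dataclass
class CostSummary:
    """Annualized cost summary for one panel or the combined district.

    ``per_capita`` and ``phc_share`` are district-level metrics and are only
    populated on summaries that combine all panels (``district_summary``).
    """

    district: str
    panel: str
    lines: list[CostLine]
    subtotal: float
    overhead_amount: float
    total: float
    per_chw: float
    per_capita: float | None = None
    phc_share: float | None = None

    def line(self, name: str) -> float:
        for ln in self.lines:
            if ln.name == name:
                return ln.annual_cost
        raise KeyError(name)


def _line_value(ing: CostIngredient, use_published: bool) -> float:
    if use_published and ing.published_annual is not None:
        return float(ing.published_annual)
    return annualize(ing)


def summarize_costs(
    model: CostModel, panel: str, use_published: bool = False
) -> CostSummary:
    """Annualize one panel: lines, subtotal, overhead and total.

    ``total = subtotal * (1 + overhead_rate)`` exactly; per-CHW cost divides
    the panel total by the panel's CHW count.
    """
    if panel not in model.panels:
        raise KeyError(f"unknown panel {panel!r} for {model.district}")
    lines = [
        CostLine(i.name, i.category, i.cost_class, _line_value(i, use_published))
        for i in model.panels[panel]
    ]
    subtotal = sum(ln.annual_cost for ln in lines)
    overhead = subtotal * model.overhead_rate
    total = subtotal + overhead
    return CostSummary(
        district=model.district,
        panel=panel,
        lines=lines,
        subtotal=subtotal,
        overhead_amount=overhead,
        total=total,
        per_chw=total / model.n_chw[panel],
    )


def district_summary(model: CostModel, use_published: bool = False) -> CostSummary:
    """Combine all panels into district totals, per-capita and PHC-share.

    Line names are prefixed with their panel so repeated items (e.g. CHW
    stipends appearing in each panel) stay distinct.
    """
    lines: list[CostLine] = []
    subtotal = overhead = total = 0.0
    for panel in model.panels:
        s = summarize_costs(model, panel, use_published=use_published)
        lines.extend(
            CostLine(f"{panel}:{ln.name}", ln.category, ln.cost_class, ln.annual_cost)
            for ln in s.lines
        )
        subtotal += s.subtotal
        overhead += s.overhead_amount
        total += s.total
    per_capita = total / model.population
    return CostSummary(
        district=model.district,
        panel="combined",
        lines=lines,
        subtotal=subtotal,
        overhead_amount=overhead,
        total=total,
        per_chw=total / model.total_chws,
        per_capita=per_capita,
        phc_share=100.0 * per_capita / model.phc_per_capita,
    )


def class_share(summary: CostSummary, classes: Iterable[str]) -> float:
    """Percent of the summary total contributed by the given cost classes.

    Overheads are excluded from the numerator (they carry no cost class), so
    the shares of all classes together sum to ``100 / (1 + overhead_rate)``.
    """
    classes = set(classes)
    if not classes:
        return 0.0
    part = sum(ln.annual_cost for ln in summary.lines if ln.cost_class in classes)
    return 100.0 * part / summary.total


def to_usd(amount: float, model: CostModel) -> float:
    if model.exchange_rate <= 0:
        raise ValidationError("exchange rate must be positive")
    return amount / model.exchange_rate


# -- serialization ----------------------------------------------------------

_INGREDIENT_COLUMNS = (
    "panel",
    "name",
    "category",
    "cost_class",
    "unit_cost",
    "quantity",
    "life_years",
    "allocation_share",
    "published_annual",
    "stipend_role",
)


def read_ingredients(path: str | Path) -> dict[str, tuple[CostIngredient, ...]]:
    """Read an ingredient CSV into panels (see :data:`_INGREDIENT_COLUMNS`)."""
    df = pd.read_csv(path)
    for col in ("panel", "name", "category", "cost_class", "unit_cost", "quantity"):
        if col not in df.columns:
            raise ValidationError(f"missing mandatory column: {col}")
    panels: dict[str, list[CostIngredient]] = {}
    for row in df.to_dict("records"):
        published = row.get("published_annual")
        role = row.get("stipend_role")
        ing = CostIngredient(
            name=str(row["name"]),
            category=str(row["category"]),
            cost_class=str(row["cost_class"]),
            unit_cost=float(row["unit_cost"]),
            quantity=float(row["quantity"]),
            life_years=float(row.get("life_years", 1.0) or 1.0),
            allocation_share=float(row.get("allocation_share", 1.0)),
            published_annual=None if pd.isna(published) else float(published),
            stipend_role=None if (role is None or pd.isna(role)) else str(role),
        )
        panels.setdefault(str(row["panel"]), []).append(ing)
    return {k: tuple(v) for k, v in panels.items()}


def write_ingredients(
    panels: Mapping[str, tuple[CostIngredient, ...]], path: str | Path
) -> None:
    rows = []
    for panel, ings in panels.items():
        for i in ings:
            rows.append(
                {
                    "panel": panel,
                    "name": i.name,
                    "category": i.category,
                    "cost_class": i.cost_class,
                    "unit_cost": i.unit_cost,
                    "quantity": i.quantity,
                    "life_years": i.life_years,
                    "allocation_share": i.allocation_share,
                    "published_annual": i.published_annual,
                    "stipend_role": i.stipend_role,
                }
            )
    pd.DataFrame(rows, columns=list(_INGREDIENT_COLUMNS)).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_district_config(path: str | Path) -> dict:
    """District parameters (population, n_chw per panel, overhead_rate,
    phc_per_capita, exchange_rate) from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("district", "population", "n_chw", "phc_per_capita"):
        if key not in cfg:
            raise ValidationError(f"district config missing key: {key}")
    return cfg


def build_model(
    panels: Mapping[str, tuple[CostIngredient, ...]], config: Mapping
) -> CostModel:
    n_chw = config["n_chw"]
    if not isinstance(n_chw, Mapping):
        n_chw = {panel: int(n_chw) for panel in panels}
    return CostModel(
        district=config["district"],
        panels=panels,
        overhead_rate=float(config.get("overhead_rate", 0.0)),
        population=int(config["population"]),
        n_chw={k: int(v) for k, v in n_chw.items()},
        phc_per_capita=float(config["phc_per_capita"]),
        exchange_rate=float(config.get("exchange_rate", 14.3)),
    )


def scale_unit_costs(model: CostModel, k: float) -> CostModel:
    """Return a copy of the model with every unit cost multiplied by ``k``."""
    panels = {
        panel: tuple(
            replace(
                i,
                unit_cost=i.unit_cost * k,
                published_annual=None
                if i.published_annual is None
                else i.published_annual * k,
            )
            for i in ings
        )
        for panel, ings in model.panels.items()
    }
    return CostModel(
        district=model.district,
        panels=panels,
        overhead_rate=model.overhead_rate,
        population=model.population,
        n_chw=model.n_chw,
        phc_per_capita=model.phc_per_capita,
        exchange_rate=model.exchange_rate,
    )
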