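"""Activity-diary data model and delimited-text I/O.

A diary records one row per activity episode of a community health worker
(CHW): who, where (district and site class), which day of the ten-day
collection window, which activity, minutes spent travelling and minutes
spent on the activity itself, plus the visit attributes recorded for home
visits (content of the visit, condition addressed, up to three recipients).

Serialization is a delimited table (comma by default, tab accepted) with a
fixed column order; multi-valued cells are semicolon-delimited.  Rows that
fail validation are rejected with a categorized reason rather than silently
repaired: accepted + rejected always equals the number of input rows.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("chwplan")


class ChwplanError(Exception):
    """Base class for package errors."""


class ValidationError(ChwplanError):
    """Input data violates the data contract (CLI exit code 2)."""


class SchemaError(ValidationError):
    """A required column is missing or the file layout is unusable."""


class SiteClass(str, enum.Enum):
    """Geographical site classes, ordered by decreasing density.

    ``rural`` denotes regrouped farm-worker settlements; ``deep_rural``
    sparsely populated remote areas.  They are distinct classes.
    """

    PERI_URBAN = "peri_urban"
    RURAL = "rural"
    DEEP_RURAL = "deep_rural"


# Activity vocabulary (union over both districts' diary forms).
ACTIVITY_CODES: frozenset[str] = frozenset(
    {
        "household_registration",
        "household_screening",
        "home_visit_other",
        "facility_visit",
        "support_group",
        "creche_ecd",
        "other_institution",
        "health_day",
        "school_health",
        "meeting",
        "phila_mtwana",
        "campaign",
        "war_room",
        "training",
        "other",
    }
)

# Activities that constitute a home visit (unit of analysis for visit
# content / condition / recipient tables).
HOME_VISIT_CODES: frozenset[str] = frozenset(
    {"household_registration", "household_screening", "home_visit_other"}
)

CONTENT_CODES: frozenset[str] = frozenset(
    {
        "screening",
        "health_education",
        "bring_medicines",
        "tracing_defaulters",
        "hbc",
        "referral",
        "dots",
        "child_health",
        "other",
    }
)

CONDITION_CODES: frozenset[str] = frozenset(
    {"mother_child", "hiv", "tb", "chronic", "nutrition", "fp", "other", "unknown"}
)

RECIPIENT_TYPES: frozenset[str] = frozenset(
    {
        "pregnant",
        "postnatal",
        "infant",
        "age1_5",
        "age5_18",
        "adult",
        "elderly",
        "family",
        "community",
        "unknown",
    }
)

MAX_RECIPIENTS = 3  # the diary form allows recording up to 3 recipients
DEFAULT_MAX_DAY = 10  # two consecutive working weeks

#: Canonical column order of the diary table.
DIARY_COLUMNS: tuple[str, ...] = (
    "chw_id",
    "district",
    "site_class",
    "day_index",
    "activity_code",
    "travel_minutes",
    "activity_minutes",
    "content_codes",
    "condition_codes",
    "recipient_types",
)

_MANDATORY = DIARY_COLUMNS[:7]
_MULTI = DIARY_COLUMNS[7:]


@dataclass(frozen=True)
class DiaryEntry:
    """One timed activity episode.

    ``travel_minutes`` and ``activity_minutes`` are non-negative; recipients
    are capped at :data:`MAX_RECIPIENTS`; ``day_index`` must fall inside the
    collection window (validated at parse time, where the window length is
    configurable).
    """

    chw_id: str
    district: str
    site_class: SiteClass
    day_index: int
    activity_code: str
    travel_minutes: float
    activity_minutes: float
    content_codes: tuple[str, ...] = ()
    condition_codes: tuple[str, ...] = ()
    recipient_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.travel_minutes < 0 or self.activity_minutes < 0:
            raise ValidationError("minutes must be non-negative")
        if self.day_index < 1:
            raise ValidationError("day_index must be >= 1")
        if len(self.recipient_types) > MAX_RECIPIENTS:
            raise ValidationError(
                f"at most {MAX_RECIPIENTS} recipients per episode"
            )

    @property
    def combined_minutes(self) -> float:
        return combined_minutes(self)


def combined_minutes(entry: DiaryEntry) -> float:
    """Travel plus activity minutes for one episode."""
    return entry.travel_minutes + entry.activity_minutes


@dataclass(frozen=True)
class RowRejection:
    row: int  # 0-based data-row index in the source file
    reason: str
    detail: str = ""


@dataclass
class DiaryDataset:
    """A validated collection of diary entries plus provenance.

    Equality compares the entries only; rejection bookkeeping and provenance
    are metadata.
    """

    entries: list[DiaryEntry]
    provenance: str = ""
    rejections: list[RowRejection] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        self.provenance = str(self.provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiaryDataset):
            return NotImplemented
        return self.entries == other.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def to_frame(self) -> pd.DataFrame:
        """Entries as a DataFrame (multi-valued fields stay tuples)."""
        df = pd.DataFrame(
            {
                "chw_id": [e.chw_id for e in self.entries],
                "district": [e.district for e in self.entries],
                "site_class": [e.site_class.value for e in self.entries],
                "day_index": [e.day_index for e in self.entries],
                "activity_code": [e.activity_code for e in self.entries],
                "travel_minutes": [e.travel_minutes for e in self.entries],
                "activity_minutes": [e.activity_minutes for e in self.entries],
                "content_codes": [e.content_codes for e in self.entries],
                "condition_codes": [e.condition_codes for e in self.entries],
                "recipient_types": [e.recipient_types for e in self.entries],
            }
        )
        df["combined_minutes"] = df["travel_minutes"] + df["activity_minutes"]
        return df


def _parse_minutes(raw: str, column: str) -> float:
    text = raw.strip()
    if not text:
        raise ValidationError(f"missing {column}")
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(f"non-numeric {column}: {text!r}") from None
    if value < 0:
        raise ValidationError(f"negative {column}: {value}")
    return int(value) if value == int(value) else value


def _parse_multi(raw: str, allowed: frozenset[str], column: str) -> tuple[str, ...]:
    text = raw.strip()
    if not text:
        return ()
    codes = tuple(c.strip() for c in text.split(";") if c.strip())
    unknown = [c for c in codes if c not in allowed]
    if unknown:
        raise ValidationError(f"unknown {column} code(s): {unknown}")
    return codes


def _parse_row(
    row: Mapping[str, str],
    allowed_activities: frozenset[str],
    max_day: int,
) -> DiaryEntry:
    activity = row["activity_code"].strip()
    if activity not in allowed_activities:
        raise ValidationError(f"unknown activity code: {activity!r}")
    try:
        site = SiteClass(row["site_class"].strip())
    except ValueError:
        raise ValidationError(
            f"unknown site class: {row['site_class']!r}"
        ) from None
    try:
        day = int(str(row["day_index"]).strip())
    except ValueError:
        raise ValidationError(f"non-integer day_index: {row['day_index']!r}") from None
    if not 1 <= day <= max_day:
        raise ValidationError(f"day_index {day} outside 1..{max_day}")
    return DiaryEntry(
        chw_id=row["chw_id"].strip(),
        district=row["district"].strip(),
        site_class=site,
        day_index=day,
        activity_code=activity,
        travel_minutes=_parse_minutes(row["travel_minutes"], "travel_minutes"),
        activity_minutes=_parse_minutes(row["activity_minutes"], "activity_minutes"),
        content_codes=_parse_multi(
            row.get("content_codes", ""), CONTENT_CODES, "content"
        ),
        condition_codes=_parse_multi(
            row.get("condition_codes", ""), CONDITION_CODES, "condition"
        ),
        recipient_types=_parse_multi(
            row.get("recipient_types", ""), RECIPIENT_TYPES, "recipient"
        ),
    )


def read_diaries(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    sep: str | None = None,
    allowed_activities: Iterable[str] | None = None,
    max_day: int = DEFAULT_MAX_DAY,
) -> DiaryDataset:
    """Read a diary table, validating every row.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema_config
        Optional mapping of canonical column name -> column name in the
        file, for files whose headers differ from :data:`DIARY_COLUMNS`.
    sep
        Field delimiter; inferred from the extension when omitted
        (``.tsv`` -> tab, otherwise comma).
    allowed_activities
        District-configurable activity vocabulary; rows with codes outside
        it are rejected (never pooled into ``other``).
    max_day
        Length of the collection window in days.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (names the column).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (schema_config or {}).items()}
    df = df.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    allowed = frozenset(allowed_activities) if allowed_activities else ACTIVITY_CODES

    entries: list[DiaryEntry] = []
    rejections: list[RowRejection] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            entries.append(_parse_row(row, allowed, max_day))
        except ValidationError as exc:
            rejections.append(RowRejection(row=i, reason=str(exc)))
            logger.info("rejected row %d of %s: %s", i, path.name, exc)
    if rejections:
        logger.warning(
            "%s: accepted %d rows, rejected %d", path.name, len(entries), len(rejections)
        )
    return DiaryDataset(entries=entries, provenance=str(path), rejections=rejections)


def _fmt_minutes(value: float) -> str:
    return str(int(value)) if value == int(value) else repr(value)


def write_diaries(dataset: DiaryDataset, path: str | Path, sep: str = ",") -> None:
    """Write a diary table in the canonical column order.

    The output is re-readable bit-identically: ``read_diaries`` of the
    written file reproduces the dataset.
    """
    path = Path(path)
    rows = []
    for e in dataset.entries:
        rows.append(
            {
                "chw_id": e.chw_id,
                "district": e.district,
                "site_class": e.site_class.value,
                "day_index": e.day_index,
                "activity_code": e.activity_code,
                "travel_minutes": _fmt_minutes(e.travel_minutes),
                "activity_minutes": _fmt_minutes(e.activity_minutes),
                "content_codes": ";".join(e.content_codes),
                "condition_codes": ";".join(e.condition_codes),
                "recipient_types": ";".join(e.recipient_types),
            }
        )
    df = pd.DataFrame(rows, columns=list(DIARY_COLUMNS))
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")
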