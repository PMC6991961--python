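"""Synthetic CHW activity-diary generator.

Real diary data from the study is not publicly available, so this module
generates diary datasets with controlled statistical structure: an activity
mix per district x site class, travel and activity durations drawn from a
log-normal law parameterized by its median (median = exp(mu)) and a
log-scale dispersion, and per-visit content/condition/recipient attributes.
Default configurations reproduce the published medians, time shares and
composition frequencies, so parameter recovery can be asserted end to end.

Durations are rounded to whole minutes (diaries record minutes) with a
floor of 1 minute.  Episodes per CHW-day are Poisson (truncated at >= 1).
Content codes are independent per-visit Bernoulli occurrences at their
configured rates (they co-occur within a visit); condition and recipient
codes are categorical draws.  Generation is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .diary import (
    ACTIVITY_CODES,
    HOME_VISIT_CODES,
    DiaryDataset,
    DiaryEntry,
    SiteClass,
    ValidationError,
)

_PROB_TOL = 1e-9
DEFAULT_DISPERSION = 0.6  # log-scale spread; unrecoverable from medians alone
DEFAULT_EPISODES_PER_DAY = 8.0
#: Recipients per home visit average 1.1: one guaranteed plus up to two
#: extras at 5% each.
EXTRA_RECIPIENT_PROB = 0.05


@dataclass(frozen=True)
class ActivityProfile:
    """Generation parameters for one activity code."""

    activity_code: str
    probability: float
    travel_median: float
    activity_median: float
    dispersion: float = DEFAULT_DISPERSION
    content_probs: Mapping[str, float] = field(default_factory=dict)
    condition_probs: Mapping[str, float] = field(default_factory=dict)
    recipient_probs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity_code not in ACTIVITY_CODES:
            raise ValidationError(f"unknown activity code: {self.activity_code!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError("activity probability must be in [0, 1]")
        if self.probability > 0 and min(self.travel_median, self.activity_median) <= 0:
            raise ValidationError("medians must be positive for active profiles")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        for name, dist in (
            ("condition_probs", self.condition_probs),
            ("recipient_probs", self.recipient_probs),
        ):
            if dist and abs(sum(dist.values()) - 1.0) > _PROB_TOL:
                raise ValidationError(f"{name} must sum to 1")
        if any(not 0.0 <= p <= 1.0 for p in self.content_probs.values()):
            raise ValidationError("content rates must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    district: str
    site_class: SiteClass
    n_chws: int
    profiles: tuple[ActivityProfile, ...]
    n_days: int = 10
    episodes_per_day_mean: float = DEFAULT_EPISODES_PER_DAY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chws < 1 or self.n_days < 1:
            raise ValidationError("n_chws and n_days must be >= 1")
        if self.episodes_per_day_mean <= 0:
            raise ValidationError("episodes_per_day_mean must be positive")
        total = sum(p.probability for p in self.profiles)
        if abs(total - 1.0) > _PROB_TOL:
            raise ValidationError(
                f"activity probabilities must sum to 1 (got {total})"
            )


def _draw_duration(rng: np.random.Generator, median: float, dispersion: float) -> int:
    if dispersion == 0:
        value = median
    else:
        value = math.exp(rng.normal(math.log(median), dispersion))
    return max(1, int(round(value)))


def _draw_categorical(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = list(dist)
    return keys[rng.choice(len(keys), p=np.asarray(list(dist.values())))]


def generate_diaries(config: GeneratorConfig) -> DiaryDataset:
    """Generate a validated diary dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    profiles = [p for p in config.profiles if p.probability > 0]
    probs = np.asarray([p.probability for p in profiles])
    probs = probs / probs.sum()

    prefix = f"{config.district[:3].upper()}-{config.site_class.value}"
    entries: list[DiaryEntry] = []
    for chw in range(1, config.n_chws + 1):
        chw_id = f"{prefix}-{chw:04d}"
        for day in range(1, config.n_days + 1):
            n_episodes = max(1, int(rng.poisson(config.episodes_per_day_mean)))
            kinds = rng.choice(len(profiles), size=n_episodes, p=probs)
            for k in kinds:
                prof = profiles[k]
                content: tuple[str, ...] = ()
                condition: tuple[str, ...] = ()
                recipients: tuple[str, ...] = ()
                if prof.activity_code in HOME_VISIT_CODES:
                    content = tuple(
                        code
                        for code, rate in prof.content_probs.items()
                        if rng.random() < rate
                    )
                    if prof.condition_probs:
                        condition = (_draw_categorical(rng, prof.condition_probs),)
                    if prof.recipient_probs:
                        n_rec = 1 + int(rng.binomial(2, EXTRA_RECIPIENT_PROB))
                        drawn = [
                            _draw_categorical(rng, prof.recipient_probs)
                            for _ in range(n_rec)
                        ]
                        recipients = tuple(dict.fromkeys(drawn))  # dedupe, keep order
                entries.append(
                    DiaryEntry(
                        chw_id=chw_id,
                        district=config.district,
                        site_class=config.site_class,
                        day_index=day,
                        activity_code=prof.activity_code,
                        travel_minutes=_draw_duration(
                            rng, prof.travel_median, prof.dispersion
                        ),
                        activity_minutes=_draw_duration(
                            rng, prof.activity_median, prof.dispersion
                        ),
                        content_codes=content,
                        condition_codes=condition,
                        recipient_types=recipients,
                    )
                )
    return DiaryDataset(entries=entries, provenance=f"generated(seed={config.seed})")


def _renormalize(dist: Mapping[str, float]) -> dict[str, float]:
    total = sum(dist.values())
    if total <= 0:
        raise ValidationError("distribution has no mass")
    return {k: v / total for k, v in dist.items()}


def default_config(
    district: str,
    site_class: SiteClass,
    n_chws: int | None = None,
    seed: int = 0,
    dispersion: float = DEFAULT_DISPERSION,
) -> GeneratorConfig:
    """Generator configuration reproducing the published study conditions.

    Activity probabilities are chosen so that the *expected share of
    combined time* per activity equals the published share-of-time column:
    with a common log-scale dispersion the expected duration of an activity
    is proportional to its median, so p(a) is proportional to
    share(a) / (travel_median(a) + activity_median(a)), where rows published
    as 0% (i.e. under 0.5%) absorb an equal split of the column's rounding
    residue.  Condition and recipient columns are
    renormalized to sum to 1 (several published columns sum to 104-118%
    because codes are recorded per visit); content rates are used as printed
    (per-visit occurrence rates).
    """
    from . import reference

    key = (district, SiteClass(site_class))
    if key not in reference.TIME_USE:
        raise ValidationError(
            f"no published parameters for district {district!r}, "
            f"site class {site_class!r}"
        )
    time_use = reference.TIME_USE[key]
    content = reference.CONTENT_RATES[key]
    condition = _renormalize(reference.CONDITION_SHARES[key])
    recipients = _renormalize(reference.RECIPIENT_SHARES[key])

    # Published share columns sum to slightly under 100% because rows under
    # 0.5% print as 0%.  Spread the residue equally over the 0% rows so the
    # expected share of every non-zero row equals its printed value.
    shares = {code: share for code, (_t, _a, share) in time_use.items()}
    residue = 100.0 - sum(shares.values())
    zero_rows = [code for code, share in shares.items() if share == 0]
    if residue > 0 and zero_rows:
        for code in zero_rows:
            shares[code] = residue / len(zero_rows)

    weights = {
        code: shares[code] / (travel + activity)
        for code, (travel, activity, _share) in time_use.items()
        if shares[code] > 0
    }
    total_w = sum(weights.values())

    profiles = []
    for code, (travel, activity, _share) in time_use.items():
        if code not in weights:
            continue
        is_visit = code in HOME_VISIT_CODES
        profiles.append(
            ActivityProfile(
                activity_code=code,
                probability=weights[code] / total_w,
                travel_median=travel,
                activity_median=activity,
                dispersion=dispersion,
                content_probs=content if is_visit else {},
                condition_probs=condition if is_visit else {},
                recipient_probs=recipients if is_visit else {},
            )
        )
    # remove float renormalization residue so the config invariant holds
    residue = 1.0 - sum(p.probability for p in profiles)
    profiles[0] = replace(profiles[0], probability=profiles[0].probability + residue)

    if n_chws is None:
        n_chws = reference.SAMPLED_CHWS[key]
    return GeneratorConfig(
        district=district,
        site_class=SiteClass(site_class),
        n_chws=n_chws,
        profiles=tuple(profiles),
        n_days=reference.N_DIARY_DAYS,
        seed=seed,
    )


# -- config (de)serialization ------------------------------------------------


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    data = {
        "district": config.district,
        "site_class": config.site_class.value,
        "n_chws": config.n_chws,
        "n_days": config.n_days,
        "episodes_per_day_mean": config.episodes_per_day_mean,
        "seed": config.seed,
        "profiles": [
            {
                "activity_code": p.activity_code,
                "probability": p.probability,
                "travel_median": p.travel_median,
                "activity_median": p.activity_median,
                "dispersion": p.dispersion,
                "content_probs": dict(p.content_probs),
                "condition_probs": dict(p.condition_probs),
                "recipient_probs": dict(p.recipient_probs),
            }
            for p in config.profiles
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    profiles = tuple(ActivityProfile(**p) for p in data.pop("profiles"))
    data["site_class"] = SiteClass(data["site_class"])
    return GeneratorConfig(profiles=profiles, **data)
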