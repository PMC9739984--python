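"""Questionnaire and 24-h recall ingestion; per-group consumption profiles.

The propensity questionnaire (PQ) records, per respondent and food group,
how many times (1-10) the group was eaten per day/week/month/year, without
portion sizes. Portion (per-capita) amounts and the preparation mix come
from a 24-h dietary recall (24HR) pooled over the cohort. Liquids reported
in mL are converted to mass through an explicit dilution table; foods seen
in the recall are matched to the coefficient table directly or through an
alias map. Each group's profile holds the times-weighted per-capita amount
(grams per consumption occasion), the times-weighted footprint coefficients
and the group's mean caloric density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from enf.errors import MissingDataError, ValidationError
from enf.foodb import CompositionEntry, FoodItemCoefficient, group_mean_kcal

PERIODS = ("day", "week", "month", "year")


@dataclass(frozen=True)
class PQResponse:
    """One frequency report: `count` times per `period` for one group."""

    respondent_id: str
    group_id: str
    count: int
    period: str

    def __post_init__(self) -> None:
        if not (1 <= self.count <= 10):
            raise ValidationError(
                f"PQ count must be in 1..10, got {self.count} "
                f"(respondent {self.respondent_id}, group {self.group_id})"
            )
        if self.period not in PERIODS:
            raise ValidationError(
                f"unknown period {self.period!r}; expected one of {PERIODS}"
            )


@dataclass(frozen=True)
class RecallObservation:
    """One 24HR line: an amount of a food, with preparation and multiplicity."""

    respondent_id: str
    food_id: str
    group_id: str
    amount: float
    unit: str  # "g" or "mL"
    preparation: str
    times: int = 1

    def __post_init__(self) -> None:
        if not (self.amount > 0):
            raise ValidationError(
                f"recall amount must be > 0, got {self.amount} "
                f"(food {self.food_id})"
            )
        if self.unit not in ("g", "mL"):
            raise ValidationError(f"unit must be g or mL, got {self.unit!r}")
        if self.times < 1:
            raise ValidationError(f"times must be >= 1, got {self.times}")


@dataclass(frozen=True)
class DilutionRule:
    """Density rule converting a volume (mL) to mass (g) for a food or group."""

    key: str  # food_id, or group_id as fallback
    grams_per_ml: float

    def __post_init__(self) -> None:
        if not (self.grams_per_ml > 0):
            raise ValidationError(
                f"grams_per_ml must be > 0, got {self.grams_per_ml} "
                f"for {self.key!r}"
            )


class DilutionTable:
    """Lookup of dilution rules: food_id first, then group_id fallback."""

    def __init__(self, rules: Iterable[DilutionRule]):
        self._rules = {r.key: r for r in rules}

    @classmethod
    def from_csv(cls, path: str | Path) -> "DilutionTable":
        df = pd.read_csv(path, dtype={"key": str})
        return cls(
            DilutionRule(rec.key, float(rec.grams_per_ml))
            for rec in df.itertuples(index=False)
        )

    def lookup(self, food_id: str, group_id: str) -> DilutionRule:
        rule = self._rules.get(food_id) or self._rules.get(group_id)
        if rule is None:
            raise MissingDataError(
                f"no dilution rule for food {food_id!r} (group {group_id!r}); "
                "liquids are never assumed 1 g/mL unless the table says so"
            )
        return rule

    def __len__(self) -> int:
        return len(self._rules)


@dataclass(frozen=True)
class GroupProfile:
    """Cohort-level consumption profile of one food group."""

    group_id: str
    per_capita_g: float  # grams per consumption occasion
    cf_per_kg: float
    wf_per_kg: float
    ef_per_kg: float
    kcal_per_100g: float

    def __post_init__(self) -> None:
        if self.per_capita_g < 0:
            raise ValidationError(
                f"per_capita_g must be >= 0 for group {self.group_id}"
            )


def volume_to_mass(amount_ml: float, rule: DilutionRule) -> float:
    """grams = mL x density (g/mL)."""
    return amount_ml * rule.grams_per_ml


def _observation_mass(obs: RecallObservation,
                      rules: DilutionTable | None) -> float:
    if obs.unit == "g":
        return obs.amount
    if rules is None:
        raise MissingDataError(
            f"observation of {obs.food_id!r} is in mL but no dilution "
            "table was supplied"
        )
    return volume_to_mass(obs.amount, rules.lookup(obs.food_id, obs.group_id))


def group_per_capita(
    observations: Sequence[RecallObservation],
    rules: DilutionTable | None = None,
    estimator: Literal["weighted_mean", "median"] = "weighted_mean",
) -> float:
    """Per-capita amount (g per occasion) for one group from pooled 24HR.

    The default estimator is the mean of mass amounts weighted by the number
    of times each food was consumed. ``estimator="median"`` gives the
    unweighted median of the (times-expanded) amounts as an alternative
    reading of the protocol.
    """
    if not observations:
        raise MissingDataError("no observations for group")
    gids = {o.group_id for o in observations}
    if len(gids) > 1:
        raise ValidationError(f"observations span several groups: {sorted(gids)}")
    masses = np.array([_observation_mass(o, rules) for o in observations])
    times = np.array([o.times for o in observations], dtype=float)
    if estimator == "median":
        expanded = np.repeat(masses, times.astype(int))
        return float(np.median(expanded))
    return float(np.average(masses, weights=times))


def group_coefficients(
    observations: Sequence[RecallObservation],
    table: Sequence[FoodItemCoefficient],
    alias_map: Mapping[str, str] | None = None,
) -> tuple[float, float, float]:
    """Times-weighted mean footprint coefficients over a group's observed foods.

    Each observed (food_id, preparation) must resolve to a coefficient row,
    directly or through ``alias_map`` (observed name -> table food_id);
    unresolved foods are reported together.
    """
    if not observations:
        raise MissingDataError("no observations for group")
    index: dict[tuple[str, str], FoodItemCoefficient] = {
        (c.food_id, c.preparation): c for c in table
    }
    by_food: dict[str, list[FoodItemCoefficient]] = {}
    for c in table:
        by_food.setdefault(c.food_id, []).append(c)
    alias_map = alias_map or {}

    coefs, weights, misses = [], [], []
    for obs in observations:
        fid = alias_map.get(obs.food_id, obs.food_id)
        row = index.get((fid, obs.preparation))
        if row is None:
            # fall back to a single-preparation food
            candidates = by_food.get(fid, [])
            if len(candidates) == 1:
                row = candidates[0]
        if row is None:
            misses.append(f"{obs.food_id!r} ({obs.preparation})")
            continue
        coefs.append((row.cf_per_kg, row.wf_per_kg, row.ef_per_kg))
        weights.append(obs.times)
    if misses:
        raise MissingDataError(
            "foods without a coefficient row (add alias-map entries): "
            + ", ".join(sorted(set(misses)))
        )
    arr = np.array(coefs, dtype=float)
    w = np.array(weights, dtype=float)
    cf, wf, ef = np.average(arr, axis=0, weights=w)
    return float(cf), float(wf), float(ef)


def build_group_profiles(
    recall: Sequence[RecallObservation],
    coefficients: Sequence[FoodItemCoefficient],
    composition: Sequence[CompositionEntry],
    rules: DilutionTable | None = None,
    alias_map: Mapping[str, str] | None = None,
    estimator: Literal["weighted_mean", "median"] = "weighted_mean",
) -> dict[str, GroupProfile]:
    """Pooled cohort profiles for every group seen in the 24HR.

    Groups with no recall observation are simply absent (never imputed as
    zero); the footprint stage treats a PQ report for an absent group as an
    error unless the caller drops it explicitly.
    """
    by_group: dict[str, list[RecallObservation]] = {}
    for obs in recall:
        by_group.setdefault(obs.group_id, []).append(obs)
    profiles: dict[str, GroupProfile] = {}
    for gid, observations in by_group.items():
        per_capita = group_per_capita(observations, rules, estimator)
        cf, wf, ef = group_coefficients(observations, coefficients, alias_map)
        kcal = group_mean_kcal(composition, gid)
        profiles[gid] = GroupProfile(gid, per_capita, cf, wf, ef, kcal)
    return profiles


def load_pq(path: str | Path) -> list[PQResponse]:
    df = pd.read_csv(path, dtype={"respondent_id": str, "group_id": str,
                                  "period": str})
    return [
        PQResponse(r.respondent_id, r.group_id, int(r.count), r.period)
        for r in df.itertuples(index=False)
    ]


def load_recall(path: str | Path) -> list[RecallObservation]:
    df = pd.read_csv(path, dtype={"respondent_id": str, "food_id": str,
                                  "group_id": str, "unit": str,
                                  "preparation": str})
    return [
        RecallObservation(r.respondent_id, r.food_id, r.group_id,
                          float(r.amount), r.unit, r.preparation,
                          int(r.times))
        for r in df.itertuples(index=False)
    ]


def load_alias_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"observed_name", "food_id"} <= set(df.columns):
        raise ValidationError(
            f"{path}: alias map needs columns observed_name, food_id"
        )
    return dict(zip(df["observed_name"], df["food_id"]))
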