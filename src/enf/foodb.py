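"""Footprint-coefficient and food-composition tables.

The footprint table carries, per food and preparation, the life-cycle
("farm to fork") coefficients: carbon (g CO2eq per kg), water (L per kg)
and ecological (m2 per kg). The composition table carries energy density
(kcal per 100 g edible portion). Both are user-supplied CSVs; this module
validates them against the questionnaire's food-group registry and exposes
the per-group mean caloric density used for the energy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from enf.errors import ValidationError

COEFFICIENT_COLUMNS = [
    "food_id", "group_id", "preparation",
    "cf_g_co2eq_per_kg", "wf_l_per_kg", "ef_m2_per_kg",
]
COMPOSITION_COLUMNS = ["food_id", "group_id", "kcal_per_100g"]


@dataclass(frozen=True)
class FoodItemCoefficient:
    """One food/preparation row of the LCA footprint table."""

    food_id: str
    group_id: str
    preparation: str
    cf_per_kg: float  # g CO2eq / kg
    wf_per_kg: float  # L / kg
    ef_per_kg: float  # m2 / kg

    def __post_init__(self) -> None:
        if not self.group_id:
            raise ValidationError(f"food {self.food_id!r}: empty group_id")
        for name in ("cf_per_kg", "wf_per_kg", "ef_per_kg"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValidationError(
                    f"food {self.food_id!r} ({self.preparation}): "
                    f"{name} must be >= 0, got {v}"
                )


@dataclass(frozen=True)
class CompositionEntry:
    """Energy density of one food, kcal per 100 g edible portion."""

    food_id: str
    group_id: str
    kcal_per_100g: float

    def __post_init__(self) -> None:
        if not (self.kcal_per_100g >= 0):
            raise ValidationError(
                f"food {self.food_id!r}: kcal_per_100g must be >= 0, "
                f"got {self.kcal_per_100g}"
            )


@dataclass
class FoodGroupRegistry:
    """Ordered registry of the questionnaire's food groups.

    The study instrument covers 41 groups; any non-empty ordered set with
    unique ids is accepted.
    """

    groups: dict[str, str] = field(default_factory=dict)  # id -> display name

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("registry must contain at least one group")

    @classmethod
    def from_ids(cls, ids: Sequence[str]) -> "FoodGroupRegistry":
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate group ids in registry")
        return cls({g: g for g in ids})

    @classmethod
    def from_file(cls, path: str | Path) -> "FoodGroupRegistry":
        """Read a registry: YAML list/mapping or one group id per line."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text)
            if isinstance(data, dict):
                return cls({str(k): str(v) for k, v in data.items()})
            return cls.from_ids([str(g) for g in data])
        ids = [line.strip() for line in text.splitlines() if line.strip()]
        return cls.from_ids(ids)

    @property
    def ids(self) -> list[str]:
        return list(self.groups)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self.groups

    def __len__(self) -> int:
        return len(self.groups)


def load_coefficients(
    path: str | Path, registry: FoodGroupRegistry
) -> list[FoodItemCoefficient]:
    """Load and validate the footprint-coefficient CSV.

    Every row must name a group present in ``registry``; offending rows are
    rejected together in one error listing them. Duplicate
    (food_id, preparation) pairs are an error, not a silent overwrite.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"coefficient file not found: {path}")
    df = pd.read_csv(path, dtype={"food_id": str, "group_id": str,
                                  "preparation": str})
    missing = [c for c in COEFFICIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    rows: list[FoodItemCoefficient] = []
    bad_groups: list[str] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # header=1
        for col in ("cf_g_co2eq_per_kg", "wf_l_per_kg", "ef_m2_per_kg"):
            v = getattr(rec, col)
            if pd.isna(v) or not isinstance(v, (int, float)):
                raise ValidationError(f"{path} row {i}: non-numeric {col}")
        try:
            item = FoodItemCoefficient(
                food_id=rec.food_id,
                group_id=rec.group_id,
                preparation=rec.preparation,
                cf_per_kg=float(rec.cf_g_co2eq_per_kg),
                wf_per_kg=float(rec.wf_l_per_kg),
                ef_per_kg=float(rec.ef_m2_per_kg),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        if item.group_id not in registry:
            bad_groups.append(
                f"row {i}: unknown group_id {item.group_id!r} "
                f"(food {item.food_id!r})"
            )
            continue
        rows.append(item)
    if bad_groups:
        raise ValidationError(
            "rows with group_id absent from registry rejected:\n  "
            + "\n  ".join(bad_groups)
        )
    keys = [(r.food_id, r.preparation) for r in rows]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (food_id, preparation) rows: {dupes}")
    return rows


def write_coefficients(
    items: Iterable[FoodItemCoefficient], path: str | Path
) -> None:
    """Write coefficients back to the CSV dialect `load_coefficients` reads."""
    df = pd.DataFrame(
        [
            (r.food_id, r.group_id, r.preparation,
             r.cf_per_kg, r.wf_per_kg, r.ef_per_kg)
            for r in items
        ],
        columns=COEFFICIENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_composition(
    path: str | Path, registry: FoodGroupRegistry
) -> list[CompositionEntry]:
    """Load the kcal-per-100-g composition CSV, validated like coefficients."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"composition file not found: {path}")
    df = pd.read_csv(path, dtype={"food_id": str, "group_id": str})
    missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    entries: list[CompositionEntry] = []
    bad_groups: list[str] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        if rec.group_id not in registry:
            bad_groups.append(f"row {i}: unknown group_id {rec.group_id!r}")
            continue
        try:
            entries.append(
                CompositionEntry(rec.food_id, rec.group_id,
                                 float(rec.kcal_per_100g))
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    if bad_groups:
        raise ValidationError(
            "composition rows with unknown group rejected:\n  "
            + "\n  ".join(bad_groups)
        )
    return entries


def group_mean_kcal(
    entries: Iterable[CompositionEntry], group_id: str
) -> float:
    """Unweighted arithmetic mean kcal/100 g over a group's foods.

    The energy estimate attributes to every group the plain mean of all
    composition-table foods that fit it; an empty group is an error rather
    than a silent 0 kcal (which would inflate adjusted footprints).
    """
    values = [e.kcal_per_100g for e in entries if e.group_id == group_id]
    if not values:
        raise MissingKcalError(group_id)
    return float(sum(values) / len(values))


class MissingKcalError(ValidationError):
    def __init__(self, group_id: str):
        super().__init__(f"no composition entries for group {group_id!r}")
        self.group_id = group_id
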