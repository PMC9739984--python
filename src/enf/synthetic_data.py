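"""Synthetic study-input generator.

Emulates the data model of a cross-sectional dietary survey: a footprint
coefficient table over food groups and preparations, a food-composition
(kcal) table, respondent covariates drawn from configurable category
marginals (defaulting to the study cohort's published frequencies, e.g.
42.1% male, 53.5% adults, 35.3% white), a 12-month propensity questionnaire
(count 1-10 per day/week/month/year) and single-day 24-h recall
observations. Food groups are partitioned into classes whose coefficient
magnitudes are synthetic but ordered realistically: the ruminant-meat class
carries carbon coefficients an order of magnitude above plant classes, so
animal-source groups dominate generated footprints.

Covariate effects are multiplicative: an entry ``{"income": {"ruminant_meat":
1.5}}`` scales consumption frequency and recall amounts of ruminant-meat
groups geometrically from 1.0 in the lowest income category to 1.5 in the
highest, yielding the monotone footprint gradients the association analyses
are meant to recover. An empty effect spec is the exact null.

All randomness flows from one seed through per-table child streams, so a
cohort is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from enf.errors import ValidationError
from enf.foodb import (
    COEFFICIENT_COLUMNS,
    COMPOSITION_COLUMNS,
    CompositionEntry,
    FoodGroupRegistry,
    FoodItemCoefficient,
)
from enf.intake import DilutionRule, DilutionTable, PQResponse, RecallObservation

# ---------------------------------------------------------------------------
# food classes: synthetic coefficient / composition / behaviour ranges

FOOD_CLASSES = (
    "ruminant_meat", "other_animal", "processed", "staple", "plant",
    "beverage",
)

#: number of groups per class in the default 41-group questionnaire
_CLASS_COUNTS_41 = {
    "ruminant_meat": 3, "other_animal": 7, "processed": 6,
    "staple": 8, "plant": 11, "beverage": 6,
}

#: per-kg coefficient ranges (CF g CO2eq, WF L, EF m2) — synthetic magnitudes
DEFAULT_COEFFICIENT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "ruminant_meat": {"cf": (25000, 45000), "wf": (10000, 17000),
                      "ef": (120, 320)},
    "other_animal": {"cf": (4000, 9000), "wf": (2500, 6000), "ef": (20, 80)},
    "processed": {"cf": (2000, 5000), "wf": (1200, 3000), "ef": (8, 30)},
    "staple": {"cf": (600, 2000), "wf": (500, 2500), "ef": (2, 12)},
    "plant": {"cf": (300, 1200), "wf": (200, 1200), "ef": (1, 8)},
    "beverage": {"cf": (150, 900), "wf": (300, 1800), "ef": (0.5, 4)},
}

_KCAL_RANGES = {
    "ruminant_meat": (180, 280), "other_animal": (120, 250),
    "processed": (250, 450), "staple": (80, 200), "plant": (20, 90),
    "beverage": (5, 60),
}

#: behavioural parameters per class: probability the group is ever consumed,
#: baseline consumption rate (occasions/day), median portion (g or mL)
_BEHAVIOUR = {
    "ruminant_meat": (0.75, 0.18, 120.0),
    "other_animal": (0.85, 0.30, 100.0),
    "processed": (0.60, 0.10, 80.0),
    "staple": (0.95, 0.60, 150.0),
    "plant": (0.80, 0.40, 100.0),
    "beverage": (0.85, 0.50, 200.0),
}

# ---------------------------------------------------------------------------
# covariate schema: ordered categories (lowest expected footprint first) and
# default marginals from the study cohort's published frequency table

_raw_marginals: dict[str, dict[str, float]] = {
    "sex": {"female": 0.579, "male": 0.421},
    "age_group": {"elderly": 0.465, "adult": 0.535},
    "ethnicity": {"non_white": 0.647, "white": 0.353},
    "schooling": {"0-5y": 0.358, "6-9y": 0.152, "10-13y": 0.309,
                  "14y+": 0.181},
    "income": {"Q1": 0.209, "Q2": 0.190, "Q3": 0.202, "Q4": 0.200,
               "Q5": 0.200},
    "fast_food": {"never": 0.657, "sometimes": 0.293, "often": 0.050},
    "snack_bar": {"never": 0.575, "hardly_ever": 0.298, "weekly": 0.128},
    "street_fair": {"never": 0.291, "sometimes": 0.386, "often": 0.323},
    "delivery": {"never": 0.619, "sometimes": 0.308, "often": 0.073},
}


def _normalized(marg: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    out = {}
    for var, cats in marg.items():
        total = sum(cats.values())
        out[var] = {c: p / total for c, p in cats.items()}
    return out


DEFAULT_MARGINALS = _normalized(_raw_marginals)

#: study-like effect specification: higher income / male / adult / white
#: categories consume more of the high-footprint animal classes
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "income": {"ruminant_meat": 1.5, "other_animal": 1.2},
    "sex": {"ruminant_meat": 1.3},
    "age_group": {"ruminant_meat": 1.2},
    "ethnicity": {"ruminant_meat": 1.15},
    "fast_food": {"processed": 1.4},
}

NULL_EFFECTS: dict[str, dict[str, float]] = {}


@dataclass
class GeneratorConfig:
    n_respondents: int = 411
    n_groups: int = 41
    seed: int = 0
    category_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {v: dict(c) for v, c in
                                 DEFAULT_MARGINALS.items()})
    effect_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {v: dict(c) for v, c in
                                 DEFAULT_EFFECTS.items()})
    coefficient_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COEFFICIENT_RANGES.items()})
    freq_noise_sd: float = 0.40   # lognormal sd of individual rates
    amount_noise_sd: float = 0.35  # lognormal sd of recall amounts

    def __post_init__(self) -> None:
        if self.n_respondents < 3:
            raise ValidationError("n_respondents must be >= 3")
        if self.n_groups < 2:
            raise ValidationError("n_groups must be >= 2")
        for var, cats in self.category_marginals.items():
            total = sum(cats.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"marginals for {var!r} sum to {total}, not 1"
                )
        for var, classes in self.effect_spec.items():
            if var not in self.category_marginals:
                raise ValidationError(f"effect on unknown variable {var!r}")
            for cls, eff in classes.items():
                if cls not in FOOD_CLASSES:
                    raise ValidationError(f"effect on unknown class {cls!r}")
                if not (eff > 0):
                    raise ValidationError(
                        f"effect must be > 0, got {eff} for {var}/{cls}"
                    )


@dataclass
class SyntheticCohort:
    """All four pipeline inputs plus the ground-truth effect spec."""

    config: GeneratorConfig
    registry: FoodGroupRegistry
    group_classes: dict[str, str]
    coefficients: pd.DataFrame   # foodb coefficient CSV dialect
    composition: pd.DataFrame    # foodb composition CSV dialect
    covariates: pd.DataFrame     # respondent_id + one column per variable
    pq: pd.DataFrame             # respondent_id, group_id, count, period
    recall: pd.DataFrame         # recall CSV dialect
    dilution: pd.DataFrame       # key, grams_per_ml

    def coefficient_items(self) -> list[FoodItemCoefficient]:
        return [
            FoodItemCoefficient(r.food_id, r.group_id, r.preparation,
                                r.cf_g_co2eq_per_kg, r.wf_l_per_kg,
                                r.ef_m2_per_kg)
            for r in self.coefficients.itertuples(index=False)
        ]

    def composition_entries(self) -> list[CompositionEntry]:
        return [
            CompositionEntry(r.food_id, r.group_id, r.kcal_per_100g)
            for r in self.composition.itertuples(index=False)
        ]

    def pq_responses(self) -> list[PQResponse]:
        return [
            PQResponse(r.respondent_id, r.group_id, int(r.count), r.period)
            for r in self.pq.itertuples(index=False)
        ]

    def recall_observations(self) -> list[RecallObservation]:
        return [
            RecallObservation(r.respondent_id, r.food_id, r.group_id,
                              float(r.amount), r.unit, r.preparation,
                              int(r.times))
            for r in self.recall.itertuples(index=False)
        ]

    def dilution_table(self) -> DilutionTable:
        return DilutionTable(
            DilutionRule(r.key, float(r.grams_per_ml))
            for r in self.dilution.itertuples(index=False)
        )

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Emit the CSV dialects the ingestion modules consume."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "coefficients": directory / "coefficients.csv",
            "composition": directory / "composition.csv",
            "covariates": directory / "covariates.csv",
            "pq": directory / "pq.csv",
            "recall": directory / "recall.csv",
            "dilution": directory / "dilution.csv",
            "registry": directory / "groups.txt",
        }
        self.coefficients.to_csv(paths["coefficients"], index=False)
        self.composition.to_csv(paths["composition"], index=False)
        self.covariates.to_csv(paths["covariates"], index=False)
        self.pq.to_csv(paths["pq"], index=False)
        self.recall.to_csv(paths["recall"], index=False)
        self.dilution.to_csv(paths["dilution"], index=False)
        paths["registry"].write_text(
            "\n".join(self.registry.ids) + "\n", encoding="utf-8"
        )
        return paths


def _assign_classes(n_groups: int) -> list[str]:
    """Partition group slots into classes, proportional to the 41-group mix.

    Largest-remainder apportionment, with every class guaranteed one slot
    once n_groups >= the number of classes, so even small questionnaires
    span the full coefficient-magnitude spectrum.
    """
    total = sum(_CLASS_COUNTS_41.values())
    quotas = {c: n_groups * k / total for c, k in _CLASS_COUNTS_41.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    if n_groups >= len(FOOD_CLASSES):
        for c in counts:
            counts[c] = max(counts[c], 1)
    remainder = n_groups - sum(counts.values())
    by_frac = sorted(FOOD_CLASSES, key=lambda c: quotas[c] - int(quotas[c]),
                     reverse=True)
    i = 0
    while remainder > 0:
        counts[by_frac[i % len(by_frac)]] += 1
        remainder -= 1
        i += 1
    while remainder < 0:  # possible only when the >=1 floor overshot
        for c in sorted(counts, key=lambda c: counts[c], reverse=True):
            if counts[c] > 1 and remainder < 0:
                counts[c] -= 1
                remainder += 1
    out: list[str] = []
    for cls in FOOD_CLASSES:
        out.extend([cls] * counts[cls])
    return out[:n_groups]


def category_multipliers(
    covariates: pd.DataFrame,
    effect_spec: Mapping[str, Mapping[str, float]],
    marginals: Mapping[str, Mapping[str, float]],
) -> dict[str, np.ndarray]:
    """Per-respondent multiplicative effect for every food class.

    Within a variable, ordered categories (registry order, lowest first) get
    multiplier effect**(k / (K-1)); effects across variables multiply.
    """
    n = len(covariates)
    mult = {cls: np.ones(n) for cls in FOOD_CLASSES}
    for var, classes in effect_spec.items():
        cats = list(marginals[var])
        ranks = covariates[var].map({c: i for i, c in enumerate(cats)})
        frac = ranks.to_numpy(dtype=float) / max(len(cats) - 1, 1)
        for cls, eff in classes.items():
            mult[cls] = mult[cls] * np.power(eff, frac)
    return mult


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort, deterministic in ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_food = np.random.default_rng(streams[0])
    rng_cov = np.random.default_rng(streams[1])
    rng_pq = np.random.default_rng(streams[2])
    rng_recall = np.random.default_rng(streams[3])

    group_ids = [f"g{i + 1:02d}" for i in range(config.n_groups)]
    classes = _assign_classes(config.n_groups)
    group_classes = dict(zip(group_ids, classes))
    registry = FoodGroupRegistry.from_ids(group_ids)

    # --- food tables -------------------------------------------------------
    coef_rows, comp_rows, dilution_rows = [], [], []
    preparations = ("raw", "boiled", "fried")
    foods_per_group = 2
    for gid, cls in zip(group_ids, classes):
        ranges = config.coefficient_ranges[cls]
        kcal_lo, kcal_hi = _KCAL_RANGES[cls]
        if cls == "beverage":
            dilution_rows.append((gid, 1.0))  # thin liquids: group default
        for f in range(foods_per_group):
            fid = f"{gid}_f{f + 1}"
            n_preps = int(rng_food.integers(1, 3))
            preps = list(rng_food.choice(preparations, size=n_preps,
                                         replace=False))
            for prep in preps:
                coef_rows.append((
                    fid, gid, prep,
                    float(rng_food.uniform(*ranges["cf"])),
                    float(rng_food.uniform(*ranges["wf"])),
                    float(rng_food.uniform(*ranges["ef"])),
                ))
            comp_rows.append((fid, gid,
                              float(rng_food.uniform(kcal_lo, kcal_hi))))
    # a couple of non-unit densities (e.g. whole milk, reconstituted powder)
    beverage_foods = [r[0] for r in coef_rows
                      if group_classes[r[1]] == "beverage"]
    for fid, dens in zip(sorted(set(beverage_foods))[:2], (1.03, 0.95)):
        dilution_rows.append((fid, dens))

    coefficients = pd.DataFrame(coef_rows, columns=COEFFICIENT_COLUMNS)
    composition = pd.DataFrame(comp_rows, columns=COMPOSITION_COLUMNS)
    dilution = pd.DataFrame(dilution_rows, columns=["key", "grams_per_ml"])

    # --- covariates --------------------------------------------------------
    n = config.n_respondents
    respondent_ids = [f"r{i + 1:04d}" for i in range(n)]
    cov_data: dict[str, list[str]] = {"respondent_id": respondent_ids}
    for var, cats in config.category_marginals.items():
        labels = list(cats)
        cov_data[var] = list(rng_cov.choice(labels, size=n,
                                            p=list(cats.values())))
    covariates = pd.DataFrame(cov_data)

    # --- consumption structure --------------------------------------------
    mult = category_multipliers(covariates, config.effect_spec,
                                config.category_marginals)
    class_arr = np.array(classes)
    p_consume = np.array([_BEHAVIOUR[c][0] for c in classes])
    base_rate = np.array([_BEHAVIOUR[c][1] for c in classes])
    base_amount = np.array([_BEHAVIOUR[c][2] for c in classes])
    mult_matrix = np.column_stack([mult[c] for c in classes])  # (n, g)

    consumed = rng_pq.random((n, config.n_groups)) < p_consume
    rates = (base_rate * mult_matrix
             * rng_pq.lognormal(0.0, config.freq_noise_sd,
                                (n, config.n_groups)))

    # choose the smallest period whose expected count reaches 1; clip to 1..10
    divisors = np.array([1.0, 7.0, 30.0, 365.0])
    period_names = np.array(["day", "week", "month", "year"])
    expected = rates[:, :, None] * divisors  # (n, g, 4)
    valid = expected >= 1.0
    period_idx = np.where(valid.any(axis=2), valid.argmax(axis=2), 3)
    counts = np.rint(
        np.take_along_axis(expected, period_idx[:, :, None], axis=2)[:, :, 0]
    )
    counts = np.clip(counts, 1, 10).astype(int)

    ii, gg = np.nonzero(consumed)
    pq = pd.DataFrame({
        "respondent_id": np.array(respondent_ids)[ii],
        "group_id": np.array(group_ids)[gg],
        "count": counts[ii, gg],
        "period": period_names[period_idx[ii, gg]],
    })

    # --- 24-h recall -------------------------------------------------------
    # a group shows up in the single-day recall with probability ~ its daily
    # rate; amounts carry the same covariate multiplier plus portion noise
    recall_prob = np.where(consumed, np.minimum(rates, 1.0), 0.0)
    rii, rgg = np.nonzero(rng_recall.random((n, config.n_groups))
                          < recall_prob)
    amounts = (base_amount[rgg] * mult_matrix[rii, rgg]
               * rng_recall.lognormal(0.0, config.amount_noise_sd,
                                      size=len(rii)))
    food_pick = rng_recall.integers(0, foods_per_group, size=len(rii))
    food_ids = [f"{group_ids[g]}_f{f + 1}" for g, f in zip(rgg, food_pick)]
    prep_lookup: dict[str, list[str]] = {}
    for r in coef_rows:
        prep_lookup.setdefault(r[0], []).append(r[2])
    preps = [prep_lookup[fid][int(rng_recall.integers(0, len(prep_lookup[fid])))]
             for fid in food_ids]
    units = np.where(class_arr[rgg] == "beverage", "mL", "g")
    times = 1 + rng_recall.poisson(0.3, size=len(rii))

    recall = pd.DataFrame({
        "respondent_id": np.array(respondent_ids)[rii],
        "food_id": food_ids,
        "group_id": np.array(group_ids)[rgg],
        "amount": amounts,
        "unit": units,
        "preparation": preps,
        "times": times,
    })

    # referential integrity: every group reported in the PQ must have at
    # least one pooled recall observation, else its profile is undefined
    seen = set(recall["group_id"])
    fallback_rows = []
    for g, gid in enumerate(group_ids):
        if gid in set(pq["group_id"]) and gid not in seen:
            fid = f"{gid}_f1"
            fallback_rows.append({
                "respondent_id": respondent_ids[
                    int(rng_recall.integers(0, n))],
                "food_id": fid,
                "group_id": gid,
                "amount": float(base_amount[g]),
                "unit": "mL" if classes[g] == "beverage" else "g",
                "preparation": prep_lookup[fid][0],
                "times": 1,
            })
    if fallback_rows:
        recall = pd.concat([recall, pd.DataFrame(fallback_rows)],
                           ignore_index=True)

    return SyntheticCohort(
        config=config, registry=registry, group_classes=group_classes,
        coefficients=coefficients, composition=composition,
        covariates=covariates, pq=pq, recall=recall, dilution=dilution,
    )


def ground_truth_report(cohort: SyntheticCohort) -> dict[str, dict]:
    """Which covariate categories should show higher median footprints.

    Effects multiply consumption of specific classes, so for every variable
    in the effect spec the last (highest-multiplier) category is expected to
    exceed the first in median footprint; under the null spec no ordering is
    expected.
    """
    report: dict[str, dict] = {}
    spec = cohort.config.effect_spec
    if not spec:
        return {"__null__": {"expect_ordering": False,
                             "note": "null effect spec: no ordering expected"}}
    for var, classes in spec.items():
        cats = list(cohort.config.category_marginals[var])
        report[var] = {
            "expect_ordering": True,
            "higher": cats[-1],
            "lower": cats[0],
            "classes": dict(classes),
            "note": (f"median footprint of {cats[-1]!r} expected above "
                     f"{cats[0]!r} via {sorted(classes)} consumption"),
        }
    return report
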