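"""Vectorized cohort evaluation and replicated calibration experiments.

The row-wise pipeline in `footprint_core` is the reference implementation;
this module provides an arithmetically identical dense-matrix path used
where thousands of synthetic cohorts must be evaluated (type-I-error
calibration and association-recovery power), plus the replicate drivers
themselves.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from enf.footprint_core import PERIOD_DIVISORS
from enf.stats import kruskal_wallis
from enf.synthetic_data import (
    GeneratorConfig,
    NULL_EFFECTS,
    SyntheticCohort,
    generate,
)


def group_profile_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Pooled group profiles computed by vectorized groupby.

    Mirrors `intake.build_group_profiles`: times-weighted mean mass per
    occasion (after mL->g dilution), times-weighted footprint coefficients
    over the observed (food, preparation) pairs, unweighted mean kcal/100 g.
    Indexed by group_id.
    """
    recall = cohort.recall.copy()
    # dilution: food-level rule wins over group-level rule
    dens = dict(zip(cohort.dilution["key"], cohort.dilution["grams_per_ml"]))
    factor = np.where(
        recall["unit"].to_numpy() == "mL",
        [dens.get(f, dens.get(g, np.nan))
         for f, g in zip(recall["food_id"], recall["group_id"])],
        1.0,
    )
    if np.isnan(factor).any():
        missing = recall.loc[np.isnan(factor), "food_id"].unique()
        raise ValueError(f"no dilution rule for {sorted(missing)}")
    recall["mass_g"] = recall["amount"].to_numpy() * factor

    merged = recall.merge(
        cohort.coefficients,
        on=["food_id", "group_id", "preparation"],
        how="left",
        validate="many_to_one",
    )
    if merged["cf_g_co2eq_per_kg"].isna().any():
        bad = merged.loc[merged["cf_g_co2eq_per_kg"].isna(),
                         "food_id"].unique()
        raise ValueError(f"unresolved coefficient rows for {sorted(bad)}")

    w = merged["times"].astype(float)
    merged["_w"] = w
    for col in ("mass_g", "cf_g_co2eq_per_kg", "wf_l_per_kg", "ef_m2_per_kg"):
        merged[f"_w_{col}"] = merged[col] * w
    g = merged.groupby("group_id")
    wsum = g["_w"].sum()
    profile = pd.DataFrame({
        "per_capita_g": g["_w_mass_g"].sum() / wsum,
        "cf_per_kg": g["_w_cf_g_co2eq_per_kg"].sum() / wsum,
        "wf_per_kg": g["_w_wf_l_per_kg"].sum() / wsum,
        "ef_per_kg": g["_w_ef_m2_per_kg"].sum() / wsum,
        "kcal_per_100g": cohort.composition.groupby("group_id")
                         ["kcal_per_100g"].mean(),
    })
    return profile.dropna(subset=["per_capita_g"])


def cohort_adjusted_footprints(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-respondent footprint table via the dense-matrix path.

    Returns the same columns as `compute_cohort_footprints` plus the
    respondent covariates, one row per respondent with at least one PQ
    report for a profiled group.
    """
    profiles = group_profile_frame(cohort)
    pq = cohort.pq[cohort.pq["group_id"].isin(profiles.index)].copy()
    divisor = pq["period"].map(PERIOD_DIVISORS).to_numpy()
    freq = pq["count"].to_numpy(dtype=float) / divisor
    prof = profiles.loc[pq["group_id"]]
    efc_kg = freq * prof["per_capita_g"].to_numpy() / 1000.0

    out = pd.DataFrame({
        "respondent_id": pq["respondent_id"].to_numpy(),
        "cf_total": efc_kg * prof["cf_per_kg"].to_numpy(),
        "wf_total": efc_kg * prof["wf_per_kg"].to_numpy(),
        "ef_total": efc_kg * prof["ef_per_kg"].to_numpy(),
        "energy_kcal": efc_kg * 10.0 * prof["kcal_per_100g"].to_numpy(),
    })
    totals = out.groupby("respondent_id", sort=True).sum()
    energy = totals["energy_kcal"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for kind in ("cf", "wf", "ef"):
            totals[f"{kind}_1000"] = np.where(
                energy > 0, totals[f"{kind}_total"] * 1000.0 / energy, np.nan
            )
    totals = totals.reset_index()
    return totals.merge(cohort.covariates, on="respondent_id", how="left")


def quintile_test_pvalue(
    cohort: SyntheticCohort,
    variable: str = "income",
    column: str = "cf_1000",
) -> float:
    """Kruskal-Wallis p for an adjusted footprint across a covariate."""
    df = cohort_adjusted_footprints(cohort).dropna(subset=[column])
    groups = [g[column].to_numpy()
              for _, g in df.groupby(variable, sort=True) if len(g) > 0]
    return kruskal_wallis(groups).p_value


def rejection_rate(
    n_replicates: int,
    seed: int,
    effect_spec: dict[str, dict[str, float]] | None = None,
    n_respondents: int = 411,
    n_groups: int = 41,
    alpha: float = 0.05,
    variable: str = "income",
    column: str = "cf_1000",
    progress: Callable[[int], None] | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of replicated cohorts whose quintile test rejects at alpha.

    With ``effect_spec=None`` (the exact null) this measures type-I error;
    with a non-null spec it measures recovery power. Replicate seeds are
    derived deterministically from ``seed``.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    pvals = np.empty(n_replicates)
    for i, s in enumerate(child_seeds):
        cfg = GeneratorConfig(
            n_respondents=n_respondents,
            n_groups=n_groups,
            seed=int(s % (2 ** 31)),
            effect_spec=(dict(effect_spec) if effect_spec is not None
                         else dict(NULL_EFFECTS)),
        )
        pvals[i] = quintile_test_pvalue(generate(cfg), variable, column)
        if progress is not None:
            progress(i + 1)
    return float(np.mean(pvals < alpha)), pvals
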