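"""End-to-end orchestration: ingest -> footprints -> strata -> stats -> CA.

A run reads the six input CSVs (coefficients, composition, PQ, recall,
covariates, dilution, optional alias map), computes per-respondent
footprints and their per-group decomposition, stratifies the cohort into
tertiles of each adjusted footprint, writes contribution tables, a
category-comparison table (n, %, CI95, medians, compact letters, p-values)
and correspondence-analysis coordinates/verdicts, plus a machine-readable
summary. Any stage failure aborts with a stage-named message and removes
partial outputs; identical inputs yield byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from enf import ca as ca_mod
from enf import foodb, intake, strata
from enf.errors import EnfError, ValidationError
from enf.footprint_core import KINDS, compute_cohort_footprints, efc_vectors
from enf.stats import kruskal_wallis, mann_whitney, pairwise_letters

log = logging.getLogger(__name__)

_ADJ_COL = {"CF": "cf_1000", "WF": "wf_1000", "EF": "ef_1000"}
_RAW_COL = {"CF": "cf_total", "WF": "wf_total", "EF": "ef_total"}


@dataclass
class RunConfig:
    coefficients: Path
    composition: Path
    pq: Path
    recall: Path
    covariates: Path
    registry: Path
    output_dir: Path
    dilution: Path | None = None
    alias_map: Path | None = None
    alpha: float = 0.05
    per_capita_mode: Literal["pooled", "individual"] = "pooled"
    tertile_basis: Literal["adjusted", "raw"] = "adjusted"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("coefficients", "composition", "pq", "recall",
                     "covariates", "registry", "dilution", "alias_map"):
            p = getattr(self, name)
            if p is None:
                continue
            p = Path(p)
            setattr(self, name, p)
            if not p.exists():
                raise ValidationError(f"{name} file not found: {p}")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent
        def resolve(v):
            return None if v is None else (base / v if not Path(v).is_absolute()
                                           else Path(v))
        inputs = raw.get("inputs", {})
        return cls(
            coefficients=resolve(inputs["coefficients"]),
            composition=resolve(inputs["composition"]),
            pq=resolve(inputs["pq"]),
            recall=resolve(inputs["recall"]),
            covariates=resolve(inputs["covariates"]),
            registry=resolve(inputs["registry"]),
            dilution=resolve(inputs.get("dilution")),
            alias_map=resolve(inputs.get("alias_map")),
            output_dir=resolve(raw.get("output_dir", "enf_output")),
            alpha=float(raw.get("alpha", 0.05)),
            per_capita_mode=raw.get("per_capita_mode", "pooled"),
            tertile_basis=raw.get("tertile_basis", "adjusted"),
        )


class _StageError(EnfError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _proportion_ci(k: int, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for a category percentage."""
    p = k / n
    half = 1.959963984540054 * np.sqrt(p * (1 - p) / n)
    return 100 * max(p - half, 0.0), 100 * min(p + half, 1.0)


def _comparison_table(
    footprints: pd.DataFrame, covariates: pd.DataFrame, alpha: float
) -> pd.DataFrame:
    """Per-variable category comparison of adjusted footprints.

    For each covariate: category n and % (with 95% CI), the median of each
    adjusted footprint, compact letters from pairwise Mann-Whitney tests and
    the global Mann-Whitney/Kruskal-Wallis p-value. Missing ('DA/DK')
    answers are dropped per variable with a logged count.
    """
    df = footprints.merge(covariates, on="respondent_id", how="inner")
    variables = [c for c in covariates.columns if c != "respondent_id"]
    rows = []
    for var in variables:
        sub = df[~df[var].isin(ca_mod.MISSING_CATEGORIES)
                 & df[var].notna()].copy()
        dropped = len(df) - len(sub)
        if dropped:
            log.info("%s: dropped %d DA/DK answers", var, dropped)
        cats = list(pd.unique(sub[var]))
        n_var = len(sub)
        per_kind: dict[str, dict] = {}
        for kind in KINDS:
            col = _ADJ_COL[kind]
            groups = [sub.loc[sub[var] == c, col].dropna().to_numpy()
                      for c in cats]
            if len(groups) >= 2 and all(len(g) for g in groups):
                if len(groups) == 2:
                    p = mann_whitney(groups[0], groups[1]).p_value
                else:
                    p = kruskal_wallis(groups).p_value
                letters = pairwise_letters(groups, alpha)
            else:
                p, letters = np.nan, ["a"] * len(cats)
            per_kind[kind] = {"p": p, "letters": letters, "groups": groups}
        for idx, cat in enumerate(cats):
            k = int((sub[var] == cat).sum())
            lo, hi = _proportion_ci(k, n_var)
            row = {
                "variable": var, "category": cat, "n": k,
                "percent": 100 * k / n_var,
                "ci95_low": lo, "ci95_high": hi,
                "dropped_da_dk": dropped,
            }
            for kind in KINDS:
                info = per_kind[kind]
                row[f"median_{_ADJ_COL[kind]}"] = (
                    float(np.median(info["groups"][idx]))
                    if len(info["groups"][idx]) else np.nan)
                row[f"letter_{kind.lower()}"] = info["letters"][idx]
                row[f"p_{kind.lower()}"] = info["p"]
            rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it also writes."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    try:
        # ---- ingest ------------------------------------------------------
        try:
            registry = foodb.FoodGroupRegistry.from_file(config.registry)
            coefficients = foodb.load_coefficients(config.coefficients,
                                                   registry)
            composition = foodb.load_composition(config.composition, registry)
        except Exception as exc:
            raise _StageError("foodb", exc) from exc
        try:
            pq = intake.load_pq(config.pq)
            recall = intake.load_recall(config.recall)
            rules = (intake.DilutionTable.from_csv(config.dilution)
                     if config.dilution else None)
            alias = (intake.load_alias_map(config.alias_map)
                     if config.alias_map else None)
            profiles = intake.build_group_profiles(
                recall, coefficients, composition, rules, alias)
        except _StageError:
            raise
        except Exception as exc:
            raise _StageError("intake", exc) from exc

        # ---- footprints --------------------------------------------------
        try:
            overrides = (
                _per_capita_overrides(recall, rules)
                if config.per_capita_mode == "individual" else None)
            footprints, addends = compute_cohort_footprints(
                pq, profiles, on_missing_profile="drop",
                per_capita_overrides=overrides)
        except Exception as exc:
            raise _StageError("footprint_core", exc) from exc
        emit_csv(footprints, "footprints.csv")
        emit_csv(addends, "addends.csv")

        # ---- strata ------------------------------------------------------
        try:
            basis = _ADJ_COL if config.tertile_basis == "adjusted" else _RAW_COL
            tertile_rows, contrib_frames = [], []
            tertiles_by_kind = {}
            for kind in KINDS:
                col = basis[kind]
                values = dict(zip(footprints["respondent_id"],
                                  footprints[col]))
                values = {r: v for r, v in values.items() if not np.isnan(v)}
                assignments, cuts = strata.assign_tertiles(values, kind)
                tertiles_by_kind[kind] = assignments
                tertile_rows.extend(
                    (a.respondent_id, kind, a.label, cuts[0], cuts[1])
                    for a in assignments)
                contrib_frames.append(
                    strata.contribution_long_table(addends, assignments,
                                                   kind))
            tertiles_df = pd.DataFrame(
                tertile_rows,
                columns=["respondent_id", "footprint_kind", "label",
                         "cut_low", "cut_high"])
            contributions = pd.concat(contrib_frames, ignore_index=True)
        except Exception as exc:
            raise _StageError("strata", exc) from exc
        emit_csv(tertiles_df, "tertiles.csv")
        emit_csv(contributions, "contributions.csv")

        # ---- stats -------------------------------------------------------
        try:
            covariates = pd.read_csv(config.covariates,
                                     dtype={"respondent_id": str})
            comparisons = _comparison_table(footprints, covariates,
                                            config.alpha)
        except Exception as exc:
            raise _StageError("stats", exc) from exc
        emit_csv(comparisons, "comparisons.csv")

        # ---- correspondence analysis ------------------------------------
        try:
            coord_rows, verdicts = [], {}
            variables = [c for c in covariates.columns
                         if c != "respondent_id"]
            cov_maps = {v: dict(zip(covariates["respondent_id"],
                                    covariates[v])) for v in variables}
            for kind in KINDS:
                for var in variables:
                    table = ca_mod.build_table(tertiles_by_kind[kind],
                                               cov_maps[var])
                    result = ca_mod.correspondence(table, config.alpha)
                    verdict, rationale = ca_mod.association_verdict(
                        result, config.alpha)
                    verdicts[f"{kind}:{var}"] = {
                        "chi2": result.chi2, "df": result.df,
                        "p_value": result.p_value,
                        "critical_chi2": result.critical_chi2,
                        "verdict": verdict, "rationale": rationale,
                        "nearest_tertile":
                            ca_mod.nearest_row_assignment(result),
                    }
                    coords = ca_mod.coordinates_frame(result)
                    coords.insert(0, "variable", var)
                    coords.insert(0, "footprint_kind", kind)
                    coord_rows.append(coords)
            ca_coords = pd.concat(coord_rows, ignore_index=True)
        except Exception as exc:
            raise _StageError("ca", exc) from exc
        emit_csv(ca_coords, "ca_coordinates.csv")
        verdict_path = out / "ca_verdicts.json"
        verdict_path.write_text(json.dumps(verdicts, indent=2,
                                           sort_keys=True),
                                encoding="utf-8")
        written.append(verdict_path)

        # ---- summary -----------------------------------------------------
        summary = {"n_respondents": int(len(footprints)),
                   "alpha": config.alpha,
                   "per_capita_mode": config.per_capita_mode,
                   "tertile_basis": config.tertile_basis,
                   "footprints": {}}
        for kind in KINDS:
            entry = {}
            for label, col in (("total", _RAW_COL[kind]),
                               ("per_1000_kcal", _ADJ_COL[kind])):
                v = footprints[col].dropna()
                entry[label] = {
                    "median": float(v.median()),
                    "iqr_low": float(v.quantile(0.25)),
                    "iqr_high": float(v.quantile(0.75)),
                    "min": float(v.min()), "max": float(v.max()),
                }
            med = {
                t.label: []
                for t in tertiles_by_kind[kind]}
            adj = dict(zip(footprints["respondent_id"],
                           footprints[_ADJ_COL[kind]]))
            for t in tertiles_by_kind[kind]:
                med[t.label].append(adj[t.respondent_id])
            entry["tertile_medians"] = {
                lbl: float(np.median(vals)) for lbl, vals in med.items()}
            summary["footprints"][kind] = entry
        summary["energy_kcal_median"] = float(
            footprints["energy_kcal"].median())
        summary["excluded_zero_energy"] = int(
            footprints["cf_1000"].isna().sum())
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2,
                                           sort_keys=True),
                                encoding="utf-8")
        written.append(summary_path)
        return summary
    except _StageError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _per_capita_overrides(recall, rules) -> dict[tuple[str, str], float]:
    """Respondent-specific per-capita amounts from each person's own 24HR.

    Groups the respondent never recalled keep the pooled profile amount
    (a single recall day cannot cover a 12-month questionnaire).
    """
    own: dict[tuple[str, str], list] = {}
    for obs in recall:
        own.setdefault((obs.respondent_id, obs.group_id), []).append(obs)
    return {
        key: intake.group_per_capita(obs_list, rules)
        for key, obs_list in own.items()
    }
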