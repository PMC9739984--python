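"""Tertile stratification and per-food-group contribution decomposition.

Respondents are split into low/medium/high thirds of the adjusted (per
1000 kcal) footprint; within each stratum the share each food group
contributes to the pooled footprint is expressed as a percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from enf.errors import ValidationError

TERTILE_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class TertileAssignment:
    respondent_id: str
    footprint_kind: str
    label: str  # low / medium / high


@dataclass
class ContributionTable:
    """Percent contribution of each food group within one stratum."""

    stratum: str  # all / low / medium / high
    footprint_kind: str
    percents: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percents.values())
        if abs(total - 100.0) > 0.01:
            raise ValidationError(
                f"contribution percents sum to {total}, not 100"
            )


def assign_tertiles(
    values: Mapping[str, float], footprint_kind: str = "CF"
) -> tuple[list[TertileAssignment], tuple[float, float]]:
    """Split respondents into low/medium/high thirds of a footprint.

    Cut points are the empirical 1/3 and 2/3 quantiles (linear
    interpolation). Membership is assigned by stable rank order (ties broken
    by input order of respondent ids) so the three groups always differ in
    size by at most one, even under heavy ties; a degenerate all-equal input
    emits a warning.
    """
    ids = list(values)
    vals = np.array([values[r] for r in ids], dtype=float)
    if len(ids) < 3 or np.isnan(vals).any():
        raise ValidationError(
            "need >= 3 respondents with defined values for tertiles"
        )
    cuts = (float(np.quantile(vals, 1 / 3)), float(np.quantile(vals, 2 / 3)))
    if np.ptp(vals) == 0:
        warnings.warn(
            "all footprint values identical; tertiles assigned by stable "
            "order only", stacklevel=2,
        )
    order = np.argsort(vals, kind="stable")
    n = len(ids)
    # balanced split: sizes differ by at most 1, larger groups first
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    assignments: list[TertileAssignment] = [None] * n  # type: ignore
    pos = 0
    for label, size in zip(TERTILE_LABELS, sizes):
        for idx in order[pos:pos + size]:
            assignments[idx] = TertileAssignment(ids[idx], footprint_kind,
                                                 label)
        pos += size
    return assignments, cuts


def contribution(
    addends: pd.DataFrame,
    members: Iterable[str],
    footprint_kind: str,
    stratum: str = "all",
) -> ContributionTable:
    """Percent contribution of each group to a stratum's pooled footprint.

    ``addends`` is the long decomposition table (respondent_id, group_id,
    kind, value); the stratum percent for group g is
    100 x sum over members of addend_g / sum over members of all addends.
    """
    members = set(members)
    if not members:
        raise ValidationError("stratum has no members")
    sub = addends[(addends["kind"] == footprint_kind)
                  & addends["respondent_id"].isin(members)]
    grand = sub["value"].sum()
    if grand <= 0:
        raise ValidationError(
            f"zero pooled {footprint_kind} total in stratum {stratum!r}"
        )
    by_group = sub.groupby("group_id")["value"].sum()
    percents = (100.0 * by_group / grand).to_dict()
    return ContributionTable(stratum, footprint_kind, percents)


def stratum_median(
    values: Mapping[str, float], members: Iterable[str]
) -> float:
    """Median adjusted footprint over a stratum (mid-mean for even n)."""
    members = list(members)
    if not members:
        raise ValidationError("stratum has no members")
    return float(np.median([values[m] for m in members]))


def contribution_long_table(
    addends: pd.DataFrame,
    tertiles: Sequence[TertileAssignment],
    footprint_kind: str,
) -> pd.DataFrame:
    """Long CSV-ready table (stratum, footprint_kind, group_id, percent).

    Covers the pooled cohort plus each tertile, sorted by descending percent
    within stratum — the tabular twin of the contribution figures.
    """
    strata: dict[str, set[str]] = {"all": set()}
    for t in tertiles:
        strata["all"].add(t.respondent_id)
        strata.setdefault(t.label, set()).add(t.respondent_id)
    rows = []
    for stratum in ("all", *TERTILE_LABELS):
        if stratum not in strata:
            continue
        table = contribution(addends, strata[stratum], footprint_kind,
                             stratum)
        for gid, pct in sorted(table.percents.items(),
                               key=lambda kv: -kv[1]):
            rows.append((stratum, footprint_kind, gid, pct))
    return pd.DataFrame(
        rows, columns=["stratum", "footprint_kind", "group_id", "percent"]
    )
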