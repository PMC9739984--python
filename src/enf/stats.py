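"""Rank-based group comparisons and normality screening.

Adjusted footprints in survey cohorts are right-skewed, so medians are
compared with the Mann-Whitney U test (two groups) and the Kruskal-Wallis
test (three or more), after a Kolmogorov-Smirnov normality screen. A
compact letter display summarizes which categories of a variable differ.

Conventions: two-sided p-values throughout; exact Mann-Whitney p by
enumeration for small tie-free samples, otherwise the normal approximation
with tie correction and (by default) continuity correction; Kruskal-Wallis
H is tie-corrected with a chi-square reference on k-1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from enf.errors import ValidationError

#: largest pooled size at which the exact Mann-Whitney null is enumerated
EXACT_MW_LIMIT = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: list[int] = field(default_factory=list)
    tie_corrected: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


def ks_normality(values: Sequence[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and SD, so the reported
    asymptotic p-value is anti-conservative (the Lilliefors situation); the
    result carries an explicit caveat note. Requires n >= 4 and non-zero
    variance.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValidationError(f"KS normality screen needs n >= 4, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("KS normality screen undefined for a constant sample")
    res = sps.kstest(x, "norm", args=(x.mean(), sd), method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="kolmogorov-smirnov (normal, estimated parameters)",
        n_per_group=[len(x)],
        notes=("parameters estimated from the sample; asymptotic p is "
               "anti-conservative (Lilliefors caveat)"),
    )


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    continuity: bool = True,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is min(U_x, U_y). ``mode="auto"`` uses the exact
    null distribution when n_x + n_y <= 12 and the pooled data are tie-free,
    else the normal approximation with tie correction; ``continuity``
    applies the 0.5 continuity correction on the approximate path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ties = _has_ties(pooled)
    if mode == "auto":
        mode = ("exact"
                if len(pooled) <= EXACT_MW_LIMIT and not ties
                else "normal_approx")
    if mode == "exact" and ties:
        raise ValidationError("exact Mann-Whitney requires tie-free data")

    nx, ny = len(x), len(y)
    if np.ptp(pooled) == 0:  # every value tied: no evidence either way
        return TestResult(nx * ny / 2.0, 1.0, "mann-whitney degenerate",
                          [nx, ny], tie_corrected=True)
    if mode == "exact":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "mann-whitney exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic",
                               use_continuity=continuity)
        method = "mann-whitney normal approximation"
        if continuity:
            method += " (continuity corrected)"
    u = min(float(res.statistic), nx * ny - float(res.statistic))
    return TestResult(u, float(min(res.pvalue, 1.0)), method, [nx, ny],
                      tie_corrected=(mode != "exact" and ties))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    if any(len(a) == 0 for a in arrs):
        raise ValidationError("Kruskal-Wallis: empty group")
    n_total = sum(len(a) for a in arrs)
    if n_total < 3:
        raise ValidationError("Kruskal-Wallis needs total n >= 3")
    pooled = np.concatenate(arrs)
    ties = _has_ties(pooled)
    if np.ptp(pooled) == 0:  # scipy raises on an all-tied pooled sample
        return TestResult(0.0, 1.0, "kruskal-wallis degenerate",
                          [len(a) for a in arrs], tie_corrected=True)
    h, p = sps.kruskal(*arrs)
    return TestResult(float(h), float(p), "kruskal-wallis",
                      [len(a) for a in arrs], tie_corrected=ties)


def _maximal_cliques(adjacency: np.ndarray) -> list[frozenset[int]]:
    """All maximal cliques of a small undirected graph (brute force)."""
    k = adjacency.shape[0]
    nodes = range(k)
    cliques: list[frozenset[int]] = []
    for size in range(k, 0, -1):
        for subset in combinations(nodes, size):
            if all(adjacency[i, j] for i, j in combinations(subset, 2)):
                fs = frozenset(subset)
                if not any(fs < c for c in cliques):
                    cliques.append(fs)
    return cliques


def pairwise_letters(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[str]:
    """Compact letter display from pairwise Mann-Whitney tests.

    Two groups share a letter iff their pairwise two-sided p-value is
    >= ``alpha`` (optionally Bonferroni-adjusted over the pairs). Letters
    correspond to maximal cliques of the not-significantly-different graph,
    ordered by first member, so e.g. ["a", "ab", "b"] marks a gradient whose
    extremes differ.
    """
    k = len(groups)
    if k == 0:
        raise ValidationError("no groups")
    if k == 1:
        return ["a"]
    n_pairs = k * (k - 1) // 2
    threshold = alpha / n_pairs if bonferroni else alpha
    adjacency = np.eye(k, dtype=bool)
    for i, j in combinations(range(k), 2):
        p = mann_whitney(groups[i], groups[j]).p_value
        adjacency[i, j] = adjacency[j, i] = p >= threshold
    cliques = _maximal_cliques(adjacency)
    cliques.sort(key=lambda c: (min(c), sorted(c)))
    letters = [""] * k
    for letter_idx, clique in enumerate(cliques):
        char = chr(ord("a") + letter_idx)
        for member in sorted(clique):
            letters[member] += char
    return letters
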