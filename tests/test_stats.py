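import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from enf.errors import ValidationError
from enf.stats import (
    kruskal_wallis,
    ks_normality,
    mann_whitney,
    pairwise_letters,
)


# ---------------------------------------------------------------------------
# independent oracles (enumeration / direct formulas), kept free of enf.stats


def mw_u_statistic(x, y):
    return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)


def mw_exact_p_bruteforce(x, y):
    """Two-sided exact Mann-Whitney p by enumerating every assignment of the
    pooled values to the two samples."""
    pooled = list(x) + list(y)
    nx = len(x)
    u_obs = mw_u_statistic(x, y)
    null_u = [
        mw_u_statistic([pooled[i] for i in idx],
                       [pooled[i] for i in range(len(pooled))
                        if i not in set(idx)])
        for idx in combinations(range(len(pooled)), nx)
    ]
    total = len(null_u)
    p_le = sum(u <= u_obs for u in null_u) / total
    p_ge = sum(u >= u_obs for u in null_u) / total
    return min(1.0, 2 * min(p_le, p_ge))


def kw_h_direct(groups):
    """Kruskal-Wallis H from the plain rank formula (mid-ranks, tie factor)."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_disjoint_pairs_exact(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(2 / 6)
        assert "exact" in res.method

    def test_single_observations(self):
        res = mann_whitney([1], [2])
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)

    def test_identical_samples_centered_u(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 4.5
        assert res.p_value >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_exact_mode_with_ties_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([1, 1], [2, 3], mode="exact")

    def test_exact_equals_bruteforce_enumeration(self, rng):
        """Exact p matches full enumeration over rank assignments for every
        sample-size pair with pooled n <= 10."""
        for nx in range(1, 6):
            for ny in range(nx, 10 - nx + 1):
                x = rng.normal(size=nx)
                y = rng.normal(size=ny) + rng.uniform(-1, 1)
                res = mann_whitney(list(x), list(y), mode="exact")
                assert res.p_value == pytest.approx(
                    mw_exact_p_bruteforce(x, y), abs=1e-12), (nx, ny)

    def test_large_or_tied_samples_use_normal_approximation(self, rng):
        res = mann_whitney(list(rng.normal(size=10)),
                           list(rng.normal(size=10)))
        assert "approximation" in res.method


class TestKruskalWallis:
    def test_identical_groups_no_separation(self):
        g = [1.0, 2.0, 3.0]
        res = kruskal_wallis([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_all_values_tied_degenerate(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0], [5.0, 5.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_rank_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kw_h_direct(groups), abs=1e-12)
        # 12/42 * (2*4 + 0 + 2*4) = 32/7 by hand
        assert res.statistic == pytest.approx(32 / 7)

    def test_matches_direct_formula_with_ties(self, rng):
        groups = [list(rng.integers(0, 6, size=8).astype(float))
                  for _ in range(3)]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kw_h_direct(groups), abs=1e-10)
        assert res.tie_corrected

    def test_two_groups_equal_mw_normal_approx_no_continuity(self, rng):
        """On two groups, H equals z^2 of the Mann-Whitney normal
        approximation without continuity correction, so the p-values agree."""
        x = list(rng.normal(size=12))
        y = list(rng.normal(1.0, 1.0, size=15))
        kw = kruskal_wallis([x, y])
        mw = mann_whitney(x, y, mode="normal_approx", continuity=False)
        assert kw.p_value == pytest.approx(mw.p_value, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0], []])


class TestKSNormality:
    def test_normal_quantile_grid_minimizes_distance(self):
        """On a grid of normal quantiles, the statistic equals the directly
        enumerated sup-distance and is close to the minimal achievable 1/(2n)."""
        n = 20
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        res = ks_normality(x)
        cdf = sps.norm.cdf(np.sort(x), loc=x.mean(), scale=x.std(ddof=1))
        d_direct = max(
            max(abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i]))
            for i in range(n)
        )
        assert res.statistic == pytest.approx(d_direct, abs=1e-12)
        assert res.statistic < 2.5 / n

    def test_constant_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([3.0, 3.0, 3.0, 3.0])

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([1.0, 2.0])

    def test_lilliefors_caveat_reported(self, rng):
        res = ks_normality(rng.normal(size=50))
        assert "estimated" in res.notes


class TestPairwiseLetters:
    def test_identical_groups_share_one_letter(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert pairwise_letters([g, g, g]) == ["a", "a", "a"]

    def test_separated_groups_get_distinct_letters(self, rng):
        lo = list(rng.uniform(0, 1, size=20))
        hi = list(rng.uniform(10, 11, size=20))
        assert pairwise_letters([lo, hi]) == ["a", "b"]

    def test_single_group(self):
        assert pairwise_letters([[1.0, 2.0]]) == ["a"]

    def test_gradient_shares_middle_letter(self, rng):
        lo = list(rng.normal(0, 1, size=25))
        mid = list(rng.normal(1.2, 1, size=25))
        hi = list(rng.normal(4, 1, size=25))
        letters = pairwise_letters([lo, mid, hi])
        # extremes must differ; shared letters exactly mirror pairwise p >= alpha
        assert set(letters[0]).isdisjoint(letters[2])
        p01 = mann_whitney(lo, mid).p_value
        assert (set(letters[0]) & set(letters[1]) != set()) == (p01 >= 0.05)

    def test_bonferroni_option_is_more_conservative(self, rng):
        groups = [list(rng.normal(m, 1, size=12)) for m in (0, 0.9, 1.8)]
        plain = pairwise_letters(groups, bonferroni=False)
        adjusted = pairwise_letters(groups, bonferroni=True)
        # adjusting can only merge groups (fewer declared differences)
        assert len(set("".join(adjusted))) <= len(set("".join(plain)))


def test_rank_tests_invariant_under_monotone_transform(rng):
    """Strictly monotone transforms of the pooled data leave every rank-based
    p-value unchanged."""
    groups = [list(rng.lognormal(0, 1, size=9)) for _ in range(3)]
    transformed = [[math.exp(v) for v in g] for g in groups]
    assert kruskal_wallis(groups).p_value == pytest.approx(
        kruskal_wallis(transformed).p_value, rel=1e-12)
    assert mann_whitney(groups[0], groups[1]).p_value == pytest.approx(
        mann_whitney(transformed[0], transformed[1]).p_value, rel=1e-12)


def test_type_one_error_calibration(rng):
    """Under identical continuous distributions, both tests reject at about
    the nominal 5% rate (n = 30 per group, 2000 replicates)."""
    n_rep = 2000
    rejections_kw = 0
    for _ in range(n_rep):
        g = rng.normal(size=(3, 30))
        if kruskal_wallis(list(g)).p_value < 0.05:
            rejections_kw += 1
    assert 0.03 <= rejections_kw / n_rep <= 0.07
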