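import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enf.errors import MissingDataError, ValidationError
from enf.footprint_core import (
    EFCVector,
    adjust_per_1000kcal,
    compute_cohort_footprints,
    daily_frequency,
    efc,
    energy_intake,
    individual_footprint,
)
from enf.intake import GroupProfile, PQResponse


class TestDailyFrequency:
    @pytest.mark.parametrize("count, period, expected", [
        (3, "week", 3 / 7),
        (1, "year", 1 / 365),
        (2, "day", 2.0),
        (5, "month", 5 / 30),
    ])
    def test_stated_divisors(self, count, period, expected):
        assert daily_frequency(count, period) == pytest.approx(expected)

    def test_unknown_period(self):
        with pytest.raises(ValidationError):
            daily_frequency(1, "decade")

    def test_zero_count(self):
        with pytest.raises(ValidationError):
            daily_frequency(0, "week")


class TestEFC:
    @pytest.mark.parametrize("freq, grams, expected", [
        (3 / 7, 150.0, 3 / 7 * 0.15),
        (0.0, 500.0, 0.0),
        (1.0, 1000.0, 1.0),
    ])
    def test_kg_per_day(self, freq, grams, expected):
        assert efc(freq, grams) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            efc(-0.1, 100)


class TestIndividualFootprint:
    def test_weighted_sum(self, simple_profiles):
        vec = EFCVector("r1", {"g1": 0.1, "g2": 0.2})
        total, addends = individual_footprint(vec, simple_profiles, "CF")
        assert total == pytest.approx(0.1 * 30000 + 0.2 * 1200)
        assert addends == {"g1": pytest.approx(3000.0),
                           "g2": pytest.approx(240.0)}

    def test_empty_vector_zero(self, simple_profiles):
        total, addends = individual_footprint(EFCVector("r1", {}),
                                              simple_profiles, "CF")
        assert total == 0.0 and addends == {}

    def test_single_group_water(self, simple_profiles):
        profiles = {"g1": GroupProfile("g1", 0, 0, 2000.0, 0, 100.0)}
        total, _ = individual_footprint(EFCVector("r", {"g1": 0.5}),
                                        profiles, "WF")
        assert total == 1000.0

    def test_missing_profile_names_group(self, simple_profiles):
        with pytest.raises(MissingDataError, match="g9"):
            individual_footprint(EFCVector("r", {"g9": 0.1}),
                                 simple_profiles, "CF")

    def test_conservation_total_equals_addends(self, simple_profiles):
        vec = EFCVector("r1", {"g1": 0.731, "g2": 0.002, "g3": 1.4})
        total, addends = individual_footprint(vec, simple_profiles, "EF")
        assert total == sum(addends.values())  # identical summation order


class TestEnergy:
    @pytest.mark.parametrize("kg, kcal100, expected", [
        (0.1, 350.0, 350.0),   # 0.1 kg = 1 portion of 100 g
        (1.0, 100.0, 1000.0),
    ])
    def test_factor_ten(self, kg, kcal100, expected):
        profiles = {"g1": GroupProfile("g1", 0, 0, 0, 0, kcal100)}
        assert energy_intake(EFCVector("r", {"g1": kg}),
                             profiles) == pytest.approx(expected)

    def test_empty_is_zero(self, simple_profiles):
        assert energy_intake(EFCVector("r", {}), simple_profiles) == 0.0


class TestAdjustment:
    @pytest.mark.parametrize("total, energy, expected", [
        (2000.0, 1000.0, 2000.0),
        (2000.0, 2000.0, 1000.0),
        (0.0, 1500.0, 0.0),
    ])
    def test_per_1000_kcal(self, total, energy, expected):
        assert adjust_per_1000kcal(total, energy) == expected

    def test_zero_energy_rejected(self):
        with pytest.raises(ValidationError):
            adjust_per_1000kcal(100.0, 0.0)


@st.composite
def cohort_case(draw):
    n_groups = draw(st.integers(min_value=1, max_value=6))
    profiles = {
        f"g{i}": GroupProfile(
            f"g{i}",
            draw(st.floats(min_value=1, max_value=400)),
            draw(st.floats(min_value=10, max_value=50000)),
            draw(st.floats(min_value=10, max_value=20000)),
            draw(st.floats(min_value=0.1, max_value=300)),
            draw(st.floats(min_value=5, max_value=500)),
        )
        for i in range(n_groups)
    }
    pq = []
    for r in range(draw(st.integers(min_value=1, max_value=5))):
        for i in range(n_groups):
            if draw(st.booleans()):
                pq.append(PQResponse(
                    f"r{r}", f"g{i}",
                    draw(st.integers(min_value=1, max_value=10)),
                    draw(st.sampled_from(["day", "week", "month", "year"])),
                ))
    return profiles, pq


@settings(max_examples=60, deadline=None, derandomize=True)
@given(cohort_case(), st.floats(min_value=0.1, max_value=10))
def test_energy_adjustment_invariance(case, scale):
    """Scaling every per-capita amount rescales totals and energy but leaves
    every per-1000-kcal footprint unchanged (the standardization removes
    overall diet size)."""
    profiles, pq = case
    if not pq:
        return
    scaled = {
        g: GroupProfile(g, p.per_capita_g * scale, p.cf_per_kg, p.wf_per_kg,
                        p.ef_per_kg, p.kcal_per_100g)
        for g, p in profiles.items()
    }
    base, _ = compute_cohort_footprints(pq, profiles)
    after, _ = compute_cohort_footprints(pq, scaled)
    for col in ("cf_total", "wf_total", "ef_total", "energy_kcal"):
        np.testing.assert_allclose(after[col], base[col] * scale, rtol=1e-9)
    for col in ("cf_1000", "wf_1000", "ef_1000"):
        np.testing.assert_allclose(after[col], base[col], rtol=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(cohort_case(), st.floats(min_value=0.1, max_value=10))
def test_coefficient_scaling_linearity(case, c):
    """Scaling all footprint coefficients by c scales every total by c."""
    profiles, pq = case
    if not pq:
        return
    scaled = {
        g: GroupProfile(g, p.per_capita_g, p.cf_per_kg * c, p.wf_per_kg * c,
                        p.ef_per_kg * c, p.kcal_per_100g)
        for g, p in profiles.items()
    }
    base, _ = compute_cohort_footprints(pq, profiles)
    after, _ = compute_cohort_footprints(pq, scaled)
    for col in ("cf_total", "wf_total", "ef_total"):
        np.testing.assert_allclose(after[col], base[col] * c, rtol=1e-9)
    np.testing.assert_allclose(after["energy_kcal"], base["energy_kcal"],
                               rtol=1e-12)


def test_monotonicity_in_efc(simple_profiles):
    """Raising any consumption component never decreases any total."""
    base = EFCVector("r", {"g1": 0.1, "g2": 0.2})
    bumped = EFCVector("r", {"g1": 0.1, "g2": 0.35})
    for kind in ("CF", "WF", "EF"):
        lo, _ = individual_footprint(base, simple_profiles, kind)
        hi, _ = individual_footprint(bumped, simple_profiles, kind)
        assert hi >= lo


def test_zero_energy_respondents_flagged_not_adjusted():
    profiles = {"g1": GroupProfile("g1", 100.0, 500.0, 500.0, 5.0, 0.0)}
    pq = [PQResponse("r1", "g1", 7, "week")]
    fp, _ = compute_cohort_footprints(pq, profiles)
    assert fp.loc[0, "cf_total"] > 0
    assert np.isnan(fp.loc[0, "cf_1000"])


def test_repeated_pq_rows_accumulate(simple_profiles):
    pq = [PQResponse("r1", "g1", 1, "day"), PQResponse("r1", "g1", 7, "week")]
    fp, _ = compute_cohort_footprints(pq, simple_profiles)
    assert fp.loc[0, "cf_total"] == pytest.approx(2 * 0.12 * 30000)
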