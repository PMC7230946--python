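"""Derivation of the 45 exposures: elementary operations, exclusion chain,
matrix derivation against a naive oracle, and the log/z transformation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietcluster import (
    count_eating_occasions,
    derive_exposure_matrix,
    energy_adjusted_intake,
    fiber_density,
    irregularity_score,
    meal_energies,
    meal_frequency,
    transform_exposures,
    validate_and_exclude,
)
from dietcluster.diaries import KCAL_PER_G, ExposureMatrix
from dietcluster.exceptions import (
    ConfigurationError,
    InputError,
    InsufficientDataError,
)
from dietcluster.variables import EXPOSURE_NAMES, SLOTS, variable_metadata

from conftest import make_diary_rows


def test_variable_registry_is_canonical():
    meta = variable_metadata()
    assert len(EXPOSURE_NAMES) == 45
    assert meta.index.is_unique
    assert set(meta["group"]) == {"fat", "carb", "protein", "frequency", "energy", "irregularity"}
    assert meta["block"].nunique() == 4


@pytest.mark.parametrize(
    "energies, expected",
    [
        ([300, 45, 600, 20, 500, 0, 0, 0], 3),
        ([0] * 8, 0),
        ([50] * 8, 8),  # the 50-kcal boundary is inclusive
        ([49.999] * 8, 0),
    ],
)
def test_count_eating_occasions(energies, expected):
    assert count_eating_occasions(energies) == expected


def test_count_eating_occasions_monotone_in_threshold():
    energies = [300, 45, 600, 20, 500, 0, 120, 75]
    counts = [count_eating_occasions(energies, t) for t in (0, 25, 50, 100, 1000)]
    assert counts == sorted(counts, reverse=True)


class TestMealEnergies:
    def test_remainder_rule(self):
        day = {
            "breakfast": 400,
            "lunch": 600,
            "evening_meal": 700,
            "mid_morning": 150,
            "later_evening": 100,
        }
        assert meal_energies(day) == (400, 600, 700, 250)

    def test_empty_day(self):
        assert meal_energies({}) == (0, 0, 0, 0)

    def test_only_snacks(self):
        assert meal_energies({"tea": 500, "other": 400}) == (0, 0, 0, 900)

    def test_closure(self):
        day = {s: 100.0 + i for i, s in enumerate(SLOTS)}
        b, l, d, s = meal_energies(day)
        assert b + l + d + s == pytest.approx(sum(day.values()), abs=1e-12)

    def test_mapping_collision_rejected(self):
        with pytest.raises(ConfigurationError):
            meal_energies({}, meal_slots={"breakfast": "tea", "lunch": "tea", "dinner": "evening_meal"})


@pytest.mark.parametrize(
    "grams, kcal, factor, expected",
    [
        (75.0, 2000.0, 4.0, 15.0),
        (0.0, 1234.0, 9.0, 0.0),
        (33.3, 2000.0, 9.0, 14.985),
    ],
)
def test_energy_adjusted_intake(grams, kcal, factor, expected):
    assert energy_adjusted_intake(grams, kcal, factor) == pytest.approx(expected)


def test_energy_adjusted_intake_zero_energy_is_undefined():
    assert math.isnan(energy_adjusted_intake(10.0, 0.0, 4.0))


@pytest.mark.parametrize(
    "grams, kcal, expected", [(20.0, 2000.0, 10.0), (0.0, 1500.0, 0.0), (26.6, 2000.0, 13.3)]
)
def test_fiber_density(grams, kcal, expected):
    assert fiber_density(grams, kcal) == pytest.approx(expected)
    assert math.isnan(fiber_density(5.0, 0.0))


class TestIrregularityScore:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([100] * 7, 0.0),
            ([50, 150], 50.0),
            ([0, 100, 200], 200.0 / 3),
        ],
    )
    def test_hand_computed_values(self, values, expected):
        assert irregularity_score(values) == pytest.approx(expected, abs=1e-9)

    def test_requires_two_days(self):
        with pytest.raises(InsufficientDataError):
            irregularity_score([1500.0])

    def test_zero_mean_is_undefined(self):
        assert math.isnan(irregularity_score([0.0, 0.0, 0.0]))

    @given(
        st.lists(st.floats(1.0, 5000.0), min_size=2, max_size=7),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, values, c):
        base = irregularity_score(values)
        scaled = irregularity_score([v * c for v in values])
        assert scaled == pytest.approx(base, abs=1e-9, rel=1e-9)

    @given(st.lists(st.floats(1.0, 5000.0), min_size=2, max_size=7))
    @settings(max_examples=200, deadline=None)
    def test_matches_naive_formula(self, values):
        x = np.array(values)
        naive = np.mean(np.abs(x - x.mean()) / x.mean() * 100.0)
        assert irregularity_score(values) == pytest.approx(naive, abs=1e-9)


class TestMealFrequency:
    def _diary(self, days_with_slots):
        rows = []
        for day, slots in days_with_slots.items():
            rows += make_diary_rows(1, day, slots)
        return pd.DataFrame(rows)

    def test_breakfast_six_of_seven(self):
        days = {d: {"breakfast": 400, "lunch": 600, "evening_meal": 700} for d in range(1, 8)}
        days[7] = {"lunch": 600, "evening_meal": 700}
        assert meal_frequency(self._diary(days), "breakfast") == pytest.approx(600 / 7)

    def test_never_present(self):
        days = {d: {"lunch": 600, "evening_meal": 700} for d in range(1, 8)}
        assert meal_frequency(self._diary(days), "breakfast") == 0.0

    def test_morning_late_requires_same_day(self):
        days = {d: {"breakfast": 400, "lunch": 500, "evening_meal": 600} for d in range(1, 8)}
        for d in (1, 2, 3):
            days[d]["mid_morning"] = 150
        for d in (3, 4):
            days[d]["later_evening"] = 120
        # overlap only on day 3 -> 1/7 days
        assert meal_frequency(self._diary(days), "morning_late_snack") == pytest.approx(100 / 7)


class TestExclusionChain:
    def _cohort(self):
        rows = []
        # p1: 7 valid days; p2: 4 valid + 3 low days; p3: valid, chronic;
        # p4: valid, missing outcome; p5: no diary at all;
        # p6: chronic AND too few valid days -> counted under too_few (earlier reason)
        for d in range(1, 8):
            rows += make_diary_rows(1, d, {"breakfast": 500})
            rows += make_diary_rows(2, d, {"breakfast": 600 if d <= 4 else 100})
            rows += make_diary_rows(3, d, {"breakfast": 800})
            rows += make_diary_rows(4, d, {"breakfast": 800})
            rows += make_diary_rows(6, d, {"breakfast": 600 if d <= 2 else 100})
        diaries = pd.DataFrame(rows)
        participants = pd.DataFrame(index=pd.Index([1, 2, 3, 4, 5, 6], name="participant_id"))
        chronic = pd.Series([False, False, True, False, False, True], index=participants.index)
        complete = pd.Series([True, True, True, False, True, True], index=participants.index)
        return diaries, participants, chronic, complete

    def test_sequential_first_reason_wins(self):
        diaries, participants, chronic, complete = self._cohort()
        rep = validate_and_exclude(diaries, participants, chronic, complete)
        r = rep.table["exclusion_reason"]
        assert r[1] == "none"  # 7 days at exactly 500 kcal: boundary inclusive
        assert r[2] == "too_few_valid_days"
        assert r[3] == "chronic_disease"
        assert r[4] == "missing_outcome"
        assert r[5] == "missing_diet"
        assert r[6] == "too_few_valid_days"  # earlier reason shadows chronic flag
        assert rep.tally["included"] == 1

    def test_duplicate_ids_rejected(self):
        diaries, participants, chronic, complete = self._cohort()
        dup = pd.concat([participants, participants.iloc[:1]])
        with pytest.raises(InputError):
            validate_and_exclude(diaries, dup, chronic, complete)


class TestDeriveExposureMatrix:
    def test_identical_days_give_zero_irregularity_and_extreme_frequencies(self):
        slots = {"breakfast": 500, "lunch": 600, "evening_meal": 700, "mid_morning": 150}
        rows = []
        for d in range(1, 8):
            rows += make_diary_rows(1, d, slots)
        m = derive_exposure_matrix(pd.DataFrame(rows))
        row = m.raw.loc[1]
        for c in EXPOSURE_NAMES:
            if c.startswith("irreg_"):
                assert row[c] == pytest.approx(0.0, abs=1e-9)
        for c in ("breakfast_freq", "lunch_freq", "dinner_freq"):
            assert row[c] == 100.0
        assert row["evening_snack_freq"] == 0.0

    def test_shape_contract(self, small_cohort, small_matrix):
        assert small_matrix.raw.shape == (400, 45)
        assert list(small_matrix.raw.columns) == list(EXPOSURE_NAMES)

    def test_energy_closure(self, small_cohort, small_matrix):
        raw = small_matrix.raw.dropna()
        total = raw["breakfast_kcal"] + raw["lunch_kcal"] + raw["dinner_kcal"] + raw["snack_kcal"]
        assert np.allclose(total, raw["energy_kcal_daily"], atol=1e-8)

    def test_macronutrient_closure_and_bounds(self, small_matrix):
        raw = small_matrix.raw.dropna()
        s = raw["protein_pct_daily"] + raw["carb_pct_daily"] + raw["fat_pct_daily"]
        assert (s <= 100 + 1e-6).all()
        freq_cols = [c for c in EXPOSURE_NAMES if c.endswith("_freq")]
        assert ((raw[freq_cols] >= 0) & (raw[freq_cols] <= 100)).all().all()
        assert raw["eating_occasions_per_day"].between(0, 8).all()
        assert (raw[[c for c in EXPOSURE_NAMES if c.startswith("irreg_")]] >= 0).all().all()

    def test_matches_naive_per_formula_recomputation(self):
        """Every derived value equals an independent scalar recomputation."""
        rng = np.random.default_rng(42)
        rows = []
        for pid in (1, 2, 3):
            for d in range(1, 8):
                slots = {}
                comp = {}
                for slot in SLOTS:
                    if rng.random() < 0.6:
                        kcal = float(rng.uniform(60, 900))
                        p = rng.uniform(0.05, 0.25) * kcal / 4
                        f = rng.uniform(0.2, 0.45) * kcal / 9
                        c = (kcal - 4 * p - 9 * f) / 4
                        comp[slot] = (p, c, 0.5 * c, f, 0.4 * f, rng.uniform(0, 5))
                        slots[slot] = kcal
                if slots:
                    rows += make_diary_rows(pid, d, slots, composition=comp)
        diaries = pd.DataFrame(rows)
        m = derive_exposure_matrix(diaries)

        for pid in (1, 2, 3):
            sub = diaries[diaries.participant_id == pid]
            per_day = {
                d: dict(zip(g["occasion"], g["energy_kcal"]))
                for d, g in sub.groupby("day")
            }
            day_tot = {d: sum(v.values()) for d, v in per_day.items()}
            valid = [d for d, e in day_tot.items() if e >= 500]

            def day_nut(d, nut):
                g = sub[sub.day == d]
                return float(g[nut].sum())

            # daily energy and composition, averaged per valid day
            exp_energy = np.mean([day_tot[d] for d in valid])
            assert m.raw.loc[pid, "energy_kcal_daily"] == pytest.approx(exp_energy, abs=1e-9)
            for nut, col in [("carb_g", "carb_pct_daily"), ("satfat_g", "satfat_pct_daily")]:
                vals = [
                    energy_adjusted_intake(day_nut(d, nut), day_tot[d], KCAL_PER_G[nut.split("_")[0]])
                    for d in valid
                ]
                assert m.raw.loc[pid, col] == pytest.approx(np.mean(vals), abs=1e-9)
            vals = [fiber_density(day_nut(d, "fiber_g"), day_tot[d]) for d in valid]
            assert m.raw.loc[pid, "fiber_density_daily"] == pytest.approx(np.mean(vals), abs=1e-9)

            # meal energies via the remainder rule
            snack = [meal_energies(per_day[d])[3] for d in valid]
            assert m.raw.loc[pid, "snack_kcal"] == pytest.approx(np.mean(snack), abs=1e-9)

            # occasion counts and frequencies
            occ = [count_eating_occasions(per_day[d].values()) for d in valid]
            assert m.raw.loc[pid, "eating_occasions_per_day"] == pytest.approx(np.mean(occ), abs=1e-9)
            bf = [per_day[d].get("breakfast", 0) >= 50 for d in valid]
            assert m.raw.loc[pid, "breakfast_freq"] == pytest.approx(100 * np.mean(bf), abs=1e-9)

            # irregularity of daily energy and of dinner energy
            assert m.raw.loc[pid, "irreg_energy"] == pytest.approx(
                irregularity_score([day_tot[d] for d in valid]), abs=1e-9
            )
            dinner = [per_day[d].get("evening_meal", 0.0) for d in valid]
            expected = irregularity_score(dinner) if np.mean(dinner) > 0 else np.nan
            got = m.raw.loc[pid, "irreg_dinner"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)

            # meal composition averaged over days the meal was eaten
            eaten = [d for d in valid if per_day[d].get("lunch", 0) > 0]
            if eaten:
                vals = [
                    energy_adjusted_intake(
                        float(sub[(sub.day == d) & (sub.occasion == "lunch")]["protein_g"].sum()),
                        per_day[d]["lunch"],
                        4.0,
                    )
                    for d in eaten
                ]
                assert m.raw.loc[pid, "protein_pct_lunch"] == pytest.approx(np.mean(vals), abs=1e-9)


class TestTransform:
    def test_normalization_contract(self, small_matrix):
        mat = transform_exposures(small_matrix.complete())
        z = mat.transformed
        assert z.mean(axis=0).abs().max() < 1e-9
        assert (z.std(axis=0, ddof=0) - 1).abs().max() < 1e-9

    def test_constant_column_becomes_zero_with_warning(self, small_matrix):
        raw = small_matrix.complete().raw.copy()
        raw["snack_kcal"] = 250.0
        with pytest.warns(UserWarning, match="constant"):
            mat = transform_exposures(ExposureMatrix(raw=raw))
        assert (mat.transformed["snack_kcal"] == 0).all()

    def test_monotone_order_preserved(self, small_matrix):
        mat = transform_exposures(small_matrix.complete())
        raw_order = np.argsort(mat.raw["energy_kcal_daily"].to_numpy())
        z_order = np.argsort(mat.transformed["energy_kcal_daily"].to_numpy())
        assert np.array_equal(raw_order, z_order)
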