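import pandas as pd
import pytest

from dietcluster import CohortConfig, derive_exposure_matrix, generate_cohort


def make_diary_rows(pid, day, slot_energies, composition=None):
    """Build diary rows for one day from a {slot: kcal} mapping.

    ``composition`` maps slot -> (protein_g, carb_g, sugar_g, fat_g,
    satfat_g, fiber_g); defaults to an Atwater-consistent 16/48/36 split.
    """
    rows = []
    for slot, kcal in slot_energies.items():
        if composition and slot in composition:
            p, c, s, f, sf, fb = composition[slot]
        else:
            p, c, f = 0.16 * kcal / 4, 0.48 * kcal / 4, 0.36 * kcal / 9
            s, sf, fb = 0.4 * c, 0.4 * f, kcal / 1000 * 8.5
        rows.append(
            {
                "participant_id": pid,
                "day": day,
                "occasion": slot,
                "energy_kcal": float(kcal),
                "protein_g": p,
                "carb_g": c,
                "sugar_g": s,
                "fat_g": f,
                "satfat_g": sf,
                "fiber_g": fb,
            }
        )
    return rows


@pytest.fixture
def diary_frame():
    def build(rows):
        return pd.DataFrame(rows)

    return build


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_participants=400, seed=11))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return derive_exposure_matrix(small_cohort.diaries)


@pytest.fixture
def normal_profile():
    """A biomarker profile far below every CMR cutoff."""
    return {
        "sex": "male",
        "waist_cm": 80.0,
        "hdl_mmol_l": 1.6,
        "non_hdl_mmol_l": 3.0,
        "sbp_mmhg": 110.0,
        "dbp_mmhg": 70.0,
        "crp_mg_l": 1.0,
        "hba1c_pct": 5.0,
        "meds_lipid": False,
        "meds_bp": False,
        "meds_glucose": False,
    }


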