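"""Canonical registry of the 45 diet-exposure variables.

Every downstream stage (derivation, transformation, clustering, modelling)
refers to exposures by the names defined here.  The registry records, per
variable, its measurement unit, its substantive group (macronutrient family,
frequency, energy, irregularity) and the latent block the synthetic-cohort
generator plants it in.  The four planted blocks mirror the empirically
recurring structure of diary-derived exposures: a fat-composition block, a
carbohydrate/fibre block, a protein-plus-regularity block, and a meal
frequency/energy block.
"""

from __future__ import annotations

import pandas as pd

#: The eight predefined diary eating-occasion slots, in within-day order.
SLOTS = (
    "before_breakfast",
    "breakfast",
    "mid_morning",
    "lunch",
    "tea",
    "evening_meal",
    "later_evening",
    "other",
)

#: Default mapping of diary slots to the three main meals.  Every slot not
#: mapped here counts as snacking; snack energy is the day's remainder.
DEFAULT_MEAL_SLOTS = {
    "breakfast": "breakfast",
    "lunch": "lunch",
    "dinner": "evening_meal",
}

#: Slot treated as the late-night snack and the morning snack in the
#: frequency variables.
LATE_SNACK_SLOT = "later_evening"
MORNING_SNACK_SLOT = "mid_morning"

MEALS = ("breakfast", "lunch", "dinner")

# (name, unit, group, planted block)
_REGISTRY = [
    # -- fat composition -------------------------------------------------
    ("fat_pct_breakfast", "% energy", "fat", "fat"),
    ("satfat_pct_breakfast", "% energy", "fat", "fat"),
    ("fat_pct_lunch", "% energy", "fat", "fat"),
    ("satfat_pct_lunch", "% energy", "fat", "fat"),
    ("fat_pct_daily", "% energy", "fat", "fat"),
    ("satfat_pct_daily", "% energy", "fat", "fat"),
    ("fat_pct_dinner", "% energy", "fat", "fat"),
    ("satfat_pct_dinner", "% energy", "fat", "fat"),
    # -- frequencies and energy ------------------------------------------
    ("eating_occasions_per_day", "occasions/day", "frequency", "freq_energy"),
    ("dinner_freq", "% of days", "frequency", "freq_energy"),
    ("breakfast_freq", "% of days", "frequency", "freq_energy"),
    ("lunch_freq", "% of days", "frequency", "freq_energy"),
    ("morning_late_snack_freq", "% of days", "frequency", "freq_energy"),
    ("snack_kcal", "kcal", "energy", "freq_energy"),
    ("evening_snack_freq", "% of days", "frequency", "freq_energy"),
    ("breakfast_kcal", "kcal", "energy", "freq_energy"),
    ("dinner_kcal", "kcal", "energy", "freq_energy"),
    ("lunch_kcal", "kcal", "energy", "freq_energy"),
    ("energy_kcal_daily", "kcal", "energy", "freq_energy"),
    # -- carbohydrate / fibre --------------------------------------------
    ("fiber_density_breakfast", "g/1000 kcal", "carb", "carb"),
    ("fiber_density_dinner", "g/1000 kcal", "carb", "carb"),
    ("fiber_density_lunch", "g/1000 kcal", "carb", "carb"),
    ("fiber_density_daily", "g/1000 kcal", "carb", "carb"),
    ("carb_pct_breakfast", "% energy", "carb", "carb"),
    ("sugar_pct_breakfast", "% energy", "carb", "carb"),
    ("carb_pct_lunch", "% energy", "carb", "carb"),
    ("sugar_pct_lunch", "% energy", "carb", "carb"),
    ("carb_pct_daily", "% energy", "carb", "carb"),
    ("sugar_pct_daily", "% energy", "carb", "carb"),
    ("carb_pct_dinner", "% energy", "carb", "carb"),
    ("sugar_pct_dinner", "% energy", "carb", "carb"),
    # -- protein ----------------------------------------------------------
    ("protein_pct_lunch", "% energy", "protein", "protein_irregularity"),
    ("protein_pct_daily", "% energy", "protein", "protein_irregularity"),
    ("protein_pct_dinner", "% energy", "protein", "protein_irregularity"),
    ("protein_pct_breakfast", "% energy", "protein", "protein_irregularity"),
    # -- irregularity scores ----------------------------------------------
    ("irreg_satfat", "score", "irregularity", "protein_irregularity"),
    ("irreg_fat", "score", "irregularity", "protein_irregularity"),
    ("irreg_breakfast", "score", "irregularity", "protein_irregularity"),
    ("irreg_lunch", "score", "irregularity", "protein_irregularity"),
    ("irreg_dinner", "score", "irregularity", "protein_irregularity"),
    ("irreg_sugar", "score", "irregularity", "protein_irregularity"),
    ("irreg_carb", "score", "irregularity", "protein_irregularity"),
    ("irreg_protein", "score", "irregularity", "protein_irregularity"),
    ("irreg_fiber", "score", "irregularity", "protein_irregularity"),
    ("irreg_energy", "score", "irregularity", "protein_irregularity"),
]

#: Ordered tuple of the 45 canonical exposure names.
EXPOSURE_NAMES = tuple(name for name, _, _, _ in _REGISTRY)

#: Planted-block labels in a fixed order.
BLOCKS = ("fat", "freq_energy", "carb", "protein_irregularity")

assert len(EXPOSURE_NAMES) == 45
assert len(set(EXPOSURE_NAMES)) == 45


def variable_metadata() -> pd.DataFrame:
    """Return the variable registry as a DataFrame indexed by name.

    Columns: ``unit``, ``group`` (fat/carb/protein/frequency/energy/
    irregularity) and ``block`` (the latent block used by the synthetic
    generator as ground truth for cluster-recovery checks).
    """
    df = pd.DataFrame(_REGISTRY, columns=["name", "unit", "group", "block"])
    return df.set_index("name")


def block_assignment() -> pd.Series:
    """Ground-truth block label per exposure (index: exposure name)."""
    return variable_metadata()["block"]
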