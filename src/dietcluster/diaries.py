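"""Derivation of the 45 diet-exposure variables from 7-day food diaries.

A diary is a long-format table with one row per participant x day x eating
occasion, carrying energy (kcal) and the macronutrient amounts in grams:

    participant_id, day, occasion, energy_kcal,
    protein_g, carb_g, sugar_g, fat_g, satfat_g, fiber_g

The eight permitted ``occasion`` values are listed in
:data:`dietcluster.variables.SLOTS`.  Sugar is a subset of carbohydrate and
saturated fat a subset of fat, so ``sugar_g <= carb_g`` and
``satfat_g <= fat_g`` row-wise.

The module implements

* diary validity (a recording day counts as valid when its total energy is
  at least 500 kcal) and the sequential participant exclusion chain,
* the elementary per-day quantities (eating-occasion counts at the 50-kcal
  threshold, meal and snack energies, energy-adjusted macronutrient
  percentages via Atwater factors, fibre density),
* day-to-day intake-irregularity scores,
* the full 45-variable exposure matrix and its log/z transformation.

Undefined values (for instance the composition of a meal that was never
eaten, or the irregularity of an intake whose mean is zero) propagate as
NaN, never as zero; a participant with any NaN exposure is the "missing
diet variable information" case of the exclusion chain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError, InsufficientDataError
from .variables import (
    DEFAULT_MEAL_SLOTS,
    EXPOSURE_NAMES,
    LATE_SNACK_SLOT,
    MEALS,
    MORNING_SNACK_SLOT,
    SLOTS,
    variable_metadata,
)

# Atwater energy factors, kcal per gram.  Sugar counts as carbohydrate and
# saturated fat as fat, so only three independent factors exist.
KCAL_PER_G = {
    "protein": 4.0,
    "carb": 4.0,
    "sugar": 4.0,
    "fat": 9.0,
    "satfat": 9.0,
}

NUTRIENT_COLS = ("protein_g", "carb_g", "sugar_g", "fat_g", "satfat_g", "fiber_g")
DIARY_COLUMNS = ("participant_id", "day", "occasion", "energy_kcal") + NUTRIENT_COLS

#: Printed analysis thresholds.
VALID_DAY_KCAL = 500.0
OCCASION_KCAL = 50.0
MIN_VALID_DAYS = 5

EXCLUSION_REASONS = (
    "missing_diet",
    "too_few_valid_days",
    "chronic_disease",
    "missing_outcome",
)


# ---------------------------------------------------------------------------
# elementary per-day operations
# ---------------------------------------------------------------------------

def count_eating_occasions(energies: Sequence[float], threshold_kcal: float = OCCASION_KCAL) -> int:
    """Number of eating occasions in a day: slots with energy >= threshold."""
    arr = np.asarray(list(energies), dtype=float)
    return int(np.sum(arr >= threshold_kcal))


def meal_energies(
    day: Mapping[str, float],
    meal_slots: Mapping[str, str] | None = None,
) -> tuple[float, float, float, float]:
    """Split a day's slot energies into (breakfast, lunch, dinner, snack) kcal.

    ``day`` maps occasion slot -> energy.  Snack energy is whatever remains
    after subtracting the three meal energies from the day total, so the
    four components always sum to the day total exactly.
    """
    meal_slots = dict(meal_slots or DEFAULT_MEAL_SLOTS)
    if set(meal_slots) != set(MEALS):
        raise ConfigurationError(f"meal_slots must map exactly {MEALS}, got {sorted(meal_slots)}")
    if len(set(meal_slots.values())) != 3:
        raise ConfigurationError("meal_slots assigns the same diary slot to two meals")
    total = float(sum(day.values()))
    b = float(day.get(meal_slots["breakfast"], 0.0))
    l = float(day.get(meal_slots["lunch"], 0.0))
    d = float(day.get(meal_slots["dinner"], 0.0))
    return b, l, d, total - b - l - d


def energy_adjusted_intake(nutrient_g: float, energy_kcal: float, kcal_per_g: float) -> float:
    """Percent contribution of a nutrient to energy; NaN when energy is zero."""
    if energy_kcal <= 0:
        return float("nan")
    return 100.0 * nutrient_g * kcal_per_g / energy_kcal


def fiber_density(fiber_g: float, energy_kcal: float) -> float:
    """Fibre intake expressed as grams per 1000 kcal; NaN when energy is zero."""
    if energy_kcal <= 0:
        return float("nan")
    return 1000.0 * fiber_g / energy_kcal


def irregularity_score(daily_values: Sequence[float]) -> float:
    """Day-to-day irregularity of an intake series on a 0-100-style scale.

    The score is the mean over valid recording days of the absolute
    deviation of each day's intake from the across-day mean, divided by
    that mean and multiplied by 100.  Zero means perfectly regular intake;
    the score is invariant under rescaling all days by a common positive
    factor.  Requires at least two days; a zero mean leaves the score
    undefined (NaN).
    """
    x = np.asarray(list(daily_values), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"irregularity needs >= 2 valid days, got {x.size}"
        )
    m = x.mean()
    if m <= 0:
        return float("nan")
    if np.all(x == x[0]):  # exact zero for constant intake, no float residue
        return 0.0
    return float(np.mean(np.abs(x - m)) / m * 100.0)


# ---------------------------------------------------------------------------
# diary-level helpers
# ---------------------------------------------------------------------------

def _check_diary_frame(diaries: pd.DataFrame) -> pd.DataFrame:
    missing = set(DIARY_COLUMNS) - set(diaries.columns)
    if missing:
        raise InputError(f"diary table lacks columns: {sorted(missing)}")
    bad = set(diaries["occasion"].unique()) - set(SLOTS)
    if bad:
        raise InputError(f"unknown eating-occasion slots: {sorted(bad)}")
    dup = diaries.duplicated(subset=["participant_id", "day", "occasion"])
    if dup.any():
        raise InputError("more than one record per participant/day/occasion slot")
    return diaries


def day_totals(diaries: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day totals of energy and every nutrient."""
    cols = ["energy_kcal", *NUTRIENT_COLS]
    return diaries.groupby(["participant_id", "day"], sort=True)[cols].sum()


def valid_day_flags(diaries: pd.DataFrame, valid_day_kcal: float = VALID_DAY_KCAL) -> pd.Series:
    """Boolean per participant-day: total energy >= the validity cutoff."""
    return day_totals(diaries)["energy_kcal"] >= valid_day_kcal


def meal_frequency(
    diary: pd.DataFrame,
    which: str,
    threshold_kcal: float = OCCASION_KCAL,
    valid_day_kcal: float = VALID_DAY_KCAL,
    meal_slots: Mapping[str, str] | None = None,
) -> float:
    """Percent of one participant's valid days on which an occasion occurs.

    ``which`` is a meal name (breakfast/lunch/dinner), a raw slot name, the
    late-night snack (``evening_snack``), or ``morning_late_snack`` which
    requires both the morning and the late-night snack to reach the energy
    threshold on the same day.
    """
    meal_slots = dict(meal_slots or DEFAULT_MEAL_SLOTS)
    _check_diary_frame(diary)
    valid = valid_day_flags(diary, valid_day_kcal)
    vdays = valid[valid].index.get_level_values("day")
    if len(vdays) == 0:
        raise InsufficientDataError("no valid recording days")
    sub = diary[diary["day"].isin(vdays)]
    piv = sub.pivot_table(
        index="day", columns="occasion", values="energy_kcal", aggfunc="sum"
    ).reindex(columns=list(SLOTS), index=vdays).fillna(0.0)
    if which == "morning_late_snack":
        hit = (piv[MORNING_SNACK_SLOT] >= threshold_kcal) & (
            piv[LATE_SNACK_SLOT] >= threshold_kcal
        )
    else:
        slot = {
            "evening_snack": LATE_SNACK_SLOT,
            "morning_snack": MORNING_SNACK_SLOT,
            **meal_slots,
        }.get(which, which)
        if slot not in SLOTS:
            raise ConfigurationError(f"unknown occasion or meal: {which!r}")
        hit = piv[slot] >= threshold_kcal
    return float(100.0 * hit.mean())


# ---------------------------------------------------------------------------
# exclusion chain
# ---------------------------------------------------------------------------

@dataclass
class ValidityReport:
    """Per-participant diary validity and inclusion decision."""

    table: pd.DataFrame  # index participant_id; n_valid_days, included, exclusion_reason
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def included_ids(self) -> pd.Index:
        return self.table.index[self.table["included"]]


def validate_and_exclude(
    diaries: pd.DataFrame,
    participants: pd.DataFrame,
    chronic_disease: pd.Series | None = None,
    outcome_complete: pd.Series | None = None,
    valid_day_kcal: float = VALID_DAY_KCAL,
    min_valid_days: int = MIN_VALID_DAYS,
    missing_diet: pd.Series | None = None,
) -> ValidityReport:
    """Apply the sequential participant exclusion chain.

    Reasons are checked in a fixed order — missing diet information, fewer
    than ``min_valid_days`` valid recording days, self-reported chronic
    disease, incomplete outcome information — and each excluded participant
    is tallied under the *first* reason that applies.

    ``missing_diet`` may be passed explicitly (e.g. the NaN-exposure flags
    from :func:`derive_exposure_matrix`); by default a participant is
    flagged when they have no diary rows or any NaN nutrient value.
    """
    if participants.index.has_duplicates:
        raise InputError("duplicate participant ids in participants table")
    _check_diary_frame(diaries)
    ids = participants.index

    valid = valid_day_flags(diaries, valid_day_kcal)
    n_valid = valid.groupby("participant_id").sum().reindex(ids, fill_value=0).astype(int)

    if missing_diet is None:
        has_rows = pd.Series(ids.isin(diaries["participant_id"].unique()), index=ids)
        nan_rows = diaries[list(("energy_kcal",) + NUTRIENT_COLS)].isna().any(axis=1)
        with_nan = set(diaries.loc[nan_rows, "participant_id"])
        missing_diet = ~has_rows | pd.Series(ids.isin(with_nan), index=ids)
    missing_diet = missing_diet.reindex(ids, fill_value=True).astype(bool)
    chronic = (
        chronic_disease.reindex(ids, fill_value=False).astype(bool)
        if chronic_disease is not None
        else pd.Series(False, index=ids)
    )
    complete = (
        outcome_complete.reindex(ids, fill_value=False).astype(bool)
        if outcome_complete is not None
        else pd.Series(True, index=ids)
    )

    reason = pd.Series("none", index=ids, dtype=object)
    reason[~complete] = "missing_outcome"
    reason[chronic] = "chronic_disease"
    reason[n_valid < min_valid_days] = "too_few_valid_days"
    reason[missing_diet] = "missing_diet"

    table = pd.DataFrame(
        {
            "n_valid_days": n_valid,
            "included": reason == "none",
            "exclusion_reason": reason,
        }
    )
    tally = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS}
    tally["included"] = int(table["included"].sum())
    return ValidityReport(table=table, tally=tally)


# ---------------------------------------------------------------------------
# the 45-variable exposure matrix
# ---------------------------------------------------------------------------

@dataclass
class ExposureMatrix:
    """Participants x 45 diet-exposure variables.

    ``raw`` holds the natural-unit values; ``transformed`` (filled by
    :func:`transform_exposures`) holds log(x + offset) columns centred and
    scaled to unit population SD.  ``meta`` carries unit/group labels per
    variable.
    """

    raw: pd.DataFrame
    transformed: pd.DataFrame | None = None
    meta: pd.DataFrame = field(default_factory=variable_metadata)
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if list(self.raw.columns) != list(EXPOSURE_NAMES):
            raise InputError("exposure matrix must carry exactly the 45 canonical variables")

    @property
    def participant_ids(self) -> pd.Index:
        return self.raw.index

    @property
    def n_participants(self) -> int:
        return len(self.raw)

    def missing_flags(self) -> pd.Series:
        """True for participants with any undefined derived variable."""
        return self.raw.isna().any(axis=1)

    def complete(self) -> "ExposureMatrix":
        """Subset to participants with all 45 variables defined."""
        keep = ~self.missing_flags()
        return ExposureMatrix(
            raw=self.raw.loc[keep],
            transformed=None if self.transformed is None else self.transformed.loc[keep],
            meta=self.meta,
            log_offset=self.log_offset,
        )

    def write(self, path: str | Path) -> None:
        """Write the raw matrix as CSV with a JSON metadata sidecar."""
        path = Path(path)
        self.raw.to_csv(path, index_label="participant_id")
        sidecar = {
            name: {"unit": row["unit"], "group": row["group"]}
            for name, row in self.meta.iterrows()
        }
        path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))


def _meal_day_frame(
    diaries: pd.DataFrame, meal_slots: Mapping[str, str]
) -> pd.DataFrame:
    """Wide per (participant, day) frame of slot energies and meal nutrients."""
    cols = ["energy_kcal", *NUTRIENT_COLS]
    piv = diaries.pivot_table(
        index=["participant_id", "day"],
        columns="occasion",
        values=cols,
        aggfunc="sum",
    )
    # flatten to e.g. ('energy_kcal','breakfast') -> 'energy_kcal@breakfast'
    piv.columns = [f"{v}@{s}" for v, s in piv.columns]
    return piv


def derive_exposure_matrix(
    diaries: pd.DataFrame,
    valid_day_kcal: float = VALID_DAY_KCAL,
    occasion_kcal: float = OCCASION_KCAL,
    meal_slots: Mapping[str, str] | None = None,
    participant_ids: Iterable | None = None,
) -> ExposureMatrix:
    """Derive all 45 exposure variables for every participant in ``diaries``.

    All averages run over valid days only (day energy >= ``valid_day_kcal``).
    Meal-specific energy-adjusted compositions use that meal's energy as the
    denominator and are averaged over the days the meal was actually eaten;
    daily compositions use daily energy.  Participants whose diary leaves
    any variable undefined carry NaN in that cell.
    """
    meal_slots = dict(meal_slots or DEFAULT_MEAL_SLOTS)
    _check_diary_frame(diaries)

    totals = day_totals(diaries)
    valid = totals["energy_kcal"] >= valid_day_kcal
    totals = totals[valid]
    wide = _meal_day_frame(diaries, meal_slots).reindex(totals.index)

    def slot_col(var: str, slot: str) -> pd.Series:
        col = f"{var}@{slot}"
        if col in wide.columns:
            return wide[col].fillna(0.0)
        return pd.Series(0.0, index=wide.index)

    per_day = pd.DataFrame(index=totals.index)
    day_e = totals["energy_kcal"]

    # daily composition
    per_day["energy_kcal_daily"] = day_e
    for nut, key in [
        ("protein", "protein_pct_daily"),
        ("carb", "carb_pct_daily"),
        ("sugar", "sugar_pct_daily"),
        ("fat", "fat_pct_daily"),
        ("satfat", "satfat_pct_daily"),
    ]:
        per_day[key] = 100.0 * totals[f"{nut}_g"] * KCAL_PER_G[nut] / day_e
    per_day["fiber_density_daily"] = 1000.0 * totals["fiber_g"] / day_e

    # meal energies and compositions
    meal_e = {}
    for meal in MEALS:
        slot = meal_slots[meal]
        e = slot_col("energy_kcal", slot)
        meal_e[meal] = e
        per_day[f"{meal}_kcal"] = e
        eaten = e > 0
        denom = e.where(eaten)
        for nut in ("protein", "carb", "sugar", "fat", "satfat"):
            g = slot_col(f"{nut}_g", slot)
            per_day[f"{nut}_pct_{meal}"] = 100.0 * g * KCAL_PER_G[nut] / denom
        per_day[f"fiber_density_{meal}"] = 1000.0 * slot_col("fiber_g", slot) / denom
    per_day["snack_kcal"] = day_e - meal_e["breakfast"] - meal_e["lunch"] - meal_e["dinner"]

    # frequencies and occasion counts
    occ_e = pd.concat({s: slot_col("energy_kcal", s) for s in SLOTS}, axis=1)
    hits = occ_e >= occasion_kcal
    per_day["eating_occasions_per_day"] = hits.sum(axis=1).astype(float)
    per_day["breakfast_present"] = hits[meal_slots["breakfast"]].astype(float)
    per_day["lunch_present"] = hits[meal_slots["lunch"]].astype(float)
    per_day["dinner_present"] = hits[meal_slots["dinner"]].astype(float)
    per_day["evening_snack_present"] = hits[LATE_SNACK_SLOT].astype(float)
    per_day["morning_late_present"] = (
        hits[MORNING_SNACK_SLOT] & hits[LATE_SNACK_SLOT]
    ).astype(float)

    grp = per_day.groupby("participant_id", sort=True)
    means = grp.mean()  # skipna: absent meals drop out of composition means

    out = pd.DataFrame(index=means.index)
    direct = [
        "energy_kcal_daily",
        "protein_pct_daily", "carb_pct_daily", "sugar_pct_daily",
        "fat_pct_daily", "satfat_pct_daily", "fiber_density_daily",
        "breakfast_kcal", "lunch_kcal", "dinner_kcal", "snack_kcal",
        "eating_occasions_per_day",
    ]
    for meal in MEALS:
        direct += [
            f"protein_pct_{meal}", f"carb_pct_{meal}", f"sugar_pct_{meal}",
            f"fat_pct_{meal}", f"satfat_pct_{meal}", f"fiber_density_{meal}",
        ]
    for c in direct:
        out[c] = means[c]
    out["breakfast_freq"] = 100.0 * means["breakfast_present"]
    out["lunch_freq"] = 100.0 * means["lunch_present"]
    out["dinner_freq"] = 100.0 * means["dinner_present"]
    out["evening_snack_freq"] = 100.0 * means["evening_snack_present"]
    out["morning_late_snack_freq"] = 100.0 * means["morning_late_present"]

    # irregularity scores: mean |x - mean| / mean * 100 over valid days
    irr_sources = {
        "irreg_energy": day_e,
        "irreg_protein": totals["protein_g"],
        "irreg_carb": totals["carb_g"],
        "irreg_sugar": totals["sugar_g"],
        "irreg_fat": totals["fat_g"],
        "irreg_satfat": totals["satfat_g"],
        "irreg_fiber": totals["fiber_g"],
        "irreg_breakfast": meal_e["breakfast"],
        "irreg_lunch": meal_e["lunch"],
        "irreg_dinner": meal_e["dinner"],
    }
    irr = pd.DataFrame(irr_sources)
    g = irr.groupby("participant_id", sort=True)
    abs_dev = (irr - g.transform("mean")).abs()
    score = abs_dev.groupby("participant_id", sort=True).mean() / g.mean() * 100.0
    score = score.where(g.mean() > 0)  # zero-mean series -> undefined
    score.loc[g.size() < 2, :] = np.nan
    for c in irr_sources:
        out[c] = score[c]

    out = out.reindex(columns=list(EXPOSURE_NAMES))
    if participant_ids is not None:
        out = out.reindex(pd.Index(participant_ids, name="participant_id"))
    out.index.name = "participant_id"
    return ExposureMatrix(raw=out)


def transform_exposures(matrix: ExposureMatrix, offset: float | None = None) -> ExposureMatrix:
    """Log-transform and z-scale every exposure column.

    Each column becomes ``log(x + offset)`` (offset defaults to the
    matrix's ``log_offset``, 1 by default, so that exact zeros — common in
    frequencies and irregularity scores — stay defined), then is centred
    and divided by its population standard deviation.  Constant columns
    map to all-zero columns with a warning.
    """
    if offset is None:
        offset = matrix.log_offset
    raw = matrix.raw
    if raw.isna().any().any():
        raise InputError("transform requires a complete raw matrix; drop flagged participants first")
    logged = np.log(raw + offset)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0)
    const = sd <= mu.abs().clip(lower=1.0) * 1e-12
    if const.any():
        warnings.warn(
            f"constant exposure columns set to zero: {list(sd.index[const])}",
            stacklevel=2,
        )
    z = (logged - mu).div(sd.where(~const, 1.0), axis=1)
    z.loc[:, const] = 0.0
    return ExposureMatrix(raw=raw, transformed=z, meta=matrix.meta, log_offset=offset)
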