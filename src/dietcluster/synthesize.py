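"""Synthetic 7-day food-diary cohorts with known ground truth.

The generator produces participant-level latent structure first and then
expands it into occasion-level diary rows, so that every downstream stage
(derivation, clustering, outcome modelling) can be validated against a
planted truth:

* Four latent traits per participant — fat composition, meal
  frequency/energy, carbohydrate/fibre composition, and protein plus
  intake-irregularity — induce a four-block correlation structure among
  the 45 derived exposures.  Each generator "driver" (a participant-level
  propensity such as the breakfast carbohydrate share or the day-to-day
  noise scale) loads on exactly one trait, with the loading chosen so that
  two same-block derived exposures reach a configurable target correlation
  (default 0.6) while exposures in different blocks stay near-independent.
* Daily macronutrient composition lives on the simplex via a
  logistic-normal (softmax of Gaussian logits), guaranteeing percentages
  in (0, 100) that sum to 100; occasion energies are log-normal per slot
  with main meals larger than snack slots, so meal skipping emerges when
  draws fall below the 50-kcal occasion threshold or a slot is absent.
* Day-to-day noise is scaled per participant by the irregularity driver,
  making the irregularity scores informative.
* Occasion energy equals the Atwater energy of its macronutrients exactly
  (4/4/9 kcal/g), sugar never exceeds carbohydrate, saturated fat never
  exceeds fat.
* Outcomes are planted by drawing case labels from a logistic model over
  exposure quartiles and then sampling biomarkers just beyond or below the
  CMR cutoffs so that the classifier reproduces the drawn labels exactly.
* Optional under-reporting multiplies a participant's energies by a factor
  decreasing in BMI (default slope 0), to exercise the BMI-restricted
  sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .associations import assign_quartiles
from .cmr import CRITERIA, CUTOFFS
from .diaries import DIARY_COLUMNS, derive_exposure_matrix, ExposureMatrix
from .exceptions import ConfigurationError
from .variables import BLOCKS, EXPOSURE_NAMES, SLOTS

# slot -> composition context
_SLOT_CONTEXT = {
    "before_breakfast": "snack",
    "breakfast": "breakfast",
    "mid_morning": "snack",
    "lunch": "lunch",
    "tea": "snack",
    "evening_meal": "dinner",
    "later_evening": "snack",
    "other": "snack",
}
_CONTEXTS = ("breakfast", "lunch", "dinner", "snack")

#: Median occasion energy per slot, kcal (main meals larger than snacks).
_SLOT_KCAL = {
    "before_breakfast": 90.0,
    "breakfast": 420.0,
    "mid_morning": 140.0,
    "lunch": 580.0,
    "tea": 170.0,
    "evening_meal": 680.0,
    "later_evening": 190.0,
    "other": 130.0,
}

#: Baseline probability that a slot is used on a given day.
_SLOT_PRESENCE = {
    "before_breakfast": 0.12,
    "breakfast": 0.90,
    "mid_morning": 0.55,
    "lunch": 0.94,
    "tea": 0.40,
    "evening_meal": 0.97,
    "later_evening": 0.45,
    "other": 0.08,
}

_MAIN_SLOTS = ("breakfast", "lunch", "evening_meal")

# person-level logit SDs of the macronutrient shares
_A_PROT, _A_CARB, _A_FAT = 0.30, 0.24, 0.24
# base share logits (softmax of these gives ~16/48/36 % energy)
_L_PROT, _L_CARB, _L_FAT = np.log(0.16), np.log(0.48), np.log(0.36)

_BASE_FIBER_DENSITY = 8.5    # g / 1000 kcal, median
_FIBER_LOG_SD = 0.35
_SUGAR_FRAC, _SUGAR_SD = 0.42, 0.60   # sugar as fraction of carbohydrate
_SATFAT_FRAC, _SATFAT_SD = 0.38, 0.40

_ENERGY_LOG_SD = 0.25        # person-level energy scale
_MEAL_SIZE_SD = 0.18         # person-level main-meal size
_DAY_SIGMA0 = 0.10           # day-level shared energy noise at irregularity z=0
_SLOT_SIGMA0 = 0.22          # day-level per-main-meal noise
_OCC_SIGMA_MAIN = 0.10       # occasion-level idiosyncratic noise, main meals
_OCC_SIGMA_SNACK = 0.28      # occasion-level idiosyncratic noise, snack slots
_COMP_DAY_REL = 1.2          # day noise on share logits, relative to person SD
_PROT_DAY_REL = 2.0          # protein share gets extra day-to-day variation
_SUGAR_DAY_SD = 0.45         # day noise on the sugar fraction logit
_SATFAT_DAY_SD = 0.40        # day noise on the saturated-fat fraction logit
_FIBER_DAY_SD = 0.24         # day noise on log fibre density
_IRR_SCALE = 0.5             # irregularity driver's effect on all day noises
_FREQ_COEF = 0.9             # frequency driver's effect on snack-slot logits
_MAIN_FREQ_COEF = 0.35
_MAIN_ENERGY_COEF = 0.3      # larger habitual eaters skip main meals less
_MEASUREMENT_SD = 0.22       # per-record log-scale nutrient coding/portion error


def _check_prob(name: str, p) -> None:
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass
class TraitLoadings:
    """How generator drivers load on the four latent traits.

    ``within_block_rho`` is the target Pearson correlation between two
    derived exposures of the same block.  Drivers load sqrt(rho) on their
    block's trait; families whose 7-day estimators are noisy (the
    irregularity scores) get a fixed attenuation-compensation factor so
    realized correlations track the target.
    """

    n_traits: int = 4
    within_block_rho: float = 0.6
    #: per-family attenuation compensation: derived-exposure estimators
    #: (7-day means, frequencies, irregularity scores) are noisy versions
    #: of their drivers, which attenuates realized correlations below the
    #: driver-level target; these factors push the affected loadings up so
    #: realized block correlations track within_block_rho
    compensation: dict = field(
        default_factory=lambda: {
            "protein_composition": 1.08,
            "fiber": 1.25,
            "frequency": 1.10,
            "irregularity": 1.25,
        }
    )
    noise_floor: float = 0.02  # minimal residual SD of any driver

    def __post_init__(self) -> None:
        if self.n_traits != len(BLOCKS):
            raise ConfigurationError(f"n_traits must be {len(BLOCKS)}, got {self.n_traits}")
        if not 0 <= self.within_block_rho < 1:
            raise ConfigurationError(
                f"within_block_rho must lie in [0, 1), got {self.within_block_rho}"
            )
        if self.noise_floor <= 0:
            raise ConfigurationError(f"noise_floor must be > 0, got {self.noise_floor}")

    def loading(self, family: str) -> float:
        base = np.sqrt(self.within_block_rho) * self.compensation.get(family, 1.0)
        return float(min(base, np.sqrt(1 - self.noise_floor**2)))


@dataclass
class EffectSpec:
    """Planted exposure-outcome effects for the logistic outcome model.

    ``exposure_effects`` maps an exposure name to the log-odds per quartile
    step (Q4 vs Q1 spans three steps).  Defaults are protective for
    carbohydrate % energy, fibre density, and eating occasions/day, with
    magnitudes emulating effect sizes typical of diary cohorts.
    ``glucose_mix_effects`` tilts *which* criteria a case meets toward the
    glucose criterion as a function of an exposure's quartile, without
    changing composite prevalence — for glucose-only sensitivity checks.
    """

    baseline_prevalence: float = 0.36
    exposure_effects: dict[str, float] = field(
        default_factory=lambda: {
            "carb_pct_daily": -0.066,
            "fiber_density_daily": -0.141,
            "eating_occasions_per_day": -0.136,
        }
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex_male": 0.25}
    )
    glucose_mix_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_prevalence <= 1:
            raise ConfigurationError(
                f"baseline_prevalence must lie in [0, 1], got {self.baseline_prevalence}"
            )
        unknown = set(self.exposure_effects) - set(EXPOSURE_NAMES)
        if unknown:
            raise ConfigurationError(f"exposure_effects name unknown exposures: {sorted(unknown)}")


@dataclass
class CohortConfig:
    """Full configuration of a synthetic cohort."""

    n_participants: int
    n_days: int = 7
    seed: int = 0
    traits: TraitLoadings = field(default_factory=TraitLoadings)
    effects: EffectSpec = field(default_factory=EffectSpec)
    sex_male_p: float = 0.617
    region_p: tuple[float, ...] = (0.732, 0.168, 0.100)  # England/Scotland/Wales
    education_p: tuple[float, ...] = (0.321, 0.275, 0.404)
    work_hours_p: tuple[float, ...] = (0.466, 0.534)  # <=40h / >40h
    sleep_p: tuple[float, ...] = (0.317, 0.650, 0.033)
    activity_p: tuple[float, ...] = (0.193, 0.691, 0.116)
    underreport_slope: float = 0.0  # log-energy reduction per BMI unit above 25

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError(
                f"n_participants must be >= 0, got {self.n_participants}"
            )
        if self.n_days < 1:
            raise ConfigurationError(f"n_days must be >= 1, got {self.n_days}")
        _check_prob("sex_male_p", self.sex_male_p)
        for name in ("region_p", "education_p", "work_hours_p", "sleep_p", "activity_p"):
            p = np.asarray(getattr(self, name), dtype=float)
            _check_prob(name, p)
            if not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ConfigurationError(f"{name} must sum to 1, got {p.sum():.4f}")
        if self.underreport_slope < 0:
            raise ConfigurationError(
                f"underreport_slope must be >= 0, got {self.underreport_slope}"
            )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

_DRIVER_BLOCK: dict[str, tuple[str, str]] = {}
for _m in _CONTEXTS:
    _DRIVER_BLOCK[f"prot_{_m}"] = ("protein_irregularity", "protein_composition")
    _DRIVER_BLOCK[f"carb_{_m}"] = ("carb", "composition")
    _DRIVER_BLOCK[f"fat_{_m}"] = ("fat", "composition")
    _DRIVER_BLOCK[f"sugar_{_m}"] = ("carb", "fraction")
    _DRIVER_BLOCK[f"satfat_{_m}"] = ("fat", "fraction")
    _DRIVER_BLOCK[f"fiber_{_m}"] = ("carb", "fiber")
_DRIVER_BLOCK["energy"] = ("freq_energy", "energy")
for _s in ("breakfast", "lunch", "dinner"):
    _DRIVER_BLOCK[f"size_{_s}"] = ("freq_energy", "energy")
for _s in ("before_breakfast", "mid_morning", "tea", "later_evening", "other"):
    _DRIVER_BLOCK[f"freq_{_s}"] = ("freq_energy", "frequency")
_DRIVER_BLOCK["freq_main"] = ("freq_energy", "frequency")
#: one irregularity driver per score family, all on the protein/regularity
#: trait, so the ten scores cohere through the trait rather than through a
#: single shared noise scale
_IRR_ASPECTS = ("energy", "meal", "prot", "carb", "fat", "sugar", "satfat", "fiber")
for _a in _IRR_ASPECTS:
    _DRIVER_BLOCK[f"irr_{_a}"] = ("protein_irregularity", "irregularity")


def _irr_scales(z: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-aspect multiplicative day-noise scales, exp(scale * driver)."""
    return {a: np.exp(_IRR_SCALE * z[f"irr_{a}"]) for a in _IRR_ASPECTS}


def _draw_drivers(rng: np.random.Generator, n: int, loadings: TraitLoadings) -> pd.DataFrame:
    traits = rng.standard_normal((n, loadings.n_traits))
    block_ix = {b: i for i, b in enumerate(BLOCKS)}
    cols = {}
    for name, (block, family) in _DRIVER_BLOCK.items():
        lam = loadings.loading(family)
        cols[name] = lam * traits[:, block_ix[block]] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    drivers = pd.DataFrame(cols)
    for i, b in enumerate(BLOCKS):
        drivers[f"trait_{b}"] = traits[:, i]
    return drivers


# ---------------------------------------------------------------------------
# diary synthesis
# ---------------------------------------------------------------------------

def _participant_table(rng: np.random.Generator, n: int, cfg: CohortConfig) -> pd.DataFrame:
    sex = np.where(rng.random(n) < cfg.sex_male_p, "male", "female")
    age = np.clip(rng.normal(40.8, 9.1, n), 19, 65)
    bmi = np.clip(rng.normal(27.0, 4.1, n), 17, 50)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 2),
            "region": rng.choice(["england", "scotland", "wales"], n, p=cfg.region_p),
            "education": rng.choice(
                ["a_levels", "degree", "other"], n, p=cfg.education_p
            ),
            "work_hours": rng.choice(["le40h", "gt40h"], n, p=cfg.work_hours_p),
            "sleep_duration": rng.choice(["lt7h", "7to8h", "ge9h"], n, p=cfg.sleep_p),
            "physical_activity": rng.choice(
                ["low", "moderate", "high"], n, p=cfg.activity_p
            ),
            "chronic_disease": np.zeros(n, dtype=bool),
            "outcome_complete": np.ones(n, dtype=bool),
        },
        index=pd.RangeIndex(1, n + 1, name="participant_id"),
    )


def _synthesize_diaries(
    rng: np.random.Generator,
    drivers: pd.DataFrame,
    bmi: np.ndarray,
    cfg: CohortConfig,
) -> pd.DataFrame:
    n, d = len(drivers), cfg.n_days
    n_slots = len(SLOTS)
    z = {c: drivers[c].to_numpy() for c in drivers.columns}
    irr = _irr_scales(z)

    # slot presence -----------------------------------------------------
    presence_p = np.empty((n, n_slots))
    for j, slot in enumerate(SLOTS):
        base = np.log(_SLOT_PRESENCE[slot] / (1 - _SLOT_PRESENCE[slot]))
        if slot in _MAIN_SLOTS:
            logit = base + _MAIN_FREQ_COEF * z["freq_main"] + _MAIN_ENERGY_COEF * z["energy"]
        else:
            logit = base + _FREQ_COEF * z[f"freq_{slot}"]
        presence_p[:, j] = 1 / (1 + np.exp(-logit))
    present = rng.random((n, d, n_slots)) < presence_p[:, None, :]

    # energies ----------------------------------------------------------
    person_e = _ENERGY_LOG_SD * z["energy"]
    size = {s: _MEAL_SIZE_SD * z[f"size_{m}"] for s, m in
            zip(_MAIN_SLOTS, ("breakfast", "lunch", "dinner"))}
    day_fac = (_DAY_SIGMA0 * irr["energy"])[:, None] * rng.standard_normal((n, d))
    underreport = -cfg.underreport_slope * np.maximum(bmi - 25.0, 0.0)

    log_e = np.empty((n, d, n_slots))
    for j, slot in enumerate(SLOTS):
        le = np.log(_SLOT_KCAL[slot]) + person_e + underreport
        if slot in size:
            le = le + size[slot]
            slot_noise = (_SLOT_SIGMA0 * irr["meal"])[:, None] * rng.standard_normal((n, d))
            occ = _OCC_SIGMA_MAIN * rng.standard_normal((n, d))
        else:
            slot_noise = 0.0
            occ = _OCC_SIGMA_SNACK * rng.standard_normal((n, d))
        log_e[:, :, j] = le[:, None] + day_fac + slot_noise + occ
    energy = np.exp(log_e) * present

    # composition -------------------------------------------------------
    comp_sigma = {
        "prot": _PROT_DAY_REL * irr["prot"],
        "carb": _COMP_DAY_REL * irr["carb"],
        "fat": _COMP_DAY_REL * irr["fat"],
    }
    shares = np.empty((n, d, n_slots, 3))  # protein, carb, fat
    sugar_frac = np.empty((n, d, n_slots))
    satfat_frac = np.empty((n, d, n_slots))
    fiber_dens = np.empty((n, d, n_slots))
    ctx_cache: dict[str, tuple] = {}
    for m in _CONTEXTS:
        lp = _L_PROT + _A_PROT * (z[f"prot_{m}"][:, None] + comp_sigma["prot"][:, None] * rng.standard_normal((n, d)))
        lc = _L_CARB + _A_CARB * (z[f"carb_{m}"][:, None] + comp_sigma["carb"][:, None] * rng.standard_normal((n, d)))
        lf = _L_FAT + _A_FAT * (z[f"fat_{m}"][:, None] + comp_sigma["fat"][:, None] * rng.standard_normal((n, d)))
        mx = np.maximum(np.maximum(lp, lc), lf)
        ep, ec, ef = np.exp(lp - mx), np.exp(lc - mx), np.exp(lf - mx)
        tot = ep + ec + ef
        sug = 1 / (1 + np.exp(-(
            np.log(_SUGAR_FRAC / (1 - _SUGAR_FRAC))
            + _SUGAR_SD * z[f"sugar_{m}"][:, None]
            + _SUGAR_DAY_SD * irr["sugar"][:, None] * rng.standard_normal((n, d))
        )))
        sat = 1 / (1 + np.exp(-(
            np.log(_SATFAT_FRAC / (1 - _SATFAT_FRAC))
            + _SATFAT_SD * z[f"satfat_{m}"][:, None]
            + _SATFAT_DAY_SD * irr["satfat"][:, None] * rng.standard_normal((n, d))
        )))
        fib = _BASE_FIBER_DENSITY * np.exp(
            _FIBER_LOG_SD * z[f"fiber_{m}"][:, None]
            + _FIBER_DAY_SD * irr["fiber"][:, None] * rng.standard_normal((n, d))
        )
        ctx_cache[m] = (ep / tot, ec / tot, ef / tot, sug, sat, fib)
    for j, slot in enumerate(SLOTS):
        sp, sc, sf, sug, sat, fib = ctx_cache[_SLOT_CONTEXT[slot]]
        shares[:, :, j, 0], shares[:, :, j, 1], shares[:, :, j, 2] = sp, sc, sf
        sugar_frac[:, :, j], satfat_frac[:, :, j], fiber_dens[:, :, j] = sug, sat, fib

    # grams from target shares, then independent per-record coding/portion
    # error on each macronutrient; energy is recomputed from the noisy
    # grams so occasion energy stays the exact Atwater sum
    protein_g = energy * shares[..., 0] / 4.0
    carb_g = energy * shares[..., 1] / 4.0
    fat_g = energy * shares[..., 2] / 9.0
    protein_g = protein_g * np.exp(_MEASUREMENT_SD * rng.standard_normal((n, d, n_slots)))
    carb_g = carb_g * np.exp(_MEASUREMENT_SD * rng.standard_normal((n, d, n_slots)))
    fat_g = fat_g * np.exp(_MEASUREMENT_SD * rng.standard_normal((n, d, n_slots)))
    energy = (4.0 * protein_g + 4.0 * carb_g + 9.0 * fat_g) * present
    sugar_g = carb_g * sugar_frac
    satfat_g = fat_g * satfat_frac
    fiber_g = (
        energy / 1000.0 * fiber_dens
        * np.exp(_MEASUREMENT_SD * rng.standard_normal((n, d, n_slots)))
    )

    # long-format assembly ------------------------------------------------
    mask = present.reshape(-1)
    pid = np.repeat(drivers.index.to_numpy() + 1, d * n_slots)[mask]
    day = np.tile(np.repeat(np.arange(1, d + 1), n_slots), n)[mask]
    occ = np.tile(np.array(SLOTS, dtype=object), n * d)[mask]

    def flat(a: np.ndarray) -> np.ndarray:
        return a.reshape(-1)[mask]

    return pd.DataFrame(
        {
            "participant_id": pid,
            "day": day,
            "occasion": occ,
            "energy_kcal": flat(energy),
            "protein_g": flat(protein_g),
            "carb_g": flat(carb_g),
            "sugar_g": flat(sugar_g),
            "fat_g": flat(fat_g),
            "satfat_g": flat(satfat_g),
            "fiber_g": flat(fiber_g),
        }
    )


# ---------------------------------------------------------------------------
# expected (noise-free) exposures — the planted truth
# ---------------------------------------------------------------------------

def expected_exposures(drivers: pd.DataFrame) -> pd.DataFrame:
    """Participant-level expected values of the 45 exposures.

    Day-to-day noise is set to zero and Bernoulli slot presence replaced by
    its probability; irregularity scores use the half-normal approximation
    ``E|x - mean| / mean ~= sqrt(2/pi) * sigma_day``.  These are the truth
    values recovery tests correlate derived exposures against.
    """
    n = len(drivers)
    z = {c: drivers[c].to_numpy() for c in drivers.columns}
    irr = _irr_scales(z)
    out = pd.DataFrame(index=pd.RangeIndex(1, n + 1, name="participant_id"))

    ctx: dict[str, dict[str, np.ndarray]] = {}
    for m in _CONTEXTS:
        lp = _L_PROT + _A_PROT * z[f"prot_{m}"]
        lc = _L_CARB + _A_CARB * z[f"carb_{m}"]
        lf = _L_FAT + _A_FAT * z[f"fat_{m}"]
        ep, ec, ef = np.exp(lp), np.exp(lc), np.exp(lf)
        tot = ep + ec + ef
        sugar_frac = 1 / (
            1 + np.exp(-(np.log(_SUGAR_FRAC / (1 - _SUGAR_FRAC)) + _SUGAR_SD * z[f"sugar_{m}"]))
        )
        satfat_frac = 1 / (
            1 + np.exp(-(np.log(_SATFAT_FRAC / (1 - _SATFAT_FRAC)) + _SATFAT_SD * z[f"satfat_{m}"]))
        )
        ctx[m] = {
            "protein": 100 * ep / tot,
            "carb": 100 * ec / tot,
            "fat": 100 * ef / tot,
        }
        ctx[m]["sugar"] = ctx[m]["carb"] * sugar_frac
        ctx[m]["satfat"] = ctx[m]["fat"] * satfat_frac
        ctx[m]["fiber"] = _BASE_FIBER_DENSITY * np.exp(_FIBER_LOG_SD * z[f"fiber_{m}"])

    # presence probabilities and expected slot energies
    presence = {}
    slot_kcal = {}
    person_e = np.exp(_ENERGY_LOG_SD * z["energy"])
    for slot in SLOTS:
        base = np.log(_SLOT_PRESENCE[slot] / (1 - _SLOT_PRESENCE[slot]))
        if slot in _MAIN_SLOTS:
            logit = base + _MAIN_FREQ_COEF * z["freq_main"] + _MAIN_ENERGY_COEF * z["energy"]
        else:
            logit = base + _FREQ_COEF * z[f"freq_{slot}"]
        presence[slot] = 1 / (1 + np.exp(-logit))
        e = _SLOT_KCAL[slot] * person_e
        if slot == "breakfast":
            e = e * np.exp(_MEAL_SIZE_SD * z["size_breakfast"])
        elif slot == "lunch":
            e = e * np.exp(_MEAL_SIZE_SD * z["size_lunch"])
        elif slot == "evening_meal":
            e = e * np.exp(_MEAL_SIZE_SD * z["size_dinner"])
        slot_kcal[slot] = e

    meal_slot = {"breakfast": "breakfast", "lunch": "lunch", "dinner": "evening_meal"}
    for meal, slot in meal_slot.items():
        out[f"{meal}_kcal"] = presence[slot] * slot_kcal[slot]
        for nut in ("protein", "carb", "sugar", "fat", "satfat"):
            out[f"{nut}_pct_{meal}"] = ctx[meal][nut]
        out[f"fiber_density_{meal}"] = ctx[meal]["fiber"]

    day_energy = sum(presence[s] * slot_kcal[s] for s in SLOTS)
    out["energy_kcal_daily"] = day_energy
    out["snack_kcal"] = day_energy - out["breakfast_kcal"] - out["lunch_kcal"] - out["dinner_kcal"]

    # daily composition: energy-weighted over contexts
    w = {m: np.zeros(n) for m in _CONTEXTS}
    for slot in SLOTS:
        w[_SLOT_CONTEXT[slot]] += presence[slot] * slot_kcal[slot]
    for nut in ("protein", "carb", "sugar", "fat", "satfat", "fiber"):
        key = "fiber_density_daily" if nut == "fiber" else f"{nut}_pct_daily"
        out[key] = sum(w[m] * ctx[m][nut] for m in _CONTEXTS) / day_energy

    out["breakfast_freq"] = 100 * presence["breakfast"]
    out["lunch_freq"] = 100 * presence["lunch"]
    out["dinner_freq"] = 100 * presence["evening_meal"]
    out["evening_snack_freq"] = 100 * presence["later_evening"]
    out["morning_late_snack_freq"] = 100 * presence["mid_morning"] * presence["later_evening"]
    out["eating_occasions_per_day"] = sum(presence[s] for s in SLOTS)

    mad = np.sqrt(2 / np.pi) * 100.0
    sig_day = _DAY_SIGMA0 * irr["energy"]
    sig_meal = np.sqrt(sig_day**2 + (_SLOT_SIGMA0 * irr["meal"]) ** 2 + _OCC_SIGMA_MAIN**2)
    out["irreg_energy"] = mad * sig_day
    for meal in ("breakfast", "lunch", "dinner"):
        out[f"irreg_{meal}"] = mad * sig_meal
    # extra relative day noise per nutrient beyond the shared energy factor
    extra = {
        "protein": _A_PROT * _PROT_DAY_REL * irr["prot"],
        "carb": _A_CARB * _COMP_DAY_REL * irr["carb"],
        "fat": _A_FAT * _COMP_DAY_REL * irr["fat"],
        "sugar": np.sqrt(
            (_A_CARB * _COMP_DAY_REL * irr["carb"]) ** 2
            + (0.24 * _SUGAR_DAY_SD * irr["sugar"]) ** 2
        ),
        "satfat": np.sqrt(
            (_A_FAT * _COMP_DAY_REL * irr["fat"]) ** 2
            + (0.24 * _SATFAT_DAY_SD * irr["satfat"]) ** 2
        ),
        "fiber": _FIBER_DAY_SD * irr["fiber"],
    }
    for nut, e in extra.items():
        out[f"irreg_{nut}"] = mad * np.sqrt(sig_day**2 + e**2)

    return out[list(EXPOSURE_NAMES)]


# ---------------------------------------------------------------------------
# outcome planting
# ---------------------------------------------------------------------------

def plant_outcome(
    exposures: pd.DataFrame | ExposureMatrix,
    spec: EffectSpec,
    seed: int,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Draw case labels from the planted logistic model, then biomarkers.

    Returns ``(case_labels, biomarker_table)``.  The biomarker table
    contains every field the CMR classifier needs (sex included) and is
    constructed so that classification reproduces the drawn labels
    exactly: a case's criterion count is drawn from {3, 4, 5}, a
    control's from {0, 1, 2}, and each biomarker is sampled strictly
    beyond or below its cutoff according to whether its criterion holds.
    """
    if isinstance(exposures, ExposureMatrix):
        exposures = exposures.raw
    rng = np.random.default_rng(seed)
    idx = exposures.index
    n = len(idx)
    if n == 0:
        return pd.Series(dtype=bool), pd.DataFrame()

    if covariates is None:
        sex = pd.Series(
            np.where(rng.random(n) < 0.617, "male", "female"), index=idx
        )
        age = pd.Series(np.clip(rng.normal(40.8, 9.1, n), 19, 65), index=idx)
    else:
        sex = covariates["sex"].reindex(idx)
        age = covariates["age"].reindex(idx)

    if spec.baseline_prevalence in (0.0, 1.0):
        eta = np.full(n, np.inf if spec.baseline_prevalence == 1.0 else -np.inf)
    else:
        eta = np.full(n, np.log(spec.baseline_prevalence / (1 - spec.baseline_prevalence)))
        for name, beta in spec.exposure_effects.items():
            if beta == 0:
                continue
            q = assign_quartiles(exposures[name].fillna(exposures[name].median()), name=name)
            eta = eta + beta * (q.labels.to_numpy() - 1)
        eta = eta + spec.covariate_effects.get("age", 0.0) * (age.to_numpy() - 40.8)
        eta = eta + spec.covariate_effects.get("sex_male", 0.0) * (
            (sex == "male").to_numpy().astype(float) - 0.617
        )
    prob = 1 / (1 + np.exp(-eta))
    case = rng.random(n) < prob

    # criterion counts consistent with the drawn labels
    count = np.where(
        case,
        rng.choice([3, 4, 5], n, p=[0.6, 0.3, 0.1]),
        rng.choice([0, 1, 2], n, p=[0.25, 0.40, 0.35]),
    )

    # which criteria hold: Gumbel-top-m weighted sampling; the glucose
    # criterion's weight may be tilted by exposure quartile
    logw = np.zeros((n, len(CRITERIA)))
    gi = CRITERIA.index("glucose")
    for name, beta in spec.glucose_mix_effects.items():
        q = assign_quartiles(exposures[name].fillna(exposures[name].median()), name=name)
        logw[:, gi] += beta * (q.labels.to_numpy() - 1)
    gumbel = rng.gumbel(size=(n, len(CRITERIA)))
    order = np.argsort(-(logw + gumbel), axis=1)
    held = np.zeros((n, len(CRITERIA)), dtype=bool)
    rows = np.arange(n)
    for j in range(len(CRITERIA)):
        held[rows, order[:, j]] = j < count

    male = (sex == "male").to_numpy()
    u = lambda lo, hi: rng.uniform(lo, hi, n)  # noqa: E731

    waist_cut = np.where(male, CUTOFFS["waist_male"], CUTOFFS["waist_female"])
    waist = np.where(held[:, 0], waist_cut + u(0.5, 18), waist_cut - u(1, 16))

    hdl_cut = np.where(male, CUTOFFS["hdl_male"], CUTOFFS["hdl_female"])
    dys = held[:, 1]
    mode = rng.random(n)  # <0.55 low HDL, <0.9 high non-HDL, else meds
    hdl = np.where(dys & (mode < 0.55), hdl_cut - u(0.05, 0.4), hdl_cut + u(0.05, 0.7))
    non_hdl = np.where(
        dys & (mode >= 0.55) & (mode < 0.9),
        CUTOFFS["non_hdl"] + u(0.05, 1.5),
        CUTOFFS["non_hdl"] - u(0.3, 1.8),
    )
    meds_lipid = dys & (mode >= 0.9)

    bp = held[:, 2]
    bp_mode = rng.random(n)
    sbp = np.where(bp & (bp_mode < 0.8), CUTOFFS["sbp"] + u(0.5, 25), CUTOFFS["sbp"] - u(3, 25))
    dbp = np.where(bp & (bp_mode >= 0.8) & (bp_mode < 0.95), CUTOFFS["dbp"] + u(0.5, 15), CUTOFFS["dbp"] - u(3, 18))
    meds_bp = bp & (bp_mode >= 0.95)

    infl = held[:, 3]
    crp_mode = rng.random(n)
    crp = np.where(
        infl,
        u(CUTOFFS["crp_low"] + 0.05, CUTOFFS["crp_high"] - 0.5),
        np.where(crp_mode < 0.92, u(0.1, CUTOFFS["crp_low"] - 0.1), u(CUTOFFS["crp_high"] + 0.5, 30)),
    )

    glu = held[:, gi]
    glu_mode = rng.random(n)
    hba1c = np.where(glu, CUTOFFS["hba1c"] + u(0.02, 1.6), CUTOFFS["hba1c"] - u(0.1, 1.0))
    meds_glucose = glu & (glu_mode < 0.05)

    bio = pd.DataFrame(
        {
            "sex": sex.to_numpy(),
            "age": np.round(np.asarray(age, dtype=float), 1),
            "waist_cm": np.round(waist, 1),
            "hdl_mmol_l": np.round(hdl, 3),
            "non_hdl_mmol_l": np.round(non_hdl, 3),
            "sbp_mmhg": np.round(sbp, 1),
            "dbp_mmhg": np.round(dbp, 1),
            "crp_mg_l": np.round(crp, 2),
            "hba1c_pct": np.round(hba1c, 2),
            "meds_lipid": meds_lipid,
            "meds_bp": meds_bp,
            "meds_glucose": meds_glucose,
            "true_prob": prob,
        },
        index=idx,
    )
    return pd.Series(case, index=idx, name="case"), bio


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A generated cohort: diaries, participant table, and ground truth."""

    diaries: pd.DataFrame
    participants: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.diaries.to_csv(outdir / "diaries.csv", index=False)
        self.participants.to_csv(outdir / "participants.csv", index_label="participant_id")
        truth = {
            k: (v.reset_index().to_dict(orient="list") if isinstance(v, (pd.DataFrame, pd.Series)) else v)
            for k, v in self.truth.items()
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Determinism contract: the same config (seed included) yields identical
    outputs.  An ``n_participants`` of zero returns empty tables.
    """
    n = config.n_participants
    if n == 0:
        empty_diary = pd.DataFrame(columns=list(DIARY_COLUMNS))
        empty_part = pd.DataFrame()
        return SyntheticCohort(empty_diary, empty_part, {"n_participants": 0})

    rng = np.random.default_rng(config.seed)
    participants = _participant_table(rng, n, config)
    drivers = _draw_drivers(rng, n, config.traits)
    drivers.index = pd.RangeIndex(0, n)
    diaries = _synthesize_diaries(rng, drivers, participants["bmi"].to_numpy(), config)

    truth_expected = expected_exposures(drivers)
    matrix = derive_exposure_matrix(diaries)
    raw = matrix.raw.reindex(participants.index)
    raw_filled = raw.apply(lambda c: c.fillna(c.median()))

    case, bio = plant_outcome(
        raw_filled, config.effects, int(rng.integers(2**31)), covariates=participants
    )
    participants = pd.concat(
        [participants, bio.drop(columns=["sex", "age", "true_prob"])], axis=1
    )
    participants["case"] = case

    drivers_out = drivers.copy()
    drivers_out.index = participants.index
    truth_expected.index = participants.index
    truth = {
        "n_participants": n,
        "seed": config.seed,
        "block_structure": {b: i for i, b in enumerate(BLOCKS)},
        "drivers": drivers_out,
        "expected_exposures": truth_expected,
        "true_prob": bio["true_prob"],
        "case": case,
    }
    return SyntheticCohort(diaries=diaries, participants=participants, truth=truth)


def sample_exposure_matrix(
    n: int, seed: int, loadings: TraitLoadings | None = None
) -> ExposureMatrix:
    """Fast path: draw the 45 exposures directly at the participant level.

    Skips diary assembly; exposures are the expected values plus a small
    multiplicative sampling perturbation, preserving the planted block
    structure.  Intended for simulation studies of the modelling stages
    where diary mechanics are irrelevant.
    """
    loadings = loadings or TraitLoadings()
    rng = np.random.default_rng(seed)
    drivers = _draw_drivers(rng, n, loadings)
    exp_vals = expected_exposures(drivers)
    noise = np.exp(0.05 * rng.standard_normal(exp_vals.shape))
    return ExposureMatrix(raw=exp_vals * noise)


# ---------------------------------------------------------------------------
# planted-exclusion fixture
# ---------------------------------------------------------------------------

def exclusion_fixture(
    n_total: int = 9018,
    n_missing_diet: int = 150,
    n_too_few_days: int = 277,
    n_chronic: int = 499,
    n_missing_outcome: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A minimal cohort with planted exclusion counts.

    Builds single-occasion diaries (one 600-kcal breakfast row per day)
    for ``n_total`` participants, then plants each exclusion reason in a
    disjoint group: no diary rows at all, only four valid recording days,
    a chronic-disease flag, or incomplete outcome information.  Returns
    ``(diaries, participants)`` ready for the exclusion chain.
    """
    for name, v in {
        "n_total": n_total, "n_missing_diet": n_missing_diet,
        "n_too_few_days": n_too_few_days, "n_chronic": n_chronic,
        "n_missing_outcome": n_missing_outcome,
    }.items():
        if v < 0:
            raise ConfigurationError(f"{name} must be >= 0, got {v}")
    planted = n_missing_diet + n_too_few_days + n_chronic + n_missing_outcome
    if planted > n_total:
        raise ConfigurationError("planted exclusion counts exceed n_total")

    rng = np.random.default_rng(seed)
    ids = np.arange(1, n_total + 1)
    order = rng.permutation(ids)
    g_missing = set(order[:n_missing_diet])
    g_few = set(order[n_missing_diet : n_missing_diet + n_too_few_days])
    g_chronic = set(order[n_missing_diet + n_too_few_days : n_missing_diet + n_too_few_days + n_chronic])
    g_out = set(order[n_missing_diet + n_too_few_days + n_chronic : planted])

    rows = []
    for pid in ids:
        if pid in g_missing:
            continue
        low_days = {5, 6, 7} if pid in g_few else set()
        for day in range(1, 8):
            kcal = 120.0 if day in low_days else 600.0
            rows.append((pid, day, "breakfast", kcal, 20.0, 80.0, 30.0, 20.0, 8.0, 6.0))
    diaries = pd.DataFrame(rows, columns=list(DIARY_COLUMNS))
    participants = pd.DataFrame(
        {
            "chronic_disease": [pid in g_chronic for pid in ids],
            "outcome_complete": [pid not in g_out for pid in ids],
        },
        index=pd.Index(ids, name="participant_id"),
    )
    return diaries, participants
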