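"""Synthetic actigraphy cohorts with plantable effect sizes.

Generates week-long (10,080 minute) vertical-acceleration count records for a
cohort containing a small SSRI-exposed subgroup.  The exposed group carries
three plantable contrasts relative to controls:

* a multiplicatively lower whole-day mean activity (``amplitude_ratio``),
* a shallower 6-9 am rise in activity (``morning_slope_ratio``),
* a shallower 6-9 pm decline (``evening_slope_ratio``),

together with an older, more-female demographic profile, higher PHQ-9
depression scores, and missing-at-random PHQ-9 missingness.  Every planted
quantity is recoverable downstream, which makes the generator the ground-truth
surface for the whole analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

MINUTES_PER_DAY = 1440
DAYS_PER_WEEK = 7
MINUTES_PER_WEEK = MINUTES_PER_DAY * DAYS_PER_WEEK

#: half-open minute-of-day windows for the morning and evening ramps
MORNING_WINDOW = (360, 540)
EVENING_WINDOW = (1080, 1260)

SSRI_GENERIC_NAMES = (
    "SERTRALINE HYDROCHLORIDE",
    "ESCITALOPRAM OXALATE",
    "FLUOXETINE HYDROCHLORIDE",
    "PAROXETINE HYDROCHLORIDE",
    "CITALOPRAM HYDROBROMIDE",
)

NON_SSRI_GENERIC_NAMES = (
    "IBUPROFEN",
    "LISINOPRIL",
    "METFORMIN HYDROCHLORIDE",
    "ATORVASTATIN CALCIUM",
    "LEVOTHYROXINE SODIUM",
    "OMEPRAZOLE",
    "AMLODIPINE BESYLATE",
)

RACE_CATEGORIES = ("Black", "White", "Mexican American", "Other Hispanic", "Other")


@dataclass(frozen=True)
class DiurnalProfile:
    """Expected counts/min for each of the 1,440 minutes of a day.

    The profile is piecewise linear: a night trough, a linear morning ramp
    over minutes [360, 540), a daytime plateau, a linear evening decline over
    [1080, 1260), and a (possibly different) late-night trough.
    """

    values: np.ndarray
    morning_ramp: float
    evening_ramp: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (MINUTES_PER_DAY,):
            raise ValueError(f"profile must have {MINUTES_PER_DAY} values, got {values.shape}")
        if np.any(values < 0):
            raise ValueError("diurnal profile values must be nonnegative")
        night = values[:300].mean()
        day = values[600:1020].mean()
        if not night < day:
            raise ValueError("night trough mean must be below daytime plateau mean")
        object.__setattr__(self, "values", values)

    @property
    def daily_mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class NoiseModel:
    """Overdispersed count noise around the diurnal profile.

    Counts are negative-binomial (gamma-Poisson) with shape ``dispersion``;
    night minutes additionally receive zero-inflation at rate
    ``zero_inflation_night`` with the surviving mean rescaled so the
    per-minute expectation still equals the profile.  ``between_person_sd``
    is the SD of a mean-one lognormal amplitude multiplier capturing
    between-person activity differences.
    """

    dispersion: float = 2.0
    zero_inflation_night: float = 0.3
    between_person_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.zero_inflation_night < 1:
            raise ValueError("zero_inflation_night must be in [0, 1)")
        if self.between_person_sd < 0:
            raise ValueError("between_person_sd must be nonnegative")


#: noiseless limit: expected counts are emitted exactly
ZERO_NOISE = None


@dataclass(frozen=True)
class EffectConfig:
    """Planted exposed-vs-control contrasts and cohort composition."""

    amplitude_ratio: float = 0.71
    morning_slope_ratio: float = 0.75
    evening_slope_ratio: float = 0.51
    prevalence: float = 0.037
    phq9_shift: float = 1.58
    phq9_missing_rate: float = 0.402
    noise_model: NoiseModel | None = field(default_factory=NoiseModel)
    seed: int = 20220407

    def __post_init__(self) -> None:
        for name in ("amplitude_ratio", "morning_slope_ratio", "evening_slope_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.phq9_missing_rate < 1:
            raise ValueError("phq9_missing_rate must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort: activity, exposure labels, demographics, PHQ-9."""

    activity: np.ndarray  # (n, 10080) counts/min
    labels: np.ndarray  # (n,) binary exposure
    demographics: pd.DataFrame  # participant_id, age, sex, race
    phq9: np.ndarray  # (n,) float, NaN = missing
    control_profile: DiurnalProfile
    exposed_profile: DiurnalProfile
    config: EffectConfig

    @property
    def n_participants(self) -> int:
        return self.activity.shape[0]

    @property
    def participant_ids(self) -> np.ndarray:
        return self.demographics["participant_id"].to_numpy()

    def medication_table(self, seed: int | None = None) -> pd.DataFrame:
        """Self-reported medication records consistent with the labels.

        Exposed participants report one SSRI (cycling through the five salts)
        plus possibly other medications; controls report 0-2 non-SSRI drugs.
        """
        rng = np.random.default_rng(self.config.seed + 11 if seed is None else seed)
        rows: list[tuple[int, str]] = []
        ssri_cycle = 0
        for pid, label in zip(self.participant_ids, self.labels):
            if label:
                rows.append((pid, SSRI_GENERIC_NAMES[ssri_cycle % len(SSRI_GENERIC_NAMES)]))
                ssri_cycle += 1
            n_other = rng.integers(0, 3)
            for name in rng.choice(NON_SSRI_GENERIC_NAMES, size=n_other, replace=False):
                rows.append((pid, str(name)))
        return pd.DataFrame(rows, columns=["participant_id", "generic_name"])


def generate_diurnal_profile(
    plateau_level: float,
    morning_ramp: float = 1.0,
    evening_ramp: float = -1.0,
) -> DiurnalProfile:
    """Build a piecewise-linear diurnal profile with exact ramp slopes.

    Night levels are implied by continuity at the plateau: the pre-morning
    trough is ``plateau - 180*morning_ramp`` and the post-evening trough is
    ``plateau + 180*evening_ramp``; both must be nonnegative.
    """
    if plateau_level <= 0:
        raise ValueError("plateau_level must be positive")
    if morning_ramp <= 0:
        raise ValueError("morning_ramp must be positive (activity rises in the morning)")
    if evening_ramp >= 0:
        raise ValueError("evening_ramp must be negative (activity falls in the evening)")
    m0, m1 = MORNING_WINDOW
    e0, e1 = EVENING_WINDOW
    night_am = plateau_level - morning_ramp * (m1 - m0)
    night_pm = plateau_level + evening_ramp * (e1 - e0)
    if night_am < 0 or night_pm < 0:
        raise ValueError("ramps too steep: implied night level is negative")
    t = np.arange(MINUTES_PER_DAY, dtype=float)
    values = np.full(MINUTES_PER_DAY, plateau_level, dtype=float)
    values[:m0] = night_am
    ramp = slice(m0, m1)
    values[ramp] = night_am + morning_ramp * (t[ramp] - m0)
    decl = slice(e0, e1)
    values[decl] = plateau_level + evening_ramp * (t[decl] - e0)
    values[e1:] = night_pm
    return DiurnalProfile(values=values, morning_ramp=morning_ramp, evening_ramp=evening_ramp)


def exposed_profile_from_control(
    control: DiurnalProfile,
    amplitude_ratio: float,
    morning_slope_ratio: float,
    evening_slope_ratio: float,
) -> DiurnalProfile:
    """Derive the exposed-group profile realising all three planted ratios.

    The exposed morning/evening ramps are the control ramps scaled by the
    slope ratios, and the plateau is solved (the whole-day mean is affine in
    the plateau with unit coefficient) so that the exposed whole-day mean is
    exactly ``amplitude_ratio`` times the control mean.
    """
    s_m = control.morning_ramp * morning_slope_ratio
    s_e = control.evening_ramp * evening_slope_ratio
    target_mean = amplitude_ratio * control.daily_mean
    # one-shot affine correction: d(mean)/d(plateau) == 1 exactly
    p0 = control.values[600:1020].mean()
    draft = generate_diurnal_profile(p0, s_m, s_e)
    plateau = p0 + (target_mean - draft.daily_mean)
    return generate_diurnal_profile(plateau, s_m, s_e)


def _night_mask() -> np.ndarray:
    minute = np.arange(MINUTES_PER_WEEK) % MINUTES_PER_DAY
    return (minute < MORNING_WINDOW[0]) | (minute >= EVENING_WINDOW[1])


def _noisy_weeks(
    mu: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Zero-inflated gamma-Poisson draws with expectation exactly ``mu``.

    ``mu`` has shape (n, 10080).  Night minutes are zeroed with probability
    ``zero_inflation_night``; the surviving mean is inflated by 1/(1-pi) so
    E[count] = mu holds at every minute.
    """
    pi = noise.zero_inflation_night
    night = _night_mask()
    mean = mu.copy()
    if pi > 0:
        mean[:, night] = mean[:, night] / (1.0 - pi)
    lam = rng.gamma(noise.dispersion, mean / noise.dispersion)
    counts = rng.poisson(lam).astype(float)
    if pi > 0:
        dropout = rng.random((mu.shape[0], int(night.sum()))) < pi
        sub = counts[:, night]
        sub[dropout] = 0.0
        counts[:, night] = sub
    return counts


def generate_participant_week(
    profile: DiurnalProfile,
    noise_model: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One participant's 10,080-minute count vector.

    With ``noise_model=None`` the profile is tiled over the 7 days exactly;
    otherwise overdispersed counts are drawn with per-minute expectation equal
    to the tiled profile.  Identical seeds give bitwise-identical weeks.
    """
    week = np.tile(profile.values, DAYS_PER_WEEK)
    if noise_model is None:
        return week
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _noisy_weeks(week[None, :], noise_model, rng)[0]


def _solve_missing_intercept(linear: np.ndarray, rate: float) -> float:
    if rate == 0:
        return -np.inf
    f = lambda a: expit(a + linear).mean() - rate
    return brentq(f, -30.0, 30.0)


DEFAULT_CONTROL_PLATEAU = 250.0
DEFAULT_MORNING_RAMP = 1.0
DEFAULT_EVENING_RAMP = -1.0

# Table-style group-conditional demographics (age in years; sex as P(female);
# race/ethnicity category probabilities), configurable via generate_cohort.
DEFAULT_DEMOGRAPHICS = {
    "age_mean": {"control": 33.1, "exposed": 49.6},
    "age_sd": {"control": 22.4, "exposed": 20.2},
    "p_female": {"control": 0.510, "exposed": 0.699},
    "race_probs": {
        "control": (0.276, 0.388, 0.260, 0.029, 0.047),
        "exposed": (0.128, 0.677, 0.124, 0.026, 0.045),
    },
}

PHQ9_CONTROL_MEAN = 2.68
PHQ9_DISPERSION = 1.35
PHQ9_MAX = 27


def generate_cohort(
    config: EffectConfig,
    n_participants: int,
    control_plateau: float = DEFAULT_CONTROL_PLATEAU,
    morning_ramp: float = DEFAULT_MORNING_RAMP,
    evening_ramp: float = DEFAULT_EVENING_RAMP,
    demographics_spec: dict | None = None,
    chunk_size: int = 250,
) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Exposure labels are Bernoulli(prevalence); exposed activity follows the
    derived exposed profile (planted amplitude and slope ratios), every
    participant gets a mean-one lognormal amplitude multiplier, and counts are
    zero-inflated negative-binomial around the personal profile.  PHQ-9 is an
    overdispersed count score on [0, 27] with a planted group mean shift and
    missing-at-random missingness driven by age and sex.
    """
    if n_participants < 20:
        raise ValueError("n_participants must be at least 20")
    if config.prevalence * n_participants < 2:
        raise ValueError(
            "expected fewer than 2 exposed participants; cannot stratify "
            f"(prevalence {config.prevalence} x n {n_participants})"
        )
    spec = DEFAULT_DEMOGRAPHICS if demographics_spec is None else demographics_spec
    rng = np.random.default_rng(config.seed)

    control = generate_diurnal_profile(control_plateau, morning_ramp, evening_ramp)
    exposed = exposed_profile_from_control(
        control, config.amplitude_ratio, config.morning_slope_ratio, config.evening_slope_ratio
    )

    labels = (rng.random(n_participants) < config.prevalence).astype(np.int8)
    group = np.where(labels == 1, "exposed", "control")

    age = np.empty(n_participants)
    sex = np.empty(n_participants, dtype=object)
    race = np.empty(n_participants, dtype=object)
    for g in ("control", "exposed"):
        idx = np.flatnonzero(group == g)
        # integer years, as in survey demographics tables
        age[idx] = np.round(
            np.clip(rng.normal(spec["age_mean"][g], spec["age_sd"][g], idx.size), 0.0, 90.0)
        )
        sex[idx] = np.where(rng.random(idx.size) < spec["p_female"][g], "female", "male")
        race[idx] = rng.choice(RACE_CATEGORIES, size=idx.size, p=spec["race_probs"][g])

    phq9_mean = np.where(labels == 1, PHQ9_CONTROL_MEAN + config.phq9_shift, PHQ9_CONTROL_MEAN)
    phq9_lam = rng.gamma(PHQ9_DISPERSION, phq9_mean / PHQ9_DISPERSION)
    phq9 = np.minimum(rng.poisson(phq9_lam), PHQ9_MAX).astype(float)
    if config.phq9_missing_rate > 0:
        z_age = (age - age.mean()) / age.std()
        linear = 0.5 * z_age + 0.3 * (sex == "male")
        alpha = _solve_missing_intercept(linear, config.phq9_missing_rate)
        missing = rng.random(n_participants) < expit(alpha + linear)
        phq9[missing] = np.nan

    noise = config.noise_model
    activity = np.empty((n_participants, MINUTES_PER_WEEK))
    base = np.where(labels[:, None] == 1, 1.0, 0.0)
    profiles = np.where(
        base, np.tile(exposed.values, DAYS_PER_WEEK), np.tile(control.values, DAYS_PER_WEEK)
    )
    if noise is None:
        activity[:] = profiles
    else:
        if noise.between_person_sd > 0:
            sd = noise.between_person_sd
            sigma = np.sqrt(np.log1p(sd**2))
            amp = rng.lognormal(-0.5 * sigma**2, sigma, n_participants)
        else:
            amp = np.ones(n_participants)
        mu = profiles * amp[:, None]
        for start in range(0, n_participants, chunk_size):
            stop = min(start + chunk_size, n_participants)
            activity[start:stop] = _noisy_weeks(mu[start:stop], noise, rng)

    demographics = pd.DataFrame(
        {
            "participant_id": np.arange(1, n_participants + 1),
            "age": age,
            "sex": sex,
            "race": race,
        }
    )
    return SyntheticCohort(
        activity=activity,
        labels=labels,
        demographics=demographics,
        phq9=phq9,
        control_profile=control,
        exposed_profile=exposed,
        config=config,
    )


def null_config(seed: int = 20220407, **overrides) -> EffectConfig:
    """An EffectConfig with every planted effect switched off."""
    defaults = dict(
        amplitude_ratio=1.0,
        morning_slope_ratio=1.0,
        evening_slope_ratio=1.0,
        phq9_shift=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return EffectConfig(**defaults)
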