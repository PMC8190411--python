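"""Cohort inclusion/exclusion and energy-intake misreporting screen.

Implements the study-population filters used in sex-stratified dietary
pattern analyses of 24-h recall data:

(a) age below a minimum (default 20 y);
(b) pregnancy;
(c) missing weight, height, PUFA intake, Zn intake, serum LA or serum DGLA;
(d) implausible energy reporting.

Energy misreporting is screened by comparing mean reported energy intake
(EI, converted to MJ/day) against predicted total energy expenditure (pTEE)
from the Vinken equation

    pTEE = 7.377 - 0.073*age + 0.0806*weight + 0.0135*height - 1.363*sex

(age in years, weight kg, standing height cm, sex 0 = male / 1 = female).
The plausibility band is the McCrory +/-1 SD propagation of the stated
coefficients of variation,

    1 SD = sqrt(CV_wEI^2 / d + CV_wpTEE^2 + CV_tmTEE^2),

with CV_wEI = 32.3 %, CV_wpTEE = 20.2 %, CV_tmTEE = 8.2 % and d = 2 recall
days. A person is an under-reporter when EI/pTEE < 1 - SD and an
over-reporter when EI/pTEE > 1 + SD; values exactly on a bound count as
plausible (the band is closed).

Serum Zn below the clinical cutoff (75 µg/dL) is *flagged* for prevalence
reporting but never used for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningConfig",
    "compute_bmi",
    "predict_tee",
    "misreport_cutoff_sd",
    "classify_reporter",
    "screen_participants",
    "apply_inclusion_filters",
]

#: Schema columns whose missingness triggers exclusion step (c).
MISSING_CHECK_COLUMNS = (
    "weight_kg",
    "height_cm",
    "pufa_intake_g",
    "zn_intake_mg",
    "serum_la",
    "serum_dgla",
)


@dataclass(frozen=True)
class ScreeningConfig:
    """Constants of the misreporting screen and inclusion filters.

    CVs are percentages; ``d_days`` is the number of recall days entering the
    within-person EI variance term; ``kcal_to_MJ`` converts reported kcal/day
    to MJ/day; ``serum_zn_cutoff`` (µg/dL) only flags low serum Zn.
    """

    cv_wEI: float = 32.3
    cv_wpTEE: float = 20.2
    cv_tmTEE: float = 8.2
    d_days: int = 2
    kcal_to_MJ: float = 0.004184
    min_age: float = 20.0
    serum_zn_cutoff: float = 75.0

    def __post_init__(self) -> None:
        if min(self.cv_wEI, self.cv_wpTEE, self.cv_tmTEE) < 0:
            raise ValueError("CVs must be non-negative")
        if self.d_days < 1:
            raise ValueError("d_days must be >= 1")
        if self.kcal_to_MJ <= 0:
            raise ValueError("kcal_to_MJ must be positive")


def compute_bmi(weight_kg, height_m):
    """Body mass index, weight (kg) / height (m) squared."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight and height must be positive")
    out = weight_kg / height_m**2
    return float(out) if out.ndim == 0 else out


def predict_tee(age, weight_kg, height_cm, sex):
    """Predicted total energy expenditure (MJ/day), Vinken equation.

    ``sex`` is coded 0 for men and 1 for women.
    """
    age = np.asarray(age, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    sex = np.asarray(sex)
    if np.any((sex != 0) & (sex != 1)):
        raise ValueError("sex must be coded 0 (male) or 1 (female)")
    if np.any(age < 0) or np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("age must be >= 0; weight and height positive")
    out = 7.377 - 0.073 * age + 0.0806 * weight_kg + 0.0135 * height_cm - 1.363 * sex.astype(float)
    return float(out) if out.ndim == 0 else out


def misreport_cutoff_sd(config: ScreeningConfig = ScreeningConfig()) -> float:
    """The +/-1 SD plausibility half-width of EI/pTEE, as a fraction.

    With the default constants (32.3, 20.2, 8.2, d = 2) this is 0.3157.
    """
    return (
        math.sqrt(config.cv_wEI**2 / config.d_days + config.cv_wpTEE**2 + config.cv_tmTEE**2)
        / 100.0
    )


def classify_reporter(ei_kcal, ptee_mj, sd_cutoff=None, config: ScreeningConfig = ScreeningConfig()):
    """Classify energy reporting as ``plausible`` / ``under`` / ``over``.

    ``ei_kcal`` is the mean reported energy intake over the recall days in
    kcal/day; ``ptee_mj`` the predicted TEE in MJ/day. Boundary ratios are
    plausible.
    """
    if sd_cutoff is None:
        sd_cutoff = misreport_cutoff_sd(config)
    ei_kcal = np.asarray(ei_kcal, dtype=float)
    ptee_mj = np.asarray(ptee_mj, dtype=float)
    if np.any(ptee_mj <= 0):
        raise ValueError("pTEE must be positive")
    if np.any(ei_kcal < 0):
        raise ValueError("energy intake must be non-negative")
    ratio = ei_kcal * config.kcal_to_MJ / ptee_mj
    out = np.where(ratio < 1.0 - sd_cutoff, "under", np.where(ratio > 1.0 + sd_cutoff, "over", "plausible"))
    return str(out) if out.ndim == 0 else out


def screen_participants(df: pd.DataFrame, config: ScreeningConfig = ScreeningConfig()) -> pd.DataFrame:
    """Per-person screening quantities for a schema-conforming table.

    Returns a frame indexed like ``df`` with columns ``bmi``, ``ptee_mj``,
    ``ei_mj``, ``ratio``, ``sd_cutoff``, ``reporter_class``,
    ``serum_zn_low``. EI is the mean of the recall-day energies.
    """
    sd = misreport_cutoff_sd(config)
    ei_kcal = df[["energy_kcal_day1", "energy_kcal_day2"]].mean(axis=1)
    ptee = predict_tee(df["age"], df["weight_kg"], df["height_cm"], df["sex"])
    bmi = compute_bmi(df["weight_kg"], df["height_cm"] / 100.0)
    out = pd.DataFrame(index=df.index)
    out["bmi"] = bmi
    out["ptee_mj"] = ptee
    out["ei_mj"] = ei_kcal * config.kcal_to_MJ
    out["ratio"] = out["ei_mj"] / out["ptee_mj"]
    out["sd_cutoff"] = sd
    out["reporter_class"] = classify_reporter(ei_kcal, ptee, sd, config)
    out["serum_zn_low"] = df["serum_zn"] < config.serum_zn_cutoff
    return out


def apply_inclusion_filters(
    df: pd.DataFrame, config: ScreeningConfig = ScreeningConfig()
) -> tuple[pd.DataFrame, dict]:
    """Apply the study exclusions (a)-(d) in order; return (filtered, log).

    The log records the number removed at each step, the final count, and the
    count/fraction of retained participants with serum Zn below
    ``serum_zn_cutoff`` (flagged only, never excluded). Step counts sum to
    input minus output rows.
    """
    required = set(MISSING_CHECK_COLUMNS) | {
        "age",
        "sex",
        "pregnant",
        "serum_zn",
        "energy_kcal_day1",
        "energy_kcal_day2",
    }
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"participant table missing columns: {sorted(missing_cols)}")

    log: dict = {"n_input": int(len(df))}
    work = df

    # (a) minimum age
    keep = work["age"] >= config.min_age
    log["removed_age"] = int((~keep).sum())
    work = work[keep]

    # (b) pregnancy
    keep = ~work["pregnant"].astype(bool)
    log["removed_pregnant"] = int((~keep).sum())
    work = work[keep]

    # (c) missing core variables
    keep = work[list(MISSING_CHECK_COLUMNS)].notna().all(axis=1)
    log["removed_missing"] = int((~keep).sum())
    work = work[keep]

    # (d) implausible energy reporting
    scr = screen_participants(work, config)
    under = scr["reporter_class"] == "under"
    over = scr["reporter_class"] == "over"
    log["removed_under_report"] = int(under.sum())
    log["removed_over_report"] = int(over.sum())
    work = work[scr["reporter_class"] == "plausible"]

    log["n_final"] = int(len(work))
    n_low = int((work["serum_zn"] < config.serum_zn_cutoff).sum())
    log["serum_zn_low_count"] = n_low
    log["serum_zn_low_pct"] = 100.0 * n_low / len(work) if len(work) else float("nan")
    if len(work) == 0:
        import warnings

        warnings.warn("all participants excluded", stacklevel=2)
    return work, log
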