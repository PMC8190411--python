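"""Synthetic cohort generator with planted dietary-pattern structure.

Emulates the statistical shape of a two-recall-day national survey cohort
(demographics, anthropometry, 34 food-group intakes on each of two days,
nutrient and energy intakes, serum fatty acids and serum Zn) together with
a ground-truth record, so every pipeline stage can be tested without any
download.

Generative model, per person i and food group g:

* demographics: age truncated-normal on [20, 80]; sex-specific normal
  weight/height; PIR uniform on [0, 5]; multinomial race (6 levels) and
  education (5 levels); Bernoulli vigorous work/recreation, lipid-lowering
  medication, supplement use; pregnancy only among women.
* intakes are log-normal: the person-level base intake has median
  ``group_medians[g]`` and log-scale SD from ``between_person_cv``. A
  standard-normal latent ``u_i`` plants the "rich in Zn, poor in PUFA"
  pattern: for planted groups the person effect is the correlated blend
  ``rho * sign_g * u_i + sqrt(1 - rho^2) * noise`` (rho =
  ``pattern2_strength``), so adherent people systematically eat more of the
  positive groups and less of the negative ones at fixed energy.
* energy balance: each person's intakes are rescaled so that expected
  daily energy equals Vinken-predicted TEE times a log-normal deviation
  (CV ``energy_balance_cv``). This is what makes the EI/pTEE misreporting
  screen operate on realistic ratios centred at 1.
* each recall day multiplies the person base by independent log-normal
  day noise (CV ``within_person_cv``; median 1, so the two days are equal
  in the zero-CV limit).
* nutrients: Zn (mg/day), PUFA (g/day) are density-weighted sums of the
  person's mean daily group intakes plus small Gaussian noise; energy is
  computed per recall day from that day's intakes.
* outcomes: the true pattern score is the sum of z-scored true usual
  intakes over the positive planted groups minus the negative ones; serum
  LA/DGLA ratio = intercept + beta_ratio * score + small age/BMI terms +
  noise, serum DGLA analogously with beta_dgla; serum LA = ratio * DGLA.
* misreporting: a ``misreport_fraction`` subset has *all reported*
  quantities (both recall days, nutrients, energy) multiplied by the under
  (< 1) or over (> 1) factor, split evenly; truth keeps the flags.

What this generator does not emulate: survey weights and clustering,
episodically-consumed foods (every group is eaten daily), food-composition
correlations beyond the linear densities, and seasonal or weekday effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .foodgroups import GROUP_IDS, N_GROUPS, default_group_table
from .screening import predict_tee

__all__ = ["CohortSpec", "TruthRecord", "default_spec", "generate_cohort", "truth_summary"]

KCAL_PER_MJ = 1.0 / 0.004184

#: planted "rich in Zn, poor in PUFA" pattern: dairy, red meat and fortified
#: breakfast cereals up; cakes/pastries and salad dressing down.
DEFAULT_PATTERN2_POS = ("G1", "G2", "G3", "G17")
DEFAULT_PATTERN2_NEG = ("G13", "G30")

_RACE_LEVELS = ("mexican_american", "other_hispanic", "nh_white", "nh_black", "nh_asian", "other_multi")
_EDU_LEVELS = ("lt_9th", "9_11th", "hs_grad", "some_college", "college_grad")

# sex-specific categorical probabilities, population-survey magnitudes
_DEMO = {
    "female": {
        "race_p": (0.097, 0.109, 0.379, 0.248, 0.137, 0.030),
        "edu_p": (0.082, 0.114, 0.192, 0.316, 0.296),
        "vig_work": 0.088,
        "vig_rec": 0.184,
        "lipid_med": 0.175,
        "supplement": 0.279,
        "weight": (75.0, 19.0),
        "height": (162.0, 7.0),
    },
    "male": {
        "race_p": (0.119, 0.103, 0.409, 0.192, 0.158, 0.019),
        "edu_p": (0.082, 0.165, 0.242, 0.255, 0.256),
        "vig_work": 0.248,
        "vig_rec": 0.256,
        "lipid_med": 0.193,
        "supplement": 0.197,
        "weight": (88.0, 18.0),
        "height": (176.0, 7.5),
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic sex stratum."""

    n_participants: int
    sex: str  # "male" | "female"
    seed: int
    group_medians: np.ndarray  # 34, g/day
    zn_density: np.ndarray  # 34, mg Zn per g
    pufa_density: np.ndarray  # 34, g PUFA per g
    energy_density: np.ndarray  # 34, kcal per g
    within_person_cv: float = 0.50
    between_person_cv: float = 0.50
    pattern2_groups_pos: tuple[str, ...] = DEFAULT_PATTERN2_POS
    pattern2_groups_neg: tuple[str, ...] = DEFAULT_PATTERN2_NEG
    pattern2_strength: float = 0.60
    beta_ratio: float = -0.8
    beta_dgla: float = 4.0
    outcome_noise_sd: float = 6.0
    misreport_fraction: float = 0.12
    misreport_factors: tuple[float, float] = (0.5, 1.6)
    energy_balance_cv: float = 0.12
    nutrient_noise_cv: float = 0.05
    pregnancy_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        for name in ("group_medians", "zn_density", "pufa_density", "energy_density"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_GROUPS,):
                raise ValueError(f"{name} must be a length-{N_GROUPS} vector")
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, v)
        if self.within_person_cv <= 0:
            raise ValueError("within_person_cv must be > 0")
        pos, neg = set(self.pattern2_groups_pos), set(self.pattern2_groups_neg)
        if not pos or not neg:
            raise ValueError("pattern group sets must be non-empty")
        if pos & neg:
            raise ValueError("pattern group sets must be disjoint")
        if not (pos | neg) <= set(GROUP_IDS):
            raise ValueError("pattern groups must be within G1..G34")
        if not 0.0 <= self.misreport_fraction < 1.0:
            raise ValueError("misreport_fraction must be in [0, 1)")
        under, over = self.misreport_factors
        if not (under < 1.0 < over):
            raise ValueError("misreport_factors must be (under < 1, over > 1)")
        if not 0.0 <= self.pattern2_strength < 1.0:
            raise ValueError("pattern2_strength must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of one generated cohort, for recovery tests."""

    true_pattern2_score: pd.Series
    planted_signs: dict[str, int]
    misreporter_flags: pd.Series  # {"none", "under", "over"}
    beta_ratio: float
    beta_dgla: float
    true_usual_intake: pd.DataFrame  # n x 34, g/day, pre-misreporting


def default_spec(sex: str, n_participants: int = 800, seed: int = 0, **overrides) -> CohortSpec:
    """The default study conditions for one sex stratum."""
    tbl = default_group_table()
    spec = CohortSpec(
        n_participants=n_participants,
        sex=sex,
        seed=seed,
        group_medians=tbl["median_g_day"].to_numpy(),
        zn_density=tbl["zn_mg_g"].to_numpy(),
        pufa_density=tbl["pufa_g_g"].to_numpy(),
        energy_density=tbl["energy_kcal_g"].to_numpy(),
    )
    return replace(spec, **overrides) if overrides else spec


def _lognorm_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate one sex stratum; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    demo = _DEMO[spec.sex]
    sex_code = 0 if spec.sex == "male" else 1

    # --- demographics & anthropometry -----------------------------------
    age = stats.truncnorm.rvs((20 - 48) / 17.5, (80 - 48) / 17.5, loc=48, scale=17.5, size=n, random_state=rng)
    w_mu, w_sd = demo["weight"]
    h_mu, h_sd = demo["height"]
    weight = np.clip(rng.normal(w_mu, w_sd, n), 40.0, None)
    height = np.clip(rng.normal(h_mu, h_sd, n), 140.0, None)
    pir = rng.uniform(0.0, 5.0, n)
    race = rng.choice(_RACE_LEVELS, size=n, p=demo["race_p"])
    education = rng.choice(_EDU_LEVELS, size=n, p=demo["edu_p"])
    vig_work = rng.random(n) < demo["vig_work"]
    vig_rec = rng.random(n) < demo["vig_rec"]
    lipid_med = rng.random(n) < demo["lipid_med"]
    supplement = rng.random(n) < demo["supplement"]
    pregnant = (rng.random(n) < spec.pregnancy_rate) & (sex_code == 1) & (age < 45)

    ptee_mj = predict_tee(age, weight, height, sex_code)

    # --- person-level usual intakes with planted pattern ------------------
    sigma_b = _lognorm_sigma(spec.between_person_cv)
    sigma_w = _lognorm_sigma(spec.within_person_cv)
    rho = spec.pattern2_strength

    u = rng.standard_normal(n)  # planted pattern-2 adherence
    eps = rng.standard_normal((n, N_GROUPS))
    signs = np.zeros(N_GROUPS)
    for g in spec.pattern2_groups_pos:
        signs[GROUP_IDS.index(g)] = 1.0
    for g in spec.pattern2_groups_neg:
        signs[GROUP_IDS.index(g)] = -1.0
    planted = signs != 0
    person_effect = eps.copy()
    person_effect[:, planted] = (
        rho * np.outer(u, signs[planted]) + math.sqrt(1.0 - rho * rho) * eps[:, planted]
    )
    base = spec.group_medians[None, :] * np.exp(sigma_b * person_effect)

    # --- energy balance rescaling ----------------------------------------
    balance_sigma = _lognorm_sigma(spec.energy_balance_cv) if spec.energy_balance_cv > 0 else 0.0
    balance = np.exp(balance_sigma * rng.standard_normal(n)) if balance_sigma > 0 else np.ones(n)
    expected_kcal = base @ spec.energy_density
    scale = ptee_mj * KCAL_PER_MJ * balance / expected_kcal
    usual_true = base * scale[:, None]  # true usual intake, g/day

    # --- recall days -------------------------------------------------------
    day_noise = np.exp(sigma_w * rng.standard_normal((2, n, N_GROUPS)) - sigma_w**2 / 2.0)
    day1 = usual_true * day_noise[0]
    day2 = usual_true * day_noise[1]
    mean_days = (day1 + day2) / 2.0

    # --- nutrients & energy ------------------------------------------------
    def _noisy(v: np.ndarray) -> np.ndarray:
        if spec.nutrient_noise_cv <= 0:
            return v
        return np.clip(v * (1.0 + spec.nutrient_noise_cv * rng.standard_normal(n)), 0.0, None)

    zn = _noisy(mean_days @ spec.zn_density)
    pufa = _noisy(mean_days @ spec.pufa_density)
    energy_d1 = _noisy(day1 @ spec.energy_density)
    energy_d2 = _noisy(day2 @ spec.energy_density)

    # --- true pattern score & serum outcomes -------------------------------
    z_usual = (usual_true - usual_true.mean(axis=0)) / usual_true.std(axis=0, ddof=1)
    true_score = z_usual[:, planted] @ signs[planted]

    bmi = weight / (height / 100.0) ** 2
    ratio = (
        25.0
        + spec.beta_ratio * true_score
        + 0.03 * (age - 48.0)
        + 0.05 * (bmi - 28.0)
        + spec.outcome_noise_sd * rng.standard_normal(n)
    )
    ratio = np.clip(ratio, 5.0, None)
    dgla = (
        150.0
        + spec.beta_dgla * true_score
        - 0.2 * (age - 48.0)
        + 1.0 * (bmi - 28.0)
        + 7.0 * spec.outcome_noise_sd * rng.standard_normal(n)
    )
    dgla = np.clip(dgla, 30.0, None)
    la = ratio * dgla
    # log-normal serum Zn: median 88 µg/dL, sigma 0.09 => ~4% below 75 µg/dL
    serum_zn = 88.0 * np.exp(0.09 * rng.standard_normal(n))

    # --- misreporting -------------------------------------------------------
    flags = np.full(n, "none", dtype=object)
    mis = rng.random(n) < spec.misreport_fraction
    under_mask = mis & (rng.random(n) < 0.5)
    over_mask = mis & ~under_mask
    flags[under_mask] = "under"
    flags[over_mask] = "over"
    factor = np.ones(n)
    factor[under_mask] = spec.misreport_factors[0]
    factor[over_mask] = spec.misreport_factors[1]

    day1_rep = day1 * factor[:, None]
    day2_rep = day2 * factor[:, None]
    zn_rep = zn * factor
    pufa_rep = pufa * factor
    energy_d1_rep = energy_d1 * factor
    energy_d2_rep = energy_d2 * factor

    # --- assemble -----------------------------------------------------------
    idx = pd.RangeIndex(n, name="participant_id")
    df = pd.DataFrame(
        {
            "sex": sex_code,
            "age": age,
            "race": race,
            "education": education,
            "pir": pir,
            "vigorous_work": vig_work.astype(int),
            "vigorous_rec": vig_rec.astype(int),
            "lipid_med": lipid_med.astype(int),
            "supplement": supplement.astype(int),
            "pregnant": pregnant.astype(int),
            "weight_kg": weight,
            "height_cm": height,
        },
        index=idx,
    )
    for j, g in enumerate(GROUP_IDS):
        df[f"{g}_day1"] = day1_rep[:, j]
    for j, g in enumerate(GROUP_IDS):
        df[f"{g}_day2"] = day2_rep[:, j]
    df["energy_kcal_day1"] = energy_d1_rep
    df["energy_kcal_day2"] = energy_d2_rep
    df["zn_intake_mg"] = zn_rep
    df["pufa_intake_g"] = pufa_rep
    df["serum_la"] = la
    df["serum_dgla"] = dgla
    df["serum_zn"] = serum_zn

    truth = TruthRecord(
        true_pattern2_score=pd.Series(true_score, index=idx, name="true_pattern2_score"),
        planted_signs={g: int(signs[GROUP_IDS.index(g)]) for g in GROUP_IDS if signs[GROUP_IDS.index(g)] != 0},
        misreporter_flags=pd.Series(flags, index=idx, name="misreporter"),
        beta_ratio=spec.beta_ratio,
        beta_dgla=spec.beta_dgla,
        true_usual_intake=pd.DataFrame(usual_true, index=idx, columns=list(GROUP_IDS)),
    )
    return df, truth


def truth_summary(truth: TruthRecord) -> pd.DataFrame:
    """Tidy summary of the ground truth (signs, slopes, misreporter tally)."""
    rows = [
        {"item": f"sign:{g}", "value": float(s)} for g, s in sorted(truth.planted_signs.items())
    ]
    rows.append({"item": "beta_ratio", "value": truth.beta_ratio})
    rows.append({"item": "beta_dgla", "value": truth.beta_dgla})
    counts = truth.misreporter_flags.value_counts()
    for flag in ("none", "under", "over"):
        rows.append({"item": f"misreporters:{flag}", "value": float(counts.get(flag, 0))})
    return pd.DataFrame(rows)
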