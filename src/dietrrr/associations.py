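"""Association layer: partial correlations, quintile tests, outcome models.

Reproduces the statistical toolkit applied to the simplified dietary
pattern scores:

* partial Pearson correlation between score and nutrient responses,
  adjusted for energy intake by residualization;
* linear trend tests of continuous variables across score quintiles (the
  ordinal quintile index 1..5 as trend variable; optional energy
  adjustment, used for food/nutrient rows but not serum rows);
* Pearson chi-square tests of categorical variables across quintiles;
* unadjusted (model 1) and covariate-adjusted (model 2) linear regressions
  of serum DGLA and the LA/DGLA ratio on the simplified score. Model 2
  adjusts for age, energy intake, PIR, race, physical activity, BMI,
  education, medication use and supplement use; categorical covariates are
  expanded to indicators against the largest category in the analyzed
  stratum.

All p-values are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "MODEL2_COVARIATES",
    "partial_correlation",
    "quintile_trend_test",
    "categorical_quintile_test",
    "outcome_regression",
]

#: the nine model-2 confounders, by schema column
MODEL2_COVARIATES = (
    "age",
    "energy_kcal",
    "pir",
    "race",
    "physical_activity",  # expands to vigorous_work + vigorous_rec indicators
    "bmi",
    "education",
    "lipid_med",
    "supplement",
)


@dataclass
class AssociationResult:
    """One association estimate with its uncertainty and context."""

    estimate: float
    se: float
    p_value: float
    model_label: str
    n_used: int
    adj_r2: float | None = None
    covariates: list[str] = field(default_factory=list)
    notes: dict = field(default_factory=dict)


def _residualize(v: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Residual of v after OLS on control (with intercept)."""
    X = np.column_stack([np.ones_like(control), control])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(a, b, control) -> AssociationResult:
    """Partial Pearson correlation of a and b given one control variable.

    Both vectors are residualized on the control (OLS with intercept); the
    Pearson correlation of the residuals is tested on n - 3 degrees of
    freedom. A constant control degenerates gracefully to the plain Pearson
    correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(control, dtype=float)
    n = len(a)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero-variance input")
    if np.var(c) > 0:
        ra, rb = _residualize(a, c), _residualize(b, c)
    else:  # constant control: no adjustment possible, plain Pearson
        ra, rb = a - a.mean(), b - b.mean()
    # residual numerically zero relative to the input scale => collinear
    if np.var(ra) <= 1e-24 * np.var(a) or np.var(rb) <= 1e-24 * np.var(b):
        raise ValueError("zero-variance residual (input collinear with control)")
    r = float(np.corrcoef(ra, rb)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(abs(t), df)
    se = float(np.sqrt((1.0 - r**2) / df))
    return AssociationResult(estimate=r, se=se, p_value=float(p), model_label="partial_corr", n_used=n)


def quintile_trend_test(outcome, quintile, adjust_energy: bool = False, energy=None) -> AssociationResult:
    """Linear trend of a continuous variable across score quintiles.

    OLS of the outcome on the ordinal quintile index (1..5), optionally
    adding energy intake as a covariate; reports the slope, SE and
    two-sided p of the index coefficient.
    """
    y = np.asarray(outcome, dtype=float)
    q = np.asarray(quintile, dtype=float)
    mask = ~(np.isnan(y) | np.isnan(q))
    if adjust_energy:
        if energy is None:
            raise ValueError("adjust_energy requires an energy vector")
        e = np.asarray(energy, dtype=float)
        mask &= ~np.isnan(e)
    y, q = y[mask], q[mask]
    if len(np.unique(q)) < 2:
        raise ValueError("need at least two populated quintiles")
    cols = {"const": np.ones_like(q), "quintile": q}
    if adjust_energy:
        cols["energy"] = np.asarray(energy, dtype=float)[mask]
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params["quintile"])
    se = float(fit.bse["quintile"])
    p = float(fit.pvalues["quintile"])
    # numerically zero-residual fits: flat outcome => slope 0, p 1; exact trend => p 0
    y_scale = max(1.0, float(np.sum(y**2)))
    if se == 0.0 or not np.isfinite(p) or fit.ssr <= 1e-24 * y_scale:
        if abs(slope) < 1e-10 * max(1.0, float(np.max(np.abs(y)))):
            slope, p = 0.0, 1.0
        else:
            p = 0.0
    return AssociationResult(
        estimate=slope,
        se=se,
        p_value=p,
        model_label="trend",
        n_used=int(fit.nobs),
        adj_r2=float(fit.rsquared_adj),
        covariates=["energy"] if adjust_energy else [],
    )


def categorical_quintile_test(category, quintile) -> AssociationResult:
    """Pearson chi-square test of a categorical variable across quintiles.

    Expected counts below 5 are flagged in ``notes`` but do not fail the
    test (matching common epidemiological practice). No continuity
    correction is applied.
    """
    cat = pd.Series(category).reset_index(drop=True)
    q = pd.Series(quintile).reset_index(drop=True)
    mask = cat.notna() & q.notna()
    cat, q = cat[mask], q[mask]
    if cat.nunique() < 2:
        raise ValueError("category has a single level")
    if q.nunique() < 2:
        raise ValueError("all observations in one quintile")
    table = pd.crosstab(cat, q)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    return AssociationResult(
        estimate=float(chi2),
        se=float("nan"),
        p_value=float(p),
        model_label="chi_square",
        n_used=int(table.to_numpy().sum()),
        notes={"dof": int(dof), "low_expected_cells": int((expected < 5).sum())},
    )


def _build_model2_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand the nine model-2 confounders into a numeric design block.

    Categorical race/education use indicator contrasts against the largest
    category in the stratum; physical activity enters as the two binary
    indicators (vigorous work, vigorous recreation).
    """
    needed = {"age", "energy_kcal", "pir", "bmi", "race", "education", "vigorous_work", "vigorous_rec", "lipid_med", "supplement"}
    missing = needed - set(covariates.columns)
    if missing:
        raise ValueError(f"model 2 requires covariates: {sorted(missing)}")
    block = covariates[["age", "energy_kcal", "pir", "bmi"]].astype(float).copy()
    for cat_col in ("race", "education"):
        ser = covariates[cat_col].astype(str)
        ref = ser.value_counts().idxmax()
        dummies = pd.get_dummies(ser, prefix=cat_col, dtype=float)
        dummies = dummies.drop(columns=f"{cat_col}_{ref}")
        block = pd.concat([block, dummies], axis=1)
        block.attrs[f"{cat_col}_reference"] = ref
    for bin_col in ("vigorous_work", "vigorous_rec", "lipid_med", "supplement"):
        block[bin_col] = covariates[bin_col].astype(float)
    return block


def outcome_regression(outcome, score, covariates: pd.DataFrame | None = None, model: str = "model1") -> AssociationResult:
    """Linear regression of a serum outcome on the simplified pattern score.

    ``model1`` is unadjusted; ``model2`` adds the nine confounders (see
    :data:`MODEL2_COVARIATES`). Complete-case rows only; reports the score
    coefficient, its SE and two-sided p, plus the adjusted R-squared of the
    whole model.
    """
    y = pd.Series(np.asarray(outcome, dtype=float)).reset_index(drop=True)
    x = pd.Series(np.asarray(score, dtype=float), name="score").reset_index(drop=True)
    design = pd.DataFrame({"score": x})
    covariate_names: list[str] = []
    attrs: dict = {}
    if model == "model2":
        if covariates is None:
            raise ValueError("model2 requires a covariate table")
        block = _build_model2_design(covariates.reset_index(drop=True))
        attrs = dict(block.attrs)
        design = pd.concat([design, block], axis=1)
        covariate_names = list(block.columns)
    elif model != "model1":
        raise ValueError("model must be 'model1' or 'model2'")

    mask = y.notna() & design.notna().all(axis=1)
    y, design = y[mask], design[mask]
    n_used = int(len(y))
    if n_used < design.shape[1] + 3:
        raise ValueError("too few complete cases for the requested model")
    X = sm.add_constant(design)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix (rank {rank} < {X.shape[1]}): {list(X.columns)}")
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        estimate=float(fit.params["score"]),
        se=float(fit.bse["score"]),
        p_value=float(fit.pvalues["score"]),
        model_label=model,
        n_used=n_used,
        adj_r2=float(fit.rsquared_adj),
        covariates=covariate_names,
        notes=attrs,
    )
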