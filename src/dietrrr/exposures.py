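"""Dietary exposures: food-group mapping, usual intake, energy adjustment.

Three standard preprocessing steps between raw 24-h recall items and
pattern extraction:

* aggregation of food items (g/day) into the 34-group scheme, with the
  dairy low-fat/whole-fat split and the grain fiber split (> 2.5 g per
  serving = good source);
* a variance-component shrinkage estimator of usual (habitual) intake from
  two recall days, removing within-person day-to-day variation — a
  deliberately simplified plug-in alternative to the full Multiple Source
  Method, which two recall days cannot identify;
* the regression residual method of energy adjustment for nutrient intakes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .foodgroups import GROUP_IDS

__all__ = [
    "map_food_groups",
    "estimate_usual_intake",
    "energy_adjust",
    "load_mapping",
    "toy_mapping",
]

FIBER_GOOD_SOURCE_G = 2.5  # strictly greater than => good source of fiber


def load_mapping(path) -> pd.DataFrame:
    """Read a food-code mapping file.

    Delimited text with columns ``food_code``, ``group_id``, ``split_rule``.
    ``split_rule`` is one of ``none``, ``dairy_fat`` (route to G1 low fat vs
    G2 whole fat by the item's low-fat attribute) or ``grain_fiber`` (route
    to G20 vs G21 by fiber per serving).
    """
    mapping = pd.read_csv(path, dtype={"food_code": str})
    needed = {"food_code", "group_id", "split_rule"}
    if not needed <= set(mapping.columns):
        raise ValueError(f"mapping file needs columns {sorted(needed)}")
    return mapping


def toy_mapping() -> pd.DataFrame:
    """The small food-code mapping shipped for tests and examples."""
    from importlib.resources import files

    return load_mapping(files("dietrrr.data").joinpath("toy_food_mapping.csv"))


def map_food_groups(items: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a food-item table into the 34 food groups (one recall day).

    ``items`` columns: ``participant_id``, ``food_code``, ``grams`` and,
    where the mapping requires a split, ``low_fat`` (boolean) or
    ``fiber_per_serving`` (g). Returns a participant-indexed frame with the
    34 ``G1..G34`` columns (g/day); unmapped groups are zero. Total grams
    are conserved.
    """
    items = items.copy()
    items["food_code"] = items["food_code"].astype(str)
    m = mapping.set_index("food_code")
    unknown = set(items["food_code"]) - set(m.index)
    if unknown:
        raise KeyError(f"unknown food codes: {sorted(unknown)}")

    rule = m.loc[items["food_code"], "split_rule"].to_numpy()
    group = m.loc[items["food_code"], "group_id"].to_numpy(dtype=object)

    dairy = rule == "dairy_fat"
    if dairy.any():
        if "low_fat" not in items.columns or items.loc[dairy, "low_fat"].isna().any():
            raise ValueError("dairy items need a low_fat attribute")
        group[dairy] = np.where(items.loc[dairy, "low_fat"].astype(bool), "G1", "G2")

    grain = rule == "grain_fiber"
    if grain.any():
        if "fiber_per_serving" not in items.columns or items.loc[grain, "fiber_per_serving"].isna().any():
            raise ValueError("grain items need a fiber_per_serving attribute")
        group[grain] = np.where(
            items.loc[grain, "fiber_per_serving"].astype(float) > FIBER_GOOD_SOURCE_G,
            "G20",
            "G21",
        )

    items["_group"] = group
    wide = (
        items.pivot_table(index="participant_id", columns="_group", values="grams", aggfunc="sum")
        .reindex(columns=list(GROUP_IDS), fill_value=0.0)
        .fillna(0.0)
    )
    wide.columns.name = None
    return wide


def estimate_usual_intake(day1: pd.DataFrame, day2: pd.DataFrame) -> pd.DataFrame:
    """Usual intake per group by variance-component shrinkage of two recall days.

    Per food group, a one-way ANOVA on persons decomposes the variance of
    the two days into between-person (sigma2_b) and within-person (sigma2_w)
    components; the usual intake of person i is the individual two-day mean
    shrunk toward the population mean:

        usual_i = mu + (mean_i - mu) * sigma2_b / (sigma2_b + sigma2_w / 2)

    Negative between-person component estimates are truncated at zero, which
    collapses everyone to the population mean. With identical recall days
    (sigma2_w = 0) the individual means are returned unchanged.
    """
    if day1.shape != day2.shape:
        raise ValueError("day matrices must have matching dimensions")
    if not day1.index.equals(day2.index) or not day1.columns.equals(day2.columns):
        raise ValueError("day matrices must share participants and groups")
    n = len(day1)
    if n < 3:
        raise ValueError("need at least 3 participants")

    d1 = day1.to_numpy(dtype=float)
    d2 = day2.to_numpy(dtype=float)
    ind_mean = (d1 + d2) / 2.0
    pop_mean = ind_mean.mean(axis=0)

    # one-way ANOVA with d=2 observations per person
    msw = ((d1 - ind_mean) ** 2 + (d2 - ind_mean) ** 2).sum(axis=0) / n  # df = n per group
    msb = 2.0 * ind_mean.var(axis=0, ddof=1)
    sigma2_w = msw
    sigma2_b = np.maximum((msb - msw) / 2.0, 0.0)

    denom = sigma2_b + sigma2_w / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, sigma2_b / denom, 0.0)
    usual = pop_mean + (ind_mean - pop_mean) * shrink
    return pd.DataFrame(usual, index=day1.index, columns=day1.columns)


def energy_adjust(nutrient, energy):
    """Energy-adjust a nutrient intake by the regression residual method.

    OLS of nutrient on total energy (with intercept); the adjusted intake is
    the residual plus the sample mean of the nutrient, so it keeps the
    original mean, is exactly uncorrelated with energy in-sample, and may be
    negative.
    """
    y = np.asarray(nutrient, dtype=float)
    e = np.asarray(energy, dtype=float)
    if y.shape != e.shape or y.ndim != 1:
        raise ValueError("nutrient and energy must be equal-length vectors")
    if len(y) < 3:
        raise ValueError("need n >= 3")
    if np.var(e) == 0:
        raise ValueError("energy has zero variance")
    slope, intercept = np.polyfit(e, y, 1)
    resid = y - (intercept + slope * e)
    out = resid + y.mean()
    if isinstance(nutrient, pd.Series):
        return pd.Series(out, index=nutrient.index, name=nutrient.name)
    return out
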