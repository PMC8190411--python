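"""The 34-group food classification used throughout the package.

Food items (g/day) are aggregated into 34 food groups adapted from the USDA
Food and Nutrient Database for Dietary Studies (FNDDS) scheme, with two
nutrition-motivated splits:

* dairy products are split into low fat (G1) vs whole fat (G2);
* cereal/grain products are split into good fiber sources, strictly more
  than 2.5 g fiber per serving (G20), vs poor sources, 2.5 g or less (G21).

Each group carries a default median intake (g/day) and per-gram nutrient
densities (Zn in mg/g, PUFA in g/g, energy in kcal/g) used by the synthetic
cohort generator. The densities are order-of-magnitude food-composition
values (e.g. red meat ~4.5 mg Zn / 100 g, fortified breakfast cereals
~15 mg Zn / 100 g, vegetable oils ~35 g PUFA / 100 g); a single global
calibration was applied so that a default cohort reproduces population-scale
daily totals (Zn ~9-13 mg/day, PUFA ~15-21 g/day, energy consistent with
predicted total energy expenditure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_IDS",
    "GROUP_LABELS",
    "N_GROUPS",
    "default_group_table",
]

N_GROUPS = 34

# (id, label, median g/day, energy kcal/g, Zn mg/g, PUFA g/g)
_GROUPS = [
    ("G1", "Low fat dairy products", 120.0, 0.50, 0.0050, 0.001),
    ("G2", "Whole fat dairy products", 90.0, 0.80, 0.0040, 0.002),
    ("G3", "Red meat", 30.0, 2.50, 0.0450, 0.005),
    ("G4", "Poultry", 25.0, 1.90, 0.0120, 0.020),
    ("G5", "Organ meat", 2.0, 1.50, 0.0400, 0.010),
    ("G6", "Fish", 10.0, 1.50, 0.0080, 0.015),
    ("G7", "Meat, poultry, fish with nonmeat items", 80.0, 1.80, 0.0200, 0.010),
    ("G8", "Frozen/shelf-stable meals, soups, gravies with meat base", 40.0, 1.20, 0.0100, 0.008),
    ("G9", "Eggs", 15.0, 1.50, 0.0110, 0.020),
    ("G10", "Legumes", 20.0, 1.20, 0.0100, 0.005),
    ("G11", "Nuts and seeds", 3.0, 5.80, 0.0300, 0.200),
    ("G12", "Flour and dry mixes, yeast breads, rolls, quick bread", 70.0, 2.70, 0.0080, 0.015),
    ("G13", "Cakes, cookies, pies, pastries, bars", 25.0, 4.00, 0.0060, 0.060),
    ("G14", "Crackers and salty snacks from grain products", 8.0, 4.80, 0.0200, 0.050),
    ("G15", "Pancakes, waffles, French toast, other grain products", 10.0, 2.50, 0.0050, 0.020),
    ("G16", "Pastas, cooked cereals, rice", 60.0, 1.30, 0.0070, 0.005),
    ("G17", "Cereals, not cooked or non-specified as to cooked", 3.0, 3.80, 0.1500, 0.010),
    ("G18", "Grain mixtures, frozen plate meals, soups", 120.0, 1.50, 0.0090, 0.012),
    ("G19", "Meat substitutes, mainly cereal protein", 1.0, 2.00, 0.0150, 0.030),
    ("G20", "Cereals, grains good source of fiber", 120.0, 1.60, 0.0100, 0.015),
    ("G21", "Cereals, grains poor source of fiber", 80.0, 1.80, 0.0060, 0.010),
    ("G22", "Fruits", 150.0, 0.60, 0.0010, 0.001),
    ("G23", "Fruit juices", 100.0, 0.45, 0.0005, 0.001),
    ("G24", "Starchy vegetables", 35.0, 0.90, 0.0040, 0.010),
    ("G25", "Dark green vegetables", 15.0, 0.35, 0.0040, 0.002),
    ("G26", "Yellow and red vegetables", 25.0, 0.40, 0.0030, 0.002),
    ("G27", "Other vegetables", 60.0, 0.35, 0.0030, 0.002),
    ("G28", "Fats", 5.0, 7.00, 0.0010, 0.100),
    ("G29", "Oils", 8.0, 8.80, 0.0005, 0.350),
    ("G30", "Salad dressing", 6.0, 4.00, 0.0020, 0.300),
    ("G31", "Sugars and sweets", 20.0, 3.50, 0.0020, 0.005),
    ("G32", "Nonalcoholic beverages", 900.0, 0.35, 0.0003, 0.0005),
    ("G33", "Alcoholic beverages", 100.0, 0.70, 0.0003, 0.0002),
    ("G34", "Formulated nutrition beverages", 15.0, 0.80, 0.0100, 0.005),
]

GROUP_IDS: tuple[str, ...] = tuple(g[0] for g in _GROUPS)
GROUP_LABELS: dict[str, str] = {g[0]: g[1] for g in _GROUPS}

# Global density calibration so that a default pTEE-balanced cohort lands on
# population-scale Zn/PUFA totals (see module docstring).
_ZN_SCALE = 0.77
_PUFA_SCALE = 0.84


def default_group_table() -> pd.DataFrame:
    """Return the default 34-group table.

    Columns: ``group_id`` (index), ``label``, ``median_g_day``,
    ``energy_kcal_g``, ``zn_mg_g``, ``pufa_g_g``.
    """
    tbl = pd.DataFrame(
        _GROUPS,
        columns=["group_id", "label", "median_g_day", "energy_kcal_g", "zn_mg_g", "pufa_g_g"],
    ).set_index("group_id")
    tbl["zn_mg_g"] = tbl["zn_mg_g"] * _ZN_SCALE
    tbl["pufa_g_g"] = tbl["pufa_g_g"] * _PUFA_SCALE
    return tbl


def as_group_vector(mapping: dict[str, float], default: float = 0.0) -> np.ndarray:
    """Expand a ``{group_id: value}`` dict into a length-34 vector in G1..G34 order."""
    unknown = set(mapping) - set(GROUP_IDS)
    if unknown:
        raise ValueError(f"unknown group ids: {sorted(unknown)}")
    return np.array([mapping.get(g, default) for g in GROUP_IDS], dtype=float)
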