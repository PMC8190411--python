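"""Best-effort ingestion of real NHANES 2011-2012 release files.

The analysis targets the public NHANES 2011-2012 files (SAS XPORT format):

* ``DEMO_G.XPT``  — demographics (RIDAGEYR, RIAGENDR, RIDRETH3, DMDEDUC2,
  INDFMPIR, RIDEXPRG);
* ``BMX_G.XPT``   — body measures (BMXWT, BMXHT);
* ``DR1TOT_G.XPT`` / ``DR2TOT_G.XPT`` — day-1/day-2 dietary totals
  (DR1TKCAL/DR2TKCAL, DR1TZINC/DR2TZINC, DR1TPFAT/DR2TPFAT);
* ``FAS_G.XPT``   — serum fatty acids (LBXLA, LBXDGL);
* ``CUSEZN_G.XPT`` — serum zinc (LBXSZN);
* ``PAQ_G.XPT``   — physical activity (PAQ605, PAQ650).

These files must be downloaded by the user; this module only maps their
variables onto the package's internal participant schema. Food-item level
files (DR1IFF_G/DR2IFF_G) additionally require an FNDDS food-code mapping
(see :func:`dietrrr.exposures.load_mapping`); a template accompanies the
toy mapping shipped with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["NHANES_VARIABLE_MAP", "read_xpt", "harmonize_nhanes"]

#: NHANES variable name -> internal schema column
NHANES_VARIABLE_MAP = {
    "SEQN": "participant_id",
    "RIDAGEYR": "age",
    "RIDRETH3": "race",
    "DMDEDUC2": "education",
    "INDFMPIR": "pir",
    "RIDEXPRG": "pregnant",
    "BMXWT": "weight_kg",
    "BMXHT": "height_cm",
    "DR1TKCAL": "energy_kcal_day1",
    "DR2TKCAL": "energy_kcal_day2",
    "DR1TZINC": "zn_intake_day1",
    "DR2TZINC": "zn_intake_day2",
    "DR1TPFAT": "pufa_intake_day1",
    "DR2TPFAT": "pufa_intake_day2",
    "LBXLA": "serum_la",
    "LBXDGL": "serum_dgla",
    "LBXSZN": "serum_zn",
    "PAQ605": "vigorous_work",
    "PAQ650": "vigorous_rec",
}


def read_xpt(path) -> pd.DataFrame:
    """Read one SAS XPORT (.xpt) file into a DataFrame."""
    return pd.read_sas(path, format="xport")


def harmonize_nhanes(merged: pd.DataFrame) -> pd.DataFrame:
    """Rename and recode a merged NHANES table to the internal schema.

    Expects a frame already merged on SEQN across the release files. Sex is
    recoded from RIAGENDR (1 = male, 2 = female) to 0/1; pregnancy from
    RIDEXPRG (1 = pregnant); the yes/no activity codes (1 = yes, 2 = no,
    7/9 = refused/unknown) to 1/0 with refused/unknown set to missing.
    Two-day nutrient intakes are averaged into ``zn_intake_mg`` and
    ``pufa_intake_g``.
    """
    df = merged.rename(columns={k: v for k, v in NHANES_VARIABLE_MAP.items() if k in merged.columns}).copy()
    if "RIAGENDR" in df.columns:
        df["sex"] = (df["RIAGENDR"] == 2).astype(int)
        df = df.drop(columns="RIAGENDR")
    if "pregnant" in df.columns:
        df["pregnant"] = (df["pregnant"] == 1).astype(int)
    for col in ("vigorous_work", "vigorous_rec"):
        if col in df.columns:
            df[col] = df[col].map({1: 1, 2: 0}).astype(float)  # 7/9 -> NaN
    for nutrient, out in (("zn_intake", "zn_intake_mg"), ("pufa_intake", "pufa_intake_g")):
        d1, d2 = f"{nutrient}_day1", f"{nutrient}_day2"
        if d1 in df.columns and d2 in df.columns:
            df[out] = df[[d1, d2]].mean(axis=1)
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    return df
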