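"""Lipid phenotype derivation and transforms.

Implements the clinical preprocessing applied to the lipid panel before
any association testing: unit conversion to mmol/L, LDL-C derivation by
the Friedewald formula (invalid above the triglyceride cutoff), and the
natural-log transform of triglycerides.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mg/dL -> mmol/L divisors (standard clinical conversion factors).
CHOLESTEROL_MGDL_PER_MMOL = 38.67
TRIGLYCERIDE_MGDL_PER_MMOL = 88.57

#: Friedewald k: LDL = TC - HDL - k * TG.
FRIEDEWALD_K = {"mmol/L": 0.45, "mg/dL": 0.20}

#: TG above this invalidates derived LDL (4.51 mmol/L == 400 mg/dL).
TG_CUTOFF = {"mmol/L": 4.51, "mg/dL": 400.0}

LIPID_COLUMNS = ["tc", "hdl", "ldl", "tg"]


def convert_units(value, analyte: str, from_unit: str):
    """Convert a lipid concentration to mmol/L.

    Parameters
    ----------
    value
        Scalar or array concentration, nonnegative (NaN passes through).
    analyte
        ``"cholesterol"`` (TC/HDL/LDL) or ``"triglyceride"``.
    from_unit
        ``"mg/dL"`` or ``"mmol/L"``; mmol/L input is returned unchanged.
    """
    if analyte not in ("cholesterol", "triglyceride"):
        raise ValueError(f"unknown analyte: {analyte!r}")
    if from_unit not in ("mg/dL", "mmol/L"):
        raise ValueError(f"unknown unit: {from_unit!r}")
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("concentrations must be nonnegative")
    if from_unit == "mmol/L":
        out = arr
    elif analyte == "cholesterol":
        out = arr / CHOLESTEROL_MGDL_PER_MMOL
    else:
        out = arr / TRIGLYCERIDE_MGDL_PER_MMOL
    return out.item() if np.isscalar(value) else out


def friedewald_ldl(tc, hdl, tg, unit: str = "mmol/L"):
    """Derive LDL-C as TC - HDL - k*TG, missing above the TG cutoff.

    k is 0.45 in mmol/L and 0.20 in mg/dL.  Returns NaN where any input
    is missing or TG exceeds 4.51 mmol/L (400 mg/dL): the formula's
    fixed TG:VLDL ratio breaks down in hypertriglyceridemia.
    """
    if unit not in FRIEDEWALD_K:
        raise ValueError(f"unknown unit: {unit!r}")
    tc_a, hdl_a, tg_a = (np.asarray(v, dtype=float) for v in (tc, hdl, tg))
    k = FRIEDEWALD_K[unit]
    with np.errstate(invalid="ignore"):
        ldl = tc_a - hdl_a - k * tg_a
        ldl = np.where(tg_a > TG_CUTOFF[unit], np.nan, ldl)
    return ldl.item() if np.isscalar(tc) else ldl


def log_transform_tg(tg):
    """Natural log of TG; missing propagates; nonpositive TG -> missing.

    A zero or negative triglyceride measurement is unusable; it is
    logged as a warning and mapped to missing rather than raising.
    """
    arr = np.asarray(tg, dtype=float)
    nonpos = ~np.isnan(arr) & (arr <= 0)
    if np.any(nonpos):
        logger.warning(
            "%d nonpositive TG value(s) set to missing before log transform",
            int(np.sum(nonpos)),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nonpos, np.nan, np.log(arr))
    return out.item() if np.isscalar(tg) else out


def prepare_lipid_panel(panel: pd.DataFrame, unit: str = "mmol/L") -> pd.DataFrame:
    """Full phenotype preparation for a lipid panel table.

    Expects columns ``sample_id, tc, hdl, tg`` and optionally ``ldl``.
    Converts mg/dL input to mmol/L, fills LDL from Friedewald's formula
    where it was not directly measured (the TG-cutoff missingness rule
    applies only to derived values), and appends ``log_tg``.
    """
    out = panel.copy()
    if unit == "mg/dL":
        for col in ("tc", "hdl", "ldl"):
            if col in out:
                out[col] = convert_units(
                    out[col].to_numpy(), "cholesterol", "mg/dL"
                )
        out["tg"] = convert_units(out["tg"].to_numpy(), "triglyceride", "mg/dL")
    elif unit != "mmol/L":
        raise ValueError(f"unknown unit: {unit!r}")

    derived = friedewald_ldl(
        out["tc"].to_numpy(), out["hdl"].to_numpy(), out["tg"].to_numpy()
    )
    if "ldl" in out:
        measured = out["ldl"].to_numpy(dtype=float)
        out["ldl"] = np.where(np.isnan(measured), derived, measured)
    else:
        out["ldl"] = derived
    out["log_tg"] = log_transform_tg(out["tg"].to_numpy())
    return out
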