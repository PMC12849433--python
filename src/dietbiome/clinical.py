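"""Derived clinical quantities and the continuous metabolic syndrome score.

The cMetS aggregates five markers — waist circumference, mean arterial
pressure, HDL cholesterol (sign-flipped), triglycerides and fasting
glucose — by (1) regressing each marker on age and sex by OLS,
(2) standardizing the residuals to mean 0 / SD 1, and (3) summing the
five standardized residual columns. Because each component is z-scored,
the score is invariant to affine unit changes of any input marker, and
higher values mean a less favorable metabolic profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("dietbiome.clinical")

__all__ = ["mean_arterial_pressure", "homa_ir", "age_sex_residual_z",
           "cmets"]


def mean_arterial_pressure(sbp, dbp):
    """MAP = DBP + (SBP − DBP)/3 (mmHg)."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp < dbp):
        raise ValueError("systolic pressure must be >= diastolic pressure")
    return dbp + (sbp - dbp) / 3.0


def homa_ir(glucose_mmol, insulin_uU_ml):
    """HOMA-IR = fasting glucose [mmol/L] x fasting insulin [µU/mL] / 22.5."""
    glucose = np.asarray(glucose_mmol, dtype=float)
    insulin = np.asarray(insulin_uU_ml, dtype=float)
    if np.any(glucose <= 0) or np.any(insulin <= 0):
        raise ValueError("glucose and insulin must be > 0")
    return glucose * insulin / 22.5


def age_sex_residual_z(values, age, sex, ddof_model: bool = True):
    """Age- and sex-adjusted standardized residuals of a marker.

    OLS of marker on intercept + age + sex indicator; residuals divided
    by the residual SD (n − p denominator by default, population SD if
    ``ddof_model=False``). Result has mean 0 and SD 1 over the sample.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "OUS":
        sex = (sex == sex[0]).astype(float)  # binary indicator
    sex = sex.astype(float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(y) == 0:
        raise ValueError("marker has zero variance")
    X = np.column_stack([np.ones(n), age, sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("age/sex design is collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = (n - X.shape[1]) if ddof_model else n
    sd = np.sqrt(resid @ resid / dof)
    if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        raise ValueError("zero residual variance (marker is an exact "
                         "function of age/sex)")
    z = resid / sd
    return z / z.std(ddof=0)  # exact unit SD regardless of denominator


def cmets(markers: pd.DataFrame, ddof_model: bool = True) -> pd.DataFrame:
    """Continuous metabolic syndrome score with audit columns.

    Expects columns ``subject_id, age, sex, wc_cm, sbp_mmhg, dbp_mmhg,
    hdl_mmol, tg_mmol, glucose_mmol``. Subjects with any missing
    component are excluded (logged). Returns subject_id, the five
    z-residual columns (HDL negated) and their sum ``cmets``.
    """
    needed = ["subject_id", "age", "sex", "wc_cm", "sbp_mmhg", "dbp_mmhg",
              "hdl_mmol", "tg_mmol", "glucose_mmol"]
    df = markers[needed].copy()
    complete = df.notna().all(axis=1)
    if not complete.all():
        logger.warning("cmets: excluding %d subject(s) with missing "
                       "components", int((~complete).sum()))
        df = df[complete]
    df = df.reset_index(drop=True)

    map_ = mean_arterial_pressure(df["sbp_mmhg"], df["dbp_mmhg"])
    comp = {
        "wc_z": df["wc_cm"].to_numpy(),
        "map_z": map_,
        "hdl_z_neg": df["hdl_mmol"].to_numpy(),
        "tg_z": df["tg_mmol"].to_numpy(),
        "glu_z": df["glucose_mmol"].to_numpy(),
    }
    out = pd.DataFrame({"subject_id": df["subject_id"]})
    for name, vals in comp.items():
        z = age_sex_residual_z(vals, df["age"], df["sex"],
                               ddof_model=ddof_model)
        out[name] = -z if name == "hdl_z_neg" else z
    out["cmets"] = (out[["wc_z", "map_z", "hdl_z_neg", "tg_z", "glu_z"]]
                    .sum(axis=1))
    return out
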