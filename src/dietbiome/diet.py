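"""Diet-quality indices: HEI-MON, PHEI-MON and aMED.

HEI-MON and PHEI-MON are threshold-table-driven: every component is
scored 0–100 against anchor intakes (adequacy, moderation or
range-optimum shape; linear between anchors) and the index is the mean of
its component scores. Where the threshold table marks an index as
kcal-standardized, component intakes are divided by ``energy/1000``
before comparison, which makes the score invariant to proportional
rescaling of intakes and energy together.

aMED is median-based: seven adequacy components (vegetables, legumes,
fruits, nuts, whole grains, fish, MUFA/SFA ratio) earn one point iff the
subject's intake strictly exceeds the pooled sample median; red/processed
meat earns a point iff strictly below its median; alcohol earns a point
below a sex-specific cutoff (default < 10 g/day for women, < 25 g/day for
men). Ties at a median score 0. Range 0–9, integer.

FFQ records are converted to daily gram intakes as frequency x portion /
28 days, with a configurable allocation map for mixed dishes (by default
50% of a burger/doner portion counts as meat).
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dietbiome.diet")

__all__ = [
    "load_thresholds",
    "ffq_daily_intake",
    "score_component",
    "score_index",
    "score_hei_mon",
    "score_phei_mon",
    "cohort_medians",
    "score_amed",
    "score_all",
    "DEFAULT_ALLOCATION",
]

#: Mixed-dish allocation: FFQ item -> {food group: fraction of portion}.
DEFAULT_ALLOCATION = {
    "burger": {"red_processed_meat": 0.5, "cereals": 0.5},
    "doner": {"red_processed_meat": 0.5, "cereals": 0.5},
}

AMED_ADEQUACY = ["vegetables", "legumes", "fruits", "nuts", "whole_grains",
                 "fish", "mufa_sfa_ratio"]


def load_thresholds(path=None) -> dict:
    """Load the component threshold table (packaged default fixture)."""
    if path is None:
        ref = resources.files("dietbiome.data") / "diet_thresholds.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def ffq_daily_intake(ffq: pd.DataFrame, item_map: dict[str, str],
                     allocation: dict | None = None) -> pd.DataFrame:
    """Convert FFQ rows to per-subject food-group intakes in g/day.

    Parameters
    ----------
    ffq : DataFrame with columns ``subject_id``, ``item``,
        ``frequency_28d`` (consumption events per 4 weeks, >= 0) and
        ``portion_g`` (> 0).
    item_map : FFQ item -> food-group name. Items absent from both the
        map and the allocation table are excluded with a logged warning.
    allocation : optional mixed-dish map item -> {group: fraction};
        defaults to :data:`DEFAULT_ALLOCATION`.
    """
    allocation = DEFAULT_ALLOCATION if allocation is None else allocation
    if (ffq["frequency_28d"] < 0).any():
        raise ValueError("frequency_28d must be >= 0")
    if (ffq["portion_g"] <= 0).any():
        raise ValueError("portion_g must be > 0")

    rows = []
    for rec in ffq.itertuples(index=False):
        g_day = rec.frequency_28d * rec.portion_g / 28.0
        if rec.item in allocation:
            for group, frac in allocation[rec.item].items():
                rows.append((rec.subject_id, group, frac * g_day))
        elif rec.item in item_map:
            rows.append((rec.subject_id, item_map[rec.item], g_day))
        else:
            logger.warning("FFQ item %r has no food-group mapping; excluded",
                           rec.item)
    long = pd.DataFrame(rows, columns=["subject_id", "group", "g_day"])
    wide = (long.pivot_table(index="subject_id", columns="group",
                             values="g_day", aggfunc="sum", fill_value=0.0)
            .rename_axis(columns=None).reset_index())
    return wide


def score_component(intake: float, entry: dict) -> float:
    """Score a single intake 0–100 against one threshold-table entry."""
    if np.isnan(intake):
        return np.nan
    d = entry["direction"]
    if d == "adequacy":
        lo, hi = entry["zero"], entry["full"]
        return 100.0 * np.clip((intake - lo) / (hi - lo), 0.0, 1.0)
    if d == "moderation":
        best, worst = entry["full"], entry["zero"]
        if intake <= best:
            return 100.0
        return 100.0 * np.clip((worst - intake) / (worst - best), 0.0, 1.0)
    if d == "optimum":
        zl, ol = entry["zero_low"], entry["opt_low"]
        oh, zh = entry["opt_high"], entry["zero_high"]
        if ol <= intake <= oh:
            return 100.0
        if intake < ol:
            return 100.0 * np.clip((intake - zl) / (ol - zl), 0.0, 1.0)
        return 100.0 * np.clip((zh - intake) / (zh - oh), 0.0, 1.0)
    raise ValueError(f"unknown scoring direction {d!r}")


def _component_intake(intakes: pd.DataFrame, entry: dict,
                      per_1000: bool) -> pd.Series:
    total = sum(intakes[g] for g in entry["groups"])
    if per_1000:
        total = total / (intakes["energy_kcal"] / 1000.0)
    return total


def score_index(intakes: pd.DataFrame, thresholds: dict, index: str,
                missing: str = "exclude") -> pd.Series:
    """Mean of component scores for one table-driven index.

    ``missing='exclude'`` yields NaN (subject excluded, logged) if any
    component cannot be scored; ``missing='impute'`` averages the
    remaining components instead.
    """
    cfg = thresholds[index]
    per_1000 = bool(cfg.get("per_1000_kcal", False))
    comp_scores = {}
    for name, entry in cfg["components"].items():
        vals = _component_intake(intakes, entry, per_1000)
        comp_scores[name] = vals.map(lambda x: score_component(x, entry))
    scores = pd.DataFrame(comp_scores, index=intakes.index)
    if missing == "impute":
        out = scores.mean(axis=1)
    else:
        out = scores.mean(axis=1)
        bad = scores.isna().any(axis=1)
        if bad.any():
            logger.warning("%s: %d subject(s) with unscorable components "
                           "excluded", index, int(bad.sum()))
            out[bad] = np.nan
    out.name = index
    return out


def score_hei_mon(intakes: pd.DataFrame, thresholds: dict | None = None,
                  **kw) -> pd.Series:
    thresholds = load_thresholds() if thresholds is None else thresholds
    return score_index(intakes, thresholds, "hei_mon", **kw)


def score_phei_mon(intakes: pd.DataFrame, thresholds: dict | None = None,
                   **kw) -> pd.Series:
    thresholds = load_thresholds() if thresholds is None else thresholds
    return score_index(intakes, thresholds, "phei_mon", **kw)


def _amed_values(intakes: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    cfg = thresholds["amed"]
    vals = {}
    for comp, groups in cfg["adequacy_components"].items():
        vals[comp] = sum(intakes[g] for g in groups)
    if (intakes["sfa_g"] <= 0).any():
        raise ValueError("sfa_g must be > 0 for the MUFA/SFA ratio")
    vals["mufa_sfa_ratio"] = intakes["mufa_g"] / intakes["sfa_g"]
    (meat_name, meat_groups), = cfg["meat_component"].items()
    vals[meat_name] = sum(intakes[g] for g in meat_groups)
    return pd.DataFrame(vals, index=intakes.index)


def cohort_medians(intakes: pd.DataFrame,
                   thresholds: dict | None = None) -> pd.Series:
    """Pooled (not sex-stratified) per-component medians, incl. MUFA/SFA."""
    thresholds = load_thresholds() if thresholds is None else thresholds
    if len(intakes) < 2:
        raise ValueError("need at least 2 subjects for cohort medians")
    vals = _amed_values(intakes, thresholds)
    for col in vals:
        if vals[col].isna().all():
            raise ValueError(f"aMED component {col!r} is entirely missing")
    return vals.median(axis=0)


def score_amed(intakes: pd.DataFrame, sex: pd.Series,
               medians: pd.Series | None = None,
               thresholds: dict | None = None) -> pd.Series:
    """Nine-component aMED score (integer 0–9) against cohort medians."""
    thresholds = load_thresholds() if thresholds is None else thresholds
    if medians is None:
        medians = cohort_medians(intakes, thresholds)
    cfg = thresholds["amed"]
    vals = _amed_values(intakes, thresholds)

    points = pd.DataFrame(index=intakes.index)
    for comp in AMED_ADEQUACY:
        points[comp] = (vals[comp] > medians[comp]).astype(int)
    (meat_name, _), = cfg["meat_component"].items()
    points[meat_name] = (vals[meat_name] < medians[meat_name]).astype(int)
    cut = sex.map(cfg["alcohol_cutoffs_g_day"])
    points["alcohol"] = (intakes["alcohol_g"].values
                         < cut.values).astype(int)
    out = points.sum(axis=1).astype(int)
    out.name = "amed"
    return out


def score_all(intakes: pd.DataFrame, sex: pd.Series,
              thresholds: dict | None = None) -> pd.DataFrame:
    """subject_id + hei_mon + phei_mon + amed for a cohort intake table."""
    thresholds = load_thresholds() if thresholds is None else thresholds
    out = pd.DataFrame({"subject_id": intakes["subject_id"]})
    out["hei_mon"] = score_hei_mon(intakes, thresholds).values
    out["phei_mon"] = score_phei_mon(intakes, thresholds).values
    out["amed"] = score_amed(intakes, sex, thresholds=thresholds).values
    return out
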