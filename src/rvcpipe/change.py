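"""Relative volume change at three aggregation levels.

Volumes are normalized to each athlete's own baseline session (CSA: Pre,
NCA: Test), giving dimensionless fractional changes:

* rRVC — per ROI: ``(Vol_k - Vol_base) / Vol_base``.
* rTVC — per tissue: voxel-count-weighted sum ``sum_i c_i * rRVC_i`` over
  the ROIs of one tissue class (GM, WM, CSF, dCSF separately).
* rBVC — whole brain: fixed-weight sum ``w_GM*rTVC_GM + w_WM*rTVC_WM +
  w_CSF*rTVC_CSF`` (dCSF excluded; the three weights cover the brain).

All values are fractions internally; reporting layers render percent.
Baseline sessions never appear as follow-up rows.  Athletes missing a
follow-up session simply lack rows for it — no imputation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .parcellation import ParcellationSpec
from .volumes import BASELINE_BY_GROUP, validate_volume_table


def compute_rrvc(
    volumes: pd.DataFrame,
    baseline_by_group: Mapping[str, str] = BASELINE_BY_GROUP,
) -> pd.DataFrame:
    """ROI-level relative volume change against each athlete's baseline.

    Returns a long frame with columns athlete_id, group, sex, sport,
    session, roi_id, rrvc — one row per follow-up session of each
    (athlete, ROI).  Every follow-up (athlete, ROI) must have a baseline
    record; a missing one is an error naming the athlete and ROI.
    """
    validate_volume_table(volumes)
    vols = volumes.copy()
    vols["baseline_session"] = vols["group"].map(dict(baseline_by_group))
    if vols["baseline_session"].isna().any():
        bad = vols.loc[vols["baseline_session"].isna(), "group"].iloc[0]
        raise ValueError(f"no baseline session configured for group {bad!r}")

    base = vols[vols["session"] == vols["baseline_session"]]
    base = base.set_index(["athlete_id", "roi_id"])["volume_mm3"]
    follow = vols[vols["session"] != vols["baseline_session"]].copy()

    key = pd.MultiIndex.from_frame(follow[["athlete_id", "roi_id"]])
    missing = ~key.isin(base.index)
    if missing.any():
        a, r = follow.loc[missing, ["athlete_id", "roi_id"]].iloc[0]
        raise ValueError(f"missing baseline volume for athlete {a}, ROI {r}")
    baseline_vol = base.loc[key].to_numpy()
    if (baseline_vol == 0).any():
        raise ValueError("baseline volume of 0 encountered")
    follow["rrvc"] = (follow["volume_mm3"].to_numpy() - baseline_vol) / baseline_vol
    out = follow[["athlete_id", "group", "sex", "sport", "session", "roi_id", "rrvc"]]
    return out.reset_index(drop=True)


def compute_rtvc(rrvc: pd.DataFrame, parcellation: ParcellationSpec) -> pd.DataFrame:
    """Tissue-level change: c_i-weighted sum of rRVC within each tissue.

    Weights come from the parcellation's atlas voxel counts, not from
    subject volumes.  Every ROI in ``rrvc`` must belong to the
    parcellation, and each (athlete, session) must carry the complete ROI
    set of every tissue it contributes to (the weights sum to 1).
    """
    parc = parcellation.frame[["roi_id", "tissue", "c_i"]]
    unknown = set(rrvc["roi_id"]) - set(parc["roi_id"])
    if unknown:
        raise ValueError(f"rRVC contains ROIs absent from parcellation: {sorted(unknown)}")
    merged = rrvc.merge(parc, on="roi_id", how="left")
    merged["weighted"] = merged["c_i"] * merged["rrvc"]
    grouped = merged.groupby(
        ["athlete_id", "group", "sex", "sport", "session", "tissue"], as_index=False
    ).agg(rtvc=("weighted", "sum"), weight_sum=("c_i", "sum"))
    off = np.abs(grouped["weight_sum"] - 1.0) > 1e-9
    if off.any():
        bad = grouped.loc[off].iloc[0]
        raise ValueError(
            f"incomplete ROI set for tissue {bad['tissue']} of athlete "
            f"{bad['athlete_id']} at session {bad['session']} "
            f"(weights sum to {bad['weight_sum']:.6f})"
        )
    return grouped.drop(columns="weight_sum")


def compute_rbvc(rtvc: pd.DataFrame, parcellation: ParcellationSpec) -> pd.DataFrame:
    """Whole-brain change: fixed-weight sum of GM/WM/CSF rTVC.

    Uses the parcellation's tissue weights ``w_X``; dCSF is excluded.
    Each (athlete, session) must have all three tissues present.
    """
    weights = parcellation.tissue_weights
    needed = [t for t in ("GM", "WM", "CSF") if t in weights] or ["GM", "WM", "CSF"]
    wide = rtvc.pivot_table(
        index=["athlete_id", "group", "sex", "sport", "session"],
        columns="tissue",
        values="rtvc",
    )
    for tissue in needed:
        if tissue not in wide.columns or wide[tissue].isna().any():
            raise ValueError(f"missing rTVC for tissue {tissue} in at least one athlete-session")
    rbvc = sum(weights[t] * wide[t] for t in needed)
    out = rbvc.rename("rbvc").reset_index()
    return out
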