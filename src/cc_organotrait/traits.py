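"""Derived phenotypes: glucose-clearance AUC, body-weight change, percent
organ weights, and group-level delta-organ/delta-BW contrasts.

The trait table is a tidy pandas DataFrame, one row per terminal mouse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cc_organotrait.simulate import ORGANS, GlucoseCurve, MouseRecord

__all__ = [
    "TRAIT_COLUMNS",
    "GroupDeltaRatio",
    "compute_auc",
    "compute_delta_bw",
    "percent_organ_weight",
    "derive_traits",
    "group_delta_ratio",
]

TRAIT_COLUMNS = (
    "mouse_id", "line", "sex", "diet",
    "bw0_g", "bw12_g", "delta_bw_g",
    "auc_wk6", "auc_wk12",
    "liver_g", "spleen_g", "heart_g",
    "pct_liver", "pct_spleen", "pct_heart",
)

_START_WEEK = 0
_END_WEEK = 12
_AUC_WINDOW = (0.0, 180.0)


def compute_auc(curve: GlucoseCurve) -> float:
    """Trapezoid-rule area under the glucose curve, min*mg/dL.

    Sums, over every adjacent pair of readings, (time difference) x
    (mean of the two glucose levels) — i.e. the full piecewise-linear
    integral from the first to the last timepoint.
    """
    t = np.asarray(curve.t_min, dtype=float)
    g = np.asarray(curve.glucose_mg_dl, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 readings")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    return float(np.sum(np.diff(t) * (g[:-1] + g[1:]) / 2.0))


def compute_delta_bw(record: MouseRecord) -> float:
    """Body-weight change over the challenge: BW at week 12 minus week 0."""
    try:
        return record.bw_g[_END_WEEK] - record.bw_g[_START_WEEK]
    except KeyError as exc:
        raise ValueError(
            f"{record.id}: missing body weight at week {exc.args[0]}"
        ) from None


def percent_organ_weight(organ_g: float, final_bw_g: float) -> float:
    """Organ weight as a percentage of final body weight."""
    if organ_g <= 0 or final_bw_g <= 0:
        raise ValueError("organ and body weight must be positive")
    return organ_g / final_bw_g * 100.0


def _auc_at_week(record: MouseRecord, week: int) -> float:
    if week not in record.ipgtt:
        raise ValueError(f"{record.id}: no IPGTT at week {week}")
    curve = record.ipgtt[week]
    lo, hi = _AUC_WINDOW
    if curve.t_min[0] != lo or curve.t_min[-1] != hi:
        raise ValueError(
            f"{record.id}: IPGTT at week {week} does not span "
            f"{lo:g}-{hi:g} min (got {curve.t_min[0]:g}-{curve.t_min[-1]:g})"
        )
    return compute_auc(curve)


def derive_traits(records: list[MouseRecord]) -> pd.DataFrame:
    """Build the per-mouse trait table from raw records.

    Every record must carry body weights at weeks 0 and 12, IPGTT curves
    spanning 0-180 min at weeks 6 and 12, and the three terminal organ
    weights; errors name the offending mouse.
    """
    rows = []
    for rec in records:
        try:
            bw0 = rec.bw_g.get(_START_WEEK)
            bw12 = rec.bw_g.get(_END_WEEK)
            if bw0 is None or bw12 is None:
                raise ValueError(f"{rec.id}: missing body weight at week 0 or 12")
            missing = [o for o in ORGANS if o not in rec.organ_wt_g]
            if missing:
                raise ValueError(f"{rec.id}: missing organ weight(s) {missing}")
            row = {
                "mouse_id": rec.id,
                "line": rec.line,
                "sex": rec.sex,
                "diet": rec.diet,
                "bw0_g": bw0,
                "bw12_g": bw12,
                "delta_bw_g": compute_delta_bw(rec),
                "auc_wk6": _auc_at_week(rec, 6),
                "auc_wk12": _auc_at_week(rec, 12),
            }
            for organ in ORGANS:
                row[f"{organ}_g"] = rec.organ_wt_g[organ]
                row[f"pct_{organ}"] = percent_organ_weight(rec.organ_wt_g[organ], bw12)
            rows.append(row)
        except ValueError:
            raise
    return pd.DataFrame(rows, columns=list(TRAIT_COLUMNS))


@dataclass(frozen=True)
class GroupDeltaRatio:
    """Per (line, sex) diet contrast: (mean organ HFD - mean organ CHD)
    over (mean BW HFD - mean BW CHD); ``undefined`` flags a zero BW
    denominator instead of returning an infinity."""

    line: str
    sex: str
    organ: str
    mean_organ_hfd: float
    mean_organ_chd: float
    mean_bw_hfd: float
    mean_bw_chd: float
    ratio: float
    undefined: bool = False


def group_delta_ratio(
    table: pd.DataFrame, line: str, sex: str, organ: str
) -> GroupDeltaRatio:
    """Diet contrast of group means for one (line, sex) cell and organ.

    BW means are final body weights (week 12).  Both diet groups must be
    non-empty; a zero BW-mean difference yields a flagged-undefined ratio.
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    cell = table[(table["line"] == line) & (table["sex"] == sex)]
    hfd = cell[cell["diet"] == "HFD"]
    chd = cell[cell["diet"] == "CHD"]
    if hfd.empty or chd.empty:
        raise ValueError(
            f"({line}, {sex}): both diet groups must be non-empty "
            f"(HFD n={len(hfd)}, CHD n={len(chd)})"
        )
    organ_col = f"{organ}_g"
    mo_h = float(hfd[organ_col].mean())
    mo_c = float(chd[organ_col].mean())
    mb_h = float(hfd["bw12_g"].mean())
    mb_c = float(chd["bw12_g"].mean())
    denom = mb_h - mb_c
    if denom == 0:
        return GroupDeltaRatio(line, sex, organ, mo_h, mo_c, mb_h, mb_c,
                               float("nan"), undefined=True)
    return GroupDeltaRatio(line, sex, organ, mo_h, mo_c, mb_h, mb_c,
                           (mo_h - mo_c) / denom)
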