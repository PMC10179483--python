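"""Broad-sense heritability and genetic coefficient of variation from
between-line variation.

The estimator is method-of-moments on the one-way random-effects model:
with ``a`` lines, ``N`` animals and unbalanced effective replication
``n0 = (N - sum(n_i^2)/N)/(a-1)``,

    Ve = MSW,   Vg = max(0, (MSB - MSW)/n0),   H2 = Vg/(Vg+Ve).

CVg is the sample standard deviation among per-line means divided by the
overall animal-level mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnovaResult",
    "VarianceComponents",
    "GeneticCV",
    "one_way_anova",
    "variance_components",
    "heritability",
    "genetic_cv",
    "heritability_table",
    "HERITABILITY_TRAITS",
]


@dataclass(frozen=True)
class AnovaResult:
    """Mean squares and design constants of a one-way line ANOVA."""

    msb: float  # between-line mean square, SSB/(a-1)
    msw: float  # within-line mean square, SSW/(N-a)
    a: int  # number of lines
    n_total: int
    n0: float  # unbalanced effective per-line sample size


@dataclass(frozen=True)
class VarianceComponents:
    trait: str
    sex: str
    diet: str
    a: int
    n_total: int
    n0: float
    msb: float
    msw: float
    vg: float
    ve: float
    h2: float
    flags: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.h2) and not (0.0 <= self.h2 <= 1.0):
            raise ValueError("H2 must lie in [0, 1]")


@dataclass(frozen=True)
class GeneticCV:
    trait: str
    sex: str
    diet: str
    sd_lines: float  # sample SD among per-line means
    overall_mean: float  # mean over all animals in the stratum
    cvg: float
    flags: str = ""


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA of *groups* (line label -> trait values).

    Requires at least 2 lines and at least one line with >= 2 replicates
    (otherwise the within-line variance is inestimable).
    """
    keys = [k for k in groups if len(groups[k]) > 0]
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    a = len(arrays)
    if a < 2:
        raise ValueError("ANOVA needs at least 2 non-empty lines")
    sizes = np.array([arr.size for arr in arrays])
    n_total = int(sizes.sum())
    if n_total == a:
        raise ValueError("all lines are singletons: within-line variance inestimable")
    grand = float(np.concatenate(arrays).mean())
    means = np.array([arr.mean() for arr in arrays])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((arr - arr.mean()) ** 2) for arr in arrays))
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    n0 = (n_total - float(np.sum(sizes**2)) / n_total) / (a - 1)
    return AnovaResult(msb=msb, msw=msw, a=a, n_total=n_total, n0=n0)


def variance_components(msb: float, msw: float, n0: float) -> tuple[float, float]:
    """Method-of-moments (Vg, Ve) from the ANOVA mean squares.

    Negative between-line estimates are clamped to 0.
    """
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    ve = msw
    vg = max(0.0, (msb - msw) / n0)
    return vg, ve


def heritability(vg: float, ve: float) -> float:
    """Broad-sense heritability Vg/(Vg+Ve); NaN when both components are 0."""
    if vg < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    total = vg + ve
    if total == 0:
        return float("nan")
    return vg / total


def genetic_cv(line_means: Sequence[float], overall_mean: float) -> float:
    """Sample SD (n-1 denominator) of per-line means over the overall
    animal-level mean; NaN when the overall mean is 0."""
    means = np.asarray(line_means, dtype=float)
    if means.size < 2:
        raise ValueError("CVg needs at least 2 line means")
    if overall_mean == 0:
        return float("nan")
    return float(means.std(ddof=1) / overall_mean)


# trait-table column -> display name used in the output table
HERITABILITY_TRAITS = {
    "delta_bw_g": "dBW",
    "auc_wk12": "AUC",
    "liver_g": "act-LWT",
    "spleen_g": "act-SWT",
    "heart_g": "act-HWT",
    "pct_liver": "pct-LWT",
    "pct_spleen": "pct-SWT",
    "pct_heart": "pct-HWT",
}

# per-animal ratio traits pooled over diets, one row per sex
_RATIO_TRAITS = {"dLW/dBW": "liver_g", "dSW/dBW": "spleen_g"}


def _stratum_row(trait_name: str, sex: str, diet: str, sub: pd.DataFrame,
                 column: str) -> dict:
    row = {
        "trait": trait_name, "sex": sex, "diet": diet,
        "a": np.nan, "N": len(sub), "n0": np.nan,
        "MSB": np.nan, "MSW": np.nan, "Vg": np.nan, "Ve": np.nan,
        "H2": np.nan, "SD_lines": np.nan, "overall_mean": np.nan,
        "CVg": np.nan, "flags": "",
    }
    flags = []
    groups = {line: g[column].to_numpy() for line, g in sub.groupby("line")}
    try:
        res = one_way_anova(groups)
    except ValueError as exc:
        row["flags"] = f"anova_failed: {exc}"
        return row
    vg, ve = variance_components(res.msb, res.msw, res.n0)
    h2 = heritability(vg, ve)
    if math.isnan(h2):
        flags.append("h2_undefined_zero_variance")
    row.update(
        a=res.a, N=res.n_total, n0=res.n0, MSB=res.msb, MSW=res.msw,
        Vg=vg, Ve=ve, H2=h2,
    )
    line_means = [float(v.mean()) for v in groups.values()]
    overall = float(sub[column].mean())
    row["SD_lines"] = float(np.std(line_means, ddof=1))
    row["overall_mean"] = overall
    if overall == 0:
        flags.append("cvg_undefined_zero_mean")
    else:
        row["CVg"] = genetic_cv(line_means, overall)
    row["flags"] = ";".join(flags)
    return row


def heritability_table(
    traits: pd.DataFrame, trait_columns: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-stratum variance components and CVg for every trait.

    One row per (trait, sex, diet) for the listed trait columns, plus the
    diet-pooled per-sex ratio traits dLW/dBW and dSW/dBW (per-animal organ
    weight over body-weight change; animals with dBW <= 0 are excluded and
    counted in the flags — the ratio is unstable near a zero denominator).
    Strata that fail ANOVA preconditions are emitted with flags, never
    silently dropped.
    """
    if traits.empty:
        raise ValueError("trait table is empty")
    if trait_columns is None:
        trait_columns = list(HERITABILITY_TRAITS)
    rows = []
    for column in trait_columns:
        name = HERITABILITY_TRAITS.get(column, column)
        for sex in ("F", "M"):
            for diet in ("CHD", "HFD"):
                sub = traits[(traits["sex"] == sex) & (traits["diet"] == diet)]
                rows.append(_stratum_row(name, sex, diet, sub, column))
    for name, organ_col in _RATIO_TRAITS.items():
        for sex in ("F", "M"):
            sub = traits[traits["sex"] == sex].copy()
            kept = sub[sub["delta_bw_g"] > 0].copy()
            dropped = len(sub) - len(kept)
            if kept.empty:
                rows.append({
                    "trait": name, "sex": sex, "diet": "pooled",
                    "a": np.nan, "N": 0, "n0": np.nan, "MSB": np.nan,
                    "MSW": np.nan, "Vg": np.nan, "Ve": np.nan, "H2": np.nan,
                    "SD_lines": np.nan, "overall_mean": np.nan, "CVg": np.nan,
                    "flags": f"no_animals_with_positive_dbw(dropped={dropped})",
                })
                continue
            kept["_ratio"] = kept[organ_col] / kept["delta_bw_g"]
            row = _stratum_row(name, sex, "pooled", kept, "_ratio")
            if dropped:
                extra = f"dropped_nonpositive_dbw={dropped}"
                row["flags"] = ";".join(filter(None, [row["flags"], extra]))
            rows.append(row)
    return pd.DataFrame(rows)
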