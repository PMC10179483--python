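"""Descriptive statistics: pairwise-complete Pearson correlation matrices
per stratum, Welch diet contrasts with star annotations, and heatmap
rendering."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats as sps

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "CorrelationMatrix",
    "ContrastResult",
    "pearson_matrix",
    "diet_contrast",
    "welch_contrast",
    "stars_for_p",
    "render_heatmap",
    "STAR_THRESHOLDS",
]

# p-value cutoffs for "*", "**", "***"
STAR_THRESHOLDS = (0.05, 0.01, 0.001)


def stars_for_p(p: float, thresholds=STAR_THRESHOLDS) -> str:
    """Map a p-value to its asterisk annotation ('' when not significant)."""
    if np.isnan(p):
        return ""
    stars = 0
    for cut in sorted(thresholds, reverse=True):
        if p < cut:
            stars += 1
    return "*" * stars


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix for one stratum, with per-cell n and an
    undefined-cell mask (n < 3 or zero variance)."""

    traits: tuple[str, ...]
    r: pd.DataFrame
    n: pd.DataFrame
    undefined: pd.DataFrame
    stratum: dict = field(default_factory=dict)


def pearson_matrix(
    traits: pd.DataFrame,
    stratum: dict | None = None,
    trait_columns: list[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations among *trait_columns* within
    the rows matching the *stratum* filter (e.g. {"sex": "F", "diet": "CHD"}).

    A missing value in one trait does not drop the mouse from other cells.
    Cells with fewer than 3 complete pairs or zero variance are flagged
    undefined (NaN r).
    """
    stratum = stratum or {}
    sub = traits
    for key, val in stratum.items():
        sub = sub[sub[key] == val]
    if sub.empty:
        raise ValueError(f"empty stratum {stratum!r}")
    if trait_columns is None:
        trait_columns = [
            c for c in sub.columns
            if c not in ("mouse_id", "line", "sex", "diet")
        ]
    k = len(trait_columns)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    undef = np.zeros((k, k), dtype=bool)
    data = sub[trait_columns].to_numpy(dtype=float)
    for i in range(k):
        for j in range(i, k):
            pair = data[:, [i, j]]
            mask = ~np.isnan(pair).any(axis=1)
            x, y = pair[mask, 0], pair[mask, 1]
            n[i, j] = n[j, i] = x.size
            if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                undef[i, j] = undef[j, i] = True
                continue
            if i == j:
                r[i, j] = 1.0
            else:
                r[i, j] = r[j, i] = float(sps.pearsonr(x, y).statistic)
    cols = list(trait_columns)
    return CorrelationMatrix(
        traits=tuple(cols),
        r=pd.DataFrame(r, index=cols, columns=cols),
        n=pd.DataFrame(n, index=cols, columns=cols),
        undefined=pd.DataFrame(undef, index=cols, columns=cols),
        stratum=dict(stratum),
    )


@dataclass(frozen=True)
class ContrastResult:
    trait: str
    grouping: str  # e.g. "line=IL72,sex=F" or "sex=F"
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    stars: str
    flags: str = ""


def welch_contrast(a, b) -> tuple[float, float]:
    """Welch two-sample t statistic and p-value on raw arrays.

    Identical zero-variance groups have no estimable standard error; the
    result is (nan, nan) and callers flag the cell.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return float("nan"), float("nan")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def diet_contrast(
    traits: pd.DataFrame, trait: str, line: str | None = None,
    sex: str | None = None,
) -> ContrastResult:
    """Welch t-test of HFD vs CHD for one trait, optionally within a
    (line, sex) cell; stars follow the 0.05/0.01/0.001 convention."""
    sub = traits
    parts = []
    if line is not None:
        sub = sub[sub["line"] == line]
        parts.append(f"line={line}")
    if sex is not None:
        sub = sub[sub["sex"] == sex]
        parts.append(f"sex={sex}")
    grouping = ",".join(parts) or "overall"
    hfd = sub.loc[sub["diet"] == "HFD", trait].dropna().to_numpy()
    chd = sub.loc[sub["diet"] == "CHD", trait].dropna().to_numpy()
    if hfd.size < 2 or chd.size < 2:
        return ContrastResult(
            trait, grouping, "HFD", "CHD", int(hfd.size), int(chd.size),
            float("nan"), float("nan"), "", flags="group_too_small",
        )
    stat, p = welch_contrast(hfd, chd)
    flags = "zero_variance" if np.isnan(p) else ""
    return ContrastResult(
        trait, grouping, "HFD", "CHD", int(hfd.size), int(chd.size),
        stat, p, stars_for_p(p), flags=flags,
    )


def render_heatmap(matrix: CorrelationMatrix, path: str | Path) -> Path:
    """Write a color-keyed heatmap of the correlation matrix spanning
    [-1, 1]; undefined cells are drawn in a distinct grey.  Output is
    byte-identical for identical input."""
    path = Path(path)
    k = len(matrix.traits)
    values = np.ma.masked_invalid(matrix.r.to_numpy())
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("#bbbbbb")
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * k + 2),) * 2)
    im = ax.imshow(values, vmin=-1.0, vmax=1.0, cmap=cmap)
    ax.set_xticks(range(k), labels=matrix.traits, rotation=90)
    ax.set_yticks(range(k), labels=matrix.traits)
    label = ", ".join(f"{k_}={v}" for k_, v in matrix.stratum.items())
    if label:
        ax.set_title(label)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return path
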