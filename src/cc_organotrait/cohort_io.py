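"""Tidy cohort CSV: one row per mouse x measurement.

Columns: ``mouse_id,line,sex,diet,measure,week,t_min,value`` with
``measure`` in {bw_g, glucose_mg_dl, liver_g, spleen_g, heart_g};
``t_min`` is empty except on glucose rows; UTF-8, "." decimal separator.
Floats are written with ``repr`` so a read of a write reproduces the
records bit-for-bit.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path

from cc_organotrait.simulate import ORGANS, GlucoseCurve, MouseRecord

__all__ = ["write_cohort", "read_cohort", "CohortParseError", "COLUMNS"]

COLUMNS = ("mouse_id", "line", "sex", "diet", "measure", "week", "t_min", "value")

_ORGAN_MEASURES = {f"{organ}_g": organ for organ in ORGANS}
_VALID_MEASURES = {"bw_g", "glucose_mg_dl", *_ORGAN_MEASURES}
_TERMINAL_WEEK = 12


class CohortParseError(ValueError):
    """Malformed cohort CSV; message names the offending row and column."""


def write_cohort(records: list[MouseRecord], path: str | Path) -> None:
    """Write *records* to the tidy cohort CSV at *path*."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in records:
            head = (rec.id, rec.line, rec.sex, rec.diet)
            for week in sorted(rec.bw_g):
                writer.writerow([*head, "bw_g", week, "", repr(rec.bw_g[week])])
            for week in sorted(rec.ipgtt):
                curve = rec.ipgtt[week]
                for t, g in zip(curve.t_min, curve.glucose_mg_dl):
                    writer.writerow(
                        [*head, "glucose_mg_dl", week, repr(t), repr(g)]
                    )
            for organ in ORGANS:
                if organ in rec.organ_wt_g:
                    writer.writerow(
                        [*head, f"{organ}_g", _TERMINAL_WEEK, "",
                         repr(rec.organ_wt_g[organ])]
                    )


def _parse_float(raw: str, row_no: int, column: str, *, positive: bool = True) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise CohortParseError(
            f"row {row_no}: non-numeric {column} value {raw!r}"
        ) from None
    if positive and value <= 0:
        raise CohortParseError(f"row {row_no}: non-positive {column} value {raw!r}")
    return value


def read_cohort(path: str | Path) -> list[MouseRecord]:
    """Read a tidy cohort CSV back into MouseRecords.

    Raises :class:`CohortParseError` naming the row and column on missing
    columns, unknown measures, non-numeric or non-positive values.
    """
    path = Path(path)
    bw: dict[str, dict[int, float]] = defaultdict(dict)
    glucose: dict[str, dict[int, list[tuple[float, float]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    organs: dict[str, dict[str, float]] = defaultdict(dict)
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortParseError("empty file: missing header")
        missing = set(COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortParseError(f"missing column(s): {', '.join(sorted(missing))}")
        for row_no, row in enumerate(reader, start=2):
            mouse_id = row["mouse_id"]
            if not mouse_id:
                raise CohortParseError(f"row {row_no}: empty mouse_id")
            if mouse_id not in meta:
                meta[mouse_id] = (row["line"], row["sex"], row["diet"])
                order.append(mouse_id)
            measure = row["measure"]
            if measure not in _VALID_MEASURES:
                raise CohortParseError(
                    f"row {row_no}: unknown measure {measure!r}"
                )
            week = int(_parse_float(row["week"], row_no, "week", positive=False))
            value = _parse_float(row["value"], row_no, "value")
            if measure == "bw_g":
                bw[mouse_id][week] = value
            elif measure == "glucose_mg_dl":
                t = _parse_float(row["t_min"], row_no, "t_min", positive=False)
                glucose[mouse_id][week].append((t, value))
            else:
                organs[mouse_id][_ORGAN_MEASURES[measure]] = value

    records = []
    for mouse_id in order:
        line, sex, diet = meta[mouse_id]
        curves = {
            week: GlucoseCurve(
                tuple(t for t, _ in sorted(pairs)),
                tuple(g for _, g in sorted(pairs)),
            )
            for week, pairs in glucose[mouse_id].items()
        }
        records.append(
            MouseRecord(
                id=mouse_id, line=line, sex=sex, diet=diet,
                bw_g=dict(bw[mouse_id]), ipgtt=curves,
                organ_wt_g=dict(organs[mouse_id]),
            )
        )
    return records
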