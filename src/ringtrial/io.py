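"""Reading and writing the ring-trial file formats.

Raw data travel as CSV, one row per plate observation, with header-named
columns matching :class:`~ringtrial.quantification.PlateObservation`.
Numeric cells may use either the decimal point or the decimal comma (the
collection spreadsheets are used across locales).  Precision reports are
rendered as CSV mirroring the published table layout (2-decimal statistics,
ratio classes as their footnote strings) and parse back losslessly at that
precision.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .precision import (
    PrecisionRow,
    RATIO_CLASS_LABELS,
    RatioClass,
    ratio_class_from_label,
)
from .quantification import (
    Condition,
    Cycle,
    Medium,
    PlateObservation,
    Role,
    RunRecord,
    Strain,
    ENDPOINTS,
)

__all__ = [
    "RawDataError",
    "RAW_COLUMNS",
    "read_raw_data",
    "write_raw_data",
    "load_reference_table",
    "reference_precision_rows",
    "render_precision_table",
    "write_precision_table",
    "parse_precision_table",
    "write_run_records",
    "read_run_records",
]

RAW_COLUMNS = (
    "lab_id", "cycle", "condition", "run_index", "role", "medium",
    "strain", "carrier", "dilution_factor", "plated_volume_ml", "cfu",
)


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data row number
    field: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}, field '{self.field}': {self.message}"


class RawDataError(ValueError):
    """Raw-data file failed validation; lists every offending row."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        lines = "\n".join(f"  {e}" for e in self.errors[:50])
        more = "" if len(self.errors) <= 50 else f"\n  ... {len(self.errors) - 50} more"
        super().__init__(f"{len(self.errors)} invalid row(s):\n{lines}{more}")


def _numeric(cell: str) -> float:
    """Parse a numeric cell, accepting both '0.4' and '0,4'."""
    return float(str(cell).strip().replace(",", "."))


def read_raw_data(path: str | Path) -> list[PlateObservation]:
    """Parse a raw-data CSV into typed plate observations.

    Every row is validated; all problems are collected and raised together
    as :class:`RawDataError` with row-numbered diagnostics.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in RAW_COLUMNS if c not in df.columns
               and c not in ("strain", "carrier")]
    if missing:
        raise RawDataError([RowError(0, c, "required column missing")
                            for c in missing])

    plates: list[PlateObservation] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            strain_cell = rec.get("strain")
            strain = None
            if strain_cell is not None and str(strain_cell).strip() not in ("", "nan"):
                strain = Strain(str(strain_cell).strip())
            carrier_cell = rec.get("carrier")
            carrier = 1
            if carrier_cell is not None and str(carrier_cell).strip() not in ("", "nan"):
                carrier = int(_numeric(carrier_cell))
            cfu = _numeric(rec["cfu"])
            if cfu != int(cfu):
                raise ValueError(f"cfu must be an integer, got {rec['cfu']}")
            plates.append(PlateObservation(
                lab_id=str(rec["lab_id"]).strip(),
                cycle=Cycle(str(rec["cycle"]).strip()),
                condition=Condition(str(rec["condition"]).strip()),
                run_index=int(_numeric(rec["run_index"])),
                role=Role(str(rec["role"]).strip()),
                medium=Medium(str(rec["medium"]).strip()),
                strain=strain,
                carrier=carrier,
                dilution_factor=_numeric(rec["dilution_factor"]),
                plated_volume_ml=_numeric(rec["plated_volume_ml"]),
                cfu=int(cfu),
            ))
        except (ValueError, KeyError, TypeError) as exc:
            field_name = _guess_field(exc, rec)
            errors.append(RowError(i, field_name, str(exc)))
    if errors:
        raise RawDataError(errors)
    return plates


def _guess_field(exc: Exception, rec: dict) -> str:
    msg = str(exc)
    for col in RAW_COLUMNS:
        if col in msg:
            return col
    for col, enum_cls in (("cycle", Cycle), ("condition", Condition),
                          ("role", Role), ("medium", Medium),
                          ("strain", Strain)):
        if enum_cls.__name__ in msg:
            return col
    return "?"


def write_raw_data(plates: Sequence[PlateObservation], path: str | Path) -> None:
    """Write plate observations as the raw-data CSV dialect."""
    df = pd.DataFrame([{
        "lab_id": p.lab_id,
        "cycle": p.cycle.value,
        "condition": p.condition.value,
        "run_index": p.run_index,
        "role": p.role.value,
        "medium": p.medium.value,
        "strain": p.strain.value if p.strain is not None else "",
        "carrier": p.carrier,
        "dilution_factor": repr(p.dilution_factor),
        "plated_volume_ml": p.plated_volume_ml,
        "cfu": p.cfu,
    } for p in plates], columns=list(RAW_COLUMNS))
    df.to_csv(path, index=False)


def load_reference_table() -> pd.DataFrame:
    """The published ring-trial precision statistics (54 rows, both cycles)."""
    ref = importlib.resources.files("ringtrial.data") / "reference_precision.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")


def reference_precision_rows(cycle: Cycle | str | None = None) -> list[PrecisionRow]:
    """Published precision statistics as PrecisionRow objects.

    The published report does not print per-row n; rows carry n=0.  The
    ratio class is the printed one (computed there from unrounded
    statistics), not re-derived from the rounded columns.
    """
    df = load_reference_table()
    if cycle is not None:
        df = df[df["cycle"] == Cycle(cycle).value]
    return [
        PrecisionRow(
            endpoint=r.endpoint,
            condition=Condition(r.condition),
            n=0,
            mean=float(r.mean),
            ci95=(float(r.ci_low), float(r.ci_high)),
            s_R=float(r.s_R),
            s_r=float(r.s_r),
            rsd_percent=float(r.rsd_percent),
            ratio_class=RatioClass(r.ratio_class),
        )
        for r in df.itertuples()
    ]


def render_precision_table(rows: Sequence[PrecisionRow]) -> pd.DataFrame:
    """Render precision rows in the published report layout (2 decimals)."""
    return pd.DataFrame([{
        "condition": r.condition.value,
        "VARIABLE": r.endpoint,
        "n": r.n,
        "Mean": _fmt(r.mean),
        "CI95_low": _fmt(r.ci95[0]),
        "CI95_high": _fmt(r.ci95[1]),
        "S_R": _fmt(r.s_R),
        "S_r": _fmt(r.s_r),
        "RSD %": _fmt(r.rsd_percent),
        "S_R/S_r": RATIO_CLASS_LABELS[r.ratio_class],
    } for r in rows])


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.2f}"


def write_precision_table(rows: Sequence[PrecisionRow], path: str | Path) -> None:
    render_precision_table(rows).to_csv(path, index=False)


def parse_precision_table(path: str | Path) -> list[PrecisionRow]:
    """Read back a rendered precision table (inverse of the writer)."""
    df = pd.read_csv(path, dtype=str).rename(
        columns={"RSD %": "rsd_percent", "S_R/S_r": "ratio"})

    def num(cell):
        return math.nan if str(cell) in ("", "nan") else _numeric(cell)

    rows = []
    for r in df.itertuples():
        rows.append(PrecisionRow(
            endpoint=r.VARIABLE,
            condition=Condition(r.condition),
            n=int(r.n) if str(r.n) not in ("", "nan") else 0,
            mean=num(r.Mean),
            ci95=(num(r.CI95_low), num(r.CI95_high)),
            s_R=num(r.S_R),
            s_r=num(r.S_r),
            rsd_percent=num(r.rsd_percent),
            ratio_class=ratio_class_from_label(r.ratio),
        ))
    return rows


def write_run_records(records: Sequence[RunRecord], path: str | Path) -> None:
    """Write run records in long form (one row per endpoint value)."""
    out = []
    for r in records:
        for endpoint in ENDPOINTS:
            v = r.endpoints.get(endpoint)
            out.append({
                "lab_id": r.lab_id,
                "cycle": r.cycle.value,
                "condition": r.condition.value,
                "run_index": r.run_index,
                "endpoint": endpoint,
                "value": "" if v is None else repr(float(v)),
                "censored": bool(r.censor_flags.get(endpoint, False)),
            })
    pd.DataFrame(out).to_csv(path, index=False)


def read_run_records(path: str | Path) -> list[RunRecord]:
    df = pd.read_csv(path, dtype=str)
    records: dict[tuple, RunRecord] = {}
    for r in df.itertuples():
        key = (r.lab_id, r.cycle, r.condition, int(_numeric(r.run_index)))
        if key not in records:
            records[key] = RunRecord(
                lab_id=str(r.lab_id), cycle=Cycle(r.cycle),
                condition=Condition(r.condition),
                run_index=int(_numeric(r.run_index)),
            )
        rec = records[key]
        value = None if str(r.value) in ("", "nan") else _numeric(r.value)
        rec.endpoints[r.endpoint] = value
        rec.censor_flags[r.endpoint] = str(r.censored) == "True"
    return list(records.values())
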