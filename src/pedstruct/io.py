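"""Reading and writing pedigree files and report artifacts.

The on-disk pedigree dialect is a header CSV with columns
``id,sire,dam,sex,birth_date,breed,alive`` (UTF-8).  Column names can be
remapped through a ``dialect`` mapping, and the codes treated as "parent
unknown" are configurable (empty cell, ``0``, ``NA`` and ``UNKNOWN`` by
default, which covers the common studbook exports).

Birth dates are accepted either as ISO dates (``2004-05-17``) or bare years
(``2004``); bare years are placed at mid-year so that interval arithmetic in
decimal years stays unbiased.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pedigree import AnimalRecord, Pedigree, PedigreeError, UNKNOWN_SEX

DEFAULT_MISSING_CODES = ("", "0", "NA", "UNKNOWN")

_SEX_MAP = {
    "m": "M", "male": "M", "1": "M", "s": "M", "stallion": "M",
    "f": "F", "female": "F", "2": "F", "mare": "F",
}
_TRUE = {"1", "true", "yes", "y", "alive", "t"}
_FALSE = {"0", "false", "no", "n", "dead", "f", ""}

_DEFAULT_COLUMNS = {
    "id": "id",
    "sire": "sire",
    "dam": "dam",
    "sex": "sex",
    "birth_date": "birth_date",
    "breed": "breed",
    "alive": "alive",
}


def parse_birth(value) -> float | None:
    """ISO date or bare year -> decimal year; None/NaN -> None."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("na", "nan"):
        return None
    try:
        year = float(s)
        if year.is_integer():
            return year + 0.5  # bare year -> July 1
        return year
    except ValueError:
        pass
    d = _dt.date.fromisoformat(s)
    start = _dt.date(d.year, 1, 1)
    return d.year + (d - start).days / 365.25


def read_pedigree(
    path,
    dialect: Mapping[str, str] | None = None,
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES,
    on_missing_parent: str = "phantom",
) -> Pedigree:
    """Read, validate and topologically order a pedigree CSV.

    ``dialect`` maps the logical names (``id``, ``sire``, ``dam``, and
    optionally ``sex``, ``birth_date``, ``breed``, ``alive``) to the actual
    column headers.  Only id/sire/dam are required.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("id", "sire", "dam"):
        if cols[key] not in df.columns:
            raise PedigreeError(f"pedigree file lacks required column {cols[key]!r}")
    missing = {c.upper() for c in missing_codes}

    def parent(v: str) -> str | None:
        v = v.strip()
        return None if v.upper() in missing else v

    records = []
    for _, row in df.iterrows():
        sex = UNKNOWN_SEX
        if cols["sex"] in df.columns:
            sex = _SEX_MAP.get(row[cols["sex"]].strip().lower(), UNKNOWN_SEX)
        by = None
        if cols["birth_date"] in df.columns:
            by = parse_birth(row[cols["birth_date"]])
        breed = row[cols["breed"]].strip() if cols["breed"] in df.columns else ""
        alive = True
        if cols["alive"] in df.columns:
            v = row[cols["alive"]].strip().lower()
            alive = v in _TRUE or (v not in _FALSE)
        records.append(
            AnimalRecord(
                id=row[cols["id"]].strip(),
                sire=parent(row[cols["sire"]]),
                dam=parent(row[cols["dam"]]),
                sex=sex,
                birth_year=by,
                breed=breed,
                alive=alive,
            )
        )
    return Pedigree.from_records(records, on_missing_parent=on_missing_parent)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the pedigree CSV dialect; ``read_pedigree`` round-trips it."""
    df = ped.to_frame()
    df["sire"] = df["sire"].fillna("UNKNOWN")
    df["dam"] = df["dam"].fillna("UNKNOWN")
    df["alive"] = df["alive"].map(lambda b: "1" if b else "0")
    df = df.rename(columns={"birth_year": "birth_date"})
    df.to_csv(path, index=False)


def subset_population(ped: Pedigree, selector: str) -> Pedigree:
    """Restrict a pedigree to a study population.

    ``"historical"`` keeps everything; ``"current"`` keeps living animals
    (their dead ancestors are retained as computational context only); any
    other string selects a breed label.  The returned pedigree's ``focal``
    mask marks the selected animals.
    """
    if selector == "historical":
        return ped
    if selector == "current":
        mask = ped.alive.copy()
        if not mask.any():
            raise PedigreeError("no living animals in pedigree")
        return ped.subset(mask)
    mask = np.array([b == selector for b in ped.breed], dtype=bool)
    if not mask.any():
        raise PedigreeError(f"no animals with breed label {selector!r}")
    return ped.subset(mask)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return {
            "__dataframe__": True,
            "index": list(map(str, obj.index)),
            "columns": list(map(str, obj.columns)),
            "data": obj.to_numpy().tolist(),
        }
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path, format: str = "json") -> None:
    """Serialize a report (dataclass, dict or DataFrame) to JSON or CSV.

    JSON stores every float at full precision so a read-back reproduces the
    numbers exactly; CSV is for matrix-shaped reports (labeled rows/columns).
    """
    if report is None:
        raise ValueError("cannot write an empty report")
    path = Path(path)
    if format == "json":
        payload = _jsonable(report)
        if payload in ({}, []):
            raise ValueError("cannot write an empty report")
        path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    elif format == "csv":
        if isinstance(report, pd.DataFrame):
            df = report
        elif isinstance(report, dict):
            df = pd.DataFrame(report)
        else:
            raise ValueError(f"cannot write {type(report).__name__} as csv")
        if df.empty:
            raise ValueError("cannot write an empty report")
        df.to_csv(path)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path):
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
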