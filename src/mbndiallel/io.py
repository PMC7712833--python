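"""Domain records and delimited-text readers/writers.

Phenotype files are comma- or tab-delimited with a header row:
``sow_id, cross, parity, year_season, tnb, sb``.  Pedigree files carry
``id, sire, dam, population`` with 0/empty meaning an unknown parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "CROSSES",
    "FarrowingRecord",
    "ParseError",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "records_to_frame",
]

#: The nine sow types of a 3-variety diallel, sire breed first, dam breed second.
CROSSES = ("EE", "ER", "ET", "RE", "RR", "RT", "TE", "TR", "TT")

PHENO_COLUMNS = ("sow_id", "cross", "parity", "year_season", "tnb", "sb")


class ParseError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class FarrowingRecord:
    """One farrowing: litter size (tnb) and number stillborn (sb) of a sow."""

    sow_id: str
    cross: str
    parity: int
    year_season: str
    tnb: int
    sb: int

    def __post_init__(self) -> None:
        if self.cross not in CROSSES:
            raise ValueError(f"unknown cross code {self.cross!r}")
        if not 1 <= self.parity <= 6:
            raise ValueError(f"parity must be in 1..6 (6 = sixth and beyond), got {self.parity}")
        if self.tnb < 0 or not 0 <= self.sb <= self.tnb:
            raise ValueError(f"need 0 <= sb <= tnb, got sb={self.sb}, tnb={self.tnb}")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def read_phenotypes(path: str | Path) -> list[FarrowingRecord]:
    """Read and validate a phenotype file; bad rows raise with their row number."""
    df = _read_delimited(path)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            records.append(
                FarrowingRecord(
                    sow_id=str(getattr(row, "sow_id")),
                    cross=str(getattr(row, "cross")),
                    parity=_as_int(getattr(row, "parity"), "parity"),
                    year_season=str(getattr(row, "year_season")),
                    tnb=_as_int(getattr(row, "tnb"), "tnb"),
                    sb=_as_int(getattr(row, "sb"), "sb"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {pos}: {exc}") from exc
    return records


def _as_int(value, name: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if f != int(f):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    return int(f)


def records_to_frame(records: list[FarrowingRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(PHENO_COLUMNS))


def write_phenotypes(records: list[FarrowingRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read an ``id, sire, dam[, population]`` file into a sorted Pedigree."""
    df = _read_delimited(path)
    needed = {"id", "sire", "dam"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    has_pop = "population" in df.columns
    rows = []
    for row in df.itertuples(index=False):
        rows.append(
            (
                str(row.id),
                _none_if_missing(row.sire),
                _none_if_missing(row.dam),
                (str(row.population) if has_pop and pd.notna(row.population) else None),
            )
        )
    try:
        return Pedigree.from_tuples(rows)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _none_if_missing(value):
    if pd.isna(value):
        return None
    s = str(value).strip()
    return None if s in ("", "0", "0.0") else s


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    rows = []
    for i, ind in enumerate(ped.ids):
        s, d = ped.sires[i], ped.dams[i]
        rows.append(
            {
                "id": ind,
                "sire": ped.ids[s] if s >= 0 else "0",
                "dam": ped.ids[d] if d >= 0 else "0",
                "population": ped.populations[i] or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
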