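"""Reading, writing and validation of single-cell slide tables.

The canonical on-disk format is a plain CSV with one row per cell:

    cell_id,x,y,cell_class,nucleus_area,nucleus_perimeter[,marker_value]

Coordinates are Cartesian in micrometres, origin at the slide's top-left
corner with y increasing downward (image convention).  ``cell_class`` is one
of ``cancer``, ``stromal``, ``lymphocyte``.  ``marker_value`` (e.g. per-cell
IHC positivity) is optional; when the column is absent the attribute is
missing, not zero.  Column names in foreign files can be remapped through a
``column_map`` dict (or a YAML file holding one).
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

CELL_CLASSES = ("cancer", "stromal", "lymphocyte")

REQUIRED_COLUMNS = (
    "cell_id",
    "x",
    "y",
    "cell_class",
    "nucleus_area",
    "nucleus_perimeter",
)
OPTIONAL_COLUMNS = ("marker_value",)


class CellTableFormatError(ValueError):
    """Raised when a cell-table file violates the expected format."""


@dataclasses.dataclass
class CellTable:
    """A per-cell slide table: the point pattern plus nuclear morphometry.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per cell with the canonical columns.  Row order is
        preserved by all I/O operations.
    slide_id : str
        Identifier of the slide the cells were measured on.
    units : str
        Unit declaration for ``x``/``y`` (fixed to micrometres).
    """

    data: pd.DataFrame
    slide_id: str = "slide"
    units: str = "um"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise CellTableFormatError(f"missing required columns: {missing}")
        cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in self.data.columns]
        self.data = self.data.loc[:, cols].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of cell centroid coordinates in µm."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def has_marker(self) -> bool:
        return "marker_value" in self.data.columns

    def class_counts(self) -> pd.Series:
        return self.data["cell_class"].value_counts()

    def subset(self, cell_class: str) -> pd.DataFrame:
        return self.data[self.data["cell_class"] == cell_class]


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        # column_map maps canonical name -> file column name
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    return df


def load_column_map(path: str | Path) -> dict:
    """Load a canonical-name -> file-column-name mapping from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return dict(cfg.get("columns", cfg))


def read_cell_table(
    path: str | Path | _io.IOBase,
    column_map: Mapping[str, str] | None = None,
    slide_id: str | None = None,
    coordinate_scale: float = 1.0,
) -> CellTable:
    """Read a delimited cell table into a validated :class:`CellTable`.

    Parameters
    ----------
    path : path or file-like
        CSV file with a header.  Lines starting with ``#`` are ignored.
    column_map : mapping, optional
        Canonical column name -> column name used in the file.
    slide_id : str, optional
        Defaults to the file stem.
    coordinate_scale : float
        Multiplier applied to x/y on read, for tables exported in other
        units (e.g. 0.5 µm per pixel).

    Raises
    ------
    CellTableFormatError
        If a required column is missing or a numeric field fails to parse
        (the error message carries the offending line number).
    """
    df = pd.read_csv(path, comment="#")
    df = _apply_column_map(df, column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableFormatError(f"missing required columns: {missing}")
    for col in ("x", "y", "nucleus_area", "nucleus_perimeter", "marker_value"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise CellTableFormatError(
                f"unparseable numeric value in column {col!r} at line {line}"
            )
        df[col] = coerced
    if coordinate_scale != 1.0:
        df["x"] = df["x"] * coordinate_scale
        df["y"] = df["y"] * coordinate_scale
    if slide_id is None:
        slide_id = Path(path).stem if isinstance(path, (str, Path)) else "slide"
    return CellTable(df, slide_id=slide_id)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table as CSV at full float precision.

    The column order is the canonical order, and a header comment declares
    the coordinate convention so files are self-describing.
    """
    with open(path, "w") as fh:
        fh.write(f"# slide_id={table.slide_id} units={table.units} "
                 "origin=top-left y-down\n")
        table.data.to_csv(fh, index=False, float_format="%.17g")


@dataclasses.dataclass
class ValidationReport:
    """Outcome of :func:`validate_cell_table`: a list of human-readable
    violation strings, empty when the table is clean."""

    violations: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok


def validate_cell_table(table: CellTable) -> ValidationReport:
    """Check invariants of a cell table without raising.

    Flags non-positive nuclear area/perimeter, duplicate cell ids,
    unknown cell classes and non-finite coordinates.
    """
    report = ValidationReport()
    df = table.data
    dup = df["cell_id"][df["cell_id"].duplicated()]
    for v in dup.unique():
        report.violations.append(f"duplicate cell_id: {v!r}")
    bad_class = df.loc[~df["cell_class"].isin(CELL_CLASSES), "cell_class"]
    for i, v in bad_class.items():
        report.violations.append(f"row {i}: unknown cell_class {v!r}")
    for col in ("nucleus_area", "nucleus_perimeter"):
        bad = df.index[~(df[col] > 0)]
        for i in bad:
            report.violations.append(f"row {i}: non-positive {col} ({df.at[i, col]!r})")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals)]
        for i in bad:
            report.violations.append(f"row {i}: non-finite coordinate {col}")
    return report
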