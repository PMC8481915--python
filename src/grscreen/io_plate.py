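"""Plate-map, per-cell and count-table I/O.

This module pins down the on-disk CSV dialects every other stage consumes:

* ``plate_map.csv`` — ``well,role,drug_id,concentration_uM,schedule_id``
  (an optional leading ``plate_id`` column groups several plates in one file)
* ``cells.csv``     — ``plate_id,well,cell_id,dna,krt19,vim,her2``
* ``counts.csv``    — ``plate_id,well,population,count``

All files are comma-delimited with a ``.`` decimal separator and a mandatory
header. Well coordinates are zero-padded 384-well names (``A01``–``P24``) and
sort row-major. Concentrations are always micromolar. Result tables written
through :func:`write_table` get a one-line JSON provenance sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROWS",
    "N_COLS",
    "ROLES",
    "CONTROL_ROLES",
    "MARKERS",
    "PlateFormatError",
    "PlateValidationError",
    "WellSpec",
    "PlateMap",
    "CellRecord",
    "normalize_well",
    "well_sort_key",
    "iter_wells",
    "dose_series",
    "read_plate_map",
    "read_plate_maps",
    "write_plate_maps",
    "read_cell_table",
    "read_cell_frame",
    "write_cell_frame",
    "records_to_frame",
    "frame_to_records",
    "read_counts",
    "write_counts",
    "write_table",
]

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24

#: Well roles. The three control roles used by GR normalization are the DMSO
#: vehicle (negative), staurosporine kill (positive) and aphidicolin arrest
#: (growth) controls; stain controls carry secondary-antibody-only cells.
ROLES = frozenset(
    {"treatment", "negative_control", "positive_control", "growth_control", "stain_control"}
)
CONTROL_ROLES = ("negative_control", "positive_control", "growth_control")

MARKERS = ("dna", "krt19", "vim", "her2")

PLATE_MAP_COLUMNS = ["well", "role", "drug_id", "concentration_uM", "schedule_id"]
CELL_COLUMNS = ["plate_id", "well", "cell_id", "dna", "krt19", "vim", "her2"]
COUNT_COLUMNS = ["plate_id", "well", "population", "count"]


class PlateFormatError(ValueError):
    """A file does not conform to the dialect (bad well, role, or duplicate)."""


class PlateValidationError(ValueError):
    """Structurally valid input violates a plate-level invariant."""


def normalize_well(well: str) -> str:
    """Return the canonical zero-padded form of a 384-well coordinate.

    Accepts ``"B2"`` or ``"B02"`` and returns ``"B02"``; raises
    :class:`PlateFormatError` for anything outside A01–P24.
    """
    w = str(well).strip().upper()
    if len(w) < 2 or w[0] not in ROWS or not w[1:].isdigit():
        raise PlateFormatError(f"invalid well coordinate {well!r}")
    col = int(w[1:])
    if not 1 <= col <= N_COLS:
        raise PlateFormatError(f"well column out of range in {well!r}")
    return f"{w[0]}{col:02d}"


def well_sort_key(well: str) -> tuple[int, int]:
    w = normalize_well(well)
    return (ROWS.index(w[0]), int(w[1:]))


def iter_wells() -> Iterable[str]:
    """All 384 well names in row-major order."""
    for r in ROWS:
        for c in range(1, N_COLS + 1):
            yield f"{r}{c:02d}"


@dataclass(frozen=True)
class WellSpec:
    """One well of a screening plate map."""

    well: str
    role: str
    drug_id: str = ""
    concentration_uM: float = 0.0
    schedule_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "well", normalize_well(self.well))
        if self.role not in ROLES:
            raise PlateFormatError(f"unknown role {self.role!r} in well {self.well}")
        if self.concentration_uM < 0:
            raise PlateValidationError(f"negative concentration in well {self.well}")
        is_treated = bool(self.drug_id) and self.concentration_uM > 0
        if (self.role == "treatment") != is_treated:
            raise PlateValidationError(
                f"well {self.well}: role {self.role!r} inconsistent with "
                f"drug_id={self.drug_id!r}, concentration={self.concentration_uM}"
            )


@dataclass
class PlateMap:
    """A validated 384-well plate layout."""

    plate_id: str
    wells: list[WellSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.wells:
            if w.well in seen:
                raise PlateFormatError(f"duplicate well {w.well} on plate {self.plate_id}")
            seen.add(w.well)
        roles = {w.role for w in self.wells}
        missing = [r for r in CONTROL_ROLES if r not in roles]
        if missing:
            raise PlateValidationError(
                f"plate {self.plate_id} lacks control role(s): {', '.join(missing)}"
            )

    def wells_by_role(self, role: str) -> list[WellSpec]:
        return [w for w in self.wells if w.role == role]

    def lookup(self) -> dict[str, WellSpec]:
        return {w.well: w for w in self.wells}

    def to_frame(self, include_plate_id: bool = False) -> pd.DataFrame:
        df = pd.DataFrame([asdict(w) for w in self.wells], columns=PLATE_MAP_COLUMNS)
        if include_plate_id:
            df.insert(0, "plate_id", self.plate_id)
        return df


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell's marker intensities (RFU, mean over the cell region)."""

    plate_id: str
    well: str
    cell_id: int
    dna: float
    krt19: float
    vim: float
    her2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "well", normalize_well(self.well))
        for m in MARKERS:
            v = getattr(self, m)
            if not np.isfinite(v) or v < 0:
                raise PlateValidationError(
                    f"cell {self.cell_id} in {self.plate_id}/{self.well}: "
                    f"{m} intensity {v!r} is not a finite non-negative number"
                )


def dose_series(c_max: float, n: int, fold: float) -> list[float]:
    """Descending geometric dose series, e.g. ``dose_series(5, 5, 2)``.

    Mirrors the screen design: n dilution steps of factor ``fold`` starting
    from the top concentration ``c_max`` (µM).
    """
    if c_max <= 0:
        raise ValueError(f"c_max must be positive, got {c_max}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if fold <= 1:
        raise ValueError(f"dilution fold must exceed 1, got {fold}")
    return [c_max / fold**i for i in range(n)]


# ---------------------------------------------------------------------------
# plate maps


def _plate_map_from_frame(df: pd.DataFrame, plate_id: str) -> PlateMap:
    wells = []
    for _, row in df.iterrows():
        wells.append(
            WellSpec(
                well=str(row["well"]),
                role=str(row["role"]).strip(),
                drug_id="" if pd.isna(row["drug_id"]) else str(row["drug_id"]),
                concentration_uM=float(row["concentration_uM"]),
                schedule_id="" if pd.isna(row["schedule_id"]) else str(row["schedule_id"]),
            )
        )
    return PlateMap(plate_id=plate_id, wells=wells)


def read_plate_maps(path: str | Path) -> list[PlateMap]:
    """Read one or more plate maps from a CSV file.

    A ``plate_id`` column groups rows into plates; without it the file holds a
    single plate named after the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"well": str, "role": str})
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if "plate_id" in df.columns:
        return [
            _plate_map_from_frame(sub, str(pid))
            for pid, sub in df.groupby("plate_id", sort=False)
        ]
    return [_plate_map_from_frame(df, path.stem)]


def read_plate_map(path: str | Path) -> PlateMap:
    """Read a single plate map; error if the file holds several plates."""
    maps = read_plate_maps(path)
    if len(maps) != 1:
        raise PlateFormatError(
            f"{path}: expected a single plate, found {len(maps)} plate_ids"
        )
    return maps[0]


def write_plate_maps(maps: Sequence[PlateMap] | PlateMap, path: str | Path) -> None:
    if isinstance(maps, PlateMap):
        maps = [maps]
    frames = [m.to_frame(include_plate_id=True) for m in maps]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-cell tables


def read_cell_frame(path: str | Path) -> pd.DataFrame:
    """Read a per-cell table as a DataFrame, validating the dialect."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[CELL_COLUMNS].copy()
    if len(df):
        df["well"] = df["well"].map(normalize_well)
        vals = df[list(MARKERS)].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PlateValidationError(
                f"{path}: row {i + 2}: {MARKERS[j]} intensity "
                f"{vals[i, j]!r} is negative or non-finite"
            )
        if df.duplicated(["plate_id", "well", "cell_id"]).any():
            dup = df[df.duplicated(["plate_id", "well", "cell_id"])].iloc[0]
            raise PlateValidationError(
                f"{path}: duplicate cell ({dup['plate_id']}, {dup['well']}, {dup['cell_id']})"
            )
    return df


def read_cell_table(path: str | Path) -> list[CellRecord]:
    """Read a per-cell table as validated records (row order preserved)."""
    return frame_to_records(read_cell_frame(path))


def write_cell_frame(df: pd.DataFrame, path: str | Path) -> None:
    df[CELL_COLUMNS].to_csv(path, index=False)


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=CELL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CellRecord]:
    return [
        CellRecord(
            plate_id=str(r.plate_id),
            well=str(r.well),
            cell_id=int(r.cell_id),
            dna=float(r.dna),
            krt19=float(r.krt19),
            vim=float(r.vim),
            her2=float(r.her2),
        )
        for r in df.itertuples(index=False)
    ]


def as_cell_frame(cells: pd.DataFrame | Sequence[CellRecord]) -> pd.DataFrame:
    """Accept either currency (DataFrame or CellRecord list) and return a frame."""
    if isinstance(cells, pd.DataFrame):
        return cells
    return records_to_frame(list(cells))


# ---------------------------------------------------------------------------
# count tables


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "population": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[COUNT_COLUMNS].copy()
    if (df["count"] < 0).any():
        raise PlateValidationError(f"{path}: negative count")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[COUNT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# provenance sidecars


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, *, seed: int | None = None,
                config=None) -> None:
    """Write a results CSV plus a one-line JSON provenance sidecar."""
    from . import __version__

    path = Path(path)
    df.to_csv(path, index=False)
    meta = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "version": __version__,
        "rows": int(len(df)),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta) + "\n")
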