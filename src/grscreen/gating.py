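"""Population gating from marker intensities.

Per-marker positivity thresholds are learned from secondary-antibody-only
stain-control wells: the cutoff is a high quantile (default 0.99, i.e. a 1%
nominal false-positive rate) of the control-cell intensity distribution for
that marker. Each cell is then labeled KRT19+ (epithelial), VIM+ (stromal) or
unassigned; HER2 positivity is an overlay label (a KRT19+ cell can also be
HER2+). A cell above both the KRT19 and VIM cutoffs is assigned to the marker
with the larger cutoff-normalized intensity — a deterministic, scale-free
tie-break — and counted once, so per-well primary labels partition the cells.

Quantile gating is scale-equivariant: rescaling one marker's intensities in
controls and samples alike leaves every label unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_plate import PlateMap, as_cell_frame

__all__ = [
    "GATE_MARKERS",
    "POPULATIONS",
    "GatingError",
    "GateThresholds",
    "GatingResult",
    "learn_thresholds",
    "assign_populations",
]

GATE_MARKERS = ("krt19", "vim", "her2")
#: populations reported in count tables (HER2+ is an overlay, not a partition)
POPULATIONS = ("KRT19+", "VIM+", "HER2+", "unassigned")


class GatingError(ValueError):
    pass


@dataclass(frozen=True)
class GateThresholds:
    """Per-marker positivity cutoffs learned from stain-control cells."""

    cutoffs: Mapping[str, float]
    quantile: float
    n_control_cells: int

    def __post_init__(self) -> None:
        if not 0.5 < self.quantile < 1.0:
            raise GatingError(f"quantile must be in (0.5, 1), got {self.quantile}")
        for m, v in self.cutoffs.items():
            if v <= 0:
                raise GatingError(f"non-positive cutoff for {m}: {v}")


def learn_thresholds(
    stain_control_cells,
    quantile: float = 0.99,
    *,
    min_cells: int = 100,
    markers: Sequence[str] = GATE_MARKERS,
) -> GateThresholds:
    """Learn per-marker cutoffs from secondary-antibody-only control cells."""
    df = as_cell_frame(stain_control_cells)
    if len(df) < min_cells:
        raise GatingError(
            f"need >= {min_cells} stain-control cells to gate, got {len(df)}"
        )
    cutoffs = {m: float(np.quantile(df[m].to_numpy(dtype=float), quantile)) for m in markers}
    return GateThresholds(cutoffs=cutoffs, quantile=quantile, n_control_cells=len(df))


@dataclass
class GatingResult:
    """Labeled cells plus the per-well population count table."""

    cells: pd.DataFrame        # input cells + population, her2_pos columns
    counts: pd.DataFrame       # plate_id, well, population, count
    thresholds: GateThresholds


def assign_populations(
    cells,
    thresholds: GateThresholds,
    plate_maps: Sequence[PlateMap] | PlateMap | None = None,
    *,
    dual_policy: str = "threshold_ratio",
) -> GatingResult:
    """Label every cell and aggregate per-well population counts.

    Primary labels KRT19+/VIM+/unassigned partition each well; the HER2+
    overlay count is reported as its own population row. When plate maps are
    given, cells in wells absent from the maps raise a join error.
    """
    if dual_policy != "threshold_ratio":
        raise GatingError(f"unknown dual-positive policy {dual_policy!r}")
    df = as_cell_frame(cells).copy()

    if plate_maps is not None:
        if isinstance(plate_maps, PlateMap):
            plate_maps = [plate_maps]
        known = {(pm.plate_id, w.well) for pm in plate_maps for w in pm.wells}
        present = set(map(tuple, df[["plate_id", "well"]].drop_duplicates().to_numpy()))
        orphans = present - known
        if orphans:
            pid, well = sorted(orphans)[0]
            raise GatingError(
                f"well {well} on plate {pid} has cells but no plate-map entry"
            )

    cut_k = thresholds.cutoffs["krt19"]
    cut_v = thresholds.cutoffs["vim"]
    krt19_pos = df["krt19"].to_numpy(dtype=float) > cut_k
    vim_pos = df["vim"].to_numpy(dtype=float) > cut_v
    # dual positives go to the marker with the larger cutoff-normalized signal
    ratio_k = df["krt19"].to_numpy(dtype=float) / cut_k
    ratio_v = df["vim"].to_numpy(dtype=float) / cut_v
    label = np.where(
        krt19_pos & vim_pos,
        np.where(ratio_k >= ratio_v, "KRT19+", "VIM+"),
        np.where(krt19_pos, "KRT19+", np.where(vim_pos, "VIM+", "unassigned")),
    )
    df["population"] = label
    df["her2_pos"] = df["her2"].to_numpy(dtype=float) > thresholds.cutoffs["her2"]

    groups = df.groupby(["plate_id", "well"], sort=True)
    primary = (
        groups["population"]
        .value_counts()
        .rename("count")
        .reset_index()
    )
    her2 = (
        groups["her2_pos"].sum().rename("count").reset_index().assign(population="HER2+")
    )
    counts = pd.concat(
        [primary, her2[["plate_id", "well", "population", "count"]]],
        ignore_index=True,
    )
    # zero-fill absent populations so every well reports all four rows
    wells = df[["plate_id", "well"]].drop_duplicates()
    full = wells.merge(pd.DataFrame({"population": list(POPULATIONS)}), how="cross")
    counts = (
        full.merge(counts, on=["plate_id", "well", "population"], how="left")
        .fillna({"count": 0})
        .astype({"count": int})
        .sort_values(["plate_id", "well", "population"], kind="stable")
        .reset_index(drop=True)
    )
    return GatingResult(cells=df, counts=counts, thresholds=thresholds)
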