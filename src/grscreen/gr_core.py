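"""Growth-rate-normalized (GR) response values from population counts.

The GR value compares a treated well's end-of-assay count x(c) against two
same-plate anchors: x_ctrl, the mean count in DMSO vehicle wells, and x_0,
the mean count in growth-arrested (aphidicolin) wells, which stands in for
the count at treatment start:

    GR(c) = 2^( log2(x(c)/x_0) / log2(x_ctrl/x_0) ) - 1

so GR = 1 for control-like growth, 0 for complete arrest, and -1 in the
limit of total cell kill (x(c) -> 0 maps to exactly -1 by continuation,
covering staurosporine-grade kills). Because the exponent is the ratio of
realized division counts, GR is a per-division metric and is comparable
between populations with different proliferation rates.

Control wells are averaged after a one-pass log10 outlier filter: a well
survives if |log10(x_i) - log10(mean(x))| stays below a class limit
(default 1.5 decades for vehicle controls, 1.0 for growth controls). The
filter is applied per plate and per population; controls are never shared
across plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_plate import PlateMap

__all__ = [
    "ControlError",
    "GRUndefinedError",
    "ControlSummary",
    "GrowthStats",
    "filter_control_counts",
    "summarize_controls",
    "gr_value",
    "gr_values",
    "compute_gr_table",
    "growth_stats",
]

GR_POPULATIONS = ("KRT19+", "VIM+", "HER2+")


class ControlError(ValueError):
    """Control wells missing, too few, or all rejected by the filter."""


class GRUndefinedError(ValueError):
    """GR undefined: the population did not grow (x_ctrl <= x_0)."""


@dataclass
class ControlSummary:
    """Per plate x population control anchors for the GR scale."""

    plate_id: str
    population: str
    x_ctrl: float
    x_0: float
    n_ctrl_used: int
    n_ctrl_excluded: int
    n_growth_used: int
    n_growth_excluded: int
    neg_limit: float
    growth_limit: float
    degenerate: bool = False  # x_ctrl <= x_0: population did not grow


@dataclass(frozen=True)
class GrowthStats:
    divisions: float
    doubling_time_h: float


def filter_control_counts(
    counts: Sequence[float], limit: float, *, center: str = "median"
) -> tuple[np.ndarray, int]:
    """One-pass log10 outlier filter over a vector of control-well counts.

    Keeps wells with |log10(x_i) - log10(center(x))| < limit, the center
    taken over the unfiltered vector. The default center is the median: an
    arithmetic mean is dragged so far by a grossly aberrant well that the
    filter would keep the outlier and reject the good wells, defeating its
    purpose (``center="mean"`` is available for the literal reading). Zero
    counts cannot survive (log10(0) is -inf). Returns (surviving counts,
    number excluded).
    """
    x = np.asarray(list(counts), dtype=float)
    if x.size == 0:
        raise ControlError("no control wells to filter")
    if center == "median":
        m = float(np.median(x))
    elif center == "mean":
        m = float(np.mean(x))
    else:
        raise ValueError(f"unknown center {center!r}")
    if m <= 0:
        raise ControlError("control counts center at zero; cannot filter")
    with np.errstate(divide="ignore"):
        dev = np.abs(np.log10(np.where(x > 0, x, np.nan)) - math.log10(m))
    keep = np.nan_to_num(dev, nan=np.inf) < limit
    if not keep.any():
        raise ControlError(f"log10 filter (limit {limit}) rejected every control well")
    return x[keep], int((~keep).sum())


def summarize_controls(
    counts: pd.DataFrame,
    plate_map: PlateMap,
    *,
    neg_limit: float = 1.5,
    growth_limit: float = 1.0,
    min_wells: int = 2,
    populations: Sequence[str] | None = None,
) -> dict[str, ControlSummary]:
    """Aggregate one plate's control wells into per-population GR anchors.

    ``counts`` is a long count table (plate_id, well, population, count)
    covering at least this plate. Returns {population: ControlSummary}.
    """
    sub = counts[counts["plate_id"] == plate_map.plate_id]
    if sub.empty:
        raise ControlError(f"no counts for plate {plate_map.plate_id}")
    neg_wells = {w.well for w in plate_map.wells_by_role("negative_control")}
    grw_wells = {w.well for w in plate_map.wells_by_role("growth_control")}
    if populations is None:
        populations = [p for p in sub["population"].unique() if p != "unassigned"]
    out: dict[str, ControlSummary] = {}
    for pop in populations:
        psub = sub[sub["population"] == pop]
        neg = psub[psub["well"].isin(neg_wells)]["count"].to_numpy(dtype=float)
        grw = psub[psub["well"].isin(grw_wells)]["count"].to_numpy(dtype=float)
        for name, vec in (("negative", neg), ("growth", grw)):
            if vec.size < min_wells:
                raise ControlError(
                    f"plate {plate_map.plate_id}, population {pop}: "
                    f"only {vec.size} {name}-control wells (need >= {min_wells})"
                )
        neg_kept, neg_excl = filter_control_counts(neg, neg_limit)
        grw_kept, grw_excl = filter_control_counts(grw, growth_limit)
        x_ctrl = float(np.mean(neg_kept))
        x_0 = float(np.mean(grw_kept))
        if x_ctrl <= 0 or x_0 <= 0:
            raise ControlError(
                f"plate {plate_map.plate_id}, population {pop}: "
                f"non-positive control mean (x_ctrl={x_ctrl}, x_0={x_0})"
            )
        out[pop] = ControlSummary(
            plate_id=plate_map.plate_id,
            population=pop,
            x_ctrl=x_ctrl,
            x_0=x_0,
            n_ctrl_used=len(neg_kept),
            n_ctrl_excluded=neg_excl,
            n_growth_used=len(grw_kept),
            n_growth_excluded=grw_excl,
            neg_limit=neg_limit,
            growth_limit=growth_limit,
            degenerate=x_ctrl <= x_0,
        )
    return out


def gr_value(x_c: float, x_ctrl: float, x_0: float) -> float:
    """GR of one treated count against the control anchors.

    Exactly 1 at x_c = x_ctrl, 0 at x_c = x_0, and -1 at x_c = 0 (limit
    continuation). Requires a proliferating control, x_ctrl > x_0 > 0.
    """
    if not (x_ctrl > x_0 > 0):
        raise GRUndefinedError(
            f"GR undefined: need x_ctrl > x_0 > 0, got x_ctrl={x_ctrl}, x_0={x_0}"
        )
    if x_c < 0:
        raise ValueError(f"negative count {x_c}")
    if x_c == 0:
        return -1.0
    return 2.0 ** (math.log2(x_c / x_0) / math.log2(x_ctrl / x_0)) - 1.0


def gr_values(x_c, x_ctrl: float, x_0: float) -> np.ndarray:
    """Vectorized :func:`gr_value`."""
    if not (x_ctrl > x_0 > 0):
        raise GRUndefinedError(
            f"GR undefined: need x_ctrl > x_0 > 0, got x_ctrl={x_ctrl}, x_0={x_0}"
        )
    x = np.asarray(x_c, dtype=float)
    if (x < 0).any():
        raise ValueError("negative count")
    denom = math.log2(x_ctrl / x_0)
    with np.errstate(divide="ignore"):
        out = 2.0 ** (np.log2(np.where(x > 0, x, 1.0) / x_0) / denom) - 1.0
    return np.where(x > 0, out, -1.0)


def compute_gr_table(
    counts: pd.DataFrame,
    plate_maps: Sequence[PlateMap] | PlateMap,
    *,
    neg_limit: float = 1.5,
    growth_limit: float = 1.0,
    min_wells: int = 2,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """GR of every treated well x population, normalized per plate.

    Returns columns plate_id, well, drug_id, concentration_uM, population,
    x_c, gr.
    """
    if isinstance(plate_maps, PlateMap):
        plate_maps = [plate_maps]
    rows = []
    for pm in plate_maps:
        summaries = summarize_controls(
            counts, pm, neg_limit=neg_limit, growth_limit=growth_limit,
            min_wells=min_wells, populations=populations,
        )
        treated = {w.well: w for w in pm.wells_by_role("treatment")}
        sub = counts[
            (counts["plate_id"] == pm.plate_id) & counts["well"].isin(treated)
        ]
        for pop, s in summaries.items():
            if s.degenerate:
                raise GRUndefinedError(
                    f"plate {pm.plate_id}, population {pop}: x_ctrl <= x_0"
                )
            psub = sub[sub["population"] == pop]
            g = gr_values(psub["count"].to_numpy(dtype=float), s.x_ctrl, s.x_0)
            for (well, x_c), gr in zip(
                psub[["well", "count"]].itertuples(index=False), g
            ):
                spec = treated[well]
                rows.append(
                    {
                        "plate_id": pm.plate_id,
                        "well": well,
                        "drug_id": spec.drug_id,
                        "concentration_uM": spec.concentration_uM,
                        "population": pop,
                        "x_c": float(x_c),
                        "gr": float(gr),
                    }
                )
    return pd.DataFrame(rows)


def growth_stats(x_ctrl: float, n_seed: float, assay_hours: float) -> GrowthStats:
    """Realized divisions and doubling time of an untreated population.

    divisions = log2(x_ctrl / n_seed) over the assay; doubling time is
    assay_hours / divisions. Requires net growth (x_ctrl > n_seed).
    """
    if not x_ctrl > n_seed > 0:
        raise ControlError(
            f"no net growth: x_ctrl={x_ctrl} must exceed n_seed={n_seed}"
        )
    divisions = math.log2(x_ctrl / n_seed)
    return GrowthStats(divisions=divisions, doubling_time_h=assay_hours / divisions)
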