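"""Population-selective drug efficacy: ranking, tests, and intensity shifts.

A drug is called *cytotoxic* on a population when the fitted GR curve's
minimum within the tested dose range falls below 0 — on the GR scale that is
net cell loss, not mere growth slowing — and *selective* when it is cytotoxic
in exactly one of the two compared populations. Per-drug summaries carry the
mean GR over the shared dose set in each population, a paired Student's t
over the dose-matched GR pairs (with Benjamini-Hochberg FDR across drugs),
and the selectivity call. Across drugs, the agreement of the two populations
is summarized by the Pearson correlation of per-drug mean GR.

Marker-intensity shifts (e.g. HER2 RFU in KRT19+ cells under treatment) are
scored per drug x dose as fold change against pooled vehicle-control cells
with an unpaired Welch's t-test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dose_response import fit_gr_curve
from .io_plate import PlateMap, as_cell_frame

__all__ = [
    "AlignmentError",
    "compare_populations",
    "population_correlation",
    "intensity_shift",
]


class AlignmentError(ValueError):
    """The two populations were not scored at identical doses for a drug."""


def _per_dose(sub: pd.DataFrame) -> pd.Series:
    # replicate wells at the same dose reduce to their median
    return sub.groupby("concentration_uM")["gr"].median()


def compare_populations(
    gr_table: pd.DataFrame,
    pop_a: str = "KRT19+",
    pop_b: str = "VIM+",
    *,
    cytotox_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-drug selectivity summary between two populations.

    Returns columns drug_id, mean_gr_a, mean_gr_b, t_stat, p_value, q_value,
    cytotoxic_a, cytotoxic_b, selective, selective_population.
    """
    rows = []
    for drug, sub in gr_table.groupby("drug_id", sort=True):
        a = _per_dose(sub[sub["population"] == pop_a])
        b = _per_dose(sub[sub["population"] == pop_b])
        if list(a.index) != list(b.index):
            raise AlignmentError(
                f"drug {drug}: dose sets differ between {pop_a} and {pop_b}"
            )
        if len(a) == 0:
            continue
        t_stat, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
        if np.isnan(p):  # zero-variance differences: no evidence of difference
            t_stat, p = 0.0, 1.0
        cytotox = {}
        for pop, series in ((pop_a, a), (pop_b, b)):
            fit = fit_gr_curve(
                series.index.to_numpy(), series.to_numpy(),
                drug_id=str(drug), population=pop,
            )
            cytotox[pop] = bool(fit.min_gr_in_range < cytotox_threshold)
        selective = cytotox[pop_a] != cytotox[pop_b]
        rows.append(
            {
                "drug_id": drug,
                "mean_gr_a": float(a.mean()),
                "mean_gr_b": float(b.mean()),
                "t_stat": float(t_stat),
                "p_value": float(p),
                "cytotoxic_a": cytotox[pop_a],
                "cytotoxic_b": cytotox[pop_b],
                "selective": selective,
                "selective_population": (
                    (pop_a if cytotox[pop_a] else pop_b) if selective else ""
                ),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df.insert(
            5, "q_value", multipletests(df["p_value"], method="fdr_bh")[1]
        )
    return df


def population_correlation(
    gr_table: pd.DataFrame, pop_a: str = "KRT19+", pop_b: str = "VIM+"
) -> tuple[float, float]:
    """Pearson r (and p) across drugs of per-drug mean GR in two populations."""
    means = (
        gr_table.groupby(["drug_id", "population"])["gr"].mean().unstack("population")
    )
    for pop in (pop_a, pop_b):
        if pop not in means.columns:
            raise AlignmentError(f"population {pop!r} absent from GR table")
    sub = means[[pop_a, pop_b]].dropna()
    if len(sub) < 3:
        raise AlignmentError(f"need >= 3 drugs for a correlation, got {len(sub)}")
    a, b = sub[pop_a].to_numpy(), sub[pop_b].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise AlignmentError("zero variance in per-drug mean GR; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def intensity_shift(
    labeled_cells,
    plate_maps: Sequence[PlateMap] | PlateMap,
    *,
    marker: str = "her2",
    population: str = "KRT19+",
) -> pd.DataFrame:
    """Marker intensity of one gated population under each drug x dose.

    Fold change and Welch's t are computed against the pooled
    population-positive cells of the vehicle-control wells. Wells with no
    population-positive cells are flagged empty (n_cells = 0, NaN stats) and
    take no part in testing.
    """
    if isinstance(plate_maps, PlateMap):
        plate_maps = [plate_maps]
    df = as_cell_frame(labeled_cells).reset_index(drop=True)
    if "population" not in df.columns:
        raise ValueError("cells must be gated first (population column missing)")

    spec_by_key = {
        (pm.plate_id, w.well): w for pm in plate_maps for w in pm.wells
    }
    roles = pd.Series(
        [
            spec_by_key[k].role if k in spec_by_key else ""
            for k in zip(df["plate_id"], df["well"])
        ],
        index=df.index,
    )
    pop_cells = df[df["population"] == population]
    ctrl = pop_cells[
        roles.loc[pop_cells.index] == "negative_control"
    ][marker].to_numpy(dtype=float)
    if ctrl.size == 0:
        raise ValueError("no population-positive cells in vehicle-control wells")
    ctrl_mean = float(ctrl.mean())

    rows = []
    treated = pop_cells[roles.loc[pop_cells.index] == "treatment"]
    for (pid, well), sub in treated.groupby(["plate_id", "well"], sort=True):
        spec = spec_by_key[(pid, well)]
        vals = sub[marker].to_numpy(dtype=float)
        rec = {
            "plate_id": pid,
            "well": well,
            "drug_id": spec.drug_id,
            "concentration_uM": spec.concentration_uM,
            "n_cells": int(vals.size),
        }
        if vals.size == 0:
            rec.update(mean_intensity=np.nan, fold_change=np.nan,
                       t_stat=np.nan, p_value=np.nan)
        else:
            t, p = (
                stats.ttest_ind(vals, ctrl, equal_var=False)
                if vals.size > 1
                else (np.nan, np.nan)
            )
            rec.update(
                mean_intensity=float(vals.mean()),
                fold_change=float(vals.mean() / ctrl_mean),
                t_stat=float(t),
                p_value=float(p),
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["control_mean"] = ctrl_mean
    out.attrs["n_control_cells"] = int(ctrl.size)
    return out
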