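"""Reverse-phase protein array (RPPA) normalization and profiling.

Each spot pairs an antibody signal with a Sypro total-protein signal from the
same lysate. The pipeline is: antibody / total-protein ratio (cancelling
per-lysate loading), log transform (base 2 by default), replicate spots
averaged on the log scale, then z-score standardization per marker across
all conditions of the screen (sample standard deviation, n-1, by default;
both the divisor and a whole-matrix pooled-SD scope are selectable).
|z| > 2 marks significantly down-/up-regulated marker x condition cells.

Downstream helpers correlate each marker's profile with an anchor (e.g. the
Ki-67 proliferation marker) and order markers by one-dimensional agglomerative
hierarchical clustering (Euclidean distance, average linkage, input-order
tie-breaks) for heat-map display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = ["RPPAError", "RPPAMatrix", "normalize_rppa", "marker_correlations", "cluster_markers"]


class RPPAError(ValueError):
    pass


@dataclass
class RPPAMatrix:
    """Markers x conditions z-score matrix with its significance mask."""

    z: pd.DataFrame
    logratio: pd.DataFrame
    log_base: float
    ddof: int
    z_threshold: float = 2.0
    significant: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.z.abs() > self.z_threshold


def normalize_rppa(
    spots: pd.DataFrame,
    *,
    log_base: float = 2.0,
    ddof: int = 1,
    scope: str = "marker",
    z_threshold: float = 2.0,
) -> RPPAMatrix:
    """Normalize an RPPA spot table to a markers x conditions z matrix.

    ``spots`` needs columns lysate_id, marker, antibody_signal, total_signal.
    ``scope`` "marker" standardizes each marker row over conditions;
    "matrix" uses the pooled mean/SD of the whole screen.
    """
    required = ["lysate_id", "marker", "antibody_signal", "total_signal"]
    missing = [c for c in required if c not in spots.columns]
    if missing:
        raise RPPAError(f"spot table missing column(s): {', '.join(missing)}")
    ab = spots["antibody_signal"].to_numpy(dtype=float)
    tot = spots["total_signal"].to_numpy(dtype=float)
    if (ab <= 0).any() or (tot <= 0).any():
        i = int(np.argmax((ab <= 0) | (tot <= 0)))
        raise RPPAError(
            f"non-positive signal at row {i} "
            f"(lysate {spots.iloc[i]['lysate_id']}, marker {spots.iloc[i]['marker']}); "
            "log transform undefined"
        )
    work = spots.assign(
        logratio=np.log(ab / tot) / np.log(log_base)
    )
    # replicate spots average on the log scale; condition order = first appearance
    cond_order = list(dict.fromkeys(work["lysate_id"]))
    marker_order = list(dict.fromkeys(work["marker"]))
    logratio = (
        work.groupby(["marker", "lysate_id"], sort=False)["logratio"]
        .mean()
        .unstack("lysate_id")
        .reindex(index=marker_order, columns=cond_order)
    )
    if logratio.isna().any().any():
        m = logratio.stack(future_stack=True)
        missing_pair = m[m.isna()].index[0]
        raise RPPAError(f"missing spot for (marker, lysate) = {missing_pair}")

    if scope == "marker":
        mu = logratio.mean(axis=1)
        sd = logratio.std(axis=1, ddof=ddof)
        flat = sd[sd == 0]
        if len(flat):
            raise RPPAError(
                f"marker {flat.index[0]!r} is constant across conditions; z undefined"
            )
        z = logratio.sub(mu, axis=0).div(sd, axis=0)
    elif scope == "matrix":
        vals = logratio.to_numpy().ravel()
        sd = float(np.std(vals, ddof=ddof))
        if sd == 0:
            raise RPPAError("whole screen is constant; z undefined")
        z = (logratio - float(np.mean(vals))) / sd
    else:
        raise RPPAError(f"unknown standardization scope {scope!r}")
    return RPPAMatrix(z=z, logratio=logratio, log_base=log_base, ddof=ddof,
                      z_threshold=z_threshold)


def marker_correlations(matrix: RPPAMatrix, anchor_marker: str = "Ki-67") -> pd.Series:
    """Pearson r of every marker's profile against the anchor marker's."""
    z = matrix.z
    if anchor_marker not in z.index:
        raise RPPAError(f"anchor marker {anchor_marker!r} not in matrix")
    if z.shape[1] < 3:
        raise RPPAError("need >= 3 conditions for correlations")
    anchor = z.loc[anchor_marker].to_numpy()
    out = {}
    for m in z.index:
        row = z.loc[m].to_numpy()
        if np.std(row) == 0 or np.std(anchor) == 0:
            out[m] = np.nan
        else:
            out[m] = float(stats.pearsonr(anchor, row)[0])
    return pd.Series(out, name=f"r_vs_{anchor_marker}")


def cluster_markers(
    matrix: RPPAMatrix, *, metric: str = "euclidean", method: str = "average"
) -> list[str]:
    """Heat-map leaf order of markers from 1-D hierarchical clustering.

    Deterministic: SciPy's linkage breaks distance ties by observation index,
    i.e. by input row order.
    """
    z = matrix.z
    if len(z) < 2:
        raise RPPAError("need >= 2 markers to cluster")
    Z = linkage(z.to_numpy(), method=method, metric=metric)
    return [z.index[i] for i in leaves_list(Z)]
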