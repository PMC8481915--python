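"""Chou-Talalay median-effect analysis and combination index.

The median-effect equation fa/fu = (D/Dm)^m linearizes as

    log(fa/(1-fa)) = m*log(D) - m*log(Dm)

so each agent (and the fixed-ratio mixture, treated as a single agent) is fit
by ordinary linear regression in log-logit space, using only points with
0 < fa < 1. The combination index at effect level fa compares the mixture
dose achieving fa with the single-agent iso-effect doses:

    CI = d_a / D_A(fa) + d_b / D_B(fa)

where d_a, d_b split the mixture's dose by the molar ratio and
D_X(fa) = Dm_X * (fa/(1-fa))^(1/m_X). CI < 1 indicates synergy, about 1
additivity, > 1 antagonism; CI50 is CI at fa = 0.5. Fraction affected is by
default 1 - x(c)/x_ctrl from raw relative viability (clamped away from 0 and
1 before the logit); computing fa from GR values instead is selectable.

Dosing schedules (simultaneous or either agent pre-treated) are analytically
identical pipelines run on separately collected datasets; the schedule is a
data label. Replicate CI estimates per schedule are ranked by mean CI and
compared pairwise with unpaired Student's t-tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynergyError",
    "MedianEffectFit",
    "CombinationResult",
    "fa_from_counts",
    "fa_from_gr",
    "fit_median_effect",
    "dose_for_fa",
    "fa_at_dose",
    "combination_index",
    "schedule_compare",
]

FA_CLAMP = 1e-6


class SynergyError(ValueError):
    pass


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters of one agent (or fixed-ratio mixture)."""

    agent_id: str
    dm: float            # median-effect dose, µM
    m: float             # slope (sigmoidicity)
    r_squared: float
    n_used: int
    effect: str = "fraction_affected"


@dataclass(frozen=True)
class CombinationResult:
    schedule_id: str
    ratio: tuple[float, float]
    fa_level: float
    ci: float
    d_a: float           # mixture component doses at the effect level, µM
    d_b: float
    iso_dose_a: float    # single-agent iso-effect doses, µM
    iso_dose_b: float

    @property
    def interpretation(self) -> str:
        if self.ci < 0.9:
            return "synergy"
        if self.ci > 1.1:
            return "antagonism"
        return "additivity"


def fa_from_counts(x_c, x_ctrl: float, clamp: float = FA_CLAMP) -> np.ndarray:
    """Fraction affected from raw relative viability: 1 - x(c)/x_ctrl."""
    if x_ctrl <= 0:
        raise SynergyError("x_ctrl must be positive")
    fa = 1.0 - np.asarray(x_c, dtype=float) / x_ctrl
    return np.clip(fa, clamp, 1.0 - clamp)


def fa_from_gr(gr, clamp: float = FA_CLAMP) -> np.ndarray:
    """Fraction affected mapped from GR values: fa = (1 - GR) / 2.

    Linear map of the GR scale [-1, 1] onto [0, 1]; selectable alternative
    to count-based fa.
    """
    fa = (1.0 - np.asarray(gr, dtype=float)) / 2.0
    return np.clip(fa, clamp, 1.0 - clamp)


def fit_median_effect(
    doses: Sequence[float],
    fa: Sequence[float],
    *,
    agent_id: str = "",
) -> MedianEffectFit:
    """Fit fa/fu = (D/Dm)^m by linear regression in log-logit space.

    Only points with fa strictly inside (0, 1) and D > 0 enter the fit;
    at least two are required. A non-positive slope (effect decreasing with
    dose) is flagged with a warning, not an error.
    """
    d = np.asarray(list(doses), dtype=float)
    f = np.asarray(list(fa), dtype=float)
    if d.shape != f.shape:
        raise SynergyError("doses and fa differ in length")
    ok = (f > 0.0) & (f < 1.0) & (d > 0.0)
    if ok.sum() < 2:
        raise SynergyError(
            f"agent {agent_id or '?'}: need >= 2 points with 0 < fa < 1, got {ok.sum()}"
        )
    x = np.log10(d[ok])
    y = np.log10(f[ok] / (1.0 - f[ok]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        warnings.warn(
            f"agent {agent_id or '?'}: inverted dose-response (m = {m:.3g})",
            stacklevel=2,
        )
        dm = np.nan
    else:
        dm = float(10.0 ** (-res.intercept / m))
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return MedianEffectFit(agent_id=agent_id, dm=dm, m=m, r_squared=r2,
                           n_used=int(ok.sum()))


def dose_for_fa(fit: MedianEffectFit, fa: float) -> float:
    """Dose achieving fraction affected fa under the fitted median-effect curve."""
    if not 0.0 < fa < 1.0:
        raise SynergyError(f"fa must be in (0, 1), got {fa}")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def fa_at_dose(fit: MedianEffectFit, dose: float) -> float:
    r = (dose / fit.dm) ** fit.m
    return float(r / (1.0 + r))


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    *,
    ratio: tuple[float, float] = (1, 5),
    fa_level: float = 0.5,
    schedule_id: str = "",
) -> CombinationResult:
    """Combination index of a fixed-ratio mixture at the given effect level."""
    if not 0.0 < fa_level < 1.0:
        raise SynergyError(f"fa_level must be in (0, 1), got {fa_level}")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise SynergyError(f"molar ratio parts must be positive, got {ratio}")
    for f in (fit_a, fit_b, fit_combo):
        if not np.isfinite(f.dm) or f.dm <= 0:
            raise SynergyError(f"agent {f.agent_id or '?'}: unusable fit (Dm = {f.dm})")
    d_total = dose_for_fa(fit_combo, fa_level)
    d_a = d_total * a / (a + b)
    d_b = d_total * b / (a + b)
    iso_a = dose_for_fa(fit_a, fa_level)
    iso_b = dose_for_fa(fit_b, fa_level)
    ci = d_a / iso_a + d_b / iso_b
    return CombinationResult(
        schedule_id=schedule_id, ratio=(float(a), float(b)), fa_level=fa_level,
        ci=float(ci), d_a=d_a, d_b=d_b, iso_dose_a=iso_a, iso_dose_b=iso_b,
    )


def schedule_compare(
    replicate_cis: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank dosing schedules by mean CI and test them pairwise.

    ``replicate_cis`` maps schedule id to its replicate CI estimates (from
    replicate wells or bootstrap). Returns (ranking, pairwise) frames; with
    a single replicate anywhere the t-tests are skipped with a warning.
    """
    if not replicate_cis:
        raise SynergyError("no schedules to compare")
    ranking = (
        pd.DataFrame(
            [
                {
                    "schedule_id": s,
                    "mean_ci": float(np.mean(v)),
                    "sd_ci": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                    "n": len(v),
                }
                for s, v in replicate_cis.items()
            ]
        )
        .sort_values("mean_ci", kind="stable")
        .reset_index(drop=True)
    )
    can_test = all(len(v) >= 2 for v in replicate_cis.values())
    rows = []
    for s1, s2 in itertools.combinations(replicate_cis, 2):
        if can_test:
            t, p = stats.ttest_ind(replicate_cis[s1], replicate_cis[s2])
            if np.isnan(p):
                t, p = 0.0, 1.0
            rows.append({"schedule_a": s1, "schedule_b": s2,
                         "t_stat": float(t), "p_value": float(p)})
        else:
            rows.append({"schedule_a": s1, "schedule_b": s2,
                         "t_stat": np.nan, "p_value": np.nan})
    if not can_test:
        warnings.warn("single-replicate schedule(s): ranking only, tests skipped",
                      stacklevel=2)
    return ranking, pd.DataFrame(rows)
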