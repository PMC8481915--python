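"""Synthetic screening-plate generator with known ground truth.

Emulates the study conditions of an image-based ex vivo drug screen on a
mixed patient-derived cell suspension: 384-well plates seeded with 1,000
cells/well, a 96-h assay, an epithelial (KRT19+) and a stromal (VIM+)
population with distinct doubling times (~220 h and ~135 h), 5-point dose
series diluted 2- or 3-fold from 5 µM, DMSO negative controls, staurosporine
kill controls, aphidicolin growth-arrest controls, and secondary-antibody-only
stain controls.

Growth model
------------
Each population grows exponentially; a drug acts on the division rate. With
k(0) = 1/doubling_time (divisions/h) and assay length T, a well at
concentration c ends at the expected count

    N(c) = n_seed * fraction * 2^(k(c) * T),
    k(c) = k(0) * log2(GR_true(c) + 1),
    GR_true(c) = GRinf + (1 - GRinf) / (1 + (c / GEC50)^h).

Under this model the GR normalization (treated count against DMSO and
growth-arrest controls) inverts the generator exactly: computed GR equals
GR_true at every dose when count noise is off. Kill controls use
GR_true = -1 (expected count 0); growth-arrest controls freeze counts at
seeding (k = 0). Death is a negative net rate, not a separate compartment —
only end counts are observed.

Counts are Poisson by default (noise="none" keeps the exact real-valued
expectations in the counts table; the per-cell table necessarily rounds to
whole cells). Marker intensities are log-normal per population; stain-control
wells hold normally growing cells whose intensities are all drawn from the
secondary-only background distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import gr_logistic
from .io_plate import (
    MARKERS,
    PlateMap,
    WellSpec,
    dose_series,
    iter_wells,
)

__all__ = [
    "POP_EPITHELIAL",
    "POP_STROMAL",
    "POP_DEBRIS",
    "PopulationTruth",
    "GRCurveTruth",
    "DrugTruth",
    "SimConfig",
    "ScreenResult",
    "default_populations",
    "make_drug_panel",
    "make_recovery_panel",
    "uniform_population",
    "expected_count",
    "simulate_well",
    "simulate_screen",
    "simulate_rppa",
    "make_rppa_truth",
    "RPPA_MARKERS",
    "loewe_additive_fa",
    "simulate_combination",
]

POP_EPITHELIAL = "KRT19+"
POP_STROMAL = "VIM+"
POP_DEBRIS = "unassigned"

_BG_MU = math.log(10.0)   # secondary-only background: median 10 RFU
_HI_MU = math.log(500.0)  # marker-positive signal: median 500 RFU
_SIGMA = 0.5              # log-scale spread of both classes


@dataclass(frozen=True)
class PopulationTruth:
    """Ground truth for one cell population in the suspension."""

    name: str                 # "epithelial" | "stromal" | "debris"
    label: str                # gating label the population should receive
    fraction: float           # proportion of seeded cells
    doubling_time_h: float
    marker_mu: Mapping[str, float]     # log-intensity location per marker
    marker_sigma: Mapping[str, float]  # log-intensity scale per marker

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0,1], got {self.fraction}")
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be positive")


@dataclass(frozen=True)
class GRCurveTruth:
    """Planted GR curve parameters of one drug on one population."""

    grinf: float
    gec50_uM: float
    h: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.grinf <= 1.0:
            raise ValueError(f"GRinf must be in [-1,1], got {self.grinf}")
        if self.gec50_uM <= 0 or self.h <= 0:
            raise ValueError("GEC50 and Hill slope must be positive")

    def gr(self, c: float) -> float:
        return float(gr_logistic(c, self.grinf, self.gec50_uM, self.h))


@dataclass(frozen=True)
class DrugTruth:
    drug_id: str
    effects: Mapping[str, GRCurveTruth]  # population label -> curve


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated screen."""

    n_seed_cells: int = 1000
    assay_hours: float = 96.0
    c_max_uM: float = 5.0
    n_doses: int = 5
    dilution_fold: float = 2.0
    noise: str = "poisson"          # "poisson" | "none"
    n_replicates: int = 1           # treatment wells per drug x dose
    seed: int = 0
    n_negative: int = 14
    n_positive: int = 6
    n_growth: int = 6
    n_stain: int = 6

    def __post_init__(self) -> None:
        if self.n_seed_cells < 1:
            raise ValueError("n_seed_cells must be >= 1")
        if self.assay_hours <= 0:
            raise ValueError("assay_hours must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def doses(self) -> list[float]:
        return dose_series(self.c_max_uM, self.n_doses, self.dilution_fold)

    @property
    def n_control_wells(self) -> int:
        return self.n_negative + self.n_positive + self.n_growth + self.n_stain


def default_populations() -> list[PopulationTruth]:
    """The two-population mixture the screens resolve, plus unstained debris.

    Fractions 77.1% epithelial / 19.5% stromal and doubling times 220 h /
    135 h are the generator presets describing the kind of suspension the
    assay sees; the remainder is an unstained debris class.
    """
    bg = {m: _BG_MU for m in MARKERS}
    sig = {m: _SIGMA for m in MARKERS}
    epi_mu = dict(bg, dna=math.log(200.0), krt19=_HI_MU, her2=math.log(400.0))
    str_mu = dict(bg, dna=math.log(200.0), vim=_HI_MU)
    return [
        PopulationTruth("epithelial", POP_EPITHELIAL, 0.771, 220.0, epi_mu, sig),
        PopulationTruth("stromal", POP_STROMAL, 0.195, 135.0, str_mu, sig),
        PopulationTruth("debris", POP_DEBRIS, 0.034, 1e9, bg, sig),
    ]


def make_drug_panel(
    n_drugs: int,
    *,
    n_selective: int = 0,
    rng: np.random.Generator | None = None,
    populations: Sequence[str] = (POP_EPITHELIAL, POP_STROMAL),
    gec50_range: tuple[float, float] = (0.4, 4.0),
) -> list[DrugTruth]:
    """Random drug panel with a planted population-selective subset.

    Selective drugs are cytotoxic on the first population (GR dips well below
    0 inside the tested dose range: GRinf in [-0.7, -0.45], GEC50 well below
    the top dose, steep slope) and merely growth-slowing on the second (GRinf
    in [0.4, 0.7]); the remainder alternates between near-inert and
    cytotoxic-on-both drugs with the same margins, so selectivity calling has
    unambiguous positives and negatives.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_selective > n_drugs:
        raise ValueError("n_selective cannot exceed n_drugs")
    pop_a, pop_b = populations
    lo, hi = gec50_range

    def toxic() -> GRCurveTruth:
        # GR at the top dose lands below about -0.3: clear net cell loss
        return GRCurveTruth(
            float(rng.uniform(-0.7, -0.45)),
            float(np.exp(rng.uniform(np.log(0.3), np.log(1.0)))),
            float(rng.uniform(1.5, 2.5)),
        )

    def mild() -> GRCurveTruth:
        # GR never drops below +0.35 anywhere: unambiguously non-cytotoxic
        return GRCurveTruth(
            float(rng.uniform(0.35, 0.8)),
            float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            float(rng.uniform(0.8, 2.5)),
        )

    drugs: list[DrugTruth] = []
    for i in range(n_drugs):
        if i < n_selective:
            effects = {pop_a: toxic(), pop_b: mild()}
        elif (i - n_selective) % 2 == 0:
            effects = {pop_a: mild(), pop_b: mild()}
        else:
            effects = {pop_a: toxic(), pop_b: toxic()}
        drugs.append(DrugTruth(f"drug{i:03d}", effects))
    return drugs


def make_recovery_panel(
    n_drugs: int,
    *,
    rng: np.random.Generator | None = None,
    populations: Sequence[str] = (POP_EPITHELIAL, POP_STROMAL),
    gec50_range: tuple[float, float] = (0.15, 1.0),
    grinf_range: tuple[float, float] = (-0.8, 0.3),
    h_range: tuple[float, float] = (1.2, 2.5),
) -> list[DrugTruth]:
    """Drug panel for parameter-recovery studies.

    Curves are kept structurally identifiable from a 5-point 2-fold series
    topping out at 5 µM: GEC50 well inside the tested doses and Hill slopes
    >= 1.2, so the asymptote GRinf is effectively reached within the series.
    (When GEC50 sits near the top dose the asymptote is extrapolation and no
    fitter can pin it down — a property of the assay design, not of the
    estimator.)
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = gec50_range
    drugs = []
    for i in range(n_drugs):
        effects = {
            pop: GRCurveTruth(
                float(rng.uniform(*grinf_range)),
                float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                float(rng.uniform(*h_range)),
            )
            for pop in populations
        }
        drugs.append(DrugTruth(f"drug{i:03d}", effects))
    return drugs


def uniform_population(
    doubling_time_h: float = 135.0, label: str = POP_EPITHELIAL
) -> list[PopulationTruth]:
    """A homogeneous suspension (fraction 1.0) for recovery studies.

    Isolates count-noise propagation from mixture effects; the default
    doubling time is the faster (stromal-like) preset so the assay spans
    ~0.7 divisions.
    """
    bg = {m: _BG_MU for m in MARKERS}
    sig = {m: _SIGMA for m in MARKERS}
    mu = dict(bg, dna=math.log(200.0), krt19=_HI_MU, her2=math.log(400.0))
    return [PopulationTruth("uniform", label, 1.0, doubling_time_h, mu, sig)]


# ---------------------------------------------------------------------------
# well-level simulation


def expected_count(
    pop: PopulationTruth,
    role: str,
    curve: GRCurveTruth | None,
    c: float,
    cfg: SimConfig,
) -> float:
    """Expected end-of-assay count of one population in one well."""
    base = cfg.n_seed_cells * pop.fraction
    k0_T = cfg.assay_hours / pop.doubling_time_h  # divisions over the assay
    if role == "growth_control":
        return base
    if role == "positive_control":
        return 0.0  # GR_true = -1, near-total kill
    if role in ("negative_control", "stain_control"):
        return base * 2.0**k0_T
    if role == "treatment":
        if curve is None:
            raise ValueError("treatment well requires a drug curve")
        gr = curve.gr(c)
        if gr + 1.0 <= 1e-12:
            if gr + 1.0 < -1e-9:
                raise ValueError(f"GR_true(c)+1 = {gr + 1.0} is negative; log undefined")
            return 0.0
        return base * 2.0 ** (k0_T * math.log2(gr + 1.0))
    raise ValueError(f"unknown role {role!r}")


def _realize_count(mean: float, cfg: SimConfig, rng: np.random.Generator) -> float:
    if cfg.noise == "poisson":
        return float(rng.poisson(mean))
    return mean


def _sample_cells(
    pop: PopulationTruth,
    n: int,
    stain_control: bool,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    out = {}
    for m in MARKERS:
        mu = _BG_MU if stain_control else pop.marker_mu[m]
        out[m] = rng.lognormal(mu, pop.marker_sigma[m], size=n)
    return out


def simulate_well(
    populations: Sequence[PopulationTruth],
    drug: DrugTruth | None,
    c: float,
    cfg: SimConfig,
    *,
    role: str = "treatment",
    rng: np.random.Generator | None = None,
    plate_id: str = "plate1",
    well: str = "A01",
) -> pd.DataFrame:
    """Simulate the per-cell table of a single well."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if role == "treatment" and drug is None:
        raise ValueError("treatment well requires a drug")
    frames = []
    cell_id = 0
    for pop in populations:
        curve = drug.effects.get(pop.label) if drug is not None else None
        if role == "treatment" and curve is None:
            curve = GRCurveTruth(1.0, 1.0, 1.0)  # drug inert on this population
        mean = expected_count(pop, role, curve, c, cfg)
        n = int(round(_realize_count(mean, cfg, rng)))
        if n == 0:
            continue
        cols = _sample_cells(pop, n, role == "stain_control", rng)
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "cell_id": np.arange(cell_id, cell_id + n),
                    **cols,
                }
            )
        )
        cell_id += n
    if not frames:
        return pd.DataFrame(columns=["plate_id", "well", "cell_id", *MARKERS])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# screen-level simulation


@dataclass
class ScreenResult:
    """Everything a downstream test needs: layout, data, and the truth."""

    plate_maps: list[PlateMap]
    counts: pd.DataFrame             # ground-truth per-well population counts
    truth: pd.DataFrame              # planted curve parameters per drug x population
    cells: pd.DataFrame | None       # per-cell table (None if not requested)
    config: SimConfig

    def truth_gr(self) -> pd.DataFrame:
        """Planted GR_true at every tested dose (long format)."""
        rows = []
        doses = self.config.doses
        for r in self.truth.itertuples(index=False):
            for c in doses:
                rows.append(
                    {
                        "drug_id": r.drug_id,
                        "population": r.population,
                        "concentration_uM": c,
                        "gr_true": float(
                            gr_logistic(c, r.grinf, r.gec50_uM, r.hill)
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _layout_plates(drugs: Sequence[DrugTruth], cfg: SimConfig) -> list[PlateMap]:
    doses = cfg.doses
    per_plate_capacity = 384 - cfg.n_control_wells
    if per_plate_capacity < cfg.n_doses:
        raise ValueError("control layout leaves no room for a dose series")
    treatments = [
        (d.drug_id, c)
        for d in drugs
        for c in doses
        for _ in range(cfg.n_replicates)
    ]
    n_plates = max(1, math.ceil(len(treatments) / per_plate_capacity))
    maps = []
    it = iter(treatments)
    for p in range(n_plates):
        wells: list[WellSpec] = []
        names = iter(iter_wells())
        for role, count in (
            ("negative_control", cfg.n_negative),
            ("positive_control", cfg.n_positive),
            ("growth_control", cfg.n_growth),
            ("stain_control", cfg.n_stain),
        ):
            for _ in range(count):
                wells.append(WellSpec(next(names), role))
        for _ in range(per_plate_capacity):
            try:
                drug_id, c = next(it)
            except StopIteration:
                break
            wells.append(WellSpec(next(names), "treatment", drug_id, c))
        maps.append(PlateMap(plate_id=f"plate{p + 1}", wells=wells))
    return maps


def simulate_screen(
    populations: Sequence[PopulationTruth] | None = None,
    drugs: Sequence[DrugTruth] | None = None,
    cfg: SimConfig | None = None,
    *,
    include_cells: bool = True,
) -> ScreenResult:
    """Simulate a full multi-plate screen.

    Lays out every drug x dose plus the control wells, draws counts and
    (optionally) per-cell marker intensities, and returns the planted truth
    for recovery tests. Fully reproducible from ``cfg.seed``.
    """
    if cfg is None:
        cfg = SimConfig()
    if populations is None:
        populations = default_populations()
    if drugs is None:
        drugs = make_drug_panel(16, rng=np.random.default_rng(cfg.seed))
    rng = np.random.default_rng(cfg.seed)
    plate_maps = _layout_plates(drugs, cfg)
    drug_by_id = {d.drug_id: d for d in drugs}

    count_rows = []
    cell_frames = []
    for pm in plate_maps:
        for w in pm.wells:
            drug = drug_by_id.get(w.drug_id) if w.drug_id else None
            realized: dict[str, float] = {}
            for pop in populations:
                curve = drug.effects.get(pop.label) if drug is not None else None
                if w.role == "treatment" and curve is None:
                    curve = GRCurveTruth(1.0, 1.0, 1.0)
                mean = expected_count(pop, w.role, curve, w.concentration_uM, cfg)
                n = _realize_count(mean, cfg, rng)
                realized[pop.label] = n
                count_rows.append(
                    {
                        "plate_id": pm.plate_id,
                        "well": w.well,
                        "population": pop.label,
                        "count": n,
                    }
                )
            if include_cells:
                cell_id = 0
                for pop in populations:
                    n = int(round(realized[pop.label]))
                    if n == 0:
                        continue
                    cols = _sample_cells(pop, n, w.role == "stain_control", rng)
                    cell_frames.append(
                        pd.DataFrame(
                            {
                                "plate_id": pm.plate_id,
                                "well": w.well,
                                "cell_id": np.arange(cell_id, cell_id + n),
                                **cols,
                            }
                        )
                    )
                    cell_id += n

    truth_rows = [
        {
            "drug_id": d.drug_id,
            "population": label,
            "grinf": curve.grinf,
            "gec50_uM": curve.gec50_uM,
            "hill": curve.h,
        }
        for d in drugs
        for label, curve in d.effects.items()
    ]
    cells = (
        pd.concat(cell_frames, ignore_index=True)
        if include_cells and cell_frames
        else (pd.DataFrame(columns=["plate_id", "well", "cell_id", *MARKERS])
              if include_cells else None)
    )
    return ScreenResult(
        plate_maps=plate_maps,
        counts=pd.DataFrame(count_rows),
        truth=pd.DataFrame(truth_rows),
        cells=cells,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# RPPA simulation

RPPA_MARKERS = (
    "p-AKT", "AKT", "p-ERK1/2", "p-S6RP", "Ki-67", "HER2", "p-HER2", "p-cMET",
)


def make_rppa_truth(
    drugs: Sequence[str],
    *,
    rng: np.random.Generator | None = None,
    planted: Mapping[tuple[str, str], float] | None = None,
    slope_sd: float = 0.3,
) -> dict[tuple[str, str], float]:
    """Per-(drug, marker) dose slopes of the log2 normalized signal.

    ``planted`` entries override the random background slopes, letting tests
    plant a known dose-dependent modulation.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    truth = {
        (d, m): float(rng.normal(0.0, slope_sd)) for d in drugs for m in RPPA_MARKERS
    }
    if planted:
        truth.update(planted)
    return truth


def simulate_rppa(
    drugs: Sequence[str],
    truth: Mapping[tuple[str, str], float],
    *,
    n_doses: int = 5,
    c_max_uM: float = 5.0,
    dilution_fold: float = 2.0,
    loading_sigma: float = 0.25,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an RPPA spot table (one lysate per drug x dose).

    True log2 antibody/total ratio of marker m in lysate (d, c) is
    ``slope(d, m) * t`` with t the dose rank scaled to [0, 1]; each lysate
    carries a multiplicative loading factor applied to both the antibody and
    the Sypro total-protein channel, so total-protein normalization removes
    loading variation by construction.
    """
    rng = np.random.default_rng(seed)
    doses = sorted(dose_series(c_max_uM, n_doses, dilution_fold))
    rows = []
    for d in drugs:
        for i, c in enumerate(doses):
            t = i / (n_doses - 1) if n_doses > 1 else 1.0
            loading = float(rng.lognormal(0.0, loading_sigma))
            total = 1000.0 * loading
            for m in RPPA_MARKERS:
                log2_ratio = truth[(d, m)] * t
                if noise_sigma > 0:
                    log2_ratio += float(rng.normal(0.0, noise_sigma))
                rows.append(
                    {
                        "lysate_id": f"{d}:{c:g}",
                        "drug_id": d,
                        "concentration_uM": c,
                        "marker": m,
                        "antibody_signal": 2.0**log2_ratio * total,
                        "total_signal": total,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# combination (synergy) simulation

def loewe_additive_fa(
    d_total: float,
    ratio: tuple[float, float],
    dm_a: float,
    m_a: float,
    dm_b: float,
    m_b: float,
) -> float:
    """Fraction affected of a Loewe-additive mixture at total dose d_total.

    Solves d_a/D_A(fa) + d_b/D_B(fa) = 1 for fa, with D_X(fa) the
    single-agent median-effect iso-effect dose. Brute-force root find; used
    as the independent oracle for additive combinations.
    """
    a, b = ratio
    w_a, w_b = a / (a + b), b / (a + b)

    def g(fa):
        r = fa / (1.0 - fa)
        return (
            d_total * w_a / (dm_a * r ** (1.0 / m_a))
            + d_total * w_b / (dm_b * r ** (1.0 / m_b))
            - 1.0
        )

    return float(brentq(g, 1e-12, 1.0 - 1e-12, xtol=1e-14))


def simulate_combination(
    dm_a: float,
    m_a: float,
    dm_b: float,
    m_b: float,
    *,
    ratio: tuple[float, float] = (1, 5),
    potency_factor: float = 1.0,
    doses: Sequence[float] | None = None,
    fa_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose / fraction-affected tables for two agents and their mixture.

    ``potency_factor`` scales the mixture's median-effect dose relative to
    the Loewe-additive prediction: 1.0 is exact additivity, 0.5 a mixture
    that needs half the additive dose (synergy), 2.0 antagonism. Optional
    Gaussian noise on logit(fa) yields replicate-style variability.
    Returns a long table with columns agent, dose_uM, fa.
    """
    rng = np.random.default_rng(seed)
    if doses is None:
        doses = sorted(dose_series(10.0 * max(dm_a, dm_b), 7, 2.0))
    rows = []

    def emit(agent, dose, fa):
        if fa_noise_sd > 0:
            logit = math.log(fa / (1 - fa)) + rng.normal(0.0, fa_noise_sd)
            fa = 1.0 / (1.0 + math.exp(-logit))
        rows.append({"agent": agent, "dose_uM": dose, "fa": fa})

    for d in doses:
        emit("a", d, (d / dm_a) ** m_a / (1 + (d / dm_a) ** m_a))
        emit("b", d, (d / dm_b) ** m_b / (1 + (d / dm_b) ** m_b))
    for d in doses:
        fa_add = loewe_additive_fa(d / potency_factor, ratio, dm_a, m_a, dm_b, m_b)
        emit("combo", d, fa_add)
    return pd.DataFrame(rows)
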