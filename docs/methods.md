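# Methods

## The GR response metric

Cell populations isolated from tumor biopsies divide at very different
rates (here ~220 h for the KRT19+ epithelial and ~135 h for the VIM+
stromal preset, i.e. 0.44 and 0.71 divisions over a 96-h assay). Over a
fixed assay window a cytostatic drug removes a larger *fraction* of the
divisions of a fast-growing population than of a slow one, so raw
end-count ratios are not comparable between populations. The GR value
normalizes per division:

    GR(c) = 2^( log2(x(c)/x_0) / log2(x_ctrl/x_0) ) − 1

* `x(c)` — end-of-assay count of the population in a treated well;
* `x_ctrl` — mean count in same-plate DMSO (vehicle) wells;
* `x_0` — mean count in same-plate 2 µM aphidicolin wells, a growth-arrest
  control standing in for the count at treatment start.

The inner ratio is "divisions realized under drug / divisions realized
untreated", so GR = 1 reproduces control growth, GR = 0 is complete
arrest, and GR < 0 is net cell loss, with −1 the total-kill limit.
`x(c) = 0` maps to exactly −1 by limit continuation rather than erroring,
because 5 µM staurosporine (kill control) wells can legitimately reach
zero. GR is undefined when the control did not grow (`x_ctrl ≤ x_0`);
that condition raises, and controls are never shared across plates.

**Control aggregation.** Control wells are averaged after a one-pass log10
filter: a well survives if |log10(x_i) − log10(center(x))| is below 1.5
decades (vehicle) or 1.0 decades (growth controls). The center is the
median of the unfiltered counts. A mean center is selectable but
self-defeating with a gross outlier: the mean is dragged within 1.5
decades of the outlier and more than that away from the good wells, so the
literal mean-filter keeps the outlier and rejects everything else. The
filter is applied once, not iterated. Both limits, the center, and the
minimum well count (2 per class) are configuration fields.

## Synthetic screen generator

The generator is the package's test bed and demo data source; it emulates
the screen design, not any particular tumor:

* 384-well plates, 1,000 cells seeded per well, 96-h assay;
* two stained populations (77.1% epithelial / 19.5% stromal presets, the
  remainder an unstained debris class) with doubling times 220 h / 135 h;
* 5-point dose series, 2-fold (default) or 3-fold dilutions from 5 µM;
* per plate: 14 DMSO negative, 6 staurosporine positive, 6 aphidicolin
  growth-arrest, and 6 secondary-antibody-only stain-control wells (the
  layout is a parameter; these defaults fill 32 wells, leaving 352
  treatment wells per plate, optionally replicated);
* log-normal marker intensities: background ln-median 10 RFU, positive
  markers ln-median 400–500 RFU, both with σ = 0.5 on the log scale, so
  the 99th-percentile background cutoff (~32 RFU) separates classes with
  essentially no false negatives and a 1% nominal false-positive rate;
* Poisson count noise by default (`noise="none"` keeps exact expectations).

**Growth model.** Each population grows exponentially and the drug acts on
the division rate: with k(0) = 1/doubling_time and GR_true(c) the planted
curve,

    N(c) = n_seed · fraction · 2^( k(c)·T ),   k(c) = k(0) · log2(GR_true(c) + 1).

This family is chosen because the GR computation inverts it *exactly*:
x_ctrl = base·2^(k0·T), x_0 = base, so the GR of a noise-free simulated
well equals GR_true(c) to machine precision at every dose. That makes the
generator a closed-form oracle for the whole normalization path. Cell
death is a negative net rate, not an explicit death compartment — only end
counts are observed, so the two are indistinguishable here. Growth-arrest
wells freeze counts at seeding; kill-control wells use GR_true = −1
(expected count 0).

With `noise="none"` the expected counts are non-integral reals; the counts
table carries them exactly (preserving the 1e-9 inversion guarantee) while
the per-cell table necessarily rounds to whole cells.

**What the generator does not emulate.** Spatial plate effects (edge
evaporation, dispensing gradients), segmentation errors and cell clumping,
marker bleed-through, drug-induced marker modulation coupled to death,
non-exponential growth (confluence, lag phases), and pharmacological
deviations from the three-parameter GR curve. Passing recovery tests
therefore demonstrates correctness of the *estimators* under the stated
noise model, not robustness to every artifact of real screens.

## Dose–response fitting

The three-parameter family GR(c) = GRinf + (1 − GRinf)/(1 + (c/GEC50)^h)
is fit by bounded least squares (GRinf ∈ [−1, 1], GEC50 ∈ [c_min/100,
c_max·100], h ∈ [0.1, 10]) with a deterministic multi-start: GEC50 on a
5-point log grid over the tested doses × h ∈ {0.5, 1, 2, 4}, a loose
first pass (analytic Jacobian), then one tight polish of the best start.
Fits are unweighted; replicate wells at a dose are reduced to their median
before fitting; refitting permuted rows returns identical parameters. If
no start converges the fit is flagged and falls back to a flat curve at
the mean GR.

Derived metrics: GR50 solves the fitted curve = 0.5 analytically and is
reported only when the crossing lies within [c_min/10, c_max·10]; the
growth-rate-corrected IC50 estimate is reported as the curve midpoint
GEC50 (the crossing definition of an "IC50" on the GR scale is not unique,
so the midpoint is used and GR50 carried alongside), suppressed when the
efficacy window 1 − GRinf < 0.1.

**Identifiability.** From a 5-point series the asymptote GRinf is only
determined if the curve levels off within the tested range; with GEC50
near the top dose the asymptote is pure extrapolation and no estimator can
recover it. The bundled recovery panel therefore draws GEC50 from
0.15–1.0 µM with h ≥ 1.2 (against the 0.31–5 µM series) — a statement
about assay design, equally true of real screens.

**Noise propagation.** Poisson counting noise enters GR through the
per-division exponent: sd(GR) ≈ (GR+1)·CV(x)/D where D is the untreated
divisions over the assay. At 1,000 cells/well and D = 0.44, a 3% count CV
becomes ~0.07–0.1 GR noise, and a 19.5% minority population (≈200 seeded
cells) is ~2× worse. The stochastic recovery study consequently uses a
homogeneous suspension (fraction 1.0, 135 h doubling) in triplicate wells
— 20 drugs × 5 doses × 3 + 32 controls = 332 wells, one plate — which is
how a scientist would design a calibration run rather than a discovery
screen.

## Selectivity calling

A drug is *cytotoxic* on a population when the fitted curve's minimum
within the tested doses (the value at the top dose; the curve is monotone)
falls below 0 — net cell loss on the GR scale — and *selective* when
cytotoxic in exactly one population. The 0 threshold is a configuration
field. Per-drug paired Student's t-tests over the five dose-matched GR
pairs are reported with Benjamini–Hochberg FDR across the panel (raw p is
kept alongside); a zero-variance difference vector yields p = 1 (no
evidence of difference). Cross-population agreement is summarized by the
Pearson correlation of per-drug mean GR.

## RPPA normalization

Each spot's antibody signal is divided by its Sypro total-protein signal
(cancelling per-lysate loading exactly — the generator plants a
multiplicative loading factor on both channels to verify this), log2
transformed (base selectable), replicate spots averaged on the log scale,
and z-scored per marker across all conditions with the sample (n−1)
standard deviation (divisor and whole-matrix scope selectable). |z| > 2
marks significant modulation. Marker ordering for heat maps uses
agglomerative clustering (Euclidean distance, average linkage); SciPy's
linkage breaks ties by observation index, i.e. input row order, so the
leaf order is deterministic.

## Combination index

Median-effect fits regress log10(fa/(1−fa)) on log10(D) using only points
with fa strictly in (0, 1); Dm = 10^(−intercept/m). Fraction affected
defaults to 1 − x(c)/x_ctrl from raw relative viability, clamped to
[1e-6, 1−1e-6] before the logit (an fa-from-GR mapping, (1−GR)/2, is
selectable). The fixed-ratio mixture is fit as a single agent; at effect
level fa (default 0.5, i.e. CI50) the mixture dose splits by the molar
ratio and CI = d_a/D_A + d_b/D_B against the single-agent iso-effect
doses. A sham self-combination gives CI = 1 identically, and CI is
invariant to a consistent change of dose units. Dosing schedules are
identical pipelines on separate datasets (the schedule is a data label);
replicate CIs per schedule are ranked by mean and compared with unpaired
Student's t-tests, skipped with a warning when any schedule has a single
replicate. The generator's Loewe-additive oracle solves
d_a/D_A(fa) + d_b/D_B(fa) = 1 by root finding on a dose grid, providing
an independent check that additive constructions score CI ≈ 1 and a
mixture planted at half the additive dose scores CI ≈ 0.5.

## Problem sizes and numerical choices

The test suite and the acceptance script run screens of 8–125 drugs (125
with a 22-drug planted selective subset, mirroring the scale of a real
single-patient panel), 16–20-drug recovery studies, 6-drug × 5-dose RPPA
tables, and 6–7-point median-effect series; these sizes make every planted
quantity recoverable while keeping a full run to tens of seconds. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; equal seeds give byte-identical result
bundles. Degenerate inputs (zero counts, constant marker rows, saturated
fa, non-growing controls, all-filtered control wells) raise typed errors
naming the offending entity rather than propagating NaNs.
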