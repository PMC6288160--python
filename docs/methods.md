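# Methods

## The model

Two *E. coli* strains form a cross-protection mutualism: an
ampicillin-resistant strain (AmpR, density `N1`, cells/µl) secretes
β-lactamase that deactivates ampicillin (`A1`, µg/ml), and a
chloramphenicol-resistant strain (ChlR, `N2`) deactivates chloramphenicol
(`A2`) intracellularly. Each strain therefore protects the *other* strain
from the antibiotic it is sensitive to. Within one 24 h growth cycle

    dN1/dt = γ1(A2) · N1 · (1 − (N1+N2)/K)
    dN2/dt = γ2(A1) · N2 · (1 − (N1+N2)/K)
    dA1/dt = −Vmax · A1/(Km + A1) · N1(t=0)
    dA2/dt = −c2 · A2 · N2

with growth rates

    γ1(A2) = 0                     for t < t_lag
             γ1R / (1 + A2/I12)    for t ≥ t_lag
    γ2(A1) = 0                                        for t < t_lag
             −γ2D + (γ2R + γ2D)/(1 + A1/I21)          for t ≥ t_lag

Chloramphenicol is bacteriostatic (γ1 ≥ 0 always); ampicillin is
bactericidal (γ2 → −γ2D at high concentration). Ampicillin degradation is
Michaelis–Menten and driven by the *initial* AmpR density of the cycle:
free enzyme carried over from the previous day dominates, and its amount
is proportional to the AmpR inoculum. This frozen driver is the inoculum
effect that makes the day-to-day map strongly nonlinear. Degradation
terms are not lagged — carried-over enzyme and intracellular deactivation
act from t = 0.

## The daily protocol

One simulated day is: grow 24 h → measure (end-of-growth densities and
the strain ratio) → migrate (a fraction `m` of each whole culture, cells
and medium, swaps into the partner patch, both transfers computed from
pre-migration states so pairwise totals are conserved exactly) → dilute
1:100 into fresh medium with antibiotics. Serial dilution makes the
dynamics a discrete map; oscillation periods are integer numbers of days.

Optional protocol noise multiplies each transferred migration fraction
and each dilution factor by an independent lognormal factor with mean 1
and CV `noise_cv` (default 0.15 in noisy ensembles). Lognormal keeps the
factors positive; one draw per patch per dilution and one per directed
transfer, in a fixed order, so a seed reproduces a run exactly.

Subpopulations whose post-dilution density falls below the extinction
threshold are set to zero. The default threshold, 0.005 cells/µl, is one
cell in the 200 µl culture volume of the experimental protocol; densities
below it are unphysical. Extinction of a strain is therefore absorbing
within a patch (only migration can re-seed it), and a run stops when all
four subpopulations are gone.

Residual antibiotic is carried into the next day at 1/(D·f) on top of the
fresh concentration (`antibiotic_carryover`, default on; the effect is
numerically negligible and the flag exists because either reading of the
protocol is defensible).

## Parameters

All rate constants live in `ModelParams`; the shipped defaults are a
calibrated set (the package's own choice) selected so that the standard
environments reproduce the system's qualitative repertoire:

| parameter | default | meaning |
|---|---|---|
| γ1R | 0.593 /h | max AmpR growth rate |
| γ2R | 0.736 /h | max ChlR growth rate |
| γ2D | 1.374 /h | max ChlR death rate under ampicillin |
| I12 | 4.01 µg/ml | chloramphenicol half-inhibition of AmpR |
| I21 | 2.18 µg/ml | ampicillin half-effect on ChlR |
| K | 1e5 cells/µl | shared carrying capacity |
| Vmax | 0.0857 µg/ml/h per cells/µl | max ampicillin deactivation per initial AmpR |
| Km | 0.676 µg/ml | Michaelis constant of deactivation |
| c2 | 2.44e-4 /h per cells/µl | chloramphenicol deactivation per ChlR |
| t_lag | 2.49 h | lag phase |
| T_cycle | 24 h | growth-cycle duration |

The two named environments are benign (10 µg/ml ampicillin, 8 µg/ml
chloramphenicol) and harsh (10/16). Under the defaults:

- benign, m = 0: asynchronous period-3 oscillations of log10(N1/N2)
  spanning several decades;
- benign, increasing m: period-3 → irregular band → period-4 points →
  synchronized period-3 (complete synchronization from m ≈ 0.17);
- harsh, m = 0: deterministic global extinction on day 8–9;
- harsh, intermediate m (≈0.04–0.10): deterministic persistence on an
  antisynchronous, largely period-2-like attractor, chaotic
  (λ ≈ 0.1/day) near the low-m onset m ≈ 0.040–0.042 and regular
  (|λ| ≤ 0.02/day) above.

Any value can be overridden from YAML (`load_params_file`, `load_config`);
unknown keys are rejected.

## Numerical choices

- Within-cycle integration: adaptive Dormand–Prince 5(4) compiled with
  numba, rtol 1e-8 / atol 1e-10 by default. The multi-decade density
  swings need tight tolerances for a reproducible bifurcation diagram.
  The cycle is split at `t_lag` so no step crosses the growth-rate
  discontinuity. A SciPy LSODA implementation of the same cycle is kept
  as the readable reference; the test suite requires agreement to 1e-6.
- Components driven below zero by truncation error are clamped to zero
  at cycle end (γ2 < 0 makes small negatives possible).
- Analysis operates on log10(N1/N2) with an additive tolerance of 0.1
  decades: the ratio spans ~4 orders of magnitude, so log space is the
  natural metric. The period detector returns the smallest p with
  |x[t] − x[t−p]| ≤ tol across the trailing 50-day window, `irregular`
  if none exists with p ≤ 25. Asymptotic value sets are single-linkage
  clusters (gap > tol starts a new cluster) of the trailing window.
- Synchronization follows the experimental criterion: peaks (strict
  local maxima over a 3-day window, plateau ties to the earliest day) of
  the two patches must coincide day-for-day over the trailing 40% of the
  series, with at least two oscillation cycles available; otherwise the
  pair is asynchronous (or undetermined if too few cycles).
- Largest Lyapunov exponent: Rosenstein-style nearest-neighbour
  divergence on delay embeddings (dimension 4, delay 1 day, Theiler
  window 6 days, linear fit over divergence times 1–10 days, ≥500-day
  series). Validated against ln 2 for the r=4 logistic map (±10%) and
  against periodic orbits (estimates within ±0.02/day of zero, which is
  also the positivity tolerance used when classifying chaos).
- Survival time τ is the last day alive (extinction day − 1), capped at
  the horizon for censored runs; P(τ) is the fraction of runs surviving
  ≥ τ; the threshold-day probability carries the exact standard error of
  a proportion. Ensembles derive per-run seeds from one root seed via
  `SeedSequence.spawn`, so any single run is reproducible.

## Synthetic data

`generate_periodic_fixture` produces daily log-ratio series with a known
integer period, a chosen amplitude in decades (default 4, matching the
observed dynamic range) and additive Gaussian noise — the ground-truth
fixtures for every analyzer. `emulate_measurements` mimics the daily
measurements: an optical-density proxy (multiplicative lognormal noise,
default CV 2%) and a binomial count model for the flow-cytometry strain
fraction. The emulation has no gating artifacts, plate effects or
density-dependent measurement error; passing tests on it demonstrate the
analyzers' correctness on clean oscillatory signals, not robustness to
every artifact of real plate-reader or cytometry data.

## Problem sizes

The standard analyses use 1000 dilution cycles with the last 50 analysed
(bifurcation), 2000 post-transient cycles (Lyapunov), and 200–300 noisy
runs per migration rate at a 10-day horizon (survival). These sizes give
reproducible periods and exponent estimates while keeping a full
bifurcation scan (126 migration rates) in the low minutes on one core.

## Design choices where the protocol was open

- Migrated liquid carries antibiotics along with cells: transfers are
  fixed volumes of whole culture.
- Noise is applied per event (per patch-dilution, per directed
  transfer), not once per day.
- The three oscillation "phase states" used as initial conditions are
  the start-of-day states of the last three cycles of a converged benign
  run — end-of-cycle states passed through the protocol's own dilution —
  so they are directly usable as inocula. Survival ensembles jitter
  their densities multiplicatively with CV 0.1 and always assign the two
  patches different phases.
- The Lyapunov scan runs in the harsh deterministic condition, where the
  antisynchronous dynamics live; a flag switches to benign.

## Limitations

- The calibrated defaults reproduce the qualitative regimes above but
  not every quantitative feature reported for the original parameter
  set, which is not public. Two known gaps, both documented by failing
  (intentionally strict) checks in `tests/test_acceptance.py`:
  the benign period-4 points near m ≈ 0.16 are embedded in the
  synchronized period-3 regime rather than flanked by irregular bands;
  and the noisy 10-day survival probability keeps rising up to m ≈
  0.12–0.15 instead of peaking near m = 0.05. The latter traces to two
  robust features of this parameter family: the m = 0 harsh collapse
  (day 8–9) is marginal enough that 15% protocol noise re-excites the
  mutualism in roughly half the runs, and at strong coupling the
  chaotic antiphase dynamics resist migration-induced synchronization,
  so coupled pairs keep rescuing each other instead of collapsing
  jointly.
- The model has no demographic stochasticity (densities are continuous
  between the threshold and K), no within-day migration, no evolution of
  resistance, and exactly two patches.
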