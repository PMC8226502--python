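# Methods

## Scope and model

`chromspace` models reversed-phase gradient UHPLC separations of a small
ionizable-drug mixture well enough to support Quality-by-Design method
development: calibrating retention models from a small screening design,
mapping where the separation meets a resolution criterion, and stress
testing the chosen working point in silico.

### Retention law

Each compound at a fixed temperature and pH follows the base-10
linear-solvent-strength (LSS) law

    log10 k(phi) = log_kw − S · phi,

with `phi` the organic fraction (0–1 internally; %B at all file/CLI
boundaries), `log_kw` the extrapolated retention factor in pure aqueous
eluent and `S` the solvent sensitivity. Base 10 follows chromatographic
convention, hence the 2.303 factors in the gradient solution.

### Gradient elution

The programmed ramp reaches the column after the dwell time
t_D = V_D / F; the inlet composition is the dwell-delayed, clamped linear
program. Band migration is modelled with the inlet-referenced migration
integral ∫ dt / (t₀ k(φ_inlet(t))) = 1 (the usual LSS simplification that
neglects the gradient's transit across the column), giving three regimes:

1. elution before the gradient arrives → isocratic, t_R = t₀(1 + k₀);
2. elution during the ramp → the closed-form LSS solution;
3. elution after the ramp → solved numerically by the general migration
   solver (analytic constant segments, dense-trapezoid ramp cumulative
   with adaptive-quadrature refinement). Regime 3 is rare in the designs
   used here; a numerical path was preferred over more closed-form
   case-work.

The same numerical solver accepts *any* retention law k(φ), which is how
the synthetic-data generator produces its "laboratory" data without going
through the fitted model class.

### Peak widths and resolution

Peaks are Gaussian with σ = (t₀/√N)(1 + k_e), where k_e is the retention
factor at the composition surrounding the band as it leaves the column.
`N` is an *apparent*, gradient-compressed plate number (default 120 000);
no separate peak-compression factor is modelled — it is absorbed into N.
This is a deliberate fixture-level simplification: real widths fold in
instrument dispersion and compression physics that a method-modelling
exercise does not need resolved. Resolution is the width-based
Rs = 2|Δt_R|/(4σ_a + 4σ_b); the critical resolution is the minimum over
*adjacent* peaks in elution order, ties resolved toward the
earlier-eluting pair, and peak-order ties broken lexicographically by
compound id everywhere for determinism.

## Calibration

The screening design crosses 2 gradient times (1.5/4.5 min), 2
temperatures (20/50 °C) and 3 pH values (2.8/4.6/6.4) at 0.8 mL/min and a
10→80 %B ramp — 12 runs. At each (T, pH) corner the two gradient runs are
inverted into (log_kw, S) by nested bracketed root finding (outer on
S ∈ [0.5, 100], inner on log_kw ∈ [−2, 10], tolerance 1e−10; brackets
fixed for reproducibility, the upper S end shrunk automatically when a
steep trial S cannot reproduce the observed retention at all). Two equal
retention times mean a gradient-insensitive solute; it is returned with
S = 0 and flagged. A corner missing either run (e.g. a degraded peak) is
left unfitted and flagged; a compound with no fittable corner is dropped
with a warning.

Corner parameters are interpolated to arbitrary (T, pH):

* linearly in 1/T(K) — the van't Hoff convention; over 20–50 °C the
  difference from linear-in-°C is small but the kelvin form is the
  physically motivated one;
* quadratically (3-point Lagrange) in pH — three pH levels support
  exactly a parabola;
* as a tensor product, so T-then-pH and pH-then-T orders agree to
  machine precision (asserted in tests).

Parameters, not predicted times, are interpolated: predictions then stay
self-consistent when tG, flow or the %B endpoints change downstream.
Queries may extrapolate up to 10% of each calibrated range (with a
warning); beyond that they are refused.

## Design space and working point

Rs_crit is evaluated on explicit (tG, T, pH) grids (default density
0.1 min × 1 °C × 0.1 pH, finer than the robustness levels); mapping is a
pure function, so re-runs are bit-identical and refined grids reproduce
shared nodes exactly. The working point is chosen on the grid only — no
continuous optimisation — as the passing node with the largest
L∞ "robustness radius" on axes normalized to [0, 1]: the half-width of
the largest axis-aligned box around the node that stays inside the grid
and contains no failing node (failing nodes at exactly the radius lie on
the open boundary of the box). L∞ geometry mirrors the ±1-level boxes of
the factorial robustness study. Ties prefer smaller tG (shorter
analyses), then smaller T, then smaller pH. Sub-regions are always
re-evaluated on a fresh grid, never sliced.

## Virtual robustness study

Six factors — tG, T, pH, flow, %B_start, %B_end — at three levels each
(defaults: 2.7/3.0/3.3 min, 38/40/42 °C, 5.8/6.0/6.2, 0.72/0.80/0.88
mL/min, 9/10/11 %B, 79/80/81 %B) are crossed into 3^6 = 729 combinations.
Enumeration order is fixed and documented: factor order (tG, T, pH, flow,
%B_start, %B_end), rightmost factor fastest, 1-based indices; published
scenario numberings from other tools use their own undocumented orders and
are not matched. Flow rescales the dead and dwell times; the %B endpoints
rescale the gradient limits. A failed prediction is recorded as a
missing Rs (counted as a failure) rather than aborting the study. The
summary reports the success rate against the criterion (default
Rs_crit ≥ 2.0), the worst combinations (stable ascending sort) and
per-factor level means of Rs_crit (main effects; the mean of a factor's
level means equals the grand mean in the balanced design).

## Quantitation

Pairwise UV response correction factors are f[i][j] = slope_i / slope_j;
printed tables of this kind are orientation-ambiguous
(row-relative-to-column vs the reverse), so the orientation here is a
documented convention and every consistency and invariance check is
orientation-agnostic. Missing lower-triangle entries are reconstructed by
reciprocal symmetry on load; pairs absent entirely stay missing.
Multiplicative consistency |f_ij · f_jk − f_ik| is validated over all
fully-present triples (default tolerance 0.02, matching 2-decimal report
rounding, which is half-up). Corrected area-percent weights raw areas by
the reference row's factors; with full-precision factors the result is
provably independent of the reference choice and of global area scaling.

## Synthetic ground truth

The packaged nine-compound mixture emulates an apixaban reaction mixture.
Its truth is deliberately *richer* than the fitted model class:

* ionizable solutes are pH-weighted mixtures of a neutral and an ionized
  species, k = (k_n + k_i·10^(pH−pKa))/(1 + 10^(pH−pKa)) — a sigmoid in
  pH, where the calibration fits a local quadratic;
* temperature enters through a van't Hoff shift, linear in 1/T(K),
  referenced to 40 °C;
* one compound (Stm2) degrades — complete peak loss, the simplest
  testable contract — at or beyond 80 °C and pH 6.4 simultaneously.

Run tables are forward-simulated through the numerical migration solver
(never the fitted model), with seeded Gaussian retention jitter and
relative area noise; all randomness flows from the single mandatory seed.

The constants are frozen fixture data authored once by
`scripts/tune_fixture.py` (shipped for transparency), chosen so that at
the nominal working point the elution order is Int6 < Stm1 < Apixaban <
Int2 < Int1 < Int5 < Stm2 < Int4 < Int3 inside a 3-minute analysis, the
critical pair is Int4/Int3 at Rs ≈ 2.4, and all peak widths fall in
(0.002, 0.02) min under the default plate number. Specific choices worth
recording:

* With N = 120 000 and the width model above, the sigma band pins the
  fixture to small solvent sensitivities (S ≈ 2.2–3.0) and log_kw ≈
  1.3–2.3; the Int4/Int3 gap at Rs 2.4 is then ≈ 0.021 min. Parameter-
  recovery sweeps still exercise the broader S ∈ [3, 30] range.
* The acidic Int6 carries pKa = 3.85 with a 0.30 log-unit neutral/ion
  retention split: the pKa sits where the quadratic-in-pH model tracks
  the sigmoid truth best against the 2.8/4.6/6.4 calibration corners
  (≤ 0.003 log units over pH 5.4–6.4, i.e. ≤ 0.01 min), while Int6 still
  loses retention monotonically — about two-fold — across the calibrated
  pH range. A transition centred mid-range would defeat a three-point
  quadratic and is physically avoidable by buffer choice anyway.
* The critical pair Int4/Int3 has nearly equal S (2.90/2.88) and equal
  van't Hoff slopes, so its selectivity scales smoothly with gradient
  time instead of collapsing at the short-tG edge of the mapped region.

### What the generator does and does not emulate

It reproduces the *structure* of the real problem — gradient/temperature/
pH retention behaviour, a pH-sensitive acid, a degradable solute, a tight
critical pair, measurement jitter — but not raw detector traces, peak
asymmetry, pressure effects, column ageing or inter-batch variability.
Passing tests therefore demonstrate that the algorithms are correct and
the workflow behaves as designed under realistic retention physics, not
that any particular laboratory separation is reproduced numerically.

## Numerical choices

* Root finding: `brentq` with fixed brackets; solver tolerance 1e−10
  (retention times reproduced to ≤ 1e−6 min on noise-free fits).
* Migration solver: 4001-point trapezoid cumulative over the ramp plus
  quadrature-refined crossing; agreement with an independent adaptive-
  quadrature oracle ≤ 1e−4 min (typically ≤ 1e−7).
* Degenerate inputs: S = 0 or an unretained sentinel (log_kw = −∞) fall
  back to isocratic/dead-time limits; b = 0 is impossible by construction
  except through S = 0.
* Report precision: retention times and Rs to 2 decimals, factors to 2
  decimals half-up; internal computation always at full precision.

## Problem sizes

The shipped studies use the 12-run design, 729-run factorial, map grids of
roughly 10³ nodes, a 1000-draw closed-form-vs-oracle sweep and 50 noisy
calibration replicates — sizes chosen to characterise the method while
keeping the whole suite interactive (tens of seconds).

## Known limitations

* The inlet-referenced migration integral ignores the gradient's
  within-column transit; the closed form and the oracle share this
  assumption (they are solutions of the same integral by different
  means), so the oracle validates the solution, not the approximation.
* No pressure modelling, detector dispersion, non-linear gradients or
  peak detection from raw signals.
* The quadratic pH model is local: it tracks a sigmoid only when the
  ionization transition does not straddle the calibrated pH range
  unsampled; strongly mid-range pKa values need more pH levels.
* Degradation is binary (peak present/absent); partial degradation and
  area trends are not modelled.
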