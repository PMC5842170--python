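# Methods

## The model chain

The package links three empirical relationships measured on a
seven-sewer pilot system (8 m PVC pipes, 57 mm inner diameter, slope 8‰,
synthetic sewage at 20.0–25.0 °C, wall-shear stresses 0.5, 0.8, 1.12,
1.29, 1.45, 2.0 and 2.5 Pa):

1. **Shear surface.** F(I, n, v) is a fitted ten-term quadratic response
   surface (coefficients reproduced bit-faithfully in
   `sewerch4.hydraulics.SHEAR_COEFFS`). It is a calibration product of
   PIV-validated CFD on that pilot geometry, not a mechanistic law: the
   package only evaluates, differentiates and inverts it. Inputs outside
   I ∈ [0, 10] ‰, n ∈ [0, 1], v ∈ [0, 3] m/s warn (extrapolation) but
   never error, and a negative evaluated F is returned as-is with a
   warning — fidelity to the printed polynomial over physical
   plausibility. The symbol table gives I in ‰ and the package takes that
   literally (I = 8 for the pilot), although the coefficient magnitudes
   hint the surface may have been calibrated on the dimensionless
   gradient; `slope_as_fraction=True` supplies the other convention. We
   document both and decide nothing the data cannot decide.
2. **Biomass quadratic.** X(F) = a·F² + b·F + c with defaults
   a = −0.0485, b = 0.161, c = −0.0142 (X in kg per sewer, F in Pa).
   Concave with an optimum at −b/(2a) ≈ 1.66 Pa: moderate shear thickens
   and densifies the biofilm, high shear strips it. The quadratic is
   positive only on ≈ [0.09, 3.23] Pa; evaluation outside warns, and
   feeding a negative X to the production law is an error (or an explicit
   clamp-to-zero policy).
3. **Production law.** Q = Y·X·θ^(T−20)·HRT, Q in mg CH₄ per litre of
   wastewater per day, θ = 1.05 the standard sanitary-engineering
   temperature base, T in °C, HRT in hours. **Units of Y:** Y is an
   effective fitted coefficient. With Q in mg/(L·day), X in kg and HRT
   in h, Y absorbs the per-litre and per-hour conversion factors; it is
   not a measurable stoichiometric yield. Because the experiment's T and
   HRT were not separately recorded with the rates, only the composite
   c* = Y·θ^(T−20)·HRT is identifiable, and the fitting layer estimates
   c* (`yield_coefficient(T, HRT)` decomposes it on request).

Two older correlations (C = 5.24×10⁻⁵·(A/V·HRT) + 0.0015 and its
temperature-corrected successor C = 6×10⁻⁵·1.05^(T−20)·(A/V·HRT) +
0.0015, both kg CH₄/m³) are included for comparison; they predict from
wetted surface area rather than biomass.

## Fitting and validation statistics

* The biomass quadratic is fitted by ordinary least squares (statsmodels
  OLS on the design [F², F, 1]); at least three distinct stresses are
  required, otherwise the design is rank-deficient and the fit refuses.
  No observation weighting: replicate variances are not available.
* The proportional methane model is fitted through the origin in closed
  form, c* = ΣXQ/ΣX², with X evaluated from a fixed biomass quadratic.
  Its standard error is √(σ̂²/ΣX²) with σ̂² = SSres/(n−1).
* R² is centered by default (1 − SSres/Σ(Q−Q̄)²) — for a through-origin
  model this is a convention, not a theorem, and the uncentered variant
  is available. A zero-variance response makes the quadratic fit's R²
  0 by convention and the statistic NaN elsewhere. Applied to the seven
  packaged average rates the proportional fit gives c* = 16.5519 and
  centered R² = 0.9558.
* Percent difference is 100·|obs − pred|/obs, referenced to the
  measurement; `pct_diff_range` reports its min and max across sewers.

## Data reduction choices

* **Maturity day**: earliest observation day d such that all record
  means in [d, d + 10 days] stay within 5% of the window mean — growth
  and sloughing in equilibrium. Window and tolerance are configurable;
  the defaults reproduce a ≈ 40–45-day maturation on the default
  synthetic curves.
* **Mean thickness** is the plain arithmetic mean of the nine chip
  points; no outlier rejection.
* **Penetration depth** interpolates linearly between the 100-µm
  microprofile steps to the threshold crossing (default threshold 0 with
  0.05 mg/L absolute tolerance, matching microelectrode resolution);
  published depths finer than the step (2050 µm) imply exactly such
  interpolation.
* **Microorganism amount**: X = ρ·δ·A − EPS. EPS may be supplied as a
  mass (canonical — the TS method measures mass) or as a fraction of TS;
  an EPS mass exceeding ρ·δ·A is an inconsistency error, not a clamp.
* **Abundance tables** are stored exactly as published, zeros included,
  with no silent renormalization. Column sums are checked against 100%
  and violations warn with the actual sum; the packaged reference table
  deliberately retains its published 105.00% column at 2.0 Pa.
  `renormalized()` rescales for downstream use. The published claim of a
  53.08% Methanospirillum increase between 1.29 and 2.0 Pa is not
  derivable from the table's proportions (which give 38.15%) and is
  presumably computed on absolute amounts; the package reproduces only
  what the table supports.
* In the end-to-end pipeline the mature thickness is the **median** of
  post-maturity record means: on noisy series the stability criterion
  occasionally fires one sample early (≈ 4% of sewers at default noise),
  and the median is insensitive to the one or two pre-plateau records
  that then leak in.

## The synthetic generator

`sewerch4.simulate` emulates the seven-sewer experiment with all defaults
fixed at the study's conditions; it exists so the analysis chain can be
exercised end to end against known truth.

* **Thickness curves** (sampled every 5 days for 60 days, nine jittered
  points per record): logistic rise reaching a 25% overshoot of the
  mature thickness at day 25, a hold at the maximum to day 30, then a
  linear slough of 20% of the peak ending at day 39, then a plateau at
  the mature value. Plateau values interpolate the published
  2.4/2.7/2.2 mm at 0.8/1.29/2.0 Pa (linear extrapolation outside). The
  shape was chosen so that *every* pre-plateau 10-day window violates the
  5% stability criterion with ≥ 2% margin: detected maturity is then
  day 40, deterministically at zero noise, consistent with the reported
  ≈ 45-day maturation. A literal rise–slough–hard-plateau curve fails
  this: a flat-topped logistic reads as a false plateau near the peak,
  and the criterion fires there or at the slough end.
* **Density**: linear in F through the published 51/62/80 kg/m³ anchors,
  ramping to the mature value by day 10 and constant after, with
  4 kg/m³ per-record Gaussian scatter (the published ± 3–5).
* **DO profiles**: linear decline from 8 mg/L at the surface (near
  air-saturation, as expected under a manhole-ventilated free surface)
  to zero at a penetration depth interpolating the published
  2050/1850/1450 µm. Readings on the 100-µm instrument grid plus the
  exact penetration point (the published depths are off-grid, so a pure
  grid cannot reproduce them under linear interpolation); noisy profiles
  are clipped at zero and re-monotonized by a running minimum.
* **Methane**: Q_true = c*·X(F) with c* = 16.55 (the value the published
  rates themselves give) and the published quadratic as truth; six daily
  values with 5% relative Gaussian scatter, negatives redrawn.
* **Community**: per-taxon linear interpolation between the renormalized
  reference columns, Dirichlet-perturbed (concentration 300, keeping
  zero taxa at zero) and renormalized to 100%. Valid for F in
  [0.8, 2.0] Pa; the bundle writer clamps the 0.5 and 2.5 Pa sewers to
  the nearest anchor — extrapolating compositions beyond the observed
  range has no support in the data.
* **Per-sewer wetted areas** are set so that ρ(F)·δ(F)·A·(1 − EPS
  fraction) equals the biomass truth X(F); the resulting ≈ 0.4–0.7 m²
  match the wetted perimeter of an 8 m pilot pipe. EPS defaults to 15%
  of TS. The truth file records all generating parameters and is never
  read by any fitting path.
* One `numpy` Generator seeded from `ExperimentConfig.seed` drives
  everything; equal seeds give byte-identical bundles.

What the generator does **not** emulate: hourly gas-chromatograph
structure within a day (only daily aggregates), substrate-concentration
effects (the COD-400 vs COD-200 contrast), pipe-size effects,
between-chip spatial correlation, or any non-Gaussian measurement error.
Passing recovery tests therefore show that the estimators are correct
and well-conditioned for data of this shape and noise scale — not that
the empirical model generalizes beyond the pilot's conditions.

## Identifiability of the quadratic's constant term

Parameter recovery on default synthetic experiments (20 seeds) returns
a and b with ≈ 3% median relative error and c* within 1.5% always, but
the constant c = −0.0142 kg only to ≈ 18% median. This is a property of
the design, not a bug: |c| is an order of magnitude below the observed
X values (0.05–0.12 kg), the design has no observations below 0.5 Pa,
and error propagation through the normal equations gives c a standard
error near 2σ for per-sewer noise σ — even σ of 1% of signal leaves a
≈ 7% median error, and single 5%-noise observations leave ≈ 32%.
Recovery of the coefficient vector is therefore judged jointly (pooled
median relative error, ≈ 3.5% at default noise) alongside the
per-coefficient bounds for a and b. Any application that cares about
X near the validity limits should treat c as weakly identified.

## Numerical notes

* The velocity inversion solves the exact quadratic (discriminant
  formula); round-trip error is < 10⁻⁹ Pa across the calibration
  envelope. When both roots are non-negative the smaller is returned by
  default (`root_policy="larger"` for the other); tiny negative roots
  from round-off (> −10⁻¹²) count as zero.
* Maturity scanning evaluates candidate start days at observation days
  only and requires at least two records per window.
* Threshold crossings in DO profiles clamp the interpolation parameter
  to [0, 1], so a record already at the threshold is returned exactly.

## Known limitations

* All three fitted forms are calibrations of one pilot system; nothing
  constrains them at other pipe diameters, slopes or substrate loads.
* The production law inherits the biomass quadratic's validity window
  ≈ [0.09, 3.23] Pa; outside it the chain errors or clamps by policy.
* Temperature enters only through θ^(T−20); the fitted c* confounds Y,
  T and HRT, and decomposing it requires externally supplied T and HRT.
* The abundance summaries start from published relative abundances;
  no sequence-level processing is included or intended.
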