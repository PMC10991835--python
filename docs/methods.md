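# Methods

## Thermal time

Daily heat accumulation is `max(0, (T_max + T_min)/2 − T_base)` with
`T_base = 10 °C`, the long-standing grapevine default. Negative daily
values are clamped to zero — the universal convention in viticulture heat
summation, although the bare formula would subtract; clamping is
configurable (`clamp=False`) for sensitivity checks. No upper temperature
cap is applied. Dates are whole calendar days; the cumulative series is a
prefix sum from the chosen start date (the first Brix sampling date), and
lookups are exact daily values with no interpolation. Gaps or inverted
temperatures in the weather table are hard errors naming the offending
dates, because a silent gap would bias every downstream rate.

## Ripening kinetics

Berry total soluble solids follow
`S(x) = S_min + (S_max − S_min)/(1 + exp(b(x − x₀)))` on the GDD axis.
The curve is fitted as printed — a logistic in x, not a log-logistic —
and under this parameterization an accumulation curve requires `b < 0`.
Evaluation uses the logistic sigmoid from scipy (`expit`), which
saturates instead of overflowing for large `|b(x − x₀)|`.

Fitting is multi-start Levenberg–Marquardt least squares (default 8
starts). Initials come from the data: `S_min ← min Brix`,
`S_max ← max Brix`, `x₀ ←` the GDD of the observation nearest the median
Brix, and `b` from the secant slope via the identity that the maximum
logistic slope is `|b|·span/4`. Restarts perturb the initials by
Gaussian noise at 20% relative scale from a fixed fitting seed, so fits
are reproducible. Convergence tolerance is 1e-10 on the relative RSS
change. Observations from replicate vines are pooled into one curve per
cultivar.

A fit is rejected (flagged, never silently kept) when: the optimizer
fails; `b ≥ 0` (flat or decreasing series); the fitted span
`S_max − S_min` is below a floor of 2 °Brix (no real rise to time); or
the transition width exceeds the observed GDD range (the data never
resolve the S-shape). The quantitative screen is our reconstruction of
the qualitative practice of excluding cultivars that "do not fit" a
sigmoid; the floor and the width rule are the two knobs, and both are
configuration.

Derived quantities: the transition width is the GDD distance between the
curve's 25% and 75% span crossings, `2·ln3/|b|` in closed form ("1st to
3rd quartile" of the response rise — the only reading consistent with
the width acting as the run of a secant through the steepest part of the
curve; the alternative reading, an IQR of the sampled GDD values, would
depend on the sampling schedule rather than the curve and is rejected).
The maximum accumulation rate is `S_max / width`. Using `S_max` rather
than the span `S_max − S_min` as the numerator over-reads the true
maximum derivative `|b|(S_max − S_min)/4` by the fixed factor
`4/(2·ln3) ≈ 1.82` at `S_min = 0`; the span variant is available
(`use_span_numerator=True`) but off by default so rates match the
conventional definition.

## Sieve-element hydraulics

One sieve element is a Hagen–Poiseuille lumen in series with its sieve
plate; the plate's pores are parallel channels, each a Sampson orifice
(`3η/r_p³`) plus a Poiseuille channel (`8η·l_p/(π·r_p⁴)`). Two modes:

* **per_pore** (reference): exact parallel-network sum over listed pore
  radii, `R_plate = [Σ_i 1/R_pore,i]⁻¹`.
* **moment** (fallback when only mean ± SD and pore count exist, as in
  published tables): `R_plate = (1/N_p)(3η/(r̄³A) + 8η·l_p/(π·r̄⁴B))`
  with `A = E[r³]/r̄³`, `B = E[r⁴]/r̄⁴` from normal raw moments
  (`E[r³] = µ³ + 3µσ²`, `E[r⁴] = µ⁴ + 6µ²σ² + 3σ⁴`). A = B = 1 at σ = 0,
  where the modes coincide exactly. The moment treatment is exact in the
  Sampson-only and Poiseuille-only limits and approximate for mixed
  terms (within 10% for CV ≤ 0.3 in the tested regimes).

All computation is in SI (meters, Pa·s, resistance Pa·s·m⁻³); the
public surface takes µm because that is the scale of anatomical
measurements. Published tables sometimes print resistance per area
units; we document SI volumetric-flow resistance and do not chase
inconsistent printed units. Default sap viscosity is 2 mPa·s.

Porosity is the direct ratio `Σ pore areas / plate area`. The
`reference` module ships published grapevine pedicel and stem
sieve-geometry summaries so that resistance partitioning (pedicel plates
dominate: plate shares well above 50%; stems split roughly evenly) and
the ~9.3× stem-to-pedicel length ratio can be recomputed without raw
micrographs. The published per-cultivar totals are not exactly
reproducible from printed means alone (they were presumably averaged per
sample with a particular pore-variation convention); the lumen-share
consistency of the Syrah row is the anchor we recompute, and the other
rows are checked qualitatively.

## Morphometrics and trait statistics

Traced area tables are ground truth (no image processing); the tracing
conventions — vascular rays > 4 cell layers excluded, sieve-element area
includes the wall — are recorded so synthetic data and documentation
stay faithful. Contrasts between climate groups are
`100·(mean_warm − mean_hot)/mean_hot`, with the hotter group as
baseline.

Regressions are OLS (statsmodels); a constant response is given r² = 0
by convention rather than NaN. AICc uses the Gaussian profile
likelihood, `n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`, with k counting the
mean-model coefficients plus the residual variance; only Δ-AICc between
rows fitted to the same rows and response is meaningful, which
`rank_models` enforces by fitting all candidates on common
complete-case rows. Two-factor ANOVA uses Type II sums of squares — the
conventional default for main-effect questions on mildly unbalanced
designs; it reduces to the classical decomposition when balanced. A
one-factor path (`factor_b=None`) is provided; interaction terms demand
fully occupied cells. Tukey HSD adjusted p-values come from the
studentized-range distribution with the Tukey–Kramer SE for unequal n
(exact; for k = 2 it reproduces the unadjusted two-sample test), and the
compact letter display uses the insert-and-absorb construction.
No multiple-testing correction is applied across separate regressions,
matching field practice for this analysis.

## Synthetic panel: what it emulates, and what not

The generator reproduces the statistical structure the analysis is
designed to detect, at a hot common-garden site:

* **Weather**: long-run mean daily temperature 22 °C with a ±2 °C
  seasonal sinusoid peaking in late July, 19.6 °C diurnal range, and
  1.5 °C day-to-day noise; the simulated study window lands in the
  hot-site bands (daily means ≈ 22.8–24.5 °C, maxima ≈ 32.6–34.4 °C).
* **Panel composition**: climate groups allocated by largest remainder
  from a 9:7:2 hot:warm:temperate mix, so n = 18 gives 9/7/2 and n = 13
  gives 7/5/1 — a designed panel, not a random draw.
* **Anatomy**: hot-climate mean phloem areas of 1.2×10⁵ (pedicel),
  1.5×10⁵ (petiole) and 0.8×10⁵ µm² (midvein) with 30% CV;
  warm-vs-hot multipliers 2.04 / 2.93 / 1.04 (the 104%/193%/4%
  contrasts); xylem drawn jointly normal with phloem at correlations
  0.59 / 0.99 / 0.93 per organ and xylem-dominated mean ratios; a
  modest red-berry petiole-phloem multiplier (1.25); whole-organ areas
  drawn independently of group. Within-cultivar section noise is 10% CV
  over 2 vines, the anatomical replication of a typical panel.
* **Ripening**: `S_min ~ N(4.5, 0.8)`, `S_max ~ N(24, 1.2)` °Brix,
  `x₀ ~ N(250, 60)` GDD; `|b| = 0.008 + 0.010·(pedicel area/10⁵ µm²) +
  N(0, 0.008)`. The coupling-noise SD is matched to the coupling signal
  so the population r² of maximum rate on pedicel phloem area is ≈ 0.5,
  the regime the analysis targets. Brix observations add 0.5 °Brix
  measurement noise on a 4-day sampling grid from veraison to harvest —
  a fixed-cadence stand-in for field protocols that sample at
  Brix-defined intervals precisely so the sigmoid rise is tracked
  (calendar grids with multi-week gaps leave the rise unsampled and make
  the slope unidentifiable, which the rejection screen then flags).
* **Physiology**: photosynthesis and midday water potential are drawn
  independently of the ripening parameters — a built-in null effect the
  model ledger should rank below the anatomy predictors.
* **Sieve geometry**: truncated-normal element dimensions centered on
  measured pedicel values (r 3.0 ± 0.6 µm, l 54 ± 13 µm, plate
  0.30 ± 0.10 µm), Poisson pore counts (mean 24), truncated-normal pore
  radii (0.22 ± 0.10 µm). Truncation at zero slightly biases means at
  large CV; at the default CVs the bias is negligible.

All draws flow from per-stage streams derived from one root seed, so
every table is reproducible and stages can be generated in any order.

What the generator does **not** emulate: vintage-to-vintage and spatial
(block) variability, berry water balance and xylem backflow,
source–sink carbon budgets, adaptive Brix-triggered sampling, and
measurement error in tracing areas beyond simple multiplicative noise.
Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes at field-realistic noise — not that real vineyards
satisfy those assumptions.

### A note on detection power at panel scale

With the coupling calibrated to r² ≈ 0.5, a 13-cultivar panel detects
the pedicel-phloem → rate regression (two-sided p < 0.05) in roughly
three quarters to four fifths of replicate seasons — the statistical
power of a correlation of ρ² = 0.5 at n = 13 is ~80–88%, not higher, no
matter how well the pipeline estimates each quantity. A single
significant panel is therefore consistent with the underlying effect,
but replication at this sample size is not guaranteed; detecting the
effect in ≥ 90% of seasons would require either ρ² ≈ 0.6 or a larger
panel (n ≈ 17–18 at ρ² = 0.5). The acceptance suite measures this rate
end-to-end over 100 seeded runs.

## Problem sizes and numerical choices

Default pipeline runs use 18 cultivars × 2 vines, 13 sampling dates, and
~80 weather days — a full analysis completes in well under a second.
Calibration checks use 10,000–20,000-cultivar panels; the moment-mode
accuracy check uses 10⁵ pores. Fit tolerances: 1e-10 relative RSS;
multi-start perturbation 20%; all test tolerances are stated per
assertion. Degenerate inputs (constant designs, single-observation
groups, empty pore lists, inverted temperatures) raise typed errors
rather than propagating NaN.
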