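# Methods

This note documents the statistical models, assumptions, parameters and
numerical choices implemented in `mpafit`, a pipeline for analysing
long-term fish-recovery time series from underwater visual census (UVC)
monitoring in marine protected areas (MPAs).

## 1. Survey data model

A UVC survey produces one row per species sighting per belt transect
(default 50 × 5 m = 250 m²). The observer assigns the number of
individuals to one of nine predetermined abundance classes (or records
an exact count) and bins estimated total lengths into 2-cm classes
(5-cm for large species). Species carry a trophic-group label (one of
PISC, MACRO, MICRO, OMNI, HERB, PLAN, DETR), a pelagic flag, a
control-area presence flag, and allometric length-weight coefficients.
A 62-species Mediterranean reef-fish trait table is packaged as the
default.

Validation rules: exactly one of abundance class / exact count per row;
abundance class in 1..9; size-class width 2 or 5 cm; every recorded
species must appear in the trait table. An optional explicit survey
*panel* (the full set of year × site × transect keys) lets transects
that recorded no sightings contribute explicit zeros; without it the
panel is inferred from the records.

## 2. Biomass and density estimation

- **Abundance classes.** Default bounds 1; 2–5; 6–10; 11–30; 31–50;
  51–100; 101–200; 201–500; 501–1000, decoded by class midpoint
  (arithmetic by default, geometric optional). The scheme is one
  configurable object; other binnings plug in.
- **Lengths.** Size classes are decoded at their midpoint
  (lower bound + width/2).
- **Weights.** W = a·L^b (W in g, L in cm). Species without
  coefficients fall back to the cube law (a = 0.01, b = 3.0) with a
  warning.
- **Descriptors.** `total` (all species), `total_reduced` (excluding
  pelagics), the seven trophic groups, and reduced group variants
  (`PISC_reduced` is produced by default). Trophic groups partition the
  species list, so group measures sum exactly to the total; reduced
  descriptors differ from their parent exactly by the pelagic
  contribution. Both identities are tested.
- **Normalisation.** Densities (individuals · 250 m⁻²) and biomasses
  (g · 250 m⁻²) are normalised to 250 m² whatever the configured
  transect area. Transects with no matching sightings yield explicit
  zero measures, so yearly means are taken over complete panels.

## 3. Yearly series

Per descriptor and response variable, transect values are pooled per
year into a global mean and standard error (sample SD over transects,
ddof = 1, divided by √n). Site-mean pooling (SE over site means) is a
config option. Years with a single transect report SE = 0 and carry a
`single_transect` flag. The time coordinate is t = year − 1995 (years
since protection began; configurable), so the first survey year 1996 is
t = 1. Sub-period series keep the absolute t so that initial-value
parameters (N0) keep their meaning across periods.

## 4. Growth-model families

Seven families are fitted to each yearly-mean series:

| family           | equation                              | parameters |
|------------------|---------------------------------------|------------|
| linear           | y = a + m·t                           | a, m       |
| exponential      | y = a·e^(b·t)                         | a, b       |
| von Bertalanffy  | y = K·(1 − e^(−r·(t − t0)))           | K, r, t0   |
| logistic         | y = K / (1 + ((K − N0)/N0)·e^(−r·t))  | K, N0, r   |
| asymptotic       | y = K + (N0 − K)·e^(−r·t)             | K, N0, r   |
| Gompertz         | y = K·e^(b·e^(r·t))                   | K, b, r    |
| Ricker           | y = N0 + (a·t)·e^(−b·t)               | N0, a, b   |

Asymptote semantics: logistic, asymptotic and von Bertalanffy approach
the carrying capacity K; Gompertz approaches K only for r < 0 (the sign
convention enforced at fitting time — with r ≥ 0 it diverges and is
reported unbounded with a warning); Ricker peaks at
N0 + (a/b)·e⁻¹ at t = 1/b; linear and exponential growth is unbounded.
Von Bertalanffy and the asymptotic family are the same curve under the
reparameterisation t0 = ln((K − N0)/K)/r; both are kept because their
parameterisations differ and the fitted minimal RSS must agree (tested
to 1e-8 relative).

## 5. Fitting

Nonlinear least squares on the yearly means (unweighted by default,
matching a global-yearly-mean analysis; inverse-variance weighting by
SE is a config option). Solver: SciPy `least_squares`
(trust-region-reflective) with analytic Jacobians for all seven
families, `x_scale='jac'`, and box constraints.

Numerical choices, all configurable:

- **Rate bounds.** Yearly rates (r, b) are boxed to |rate| ≤ 3 per
  year: e³ ≈ 20-fold change per year already far exceeds plausible
  fish-assemblage dynamics, and the bound keeps exponentials float-safe
  and the least-squares surface smooth.
- **Multi-start.** A data-driven initial guess (K0 = 1.05·max,
  N0 = first positive value, slopes from OLS on (t, y) or (t, log y))
  plus up to 20 seeded restarts alternating local multiplicative jitter
  around the guess and global scale exploration (which covers sign
  flips — necessary for ridge geometries such as von Bertalanffy
  mimicking an exponential with K < 0, r < 0).
- **Early stopping.** Restarting stops after 5 consecutive restarts
  without a relative RSS improvement of 1e-6.
- **Iteration budget.** `max_nfev` = 100 per start. Runs that exhaust
  the budget still provide candidate points if their RSS is finite;
  on flat ridges the budget-limited point is the practical optimum.
- **Perfect fits.** RSS ≤ max(1e-300, 1e-12·SStot) is snapped to 0 and
  flagged `perfect_fit`; this occurs only on noiseless synthetic data.

All randomness flows from explicit seeds. In the full analysis each
(descriptor, variable, period, area) cell derives its own seed from the
run seed and a CRC-32 of the cell key, so results do not depend on cell
enumeration order and two runs with the same input and seed produce
byte-identical bundles.

## 6. Model selection

Candidates are ranked by the small-sample Akaike criterion in its
least-squares form,

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1),

with k counting the curve parameters plus the error variance. Models
within 2 AICc units of the best are treated as equivalently supported;
within that set the fit with the greatest R² (R² = 1 − RSS/SStot, the
nonlinear approximation) is selected. Remaining ties go to the lower
AICc, then to the fewer-parameter model, then to the family name, so
selection is deterministic and invariant to input ordering. The applied
rule is recorded (`lowest_aicc` or `tiebreak_r2`).

Edge cases:

- RSS = 0 maps to AICc = −∞ (perfect fits win outright and are
  flagged).
- R² is undefined (reported as `None`) for a constant response
  (SStot = 0).
- With n = k + 1 points the AICc correction term is undefined. Fits of
  such families are excluded from AICc ranking; if *no* candidate has a
  defined AICc (e.g. a 4-point period where even 2-parameter families
  hit n − k − 1 = 0), selection falls back to ranking the converged
  fits by R² alone and records `greatest_r2_only`. This keeps short
  last-period windows analysable while marking that AICc support was
  unavailable.
- Fewer than n_params + 2 points: the family is excluded with a
  structured `insufficient_data` record. Periods with fewer than 4
  surveyed years are skipped entirely with a skip reason.

## 7. Carrying capacity

- **Asymptote method.** For a selected saturating fit the capacity is
  the fitted K, together with the time to reach 95% of it (fraction
  configurable): closed forms for logistic
  (t = ln[((K−N0)/N0)·(f/(1−f))]/r) and asymptotic
  (t = ln[(K−N0)/(K(1−f))]/r), Brent root-finding (tolerance 1e-6
  years) for von Bertalanffy and Gompertz.
- **Peak method.** A selected Ricker fit reports its analytic peak.
- **No finite capacity.** Linear/exponential selections yield an
  explicit record with `method='none'`, not an error.
- **Exponential projection.** When the first (well-enforced) period
  selects exponential growth with b > 0, the trend a·e^(b·t) is
  evaluated at the whole-study horizon (t = 23 years by default,
  configurable). The output is labelled `exponential_projection`, never
  an asymptote: it is an interpretation of what the series could have
  reached, not a fitted plateau.

The K read-off is meaningful when the fitted curve actually grows
toward K (positive fitted rate); a saturating family fitted to a
declining series still reports its K parameter, and downstream readers
should check the provenance parameters included in every estimate.

## 8. Enforcement periods

The analysis runs per period: the whole monitored span (1996–2018), the
early well-enforced window (1996–2009) and the window after enforcement
was restored (2015–2018); boundaries are config. The default survey
calendar is 1996–2018 minus {1999, 2001, 2011, 2012} (19 surveyed
years). Control-area data are summarised as series only (no curve
fitting) unless explicitly requested.

## 9. Synthetic data

Two generators (both fully seed-deterministic):

- `simulate_series`: yearly means drawn from a known growth curve with
  multiplicative lognormal noise (default; respects the positivity and
  scale-dependence of biomass data) or additive Gaussian noise
  (truncated at 0 with a warning). Used for parameter-recovery
  experiments where the generator is the oracle.
- `simulate_survey`: emulates the full design — years × sites ×
  transects, species drawn per trophic group following configured
  group-level trajectories, abundance-class emission and length classes
  — so every pipeline stage can be exercised end to end. The observer's
  class assignment is modelled as *stochastic rounding* between the two
  classes whose midpoints bracket the noisy expected count, which makes
  the midpoint decode exactly unbiased; a naive count-then-bin emission
  has midpoint-decode bias of up to ±30% near class bounds, which would
  contaminate round-trip tests with an artefact of the class scheme
  rather than of the pipeline. An optional enforcement lapse multiplies
  expected levels by a depression factor within a year range.
- `simulate_lapse_series`: an exponential track a·e^(b·t) whose means
  are multiplied by a depression factor during the lapse years
  (2010–2014 by default), with growth resuming on the original track
  afterwards. The qualitative selection signature (whole period
  saturating/peaked, first period exponential) only manifests when the
  within-window growth is moderate — a few-fold increase over the
  monitored years, as observed in long-term MPA series; at fast rates
  the exponential rise dwarfs the dip.

## 10. Limitations

- UVC counts are not detectability-corrected; abundance classes bound
  the information available, and midpoint decoding is a convention.
- R² for nonlinear fits is an approximation; it is used only inside the
  published selection rule, not as a goodness-of-fit test.
- AICc on short windows (4–5 points) is fragile by construction; the
  R²-only fallback is a pragmatic, clearly-flagged device, not a
  principled small-sample criterion.
- The exponential projection extrapolates far beyond the fitted window;
  it bounds a counterfactual and should never be read as an estimate of
  a realised carrying capacity.
- Fitted K values are point estimates; no confidence intervals or
  model-averaged estimates are produced.
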