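# Methods

This note documents the models, the regression machinery, the unit
conventions, the synthetic-data generator, and the numerical choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and units

A `SolubilityRecord` is one equilibrium observation
(T [K], P [MPa], ρ₁ [kg/m³], y₂ [–]), optionally carrying the g/L
equilibrium solubility, the triplicate standard deviation and the k=2
expanded uncertainty. These units are frozen package-wide; kg/m³ and g/L
are treated as numerically identical. Every correlation absorbs a change
of density or pressure unit into its own constants, so fitted AARD is
unit-invariant (this is verified by a test that refits after rescaling).
The gas constant is R = 8.314 J/(mol·K) everywhere, matching the
convention under which the enthalpy read-outs are quoted.

The built-in codeine phosphate dataset stores the mole fractions at their
reported precision (3–4 significant figures × 10⁻⁵), not extended
precision. The reported g/L column and the reported mole fractions agree
with the conversion `S = ρ₁ (M_s/M_CO₂) y₂/(1−y₂)` to better than 0.5%,
which is the rounding floor of the printed values; whether the g/L column
was computed from rounded or unrounded mole fractions cannot be
distinguished below that floor and does not affect anything downstream.

One documented quirk: the assay-geometry volumes are quoted in the source
material with inconsistent unit labels ("600 × 10⁻⁶ m³" for a 600 µL
loop). Both volumes are interpreted as liters (V₁ = 6×10⁻⁴ L,
V_s = 5×10⁻³ L); this interpretation reproduces the relation between the
reported g/L and mole-fraction columns exactly.

## The nine models

**Peng–Robinson EoS (8 parameters: a₂, b₂, β, γ, Δ_subδ, K₁, K₂, K₃).**
Solid–fluid equilibrium for a dilute solute:

    y₂ = P_sub · φ₂_sat / (P · φ̂₂) · exp((P − P_sub) v₂ / (R T))

- φ₂_sat = 1: standard for a solid with negligible sublimation pressure;
  no closure exists for it otherwise.
- φ̂₂ is the PR fugacity coefficient of the solute in the dilute limit
  (mixture quantities collapse to the pure-solvent ones). The cross term
  uses the van der Waals combining rule a₁₂ = (1 − k₁₂)√(a₁a₂) with
  k₁₂ = 0 by default (configurable). A test verifies this expression is
  the exact y₂ → 0 limit of the full two-component PR formula.
- Solvent a₁, b₁ come from the CO₂ critical constants
  (T_c = 304.13 K, P_c = 7.377 MPa, ω = 0.225, configurable) with the
  T-dependent α; an alternative `solvent_ab="fixed"` mode accepts a
  numeric pair. The pure-solvent cubic is solved per (T, P) once per
  dataset; the tabulated NIST density column feeds only the molar-volume
  closure and the density-based models, never the cubic.
- v₂ = K₁ + K₂ρ₁ + K₃ρ₁² (m³/mol); negative values are rejected by the
  fitting penalty, not clamped.
- R ln P_sub = β + γ/T + Δ_subδ ln(T/298.15). The pressure unit of P_sub
  is fixed to MPa internally; since β absorbs any unit change, only the
  enthalpy read-out ΔH_sub = (−γ + Δ_subδ·T)·R is unit-independent, and
  that is the quantity reported.
- Root selection: smallest real Z > B for the dense branch (largest for
  vapor); above the critical point exactly one physical root exists. At
  exactly (T_c, P_c) the cubic has a triple root (Z_c = 0.3074) and
  numerical root clustering limits accuracy to ~0.02 in Z there.

**Density-based (3–6 parameters).** Chrastil, Méndez-Santiago–Teja (MT),
Bartle (P_ref = 0.1 MPa, ρ_ref = 700 kg/m³, fixed constants excluded
from the parameter count), Sodeifian, Reddy–Garlapati (reduced
coordinates from the solvent critical point). The Chrastil mass-action
law is evaluated as a mole ratio, (M_CO₂/M_s)·ρ₁^(κ−1)·exp(A₁ + B₁/T),
then mapped to a fraction, so it stays bounded in (0, 1). The Sodeifian
correlation is implemented in its log form, ln y₂ = A₄ + B₄P²/T + …,
which is the form under which published parameter sets for this model
family reproduce measured solubilities; a linear-in-y₂ reading renders
them meaningless.

**Expanded-liquid models (3/4/6 parameters).** y₂ = (f₂ˢ/f₂ᴸ)/γ₂^∞ with
γ₂^∞ = exp(l₁ + l₂x + l₃x²), x = P/(RT), P in MPa. The fugacity ratio is
the ideal fusion term ΔH₂ᵐ/(RT)·(T/T_m − 1) minus the ΔC_p double
integral, with ΔC_p = 0 (case 1), D (case 2), or β₁ + β₂T + β₃T²
(case 3). The case-3 closed form is the exact antiderivative; a test
checks it against adaptive double quadrature to < 10⁻⁶ relative error.
Codeine phosphate fusion data: ΔH₂ᵐ = 31 358.83 J/mol, T_m = 428.15 K
(overridable per solute). Note the three ΔC_p temperature brackets are
nearly collinear over a 30 K study window, so fitted β magnitudes are
poorly identified individually (enormous, mutually cancelling values are
typical) even when the fit itself is excellent.

## Fitting

The regression objective is OF = Σᵢ|y₂ᵢ^exp − y₂ᵢ^calc|/y₂ᵢ^exp (no 1/N);
AARD% = 100·OF/N. Predictions that are non-positive or non-finite incur a
finite per-point penalty (10⁴ plus a term growing with the violation) so
the simplex is pushed back smoothly instead of hitting a cliff; models
whose forward map can overflow raise a typed evaluation error that the
objective converts into the same penalty.

`fit()` runs Nelder–Mead (`scipy.optimize.minimize`, adaptive simplex for
> 4 parameters, xatol 10⁻⁸, fatol 10⁻¹⁰, 5×10⁴ iteration cap) from
`n_starts` points (default 32) and keeps the best terminal value. Start 0
is a data-informed template; the rest multiply each nonzero coordinate by
exp(U(−j, j)) with jitter j = 0.5, seeded by a single integer, so a fit
is bit-for-bit reproducible from (data, config).

Initialization exploits the fact that every model here is exactly linear
in (possibly transformed) parameters on an appropriate scale:

- Chrastil: OLS of ln(y₂/(1−y₂)) − ln(M_CO₂/M_s) on [ln ρ₁, 1, 1/T];
- MT: OLS of T ln(y₂P) on [1, ρ₁, T]; Bartle: OLS of ln(y₂P/P_ref) on
  [1, 1/T, ρ₁ − ρ_ref];
- Sodeifian: OLS of ln y₂ on its six basis functions; Reddy–Garlapati:
  OLS of y₂ on its six reduced-coordinate terms;
- expanded-liquid: OLS of ln y₂ − (ideal fusion term) on the l-polynomial
  and ΔC_p bracket columns of the selected case;
- PR EoS: with s = √a₂ and the sublimation pressure dropped against P in
  the Poynting term, ln y₂ is linear in (s, b₂, β, γ, Δ_subδ, K₁, K₂, K₃);
  the OLS solution (s, b₂ clamped to ≥ 0) seeds the search, with a fixed
  magnitude template as fallback.

These starts put every model in the right basin; the multi-start jitter
guards against the remainder. A practical consequence is that the
best-found optimum is stable across seeds, and for several models it is
slightly *deeper* than historical single-start simplex fits of the same
data — AARD differences of a few tenths of a percentage point in this
package's favour are expected and are a property of the optimization, not
of the models.

Fit statistics are computed on the mole-fraction scale for all models:
SSE, RMSE = √(SSE/N), R², adjusted R², AIC = N ln(SSE/N) + 2Q and
AICc = AIC + 2Q(Q+1)/(N−Q−1), with Q counting only fitted parameters
(reference constants and critical constants excluded). Rankings sort by
AICc ascending with ties broken by fewer parameters, then name. Because
the objective is AARD while AIC is SSE-based, the AICc ranking of refits
need not coincide with rankings computed from other software's terminal
points; both are reported rather than reconciled.

Bounds: only the PR EoS model is bounded (a₂ ≥ 0 for the square-root
combining rule, b₂ ≥ 0); all other parameters are free.

## Enthalpy decomposition and MT consistency

ΔH_total = −B₁·R/1000 kJ/mol from the Chrastil slope, ΔH_sub = −B₃·R/1000
from the Bartle slope, ΔH_solv = ΔH_total − ΔH_sub (exact arithmetic
identity, provenance labels attached). The PR-EoS route
ΔH_sub(T) = (−γ + Δ_subδ·T)·R is exposed for parameter sets in which γ is
identified (e.g. published constants); in unconstrained 8-parameter
refits γ and β are nearly collinear with the other closures and the
read-out is not reliable.

The MT consistency diagnostic plots T ln(y₂P) − C₂T against ρ₁ for the
fitted C₂; thermodynamically consistent data collapse onto one straight
line (the package reports the least-squares line and its R², which
degrades monotonically as C₂ moves away from the fitted value).

## Synthetic data

`GeneratorSpec` defaults mirror the measurement design: the 4 × 6
(T, P) grid of the built-in dataset with its tabulated densities, a
Chrastil generating model with the fitted-scale constants
(κ = 2.8403, A₁ = −4.0221, B₁ = −5284.7), and multiplicative lognormal
noise with cv = 0.05 — the scale of the triplicate assay standard
deviations (3–8% of y₂). Noise is y_obs = y_true·exp(ε),
ε ~ N(0, √ln(1+cv²)), seeded; its mean is 1 to O(cv²), matching the
relative-error structure that the AARD objective assumes. The generator
emulates the grid design and relative noise of saturation-assay data; it
does not simulate assay-level replicates, absorbance noise, density
measurement error, or any T–P correlation structure, so recovery results
bound optimizer/identifiability error, not instrument systematics.

`recovery_experiment` runs generate → refit over seeded replicates and
reports per-parameter bias/RMSE and AARD quantiles. On this grid at 5%
noise the leading parameters (κ, l₁) are recovered within 15%
essentially always, while small-magnitude or collinear companions
(Chrastil A₁, the expanded-liquid l₃) have wider relative spreads — a
property of the design window, not of the optimizer (their recovery
improves as the noise shrinks, which a test verifies monotonically).

## Command line

`scsol fit | evaluate | simulate | report` wrap the library thinly: per
model JSON results, an AICc ranking table, the enthalpy report, the MT
consistency CSV, and a manifest (inputs, seeds, version) sufficient to
reproduce deterministic outputs. Exit codes: 0 success, 2 usage,
3 validation, 4 numerical failure.

## Problem sizes and determinism

The study dataset is 24 points; a full nine-model refit at 32 starts
takes on the order of a minute on one core, dominated by the 8-parameter
PR-EoS model. The test suite and acceptance script fix every seed; the
acceptance script recomputes its three quantities from scratch at 32
starts with the caller's seed. Monte Carlo sizes used in tests
(50 recovery replicates, 10⁴ noise draws) were chosen so the checked
fractions have negligible sampling error at the asserted thresholds.

## Known limitations

- The PR-EoS sublimation-pressure unit is absorbed into β; only enthalpy
  read-outs are portable across unit conventions.
- The full mixture PR EoS (composition-dependent mixing) exists only as a
  test oracle for the dilute limit; no vapor–liquid equilibrium, no other
  cubic EoS.
- No uncertainty intervals on fitted parameters, and no expanded-
  uncertainty propagation for the assay (component uncertainties of the
  source measurements are not available).
- Activity-coefficient pressure-polynomial form is fixed; no
  composition-dependent activity models.
- AARD-optimal and SSE-optimal parameter sets differ slightly; model
  rankings by AICc inherit that choice (see Fitting).
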