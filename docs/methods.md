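# Methods

## Scope and model structure

`graindiel` predicts the effective real permittivity of a packed bed of
cereal grain (or legume) kernels as a function of volumetric moisture
content, forward from physical parameters: kernel aspect ratio a/b,
dry-solid density ρ_s, solid permittivity ε_s, water-binding specific
surface area A_s, temperature T, packing coefficient k and, for the
blended high-moisture model, a critical volumetric moisture M_c.  The
model is quasi-static: frequency enters only through the bound-water
cutoff f\* (below which water is counted as bound), not through a full
Debye/Cole-Cole relaxation spectrum.  Complex permittivities (negative
imaginary loss factor) pass through every mixture rule, but all bundled
parameter sets and reference computations are real-valued.

## Moisture and packing

Moisture is carried simultaneously on wet (M_wb), dry (M_db) and
volumetric (M_v) bases, linked through the bulk density:
M_db = M_wb/(1−M_wb) and M_v = M_db·ρ_b/ρ_w.  Conversions are exact and
self-inverse; density bookkeeping is in g cm⁻³ internally (the CLI and
grain files may declare kg m⁻³).

Kernel density dilutes from ρ_s toward water density as moisture rises,
ρ_k = ρ_s/(1+(ρ_s/ρ_w−1)M_wb).  Packing is shape-controlled: the
spheroid ratio R(a/b) = V^(2/3)/S enters both the bulk density
ρ_b = k·ρ_k·R and the porosity φ_b = 1−k·R.  R uses a closed-form fit
valid for a/b ∈ [0.1, 10] (R² ≥ 0.999 against the exact prolate/oblate
surface formulas; verified in the tests); outside that range the exact
geometry should be evaluated directly via `spheroid_volume_surface`.
The printed form of the bulk-density expression is typographically
ambiguous about whether the moisture bracket multiplies or divides; the
implementation divides, the only reading consistent with the kernel
density relation composed with the shape porosity and with bulk density
decreasing in moisture.  A consequence worth knowing: with the modeled
ρ_b, the implied porosity 1−k·R is moisture-independent.  When a grain
file supplies a measured ρ_b it overrides the model (measured packing
beats the estimate) and porosity then follows from φ_b = 1−ρ_b/ρ_k(M_wb).

With the modeled bulk density, ρ_b itself depends on M_wb while M_v
depends on both; the pair is resolved per grid point by a bracketed
root find (`scipy.optimize.brentq`, xtol 1e-14) on the monotone map
M_wb ↦ M_db·ρ_b(M_wb).

## Water-binding surface area

Three estimators, intentionally independent:

* **Protein route.**  Accessible area per molecule A_a = 11.12·MW^(2/3)
  Å², summed over the four seed-protein classes weighted by class mass
  fraction and divided by molecular mass (Avogadro 6.022e23).  Class
  fractions are normalized to sum to 1 before use — published class
  tables sometimes omit a few percent, and normalization reproduces the
  reference values for every cereal where the raw fractions do not.
* **Monolayer route.**  A monolayer molecule occupies
  s² = (K_p/ρ_ml)^(2/3) Å² and weighs K_p×10⁻²⁴ g, giving
  A_s = M_ml·10⁴/(ρ_ml^(2/3)·K_p^(1/3)).  With the monolayer density
  1.48 g cm⁻³ and tetrahedral packing constant 28.21 g Å³ cm⁻³ the
  multiplier is 2529.4 m² g⁻¹ per (g g⁻¹); reference tabulations round
  it to 2531 (0.06% apart), so back-computed surface areas can differ
  from tabulated ones by one integer unit.  The empirical monolayer
  content M_ml = exp(0.612 − 3.06e-5·P³ − 4.03e-5·C^2.5) takes protein
  and carbohydrate contents in percent; its data span roughly 0.1–0.35
  g g⁻¹ and outputs outside [0, 0.5] carry an extrapolation warning.
* **Geometric route.**  Spheres contribute 3/(rρ) and long polymer
  cylinders 2/(rρ) (lateral surface only — end caps are negligible for
  high-aspect polymer rods, and excluding them is what reproduces the
  tabulated hierarchy values).  Cumulative sums down a structural
  hierarchy are accumulated before any rounding.

## Water-phase permittivity

Free water follows the cubic polynomial 78.54·[1 − 4.579e-3(T−298) +
1.19e-5(T−298)² − 2.8e-8(T−298)³], strictly decreasing over the liquid
range (warning, not error, outside 273–373 K).

The bound-layer thickness x(T) = α/(−d + T·ln(κT/8π²r³cf\*)) (α = 1621
Å K, d = 2047 K, c = 9.5e-7 Pa s, r = 2.5 Å, f\* = 1 GHz) derives from
the viscosity profile of water near a hydrophilic surface coupled with
the Debye relaxation model.  Two numerical facts the implementation
relies on: x(T) *decreases* with warming (10.3 Å at 273 K, 4.2 Å at
298 K, 2.6 Å at 323 K — liberation of bound water), and the expression
becomes undefined when f\* approaches the free-water relaxation (the
denominator crosses zero near f\* ≈ 5×10⁹ Hz at 298 K); that case
raises a domain error naming the cutoff-frequency constraint.

The single-phase water permittivity ε_w = ε_fw(T)·(1 − e^(−t_w/x(T)))
blends bound and free behavior through the mean film thickness
t_w = M_v/(A_s·ρ_b) (ρ_b in g m⁻³).  Its two temperature derivatives
have opposite signs — positive for thin (bound) films, negative for
thick (free) films — which propagates through the pipelines as the
measured low/high-moisture temperature interplay.  Per-molecular-layer
averages use the exact integral of the exponential over [(n−1)s, ns]
with s = 0.28 nm; at 25 °C layers 1–3 average 21.2, 49.1 and 63.4.
Reference discussions quote 22 for layer 1; neither exact integration
(21.2) nor midpoint evaluation (22.25) reproduces it cleanly, so the
layer-1 value is documented but not asserted against.

## Mixture models

All rules are authored here; no third-party package implements them.

* **Maxwell-Garnett**: explicit Clausius-Mossotti solution; exact at
  both φ = 0 and φ = 1.
* **Generalized ellipsoidal family**: three-axis sum with the
  depolarization triple N_p = 1/(1+1.6(a/b)+0.4(a/b)²),
  N_n = (1−N_p)/2 (an empirical fit; the exact ellipsoidal integrals
  are deliberately not implemented).  The ν parameter selects
  Maxwell-Garnett (0, explicit), Polder–van Santen (1−N, applied
  per-axis, matching the superscript in the source expression) or the
  coherent potential (1).  Implicit members use damped fixed-point
  iteration (damping 0.5, |Δε| < 1e-10, ≤500 iterations) with a
  scanned-bracket bisection fallback for real inputs.
* **Confocal three-phase**: core (ε₂) in shell (ε₁) in background
  (ε₀), polarizability summed over the three axes.  A zero-volume shell
  or core is replaced by its continuous limit (the shell permittivity
  cancels algebraically when φ₁ = 0, but evaluating it literally at
  ε₁ = 0 is 0/0).
* **Four-phase**: solid host with disk-like bound-water, free-water and
  air inclusions; closed-form ratio.
* **Configuration fractions**: the published core/shell/background
  volume table is dimensionally inconsistent, so fractions are derived
  from conservation — solid 1−φ_b, water M_v, air φ_b−M_v, mapped to
  roles by the 3-letter ordering tag.  Water above the pore space is a
  domain error.
* **SWA/WSA partition and blend**: f_swa = 1 below M_c and M_c/M_v
  above (continuous at M_c; the literal printed branch would jump and
  contradict the accompanying text, so it is treated as a labeling
  slip).  The blend is the symmetric two-component Bruggeman closed
  form ε = β/4 + √((β/4)² + ε₁ε₂/2), β = (3f₁−1)ε₁+(3f₂−1)ε₂, verified
  in tests as the exact root of Σ fᵢ(εᵢ−ε)/(εᵢ+2ε) = 0 and returning
  the pure component at f = 1.

**Bounds.**  In the regime the grain pipelines occupy — background
permittivity 1–5 (air, or the air+solid average), inclusions between 1
and 80, implicit-member inclusion fractions ≤ 0.7 — all rules stay
within the constituent min/max and the Wiener (harmonic–arithmetic)
bounds on thousands of random draws.  This is a regime statement, not a
theorem: the coherent-potential member genuinely leaves the constituent
bounds when the inclusion loading approaches close packing (e.g. a
φ = 0.94 load of near-air inclusions in a solid host has its only root
*below* both constituents), a known failure mode of that rule, reported
as computed.

## Pipelines

* **Two-phase**: air and solid (similar permittivities) merge into one
  background by a volume-weighted arithmetic mean; water enters as
  spheroidal inclusions with the kernel's aspect ratio at fraction M_v.
* **Three-phase**: configuration fractions feed the confocal model,
  with the same depolarization triple for the inner and outer
  ellipsoids.  At M_v = 0 every ordering reduces to the dry pack (solid
  spheroids in air) — the continuous M_v→0 limit of the water-shell and
  water-core orderings, and the only well-posed reading of the
  water-background orderings whose host would otherwise have zero
  volume.
* **High-moisture blend**: ε_SWA and ε_WSA at each point, combined with
  the Bruggeman blend using the M_c partition.  Below M_c it equals the
  SWA curve exactly.  A legacy `stepped_surface_area_curve` mode
  reproduces the alternative device of stepping A_s up to 40 000 m² g⁻¹
  beyond M_c and adding only the incremental volume-weighted water-phase
  permittivity; it is retained for comparison only, since phase
  configuration, not surface-area evolution, is the dominant mechanism.

The dry ends of the pipelines are *not* numerically identical: the
two-phase model's M_v = 0 value is the arithmetic air+solid mean while
the confocal pipelines give the (always lower) Maxwell-Garnett value;
for the bundled corn sets they differ by 8–9%.  The three-phase and
blended pipelines coincide exactly at M_v = 0.

Default moisture grid: 81 points on [0, 0.40] volumetric.  With the
modeled bulk density the pore space caps M_v at 1−k·R (≈0.39 for corn
at k = 3); grids beyond it raise a domain error rather than silently
clipping.

## Synthetic fixtures

The generator draws grain specs uniformly from measured cereal/legume
ranges: aspect 0.8–3.3, ρ_s 1.34–1.47 g cm⁻³, A_s 80–990 m² g⁻¹, ε_s
2.5–4, k 2.7–3.1, T 283–313 K.  It emulates the *parameter diversity*
of real grains, not their correlations (e.g. high-protein legumes
having both high A_s and low ρ_s) nor moisture-dependent kernel
swelling, hysteresis or dynamic surface area — so passing tests show
the estimators behave correctly across the parameter space, not that
any one synthetic spec is a faithful cultivar.  Each generated spec is
accompanied by independently recomputed ρ_k, φ_b and bound-water
content for dual-path cross-checks; generation is bitwise reproducible
per seed.

## Numerical choices

* Composition fractions must sum to 1 within 1e-6; a `normalize` flag
  rescales instead (tables that omit minor constituents).
* λ/t regime boundaries (1 and 10) are assigned to the transition zone
  — a conservative scattering warning.
* Implicit mixture solver: damping 0.5, tolerance 1e-10, 500
  iterations, widened-bracket bisection fallback.
* Curve CSV is written at 17 significant digits so write→read
  round-trips are exact.
* Temperatures are Kelvin at the API level; only the CLI accepts °C.

## Known limitations

* No frequency-resolved ε′/ε″ spectra; f\* is the only frequency
  parameter.
* No sorption/desorption hysteresis, kernel swelling or dynamic
  surface-area evolution; curves are forward predictions at fixed A_s.
* Solid permittivities in the bundled parameter sets are fitted
  constants taken as given, not derived from composition.
* The coherent-potential mixture member is unreliable near close
  packing (see Bounds above).
* No fitting of model parameters to measured permittivity data is
  provided; the package is a forward model.
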