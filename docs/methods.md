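# Methods

## Model

A thin segment of growing primary cell wall is treated as an evolving
continuum under the incompressible flow **u** = α(x, −y, 0): material is
deposited at the inner surface y = 1, advected outward and stretched axially
at the prescribed strain rate α. Every field equation is pure
advection–reaction, so the whole system reduces to ODEs in material age
along characteristics y = yᵢ e^(−α(t−τ)). Two material families coexist: the
*thinning* region (present at t = 0, extension uniform, L = e^(αt)) and the
*expanding* region (deposited later, extension fixed by position, L = 1/y).
Because deposited material always starts from the same unstressed, fully
bonded state, every expanding-region field depends on position only through
the material age — one characteristic solution serves the entire region,
which the implementation exploits heavily.

Per cohort the model tracks:

- cellulose angle θ = arctan(tan θ₀ · L) and extension
  (1/L_C) dL_C/dt = α sin²θ (closed form available in both regions);
- hemicellulose stress: a Maxwell element dσ_H/dt + ω σ_H = ds/dt with
  s = L/L₀ − 1 and ω = ω₀/μ; σ_H equals the elastic strain, which drives
  breakage;
- bond survival: dn/dt = −k̆₀ e^(γ²ς σ_H²) n for strands and
  dn_hot/dt = −e^(β_hot²ς(1−n)σ_H²) n_hot for hotspots. An intact hotspot
  (n = 1) breaks at its unstressed baseline rate regardless of load; as
  strands fail the cluster weakens;
- enzyme action: expansin either grows the spring resting length,
  dL₀/dt = E(L/L₀ − 1), or relaxes the dashpot, dμ/dt = Eμ(1 − Mμ) so that
  ω ramps from ω₀ to ω₀M; hotspot- and strand-cutting hydrolases are
  modelled by raising β_hot and γ.

The axial stress resultant integrates the composite stress over the wall
thickness, Σ = ∫(1 + a₁n_hot)σ_C + a₂ n n_hot σ_H dy + Γα, truncated at an
outer cut-off ε below which fibres are taken as broken. Its steady state Σ∞
proxies the yield threshold of the wall.

## Parameters and defaults

| group | default | meaning |
|---|---|---|
| α | scenario | strain rate relative to the unstressed hotspot breakage rate |
| θ₀ | 0.1 rad | cellulose deposition angle from the transverse axis |
| β_hot, γ | 0.01, 0.05 | hotspot / strand breakage sensitivities (β_hot = √n₀·β < γ: clusters are the stronger bond) |
| k̆₀ | 1 | strand-to-hotspot unstressed breakage-rate ratio |
| ς, ς_hot | 1 | breakage-energy constant κl₀²/(2k_BT) |
| ω₀ | 1 | ν_H/(μ₀k₀,hot), Maxwell rate ratio at deposition |
| a₁ | 0.1 (0.1–0.6) | cellulose-stress boost from hotspot crosslinking |
| a₂ | 0.025 | hemicellulose-to-cellulose stiffness-density ratio (from ν_H/ν_C = 1/20 and a fibre-density ratio of 0.5) |
| M | 3 | μ₀/μ₁, dashpot relaxation depth under expansin |
| Γ | 0 | pectin extensional viscosity (neglected throughout) |
| ε | 10⁻⁴ | outer-wall cut-off |
| E | 5 in enzyme scenarios | nondimensional expansin rate |
| Q | 10 | derivative threshold locating the survival switch-over |

ω₀ is a free configuration value: the physical constants pin every other
group but not the product μ₀k₀,hot, so an order-unity ratio is assumed —
Maxwell relaxation and hotspot breakage compete on the same clock, which is
the regime where enzyme action is mechanically interesting. Quantitative
curve levels (not the qualitative orderings asserted in tests) depend on
this choice. E = 5 is used in the enzyme scenarios so that expansin action
is fast enough relative to transit to show its full effect.

## Numerics

- **Profiles in log position.** All wall integrals are taken in u = ln y,
  where the integrands are smooth and the steep 1/y growth near the
  cut-off flattens. Survival integrals G, G_hot and the resultant terms are
  accumulated with composite Gauss–Legendre panels (order 6), doubling the
  panel count until probes settle below 10⁻⁹.
- **Suffix accumulation.** The breakage integrands blow up double-
  exponentially towards the outer wall; cumulative integrals are summed
  from the inner surface downward so that the physically meaningful small-G
  region keeps full relative precision (a prefix sum cancels
  catastrophically). Exponents are clamped at 350 — far beyond where
  survival underflows to zero — so no overflow can occur.
- **Nested integral.** G_hot needs n(y) inside its integrand; n is built
  once per parameter set on the panel grid and interpolated monotonically
  (PCHIP), keeping the nesting linear instead of quadratic.
- **Resting length.** L₀ has no closed form; it is advanced by a two-stage
  forward difference (explicit trapezoid) with step min(10⁻³, 0.01/α),
  halved until the end-point stress changes by < 10⁻⁶. The Maxwell stress
  then comes from the integrating-factor solution in an exponentially
  weighted incremental form that cannot overflow for large ωt.
- **Cellulose extension.** The reorientation integral has an elementary
  antiderivative, L_C(y) = √(tan²θ₀ + y²)/(y√(tan²θ₀ + 1)); the
  implementation uses it directly and the tests check it against
  independent adaptive quadrature and the ODE solver.
- **Brute-force oracle.** The full coupled system is integrated with an
  adaptive 8th-order explicit scheme (rtol 10⁻¹⁰) in log-survival
  variables, with the breakage rate capped at 10⁴: past the cap survival
  is already far below double precision, so the cap changes nothing
  measurable while keeping the system integrable explicitly. Cohorts are
  placed so their positions at evaluation time coincide with the
  quadrature nodes; since all deposited cohorts share one age trajectory,
  a single dense solution serves them all.

## Asymptotic reduction

For small β_hot and γ the survival profiles are near power laws
y^(k̆₀/α), y^(1/α) down to switch-over positions χ = γᾰ/√ln(αQ/k̆₀) and
χ_hot = β_hotᾰ/√ln(αQ) (ᾰ = α/(α+ω)), below which survival collapses.
The projection factor sin(arctan(tanθ₀/y)) is expanded piecewise in three
regions split at tanθ₀ + δ and tanθ₀/2; δ is chosen by 1-D minimisation of
the expansion's mean-squared error on [ε, 1] (MSE ≈ 1.5·10⁻⁷ at θ₀ = 0.1,
δ ≈ 0.060). Squaring the series, integrating against 1/y and Taylor-
expanding the exponential gives a piecewise L_C of the form
b₁(1 + tan²θ₀/2y²), b₂y^(−b₀)(1 − H + H²/2), b₃/y·(1 + y²/2tan²θ₀), with
b₁ fixed by L_C(1) = 1 and b₂, b₃ by continuity at the region boundaries.
The correction series H is defined only up to an additive constant
(absorbed into b₂); centring it at the expansion point y = tanθ₀ keeps the
quadratic truncation of e^(−H) accurate and holds the piecewise L_C within
2.3 % of the exact form at θ₀ = 0.1. All constants are derived
symbolically from this recipe at runtime, never transcribed.

The reduced steady resultant Σ₁ + Σ₂(α) + Σ₃(α) then consists of elementary
power integrals: Σ₁ is pure geometry, Σ₂ integrates y^(1/α) against the
piecewise cellulose integrand down to χ_hot, and Σ₃ is a closed form cut at
χ. A further small-/large-α simplification drops the Z^(1/α) terms or the
subdominant rational coefficients. Both variants track full quadrature
within ≈ 2 % across α ∈ [1, 100] for the tested sensitivity pairs; the
residual error is dominated by the α-independent truncation bias of the
piecewise L_C, so it is flat below α ≈ 10 and falls beyond. The large-α
limit is constant up to a double-logarithmic drift through the shrinking
switch-over position — the plateau of the yield threshold.

## Model properties worth knowing

- **Transient monotonicity.** The thinning-region material carries exactly
  the state of the expanding-region profile at the boundary y = e^(−αt)
  (identical age and extension history), so
  Σ(t) = ∫_{y_t}^1 f dy + (y_t − ε)f(y_t) with f the steady integrand, and
  dΣ/dt = −αy_t(y_t − ε)f′(y_t) ≥ 0 whenever f decreases towards the outer
  wall — which it does at the default parameters for all ω₀ ∈ [0.3, 10].
  The semi-analytic transient therefore rises monotonically to Σ∞; it
  cannot overshoot. A transient stress peak would require a non-monotone
  steady integrand (e.g. a cut-off that breaks, rather than truncates,
  highly extended cellulose).
- **Enzyme-response regimes.** At a₁ = 0.1 both expansin mechanisms lower
  Σ∞ at pre-plateau strain rates while raising n_hot pointwise (loosening
  without weakening); the viscosity mechanism does so across the whole
  range. For the resting-length mechanism at larger α, and for either
  mechanism at a₁ = 0.6, the survival gain in the a₁-weighted cellulose
  term outweighs the hemicellulose relaxation and the resultant rises —
  the same competition in both cases.
- **Cutting-enzyme asymmetry.** Hotspot-targeting action (β_hot) collapses
  n_hot far more than matched strand-targeting action (γ) does, because the
  hotspot survival couples to n only through the bounded factor (1 − n).
  On Σ∞ at ω₀ = 1 the two are comparable — γ acts through the a₂-weighted
  hemicellulose term, whose weight exceeds the a₁b₃ coefficient of the
  hotspot-cellulose term; the Σ∞ asymmetry emerges in the stiff-spring
  regime (larger ω₀) where the hemicellulose term is suppressed.

## What the tests do and do not show

The suite validates the semi-analytic solution against an independent
brute-force integration of the same governing equations, the asymptotic
reduction against full quadrature, and the qualitative mechanics (plateau,
reorientation stiffening, expansin loosening-without-weakening, hydrolase
asymmetry on the hotspot density). It does not calibrate the model to
measured creep data: the parameter defaults are literature-scale constants,
absolute stress levels depend on the unprinted ω₀, and pectin dynamics,
bond reformation, radial growth and tissue-scale coupling are outside the
model.
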