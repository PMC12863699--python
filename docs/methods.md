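# Methods

## Model and assumptions

The state is (S, I, P): susceptible prey, infected prey, predators. The
dynamics are a Caputo fractional-order system of order α ∈ (0, 1],

    D^α S = Λ/(1+kP) − μS − βSI + ωI
    D^α I = βSI − (δ+ω)I − mIP/(1+aI)
    D^α P = nIP/(1+aI) − dP

with all rate parameters in units of 1/time^α (the package works
exclusively in this rescaled parameterisation; no unscaled variant is
exposed). Assumptions baked into the structure: recruitment of
susceptibles is constant (no logistic self-limitation) and is the only
term the fear factor 1/(1+kP) multiplies; the disease is SIS with no
vertical transmission; predators consume infected prey only (pathogen-
induced vulnerability), with a Holling type-II response; the predator's
numerical response shares the prey-consumption saturation. The memory
effect enters only through the order α.

Parameters, with defaults of the packaged study scenario
(`fearsis.TABLE_DEFAULT`):

| name | meaning | unit | default |
|---|---|---|---|
| Λ | susceptible recruitment | density/time^α | 10 |
| k | fear level | 1/density | 0.4 |
| μ | susceptible mortality | 1/time^α | 0.5 |
| β | infection rate | 1/(density·time^α) | 1.5 |
| ω | recovery rate | 1/time^α | 0.5 |
| δ | infected mortality | 1/time^α | 0.5 |
| m | predation rate | 1/time^α | 4 |
| a | half-saturation constant | 1/density | 1 |
| n | predator conversion rate | 1/time^α | 1 |
| d | predator mortality | 1/time^α | 0.5 |
| α | derivative order | — | 0.95 |

## Equilibria

R₀ = βΛ/((δ+ω)μ). The disease-free point is (Λ/μ, 0, 0); the endemic
predator-free point (Λ/(μR₀), (R₀−1)Λ/(δR₀), 0) exists iff R₀ > 1 (at
R₀ = 1 exactly it coincides with the disease-free point and is reported
absent-degenerate). The interior point (η, σ, κ) has σ = d/(n−ad) pinned
by the predator balance; eliminating S via
S(P) = [(δ+ω)(1+aσ)+mP]/(β(1+aσ)) and substituting into the susceptible
balance multiplied by (1+kP) gives ζ₁P² + ζ₂P + ζ₃ = 0 with

    ζ₁ = km(μ+βσ)
    ζ₂ = m(μ+βσ) + k(1+aσ)(μ(δ+ω)+βσδ)
    ζ₃ = (1+aσ)(μ(δ+ω)+βσδ−βΛ).

These coefficients were rederived from the steady-state system rather
than transcribed (an exact symbolic solve is the independent oracle in
the tests; the rederivation reproduces the reference interior points
(18.39, 1, 0.05) and (6.3, 1, 1.39) to all printed digits). Since
ζ₁, ζ₂ ≥ 0, a unique positive root exists iff ζ₃ < 0, equivalently
Λ > δσ and R₀ > Λ/(Λ−δσ) — exactly the region past the predator-invasion
threshold, which is also where the predator-free point's invasion
eigenvalue nÎ/(1+aÎ) − d turns positive. The root is evaluated in the
cancellation-free form κ = −2ζ₃/(ζ₂+√(ζ₂²−4ζ₁ζ₃)) (for k = 0 the
equation degenerates to linear and κ = −ζ₃/ζ₂).

## Stability

Matignon's condition: an equilibrium is LAS iff every Jacobian eigenvalue
satisfies |arg λ| > απ/2. The package always evaluates the analytic
general-state Jacobian numerically at the equilibrium; simplified
per-equilibrium expressions are used only as cross-checks in tests. The
report carries the margin m(α) = απ/2 − min|arg λ| (negative ⇔ LAS) and,
when the spectrum is {negative real, complex pair with positive real
part}, the critical order α\* = (2/π)·atan(Im/Re). Classification
tolerances: eigenvalues within 1e−10 of zero, or margins within 1e−6 rad
of the cone, yield "marginal". The fractional Routh–Hurwitz clauses on
λ³+c₁λ²+c₂λ+c₃ (with the standard cubic discriminant) are provided as an
independent sufficient test; clause (i) is the classical Hurwitz
criterion, decisive for any α, and the instability clause (Δ<0, c₁<0,
c₂<0, α>2/3) is the decisive converse. When neither applies the report
answers "indecisive" — the criterion is never forced.

The Lyapunov-derived global-stability conditions are sufficient only;
a False result is reported as "inconclusive for GAS". The biomass
functional A = S + I + (m/n)P satisfies D^α A + θA ≤ Λ with
θ = min(μ, δ, d) (the tightest admissible choice), so A is ultimately
bounded by Λ/θ; the bound γ = Λ/θ·(1+ε) with ε = 0.01 enters the
interior-point condition. The γ₂ term ηγ mixes a density with the bound
as stated in the source analysis; it is retained as given since the
predicate is only sufficient. Note the disease-free global condition
Λkn/(dm) < R₀ < 1 − ω/(βS̃) is unsatisfiable for the default scenario's
Λ, μ, ω, δ at any β (the left side of 20β + 0.5/(20β) < 1 has minimum
√2); the tests exercise a satisfiable instance at small ω instead.

## Numerical integration

The solver is the fractional Adams–Bashforth–Moulton predictor-corrector
for the Volterra integral form of the Caputo problem: fractional
rectangle-rule predictor, fractional trapezoid-rule corrector
(re-applied `corrector_iterations` times, default 1), full memory — no
short-memory truncation, because the algebraic tails are precisely what
shifts fractional Hopf behaviour. Weights depend only on the step lag
c = n−j and are precomputed once as stabilised power differences
((c+1)^α − c^α etc.), avoiding cancellation at large n; the cost is
O(N²). At α = 1 the weights collapse to the classical Euler/trapezoid
pair.

Defaults: h = 0.05, t_end = 2000 for attractor classification (the
source analysis states no numerical settings; these resolve the default
scenario's dynamics, whose rates are O(1), and long enough that t^−α
transients fall well below the 1% amplitude tolerance), overridable
everywhere. The scheme is explicit in the predictor: step sizes must
resolve the fastest local rate (≈ mP for the infected-prey equation).
Inside the ultimately bounded region A ≤ Λ/θ this holds comfortably at
h = 0.05 for parameters within ~25% of the default scenario — the regime
the non-negativity property tests sample; far-from-attractor initial
states (e.g. predator densities ≫ the sustained level) need smaller h,
and divergent runs raise `IntegrationError` carrying the partial
trajectory. States are never clamped inside the dynamics; a reporting
helper clamps round-off negatives only.

Initial conditions for scenario runs default to the equilibrium of
interest (interior if present, else predator-free, else disease-free)
with positive components inflated by 5%; components that are exactly
zero at that equilibrium are seeded with a 0.1 inoculum so runs start in
the interior. Sweeps warm-start each grid point from the previous
point's final state (continuation), discard the first half of each
trajectory and classify "cycle" when any component's relative amplitude
(max−min)/max(1, |mean|) exceeds 1e−2.

### Mittag-Leffler function

E_α(z) for real z is evaluated by three regimes keyed to
s = |z|^(1/α): plain float series (s ≤ 10, where cancellation loses at
most ~4 digits; terms formed in log space to avoid overflow), elevated-
precision series via mpmath with 25 + s/ln10 digits (10 < s ≤ 60; the
Γ argument αn+1 is formed at working precision — forming it in double
loses ~1e−13 relative and is amplified by the peak term), and the
algebraic large-argument expansion −Σ z^−k/Γ(1−αk) (s > 60, optimal
truncation error ~e^−s; Γ-pole terms are skipped). Accuracy is ~1e−10
absolute for |z| ≤ 50 across the orders exercised; positive arguments
whose result would overflow a double raise `OverflowError`. E_α governs
the linear Caputo test equation, so the integrator is validated against
it; the empirical convergence order is measured as the log–log slope of
endpoint errors against the finest grid and reaches ≈ min(2, 1+α)
(2.14, 2.10, 1.83 at α = 1, 0.95, 0.6 with ±0.3 test bands — the
fractional orders sit slightly above 1+α at these step sizes).

## Bifurcation location

Forward thresholds in β are closed forms: β₁\* = (δ+ω)μ/Λ (R₀ = 1) and
β₂\* = (δ+ω)μ/(Λ−δσ) (predator invasion, requiring n > ad and Λ > δσ).
Hopf thresholds are roots of the Matignon margin in any named parameter
(including α itself), bracketed and solved by `brentq` to 1e−6; at the
root the spectrum is verified to be a negative real eigenvalue plus a
complex pair with positive real part, and transversality (nonzero margin
slope) is checked by a centred difference. For the parameter α the
margin is strictly increasing at fixed spectrum, so the root is unique
and equals (2/π)·atan(Im/Re) of the unstable pair — asserted as a
cross-check. The sweep route (warm-started continuation plus amplitude
classification) is a validation mode; thresholds are reported from the
eigenvalue route, which is deterministic and step-size-free.

For the default scenario the computed thresholds are β₁\* = 0.05,
β₂\* = 0.052632, β₃\* = 0.065263, β₄\* ≈ 1.7973, k\* ≈ 0.681,
α\* ≈ 0.9109. The first three agree with their reference values (0.05,
0.0526, 0.0651) to ≤0.3% and are regression anchors. The reference
values k\* ≈ 2.3165 and α\* ≈ 0.7367 could not be reconciled with the
eigenvalue computation under the same parameter set (the margin at
k = 2.3165 is −0.15 rad, firmly stable), and β₄\* ≈ 1.8367 agrees only
to ~2%; `reference_threshold_comparison()` reports the package's own
values for all six with the relative differences, flagging the last
three as diagnostic.

## What the scenarios do and do not show

The packaged scenarios are the hypothetical parameter set above with β,
k and α varied; they are not calibrated to any organism, so passing
tests demonstrate internal consistency of the analysis (closed forms vs.
simulation vs. independent oracles), not ecological realism. Random-
draw property tests sample broadly around that set for algebraic
properties (existence partitions, residuals, Routh–Hurwitz/Matignon
agreement) and within ±25% of it for simulation-based properties, per
the step-size limits above. Known limitations: no adaptive stepping and
no other fractional operators; no continuation of the limit cycle itself
(amplitudes come from simulation, not Floquet analysis); global-
stability predicates are one-sided; the interior point's characteristic
coefficients come from the numerical Jacobian, so extreme parameter
magnitudes are subject to ordinary floating-point conditioning.
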