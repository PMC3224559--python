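# Methods

## Model family

All models are deterministic compartmental (fluid-queue) descriptions of
a patient cohort normalized to 1; absolute counts are a presentation
multiplication by N₀ at output. Time is in days and every rate constant
in day⁻¹ throughout, because the observable timescales of surge response
(saturation within days, complete treatment within weeks) live there.

**Unconstrained chain.** `Ns → Na → Nd` with first-order rates `ka`, `kd`
is the classic sequential-decay system; its closed forms are
`Ns = e^{-ka t}`, `Na = ka/(kd−ka)(e^{-ka t} − e^{-kd t})` and `Nd` by
conservation, with the admitted census peaking at
`t₁ = ln(kd/ka)/(kd−ka)`. The peak value `Na^max` depends only on the
rates — the model's notion of surge capacity is kinetic, not a bed count,
and inverting a bed count into rates is deliberately out of scope.

**Capacity limit.** From `t₁` the center is saturated: one admission per
discharge at a zeroth-order throughput `k′` (assumed no faster than `kd`,
reflecting a hospital full of critically injured patients), so the queue
declines linearly and vanishes at `t₂ = t₁ + Ns(t₁)/k′`; afterwards the
admitted census relaxes at the pre-event rate `kd`. The 99%-discharge
time has the closed form `t₉₉ = t₂ − ln((1−θ)/Na^max)/kd` with the
threshold θ exposed as a parameter (0.99 is a convention, not physics).

**Two centers.** The pediatric cohort is admitted to the adult center
(`kpaa`, `kpda`) or the PTC (`kpap`, `kpdp`); adults are never triaged to
the PTC. Four regimes follow: both centers free (region I, total
admission rate `k = kpaa + kpap`), adult center saturated (II), both
saturated (III, combined throughput `κ = ka′ + kp′`), and post-surge
relaxation (IV). The derivation assumes the adult center saturates
first, which holds exactly iff `kpdp ≤ kpda`; the opposite case is the
same model with the two centers' labels swapped, and the solver either
raises with that instruction or performs the swap (`allow_relabel=True`).
`t₂ = t₁p + B/κ` is closed-form; `t₉₉` solves the two-exponential
transcendental `C e^{-kpda Δ} + D e^{-kpdp Δ} = 1 − θ` by bracketed
Brent iteration on `[t₂, t₂ + 10³/min(kpda, kpdp)]` (the discharged
fraction is monotone there, so the bracket is guaranteed).

**Death rates.** The mortality extension adds a deceased compartment fed
at per-compartment rates `ω_s, ω_a, ω_p, ω_d`, with composite decay
constants (`λ_s = k + ω_s`, etc.). While a center runs at capacity its
census is constant — deaths there are backfilled from the queue — so
at-capacity inpatient mortality enters the deceased flow as the constant
rates `ω_a′`, `ω_p′`. These are unstated in the source material for the
historical scenario; the package sets `ω_a′ = ω_a` and `ω_p′ = ω_p`
(no basis for a steady-state distinction). The no-PTC comparator is the
same model with `kpap = kp′ = 0` — one code path, one death model for
both arms — in which the at-capacity regime is terminal and `ω_p′` drops
out (no PTC inpatients exist). Note one structural consequence: as the
PTC's scale tends to zero the model does *not* converge exactly to the
comparator, because the governing equations keep the constant `ω_p′`
inflow in region III regardless of the (vanishing) PTC census; the gap
is ≈ 6×10⁻⁴ in deceased fraction at 10 d for the historical rates.

## Parameter estimation

Historical reports give timescales, not rates. With observations
`(t₁, t₉₉)` and the closure constraint `τ = t₉₉ − t₂`, the three defining
equations are solved simultaneously by multidimensional root finding
(scipy `hybr`) in log-rate space, which enforces positivity without
penalties. The system has two branches (admission slower or faster than
discharge); the branch is chosen by the initial guess, `(ka, kd) =
(0.1, 1.0)` or `(1.0, 0.1)`, with a handful of deterministic perturbed
restarts before reporting failure with the final residuals. The branch is
part of the result, never silent. Note that the constraint can make a
branch infeasible: for the historical inputs (τ = 2 d) the
admission-faster branch has no solution — its minimum attainable τ is
about 7 d — and the fit raises rather than returning a near-miss.

Uncertainties follow the curvature recipe: with unit variance on each
observed timescale, `σ_p² = 2 / (∂²SSE/∂p²)`, profiling the SSE along
each parameter over an 11-point ±20% grid with the others fixed. The
curvature is read off a centered degree-4 polynomial fit: the SSE of an
exactly-solvable system is locally quadratic with substantial quartic
corrections over a ±20% window, and a plain quadratic fit over that
window underestimates the at-optimum curvature by ~7% for the discharge
rate. Covariances are neglected by construction.

## Sensitivity analysis

`S_ij = ∂X_i/∂p_j` and `V_ij = S_ij² σ_j²` rank parameter influence per
output. For the single-center model all nine partials of `(t₁, t₂, t₉₉)`
w.r.t. `(ka, kd, k′)` are closed-form (`∂t₁/∂k′ ≡ 0`, and
`∂t₉₉/∂k′ = ∂t₂/∂k′` because region II converts queue into discharges
one-for-one, leaving `Nd(t₂)` independent of `k′`). Every element is
verified against central finite differences in the tests.

For the two-center model the four timescales are differentiated
numerically: absolute steps of ±0.001 day⁻¹ (the parameters are
O(0.1–1)), averaging the forward and backward one-sided differences;
step halving changes no element by more than 1%. The reference
configuration sets the PTC equal to the fitted adult center, which is
exactly the exchange-symmetric point where the saturation order flips —
the physical timescales have a kink there. Difference quotients
therefore use the smooth continuation of the adult-faster closed forms
across the boundary rather than the relabeled (branch-switched)
solution; the continuation is verified against the ODE integrator on the
valid side. Parameter uncertainties: the adult-center-side rates carry
the fitted σ values; the PTC-side rates, for which no data exist, carry
variance equal to 35% of the parameter value.

## Computational experiments

The scale-factor scan multiplies the PTC triple `(kpap, kpdp, kp′)` by a
single factor s — uniform mode, preserving the adult center's internal
rate proportions — or pins `kpdp = kpda` and scales only the other two
(fixed-discharge mode). The default grid is 60 points, logarithmic from
10⁻³ to 0.999, matching the range a planner would explore from
"negligible PTC" to "as good as the adult center"; per-point boundary
failures are recorded without aborting the scan. The t₉₉ peak (the
trapping effect: a slow-discharging PTC accumulates patients it cannot
release) is refined from the coarse argmax by bounded golden-section
search to 10⁻⁴ in s, and the baseline crossing by Brent bracketing
between grid points.

The mortality comparison uses literature rates entered as the package's
defaults: in-hospital 0.086/15 ≈ 5.73×10⁻³ day⁻¹ (8.6% of admitted
patients dead over 15 days, as a simple proportion rather than an
exponential-hazard conversion), untreated-surge rate scaled by 0.93/0.07
(7% of earthquake fatalities died while hospitalized) ≈ 7.62×10⁻²
day⁻¹, and discharged patients at the background 2×10⁻⁵ day⁻¹ taken as
printed rather than recomputed from 8/1000/yr. The outcome is the
deceased fraction at a fixed horizon (10 d, when the historical hospital
ceased operations); t₉₉ is not defined under mortality, since "99%
discharged" loses meaning when part of the cohort dies.

## Numerical choices

- Degenerate rates: generic closed forms have removable singularities at
  equal rates. Within a relative tolerance of 10⁻⁸ the analytic limit
  forms are used (`Na = ka·t·e^{-ka t}`, `t₁ = 1/ka`); the
  four-compartment delayed chain raises instead, as no limit forms are
  provided there. The region-II constants of the two-center model are
  singular at `kpdp = kpap`, which likewise raises.
- Region membership uses half-open intervals `[0, t₁) [t₁, t₂) [t₂, ∞)`;
  the zeroth-order queue is clamped at zero exactly at the analytic t₂
  (floating-point can drive it to ~−10⁻¹⁶ just past the intercept).
- At the exactly-symmetric two-center point the region-II width is the
  log of a quantity equal to 1 up to rounding; a resulting offset down to
  −10⁻⁶·t₁a is clamped to zero, anything more negative is an error.
- Root finding: Brent with `xtol = 10⁻¹²` d for t₉₉ (tight so that
  difference quotients through it are not noise-dominated).
- Mortality closed forms are evaluated through `expm1`-based exponential
  integrals, exact in the `ω → 0` limits (the death-free limit reproduces
  the PTC model to 10⁻⁹ without special-casing).
- The verification oracle is classical fixed-step RK4 restarted exactly
  at the analytically known breakpoints — with exact restarts there is no
  event-location error, and zero-width regimes (symmetric rates) are
  deduplicated. Default step 10⁻⁴ d; the tests use 1–2×10⁻³ d, where the
  global error (≈(λh)⁴) is still two orders below the 10⁻⁶ comparison
  tolerance. Problem sizes in the suite — 50 random parameterizations per
  model variant on ~10–30-day horizons — keep the full run to a few
  minutes on one core.

## Limitations

- Deterministic fluid approximation: valid for large cohorts; for tens
  of patients a discrete stochastic treatment would be more appropriate.
- "Discharge" aggregates all dispositions (home, transfer, death) except
  in the explicit mortality extension.
- The delayed-surge generalization is provided for the single-center
  unconstrained chain only; combining the delay with capacity limits or
  the PTC follows the same algorithm but is not implemented.
- Local sensitivity only — derivatives at a point with independent
  parameter variances; no global (Sobol-type) analysis.
- The adult cohort is assumed never to compete with children for PTC
  beds, and cost/resource tradeoffs are outside the model.
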