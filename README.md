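# surgekinetics

Deterministic population-kinetics models of mass-casualty disaster surge
triage, with and without a pediatric trauma center (PTC).

After a sudden mass-casualty event, a cohort of N₀ patients waits for
admission to a trauma center. When the queue is long its behavior is well
approximated by a fluid (deterministic) model: a compartmental chain

```
N_s --k_a--> N_a --k_d--> N_d
```

where N_s is the surge awaiting admission, N_a the admitted census, N_d the
discharged population, and k_a, k_d are first-order rate constants (day⁻¹).
Real centers saturate: once N_a reaches the kinetic surge capacity
N_a^max = N_a(t₁), admissions and discharges run one-for-one at a
zeroth-order throughput k′ until the queue vanishes at t₂ = t₁ + N_s(t₁)/k′,
after which discharges relax exponentially. The operational endpoint is
t₉₉, the time at which 99% of the cohort has been discharged.

The two-center extension splits the pediatric cohort between an adult
center (rates k_paa, k_pda) and a PTC (k_pap, k_pdp), each with its own
at-capacity throughput (k_a′, k_p′), producing four piecewise regimes; a
further extension adds explicit per-compartment death rates ω and a
deceased compartment. Everything is solved in closed form; a fixed-step
Runge–Kutta integrator of the governing ODEs serves as an independent
verification oracle throughout the test suite.

The package is aimed at disaster-preparedness modelers and public-health
planners who want a transparent, fully analytic baseline for questions
like: *how much faster would the pediatric surge be treated if a PTC were
available, and how slow can that PTC be before it starts to hurt?*

## Worked example

The bundled historical scenario is the Israeli Defense Forces field
hospital that responded to the 2010 Haiti earthquake: 1111 patients
treated over 10 days, capacity reached before day 2. With the closure
constraint τ = t₉₉ − t₂ = t₁ = 2 d, the rates are identified uniquely:

```bash
$ surgekin fit --t1 2 --t99 10 --tau 2
k_a = 0.158 +/- 0.066 day^-1
k_d = 1.151 +/- 0.378 day^-1
k'  = 0.122 +/- 0.014 day^-1
branch: ka<kd  residual: 3.99e-30
```

The admission rate (0.158/d) is the slowest step; the uncertainties are
one standard deviation from the curvature of the squared-error surface.
Adding a hypothetical PTC running at the same rates as the adult center
(`python examples/ptc_what_if.py`):

```
queue exhausted at t2 = 4.07 d   (was 8 d with no PTC)
99% discharged at t99 = 6.52 d  (was 10 d with no PTC)
```

— admission time is nearly halved and total treatment time cut by more
than a third. A *slow* PTC is another matter
(`python examples/trapping_effect_scan.py`): scaling all PTC rates by a
factor s shows t₉₉ *rising* to a peak near s ≈ 0.045 (patients trapped in
a center that cannot discharge them) and only falling below the 10-day
baseline for s > 0.41. With literature death rates
(`python examples/mortality_with_and_without_ptc.py`), 24.1% of the
pediatric surge is deceased at day 10 without a PTC versus 15.3% with
one — a 37% relative mortality-risk reduction.

Other entry points: `surgekin simulate --config <scenario.yaml> --out
traj.csv [--oracle]` writes closed-form (and optionally RK-integrated)
trajectories for any model variant; `surgekin sensitivity` prints the
local sensitivity and variance matrices; `examples/` holds one short
narrative script per capability.

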