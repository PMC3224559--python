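"""Fit the capacity model to the 2010 Haiti field-hospital timescales.

The IDF mobile field hospital treated 1111 patients in 10 days and
saturated before day 2.  With the closure assumption tau = t99 - t2 = t1
= 2 days, the three defining equations identify the admission rate ka,
the discharge rate kd, and the at-capacity throughput k' uniquely on the
admission-slower branch.
"""

from surgekinetics import (
    capacity_breakpoints,
    capacity_t99,
    fit_capacity_model,
    haiti_observations,
)

obs = haiti_observations()
fit = fit_capacity_model(obs)

print(f"observed:  t1 = {obs.t1_obs:g} d, t99 = {obs.t99_obs:g} d, tau = {obs.tau:g} d")
for name, value, sigma in zip(("k_a", "k_d", "k' "),
                              (fit.rates.ka, fit.rates.kd, fit.rates.k_prime),
                              fit.sigmas):
    print(f"{name} = {value:.3f} +/- {sigma:.3f} day^-1")

ts = capacity_breakpoints(fit.rates)
print(f"round trip: t1 = {ts.t1:.3f} d, t2 = {ts.t2:.3f} d, t99 = {capacity_t99(fit.rates):.3f} d")
# k_a is the pre-capacity admission rate of the surge cohort; k_d the
# pre-capacity discharge rate; k' the one-in-one-out throughput while the
# center is saturated. The round trip reproduces the observations exactly
# because the fit is root finding, not least squares.
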