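"""A surge that develops with a delay after the inciting event.

For slow-onset events (pandemics, floods, radiation exposure) the
affected population converts into the treatment-seeking surge at a
finite exposure rate ks, shifting and flattening the surge peak.
"""

from surgekinetics import DelayedRateSet, delayed_model_at, time_of_max_surge_delayed

rates = DelayedRateSet(ks=0.5, ka=0.2, kd=1.0)
t_peak = time_of_max_surge_delayed(rates)
peak = delayed_model_at(t_peak, rates)

print(f"exposure rate ks = {rates.ks} /d, admission ka = {rates.ka} /d, discharge kd = {rates.kd} /d")
print(f"surge peaks at t = {t_peak:.2f} d with {100 * peak.Ns:.1f}% of the cohort waiting")
for t in (0.0, 2.0, 5.0, 10.0, 20.0):
    s = delayed_model_at(t, rates)
    print(f"  t = {t:4.1f} d  exposed {s.Ne:.3f}  surge {s.Ns:.3f}  "
          f"admitted {s.Na:.3f}  discharged {s.Nd:.3f}")
# With a sudden event (ks -> infinity) the surge peak sits at t = 0; a
# finite exposure rate both delays the peak and lowers it, which relaxes
# the instantaneous load on the trauma center.
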