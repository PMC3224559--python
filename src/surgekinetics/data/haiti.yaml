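# Historical baseline scenario: the Israeli Defense Forces mobile field
# hospital that responded to the 2010 Haiti earthquake.  1111 patients were
# treated over 10 days and the hospital saturated before day 2; the closure
# assumption tau = t99 - t2 = t1 = 2 days makes the rate fit unique.
# Death rates: in-hospital 0.086/15 per day (Hanshin-Awaji, 8.6% of admitted
# patients over 15 days); untreated surge scaled by 0.93/0.07 (Chi-Chi: 7% of
# fatalities died while hospitalized); discharged at the US background rate.
variant: ptc_mortality
n0_persons: 1111
fit:
  t1_days: 2.0
  t99_days: 10.0
  tau_days: 2.0
deaths:
  omega_s_per_day: 0.07617142857142857   # (0.93/0.07) * 0.086/15
  omega_a_per_day: 0.005733333333333333  # 0.086/15
  omega_p_per_day: 0.005733333333333333
  omega_d_per_day: 2.0e-5                # 8 per 1000 per year
threshold: 0.99
t_max_days: 14.0
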