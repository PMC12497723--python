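"""Weibull time-to-onset analysis of a synthetic exposed cohort.

Onsets are generated at shape 0.38 / scale 46.9 days (a strongly
front-loaded hazard).  The example computes onset days from therapy-start
and event dates, summarises them, fits the Weibull by maximum likelihood
and prints the failure-type classification.
"""

import pvsignal as pv

config = pv.SyntheticConfig(
    n_cases=4_000, p_exposed=0.6, p_onset_recorded=1.0, seed=2
)
cases = pv.assemble_cases(pv.generate(config))
exposed, _ = pv.filter_primary_suspect(cases, config.target_drug)

sample = pv.compute_onsets(exposed, config.target_drug)
median, q1, q3 = pv.summarize_onsets(sample)
print(f"{len(sample.days)} onsets "
      f"({sample.n_excluded_missing} excluded for missing dates, "
      f"{sample.n_excluded_negative} negative)")
print(f"median {median:.0f} days, IQR {q1:.0f}-{q3:.0f}")

labels = ("0-30", "31-60", "61-90", "91-180", "181-360", ">360")
for label, count, frac in zip(labels, pv.bin_onsets(sample),
                              pv.bin_fractions(pv.bin_onsets(sample))):
    print(f"  {label:8s} {count:5d}  ({frac:.1f}%)")

fit = pv.fit_weibull(sample)
print(f"\nWeibull scale alpha = {fit.alpha:.1f} days "
      f"({fit.alpha_lo:.1f}-{fit.alpha_hi:.1f})")
print(f"Weibull shape beta  = {fit.beta:.3f} "
      f"({fit.beta_lo:.3f}-{fit.beta_hi:.3f}) -> {fit.classification}")
print("Shape < 1 with its whole CI below 1 means the hazard decreases "
      "with time on drug: most events arise early in therapy.")
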