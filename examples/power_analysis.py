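"""Sample-size planning for a two-group eyeblink experiment.

The primary outcome is normalized eye closure; a meaningful group
difference of 0.2 NEC with a between-mouse SD of about 0.2 is a
standardized effect of d = 1. At 80% power and two-sided alpha 0.05 the
noncentral-t iteration returns 17 mice per group.
"""

from eyeblink.stats_models import power_sample_size, t_test_power

n = power_sample_size(delta=0.2, sd=0.2, power=0.80, alpha=0.05)
print(f"required mice per group: {n}")
print(f"power at n={n}: {t_test_power(1.0, n):.3f}")
print(f"power at n={n - 1}: {t_test_power(1.0, n - 1):.3f} (just below 80%)")

for d in (0.5, 0.8, 1.0, 1.5):
    print(f"effect size d={d}: n per group = "
          f"{power_sample_size(d, 1.0, power=0.80, alpha=0.05)}")
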