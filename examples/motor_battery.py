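"""Run the four motor-task analyses on simulated tables.

Ladder: two-part analysis (mixed logistic on clean sweeps, mixed beta on
mixed-trial proportions). Rotarod: Cox proportional hazards with per-mouse
frailty on latencies censored at 300 s. Beam and grip: log-scale linear
mixed models, with grip strength back-translated to newton. The simulated
tables carry no genotype effect, so genotype p-values should usually be
non-significant while day/width effects are detected.
"""

from eyeblink.motor_tasks import (
    beam_analyze,
    grip_analyze,
    ladder_analyze,
    rotarod_analyze,
)
from eyeblink.simulate import MotorParams, simulate_motor_tables

tables = simulate_motor_tables(MotorParams(n_per_genotype=8, seed=3))

logit, beta = ladder_analyze(tables["ladder"], random="intercept")
print("ladder clean-sweep logistic (Wald chi-square):")
print(logit.terms.round(4).to_string(index=False))
print("ladder mixed-trial beta regression (LR):")
print(beta.terms.round(4).to_string(index=False))

cox = rotarod_analyze(tables["rotarod"])
print(f"\nrotarod Cox frailty: {cox.extra['n_events']} falls, "
      f"frailty variance {cox.extra['theta']:.3f}")
print(cox.terms.round(4).to_string(index=False))

beam = beam_analyze(tables["beam"])
print("\nbalance beam log-time LMM (width effect should be negative and"
      " strong):")
print(beam.terms.round(4).to_string(index=False))

grip = grip_analyze(tables["grip"])
print("\ngrip strength, back-translated group means (newton):")
print(grip.extra["back_translated"].round(2).to_string(index=False))
d = grip.extra["difference"]
print(f"difference {d['estimate']:.2f} N "
      f"[{d['ci_low']:.2f}, {d['ci_high']:.2f}], p = {d['p']:.2f}")
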