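"""Simulate a small eyeblink-conditioning cohort and score it.

Builds a 4-mouse cohort (2 per genotype) over six training days, runs the
full scoring path (50 Hz zero-phase filter, baseline alignment, 7x IQR
validity, UR normalization, CR detection) and prints the per-day CR
proportions. Expect the CR proportion to grow over days 1-3, dip at the
ISI switch (day 4 here) and grow again.
"""

from eyeblink.cr_metrics import aggregate_cohort, score_cohort
from eyeblink.simulate import SimParams, simulate_cohort

params = SimParams(n_per_genotype=2, days_phase1=3, days_phase2=3,
                   n_blocks=6, seed=1)
trials, truth = simulate_cohort(params)
print(f"simulated {len(trials)} trials "
      f"({params.n_per_genotype * 2} mice x {params.n_days} days)")

cr_table, summaries, qc = score_cohort(trials)
print(f"valid CS-only trials scored: {len(cr_table)}; "
      f"invalid trials: {qc['n_invalid'].sum()}")

agg = aggregate_cohort(summaries)
print("\nmean CR proportion per day and genotype "
      "(fraction of valid CS-only trials with a conditioned response):")
print(agg.pivot(index="day", columns="genotype",
                values="cr_proportion_mean").round(3))
print("\nmean peak latency (ms after CS onset) on CR trials — adapts toward"
      " the US onset (250 ms on days 1-3, 500 ms on days 4-6):")
print(agg.pivot(index="day", columns="genotype",
                values="mean_peak_ms_mean").round(0))
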