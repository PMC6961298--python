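"""Full pipeline on a small simulated cohort: phantoms → voxel fitting →
VOI aggregation → group statistics.

Simulates a 12 + 8 patient cohort of stretched-exponential phantoms at
SNR 100, fits the SEM model at every tumor voxel, aggregates to
per-patient VOI values and prints the group comparison.  Fitted group
means should track the generated truth closely.
"""

from mbdwi import SimConfig, fit_cohort, generate_cohort
from mbdwi.stats import parameter_comparison_table

sim = generate_cohort(SimConfig(seed=11, n_responders=12, n_nonresponders=8))
table = fit_cohort(sim)  # fits the generating model (SEM)

print(parameter_comparison_table(table).to_string(index=False))
print()
for param in ("ddc", "alpha"):
    for group in ("responder", "non-responder"):
        sub = table[table["group"] == group]
        print(f"{param:>5} {group:>13}: fitted {sub[param].mean():.3f} "
              f"vs generated {sub['true_' + param].mean():.3f}")
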