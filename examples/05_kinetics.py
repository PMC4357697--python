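"""Initial-rate kinetics from densitometric cleavage time courses.

Cleavage fractions at early time points are fit by ordinary least squares;
slopes are normalized per unit enzyme and compared as ratios against a
reference substrate.
"""

from minicleave import initial_rate, preference_profile, relative_rates
from minicleave.simulate import simulate_timecourse

# three substrates cleaved at different true rates (fraction/min), sampled
# at 15/30/45 min with mild densitometric noise
slopes = {"pKS-ACCU": 0.010, "NGS-ACCU": 0.0085, "NGS-AUCU": 0.0038}
courses = simulate_timecourse(slopes, [15, 30, 45], noise_sd=0.005, rng=4)

estimates = [initial_rate(tc) for tc in courses]
for e in estimates:
    print(f"{e.substrate_id:>9}: slope {e.slope:.4f} +/- {e.stderr:.4f} /min")

table = relative_rates(estimates, "pKS-ACCU").set_index("substrate_id")
for sub, row in table.iterrows():
    print(f"{sub:>9}: relative rate {row.relative_rate:.2f} "
          f"({row.percent_reduction:+.0f}% vs reference)")
print("(a substrate with a substituted core cleaves ~62% slower, matching")
print(" the preference ordering pKS-ACCU > NGS-ACCU > NGS-AUCU)")

profile = preference_profile(estimates, "pKS-ACCU")
print("preference profile (per-enzyme, reference = pKS-ACCU):")
print(profile.round(2).to_string())
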