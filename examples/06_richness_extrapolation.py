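"""Extrapolate total vOTU richness from a survey with a BCa bootstrap.

Uses the survey proportions (217 vOTUs across 123 of 2004 sampled species)
and scales the per-species rate to 74,140 described vertebrates, with a 95%
bias-corrected and accelerated bootstrap interval over species resampling.
"""
from ervi.stats import RichnessInput, estimate_total_votus, prevalence_summary

prev = prevalence_summary(123, 2004)
print(f"invaded species: {prev.n_hit}/{prev.n_total} = {prev.percent}%")

counts = {f"species{i}": c for i, c in enumerate([1] * 73 + [3] * 44 + [2] * 6 + [0] * 1881)}
estimate = estimate_total_votus(RichnessInput(counts, n_total_species=74140, reps=10000, seed=1234))
print(f"rate-scaled richness: {estimate.point:.1f} vOTUs "
      f"(95% BCa CI {estimate.ci_low:.1f} - {estimate.ci_high:.1f}; "
      f"z0 = {estimate.z0:.4f}, a = {estimate.a:.4f}, {estimate.reps} replicates)")
print()
print("The point estimate is the mean per-species vOTU count scaled to all")
print("described vertebrates; the interval reflects species-sampling noise.")
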