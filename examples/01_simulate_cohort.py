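"""Generate a synthetic diabetes cohort and apply the complete-case filter.

The generator draws each participant's latent healthcare-use profile, true
annual visit counts (Poisson), bins them to the questionnaire's four ordinal
levels, and blanks visit answers completely at random for roughly 47% of
records — which is what the complete-case filter then removes.
"""

import careprofiles as cp

cfg = cp.default_config(seed=1)
sim = cp.simulate_cohort(cfg, n=1033)
kept, n_excluded = cp.filter_clustering_complete(sim.cohort)

print(f"simulated records:        {len(sim.cohort)}")
print(f"excluded (missing visit): {n_excluded}")
print(f"clustering sample:        {len(kept)}")
print()
print("Ordinal visit answers of the first records:")
print(sim.cohort.df.filter(like="visit_").head(5).to_string())
print()
print("Each row is one participant; 'never'/'once'/'2-3'/'4+' are the")
print("questionnaire's visit-frequency categories for the past 12 months.")
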