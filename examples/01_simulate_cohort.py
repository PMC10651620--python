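"""Generate a synthetic longitudinal cohort and inspect its structure.

The generator emulates an aging cohort: each subject is assigned one of
four decline phenotypes, memory (CVLT points) and gait speed (m/s) follow
subject-specific lines around group-mean annual slopes, and a quantified
metabolite panel (µM) carries planted group×time effects, correlated
modules, and left-censoring at per-metabolite limits of detection.
"""

from dualtraj import simulate as sim

params = sim.default_params("desk", seed=1)
dataset, truth = sim.generate_cohort(params)

print(f"subjects: {len(dataset.subjects)}")
print(f"visits:   {len(dataset.visits)} "
      f"(mean {len(dataset.visits) / len(dataset.subjects):.2f} per subject)")
print(f"metabolites: {len(dataset.panel.metabolites)}")
print("planted group sizes:")
print(truth.group.value_counts().to_string())
frac = dataset.panel.below_lod.mean(axis=0)
print(f"median below-LOD fraction: {frac.median():.3f}")
# The group sizes reflect the configured proportions (0.47/0.20/0.20/0.13);
# the below-LOD fraction tracks the configured censoring quantile (0.05).
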