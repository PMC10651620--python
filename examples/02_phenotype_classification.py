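"""Estimate annual memory/gait slopes and classify the four decline groups.

Each subject's annual rate of change is the OLS slope over their visits
(points with a dementia diagnosis onward are excluded); the lowest tertile
of each slope distribution defines "declining", and the cross of the two
indicators yields no-decline / memory-only / gait-only / dual-decline.
"""

from dualtraj import simulate as sim
from dualtraj.cohort import apply_baseline_filters
from dualtraj.phenotype import classify_phenotypes, estimate_annual_slopes, tertile_cutpoints

dataset, truth = sim.generate_cohort(sim.default_params("desk", seed=1))
dataset, excluded = apply_baseline_filters(dataset)
print(f"excluded at baseline: {len(excluded)}")

slopes, omitted = estimate_annual_slopes(dataset)
cuts = tertile_cutpoints(slopes)
print(f"tertile cut-points: memory {cuts.memory_cut:.3f} points/yr, "
      f"gait {cuts.gait_cut:.4f} m/s/yr")

labels, _ = classify_phenotypes(slopes, cuts)
print(labels["label"].value_counts().to_string())

merged = labels.merge(
    truth.group.rename("true_group"), left_on="subject_id", right_index=True
)
acc = (merged["label"] == merged["true_group"]).mean()
print(f"agreement with planted groups: {acc:.2f}")
# Tertile cuts force about one third of subjects into each declining arm;
# agreement with the planted labels is imperfect because slopes are
# estimated from noisy trajectories with ~2.7 visits each.
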