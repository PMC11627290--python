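"""Cluster conditions by feature-prevalence profile.

Each condition (aging, comparison diseases) is a vector of feature
prevalences (percent of individuals affected). Conditions are clustered
with uncentered similarity and average linkage; missing cells are handled
pairwise-complete. The 2-SD abnormality rule converts continuous
measurements into a prevalence first.
"""

import numpy as np

import phenomine as pm

# deriving a prevalence from continuous values: percent of elderly more
# than 2 SD away from the young mean
rng = np.random.default_rng(31)
elderly_lactate = rng.normal(1.8, 0.9, size=200)  # mmol/l, shifted upward
p = pm.abnormality_prevalence(young_mean=1.0, young_sd=0.3, elderly_values=elderly_lactate)
print(f"lactate accumulation prevalence: {p:.1f}% of elderly beyond the 2-SD band")

profiles = {
    "aging":            [62, 38, 25, 12, 30],
    "werner syndrome":  [70, 45, 30, 15, 35],
    "progeria":         [65, 40, 28, 18, 33],
    "melas":            [10, 80, 60, 55, 8],
    "merrf":            [12, 75, 65, 50, 10],
    "control disease":  [5, 5, 8, 90, 4],
}
features = ["cataract", "myopathy", "hearing loss", "seizures", "osteoporosis"]
records = [
    pm.PrevalenceRecord(f, cond, float(v), cohort_size=1000)
    for cond, vals in profiles.items()
    for f, v in zip(features, vals)
]
matrix = pm.to_matrix(records)
print(f"\n{len(matrix.conditions)} conditions x {len(matrix.features)} features, "
      f"{matrix.total_cohort_size} individuals total")

dend = pm.condition_clustering(matrix, n_boot=100, seed=32)
print(pm.to_newick(dend))
print("\nAging clusters with the premature-aging diseases (similar prevalence")
print("profiles), away from the mitochondrial and control conditions; internal")
print("labels are AU|BP support percentages.")
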