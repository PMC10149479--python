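"""Longitudinal adherence-trajectory clustering.

Builds the 5-year quarterly CMA matrix for patients with >= 3 years of
follow-up, imputes missing tails with trajectory means, fits k-means for
k = 2..6, reports the quality criteria, and writes centroids,
assignments and group shares for the selected model.

Usage: python analysis/03_trajectories.py [seed]
"""

import sys

sys.path.insert(0, "src")

import pandas as pd

from hivcma import claims_io, trajectories

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 42

cma3 = pd.read_csv("results/cma_3m.csv")
tables = claims_io.read_tables("results/cohort")
elig = claims_io.apply_eligibility(tables)
trj = cma3[cma3["patient_id"].isin(elig.analysis_ids["trajectory"])]

idx, mat, obs = trajectories.build_trajectory_matrix(trj)
print(f"{len(idx)} patients with >=12 observed quarters; "
      f"{(~obs).sum()} of {obs.size} cells imputed")
full = trajectories.impute_trajectory(mat)

model, crit = trajectories.select_k(full, range(2, 7), seed=seed)
print(crit.round(3).to_string(index=False))
print(f"selected k={model.k} by the Calinski-Harabasz criterion")

shares = trajectories.group_shares(model)
for label, share in sorted(shares.items(), key=lambda kv: -kv[1]):
    print(f"  {label:<26s} {share:.1%}")

pd.DataFrame(model.centroids, columns=[f"q{j}" for j in range(20)]).assign(
    label=[model.labels[j] for j in range(model.k)]
).to_csv("results/trajectory_centroids.csv", index=False)
pd.DataFrame({"patient_id": idx, "cluster": model.assignments,
              "label": [model.labels[a] for a in model.assignments]}
             ).to_csv("results/trajectory_assignments.csv", index=False)
crit.to_csv("results/trajectory_criteria.csv", index=False)
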