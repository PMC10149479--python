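"""Generate the synthetic claims cohort used by the downstream analyses.

Writes the four canonical tables plus ground truth to results/cohort/
and prints the generated margins (sex, mental-health prevalence,
behaviour-class shares) next to the scenario's planted values.

Usage: python analysis/01_generate_cohort.py [n_patients] [seed]
"""

import sys

sys.path.insert(0, "src")

from hivcma import claims_io, synth

n = int(sys.argv[1]) if len(sys.argv) > 1 else 3000
seed = int(sys.argv[2]) if len(sys.argv) > 2 else 42

cfg = synth.study_scenario(n_patients=n, seed=seed)
tables, truth = synth.generate_cohort(cfg)
claims_io.write_tables(tables, "results/cohort")
truth.patients.to_csv("results/cohort/ground_truth.csv", index=False)

shares = truth.patients["behaviour_class"].value_counts(normalize=True)
print(f"generated {n} patients (seed {seed}) -> results/cohort/")
print(f"  pharmacy claims: {len(tables.pharmacy):>7d}")
print(f"  diagnosis claims:{len(tables.diagnoses):>7d}")
print(f"  lab results:     {len(tables.labs):>7d}")
print(f"  female share:    {(tables.patients['sex'] == 'female').mean():.3f}"
      f"  (planted {cfg.female_prob})")
for name, target in zip(synth.CLASS_NAMES, cfg.class_shares):
    print(f"  {name:<26s} {shares.get(name, 0):.3f}  (planted {target:.3f})")
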