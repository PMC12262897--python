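"""Select the split function and threshold constant by grid search.

Mirrors the published protocol: fix one train/validation split, fit a full
BiMM for every candidate — k1 from 0.05 to 0.95 and k2 from 1.05 to 1.95
in steps of 0.05, plus the parameter-free h3 (39 candidates) — and keep
the candidate with the highest validation AUC. Selection runs on a
validation split carved from the training persons, never on the final
test set.
"""

import dataclasses

from bimm import (
    RFParams,
    default_fixture_config,
    generate_cohort,
    grid_search_split,
    partition_by_individual,
)

config = dataclasses.replace(default_fixture_config(seed=0), n_persons=400)
cohort = generate_cohort(config)

train_all, test = partition_by_individual(cohort, 0.7, seed=1)
train, val = partition_by_individual(train_all, 0.7, seed=2)

spec, best_auc, trace = grid_search_split(
    train,
    val,
    RFParams(n_trees=60, min_samples_leaf=5, majority_class_weight=0.37),
    max_iter=15,
    seed=3,
)

print(f"candidates evaluated: {len(trace)}")
print(f"selected: {spec.kind} with constant {spec.constant}")
print(f"validation AUC: {best_auc:.4f}")
print()
print("AUC by candidate (head):")
print(trace.head(8).round(4).to_string(index=False))
print()
print("The trace records one full BiMM fit per (function, constant) pair;")
print("ties go to h1 before h2 before h3, then to the smaller constant.")
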