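"""Normalize trajectories, extract the geometric feature pool, build class
prototypes, and classify one held-out sequence with single-descriptor
DTW weak classifiers.
"""

import numpy as np

from geomexpr import (
    GenConfig,
    build_feature_pool,
    build_prototypes,
    compute_reference,
    default_class_models,
    extract_all,
    generate_dataset,
    normalize_sequence,
    resample_sequence,
    weak_classify,
)

data = generate_dataset(default_class_models(), GenConfig(n_per_class=10, seed=1))
held_out, train = data[0], data[1:]

ref = compute_reference(train)  # average neutral-frame geometry
train_n = [resample_sequence(normalize_sequence(s, ref), 16) for s in train]
pool = build_feature_pool(52)
print(f"feature pool: {len(pool)} descriptors "
      f"({sum(f.kind == 'type1' for f in pool)} type-1, "
      f"{sum(f.kind == 'type2' for f in pool)} type-2)")

bank = build_prototypes(train_n, pool)
print(f"prototype bank: {bank.n_classes} classes x {len(pool)} descriptors, "
      f"{bank.values.shape[2]} elements each")

x = extract_all(normalize_sequence(held_out, ref), pool)
votes = [weak_classify(x, bank, f) for f in pool[:40]]
counts = {c: votes.count(c) for c in bank.classes}
print(f"true class {held_out.label}; votes of the first 40 weak classifiers: {counts}")
# Single descriptors are noisy voters - most agree with the true class
# here only because the synthetic classes are well separated; boosting
# exists to weight and combine them.
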