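"""Train a tiny CNN ensemble and ask it to recommend a scattering model.

A micro dataset (sphere vs oriented cylinder, easily separable patterns) is
simulated, two seed-varied compact CNNs are trained, and a fresh sphere image
is fed to the ensemble; its top-5 SoftMax scores over the 46-model catalogue
are printed next to the 1/46 = 0.021 uniform baseline. Takes a few minutes on
one CPU core.
"""

import numpy as np

from sansml import (
    EnsembleModel,
    SamplingPlan,
    TrainingConfig,
    clean_dataset,
    generate_dataset,
    get_config,
    recommend,
    simulate_pattern,
    split_dataset,
    train_model,
)
from sansml.preprocessing import preprocess_stack

plan = SamplingPlan(
    models=["sphere", "cylinder aniso"],
    points_per_model=30,
    absorption_levels=(0.0,),
    configs=[get_config(24)],
    n_neutrons=50_000,
    base_seed=3,
)
cleaned, _ = clean_dataset(generate_dataset(plan))
parts = split_dataset(cleaned, (0.70, 0.20, 0.10), seed=3)
Xtr = preprocess_stack(parts["train"].data)
Xte = preprocess_stack(parts["test"].data)
print(f"dataset: {len(Xtr)} train / {len(Xte)} test images")

members = []
for seed in (0, 1):
    cfg = TrainingConfig(epochs=3, lr=1e-3, seed=seed, batch_size=16)
    m = train_model("compact", (Xtr, parts["train"].target), (Xte, parts["test"].target), cfg)
    print(f"member seed {seed}: test accuracy per epoch "
          f"{[round(a, 2) for a in m.history['test_acc']]}")
    members.append(m)

ensemble = EnsembleModel(members)
probe = simulate_pattern("sphere", {"radius": 80.0, "background": 0.01},
                         config=get_config(24), n_neutrons=100_000, seed=99)
rec = recommend(ensemble, probe.counts, k=5)
print(f"\ntop-5 recommendation for an unseen sphere pattern "
      f"(uniform baseline {rec.baseline:.3f}):")
for name, score in rec.ranked:
    print(f"  {score:.3f}  {name}")
print("a well-trained ensemble concentrates its SoftMax mass on 'sphere';"
      " scores near the baseline mean the image carries no usable signature")
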