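"""Residue-level functional-site scoring with class activation maps.

Trains the network on a small synthetic dataset, then asks, for a test
protein that carries a function label: which residues drive that
prediction?  The gradient-weighted class activation map scores every
residue in [0, 1]; residues scoring >= 0.5 are called as functional sites
and compared against the planted ground-truth motif residues.

Run:  python examples/03_functional_sites.py
"""

import numpy as np

from evograph import (
    SyntheticFunctionSpec,
    TrainConfig,
    activation_scores,
    call_functional_sites,
    generate_function_dataset,
    site_agreement,
    train,
)

spec = SyntheticFunctionSpec(n_proteins=1000, length=30, seed=5)
dataset, site_map = generate_function_dataset(spec)
tc = TrainConfig(seed=5, max_epochs=600, patience=600, target_validation_loss=1.0)
params, _ = train(dataset, tc, hidden=32)

shown = 0
agreements = []
for idx in dataset.splits["test"]:
    for c in range(spec.n_labels):
        if (idx, c) not in site_map:
            continue
        g = dataset.proteins[idx]
        profile = activation_scores(params, g, c, class_label=dataset.vocabulary[c])
        called = call_functional_sites(profile, cutoff=0.5)
        truth = site_map[(idx, c)]
        agreement = site_agreement(profile, set(truth), cutoff=0.5)
        agreements.append(agreement["auroc"])
        if shown < 3:
            shown += 1
            print(f"{g.protein_id}, label {dataset.vocabulary[c]}:")
            print(f"  planted motif residues: {truth}")
            print(f"  called sites (score >= 0.5): {called}")
            print(f"  AUROC {agreement['auroc']:.3f}  "
                  f"precision {agreement['precision']:.2f}  "
                  f"recall {agreement['recall']:.2f}")
            top = np.argsort(profile.scores)[::-1][:5]
            print("  top residues:",
                  [(int(i) + 1, round(float(profile.scores[i]), 2)) for i in top])

print(f"\nmedian AUROC of planted-site recovery over "
      f"{len(agreements)} (protein, label) pairs: {np.median(agreements):.3f}")
# AUROC near 1 means the activation profile ranks the causal motif residues
# above the rest of the chain, i.e. the model's evidence localizes on the
# residues that actually determine the label.
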