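"""Expected-gradients attribution on the hierarchical simulation.

Trains the CNN on labels from the hierarchical enhancer/silencer rule
(promoter 20, enhancers 5 and 35, silencer 45), computes per-cell signed
attribution maps, and aggregates the population top decile per entry:
the ON map should peak at the enhancer-promoter entries (5,20) and (20,35),
the OFF map should be most negative at the silencer-promoter entry (20,45),
and the companion median-distance maps show those entries act via contact.
"""

import numpy as np

from tracenet import (
    ClassifierConfig,
    HierarchicalRule,
    aggregate_extreme_decile,
    build_dataset,
    calibrate_contact_threshold,
    compute_attributions,
    label_hierarchical,
    median_distance_of_extreme_decile,
    simulate_ensemble,
    train_cnn,
)
from tracenet.polymer_sim import fast_config

ens = simulate_ensemble(fast_config(n_examples=6000, seed=0))
coords = ens.coords()
d = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
rule = HierarchicalRule()
rule.contact_threshold = calibrate_contact_threshold(ens, 0.30, rule)
labels = label_hierarchical(ens, rule, seed=1)
ds = build_dataset(d, labels, seed=2)
model = train_cnn(ds, ClassifierConfig(seed=3))

rng = np.random.default_rng(4)
Xtr = ds.standardized_matrices("train")
background = Xtr[rng.choice(len(Xtr), 100, replace=False)]
test_idx = ds.indices("test")
sel = rng.choice(len(test_idx), 400, replace=False)
attr = compute_attributions(
    model, ds.standardized_matrices("test")[sel], background,
    n_samples=32, seed=5,
)
y_sel = ds.labels[test_idx[sel]]
agg = aggregate_extreme_decile(attr, y_sel)
med = median_distance_of_extreme_decile(attr, ds.matrices[test_idx[sel]], y_sel)

iu = np.triu_indices(52, k=2)
on_vals = agg.on_top_decile_mean[iu]
top = np.argsort(on_vals)[::-1][:3]
print("strongest ON-predictive entries (1-based barcodes):")
for k in top:
    i, j = iu[0][k], iu[1][k]
    print(f"  ({i + 1:2d},{j + 1:2d}): top-decile SHAP {on_vals[k]:.4f}, "
          f"median distance {med['on_median_distance'][i, j]:.0f} nm")
k = np.argmin(agg.off_bottom_decile_mean[iu])
i, j = iu[0][k], iu[1][k]
print(f"strongest OFF-predictive entry: ({i + 1},{j + 1}) with "
      f"bottom-decile SHAP {agg.off_bottom_decile_mean[i, j]:.4f}, "
      f"median distance {med['off_median_distance'][i, j]:.0f} nm")
print(f"(contact threshold was {rule.contact_threshold:.0f} nm; small median "
      "distances at the peaks confirm these are contact-driven features)")
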