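"""Higher-order cooperativity from attribution co-occurrence.

Compares two hierarchical simulations that differ only in enhancer wiring:
independent (either enhancer activates at 0.8) versus cooperative (single
contact 0.1, both contacts 0.8). For each matrix entry the cooperativity
map gives the average frequency with which other entries are simultaneously
attribution-extreme in the same cells; cooperative wiring should produce a
stronger peak at the enhancer-promoter entries in ON cells. In OFF cells
the ordering tends to reverse (under independent wiring both enhancers
must be disengaged at once for the cell to be OFF), though at demo scale
that contrast sits near the noise floor.
"""

import numpy as np

from tracenet import (
    ClassifierConfig,
    HierarchicalRule,
    build_dataset,
    calibrate_contact_threshold,
    compute_attributions,
    cooperativity_map,
    label_hierarchical,
    simulate_ensemble,
    train_cnn,
)
from tracenet.polymer_sim import fast_config

ens = simulate_ensemble(fast_config(n_examples=6000, seed=0))
coords = ens.coords()
d = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)

EP_ENTRIES = [(4, 19), (19, 34)]  # 0-based E1-P and E2-P


def run(variant):
    rule = (HierarchicalRule() if variant == "independent"
            else HierarchicalRule.cooperative_default())
    # both variants calibrated to the same achievable class balance (the
    # cooperative wiring caps the expected ON fraction below 0.2)
    rule.contact_threshold = calibrate_contact_threshold(ens, 0.15, rule)
    labels = label_hierarchical(ens, rule, seed=1)
    ds = build_dataset(d, labels, seed=2)
    model = train_cnn(ds, ClassifierConfig(seed=3))
    rng = np.random.default_rng(4)
    Xtr = ds.standardized_matrices("train")
    bg = Xtr[rng.choice(len(Xtr), 100, replace=False)]
    test_idx = ds.indices("test")
    sel = rng.choice(len(test_idx), 400, replace=False)
    attr = compute_attributions(
        model, ds.standardized_matrices("test")[sel], bg, n_samples=16, seed=5
    )
    y = ds.labels[test_idx[sel]]
    out = {}
    for side in ("on", "off"):
        cmap = cooperativity_map(attr, y, side=side, percentile=95.0,
                                 n_permutations=0)
        peak = max(
            np.nanmax(cmap.avg_cooccurrence[i - 1 : i + 2, j - 1 : j + 2])
            for i, j in EP_ENTRIES
        )
        out[side] = peak
    return out


results = {v: run(v) for v in ("independent", "cooperative")}
print("peak co-occurrence at enhancer-promoter entries:")
for side in ("on", "off"):
    print(f"  {side.upper():3s} cells: cooperative "
          f"{results['cooperative'][side]:.3f} vs independent "
          f"{results['independent'][side]:.3f}")
print("(ON cells: cooperative > independent reveals the hub requirement. "
      "In OFF cells the ordering tends to reverse - independent wiring "
      "silences only when both enhancers disengage at once - but that "
      "contrast is subtle and needs larger samples than this demo uses)")
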