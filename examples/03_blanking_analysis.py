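"""Occlusion (blanking) interpretation of a trained CNN.

Slides a window of barcodes across the test matrices, zeroes the window's
rows and columns (the dataset average in standardized space), and converts
the resulting AUC into a normalized predictability score (100 = unblanked,
0 = chance). On the contact-rule simulation the profile should be flat near
100 everywhere except windows touching the enhancer (monomer 20) or the
promoter (monomer 40), where it dips.
"""

import numpy as np

from tracenet import (
    ClassifierConfig,
    ContactRule,
    NoiseSpec,
    blanking_scan,
    build_dataset,
    label_binary_contact,
    simulate_ensemble,
    train_cnn,
)
from tracenet.polymer_sim import fast_config

ens = simulate_ensemble(fast_config(n_examples=6000, seed=0))
coords = ens.coords()
d = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
labels = label_binary_contact(ens, ContactRule(), NoiseSpec(0.5), seed=1)
ds = build_dataset(d, labels, seed=2)
model = train_cnn(ds, ClassifierConfig(seed=3))

prof = blanking_scan(
    model,
    ds.standardized_matrices("test"),
    ds.split_labels("test"),
    window_size=5,
    n_trials=5,
    seed=4,
)
mp = prof.mean_profile()
print(f"unblanked test AUC: {prof.base_auc:.3f}")
print("predictability by window center (1-based barcode):")
for c, v in zip(prof.centers, mp):
    marker = " <-- enhancer" if c == 20 else (" <-- promoter" if c == 40 else "")
    print(f"  {c:2d}: {v:6.1f}{marker}")
print(f"minimum {mp.min():.1f} at center {prof.centers[mp.argmin()]}")
print("(scores near 100 mean the window carried no unique information; "
      "the dips localize the regulatory elements the rule actually used)")
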