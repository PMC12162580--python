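"""Generate a small phantom dataset and describe what it contains.

Each slice mimics an axial orbital-apex CT section: per side a dark
air-filled sphenoid sinus (SS), a bright internal carotid artery disc (ICA)
touching the sinus' lateral border, and a thin optic-canal ring (OC) that
may carry a fracture (gap + displaced fragment).  Boxes cover the canal and
carry one of four categories: Fracture/Non-fracture x Right/Left.
"""

import numpy as np

from apexseg.phantom import CATEGORY_NAMES, PhantomConfig, generate_dataset

config = PhantomConfig()          # 64x64, default intensities and textures
train, test = generate_dataset(50, config, seed=7)

print(f"train slices: {len(train)}   test slices: {len(test)} (8:2 split)")
counts = np.zeros(4, dtype=int)
for s in train + test:
    for b in s.boxes:
        counts[b.category] += 1
for cat, n in zip(CATEGORY_NAMES, counts):
    print(f"  {cat:16s} {n:3d} boxes")
px = np.bincount(np.concatenate([s.mask.ravel() for s in train]),
                 minlength=4)
print("train pixel fractions  background/OC/ICA/SS:",
      np.round(px / px.sum(), 4))
# The canal ring is by far the smallest class -- the segmentation task is
# heavily class-imbalanced, which is why the training loss offers a Dice term.
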