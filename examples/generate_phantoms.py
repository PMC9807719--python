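"""Generate synthetic brain phantoms and inspect their class structure.

Creates a small seeded phantom set, prints the class allocation, and shows
the lesion-position/intensity features that make the three classes
separable by construction.
"""

import numpy as np

from tumorcnn import PhantomConfig, generate, lesion_features
from tumorcnn.data_io import LABEL_NAMES

manifest = generate(PhantomConfig(n_samples=60, image_size=64, seed=0))
print(f"generated {len(manifest)} phantoms, class counts {manifest.class_counts}")

feats = np.array([lesion_features(r.image) for r in manifest.records])
labels = manifest.labels
print("\nper-class lesion features (mean over samples):")
print(f"{'class':<14} {'radial distance':>16} {'area fraction':>14} {'peak intensity':>15}")
for c, name in enumerate(LABEL_NAMES):
    f = feats[labels == c]
    print(f"{name + '-like':<14} {f[:, 0].mean():>16.3f} {f[:, 1].mean():>14.4f} "
          f"{f[:, 2].mean():>15.3f}")
print("\nmeningioma-like lesions sit at the head rim (large radial distance),")
print("pituitary-like ones near the center; the glioma-like blob is the only")
print("mid-intensity lesion — position plus brightness separate the classes.")
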