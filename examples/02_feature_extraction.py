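"""Per-layer unit counts and pre-activation feature extraction.

The packaged 8-layer reference spec reproduces the classic architecture's
per-layer feature dimensions from its kernel/stride/padding geometry alone.
The desk-scale surrogate network (random seeded weights, fan-in scaled) is
what the synthetic analyses use: its features are deterministic given the
spec, and stored before the nonlinearity.
"""

import numpy as np

from featuregain.network import (
    default_spec,
    extract_features,
    layer_unit_counts,
    reference_8layer_spec,
)
from featuregain.stimuli import generate_synthetic_images

ref = reference_8layer_spec()
print("reference 8-layer architecture, pre-activation units per layer:")
for label, count in zip(ref.labels, layer_unit_counts(ref)):
    print(f"  {label}: {count:>7d}")

spec = default_spec(n_layers=5)
image = generate_synthetic_images(1, 32, seed=1)[0]
tensor = extract_features(spec, image)
print("\ndesk-scale 5-layer surrogate on a 32-pixel synthetic image:")
for label, z in zip(tensor.labels, tensor.layers):
    print(f"  {label}: {len(z):>5d} units, "
          f"{np.mean(z < 0):.0%} negative pre-activations "
          f"(stored unrectified), mean |z| = {np.abs(z).mean():.3f}")
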