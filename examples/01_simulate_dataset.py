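"""Generate a labeled synthetic root-tip dataset.

Renders 4-channel images (fluorescence 405/458 nm, two brightfield
channels) of a curved root whose developmental zones — meristematic (MZ),
early elongation (EEZ), late elongation (LEZ) — are tiled with cells
obeying the morphological length/width rules, plus ground-truth masks and
a metadata table, for a two-line × two-treatment study design.
"""

import numpy as np

from phroot.synthetic import SyntheticConfig, generate_dataset

config = SyntheticConfig(image_size=128, seed=1)
groups = [("Col-0", "mock"), ("Col-0", "BL"), ("bri1-301", "mock"), ("bri1-301", "BL")]
samples, metadata = generate_dataset(config, 3, groups, out_dir="scratch/example_data")

print(metadata.to_string(index=False))
sample = samples[0]
for zone, label in (("MZ", 4), ("EEZ", 2), ("LEZ", 3)):
    sel = sample.mask.labels == label
    measured = (
        sample.image.channel("fl458").astype(float)[sel]
        / sample.image.channel("fl405").astype(float)[sel]
    ).mean()
    print(f"{zone}: configured 458/405 ratio {sample.truth[zone]:.3f}, "
          f"measured over ground-truth pixels {measured:.3f}")
print("Zone pixel counts:", {int(k): int(v) for k, v in
      zip(*np.unique(sample.mask.labels, return_counts=True))})
# The measured ratios match the configured per-zone values up to the 5%
# multiplicative acquisition noise; labels are 0=background 1=root 2=EEZ 3=LEZ 4=MZ.
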