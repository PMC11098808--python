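"""Reproduce the study's dataset arithmetic: 155 -> 310 -> 61-sample test set.

Builds a manifest with the study's pre-augmentation composition (65 / 57 /
33 originals), doubles it with one offset+flip variant per image, then
applies the stratified 8:2 test split and 8:2 validation split.
"""

from collections import Counter

from resmini import (AugmentPolicy, ImageRecord, Split, SplitConfig,
                     augment_dataset, make_splits)

classes = ["ages_3_5", "ages_7_12", "adults"]
records = [
    ImageRecord(f"{classes[label]}_{i}", f"{classes[label]}_{i}.png",
                label, classes[label])
    for label, n in enumerate((65, 57, 33)) for i in range(n)
]
print(f"originals: {len(records)}")

augmented, _ = augment_dataset(records, AugmentPolicy(seed=0))
print(f"after augmentation: {len(augmented)} "
      f"({Counter(r.class_name for r in augmented)})")

assigned = make_splits(augmented, SplitConfig(seed=0))
sizes = Counter(r.split.value for r in assigned)
print(f"split sizes: {dict(sizes)}")
print("\nEach original gains exactly one offset+flip variant (155 -> 310); "
      "floor-per-class 20% of 130/114/66 gives the 61-record test set.")
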