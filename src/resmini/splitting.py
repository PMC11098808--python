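"""Stratified dataset splitting: 8:2 train/test, then 8:2 train/val.

Per class ``c`` with ``n_c`` records, the held-out part receives exactly
``floor(fraction * n_c)`` records chosen by a seeded shuffle; the rest stay.
With the study's post-augmentation class sizes 130/114/66 and a 20% test
fraction this yields 26 + 22 + 13 = 61 test records.  The seeded shuffle is
the only stochastic element, so a fixed seed fixes the split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .slice_io import ImageRecord, Split


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_fraction, self.val_fraction_of_train):
            if not 0 < f < 1:
                raise ValueError(f"fractions must be in (0, 1), got {f}")


def stratified_split(records: list[ImageRecord], fraction: float, seed: int,
                     ) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Disjoint, exhaustive (rest, held-out) partition, stratified by class.

    Held-out size per class is ``floor(fraction * n_c)`` — the rounding
    rule under which 20% of 130/114/66 totals 61.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    labels = sorted({r.label for r in records})
    rng = np.random.default_rng(seed)
    rest: list[ImageRecord] = []
    held: list[ImageRecord] = []
    for label in labels:
        members = [r for r in records if r.label == label]
        if not members:
            raise ValueError(f"class {label} has zero records")
        n_held = int(np.floor(fraction * len(members)))
        order = rng.permutation(len(members))
        held += [members[i] for i in order[:n_held]]
        rest += [members[i] for i in order[n_held:]]
    return rest, held


def make_splits(records: list[ImageRecord], config: SplitConfig,
                ) -> list[ImageRecord]:
    """Assign train/val/test to unassigned records (test first, then val).

    Output order: train, then val, then test (each in shuffled class order).
    """
    for r in records:
        if r.split is not Split.UNASSIGNED:
            raise ValueError(f"record {r.image_id!r} already assigned")
    train_val, test = stratified_split(records, config.test_fraction, config.seed)
    train, val = stratified_split(train_val, config.val_fraction_of_train,
                                  config.seed + 1)
    return ([replace(r, split=Split.TRAIN) for r in train]
            + [replace(r, split=Split.VAL) for r in val]
            + [replace(r, split=Split.TEST) for r in test])
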