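"""Deterministic dataset splitting."""

from __future__ import annotations

import numpy as np

from .annotations import AnnotatedImage


def split_dataset(dataset: list[AnnotatedImage],
                  ratio: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> dict[str, list[AnnotatedImage]]:
    """Shuffled train/val/test split.  Val and test sizes are
    floor(n * r / sum(ratio)); the remainder goes to train."""
    n = len(dataset)
    total = sum(ratio)
    n_val = n * ratio[1] // total
    n_test = n * ratio[2] // total
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    test_idx = set(order[n_val : n_val + n_test].tolist())
    splits = {"train": [], "val": [], "test": []}
    for i, ann in enumerate(dataset):
        tag = "val" if i in val_idx else "test" if i in test_idx else "train"
        ann.split = tag
        splits[tag].append(ann)
    return splits
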