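"""Train/test splitting of (augmented) tooth datasets.

The global train size is floor(train_fraction × N). Stratified mode (the
default) floors a per-class quota and then tops up from the largest classes
until the global count is met, so the printed arithmetic — 2688 objects at
fraction 0.70 → 1881 train / 807 test — holds exactly. Splitting happens
over the *augmented* objects by default, which lets variants of one physical
tooth straddle the split; ``group_aware`` splits by source tooth instead and
avoids that leakage at the price of approximate counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["DatasetSplit", "split_dataset", "split_indices"]


@dataclass
class DatasetSplit:
    train_fraction: float = 0.70
    stratified: bool = True
    group_aware: bool = False
    seed: int = 0
    train_ids: List[int] = field(default_factory=list)
    test_ids: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_indices(
    labels: Sequence,
    cfg: DatasetSplit,
    groups: Optional[Sequence] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Return (train_idx, test_idx) over positions of ``labels``."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 objects to split")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(cfg.seed)
    n_train = int(math.floor(cfg.train_fraction * n))

    if cfg.group_aware:
        if groups is None:
            raise ValueError("group_aware split requires group identifiers")
        groups = np.asarray(groups, dtype=object)
        uniq = sorted(set(groups.tolist()), key=str)
        order = rng.permutation(len(uniq))
        train_groups = set()
        count = 0
        for gi in order:
            if count >= n_train:
                break
            train_groups.add(uniq[gi])
            count += int((groups == uniq[gi]).sum())
        mask = np.array([g in train_groups for g in groups])
        return np.where(mask)[0], np.where(~mask)[0]

    if not cfg.stratified:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    classes = sorted(set(labels.tolist()), key=str)
    counts = {c: int((labels == c).sum()) for c in classes}
    for c in classes:
        if counts[c] < 2:
            raise ValueError(
                f"class {c!r} has only {counts[c]} object(s); stratified "
                "splitting needs at least one on each side"
            )
    quota = {c: max(1, math.floor(cfg.train_fraction * counts[c])) for c in classes}
    quota = {c: min(q, counts[c] - 1) for c, q in quota.items()}
    deficit = n_train - sum(quota.values())
    # top up (or shave) from the largest classes, deterministically
    by_size = sorted(classes, key=lambda c: (-counts[c], str(c)))
    k = 0
    while deficit != 0:
        c = by_size[k % len(by_size)]
        if deficit > 0 and quota[c] < counts[c] - 1:
            quota[c] += 1
            deficit -= 1
        elif deficit < 0 and quota[c] > 1:
            quota[c] -= 1
            deficit += 1
        k += 1
        if k > 10 * len(by_size) * (abs(deficit) + 1):
            raise ValueError("stratified quotas cannot meet the global train count")
    train_idx: List[int] = []
    test_idx: List[int] = []
    for c in classes:
        members = np.where(labels == c)[0]
        members = members[rng.permutation(len(members))]
        train_idx.extend(members[: quota[c]].tolist())
        test_idx.extend(members[quota[c] :].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def split_dataset(objects: Sequence, cfg: DatasetSplit):
    """Partition objects into (train, test) lists.

    Stratification keys on each object's ``label``; group-aware mode keys on
    the part of ``source_id`` before the augmentation-variant suffix ``#``.
    The index lists are recorded on ``cfg.train_ids`` / ``cfg.test_ids``.
    """
    labels = [getattr(o, "label", None) for o in objects]
    groups = None
    if cfg.group_aware:
        groups = [str(getattr(o, "source_id", "") or "").split("#")[0] for o in objects]
    tr, te = split_indices(labels, cfg, groups=groups)
    cfg.train_ids = tr.tolist()
    cfg.test_ids = te.tolist()
    return [objects[i] for i in tr], [objects[i] for i in te]
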