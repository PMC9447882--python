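"""Outcome-stratified 5-group partition and the derived 4 CV folds.

Records are split into k groups so that the favorable-outcome (CPC 1/2)
count and the non-favorable count each differ by at most one across groups.
Remainder records of both classes are handed to groups in one shared seeded
order, so the groups that receive a spare positive are among those receiving
a spare negative; with n = 8274 and 286 positives over 5 groups this yields
the size multiset {1654, 1654, 1655, 1655, 1656} with positives
{57, 57, 57, 57, 58}.  One group (the first in the seeded order) is reserved
as the held-out test set; the remaining four groups give four train/validation
fold pairs, each group validating exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["SplitPlan", "SplitError", "stratified_split", "cv_folds"]


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    group_assignment: np.ndarray  # record index -> group in {0..k-1}
    k: int
    test_group: int
    seed: int

    def group_indices(self, g: int) -> np.ndarray:
        return np.nonzero(self.group_assignment == g)[0]

    @property
    def group_sizes(self) -> list[int]:
        return [int((self.group_assignment == g).sum()) for g in range(self.k)]

    def positives_per_group(self, labels: np.ndarray) -> list[int]:
        labels = np.asarray(labels).astype(bool)
        return [int(labels[self.group_indices(g)].sum()) for g in range(self.k)]

    @property
    def test_indices(self) -> np.ndarray:
        return self.group_indices(self.test_group)

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "test_group": self.test_group,
            "seed": self.seed,
            "groups": [self.group_indices(g).tolist() for g in range(self.k)],
        })

    @staticmethod
    def from_json(text: str) -> "SplitPlan":
        d = json.loads(text)
        n = sum(len(g) for g in d["groups"])
        assignment = np.empty(n, dtype=int)
        for g, idx in enumerate(d["groups"]):
            assignment[idx] = g
        return SplitPlan(assignment, int(d["k"]), int(d["test_group"]), int(d["seed"]))


def stratified_split(labels, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition records into k outcome-stratified groups.

    Both classes are spread as evenly as possible (per-class counts differ by
    at most one across groups); group order and within-class shuffling are
    seeded, so the plan is reproducible.  The first group in the seeded
    remainder order is designated the test group.
    """
    labels = np.asarray(labels).astype(bool)
    n = len(labels)
    if k < 2:
        raise SplitError(f"k must be >= 2, got {k}")
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n_pos < k or n_neg < k:
        raise SplitError(
            f"stratification impossible: need >= {k} records of each class, "
            f"have {n_pos} positives / {n_neg} negatives"
        )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    # one shared seeded group order receives the remainders of both classes,
    # nesting the spare-positive groups inside the spare-negative groups
    group_order = rng.permutation(k)

    assignment = np.empty(n, dtype=int)
    for mask in (labels, ~labels):
        idx = np.nonzero(mask)[0]
        rng.shuffle(idx)
        base, extra = divmod(len(idx), k)
        counts = np.full(k, base, dtype=int)
        counts[group_order[:extra]] += 1
        groups = np.repeat(np.arange(k), counts)
        assignment[idx] = groups
    # the last group in the seeded order never receives a remainder record,
    # so the held-out test group is always a smallest group
    return SplitPlan(assignment, k, test_group=int(group_order[-1]), seed=seed)


def cv_folds(plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Four (train, validation) index pairs over the non-test groups."""
    if plan.k < 3:
        raise SplitError("cv_folds needs at least 3 groups (test + 2)")
    folds = []
    non_test = [g for g in range(plan.k) if g != plan.test_group]
    for val_g in non_test:
        val = plan.group_indices(val_g)
        train = np.concatenate([plan.group_indices(g) for g in non_test if g != val_g])
        folds.append((np.sort(train), np.sort(val)))
    return folds
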