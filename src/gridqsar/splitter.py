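"""Training/test division by sphere exclusion in autoscaled descriptor space.

Compounds are visited in descending activity (ties broken by id).  Each
visited unassigned compound seeds the training set; every unassigned compound
within the exclusion radius of it (Euclidean distance in autoscaled
descriptor space) is sent to the test set.  Radius 0 therefore puts
everything in training; large radii push everything but the first seed out.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_io import ActivityRecord
from .descriptor_table import FieldDescriptorMatrix, autoscale

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    training_ids: list[str]
    test_ids: list[str]
    radius: float = float("nan")

    def __post_init__(self) -> None:
        if not self.training_ids:
            raise ValueError("training set is empty")
        if set(self.training_ids) & set(self.test_ids):
            raise ValueError("training and test sets overlap")

    @property
    def n_train(self) -> int:
        return len(self.training_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["compound_id", "set"])
            for cid in self.training_ids:
                writer.writerow([cid, "train"])
            for cid in self.test_ids:
                writer.writerow([cid, "test"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "SplitResult":
        train: list[str] = []
        test: list[str] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                label = row["set"].strip().lower()
                if label == "train":
                    train.append(row["compound_id"])
                elif label == "test":
                    test.append(row["compound_id"])
                else:
                    raise ValueError(f"unknown set label {row['set']!r}")
        return cls(training_ids=train, test_ids=test)


def _activity_order(activities: Sequence[ActivityRecord]) -> list[str]:
    return [r.compound_id for r in sorted(activities, key=lambda r: (-r.pIC50, r.compound_id))]


def sphere_exclusion(
    matrix: FieldDescriptorMatrix,
    activities: Sequence[ActivityRecord],
    radius: float,
) -> SplitResult:
    """Partition all compounds into training and test sets (see module doc)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    ids = matrix.compound_ids
    act_ids = {r.compound_id for r in activities}
    if set(ids) != act_ids:
        raise ValueError("compound ids of matrix and activities disagree")
    scaled = autoscale(matrix)
    row_of = {cid: i for i, cid in enumerate(ids)}
    order = _activity_order(activities)

    assigned: dict[str, str] = {}
    for cid in order:
        if cid in assigned:
            continue
        assigned[cid] = "train"
        seed = scaled[row_of[cid]]
        for other in order:
            if other in assigned:
                continue
            dist = float(np.linalg.norm(scaled[row_of[other]] - seed))
            if dist <= radius:
                assigned[other] = "test"
    train = [cid for cid in order if assigned[cid] == "train"]
    test = [cid for cid in order if assigned[cid] == "test"]
    logger.info("sphere exclusion: radius=%g -> %d train / %d test", radius, len(train), len(test))
    return SplitResult(training_ids=train, test_ids=test, radius=radius)


def find_radius(
    matrix: FieldDescriptorMatrix,
    activities: Sequence[ActivityRecord],
    target_test_fraction: float,
    tol_count: int = 0,
    max_iter: int = 100,
) -> SplitResult:
    """Bisect the exclusion radius until the test-set size is within
    ``tol_count`` of round(target_test_fraction × n).

    Test-set size is non-decreasing in the radius, so plain bisection applies.
    If the exact target is unreachable (e.g. duplicated rows force jumps in
    the achievable sizes) the closest achievable split is returned with a
    warning.
    """
    if not 0 < target_test_fraction < 1:
        raise ValueError("target_test_fraction must be in (0, 1)")
    n = len(matrix.compound_ids)
    target = int(round(target_test_fraction * n))

    lo, hi = 0.0, 1.0
    split_lo = sphere_exclusion(matrix, activities, lo)
    if abs(split_lo.n_test - target) <= tol_count:
        return split_lo
    split_hi = sphere_exclusion(matrix, activities, hi)
    while split_hi.n_test < target and hi < 1e6:
        hi *= 2.0
        split_hi = sphere_exclusion(matrix, activities, hi)

    best = split_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        split = sphere_exclusion(matrix, activities, mid)
        if abs(split.n_test - target) < abs(best.n_test - target):
            best = split
        if abs(split.n_test - target) <= tol_count:
            best = split
            break
        if split.n_test < target:
            lo = mid
        else:
            hi = mid
    if abs(best.n_test - target) > tol_count:
        warnings.warn(
            f"find_radius: target test size {target} unreachable; "
            f"closest achievable is {best.n_test}",
            stacklevel=2,
        )
    return best
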