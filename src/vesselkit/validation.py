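"""Grouped five-fold cross-validation: partition plans and fold-level errors.

Samples (biological replicates), not individual images, are the unit of
assignment: all images of a sample share one partition within a fold, which
prevents leakage between near-identical images of the same construct. Each
fold splits the samples into three disjoint partitions — train, validation,
and holdout — where the holdout is entirely segregated from the training
process. By default the holdout set is drawn once and held fixed across all
folds (the stricter reading of "entirely segregated"); a rotating holdout is
available behind a flag. Fold-level error is the mean percent error over the
samples of a partition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import percent_error

PARTITIONS = ("train", "validation", "holdout")


@dataclass
class PartitionPlan:
    """Per-fold assignment of every sample to train/validation/holdout."""

    fold_count: int
    assignments: dict[int, dict[str, str]]  # fold -> {sample_id: partition}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_count < 2:
            raise ValidationError("fold_count must be >= 2")
        samples = None
        for fold, mapping in self.assignments.items():
            if samples is None:
                samples = set(mapping)
            elif set(mapping) != samples:
                raise ValidationError(f"fold {fold} does not cover the same samples as fold 1")
            for sid, part in mapping.items():
                if part not in PARTITIONS:
                    raise ValidationError(f"unknown partition {part!r} for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(next(iter(self.assignments.values())))

    def partition(self, fold: int, sample_id: str) -> str:
        return self.assignments[fold][sample_id]

    def members(self, fold: int, partition: str) -> list[str]:
        return sorted(s for s, p in self.assignments[fold].items() if p == partition)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "fold": fold, "partition": part}
            for fold in sorted(self.assignments)
            for sid, part in sorted(self.assignments[fold].items())
        ]
        return pd.DataFrame(rows)


@dataclass
class FoldErrorReport:
    fold: int
    partition: str
    percent_error: float

    def __post_init__(self) -> None:
        if self.partition not in PARTITIONS:
            raise ValidationError(f"unknown partition {self.partition!r}")
        if self.percent_error < 0:
            raise ValidationError("percent_error must be >= 0")


def make_partitions(
    sample_ids: list[str],
    fold_count: int = 5,
    holdout_fraction: float = 0.2,
    validation_fraction: float = 0.2,
    seed: int = 0,
    rotate_holdout: bool = False,
) -> PartitionPlan:
    """Randomly assign samples to train/validation/holdout for each fold.

    Partition sizes are ``floor(fraction × n)`` for holdout and validation and
    must all be at least one sample. With the default fixed holdout, the
    holdout samples are drawn once and reused in every fold, and only the
    validation/train split of the remainder varies per fold; with
    ``rotate_holdout=True`` the holdout is redrawn per fold. Deterministic for
    a fixed seed.
    """
    ids = list(dict.fromkeys(str(s) for s in sample_ids))
    if len(ids) != len(sample_ids):
        raise ValidationError("sample_ids must be unique")
    if fold_count < 2:
        raise ValidationError("fold_count must be >= 2")
    if not (0 < holdout_fraction < 1 and 0 < validation_fraction < 1):
        raise ValidationError("fractions must be in (0, 1)")
    if holdout_fraction + validation_fraction >= 1:
        raise ValidationError("holdout_fraction + validation_fraction must be < 1")
    n = len(ids)
    n_hold = int(math.floor(holdout_fraction * n))
    n_val = int(math.floor(validation_fraction * n))
    n_train = n - n_hold - n_val
    if min(n_hold, n_val, n_train) < 1:
        minimum = int(math.ceil(max(1 / holdout_fraction, 1 / validation_fraction))) + 1
        raise ValidationError(
            f"{n} samples are too few for non-empty partitions at these fractions; "
            f"need at least {minimum}"
        )
    rng = np.random.default_rng(seed)
    assignments: dict[int, dict[str, str]] = {}
    fixed_holdout: list[str] | None = None
    if not rotate_holdout:
        fixed_holdout = list(rng.choice(ids, size=n_hold, replace=False))
    for fold in range(1, fold_count + 1):
        if rotate_holdout:
            holdout = list(rng.choice(ids, size=n_hold, replace=False))
        else:
            holdout = list(fixed_holdout)  # type: ignore[arg-type]
        remaining = [s for s in ids if s not in holdout]
        validation = list(rng.choice(remaining, size=n_val, replace=False))
        mapping = {}
        for s in ids:
            if s in holdout:
                mapping[s] = "holdout"
            elif s in validation:
                mapping[s] = "validation"
            else:
                mapping[s] = "train"
        assignments[fold] = mapping
    return PartitionPlan(fold_count, assignments, seed)


def check_no_leakage(plan: PartitionPlan) -> None:
    """Raise if any fold's partitions overlap or fail to cover all samples."""
    all_samples = set(plan.sample_ids)
    for fold in sorted(plan.assignments):
        seen: set[str] = set()
        for part in PARTITIONS:
            members = set(plan.members(fold, part))
            if members & seen:
                raise ValidationError(f"fold {fold}: samples in multiple partitions: {members & seen}")
            seen |= members
        if seen != all_samples:
            raise ValidationError(f"fold {fold}: partitions do not cover all samples")


def partition_error(
    results: list[tuple[str, float, float]],
    plan: PartitionPlan,
    fold: int,
    partition: str,
) -> FoldErrorReport:
    """Mean percent error over the samples of one fold's partition.

    ``results`` rows are (sample_id, reference_density, measured_density);
    every listed sample must belong to the stated fold/partition.
    """
    if partition not in PARTITIONS:
        raise ValidationError(f"unknown partition {partition!r}")
    if not results:
        raise ValidationError("partition_error needs at least one sample result")
    errors = []
    for sid, ref, meas in results:
        actual = plan.partition(fold, str(sid))
        if actual != partition:
            raise ValidationError(
                f"sample {sid!r} is in partition {actual!r} of fold {fold}, not {partition!r}"
            )
        errors.append(percent_error(ref, meas))
    return FoldErrorReport(fold, partition, float(np.mean(errors)))


def fold_error_table(reports: list[FoldErrorReport]) -> pd.DataFrame:
    """Fold / Partition / % Error table."""
    return pd.DataFrame(
        {
            "fold": [r.fold for r in reports],
            "partition": [r.partition for r in reports],
            "percent_error": [r.percent_error for r in reports],
        }
    )


def compare_test_vs_combined(
    test_only_accuracies: list[float], combined_accuracies: list[float]
) -> float:
    """Absolute difference in mean accuracy (percentage points).

    Used to check that reporting combined train+test data does not skew
    accuracy relative to test-only data (the design check is a difference
    within 2 percentage points).
    """
    if not test_only_accuracies or not combined_accuracies:
        raise ValidationError("both accuracy lists must be non-empty")
    return float(abs(np.mean(test_only_accuracies) - np.mean(combined_accuracies)))


def write_plan_csv(plan: PartitionPlan, path: str | Path) -> Path:
    p = Path(path)
    plan.to_frame().to_csv(p, index=False)
    return p


def read_plan_csv(path: str | Path, seed: int = 0) -> PartitionPlan:
    df = pd.read_csv(path)
    assignments: dict[int, dict[str, str]] = {}
    for _, row in df.iterrows():
        assignments.setdefault(int(row["fold"]), {})[str(row["sample_id"])] = str(row["partition"])
    fold_count = len(assignments)
    return PartitionPlan(fold_count, assignments, seed)
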