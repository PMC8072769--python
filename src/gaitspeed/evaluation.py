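"""Cross-validation protocols and descriptive accuracy statistics.

Two protocols evaluate the speed classifier:

* **Method 1** — k-fold cross-validation with three subsamples: the data
  are split into k near-equal folds and *every ordered pair* of distinct
  folds serves once as (validation, test) with the remaining k-2 folds
  training, giving k*(k-1) train/validate/test combinations (e.g. 272
  combinations for k=17, 306 for k=18).
* **Method 2** — repeated random sub-sampling: n independent random
  partitions into train/validation/test subsets of fixed sizes.

Per-combination test accuracies are summarised with Tukey boxplot
statistics (quartiles, adjacent values, outlier count).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import ModelConfig, TrainingConfig, build_model, train, accuracy_percent
from .signals import WalkingSpeedPattern

__all__ = [
    "Assignment",
    "SplitPlan",
    "SummaryStats",
    "CVResult",
    "make_kfold_plan",
    "make_random_plan",
    "run_cv",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Assignment:
    """One train/validation/test partition (pattern indices)."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        a, b, c = set(self.train), set(self.val), set(self.test)
        if a & b or a & c or b & c:
            raise ValueError("train/val/test subsets must be pairwise disjoint")


@dataclass(frozen=True)
class SplitPlan:
    """A full cross-validation plan: method, sizes and all assignments."""

    method: str  # "kfold_combinations" | "repeated_random"
    n_patterns: int
    assignments: tuple[Assignment, ...]
    seed: int
    k: int | None = None
    n_repeats: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "n_patterns": self.n_patterns,
            "seed": self.seed,
            "k": self.k,
            "n_repeats": self.n_repeats,
            "assignments": [
                {"train": list(a.train), "val": list(a.val), "test": list(a.test)}
                for a in self.assignments
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return SplitPlan(
            method=d["method"],
            n_patterns=d["n_patterns"],
            seed=d["seed"],
            k=d.get("k"),
            n_repeats=d.get("n_repeats"),
            assignments=tuple(
                Assignment(tuple(a["train"]), tuple(a["val"]), tuple(a["test"]))
                for a in d["assignments"]
            ),
        )


@dataclass(frozen=True)
class SummaryStats:
    """Tukey boxplot summary of per-combination accuracies (%)."""

    n: int
    mean: float
    sd: float
    p25: float
    p50: float
    p75: float
    min: float
    max: float
    lower_adjacent: float
    upper_adjacent: float
    range: float
    iqr: float
    n_outliers: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVResult:
    """Per-assignment test accuracies plus their descriptive summary."""

    accuracies: list[float]
    summary: SummaryStats
    n_failed: int = 0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"assignment": range(len(self.accuracies)), "accuracy": self.accuracies}
        ).to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary.as_dict(), indent=2))


def _make_folds(
    n_patterns: int, k: int, seed: int, stratify_labels: Sequence[int] | None
) -> list[np.ndarray]:
    """Split indices into k near-equal folds, optionally stratified."""
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        order = rng.permutation(n_patterns)
        return [np.sort(f) for f in np.array_split(order, k)]
    labels = np.asarray(stratify_labels)
    if len(labels) != n_patterns:
        raise ValueError("stratify_labels length must equal n_patterns")
    folds: list[list[int]] = [[] for _ in range(k)]
    slot = 0
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for i in idx:  # round-robin keeps folds near-equal and class-balanced
            folds[slot % k].append(int(i))
            slot += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def make_kfold_plan(
    n_patterns: int,
    k: int,
    seed: int = 0,
    stratify_labels: Sequence[int] | None = None,
) -> SplitPlan:
    """Method 1: all k*(k-1) ordered (validation, test) fold pairs.

    For each ordered pair of distinct folds (v, t), fold v validates,
    fold t tests and the remaining k-2 folds train.  Folds are stratified
    by class when labels are supplied.
    """
    if k < 3:
        raise ValueError("k must be at least 3 (need train, validation and test folds)")
    if k > n_patterns:
        raise ValueError(f"k={k} exceeds the number of patterns ({n_patterns})")
    if n_patterns % k != 0:
        warnings.warn(
            f"{n_patterns} patterns not divisible by k={k}; using near-equal folds",
            stacklevel=2,
        )
    folds = _make_folds(n_patterns, k, seed, stratify_labels)
    assignments = []
    for v in range(k):
        for t in range(k):
            if v == t:
                continue
            train_idx = np.concatenate([folds[j] for j in range(k) if j not in (v, t)])
            assignments.append(
                Assignment(
                    tuple(int(i) for i in np.sort(train_idx)),
                    tuple(int(i) for i in folds[v]),
                    tuple(int(i) for i in folds[t]),
                )
            )
    return SplitPlan("kfold_combinations", n_patterns, tuple(assignments), seed, k=k)


def make_random_plan(
    n_patterns: int,
    sizes: tuple[int, int, int],
    n_repeats: int,
    seed: int = 0,
    stratify_labels: Sequence[int] | None = None,
) -> SplitPlan:
    """Method 2: repeated random sub-sampling with fixed subset sizes.

    Each repeat draws an independent uniform partition into train /
    validation / test subsets of exactly ``sizes``; with labels supplied
    the shuffle is stratified per class proportionally.
    """
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != n_patterns:
        raise ValueError(f"sizes {sizes} must sum to n_patterns={n_patterns}")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_repeats):
        if stratify_labels is None:
            perm = rng.permutation(n_patterns)
        else:
            # per-class shuffle, then interleave so fixed-size cuts stay balanced
            labels = np.asarray(stratify_labels)
            per_class = [rng.permutation(np.flatnonzero(labels == c)) for c in np.unique(labels)]
            interleaved: list[int] = []
            i = 0
            while any(i < len(p) for p in per_class):
                for p in per_class:
                    if i < len(p):
                        interleaved.append(int(p[i]))
                i += 1
            perm = np.array(interleaved)
        assignments.append(
            Assignment(
                tuple(int(i) for i in np.sort(perm[:n_train])),
                tuple(int(i) for i in np.sort(perm[n_train:n_train + n_val])),
                tuple(int(i) for i in np.sort(perm[n_train + n_val:])),
            )
        )
    return SplitPlan(
        "repeated_random", n_patterns, tuple(assignments), seed, n_repeats=n_repeats
    )


def summarize(accuracies: Sequence[float]) -> SummaryStats:
    """Tukey boxplot statistics of a list of accuracies (%).

    Percentiles use linear interpolation between closest ranks; adjacent
    values are the most extreme observations within 1.5*IQR of the
    quartiles; observations beyond the fences count as outliers.
    """
    x = np.asarray(accuracies, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty accuracy list")
    p25, p50, p75 = np.percentile(x, [25, 50, 75])
    iqr = p75 - p25
    lo_fence, hi_fence = p25 - 1.5 * iqr, p75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return SummaryStats(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        min=float(x.min()),
        max=float(x.max()),
        lower_adjacent=float(inside.min()),
        upper_adjacent=float(inside.max()),
        range=float(x.max() - x.min()),
        iqr=float(iqr),
        n_outliers=int(np.count_nonzero((x < lo_fence) | (x > hi_fence))),
    )


def run_cv(
    plan: SplitPlan,
    patterns: Sequence[WalkingSpeedPattern],
    model_config: ModelConfig | None = None,
    train_config: TrainingConfig | None = None,
    progress: bool = False,
) -> CVResult:
    """Train and test one model per assignment; summarise test accuracies.

    Each assignment trains a freshly initialised model whose seed is
    derived deterministically from the plan seed and the assignment
    index.  Assignments whose training fails (e.g. divergence) are
    recorded and excluded from the summary with a warning count.
    """
    if plan.n_patterns != len(patterns):
        raise ValueError("plan was built for a different number of patterns")
    model_config = model_config or ModelConfig()
    base_train = train_config or TrainingConfig()
    accuracies: list[float] = []
    n_failed = 0
    for idx, a in enumerate(plan.assignments):
        run_seed = (plan.seed * 100003 + idx) % (2**31 - 1)
        cfg = TrainingConfig(**{**asdict(base_train), "seed": run_seed})
        try:
            model = build_model(model_config, seed=run_seed)
            trained = train(
                model,
                [patterns[i] for i in a.train],
                [patterns[i] for i in a.val],
                cfg,
            )
            acc = accuracy_percent(trained, [patterns[i] for i in a.test])
        except RuntimeError as exc:
            logger.warning("assignment %d failed: %s", idx, exc)
            n_failed += 1
            continue
        accuracies.append(acc)
        if progress:
            logger.info("assignment %d/%d: test accuracy %.2f%%", idx + 1, len(plan.assignments), acc)
    if n_failed:
        warnings.warn(f"{n_failed} assignment(s) failed to train and were excluded", stacklevel=2)
    return CVResult(accuracies, summarize(accuracies), n_failed=n_failed)
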