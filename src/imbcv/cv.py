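"""Balanced k-fold cross-validation with sampling inside or outside the loop.

Two protocols are implemented side by side:

* ``correct`` ("CV includes sampling") — the folds are formed on the original
  data and the sampler is applied, fold by fold, to the k-1 training folds
  only; the test fold is never touched.
* ``incorrect`` ("sampling followed by CV") — the sampler is applied once to
  the whole dataset and the folds are then formed on the resampled data, so
  replicas or synthetic copies of a test sample can sit in the training
  partition.  This is the flawed procedure under study and is intentionally
  left exactly as flawed as described: folds are balanced on the
  post-sampling labels with no awareness of replica lineage.

Folds are *balanced*: within each class, samples are shuffled and dealt
round-robin, so fold sizes and the imbalance level differ by at most one
sample per class across folds.  Per-fold measures are averaged over the k
folds (AUC included — the reported AUC is a mean of per-fold AUCs, not a
pooled statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, fit, predict_classes, predict_scores
from .datasets import Dataset, NullDesign, generate_null_dataset
from .metrics import (
    MEASURE_NAMES,
    FoldPredictions,
    PerformanceMeasures,
    compute_measures,
)
from .sampling import SamplingConfig, apply_sampler

__all__ = [
    "FoldAssignment",
    "CVProtocol",
    "make_balanced_folds",
    "run_cv",
    "run_cv_detailed",
    "run_replicated_cv",
    "summarize_runs",
    "spawn_seeds",
]

ALL_COLUMNS = list(MEASURE_NAMES) + ["Precision"]


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (0-based, in [0, k)) per sample."""

    fold_index: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


@dataclass(frozen=True)
class CVProtocol:
    mode: str  # correct | incorrect
    sampler: SamplingConfig = field(default_factory=SamplingConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("correct", "incorrect"):
            raise ValueError(f"mode must be 'correct' or 'incorrect', got {self.mode!r}")
        if self.k < 2:
            raise ValueError("need at least 2 folds")


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds (< 2**31) from one root seed.

    Children are generated by position, so shrinking ``n`` leaves earlier
    children unchanged — run i of a replicated experiment is the same whether
    100 or 1000 runs are requested.
    """
    return np.array(
        [ss.generate_state(1)[0] % (2**31) for ss in np.random.SeedSequence(seed).spawn(n)],
        dtype=np.int64,
    )


def make_balanced_folds(labels: np.ndarray, k: int, seed) -> FoldAssignment:
    """Per-class shuffle followed by round-robin dealing into k folds.

    Guarantees that, within each class, fold counts differ by at most one —
    every fold carries (approximately) the same size and imbalance level.
    Errors if any class has fewer than k samples, since some fold would then
    lack that class entirely.
    """
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fold_index = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than k={k}; "
                "a test fold would not contain it"
            )
        idx = rng.permutation(idx)
        fold_index[idx] = np.arange(len(idx)) % k
    return FoldAssignment(fold_index, k)


def _evaluate_fold(train: Dataset, test: Dataset, classifier: ClassifierSpec) -> PerformanceMeasures:
    model = fit(classifier, train)
    scores = predict_scores(model, test.features)
    classes = predict_classes(model, test.features)
    return compute_measures(FoldPredictions(test.labels, classes, scores))


def run_cv_detailed(data: Dataset, protocol: CVProtocol):
    """One cross-validation run; returns (per-fold measures, per-fold test Datasets).

    The test datasets are exposed so that diagnostics can inspect provenance
    (e.g. verify that correct-CV test folds contain only original samples).
    """
    data.validate()
    fold_ss, sampler_ss = np.random.SeedSequence(protocol.seed).spawn(2)
    fold_rng = np.random.default_rng(fold_ss)

    if protocol.mode == "incorrect":
        sampled = apply_sampler(data, protocol.sampler, np.random.default_rng(sampler_ss))
        folds = make_balanced_folds(sampled.labels, protocol.k, fold_rng)
        working = sampled
        fold_sampler_rngs = [None] * protocol.k
    else:
        folds = make_balanced_folds(data.labels, protocol.k, fold_rng)
        working = data
        fold_sampler_rngs = [np.random.default_rng(s) for s in sampler_ss.spawn(protocol.k)]

    per_fold: list[PerformanceMeasures] = []
    test_sets: list[Dataset] = []
    for fold in range(protocol.k):
        test = working.subset(folds.test_indices(fold))
        train = working.subset(folds.train_indices(fold))
        if protocol.mode == "correct":
            train = apply_sampler(train, protocol.sampler, fold_sampler_rngs[fold])
        if len(np.unique(test.labels)) < 2:
            warnings.warn(
                f"fold {fold} test set contains a single class; skipping its measures",
                stacklevel=2,
            )
            continue
        per_fold.append(_evaluate_fold(train, test, protocol.classifier))
        test_sets.append(test)
    if not per_fold:
        raise RuntimeError("all folds were degenerate; no measures computed")
    return per_fold, test_sets


def run_cv(data: Dataset, protocol: CVProtocol) -> PerformanceMeasures:
    """One cross-validation run; measures averaged over the k folds."""
    per_fold, _ = run_cv_detailed(data, protocol)
    mean = {
        name: float(np.mean([m.as_dict()[name] for m in per_fold])) for name in ALL_COLUMNS
    }
    return PerformanceMeasures(**mean)


def run_replicated_cv(design_or_data, protocol: CVProtocol, runs: int, seed: int) -> pd.DataFrame:
    """Replicate ``run_cv`` with independent randomness per run.

    If given a :class:`NullDesign`, each run simulates a fresh dataset; if
    given a fixed :class:`Dataset`, each run re-randomizes only the folds and
    the sampler.  Returns one row per run with the seven measure columns.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    seeds = spawn_seeds(seed, 2 * runs).reshape(runs, 2)
    rows = []
    for i in range(runs):
        data_seed, protocol_seed = int(seeds[i, 0]), int(seeds[i, 1])
        if isinstance(design_or_data, NullDesign):
            data = generate_null_dataset(replace(design_or_data, seed=data_seed))
        else:
            data = design_or_data
        m = run_cv(data, replace(protocol, seed=protocol_seed))
        rows.append({"run": i, **m.as_dict()})
    return pd.DataFrame(rows)


def summarize_runs(per_run: pd.DataFrame) -> pd.DataFrame:
    """Mean and Monte-Carlo standard error of each measure over runs."""
    out = []
    for name in ALL_COLUMNS:
        vals = per_run[name].to_numpy()
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        out.append({"measure": name, "mean": vals.mean(), "se": se, "runs": len(vals)})
    return pd.DataFrame(out)
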