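"""Resampling techniques for class-imbalanced data.

Three balancing strategies, all pure functions of (dataset, seed):

* random undersampling — keep all minority samples and an equally sized
  without-replacement draw from the majority;
* simple oversampling — keep all majority samples and draw ``n_maj`` minority
  samples *with* replacement (the drawn rows are exact replicas);
* SMOTE — for each minority sample generate ``percent_over/100`` synthetic
  rows by interpolating toward one of its k nearest minority neighbours, then
  retain ``percent_under/100`` majority rows per synthetic row.

Replica and synthetic rows carry provenance tags so downstream diagnostics
can detect when generated rows leak into a test partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import Dataset, REPLICA, SYNTHETIC

__all__ = [
    "SamplingConfig",
    "random_undersample",
    "simple_oversample",
    "smote",
    "apply_sampler",
    "SAMPLER_NAMES",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Which sampler to apply and with what parameters.

    ``percent_over`` is the number of synthetic samples per original minority
    sample times 100 (so 500 means five synthetic rows per minority row);
    it must be a positive multiple of 100.  ``percent_under`` is the number of
    majority rows retained, as a percentage of the synthetic count.
    ``k_neighbors`` is the SMOTE neighbourhood size (default 5).
    """

    method: str = "none"  # none | undersample | oversample | smote
    percent_over: int = 100
    percent_under: int = 100
    k_neighbors: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("none", "undersample", "oversample", "smote"):
            raise ValueError(f"unknown sampling method {self.method!r}")
        if self.percent_over <= 0 or self.percent_over % 100 != 0:
            raise ValueError(
                f"percent_over must be a positive multiple of 100, got {self.percent_over}"
            )
        if self.percent_under < 0:
            raise ValueError("percent_under must be non-negative")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


#: CLI / config names for the samplers used in the simulation study
SAMPLER_NAMES = {
    "none": SamplingConfig(method="none"),
    "under": SamplingConfig(method="undersample"),
    "over": SamplingConfig(method="oversample"),
    "smote100": SamplingConfig(method="smote", percent_over=100),
    "smote200": SamplingConfig(method="smote", percent_over=200),
    "smote500": SamplingConfig(method="smote", percent_over=500),
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_undersample(data: Dataset, seed) -> Dataset:
    """Balance by discarding majority rows: keep all n_min minority samples plus
    n_min majority samples drawn without replacement.  Output size 2*n_min."""
    rng = _rng(seed)
    min_idx = np.flatnonzero(data.labels == 1)
    maj_idx = np.flatnonzero(data.labels == 0)
    if len(min_idx) < 1:
        raise ValueError("undersampling requires at least one minority sample")
    keep_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
    return data.subset(np.concatenate([min_idx, keep_maj]))


def simple_oversample(data: Dataset, seed) -> Dataset:
    """Balance by replication: keep all n_maj majority rows and draw n_maj
    minority rows with replacement.  Output size 2*n_maj; the drawn rows are
    bitwise copies of originals, tagged ``replica``.

    The minority originals are not retained alongside the draw — the balanced
    set consists of the majority rows plus exactly the n_maj drawn replicas.
    """
    rng = _rng(seed)
    min_idx = np.flatnonzero(data.labels == 1)
    maj_idx = np.flatnonzero(data.labels == 0)
    if len(min_idx) < 1:
        raise ValueError("oversampling requires at least one minority sample")
    draws = rng.choice(min_idx, size=len(maj_idx), replace=True)
    features = np.concatenate([data.features[maj_idx], data.features[draws]])
    labels = np.concatenate([data.labels[maj_idx], data.labels[draws]])
    provenance = np.concatenate(
        [data.provenance[maj_idx], np.full(len(draws), REPLICA, dtype=object)]
    )
    return Dataset(features, labels, provenance)


def smote(data: Dataset, config: SamplingConfig, seed=None) -> Dataset:
    """Synthetic Minority Oversampling TEchnique.

    For each minority sample x, generate ``percent_over/100`` synthetic rows
    ``x + u * (z - x)`` with u ~ Uniform(0, 1) drawn once per synthetic row
    (shared across features) and z chosen uniformly among x's ``k_neighbors``
    nearest minority neighbours (Euclidean distance on the raw features, self
    excluded, distance ties broken by lowest sample index).  The output keeps
    the minority originals, adds the synthetic rows (tagged ``synthetic``) and
    retains ``percent_under/100 * n_synthetic`` majority rows drawn without
    replacement.

    Row layout (stable, relied on by diagnostics): minority originals in input
    order, then synthetic rows grouped by parent (``percent_over/100``
    consecutive rows per parent, parents in input order), then the retained
    majority rows.
    """
    rng = _rng(seed if seed is not None else config.seed)
    min_idx = np.flatnonzero(data.labels == 1)
    maj_idx = np.flatnonzero(data.labels == 0)
    n_min = len(min_idx)
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")

    k = config.k_neighbors
    if n_min - 1 < k:
        warnings.warn(
            f"minority class has only {n_min} samples; reducing SMOTE neighbour "
            f"pool from {k} to {n_min - 1}",
            stacklevel=2,
        )
        k = n_min - 1

    x_min = data.features[min_idx]
    dist = cdist(x_min, x_min)
    np.fill_diagonal(dist, np.inf)  # self excluded
    # stable argsort => ties broken by lowest index, reproducible
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]

    per_sample = config.percent_over // 100
    parents = np.repeat(np.arange(n_min), per_sample)
    chosen = neighbors[parents, rng.integers(0, k, size=len(parents))]
    u = rng.random(len(parents))
    synthetic = x_min[parents] + u[:, None] * (x_min[chosen] - x_min[parents])

    n_synth = len(parents)
    m = int(round(config.percent_under / 100 * n_synth))
    if m > len(maj_idx):
        warnings.warn(
            f"requested {m} majority rows but only {len(maj_idx)} available; keeping all",
            stacklevel=2,
        )
        m = len(maj_idx)
    keep_maj = rng.choice(maj_idx, size=m, replace=False)

    features = np.concatenate([data.features[min_idx], synthetic, data.features[keep_maj]])
    labels = np.concatenate(
        [np.ones(n_min + n_synth, dtype=int), np.zeros(m, dtype=int)]
    )
    provenance = np.concatenate(
        [
            data.provenance[min_idx],
            np.full(n_synth, SYNTHETIC, dtype=object),
            data.provenance[keep_maj],
        ]
    )
    return Dataset(features, labels, provenance)


def apply_sampler(data: Dataset, config: SamplingConfig, seed=None) -> Dataset:
    """Dispatch on ``config.method``; ``seed`` overrides ``config.seed``."""
    s = seed if seed is not None else config.seed
    if config.method == "none":
        return data
    if config.method == "undersample":
        return random_undersample(data, s)
    if config.method == "oversample":
        return simple_oversample(data, s)
    return smote(data, config, s)
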