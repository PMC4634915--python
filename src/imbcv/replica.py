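"""Probability that a test sample has a replica in the training partition.

After simple oversampling, each minority sample appears on average
r = n_maj / n_min times.  When cross-validation is applied *after* the
oversampling step, the copies of one sample are scattered across the folds,
so a sample evaluated in the test fold usually has an identical twin in the
training fold.  For a set of ``n`` rows in which the test sample has exactly
``r`` copies, the probability that at least one of the other copies lands in
the training partition, given that this copy is in a test partition of
``n * p_test`` rows, is the closed form

    1 - C(n - r, n*p_test - r) / C(n - 1, n*p_test - 1)     if n*p_test >= r
    1                                                        otherwise

(with fewer test slots than copies, at least one copy must be in training).
Two remarks on interpretation, both verified by the Monte-Carlo oracle below:

* The formula is exact for the set actually partitioned.  Evaluating it at
  the original size n = n_min + n_maj (as the accompanying illustration
  curves do) idealizes the split as acting on the original samples; after
  oversampling the partitioned set really has 2*n_maj rows, and the two
  evaluations differ only marginally (third decimal at n = 100).
* The formula assumes each minority sample has *exactly* r copies.  Actual
  with-replacement oversampling replicates multinomially, which inflates the
  leakage probability near balance (duplicates arise even at r = 1, where
  the exact-replication probability is 0).  The oracle supports both models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ReplicaSpec",
    "replica_probability",
    "monte_carlo_replica_probability",
    "replica_probability_curve",
]


@dataclass(frozen=True)
class ReplicaSpec:
    """Inputs to the closed form.

    ``n`` is the size of the set over which the train/test split is taken;
    ``r = n_maj / n_min`` must be an integer (exact replication), and
    ``n * p_test`` must be an integer test-set size.
    """

    n: int
    n_min: int
    n_maj: int
    p_test: float

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.n_maj < self.n_min:
            raise ValueError("need 1 <= n_min <= n_maj")
        if not 0.0 < self.p_test < 1.0:
            raise ValueError("p_test must be in (0, 1)")
        if self.n_maj % self.n_min != 0:
            raise ValueError(
                f"n_maj/n_min = {self.n_maj}/{self.n_min} is not an integer; the "
                "closed form assumes exact replication — use the Monte-Carlo "
                "oracle for fractional replication factors"
            )
        t = self.n * self.p_test
        if abs(t - round(t)) > 1e-9:
            raise ValueError(
                f"n * p_test = {t} is not an integer test-set size; use the "
                "Monte-Carlo oracle"
            )

    @property
    def r(self) -> int:
        return self.n_maj // self.n_min

    @property
    def test_size(self) -> int:
        return int(round(self.n * self.p_test))


def _log_comb(a: float, b: float) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _closed_form(n: float, r: float, test_size: float) -> float:
    """The formula with real-valued arguments (gamma continuation of the
    binomial coefficients); exact when n, r and test_size are integers."""
    if test_size < r:
        return 1.0
    if r <= 1:
        return 0.0
    log_ratio = _log_comb(n - r, test_size - r) - _log_comb(n - 1, test_size - 1)
    return float(1.0 - np.exp(log_ratio))


def replica_probability(spec: ReplicaSpec) -> float:
    """Closed-form leakage probability; log-gamma arithmetic, safe for n ~ 1e4."""
    return _closed_form(spec.n, spec.r, spec.test_size)


def monte_carlo_replica_probability(
    n_min: int,
    n_maj: int,
    p_test: float,
    reps: int,
    seed: int,
    replication: str = "exact",
) -> tuple[float, float]:
    """Empirical leakage frequency, with standard error.

    Builds the balanced set (n_maj majority rows plus n_maj minority rows),
    draws a uniformly random test partition of the stated proportion
    conditioned on a fixed minority row being in it, and records whether a
    copy of that row's originating sample sits in the training partition.

    ``replication="exact"`` repeats each minority sample exactly
    r = n_maj/n_min times (the closed form's model; requires integer r);
    ``replication="pipeline"`` draws the n_maj minority rows with
    replacement, as simple oversampling actually does.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 < p_test < 1.0:
        raise ValueError("p_test must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_rows = 2 * n_maj
    test_size = int(round(n_rows * p_test))
    if test_size < 1 or test_size >= n_rows:
        raise ValueError("test partition would be empty or the whole set")

    if replication == "exact":
        if n_maj % n_min != 0:
            raise ValueError(
                "exact replication requires n_maj divisible by n_min; use "
                "replication='pipeline'"
            )
        fixed_ids = np.repeat(np.arange(n_min), n_maj // n_min)
    elif replication != "pipeline":
        raise ValueError("replication must be 'exact' or 'pipeline'")

    hits = 0
    for _ in range(reps):
        ids = fixed_ids if replication == "exact" else rng.integers(0, n_min, size=n_maj)
        # rows: 0..n_maj-1 minority (identity ids), n_maj..2*n_maj-1 majority.
        # Condition on minority row 0 being in the test partition: the other
        # test members are a uniform draw of test_size-1 from the remaining rows.
        others = 1 + rng.permutation(n_rows - 1)
        train = others[test_size - 1 :]
        train_min = train[train < n_maj]
        hits += bool(np.any(ids[train_min] == ids[0]))
    est = hits / reps
    se = float(np.sqrt(est * (1 - est) / reps))
    return est, se


def replica_probability_curve(n: int, p_test: float, p_min_grid) -> "pd.DataFrame":
    """Leakage probability as a function of the minority proportion.

    Evaluates the closed form at r = (1 - p_min) / p_min for each grid value,
    using the gamma continuation for non-integer replication factors so the
    curve is smooth.  Non-increasing in p_min: more balance, less leakage.
    """
    import pandas as pd

    rows = []
    for p_min in p_min_grid:
        if not 0.0 < p_min <= 0.5:
            raise ValueError("p_min must be in (0, 0.5]")
        r = (1.0 - p_min) / p_min
        rows.append({"p_min": p_min, "probability": _closed_form(n, r, n * p_test)})
    return pd.DataFrame(rows)
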