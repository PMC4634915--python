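"""Null-signal class-imbalanced datasets and the container they flow through.

The simulation design used throughout this package is deliberately
uninformative: every feature is an independent standard-normal draw and the
class labels are assigned by count, independently of the features.  Any
cross-validated performance estimate that deviates from its chance value
(AUC = 0.5, GM = 0.5, PA_min + PA_maj = 1) on such data therefore measures a
defect of the evaluation protocol, not of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NullDesign", "Dataset", "generate_null_dataset", "write_dataset", "read_dataset"]

#: provenance tags carried per sample
ORIGINAL = "original"
REPLICA = "replica"
SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class NullDesign:
    """Parameters of a null (no class signal) simulated dataset.

    Parameters
    ----------
    n : int
        Total number of samples, at least 4.
    p : int
        Number of features, at least 1.
    minority_fraction : float
        Proportion of samples in the minority (positive) class, in (0, 0.5].
        The minority count is the deterministic ``round(minority_fraction * n)``
        — the imbalance level is a fixed design quantity, not a random draw.
    seed : int
        Seed for the random number generator.
    """

    n: int
    p: int
    minority_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"need n >= 4, got {self.n}")
        if self.p < 1:
            raise ValueError(f"need p >= 1, got {self.p}")
        if not 0.0 < self.minority_fraction <= 0.5:
            raise ValueError(
                f"minority_fraction must be in (0, 0.5], got {self.minority_fraction}"
            )
        if self.n_min < 2:
            raise ValueError(
                f"design yields n_min={self.n_min} < 2; cross-validation and "
                "SMOTE are undefined for fewer than 2 minority samples"
            )

    @property
    def n_min(self) -> int:
        return int(round(self.minority_fraction * self.n))

    @property
    def n_maj(self) -> int:
        return self.n - self.n_min


@dataclass
class Dataset:
    """A feature matrix with binary labels; minority class coded 1 (positive).

    ``provenance`` tags each row as an original sample, an exact replica
    produced by oversampling, or a synthetic interpolation produced by SMOTE.
    Diagnostics (e.g. checking that correct CV never tests on generated rows)
    rely on these tags; the classifiers never see them.
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must equal the number of feature rows")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary 0/1 with minority coded 1")
        if self.provenance is None:
            self.provenance = np.full(len(self.labels), ORIGINAL, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != self.labels.shape:
                raise ValueError("provenance length must match labels")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_min(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_maj(self) -> int:
        return int(np.sum(self.labels == 0))

    def validate(self) -> None:
        """Check the class-imbalance invariants (both classes present, minority <= majority)."""
        if self.n_min == 0 or self.n_maj == 0:
            raise ValueError("both classes must be present")
        if self.n_min > self.n_maj:
            raise ValueError(
                f"minority count {self.n_min} exceeds majority count {self.n_maj}; "
                "minority must be the rarer class"
            )

    def subset(self, idx: np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(self.features[idx], self.labels[idx], self.provenance[idx])


def generate_null_dataset(design: NullDesign) -> Dataset:
    """Draw a dataset from the null design: i.i.d. N(0, 1) features, labels by count.

    Exactly ``round(minority_fraction * n)`` rows are labelled minority; which
    rows is randomized (by exchangeability this is irrelevant, but it avoids
    accidental order effects downstream).  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    features = rng.standard_normal((design.n, design.p))
    labels = np.zeros(design.n, dtype=int)
    minority_rows = rng.choice(design.n, size=design.n_min, replace=False)
    labels[minority_rows] = 1
    return Dataset(features, labels)


def to_frame(data: Dataset) -> pd.DataFrame:
    """One row per sample, feature columns f1..fp, last column ``label``."""
    df = pd.DataFrame(
        data.features, columns=[f"f{j + 1}" for j in range(data.features.shape[1])]
    )
    df["label"] = data.labels
    return df


def write_dataset(data: Dataset, path, sep: str = ",") -> None:
    """Persist a dataset as a delimited table (header row, label last)."""
    to_frame(data).to_csv(path, sep=sep, index=False)


def read_dataset(path, sep: str = ",", label_col: str = "label") -> Dataset:
    """Read a delimited table with a binary label column back into a Dataset."""
    df = pd.read_csv(path, sep=sep)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found")
    labels = df[label_col].to_numpy()
    features = df.drop(columns=[label_col]).to_numpy(dtype=float)
    return Dataset(features, labels)
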