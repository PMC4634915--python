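"""Simulation-study orchestration and the real-data protocol.

The simulation study runs every combination of sample size, feature count,
fold count, sampler and CV protocol on null-signal data and reports the
Monte-Carlo mean and standard error of each performance measure.  Because
the data carry no class signal, the correct protocol must average to the
chance values (AUC = GM = 0.5, PA_min + PA_maj = 1) and any systematic
departure under the incorrect protocol quantifies resampling leakage bias.

The full-scale grid is n in {100, 500, 1000, 10000}, p in {10, 100},
k in {2, 5, 10} with 1000 runs per cell; ``runs`` is configurable downward
so that reduced versions finish in minutes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec
from .cv import ALL_COLUMNS, CVProtocol, run_replicated_cv, spawn_seeds, summarize_runs
from .datasets import Dataset, NullDesign
from .sampling import SAMPLER_NAMES, SamplingConfig

__all__ = [
    "SimulationGrid",
    "run_simulation_study",
    "preprocess_expression_table",
    "run_real_data_study",
    "plot_auc_bars",
]

RESULT_COLUMNS = ["n", "p", "k", "sampler", "mode", "measure", "mean", "se", "runs"]


@dataclass(frozen=True)
class SimulationGrid:
    n_values: tuple = (100, 500, 1000, 10000)
    p_values: tuple = (10, 100)
    k_values: tuple = (2, 5, 10)
    samplers: tuple = ("under", "over", "smote100", "smote200", "smote500")
    modes: tuple = ("correct", "incorrect")
    runs: int = 1000
    seed: int = 0
    minority_fraction: float = 0.1
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)


def _resolve_sampler(name_or_config) -> tuple[str, SamplingConfig]:
    if isinstance(name_or_config, SamplingConfig):
        return name_or_config.method, name_or_config
    if name_or_config not in SAMPLER_NAMES:
        raise ValueError(
            f"unknown sampler {name_or_config!r}; known: {sorted(SAMPLER_NAMES)}"
        )
    return name_or_config, SAMPLER_NAMES[name_or_config]


def _run_cell(grid: SimulationGrid, n, p, k, sampler, mode, cell_seed) -> pd.DataFrame:
    name, config = _resolve_sampler(sampler)
    design = NullDesign(n=n, p=p, minority_fraction=grid.minority_fraction, seed=0)
    protocol = CVProtocol(mode=mode, sampler=config, classifier=grid.classifier, k=k)
    per_run = run_replicated_cv(design, protocol, grid.runs, int(cell_seed))
    summary = summarize_runs(per_run)
    summary.insert(0, "mode", mode)
    summary.insert(0, "sampler", sampler if isinstance(sampler, str) else name)
    summary.insert(0, "k", k)
    summary.insert(0, "p", p)
    summary.insert(0, "n", n)
    return summary


def run_simulation_study(grid: SimulationGrid, out_dir=None, n_jobs: int = 1) -> pd.DataFrame:
    """One long-format results table: a row per cell x sampler x mode x measure.

    Cells are written incrementally to ``out_dir/simulation_results.csv`` when
    an output directory is given (with a manifest of the grid), so a partial
    run still leaves usable results; a failing cell is logged and skipped.
    ``n_jobs`` parallelizes across cells with joblib (results are identical to
    the serial run: every cell owns a pre-spawned seed).
    """
    out_path = manifest_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "simulation_results.csv"
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(
            json.dumps(
                {
                    "n_values": list(grid.n_values),
                    "p_values": list(grid.p_values),
                    "k_values": list(grid.k_values),
                    "samplers": list(grid.samplers),
                    "modes": list(grid.modes),
                    "runs": grid.runs,
                    "seed": grid.seed,
                    "minority_fraction": grid.minority_fraction,
                    "classifier": grid.classifier.kind,
                },
                indent=2,
            )
        )

    cells = [
        (n, p, k, s, m)
        for n in grid.n_values
        for p in grid.p_values
        for k in grid.k_values
        for s in grid.samplers
        for m in grid.modes
    ]
    cell_seeds = spawn_seeds(grid.seed, len(cells))

    if n_jobs != 1:
        from joblib import Parallel, delayed

        frames = Parallel(n_jobs=n_jobs)(
            delayed(_run_cell)(grid, *cell, seed)
            for cell, seed in zip(cells, cell_seeds)
        )
        if out_path is not None:
            pd.concat(frames, ignore_index=True).to_csv(out_path, index=False)
        return pd.concat(frames, ignore_index=True)

    frames = []
    first_write = True
    for cell, cell_seed in zip(cells, cell_seeds):
        try:
            summary = _run_cell(grid, *cell, cell_seed)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"cell {cell} failed: {exc}", stacklevel=2)
            continue
        frames.append(summary)
        if out_path is not None:
            summary.to_csv(out_path, mode="w" if first_write else "a", header=first_write, index=False)
            first_write = False

    if not frames:
        raise RuntimeError("every simulation cell failed")
    return pd.concat(frames, ignore_index=True)


def preprocess_expression_table(
    df: pd.DataFrame,
    label_col: str,
    minority_label,
    max_missing_fraction: float = 0.10,
    n_top_variance: int = 1000,
) -> Dataset:
    """Standard expression-matrix preprocessing before model evaluation.

    Features with more than ``max_missing_fraction`` missing values are
    dropped, remaining gaps are replaced with zeros, and only the
    ``n_top_variance`` highest-variance features are retained (all of them if
    fewer).  Labels are binarized by declaring one value the minority class.
    """
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found")
    labels_raw = df[label_col]
    feats = df.drop(columns=[label_col])
    non_numeric = [
        c for c in feats.columns if not pd.api.types.is_numeric_dtype(feats[c])
    ]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns: {non_numeric}")

    keep = feats.columns[feats.isna().mean() <= max_missing_fraction]
    feats = feats[keep].fillna(0.0)
    if feats.shape[1] > n_top_variance:
        variances = feats.var(axis=0, ddof=1)
        top = variances.sort_values(ascending=False, kind="stable").index[:n_top_variance]
        # preserve original column order for determinism
        feats = feats[[c for c in feats.columns if c in set(top)]]

    if not (labels_raw == minority_label).any():
        raise ValueError(f"declared minority label {minority_label!r} absent from table")
    labels = (labels_raw == minority_label).astype(int).to_numpy()
    data = Dataset(feats.to_numpy(dtype=float), labels)
    data.validate()
    return data


def run_real_data_study(
    table_path,
    label_col: str,
    minority_label,
    samplers=("under", "over", "smote100", "smote200", "smote500"),
    modes=("correct", "incorrect"),
    k: int = 5,
    runs: int = 500,
    seed: int = 0,
    classifier: ClassifierSpec | None = None,
    preprocess: bool = False,
    sep: str = ",",
) -> pd.DataFrame:
    """Correct-vs-incorrect comparison on one delimited real dataset.

    Each run re-randomizes the folds and the sampler on the fixed data; the
    output schema matches :func:`run_simulation_study` so the same plotting
    applies.  ``preprocess=True`` applies the expression-matrix filters first.
    """
    df = pd.read_csv(table_path, sep=sep)
    if preprocess:
        data = preprocess_expression_table(df, label_col, minority_label)
    else:
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not found")
        if not (df[label_col] == minority_label).any():
            raise ValueError(f"declared minority label {minority_label!r} absent from table")
        labels = (df[label_col] == minority_label).astype(int).to_numpy()
        data = Dataset(df.drop(columns=[label_col]).to_numpy(dtype=float), labels)
        data.validate()

    classifier = classifier or ClassifierSpec()
    combos = [(s, m) for s in samplers for m in modes]
    combo_seeds = spawn_seeds(seed, len(combos))
    frames = []
    for (sampler, mode), cseed in zip(combos, combo_seeds):
        name, config = _resolve_sampler(sampler)
        protocol = CVProtocol(mode=mode, sampler=config, classifier=classifier, k=k)
        per_run = run_replicated_cv(data, protocol, runs, int(cseed))
        summary = summarize_runs(per_run)
        summary.insert(0, "mode", mode)
        summary.insert(0, "sampler", sampler if isinstance(sampler, str) else name)
        summary.insert(0, "k", k)
        summary.insert(0, "p", data.features.shape[1])
        summary.insert(0, "n", len(data))
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def plot_auc_bars(results: pd.DataFrame, ax=None):
    """Grouped bars of mean AUC by sampler, correct vs incorrect protocol."""
    import matplotlib.pyplot as plt

    auc = results[results["measure"] == "AUC"]
    samplers = list(dict.fromkeys(auc["sampler"]))
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(samplers) + 2, 4))
    width = 0.38
    x = np.arange(len(samplers))
    for off, mode in ((-width / 2, "correct"), (width / 2, "incorrect")):
        sub = auc[auc["mode"] == mode].set_index("sampler")
        means = [sub.loc[s, "mean"] if s in sub.index else np.nan for s in samplers]
        ax.bar(x + off, means, width, label=f"{mode} CV")
    ax.axhline(0.5, color="grey", linestyle=":", linewidth=1)
    ax.set_xticks(x)
    ax.set_xticklabels(samplers)
    ax.set_ylabel("cross-validated AUC")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
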