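"""Samplers: exact output sizes, replica fidelity, SMOTE geometry, purity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imbcv import (
    Dataset,
    NullDesign,
    SamplingConfig,
    apply_sampler,
    generate_null_dataset,
    random_undersample,
    simple_oversample,
    smote,
)
from imbcv.datasets import ORIGINAL, REPLICA, SYNTHETIC


def _rows(a):
    return {tuple(r) for r in a}


# ---------------------------------------------------------------- undersampling


def test_undersample_sizes_and_identity(imbalanced_data):
    out = random_undersample(imbalanced_data, seed=0)
    assert len(out) == 2 * imbalanced_data.n_min == 20
    assert out.n_min == out.n_maj == 10
    # minority rows bitwise identical
    assert _rows(out.features[out.labels == 1]) == _rows(
        imbalanced_data.features[imbalanced_data.labels == 1]
    )
    assert set(out.provenance) == {ORIGINAL}


def test_undersample_majority_without_replacement(imbalanced_data):
    out = random_undersample(imbalanced_data, seed=1)
    maj_out = out.features[out.labels == 0]
    # no duplicates, and every row comes from the input majority
    assert len(_rows(maj_out)) == len(maj_out)
    assert _rows(maj_out) <= _rows(imbalanced_data.features[imbalanced_data.labels == 0])


def test_undersample_balanced_input_is_permutation():
    rng = np.random.default_rng(0)
    data = Dataset(rng.normal(size=(8, 2)), np.array([1] * 4 + [0] * 4))
    out = random_undersample(data, seed=3)
    assert _rows(out.features) == _rows(data.features)
    assert len(out) == len(data)


# ---------------------------------------------------------------- oversampling


def test_oversample_sizes_and_replica_fidelity(imbalanced_data):
    out = simple_oversample(imbalanced_data, seed=0)
    assert len(out) == 2 * imbalanced_data.n_maj == 180
    assert out.n_min == out.n_maj == 90
    # every drawn minority row is a bitwise copy of some original
    originals = _rows(imbalanced_data.features[imbalanced_data.labels == 1])
    assert _rows(out.features[out.labels == 1]) <= originals
    assert list(out.provenance[out.labels == 1]) == [REPLICA] * 90
    assert list(out.provenance[out.labels == 0]) == [ORIGINAL] * 90


def test_oversample_balanced_input_doubles_classes():
    rng = np.random.default_rng(1)
    data = Dataset(rng.normal(size=(10, 2)), np.array([1] * 5 + [0] * 5))
    out = simple_oversample(data, seed=2)
    assert len(out) == 10 and out.n_min == out.n_maj == 5


def test_oversample_expected_copy_count():
    """Each minority sample is drawn n_maj/n_min times in expectation."""
    data = generate_null_dataset(NullDesign(60, 1, minority_fraction=0.2, seed=9))
    n_min, n_maj = data.n_min, data.n_maj  # 12, 48
    target = data.features[data.labels == 1][0]
    counts = []
    for seed in range(500):
        out = simple_oversample(data, seed=seed)
        counts.append(np.sum(np.all(out.features[out.labels == 1] == target, axis=1)))
    mean = np.mean(counts)
    expected = n_maj / n_min
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - expected) < 3 * se + 1e-9


# ----------------------------------------------------------------------- SMOTE


def test_smote_output_counts():
    data = generate_null_dataset(NullDesign(1000, 5, 0.1, seed=4))
    out = smote(data, SamplingConfig(method="smote", percent_over=100, percent_under=100), seed=0)
    assert len(out) == 300  # 100 originals + 100 synthetic + 100 majority
    assert out.n_min == 200 and out.n_maj == 100
    tags = list(out.provenance)
    assert tags.count(SYNTHETIC) == 100 and tags.count(ORIGINAL) == 200


@pytest.mark.parametrize("percent_over,expected_total", [(200, 500), (500, 1100)])
def test_smote_percent_over_scaling(percent_over, expected_total):
    data = generate_null_dataset(NullDesign(1000, 5, 0.1, seed=4))
    cfg = SamplingConfig(method="smote", percent_over=percent_over, percent_under=100)
    out = smote(data, cfg, seed=0)
    n_synth = percent_over  # per 100 minority samples
    assert len(out) == 100 + n_synth + n_synth == expected_total


def test_smote_two_minority_points_interpolates_segment(tiny_minority_data):
    """With n_min=2 the only neighbour is the other point: every synthetic row
    must lie on the segment joining the two minority samples."""
    cfg = SamplingConfig(method="smote", percent_over=500, percent_under=0, k_neighbors=1)
    out = smote(tiny_minority_data, cfg, seed=8)
    a, b = tiny_minority_data.features[:2]
    synth = out.features[np.asarray(out.provenance) == SYNTHETIC]
    assert len(synth) == 10
    for s in synth:
        u = (s - a) / (b - a)
        assert np.allclose(u, u[0]) and 0.0 <= u[0] <= 1.0


def test_smote_rows_between_parent_and_a_neighbor():
    """Each synthetic row sits coordinatewise inside the bounding box of its
    parent and one of the parent's k nearest minority neighbours (neighbours
    recomputed brute-force here)."""
    data = generate_null_dataset(NullDesign(200, 3, 0.1, seed=6))
    k = 5
    cfg = SamplingConfig(method="smote", percent_over=200, percent_under=100, k_neighbors=k)
    out = smote(data, cfg, seed=3)
    x_min = data.features[data.labels == 1]
    synth = out.features[np.asarray(out.provenance) == SYNTHETIC]
    per_sample = cfg.percent_over // 100
    for j, s in enumerate(synth):
        parent = x_min[j // per_sample]
        d = np.linalg.norm(x_min - parent, axis=1)
        d[j // per_sample] = np.inf
        neighbors = x_min[np.argsort(d, kind="stable")[:k]]
        lo = np.minimum(parent, neighbors)
        hi = np.maximum(parent, neighbors)
        ok = ((s >= lo - 1e-12) & (s <= hi + 1e-12)).all(axis=1)
        assert ok.any(), f"synthetic row {j} outside every parent/neighbour box"


def test_smote_synthetic_rows_are_new_points():
    data = generate_null_dataset(NullDesign(300, 4, 0.1, seed=2))
    out = smote(data, SamplingConfig(method="smote"), seed=1)
    synth = out.features[np.asarray(out.provenance) == SYNTHETIC]
    assert _rows(synth).isdisjoint(_rows(data.features))


def test_smote_neighbor_pool_reduction_warns(tiny_minority_data):
    cfg = SamplingConfig(method="smote", percent_over=100, percent_under=100, k_neighbors=5)
    with pytest.warns(UserWarning, match="reducing SMOTE neighbour pool"):
        smote(tiny_minority_data, cfg, seed=0)


def test_smote_majority_retention_capped_with_warning():
    rng = np.random.default_rng(3)
    data = Dataset(rng.normal(size=(10, 2)), np.array([1] * 5 + [0] * 5))
    cfg = SamplingConfig(method="smote", percent_over=500, percent_under=100, k_neighbors=3)
    with pytest.warns(UserWarning, match="keeping all"):
        out = smote(data, cfg, seed=0)
    assert out.n_maj == 5  # capped at the available majority


# ------------------------------------------------------------------ properties


@given(
    n_min=st.integers(3, 12),
    n_maj=st.integers(12, 40),
    seed=st.integers(0, 1000),
    method=st.sampled_from(["undersample", "oversample", "smote"]),
)
@settings(max_examples=40, deadline=None)
def test_samplers_are_pure_and_counts_match_closed_forms(n_min, n_maj, seed, method):
    rng = np.random.default_rng(seed)
    data = Dataset(
        rng.normal(size=(n_min + n_maj, 3)),
        np.array([1] * n_min + [0] * n_maj),
    )
    before = data.features.copy(), data.labels.copy()
    cfg = SamplingConfig(method=method, percent_over=200, percent_under=100, k_neighbors=2)
    out = apply_sampler(data, cfg, seed=seed)
    np.testing.assert_array_equal(data.features, before[0])
    np.testing.assert_array_equal(data.labels, before[1])
    if method == "undersample":
        assert (out.n_min, out.n_maj) == (n_min, n_min)
    elif method == "oversample":
        assert (out.n_min, out.n_maj) == (n_maj, n_maj)
    else:
        n_synth = 2 * n_min
        assert out.n_min == n_min + n_synth
        assert out.n_maj == min(n_synth, n_maj)


def test_sampler_determinism(imbalanced_data):
    for method in ("undersample", "oversample", "smote"):
        cfg = SamplingConfig(method=method, k_neighbors=3)
        a = apply_sampler(imbalanced_data, cfg, seed=11)
        b = apply_sampler(imbalanced_data, cfg, seed=11)
        np.testing.assert_array_equal(a.features, b.features)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SamplingConfig(method="nearmiss")
    with pytest.raises(ValueError):
        SamplingConfig(method="smote", percent_over=150)
    with pytest.raises(ValueError):
        SamplingConfig(method="smote", k_neighbors=0)
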