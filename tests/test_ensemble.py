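import numpy as np
import pytest

import premirclass as pm
from premirclass.ensemble import ScalingParams
from premirclass.errors import PremirclassError

FAST_GRID = pm.GridConfig(c_exponents=(-1, 3, 7), gamma_exponents=(-7, -3, 1))


@pytest.fixture(scope="module")
def trained_k3(separable_table):
    return pm.train_ensemble(separable_table, k=3, grid=FAST_GRID, seed=0)


def test_scaling_maps_to_unit_interval():
    X = np.array([[0.0, 5.0, 7.0], [10.0, -5.0, 7.0], [5.0, 0.0, 7.0]])
    params = ScalingParams.fit(X)
    scaled = params.transform(X)
    assert scaled.min() >= -1.0 and scaled.max() <= 1.0
    assert np.all(scaled[:, 2] == 0.0)  # constant column


def test_partition_k1_is_single_block(separable_table):
    scaling = ScalingParams.fit(separable_table.X)
    blocks = pm.partition_negatives(
        scaling.transform(separable_table.X), separable_table.labels, 1
    )
    assert len(blocks) == 1 and len(blocks[0]) == 90


def test_partition_sort_and_cut_rule():
    """5 negatives at distances 1..5 from the positive centroid, k=2."""
    X = np.array([[0.0], [0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
    labels = np.array([1, 1, -1, -1, -1, -1, -1])
    blocks = pm.partition_negatives(X, labels, 2)  # already in scaled-like space
    assert [len(b) for b in blocks] == [3, 2]
    assert list(blocks[0]) == [2, 3, 4] and list(blocks[1]) == [5, 6]


def test_partition_block_sizes_near_equal():
    """5428 negatives, k=3 -> 1810/1809/1809 (the historical third)."""
    n_neg = 5428
    X = np.vstack([np.zeros((10, 1)), np.arange(1, n_neg + 1).reshape(-1, 1)])
    labels = np.array([1] * 10 + [-1] * n_neg)
    blocks = pm.partition_negatives(X, labels, 3)
    assert [len(b) for b in blocks] == [1810, 1809, 1809]


def test_partition_k_exceeding_negatives_errors():
    X = np.zeros((4, 1))
    labels = np.array([1, 1, -1, -1])
    with pytest.raises(PremirclassError):
        pm.partition_negatives(X, labels, 3)


@pytest.mark.parametrize(
    "votes,expected",
    [
        ([+1, +1, -1], +1),  # strict majority, k=3
        ([+1, -1], -1),  # even k tie: latter half (far negatives) wins
        ([-1, +1], +1),
        ([+1, -1, +1, -1], -1),  # 2-2 tie, latter half (+,-) tied, last decides
        ([-1, +1, -1, +1], +1),
        ([+1, +1, -1, -1], -1),  # latter half unanimous negative
    ],
)
def test_majority_tie_cascade(votes, expected):
    assert pm.aggregate_majority(np.array([votes]))[0] == expected


def test_k1_majority_equals_mean_distance(separable_table):
    model = pm.train_ensemble(separable_table, k=1, grid=FAST_GRID, seed=0)
    X = separable_table.X
    assert np.array_equal(pm.predict_majority(model, X), pm.predict_mean_distance(model, X))


def test_separable_training_set_is_fit_perfectly(trained_k3, separable_table):
    for predict in (pm.predict_majority, pm.predict_mean_distance):
        assert np.array_equal(predict(trained_k3, separable_table.X), separable_table.labels)


def test_training_is_deterministic(separable_table):
    a = pm.train_ensemble(separable_table, k=2, grid=FAST_GRID, seed=3)
    b = pm.train_ensemble(separable_table, k=2, grid=FAST_GRID, seed=3)
    X = separable_table.X
    assert np.array_equal(pm.predict_majority(a, X), pm.predict_majority(b, X))
    assert np.array_equal(pm.predict_mean_distance(a, X), pm.predict_mean_distance(b, X))


def test_mean_distance_dispatches_each_sample_once(trained_k3, separable_table):
    _, dispatch = pm.predict_mean_distance(trained_k3, separable_table.X, return_dispatch=True)
    assert dispatch.shape == (separable_table.n_samples,)
    assert set(np.unique(dispatch)) <= {0, 1, 2}
    counts = np.bincount(dispatch, minlength=3)
    assert counts.sum() == separable_table.n_samples


def test_sample_at_centroid_dispatches_to_that_submodel(trained_k3):
    for i, sub in enumerate(trained_k3.submodels):
        # invert the scaling so the raw-space point lands on the stored centroid
        span = trained_k3.scaling.col_max - trained_k3.scaling.col_min
        raw = trained_k3.scaling.col_min + (sub.centroid + 1.0) * span / 2.0
        assert trained_k3.dispatch_indices(raw[None, :])[0] == i


def test_serialization_round_trip(tmp_path, trained_k3, separable_table):
    path = tmp_path / "model.joblib"
    pm.save_model(trained_k3, path)
    back = pm.load_model(path)
    X = separable_table.X
    assert back.k == trained_k3.k and back.feature_names == trained_k3.feature_names
    assert np.array_equal(back.predict(X), trained_k3.predict(X))
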