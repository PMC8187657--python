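"""Classifier training, evaluation metrics, baselines, protocol operations."""

import numpy as np
import pytest

from tracenet.models import (
    ClassifierConfig,
    ModelError,
    add_coordinate_jitter,
    average_similarity_classifier,
    compute_auc,
    downsample_training,
    ep_contact_predictor,
    evaluate_classifier,
    grid_search,
    kfold_cross_validate,
    odds_ratio,
    train_cnn,
    train_dnn,
    train_random_forest,
)
from tracenet.trace_data import LabeledDataset, build_dataset

B = 52


@pytest.fixture(scope="module")
def separable_dataset():
    """ON = positive-shifted matrices, OFF = negative-shifted; trivially separable."""
    rng = np.random.default_rng(0)
    n = 240
    labels = (np.arange(n) % 2).astype(int)
    base = rng.normal(size=(n, B, B))
    base = (base + base.transpose(0, 2, 1)) / 2
    shift = np.where(labels == 1, 2.0, -2.0)[:, None, None]
    matrices = np.abs(base) + 100.0 + shift * 10.0
    return build_dataset(matrices, labels, seed=1)


FAST = dict(
    epochs=12,
    occlusion_max_window=0,
    conv_blocks=((4, 3),),
    dense_units=(8,),
    batch_size=64,
)


def test_cnn_separates_trivial_classes(separable_dataset):
    model = train_cnn(separable_dataset, ClassifierConfig(seed=2, **FAST))
    auc = compute_auc(
        separable_dataset.split_labels("train"),
        model.predict_proba(separable_dataset.standardized_matrices("train")),
    )
    assert auc == 1.0
    assert len(model.history["train_loss"]) == FAST["epochs"]


def test_dnn_and_rf_separate_trivial_classes(separable_dataset):
    dnn = train_dnn(separable_dataset, ClassifierConfig(seed=3, **FAST))
    rf = train_random_forest(
        separable_dataset, ClassifierConfig(rf_params={"n_estimators": 50}, seed=4)
    )
    for model in (dnn, rf):
        auc = compute_auc(
            separable_dataset.split_labels("test"),
            model.predict_proba(separable_dataset.standardized_matrices("test")),
        )
        assert auc == 1.0


def test_training_requires_norm_stats(separable_dataset):
    bare = separable_dataset.replace(norm_stats=None)
    with pytest.raises(ModelError, match="norm_stats"):
        train_cnn(bare, ClassifierConfig(seed=0, **FAST))


# ---------------------------------------------------------------------------
# AUC / evaluation
# ---------------------------------------------------------------------------

def test_auc_hand_cases():
    assert compute_auc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0
    assert compute_auc([1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
    with pytest.raises(ModelError):
        compute_auc([1, 1], [0.2, 0.3])


def test_auc_equals_pair_enumeration():
    labels = np.array([1, 0, 1, 0, 1, 0])
    scores = np.array([0.9, 0.8, 0.7, 0.7, 0.2, 0.1])
    wins = ties = 0
    for sp in scores[labels == 1]:
        for sn in scores[labels == 0]:
            wins += sp > sn
            ties += sp == sn
    expected = (wins + 0.5 * ties) / (3 * 3)
    assert compute_auc(labels, scores) == pytest.approx(expected)


def test_evaluation_report_confusion_consistency(separable_dataset):
    model = train_random_forest(
        separable_dataset, ClassifierConfig(rf_params={"n_estimators": 20}, seed=5)
    )
    rep = evaluate_classifier(model, separable_dataset, n_bootstrap=100)
    counts = rep.confusion
    assert sum(counts.values()) == rep.n
    assert 0.0 <= rep.auc <= 1.0
    fpr, tpr = rep.roc_points[:, 0], rep.roc_points[:, 1]
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


# ---------------------------------------------------------------------------
# odds ratio
# ---------------------------------------------------------------------------

def test_odds_ratio_closed_forms():
    pred = np.array([1] * 20 + [1] * 10 + [0] * 10 + [0] * 20)
    actual = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
    orr, ci = odds_ratio(pred, actual, n_bootstrap=200, seed=0)
    assert orr == pytest.approx(4.0)
    assert ci[0] <= orr <= ci[1]


def test_odds_ratio_independence_is_one():
    # cells proportional: prediction independent of truth
    pred = np.array([1, 1, 0, 0] * 25)
    actual = np.array([1, 0, 1, 0] * 25)
    orr, _ = odds_ratio(pred, actual, n_bootstrap=50, seed=0)
    assert orr == pytest.approx(1.0)


def test_odds_ratio_zero_cell_haldane():
    pred = np.array([1] * 5 + [0] * 10)
    actual = np.array([1] * 5 + [1] * 5 + [0] * 5)
    orr, _ = odds_ratio(pred, actual, n_bootstrap=50, seed=0)
    assert orr == pytest.approx((5.5 * 5.5) / (0.5 * 5.5))
    with pytest.raises(ModelError):
        odds_ratio(pred, actual[:-1])


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def test_ep_contact_threshold_boundary():
    m = np.zeros((3, B, B))
    m[0, 19, 39] = m[0, 39, 19] = 100.0
    m[1, 19, 39] = m[1, 39, 19] = 200.0
    m[2, 19, 39] = m[2, 39, 19] = 150.0
    np.testing.assert_array_equal(ep_contact_predictor(m), [1, 0, 1])


def test_ep_contact_rejects_standardized_input():
    with pytest.raises(ModelError, match="RAW"):
        ep_contact_predictor(np.random.default_rng(0).normal(size=(2, B, B)))


def test_average_similarity_nearest_centroid(rng):
    train = rng.normal(size=(10, B, B))
    y = np.array([1] * 5 + [0] * 5)
    mean_on, mean_off = train[:5].mean(0), train[5:].mean(0)
    test = np.stack([mean_on, mean_off, (mean_on + mean_off) / 2])
    pred = average_similarity_classifier(train, y, test)
    np.testing.assert_array_equal(pred, [1, 0, 0])  # equidistant -> OFF


def test_average_similarity_matches_brute_force(rng):
    train = rng.normal(size=(10, B, B))
    y = (np.arange(10) % 2).astype(int)
    test = rng.normal(size=(6, B, B))
    pred = average_similarity_classifier(train, y, test)
    mean_on, mean_off = train[y == 1].mean(0), train[y == 0].mean(0)
    for k in range(6):
        d_on = np.sqrt(((test[k] - mean_on) ** 2).sum())
        d_off = np.sqrt(((test[k] - mean_off) ** 2).sum())
        assert pred[k] == (1 if d_on < d_off else 0)
    with pytest.raises(ModelError):
        average_similarity_classifier(train, np.ones(10), test)


# ---------------------------------------------------------------------------
# protocol operations
# ---------------------------------------------------------------------------

def test_kfold_partitions_are_stratified(separable_dataset):
    reports = kfold_cross_validate(
        separable_dataset,
        k=4,
        config=ClassifierConfig(
            kind="rf", rf_params={"n_estimators": 10}, seed=0
        ),
        n_bootstrap=20,
    )
    assert len(reports) == 4
    sizes = [r.n for r in reports]
    assert max(sizes) - min(sizes) <= 1
    pool = len(separable_dataset.indices("train")) + len(
        separable_dataset.indices("val")
    )
    assert sum(sizes) == pool
    with pytest.raises(ModelError):
        kfold_cross_validate(separable_dataset, k=1)


def test_jitter_statistics_and_identity(rng):
    coords = rng.normal(scale=100, size=(200, B, 3))
    same = add_coordinate_jitter(coords, 0.0, seed=1)
    np.testing.assert_array_equal(same, coords)
    sigma = 50.0
    moved = add_coordinate_jitter(coords, sigma, seed=1)
    disp = np.linalg.norm(moved - coords, axis=-1)
    # 3D Gaussian displacement norm is chi(3): mean sigma*sqrt(8/pi)
    expected = sigma * np.sqrt(8 / np.pi)
    assert disp.mean() == pytest.approx(expected, rel=0.02)


def test_jitter_changes_distances_pre_matrix(rng):
    coords = rng.normal(scale=100, size=(5, B, 3))
    moved = add_coordinate_jitter(coords, 30.0, seed=2)
    d0 = np.linalg.norm(coords[:, 0] - coords[:, -1], axis=-1)
    d1 = np.linalg.norm(moved[:, 0] - moved[:, -1], axis=-1)
    assert not np.allclose(d0, d1)


def test_downsample_training_only(separable_dataset):
    ds = downsample_training(separable_dataset, 0.5, seed=0)
    n_train0 = len(separable_dataset.indices("train"))
    assert len(ds.indices("train")) == pytest.approx(n_train0 * 0.5, abs=1)
    assert len(ds.indices("test")) == len(separable_dataset.indices("test"))
    assert len(ds.indices("val")) == len(separable_dataset.indices("val"))
    f0 = separable_dataset.labels[separable_dataset.indices("train")].mean()
    f1 = ds.labels[ds.indices("train")].mean()
    assert abs(f0 - f1) <= 0.02
    assert downsample_training(separable_dataset, 1.0) is separable_dataset


def test_checkpoint_round_trip(separable_dataset, tmp_path):
    model = train_cnn(separable_dataset, ClassifierConfig(seed=11, **FAST))
    X = separable_dataset.standardized_matrices("test")
    before = model.predict_proba(X)
    path = tmp_path / "model.npz"
    model.save(path)
    from tracenet.models import TrainedClassifier

    back = TrainedClassifier.load(path)
    np.testing.assert_allclose(back.predict_proba(X), before, atol=1e-6)
    assert back.config.seed == 11
    np.testing.assert_allclose(
        back.norm_stats.mean, separable_dataset.norm_stats.mean
    )


def test_grid_search_selects_by_validation_auc(separable_dataset):
    good = ClassifierConfig(kind="rf", rf_params={"n_estimators": 30}, seed=0)
    # a learning rate this large diverges to NaN loss -> ranked last
    broken = ClassifierConfig(
        kind="cnn", learning_rate=1e6, seed=0,
        **{k: v for k, v in FAST.items() if k != "epochs"}, epochs=2,
    )
    best, table = grid_search(separable_dataset, [broken, good])
    assert best is good
    assert table.iloc[-1]["config"] is broken
    assert table.iloc[-1]["val_auc"] < 0.6 or np.isnan(table.iloc[-1]["val_auc"])
    single, _ = grid_search(separable_dataset, [good])
    assert single is good
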