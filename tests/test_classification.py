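"""Classifier: training-set assembly, cross-validation, importances, UMAP."""

import numpy as np
import pandas as pd
import pytest

import gliascreen as gs
from gliascreen.classification import (ClassificationError, TrainingSet,
                                       assemble_training_set, classify_objects,
                                       cross_validate, embed_features,
                                       rank_feature_importance, train_classifier)
from gliascreen.features import feature_columns


def _toy_pool(n_per_class=500, seed=0, classes=("a", "b")):
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for i, cls in enumerate(classes):
        X = rng.normal(5 * i, 1, size=(n_per_class, 3))
        frames.append(pd.DataFrame(X, columns=["f1", "f2", "f3"]))
        labels += [cls] * n_per_class
    return pd.concat(frames, ignore_index=True), np.array(labels, dtype=object)


# ------------------------------------------------------------ assembly

def test_balanced_sampling_exact():
    pool, y = _toy_pool(1000)
    ts = assemble_training_set(pool, y, per_class=400, classes=("a", "b"), seed=1)
    assert ts.per_class_counts == {"a": 400, "b": 400}
    assert not ts.imbalanced_classes


def test_pool_limited_class_flagged():
    pool, y = _toy_pool(100)
    ts = assemble_training_set(pool, y, per_class=400, classes=("a", "b"), seed=1)
    assert ts.per_class_counts["a"] == 100
    assert set(ts.imbalanced_classes) == {"a", "b"}


def test_absent_class_named_in_error():
    pool, y = _toy_pool(50)
    with pytest.raises(ClassificationError, match="necrotic"):
        assemble_training_set(pool, y, per_class=10, classes=("a", "necrotic"))


def test_sampling_deterministic():
    pool, y = _toy_pool(1000)
    a = assemble_training_set(pool, y, per_class=300, classes=("a", "b"), seed=9)
    b = assemble_training_set(pool, y, per_class=300, classes=("a", "b"), seed=9)
    pd.testing.assert_frame_equal(a.features, b.features)


def test_lps_stratum_balance():
    pool, y = _toy_pool(1000)
    lps = np.tile([False, True], len(pool) // 2)
    ts = assemble_training_set(pool, y, per_class=400, classes=("a", "b"),
                               lps=lps, balance_lps=True, seed=0)
    for cls in ("a", "b"):
        sel = ts.lps[ts.labels == cls]
        assert abs(sel.sum() - len(sel) / 2) <= 1


# ------------------------------------------------------------ training

def test_separable_classes_training_recall_one():
    pool, y = _toy_pool(200)
    ts = TrainingSet(features=pool, labels=y)
    model = train_classifier(ts, seed=0)
    pred = classify_objects(model, pool)
    assert (pred == y).mean() == 1.0


def test_single_class_rejected():
    pool, y = _toy_pool(50, classes=("a",))
    with pytest.raises(ClassificationError):
        train_classifier(TrainingSet(features=pool, labels=y))


def test_training_deterministic_given_seed():
    pool, y = _toy_pool(200, seed=3)
    probe, _ = _toy_pool(50, seed=4)
    p1 = classify_objects(train_classifier(TrainingSet(pool, y), seed=7), probe)
    p2 = classify_objects(train_classifier(TrainingSet(pool, y), seed=7), probe)
    assert (p1 == p2).all()


# ------------------------------------------------------------ CV

def test_every_object_predicted_once_out_of_fold():
    pool, y = _toy_pool(50, classes=("a", "b"))
    cm = cross_validate(TrainingSet(pool, y), k=5, seed=0)
    assert cm.matrix.to_numpy().sum() == len(pool)
    norm = cm.normalized()
    np.testing.assert_allclose(norm.sum(axis=1), 1.0, atol=1e-9)


def test_identical_distributions_give_chance_recall():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("wxyz"))
    y = np.array((["a"] * 100 + ["b"] * 100 + ["c"] * 100 + ["d"] * 100), dtype=object)
    cm = cross_validate(TrainingSet(X, y), k=5, seed=0)
    acc = np.diag(cm.matrix.to_numpy()).sum() / 400
    assert 0.1 <= acc <= 0.45   # chance = 0.25


def test_small_class_rejected():
    pool, y = _toy_pool(3, classes=("a", "b"))
    with pytest.raises(ClassificationError):
        cross_validate(TrainingSet(pool, y), k=5)


def test_recall_monotone_in_intensity_separation():
    """Widening class-conditional intensity separation never hurts recall."""
    recalls = []
    for sep in (0.3, 1.0, 2.0):
        rng = np.random.default_rng(17)
        X = np.concatenate([rng.normal(0, 1, (120, 2)),
                            rng.normal(sep * 3, 1, (120, 2))])
        y = np.array(["a"] * 120 + ["b"] * 120, dtype=object)
        cm = cross_validate(TrainingSet(pd.DataFrame(X, columns=["u", "v"]), y),
                            k=3, seed=0)
        recalls.append(cm.recall.median())
    assert recalls[0] <= recalls[1] + 0.02 and recalls[1] <= recalls[2] + 0.02


# ------------------------------------------------------------ prediction

def test_column_mismatch_listed():
    pool, y = _toy_pool(100)
    model = train_classifier(TrainingSet(pool, y), seed=0)
    with pytest.raises(ClassificationError, match="f3"):
        classify_objects(model, pool.drop(columns="f3"))


def test_empty_table_empty_labels():
    pool, y = _toy_pool(100)
    model = train_classifier(TrainingSet(pool, y), seed=0)
    labels = classify_objects(model, pool.iloc[:0])
    assert len(labels) == 0


def test_bright_neuo_object_classified_neuron(labeled_pool):
    pool, y = labeled_pool
    cols = feature_columns(pool)
    ts = assemble_training_set(pool, y, per_class=100, feature_cols=cols, seed=0)
    model = train_classifier(ts, seed=0)
    neurons = pool[y == "neuron"].head(20)
    pred, scores = classify_objects(model, neurons, return_scores=True)
    assert (pred == "neuron").mean() > 0.9
    assert (scores.idxmax(axis=1) == "neuron").mean() > 0.9


# ------------------------------------------------------------ importances

def test_informative_feature_ranks_first():
    rng = np.random.default_rng(2)
    n = 400
    X = pd.DataFrame({
        "const1": np.ones(n), "const2": np.full(n, 3.0),
        "signal": np.concatenate([rng.normal(0, 1, n // 2), rng.normal(6, 1, n // 2)]),
    })
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
    model = train_classifier(TrainingSet(X, y), seed=0)
    imp = rank_feature_importance(model)
    assert imp.index[0] == "signal"
    assert imp[["const1", "const2"]].max() < 0.01
    assert imp.sum() == pytest.approx(1.0)
    assert len(imp) == 3 and (imp >= 0).all()


def test_expected_feature_families_in_top_ten(labeled_pool):
    pool, y = labeled_pool
    cols = feature_columns(pool)
    ts = assemble_training_set(pool, y, per_class=150, feature_cols=cols, seed=0)
    model = train_classifier(ts, seed=0)
    top = list(rank_feature_importance(model).index[:10])
    assert any(c.startswith("hoechst_") for c in top)
    assert any(c in ("shape_area", "shape_equivalent_diameter", "shape_major_axis",
                     "shape_minor_axis") for c in top)
    assert any(c.startswith(("ib4_", "neuo_")) for c in top)


def test_unfitted_model_rejected():
    from sklearn.ensemble import RandomForestClassifier
    from gliascreen.classification import ClassifierModel
    bad = ClassifierModel(estimator=RandomForestClassifier(), feature_names=["x"],
                          classes=["a"], seed=0)
    with pytest.raises(ClassificationError):
        rank_feature_importance(bad)


# ------------------------------------------------------------ embedding

def test_umap_embedding_contract():
    rng = np.random.default_rng(0)
    blob1 = rng.normal(0, 0.3, size=(60, 6))
    blob2 = rng.normal(8, 0.3, size=(60, 6))
    X = pd.DataFrame(np.concatenate([blob1, blob2]))
    emb = embed_features(X, n_neighbors=10, seed=4)
    assert emb.shape == (120, 2)
    emb2 = embed_features(X, n_neighbors=10, seed=4)
    np.testing.assert_allclose(emb, emb2)
    # well-separated blobs stay separated in the embedding
    d_intra = np.percentile(
        np.linalg.norm(emb[:60] - emb[:60].mean(0), axis=1), 95)
    d_inter = np.linalg.norm(emb[:60].mean(0) - emb[60:].mean(0))
    assert d_inter > d_intra
    with pytest.raises(ClassificationError):
        embed_features(X.head(5), n_neighbors=10)
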