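"""Feature extraction, Hopkins statistic, SMOTE bagging classifier."""

from __future__ import annotations

import numpy as np
import pytest

from kerndom.classify import (
    FEATURE_ORDER,
    BaggingModel,
    extract_features,
    feature_matrix,
    hopkins,
    predict,
    smote_balance,
    train,
)
from kerndom.contacts import ContactGraph, build_contact_graph
from kerndom.synth import FixtureSpec, make_chain

from conftest import toy_chain


def separable_data(n_a=600, n_b=400, seed=0, d=5, gap=6.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_a, d)), rng.normal(gap, 1, (n_b, d))])
    y = np.array(["single"] * n_a + ["multi"] * n_b)
    return X, y


class TestExtractFeatures:
    def test_mean_hydrophobicity_arithmetic(self):
        chain = toy_chain(
            [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], hydro=[1.0, 2.0, 3.0]
        )
        graph = build_contact_graph(chain, cutoff=4.0)
        fv = extract_features(chain, graph)
        assert fv["hydro_mean"] == pytest.approx(2.0)
        assert fv["n_residues"] == 3

    def test_path_graph_has_zero_clustering(self):
        chain = toy_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
        graph = build_contact_graph(chain)
        fv = extract_features(chain, graph)
        assert fv["clustering_global"] == 0.0
        assert fv["clustering_avg_local"] == 0.0

    def test_collinear_ca_coordinates(self):
        n = 12
        chain = toy_chain(np.arange(n)[:, None] * [3.8, 0, 0])
        fv = extract_features(chain, build_contact_graph(chain))
        assert fv["pca_var2"] == pytest.approx(0.0, abs=1e-9)
        assert fv["pca_var3"] == pytest.approx(0.0, abs=1e-9)
        assert fv["pca_evr1"] == pytest.approx(1.0)

    def test_fixed_feature_order_and_finiteness(self, two_blob, two_blob_graph):
        chain, _ = two_blob
        fv = extract_features(chain, two_blob_graph, seed=3)
        assert list(fv) == FEATURE_ORDER
        assert np.isfinite(feature_matrix([fv])).all()

    def test_rigid_motion_invariance_of_geometry_features(self, two_blob):
        chain, _ = two_blob
        graph = build_contact_graph(chain)
        fv0 = extract_features(chain, graph, seed=5)
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(scale=40, size=3)
        for res in chain.residues:
            res.ca_coord = res.ca_coord @ q.T + shift
            for a in res.atoms:
                a.coord = a.coord @ q.T + shift
        from kerndom.structure import radius_of_gyration

        radius_of_gyration(chain)
        fv1 = extract_features(chain, build_contact_graph(chain), seed=5)
        for key in ("radius_of_gyration", "pca_var1", "pca_var2", "pca_var3",
                    "hopkins_stat", "dip_stat"):
            assert fv1[key] == pytest.approx(fv0[key], abs=1e-6), key

    def test_size_mismatch_rejected(self):
        chain = toy_chain([[0, 0, 0], [3.8, 0, 0]])
        with pytest.raises(ValueError, match="nodes"):
            extract_features(chain, ContactGraph(adjacency=np.zeros((5, 5))))


class TestHopkins:
    def test_uniform_points_near_half(self):
        rng = np.random.default_rng(0)
        values = []
        for seed in range(100):
            X = rng.uniform(0, 10, size=(60, 3))
            values.append(hopkins(X, seed=seed))
        assert 0.35 < np.mean(values) < 0.65

    def test_clustered_points_near_one(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.2, (30, 3)), rng.normal(20, 0.2, (30, 3))]
        )
        assert hopkins(X, seed=0) > 0.8

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hopkins(np.zeros((12, 3)))

    def test_seed_determinism(self):
        X = np.random.default_rng(3).normal(size=(40, 3))
        assert hopkins(X, seed=11) == hopkins(X, seed=11)


class TestSmote:
    def test_exact_balance_and_interpolation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = np.array(["multi"] * 22 + ["single"] * 8)
        Xb, yb = smote_balance(X, y, rng)
        _, counts = np.unique(yb, return_counts=True)
        assert counts[0] == counts[1] == 22
        # synthetic points lie within the minority's bounding box
        mino = X[y == "single"]
        synth = Xb[30:]
        assert (synth >= mino.min(axis=0) - 1e-9).all()
        assert (synth <= mino.max(axis=0) + 1e-9).all()

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        y = np.array(["multi"] * 5 + ["single"] * 5)
        Xb, yb = smote_balance(X, y, rng)
        assert len(yb) == 10


class TestBagging:
    def test_separable_data_high_holdout_accuracy(self):
        X, y = separable_data(seed=2)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        cut = int(0.8 * len(y))
        tr, te = idx[:cut], idx[cut:]
        model = train(X[tr], y[tr], n_estimators=25, seed=1)
        preds = [predict(model, x)[0] for x in X[te]]
        assert np.mean(np.array(preds) == y[te]) >= 0.95

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="class"):
            train(X, np.array(["single"] * 20), n_estimators=5)

    def test_seed_determinism(self):
        X, y = separable_data(80, 60, seed=4)
        probe = np.random.default_rng(9).normal(3, 1, size=(10, 5))
        a = train(X, y, n_estimators=12, seed=7)
        b = train(X, y, n_estimators=12, seed=7)
        pa = [predict(a, x) for x in probe]
        pb = [predict(b, x) for x in probe]
        assert pa == pb

    def test_centroid_probe_confident(self):
        X, y = separable_data(200, 150, seed=5)
        model = train(X, y, n_estimators=20, seed=0)
        label, frac = predict(model, np.full(5, 6.0))  # class-b centroid
        assert label == "multi" and frac > 0.9
        label, frac = predict(model, np.zeros(5))
        assert label == "single" and frac < 0.1

    def test_missing_feature_rejected(self, two_blob, two_blob_graph):
        X, y = separable_data(30, 30, seed=6)
        model = train(X, y, n_estimators=3, seed=0,
                      feature_order=[f"f{i}" for i in range(5)])
        with pytest.raises(ValueError, match="missing"):
            predict(model, {"f0": 1.0})
        with pytest.raises(ValueError, match="expected 5"):
            predict(model, np.zeros(4))

    def test_tie_votes_multi(self):
        X, y = separable_data(30, 30, seed=8)
        model = train(X, y, n_estimators=2, seed=0)
        # force a tie with two stub estimators that disagree everywhere
        from sklearn.tree import DecisionTreeClassifier

        t1 = DecisionTreeClassifier().fit([[0.0]] * 2 + [[1.0]] * 2,
                                          ["single"] * 2 + ["multi"] * 2)
        t2 = DecisionTreeClassifier().fit([[0.0]] * 2 + [[1.0]] * 2,
                                          ["multi"] * 2 + ["single"] * 2)
        model.estimators = [t1, t2]
        model.feature_order = ["f0"]
        label, frac = predict(model, np.array([0.0]))
        assert frac == 0.5 and label == "multi"

    def test_model_round_trip(self, tmp_path):
        X, y = separable_data(30, 30, seed=10)
        model = train(X, y, n_estimators=4, seed=3)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = BaggingModel.load(path)
        probe = np.random.default_rng(1).normal(size=(5, 5))
        assert [predict(loaded, x) for x in probe] == [predict(model, x) for x in probe]


class TestEndToEndClassification:
    def test_fixture_chains_classified_correctly(self):
        """Two-blob fixtures read as multi, one-blob as single (>= 90%)."""
        from kerndom.synth import make_feature_dataset

        table, labels = make_feature_dataset(35, 35, seed=5)
        X = table.to_numpy(float)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(labels))
        tr, te = idx[:50], idx[50:]
        model = train(X[tr], labels[tr], n_estimators=30, seed=2)
        preds = np.array([predict(model, x)[0] for x in X[te]])
        assert np.mean(preds == labels[te]) >= 0.9
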