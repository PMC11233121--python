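import numpy as np
import pytest

import protfuse as pf
from protfuse.downstream import (AffinityExample, concordance_index,
                                 fit_affinity_head, fit_classifier_head,
                                 ligand_fingerprint, metrics, predict_affinity,
                                 predict_classifier, rm2_index)
from protfuse.fixtures import BUILTIN_SMILES, make_affinity_task
from protfuse.sequence_embedding import toy_embedder


class TestLigandFingerprint:
    def test_methane_bit_pattern_locked(self):
        fp = ligand_fingerprint("C")
        assert sorted(np.flatnonzero(fp).tolist()) == [1264]

    def test_deterministic(self):
        for smi in BUILTIN_SMILES:
            assert np.array_equal(ligand_fingerprint(smi), ligand_fingerprint(smi))
            assert set(np.unique(ligand_fingerprint(smi))) <= {0.0, 1.0}

    def test_invalid_smiles_raises_with_string(self):
        with pytest.raises(ValueError, match="not_a_smiles"):
            ligand_fingerprint("not_a_smiles")


class TestAffinityHead:
    @pytest.fixture(scope="class")
    def task(self):
        structs = pf.make_dataset(pf.FixtureSpec(n_structures=8,
                                                 residues_range=(15, 30), seed=3))
        rows = make_affinity_task(structs, seed=3)
        fps = {s: ligand_fingerprint(s) for s in BUILTIN_SMILES}
        emb = {s.id: toy_embedder.embed(s.sequence) for s in structs}
        return [AffinityExample(emb[p], fps[s], y) for p, s, y in rows]

    def test_gp_interpolates_training_point(self, task):
        model = fit_affinity_head(task[:30], seed=0, noise_level=1e-8)
        pred = predict_affinity(model, task[:1])[0]
        assert pred == pytest.approx(task[0].label, abs=1e-3)

    def test_noise_free_fixture_test_pearson(self, task):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(task))
        n_test = len(task) // 5
        test = [task[i] for i in perm[:n_test]]
        train = [task[i] for i in perm[n_test:]]
        model = fit_affinity_head(train, seed=0)
        y = np.array([e.label for e in test])
        m = metrics(y, y_pred=predict_affinity(model, test))
        assert m["pearson"] >= 0.9

    def test_seeded_determinism(self, task):
        m1 = fit_affinity_head(task[:20], seed=1)
        m2 = fit_affinity_head(task[:20], seed=1)
        np.testing.assert_array_equal(predict_affinity(m1, task[20:30]),
                                      predict_affinity(m2, task[20:30]))

    def test_too_few_examples(self, task):
        with pytest.raises(ValueError):
            fit_affinity_head(task[:2])


class TestClassifierHead:
    def test_separable_classes_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 1, size=(40, 10)),
                       rng.normal(3, 1, size=(40, 10))])
        y = np.repeat([0, 1], 40)
        model = fit_classifier_head(X, y, seed=0, n_estimators=50)
        proba = predict_classifier(model, X)
        assert (proba.argmax(axis=1) == y).mean() == 1.0

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(60, 8))
        y = (X[:, 0] > 0).astype(int)
        p1 = predict_classifier(fit_classifier_head(X, y, seed=3), X)
        p2 = predict_classifier(fit_classifier_head(X, y, seed=3), X)
        np.testing.assert_array_equal(p1, p2)

    def test_label_permutation_control_near_chance(self, rng):
        X = rng.normal(size=(300, 10))
        y_signal = (X[:, 0] + 0.1 * rng.normal(size=300) > 0).astype(int)
        y_perm = rng.permutation(y_signal)
        model = fit_classifier_head(X[:150], y_perm[:150], seed=0,
                                    n_estimators=100)
        acc = (predict_classifier(model, X[150:]).argmax(axis=1)
               == y_perm[150:]).mean()
        assert 0.4 <= acc <= 0.6

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_classifier_head(rng.normal(size=(10, 3)), np.zeros(10))


def auroc_pair_oracle(y_true, scores):
    """Exhaustive pairwise concordance count (ties get half credit)."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2, 3, 4])
        m = metrics(y, y_pred=y.copy())
        assert m["mse"] == 0 and m["ci"] == 1.0
        assert m["pearson"] == pytest.approx(1.0)
        assert m["rm2"] == pytest.approx(1.0)

    def test_reversed_ranking(self):
        y = np.array([1.0, 2, 3, 4, 5])
        m = metrics(y, y_pred=y[::-1].copy())
        assert m["ci"] == 0.0
        assert m["spearman"] == pytest.approx(-1.0)

    def test_five_point_hand_example(self):
        # one discordant pair of C(5,2)=10
        assert concordance_index([1, 2, 3, 4, 5], [1, 3, 2, 4, 5]) \
            == pytest.approx(9 / 10)

    def test_ci_monotone_transform_invariance(self, rng):
        y, f = rng.normal(size=40), rng.normal(size=40)
        base = concordance_index(y, f)
        assert concordance_index(y, np.exp(f)) == pytest.approx(base)
        assert concordance_index(y, 3 * f + 7) == pytest.approx(base)

    def test_ci_constant_truth_undefined(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_auroc_equals_exhaustive_pair_count(self, rng):
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1  # both classes present
        s = rng.normal(size=200)
        m = metrics(y.astype(float), y_score=s)
        assert m["auroc"] == pytest.approx(auroc_pair_oracle(y, s), abs=1e-12)

    def test_auroc_perfect_separation(self):
        y = np.array([0.0, 0, 1, 1])
        m = metrics(y, y_score=np.array([0.1, 0.2, 0.8, 0.9]))
        assert m["auroc"] == 1.0

    def test_rm2_equals_r2_for_through_origin_data(self, rng):
        f = rng.uniform(1, 5, size=50)
        y = 1.0 * f  # identical ordinary and through-origin fits
        assert rm2_index(y, f) == pytest.approx(1.0)
        # noisy through-origin data keeps rm2 <= r2
        y2 = f + 0.3 * rng.normal(size=50)
        r2 = np.corrcoef(y2, f)[0, 1] ** 2
        assert rm2_index(y2, f) <= r2 + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            metrics(np.zeros(3), y_pred=np.zeros(4))
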