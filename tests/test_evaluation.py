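"""Metric definitions, LOSO fold algebra and the 3-class label mapping."""

import numpy as np
import pandas as pd
import pytest

from mfvan import (
    aggregate,
    class_metrics,
    confusion,
    evaluate_loso,
    loso_folds,
    map_to_3class,
)


def brute_force_metrics(y_true, y_pred, classes):
    """Independent recomputation of all metrics by direct counting."""
    out = {}
    f1s, recs = [], []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1)
        f1s.append(f1)
        recs.append(rec)
    acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    return out, acc, float(np.mean(f1s)), float(np.mean(recs))


class TestConfusion:
    def test_perfect_prediction(self):
        t = confusion(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        np.testing.assert_array_equal(t.counts, [[2, 0], [0, 1]])
        assert aggregate(t).accuracy == 1.0

    def test_direct_counts(self):
        t = confusion(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        tp, fp, fn, tn = t.tp_fp_fn_tn("a")
        assert (tp, fp, fn) == (1, 0, 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            confusion(["a", "zzz"], ["a", "a"], ["a", "b"])
        with pytest.raises(ValueError):
            confusion(["a"], ["a", "b"], ["a", "b"])

    def test_random_case_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        classes = ["x", "y", "z"]
        y_true = [classes[i] for i in rng.integers(3, size=200)]
        y_pred = [classes[i] for i in rng.integers(3, size=200)]
        t = confusion(y_true, y_pred, classes)
        for i, a in enumerate(classes):
            for j, b in enumerate(classes):
                assert t.counts[i, j] == sum(
                    1 for tt, pp in zip(y_true, y_pred) if tt == a and pp == b
                )


class TestClassMetrics:
    def test_simple_case(self):
        t = confusion(["a", "a"], ["a", "b"], ["a", "b"])
        prec, rec, f1 = class_metrics(t, "a")
        assert (prec, rec) == (1.0, 0.5)
        assert f1 == pytest.approx(2 / 3)

    def test_degenerate_zero_convention(self):
        t = confusion(["b", "b"], ["b", "b"], ["a", "b"])
        assert class_metrics(t, "a") == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("x", [0.25, 0.5, 1.0])
    def test_f1_equals_x_when_precision_equals_recall(self, x):
        # harmonic mean identity checked through real confusion tables
        n = 8
        tp = int(n * x)
        y_true = ["a"] * n + ["b"] * n
        y_pred = ["a"] * tp + ["b"] * (n - tp) + ["b"] * tp + ["a"] * (n - tp)
        t = confusion(y_true, y_pred, ["a", "b"])
        prec, rec, f1 = class_metrics(t, "a")
        assert prec == rec == pytest.approx(x)
        assert f1 == pytest.approx(x)


class TestAggregate:
    def test_uf1_is_mean_of_class_f1(self):
        rng = np.random.default_rng(2)
        classes = ["a", "b", "c"]
        y_true = [classes[i] for i in rng.integers(3, size=120)]
        y_pred = [classes[i] for i in rng.integers(3, size=120)]
        rep = aggregate(confusion(y_true, y_pred, classes))
        f1s = [rep.per_class[c]["f1"] for c in classes]
        assert rep.uf1 == pytest.approx(np.mean(f1s), abs=1e-15)

    def test_oracle_equivalence_on_random_tables(self):
        """All metrics match brute-force recomputation to 1e-12 on 500 tables."""
        rng = np.random.default_rng(7)
        classes = ["a", "b", "c"]
        for _ in range(500):
            n = int(rng.integers(5, 60))
            y_true = [classes[i] for i in rng.integers(3, size=n)]
            y_pred = [classes[i] for i in rng.integers(3, size=n)]
            rep = aggregate(confusion(y_true, y_pred, classes))
            per, acc, uf1, uar = brute_force_metrics(y_true, y_pred, classes)
            assert abs(rep.accuracy - acc) < 1e-12
            assert abs(rep.uf1 - uf1) < 1e-12
            assert abs(rep.uar - uar) < 1e-12
            for c in classes:
                assert abs(rep.per_class[c]["precision"] - per[c][0]) < 1e-12
                assert abs(rep.per_class[c]["recall"] - per[c][1]) < 1e-12
                assert abs(rep.per_class[c]["f1"] - per[c][2]) < 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import accuracy_score, f1_score, recall_score

        rng = np.random.default_rng(5)
        classes = ["a", "b", "c"]
        y_true = [classes[i] for i in rng.integers(3, size=150)]
        y_pred = [classes[i] for i in rng.integers(3, size=150)]
        rep = aggregate(confusion(y_true, y_pred, classes))
        assert rep.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert rep.uf1 == pytest.approx(f1_score(y_true, y_pred, average="macro", zero_division=0))
        assert rep.uar == pytest.approx(recall_score(y_true, y_pred, average="macro", zero_division=0))
        assert rep.weighted_f1 == pytest.approx(
            f1_score(y_true, y_pred, average="weighted", zero_division=0)
        )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        classes = ["a", "b", "c"]
        y_true = [classes[i] for i in rng.integers(3, size=90)]
        y_pred = [classes[i] for i in rng.integers(3, size=90)]
        rep = aggregate(confusion(y_true, y_pred, classes))
        perm = {"a": "c", "b": "a", "c": "b"}
        rep2 = aggregate(
            confusion([perm[t] for t in y_true], [perm[p] for p in y_pred], classes)
        )
        assert rep2.uf1 == pytest.approx(rep.uf1)
        assert rep2.uar == pytest.approx(rep.uar)
        assert rep2.accuracy == pytest.approx(rep.accuracy)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate(confusion([], [], ["a", "b"]))


def random_manifest(rng, n_subjects, min_samples=2, max_samples=8):
    rows = []
    for s in range(n_subjects):
        for i in range(int(rng.integers(min_samples, max_samples + 1))):
            rows.append(
                {"sample_id": f"s{s}_{i}", "subject_id": f"subj{s}", "label": "x", "dataset": "synthetic"}
            )
    return pd.DataFrame(rows)


class TestLosoFolds:
    def test_each_subject_held_out_once(self, rng):
        m = random_manifest(rng, 3)
        spec = loso_folds(m)
        assert [f[0] for f in spec.folds] == sorted(m["subject_id"].unique())

    def test_partition_and_disjointness(self, rng):
        """Set-algebra oracle on a random 20-subject manifest."""
        m = random_manifest(rng, 20)
        spec = loso_folds(m)
        all_ids = set(m["sample_id"])
        test_sets = [set(t) for _, _, t in spec.folds]
        assert set().union(*test_sets) == all_ids
        for i in range(len(test_sets)):
            for j in range(i + 1, len(test_sets)):
                assert not test_sets[i] & test_sets[j]
        subj = m.set_index("sample_id")["subject_id"]
        for held, train_ids, test_ids in spec.folds:
            assert not set(train_ids) & set(test_ids)
            assert {subj[t] for t in test_ids} == {held}
            assert held not in {subj[t] for t in train_ids}

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            loso_folds(random_manifest(rng, 1))


class TestMapTo3Class:
    @pytest.mark.parametrize(
        "label,dataset,expected",
        [
            ("disgust", "casme2", "negative"),
            ("happiness", "casme2", "positive"),
            ("repression", "casme2", "negative"),
            ("surprise", "samm", "surprise"),
            ("anger", "samm", "negative"),
            ("contempt", "samm", "negative"),
            ("fear", "samm", "negative"),
            ("sadness", "samm", "negative"),
            ("happiness", "samm", "positive"),
            ("negative", "smic", "negative"),
            ("positive", "smic", "positive"),
            ("surprise", "smic", "surprise"),
        ],
    )
    def test_mapping(self, label, dataset, expected):
        assert map_to_3class(label, dataset) == expected

    def test_unmappable_label_raises(self):
        with pytest.raises(ValueError, match="others"):
            map_to_3class("others", "casme2")
        with pytest.raises(ValueError):
            map_to_3class("negative", "unknown_ds")


class TestEvaluateLoso:
    def _manifest(self, rng, n_subjects=5, per=6):
        rows = []
        classes = ["negative", "positive", "surprise"]
        for s in range(n_subjects):
            for i in range(per):
                rows.append(
                    {
                        "sample_id": f"s{s}_{i}",
                        "subject_id": f"subj{s}",
                        "label": classes[i % 3],
                        "dataset": "synthetic",
                    }
                )
        return pd.DataFrame(rows)

    def test_perfect_trainer_scores_one(self, rng):
        m = self._manifest(rng)

        def perfect(train_rows, test_rows, seed):
            return test_rows["label"].tolist()

        folds, pooled, failures = evaluate_loso(perfect, m, ["negative", "positive", "surprise"])
        assert pooled.accuracy == 1.0 and pooled.uf1 == 1.0 and pooled.uar == 1.0
        assert not failures

    def test_majority_trainer_on_balanced_data(self, rng):
        m = self._manifest(rng)

        def majority(train_rows, test_rows, seed):
            top = train_rows["label"].mode()[0]
            return [top] * len(test_rows)

        _, pooled, _ = evaluate_loso(majority, m, ["negative", "positive", "surprise"])
        assert pooled.accuracy == pytest.approx(1 / 3, abs=1e-9)
        assert pooled.uar == pytest.approx(1 / 3, abs=1e-9)

    def test_determinism_and_failure_recording(self, rng):
        m = self._manifest(rng)
        calls = []

        def flaky(train_rows, test_rows, seed):
            calls.append(seed)
            if test_rows["subject_id"].iloc[0] == "subj2":
                raise RuntimeError("boom")
            rstate = np.random.default_rng(seed)
            classes = ["negative", "positive", "surprise"]
            return [classes[i] for i in rstate.integers(3, size=len(test_rows))]

        f1, p1, fail1 = evaluate_loso(flaky, m, ["negative", "positive", "surprise"], seed=4)
        calls.clear()
        f2, p2, fail2 = evaluate_loso(flaky, m, ["negative", "positive", "surprise"], seed=4)
        assert fail1 == fail2 == ["subj2"]
        assert p1.as_dict() == p2.as_dict()

    def test_pooled_accuracy_is_weighted_mean_of_folds(self, rng):
        m = random_manifest(rng, 6)
        m["label"] = [["a", "b"][i % 2] for i in range(len(m))]

        def noisy(train_rows, test_rows, seed):
            r = np.random.default_rng(seed)
            return [["a", "b"][i] for i in r.integers(2, size=len(test_rows))]

        folds, pooled, _ = evaluate_loso(noisy, m, ["a", "b"], seed=0)
        weighted = sum(f.accuracy * f.n_samples for f in folds) / sum(f.n_samples for f in folds)
        assert pooled.accuracy == pytest.approx(weighted, abs=1e-12)
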