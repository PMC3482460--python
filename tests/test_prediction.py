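"""Classifier training, cross-validated metrics, AUC and multi-label scoring."""

import warnings

import numpy as np
import pytest

from mcfp import (
    AlphabetMismatchError,
    LabeledFingerprintSet,
    MonomerAlphabet,
    PeptideRecord,
    cross_validate,
    evaluate_multilabel,
    predict,
    roc_auc,
    train_classifier,
)
from mcfp.fingerprint import MCFP


def labeled_set(vectors, labels, alphabet):
    fps = [
        MCFP({i: c for i, c in enumerate(v) if c}, alphabet) for v in vectors
    ]
    return LabeledFingerprintSet(fps, list(labels), [f"P{i}" for i in range(len(fps))])


def separable_set(n_per_class=12, seed=0):
    """Two classes with disjoint monomer supports: trivially separable."""
    rng = np.random.default_rng(seed)
    alpha = MonomerAlphabet.from_codes(list("ABCDEF"))
    vectors, labels = [], []
    for _ in range(n_per_class):
        vectors.append([rng.integers(1, 4), rng.integers(0, 3), 0, 0, 0, 0])
        labels.append("x")
        vectors.append([0, 0, 0, rng.integers(1, 4), rng.integers(0, 3), 0])
        labels.append("y")
    return labeled_set(vectors, labels, alpha), alpha


class TestTrainPredict:
    @pytest.mark.parametrize("kind", ["naive_bayes", "linear"])
    def test_separable_classes_fit_perfectly(self, kind):
        data, _ = separable_set()
        model = train_classifier(data, kind)
        correct = sum(
            predict(model, fp)[0] == label
            for fp, label in zip(data.fps, data.labels)
        )
        assert correct == len(data)

    def test_naive_bayes_matches_hand_posterior(self):
        """2 classes, 2 monomers, Laplace smoothing: P(m1|x) = 3/4 etc., so
        a single-m1 test peptide has posterior 0.75 for class x."""
        alpha = MonomerAlphabet.from_codes(["m1", "m2"])
        data = labeled_set([[2, 0], [0, 2]], ["x", "y"], alpha)
        model = train_classifier(data, "naive_bayes")
        label, scores = predict(model, MCFP({0: 1}, alpha))
        assert label == "x"
        assert scores["x"] == pytest.approx(0.75, abs=1e-9)
        assert scores["y"] == pytest.approx(0.25, abs=1e-9)

    def test_identical_fingerprints_tie_break_to_first_label(self):
        alpha = MonomerAlphabet.from_codes(["m1"])
        data = labeled_set([[1], [1]], ["zeta", "alpha"], alpha)
        model = train_classifier(data, "naive_bayes")
        label, scores = predict(model, MCFP({0: 1}, alpha))
        assert scores["alpha"] == pytest.approx(scores["zeta"])
        assert label == "alpha"

    def test_single_class_rejected(self):
        alpha = MonomerAlphabet.from_codes(["m1"])
        data = labeled_set([[1], [2]], ["x", "x"], alpha)
        with pytest.raises(ValueError):
            train_classifier(data)

    def test_alphabet_mismatch_rejected(self):
        data, _ = separable_set()
        model = train_classifier(data)
        other = MonomerAlphabet.from_codes(["q", "r"])
        with pytest.raises(AlphabetMismatchError):
            predict(model, MCFP({0: 1}, other))

    def test_gaussian_event_model_available(self):
        data, _ = separable_set()
        model = train_classifier(
            data, "naive_bayes", {"event_model": "gaussian"}
        )
        assert predict(model, data.fps[0])[0] == data.labels[0]

    def test_multilabel_records_rejected_in_labeled_set(self):
        alpha = MonomerAlphabet.from_codes(["A"])
        rec = PeptideRecord("P1", "", frozenset({"a", "b"}), ("A",))
        with pytest.raises(ValueError, match="single-activity"):
            LabeledFingerprintSet.from_records([rec], alpha)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_reversed_scores(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [True, True, False, False]) == 0.0

    def test_tied_toy_set_matches_pair_counting(self):
        """6 scores with ties; brute-force over all pos-neg pairs with 1/2
        credit for ties."""
        scores = [0.5, 0.5, 0.3, 0.5, 0.3, 0.1]
        pos = [True, True, True, False, False, False]
        expected = 0.0
        pairs = 0
        for sp, fp in zip(scores, pos):
            if not fp:
                continue
            for sn, fn in zip(scores, pos):
                if fn:
                    continue
                pairs += 1
                expected += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert roc_auc(scores, pos) == pytest.approx(expected / pairs, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [False, False])

    def test_random_sets_match_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 60))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            pos = rng.random(n) < 0.5
            if pos.all() or not pos.any():
                continue
            num = pairs = 0.0
            for sp in scores[pos]:
                for sn in scores[~pos]:
                    pairs += 1
                    num += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            assert roc_auc(scores, pos) == pytest.approx(num / pairs, abs=1e-12)


class TestCrossValidate:
    def _five_class_set(self, seed=0):
        from mcfp import default_config, filter_dataset, fingerprint_records, generate_dataset

        records = generate_dataset(
            default_config(scale=0.15, enrichment=8.0,
                           multi_activity_fraction=0.0, seed=seed)
        )
        kept, _ = filter_dataset(records, min_class_size=3)
        fps, alpha = fingerprint_records(kept)
        return LabeledFingerprintSet.from_records(kept, alpha)

    def test_separable_multiclass_is_diagonal(self):
        data = self._five_class_set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            result = cross_validate(data, "naive_bayes", n_folds=5, seed=0)
        assert result.accuracy >= 0.95
        cells = result.confusion.cells
        assert np.trace(cells) >= 0.95 * cells.sum()

    def test_metric_identities(self):
        """F = 2PR/(P+R); accuracy = trace/total; recall = diagonal/row sum."""
        data = self._five_class_set(seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            result = cross_validate(data, "linear", n_folds=5, seed=2)
        cells = result.confusion.cells
        labels = result.confusion.labels
        assert result.accuracy == pytest.approx(np.trace(cells) / cells.sum())
        for i, label in enumerate(labels):
            m = result.per_class[label]
            if m.precision + m.recall > 0:
                assert m.f_measure == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall)
                )
            if cells[i].sum():
                assert m.recall == pytest.approx(cells[i, i] / cells[i].sum())

    def test_row_sums_are_class_sizes_for_any_kind(self):
        data = self._five_class_set(seed=1)
        sums = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for kind in ("naive_bayes", "linear"):
                result = cross_validate(data, kind, n_folds=5, seed=1)
                sums[kind] = result.confusion.cells.sum(axis=1).tolist()
        expected = [data.labels.count(c) for c in data.classes]
        assert sums["naive_bayes"] == sums["linear"] == expected

    def test_same_seed_identical_metrics(self):
        data = self._five_class_set(seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            r1 = cross_validate(data, "naive_bayes", n_folds=5, seed=9)
            r2 = cross_validate(data, "naive_bayes", n_folds=5, seed=9)
        assert r1.to_dict() == r2.to_dict()

    def test_shuffled_labels_give_chance_auc(self):
        """Permutation null: shuffling labels drives per-class AUC to ~0.5
        (averaged over repetitions)."""
        data = self._five_class_set(seed=4)
        rng = np.random.default_rng(0)
        aucs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for _ in range(10):
                labels = list(rng.permutation(data.labels))
                shuffled = LabeledFingerprintSet(data.fps, labels, data.ids)
                res = cross_validate(shuffled, "naive_bayes", n_folds=5,
                                     seed=int(rng.integers(2**31)))
                aucs.extend(m.auc for m in res.per_class.values())
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1

    def test_bad_fold_counts_rejected(self):
        data = self._five_class_set()
        with pytest.raises(ValueError):
            cross_validate(data, n_folds=1)
        with pytest.raises(ValueError):
            cross_validate(data, n_folds=len(data) + 1)

    def test_small_class_triggers_stratification_warning(self):
        data = self._five_class_set()
        with pytest.warns(UserWarning, match="stratification"):
            cross_validate(data, "naive_bayes", n_folds=10, seed=0)


class TestEvaluateMultilabel:
    def _model(self):
        alpha = MonomerAlphabet.from_codes(["a1", "a2", "t1", "t2", "s1"])
        vectors = [
            [2, 1, 0, 0, 0], [1, 2, 0, 0, 0], [2, 2, 0, 0, 0],
            [0, 0, 2, 1, 0], [0, 0, 1, 2, 0], [0, 0, 2, 2, 0],
            [0, 0, 0, 0, 3], [1, 0, 0, 0, 2], [0, 0, 0, 1, 3],
        ]
        labels = ["antibiotic"] * 3 + ["toxin"] * 3 + ["siderophore"] * 3
        data = labeled_set(vectors, labels, alpha)
        return train_classifier(data, "naive_bayes"), alpha

    def test_prediction_correct_iff_in_known_set(self):
        """Hand-built 10-record multi-label fixture scored by enumeration."""
        model, alpha = self._model()
        comps = {
            "antibiotic": ("a1", "a1", "a2"),
            "toxin": ("t1", "t2", "t2"),
            "siderophore": ("s1", "s1"),
        }
        eval_records = []
        expected_flags = []
        known_sets = [
            ("antibiotic", {"antibiotic", "toxin"}),
            ("antibiotic", {"antibiotic"}),
            ("antibiotic", {"toxin"}),
            ("antibiotic", {"siderophore", "toxin"}),
            ("toxin", {"antibiotic", "toxin"}),
            ("toxin", {"toxin"}),
            ("toxin", {"siderophore"}),
            ("siderophore", {"siderophore", "antibiotic"}),
            ("siderophore", {"antibiotic"}),
            ("siderophore", {"siderophore"}),
        ]
        for i, (true_kind, known) in enumerate(known_sets):
            rec = PeptideRecord(
                f"E{i:02d}", "", frozenset(known), comps[true_kind]
            )
            eval_records.append(rec)
            expected_flags.append(true_kind in known)
        result = evaluate_multilabel(model, eval_records)
        assert [row["correct"] for row in result.rows] == expected_flags
        assert result.percent_correct == pytest.approx(
            100.0 * sum(expected_flags) / len(expected_flags)
        )

    def test_known_pair_predicted_member_counts_correct(self):
        model, _ = self._model()
        rec = PeptideRecord(
            "E1", "", frozenset({"antibiotic", "toxin"}), ("a1", "a1", "a2")
        )
        result = evaluate_multilabel(model, [rec])
        assert result.rows[0]["predicted"] == "antibiotic"
        assert result.rows[0]["correct"]
        assert result.percent_correct == 100.0

    def test_unknown_monomers_ignored_at_prediction(self):
        model, _ = self._model()
        rec = PeptideRecord(
            "E2", "", frozenset({"toxin"}), ("t1", "t2", "NewMonomer")
        )
        result = evaluate_multilabel(model, [rec])
        assert result.rows[0]["predicted"] == "toxin"
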