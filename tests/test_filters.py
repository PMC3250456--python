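"""Sentence classifier, context overlap, and cohesion filter tests."""

from __future__ import annotations

import pytest

from storyline.corpus import Document
from storyline.filters import (
    CONTEXT,
    RESULT,
    GazetteerRecognizer,
    SentenceClassifierModel,
    SentenceRecord,
    TrainingError,
    annotate_entities,
    classify_sentence,
    cohesion_filter,
    context_overlap_filter,
    load_labeled_sentences,
    save_labeled_sentences,
    train_classifier,
)
from storyline.synthetic import SynthesisParams, generate_labeled_sentences


def _rec(pos, n, text, label=None):
    return SentenceRecord("d", pos, n, text, label)


class TestTraining:
    def test_priors_from_class_counts(self):
        labeled = (
            [_rec(0, 10, "early text", CONTEXT)] * 449
            + [_rec(9, 10, "late text", RESULT)] * 565
        )
        model = train_classifier(labeled)
        assert model.prior[CONTEXT] == pytest.approx(449 / 1014)
        assert model.prior[RESULT] == pytest.approx(565 / 1014)

    def test_pure_context_bin_approaches_one_without_smoothing(self):
        labeled = (
            [_rec(0, 10, "a", CONTEXT)] * 50 + [_rec(9, 10, "b", RESULT)] * 50
        )
        model = train_classifier(labeled, alpha=1e-9)
        assert model.bin_likelihood[0][CONTEXT] == pytest.approx(1.0, abs=1e-6)

    def test_unseen_phrase_is_uninformative(self):
        labeled = [_rec(0, 4, "a", CONTEXT), _rec(3, 4, "b", RESULT)]
        model = train_classifier(labeled, phrase_lexicon=("observed",))
        assert model.phrase_likelihood["observed"][CONTEXT] == 0.5
        assert model.phrase_likelihood["observed"][RESULT] == 0.5

    def test_single_class_training_is_error(self):
        with pytest.raises(TrainingError):
            train_classifier([_rec(0, 4, "a", CONTEXT)])

    def test_dft_invariants(self):
        r = _rec(0, 7, "first")
        assert r.dft == 0.0 and r.bin == 0
        assert _rec(6, 7, "last").bin == 8


class TestClassification:
    @pytest.fixture(scope="class")
    @staticmethod
    def model():
        labeled = generate_labeled_sentences(SynthesisParams(rng_seed=13))
        return train_classifier(labeled)

    def test_first_sentence_with_context_phrase_is_context(self, model):
        s = _rec(0, 8, "We investigated the signaling cascade.")
        assert classify_sentence(model, s) == CONTEXT

    def test_last_bin_sentence_with_result_phrase_is_result(self, model):
        s = _rec(7, 8, "A strong decrease was observed in all samples.")
        assert classify_sentence(model, s) == RESULT

    def test_exact_posterior_tie_goes_to_context(self):
        model = SentenceClassifierModel(
            prior={CONTEXT: 0.5, RESULT: 0.5},
            bin_likelihood=[{CONTEXT: 0.5, RESULT: 0.5}] * 10,
            phrase_likelihood={},
            phrase_lexicon=(),
        )
        assert classify_sentence(model, _rec(2, 5, "anything")) == CONTEXT

    def test_cross_validated_accuracy_on_generative_data(self):
        """10-fold CV accuracy >= 90% on sentences drawn from the
        classifier's own generative assumptions."""
        from sklearn.model_selection import KFold

        data = generate_labeled_sentences(SynthesisParams(rng_seed=42))
        correct = 0
        for train_idx, test_idx in KFold(n_splits=10).split(data):
            model = train_classifier([data[i] for i in train_idx])
            for i in test_idx:
                if classify_sentence(model, data[i]) == data[i].label:
                    correct += 1
        assert correct / len(data) >= 0.90


def _doc(doc_id, sentences, mesh=("M",)):
    return Document(doc_id, f"title {doc_id}", list(sentences), list(mesh), [])


class TestContextOverlap:
    def test_hand_computed_jaccard(self):
        d1 = _doc("a", ["alphaq betaq gammaq here.", "resultq text."])
        d2 = _doc("b", ["betaq gammaq deltaq here.", "other resultq."])
        labels = {"a": [CONTEXT, RESULT], "b": [CONTEXT, RESULT]}
        ok, scores = context_overlap_filter([d1, d2], labels, j_min=0.4)
        # {alphaq, betaq, gammaq} vs {betaq, gammaq, deltaq} -> 2/4 = 0.5
        assert scores == [pytest.approx(0.5)]
        assert ok

    def test_identical_context_sets_score_one(self):
        d1 = _doc("a", ["alphaq betaq."])
        d2 = _doc("b", ["alphaq betaq."])
        labels = {"a": [CONTEXT], "b": [CONTEXT]}
        _, scores = context_overlap_filter([d1, d2], labels, 0.05)
        assert scores == [pytest.approx(1.0)]

    def test_document_without_context_sentences_scores_zero(self):
        d1 = _doc("a", ["alphaq betaq."])
        d2 = _doc("b", ["alphaq betaq."])
        labels = {"a": [CONTEXT], "b": [RESULT]}
        ok, scores = context_overlap_filter([d1, d2], labels, 0.05)
        assert scores == [0.0]
        assert not ok

    def test_raising_j_min_never_adds_survivors(self):
        d1 = _doc("a", ["alphaq betaq gammaq here.", "x."])
        d2 = _doc("b", ["betaq gammaq deltaq here.", "y."])
        labels = {"a": [CONTEXT, RESULT], "b": [CONTEXT, RESULT]}
        passes = [
            context_overlap_filter([d1, d2], labels, j)[0]
            for j in (0.1, 0.3, 0.5, 0.7)
        ]
        # once it fails it stays failed
        assert passes == sorted(passes, reverse=True)

    def test_idempotent(self):
        d1 = _doc("a", ["alphaq betaq."])
        d2 = _doc("b", ["alphaq gammaq."])
        labels = {"a": [CONTEXT], "b": [CONTEXT]}
        first = context_overlap_filter([d1, d2], labels, 0.05)
        second = context_overlap_filter([d1, d2], labels, 0.05)
        assert first == second


class TestEntityRecognition:
    def test_gazetteer_hits(self):
        rec = GazetteerRecognizer(["PARP", "NF-kappaB"])
        assert rec("PARP inhibits NF-kappaB") == {"PARP", "NF-kappaB"}

    def test_no_hit_gives_empty_set(self):
        rec = GazetteerRecognizer(["PARP"])
        assert rec("nothing relevant") == set()

    def test_longest_match_wins(self):
        rec = GazetteerRecognizer(["pyruvate kinase", "kinase"])
        assert rec("regulation of pyruvate kinase activity") == {"pyruvate kinase"}
        assert rec("a kinase cascade") == {"kinase"}

    def test_case_insensitive_and_word_bounded(self):
        rec = GazetteerRecognizer(["parp"])
        assert rec("PARP1-independent; PARP was cleaved") == {"parp"}
        assert rec("parpx") == set()

    def test_empty_gazetteer_is_error(self):
        with pytest.raises(ValueError):
            GazetteerRecognizer([])

    def test_annotate_all_sentences(self):
        docs = [_doc("a", ["PARP here.", "nothing."])]
        ann = annotate_entities(docs, GazetteerRecognizer(["PARP"]))
        assert ann.entities("a", 0) == {"PARP"}
        assert ann.entities("a", 1) == set()


class TestCohesionFilter:
    def test_single_edge_path_and_jaccard(self):
        d1 = _doc("a", ["X binds stuff."])
        d2 = _doc("b", ["X and Y interact."])
        ann = annotate_entities([d1, d2], GazetteerRecognizer(["X", "Y"]))
        ok, path, score = cohesion_filter([d1, d2], ann)
        assert ok
        assert path == [("a", 0), ("b", 0)]
        assert score == pytest.approx(0.5)  # |{X}| / |{X, Y}|

    def test_no_shared_entity_fails(self):
        d1 = _doc("a", ["X binds stuff."])
        d2 = _doc("b", ["Y acts alone."])
        ann = annotate_entities([d1, d2], GazetteerRecognizer(["X", "Y"]))
        ok, path, _ = cohesion_filter([d1, d2], ann)
        assert not ok and path is None

    def test_tied_paths_prefer_earliest_positions(self):
        d1 = _doc("a", ["X early.", "X late."])
        d2 = _doc("b", ["X again.", "X more."])
        ann = annotate_entities([d1, d2], GazetteerRecognizer(["X"]))
        ok, path, _ = cohesion_filter([d1, d2], ann)
        assert ok and path == [("a", 0), ("b", 0)]

    def test_best_scoring_path_chosen(self):
        # sentence 1 of each doc shares two entities (Jaccard 1), sentence 0
        # only one of three
        d1 = _doc("a", ["X with Z here.", "X and Y combine."])
        d2 = _doc("b", ["Z alone maybe.", "X and Y again."])
        ann = annotate_entities([d1, d2], GazetteerRecognizer(["X", "Y", "Z"]))
        ok, path, score = cohesion_filter([d1, d2], ann)
        assert ok
        assert path == [("a", 1), ("b", 1)]
        assert score == pytest.approx(1.0)

    def test_removing_gazetteer_entries_never_adds_survivors(self):
        d1 = _doc("a", ["X binds."])
        d2 = _doc("b", ["X acts."])
        full = annotate_entities([d1, d2], GazetteerRecognizer(["X"]))
        assert cohesion_filter([d1, d2], full)[0]
        reduced = annotate_entities([d1, d2], GazetteerRecognizer(["Q"]))
        assert not cohesion_filter([d1, d2], reduced)[0]


class TestLabeledSentenceIO:
    def test_tsv_roundtrip(self, tmp_path):
        records = generate_labeled_sentences(SynthesisParams(), n_docs=5)
        path = str(tmp_path / "train.tsv")
        save_labeled_sentences(path, records)
        back = load_labeled_sentences(path)
        assert back == records
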