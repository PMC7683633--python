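"""Position features, role classification, event assembly."""

import numpy as np
import pytest

from eventbtm import roles, synthetic
from eventbtm.corpus_io import sentence_from_text
from eventbtm.roles import (
    RoleClassifier,
    RoleConfig,
    WordVectorTable,
    assemble_events,
    lexical_features,
    make_training_examples,
    position_distances,
    read_events,
    write_events,
)
from eventbtm.schema import (
    ArgumentCategory,
    MetaEventType,
    NONE_ROLE,
    Span,
    TriggerCategory,
    validate_event,
)


class TestPositionDistances:
    def test_worked_example_distances(self, example_sentence):
        _, spans = example_sentence
        d_pft, d_pfa = position_distances(
            spans["target"], spans["trigger"], spans["arg1"])
        assert (d_pft, d_pfa) == (5, 7)

    def test_self_distance_zero(self, example_sentence):
        _, spans = example_sentence
        d_pft, _ = position_distances(
            spans["trigger"], spans["trigger"], spans["arg1"])
        assert d_pft == 0

    def test_unit_offset(self):
        assert position_distances(Span(3, 3), Span(2, 2), Span(0, 0)) == (1, 3)

    def test_overlap_gives_zero_not_error(self):
        assert position_distances(Span(1, 3), Span(2, 5), Span(0, 0))[0] == 0


class TestLexicalFeatures:
    def test_worked_example_null_slots(self, example_sentence, word_vectors):
        """Trigger and argument adjacent, argument sentence-initial: E_1tf,
        E_2tf, E_2tb are NULL; E_1tb is the vector of 'the'."""
        sent, spans = example_sentence
        wv = WordVectorTable.random([t.surface.lower() for t in sent.tokens],
                                    8, seed=2)
        v = lexical_features(sent, spans["trigger"], spans["arg1"], 1, wv)
        d = 8
        E_1tf, E_1tb = v[2 * d: 3 * d], v[3 * d: 4 * d]
        E_2tf, E_2tb = v[4 * d: 5 * d], v[5 * d: 6 * d]
        assert not E_1tf.any() and not E_2tf.any() and not E_2tb.any()
        np.testing.assert_array_equal(E_1tb, wv.vec("the"))
        assert v[-1] == 1.0

    def test_generic_case_has_no_null_slots(self):
        sent = sentence_from_text("alpha beta gamma delta epsilon zeta")
        wv = WordVectorTable.random(sent.surfaces, 4, seed=3)
        v = lexical_features(sent, Span(1, 1), Span(4, 4), 2, wv)
        d = 4
        for i in range(6):
            assert v[i * d: (i + 1) * d].any()

    def test_dimension_is_six_dw_plus_one(self, example_sentence):
        sent, spans = example_sentence
        wv = WordVectorTable.random(["task"], 100, seed=1)
        v = lexical_features(sent, spans["trigger"], spans["arg1"], 0, wv)
        assert v.shape == (601,)


@pytest.fixture(scope="module")
def classifier(word_vectors, role_table):
    return RoleClassifier(word_vectors, role_table, RoleConfig(seed=11))


class TestSentenceFeatures:
    def test_tanh_range(self, classifier):
        sent = sentence_from_text("patient completed delayed memory task now")
        v = classifier.sentence_features(sent, Span(1, 1), Span(2, 4))
        assert np.all(np.abs(v) < 1.0)

    def test_deterministic(self, classifier):
        sent = sentence_from_text("patient completed delayed memory task now")
        a = classifier.sentence_features(sent, Span(1, 1), Span(2, 4))
        b = classifier.sentence_features(sent, Span(1, 1), Span(2, 4))
        np.testing.assert_array_equal(a, b)

    def test_short_sentence_padded(self, classifier):
        sent = sentence_from_text("ok")
        v = classifier.sentence_features(sent, Span(0, 0), Span(0, 0))
        assert v.shape == (classifier.config.hidden,)

    def test_max_pool_sensitive_to_token_content(self, role_table):
        a = sentence_from_text("patient completed reading task quietly today")
        b = sentence_from_text("patient completed reading task clustering today")
        wv = WordVectorTable.random(sorted(set(a.surfaces) | set(b.surfaces)),
                                    100, seed=6)
        clf = RoleClassifier(wv, role_table, RoleConfig(seed=6))
        va = clf.sentence_features(a, Span(1, 1), Span(2, 3))
        vb = clf.sentence_features(b, Span(1, 1), Span(2, 3))
        assert not np.array_equal(va, vb)


class TestClassifier:
    def test_probabilities_sum_to_one(self, classifier):
        sent = sentence_from_text("patient completed delayed memory task")
        p = classifier.classify(sent, Span(1, 1), Span(2, 4), 3)
        assert p.shape == (classifier.n_classes,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p >= 0)

    def test_role_conditioned_predictions_renormalised(self, classifier):
        sent = sentence_from_text("patient completed delayed memory task")
        preds = classifier.predict_roles(
            sent, Span(1, 1), Span(2, 4), MetaEventType.PerformCognitiveTask)
        total = sum(p.probability for p in preds)
        assert total == pytest.approx(1.0, abs=1e-9)
        # candidates: none + the meta-event's two roles
        assert len(preds) == 3

    def test_training_reaches_high_role_accuracy(self, small_bundle, word_vectors,
                                                 role_table):
        clf = RoleClassifier(word_vectors, role_table,
                             RoleConfig(seed=11, epochs=8))
        examples, eval_pairs = [], []
        for doc in small_bundle.corpus.documents:
            for sent in doc.sentences:
                evs = [e for e in small_bundle.events_by_doc[doc.id]
                       if e.sentence_id == sent.id]
                pairs = []
                for ev in evs:
                    cat = TriggerCategory[ev.meta_event.name]
                    for a in ev.arguments:
                        pairs.append((ev.trigger, cat, a.span))
                        eval_pairs.append(
                            (sent, ev.trigger, a.span, ev.meta_event, a.role.index))
                examples.extend(make_training_examples(sent, evs, pairs, role_table))
        clf.train(examples[:400])
        hits = sum(
            clf.predict_roles(s, t, a, m)[0].role.index == gold
            for s, t, a, m, gold in eval_pairs[:80]
        )
        assert hits / 80 > 0.9

    def test_training_deterministic_per_seed(self, small_bundle, word_vectors,
                                             role_table):
        sent = small_bundle.all_sentences()[0]
        evs = small_bundle.events_by_doc["doc0000"][:1]
        cat = TriggerCategory[evs[0].meta_event.name]
        pairs = [(evs[0].trigger, cat, a.span) for a in evs[0].arguments]
        examples = make_training_examples(sent, evs, pairs, role_table)
        histories = []
        for _ in range(2):
            clf = RoleClassifier(word_vectors, role_table,
                                 RoleConfig(seed=4, epochs=3))
            histories.append(clf.train(examples))
        assert histories[0] == histories[1]


class TestAssembleEvents:
    def _predict_fixed(self, role, prob=0.9):
        def predict(sentence, trigger, argument, meta):
            return [roles.RolePrediction(role, prob),
                    roles.RolePrediction(NONE_ROLE, 1 - prob)]
        return predict

    def test_deduce_result_event_assembled(self, role_table, example_sentence):
        sent, spans = example_sentence
        research_object = role_table.slots(MetaEventType.DeduceResult)[0].role
        events = assemble_events(
            sent,
            [(spans["trigger"], TriggerCategory.DeduceResult)],
            [(spans["arg1"], ArgumentCategory.ExperimentalTask)],
            self._predict_fixed(research_object),
            role_table,
        )
        assert len(events) == 1
        ev = events[0]
        assert ev.meta_event is MetaEventType.DeduceResult
        assert len(ev.arguments) == 1
        assert ev.arguments[0].role == research_object
        assert validate_event(ev, role_table) == []

    def test_trigger_without_arguments_kept(self, role_table, example_sentence):
        sent, spans = example_sentence
        events = assemble_events(
            sent, [(spans["trigger"], TriggerCategory.DeduceResult)], [],
            self._predict_fixed(NONE_ROLE), role_table)
        assert len(events) == 1 and events[0].arguments == []

    def test_inadmissible_category_dropped(self, role_table, example_sentence):
        sent, spans = example_sentence
        research_object = role_table.slots(MetaEventType.DeduceResult)[0].role
        events = assemble_events(
            sent,
            [(spans["trigger"], TriggerCategory.DeduceResult)],
            [(spans["arg2"], ArgumentCategory.ExperimentalMeasurement)],
            self._predict_fixed(research_object),
            role_table,
        )
        assert events[0].arguments == []

    def test_assembled_events_always_validate(self, role_table, example_sentence):
        sent, spans = example_sentence
        research_object = role_table.slots(MetaEventType.DeduceResult)[0].role
        # two arguments competing for the same 0..1 role: best kept, other dropped
        events = assemble_events(
            sent,
            [(spans["trigger"], TriggerCategory.DeduceResult)],
            [(spans["arg1"], ArgumentCategory.ExperimentalTask),
             (Span(4, 5, "BOLD responses"), ArgumentCategory.CognitiveFunction)],
            self._predict_fixed(research_object),
            role_table,
        )
        assert len(events[0].arguments) == 1
        assert validate_event(events[0], role_table) == []


class TestEventRecords:
    def test_round_trip(self, role_table, example_sentence, tmp_path):
        sent, spans = example_sentence
        research_object = role_table.slots(MetaEventType.DeduceResult)[0].role
        events = assemble_events(
            sent, [(spans["trigger"], TriggerCategory.DeduceResult)],
            [(spans["arg1"], ArgumentCategory.ExperimentalTask)],
            TestAssembleEvents()._predict_fixed(research_object),
            role_table, sentence_id=3, document_id="doc7")
        p = tmp_path / "events.tsv"
        write_events(events, p)
        back = read_events(p, role_table)
        assert len(back) == 1
        assert back[0].document_id == "doc7"
        assert back[0].trigger == events[0].trigger
        assert back[0].arguments[0].role == research_object


class TestSerialization:
    def test_save_load_identical_scores(self, classifier, word_vectors,
                                        role_table, tmp_path):
        sent = sentence_from_text("patient completed delayed memory task")
        classifier.save(tmp_path / "roles.npz")
        back = RoleClassifier.load(tmp_path / "roles.npz", word_vectors, role_table)
        a = classifier.classify(sent, Span(1, 1), Span(2, 4), 2)
        b = back.classify(sent, Span(1, 1), Span(2, 4), 2)
        np.testing.assert_array_equal(a, b)
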