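"""Event canonicalisation, biterms, and the collapsed Gibbs sampler."""

import itertools

import numpy as np
import pytest
from oracles import exact_posterior

from eventbtm import btm
from eventbtm.btm import (
    BitermSet,
    build_biterms,
    biterm_probability,
    canonicalize_event,
    corpus_log_likelihood,
    gibbs_fit,
    infer_document_topics,
    read_model,
    top_events,
    write_model,
)
from eventbtm.schema import (
    ArgumentCategory,
    EventArgument,
    EventMention,
    MetaEventType,
    Span,
)


def _deduce_event(role_table, trigger="reveals", args=(("task difficulty", 0),
                                                      ("BOLD responses", 1))):
    slots = role_table.slots(MetaEventType.DeduceResult)
    cats = [ArgumentCategory.ExperimentalTask, ArgumentCategory.GrossBrainAnatomy]
    return EventMention(
        MetaEventType.DeduceResult, Span(2, 2, trigger),
        [EventArgument(Span(0, 1, text), cats[i], slots[i].role)
         for text, i in args],
    )


class TestCanonicalization:
    def test_stemmed_sorted_key(self, role_table):
        ev = _deduce_event(role_table)
        assert canonicalize_event(ev) == \
            "DeduceResult|reveal|bold_respons+task_difficulti"

    def test_position_independent(self, role_table):
        a = _deduce_event(role_table)
        b = _deduce_event(role_table)
        b.sentence_id, b.document_id = 9, "other"
        assert canonicalize_event(a) == canonicalize_event(b)

    def test_meta_event_enters_key(self, role_table):
        a = _deduce_event(role_table)
        b = _deduce_event(role_table)
        b.meta_event = MetaEventType.AnalyzeData
        assert canonicalize_event(a, "type+trigger") != \
            canonicalize_event(b, "type+trigger")

    def test_granularities_nest(self, role_table):
        ev = _deduce_event(role_table)
        assert canonicalize_event(ev, "type") == "DeduceResult"
        assert canonicalize_event(ev, "type+trigger") == "DeduceResult|reveal"


def _events(role_table, triggers):
    return [_deduce_event(role_table, trigger=t, args=()) for t in triggers]


class TestBuildBiterms:
    def test_all_pairs_within_document(self, role_table):
        bset = build_biterms({"d": _events(role_table, ["finds", "shows", "proves"])})
        assert len(bset) == 3
        assert sorted(bset.biterms) == [(0, 1), (0, 2), (1, 2)]

    def test_single_event_document_contributes_nothing(self, role_table):
        bset = build_biterms({
            "a": _events(role_table, ["finds"]),
            "b": _events(role_table, ["finds", "shows"]),
        })
        assert len(bset) == 1 and bset.by_document["a"] == []

    def test_multiset_semantics_across_documents(self, role_table):
        bset = build_biterms({
            "a": _events(role_table, ["finds", "shows"]),
            "b": _events(role_table, ["finds", "shows"]),
        })
        assert bset.biterms == [(0, 1), (0, 1)]

    def test_self_pair_when_mentions_share_key(self, role_table):
        bset = build_biterms({"a": _events(role_table, ["finds", "finds"])})
        assert bset.biterms == [(0, 0)]

    def test_zero_biterms_is_an_error(self, role_table):
        with pytest.raises(ValueError, match="no biterms"):
            build_biterms({"a": _events(role_table, ["finds"])})

    def test_sliding_window_subsets_full_pairs(self, role_table):
        events = _events(role_table, ["a", "b", "c", "d"])
        full = build_biterms({"d": events})
        windowed = build_biterms({"d": events}, window=2)
        assert set(windowed.biterms) <= set(full.biterms)
        assert len(windowed) == 3  # consecutive pairs only


def _bset(pairs, W):
    return BitermSet([f"e{i}" for i in range(W)], list(pairs),
                     ["d"] * len(pairs), {"d": list(pairs)})


class TestGibbsSampler:
    def test_single_topic_closed_form(self):
        pairs = [(0, 1), (0, 2), (1, 2), (0, 0)]
        bset = _bset(pairs, 3)
        st = gibbs_fit(bset, K=1, alpha=1.0, beta=0.5, iterations=4, burn_in=2,
                       seed=0)
        np.testing.assert_allclose(st.theta, [1.0])
        counts = np.zeros(3)
        for i, j in pairs:
            counts[i] += 1
            counts[j] += 1
        expected = (counts + 0.5) / (counts.sum() + 3 * 0.5)
        np.testing.assert_allclose(st.phi[0], expected, atol=1e-12)

    def test_marginals_match_enumeration_oracle(self):
        """Collapsed Gibbs against brute-force enumeration on a tiny
        instance, including the co-assignment structure (which, unlike the
        singleton marginals, is not fixed by label symmetry)."""
        pairs = [(0, 1), (0, 2), (1, 2), (0, 0)]
        W, K, alpha, beta = 3, 2, 1.0, 0.5
        marg, co = exact_posterior(pairs, W, K, alpha, beta)
        st = gibbs_fit(_bset(pairs, W), K, alpha, beta, iterations=3500,
                       burn_in=500, seed=11, keep_samples=True)
        n = st.samples.shape[0]
        se = np.sqrt(np.maximum(marg * (1 - marg), 1e-4) / n)
        # autocorrelated chain: inflate the nominal MC standard error
        assert np.all(np.abs(st.assignment_marginals - marg) < 5 * 3 * se)
        co_hat = np.zeros_like(co)
        for b in range(len(pairs)):
            for c in range(len(pairs)):
                co_hat[b, c] = np.mean(st.samples[:, b] == st.samples[:, c])
        se_co = np.sqrt(np.maximum(co * (1 - co), 1e-4) / n)
        assert np.all(np.abs(co_hat - co) < 5 * 3 * se_co)

    def test_same_seed_identical_fit(self):
        bset = _bset([(0, 1), (1, 2), (0, 2)], 3)
        a = gibbs_fit(bset, 2, 1.0, 0.1, iterations=40, burn_in=20, seed=3)
        b = gibbs_fit(bset, 2, 1.0, 0.1, iterations=40, burn_in=20, seed=3)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_invalid_hyperparameters_rejected(self):
        bset = _bset([(0, 1)], 2)
        with pytest.raises(ValueError):
            gibbs_fit(bset, 0)
        with pytest.raises(ValueError):
            gibbs_fit(bset, 2, alpha=-1.0)
        with pytest.raises(ValueError):
            gibbs_fit(bset, 2, iterations=10, burn_in=10)

    def test_simplex_invariants_across_seeds_and_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            W = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 8))
            K = int(rng.integers(1, 4))
            pairs = [tuple(sorted(rng.integers(0, W, 2))) for _ in range(n_b)]
            st = gibbs_fit(_bset(pairs, W), K,
                           alpha=float(rng.uniform(0.1, 5)),
                           beta=float(rng.uniform(0.01, 1)),
                           iterations=12, burn_in=6,
                           seed=int(rng.integers(1 << 30)))
            assert st.theta.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(st.theta >= 0)
            np.testing.assert_allclose(st.phi.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(st.phi >= 0)


def _hand_state():
    """theta=(0.6,0.4); phi rows from the worked joint-probability example."""
    W = 2
    return btm.TopicModelState(
        K=2, alpha=1.0, beta=0.1, vocabulary=["e1", "e2"],
        z=np.zeros(0, dtype=int), n_k=np.zeros(2), n_ek=np.zeros((2, W)),
        theta=np.array([0.6, 0.4]),
        phi=np.array([[0.5, 0.5], [0.9, 0.1]]),
        seed=0, iterations=1, burn_in=0,
        assignment_marginals=np.zeros((0, 2)),
    )


class TestBitermProbability:
    def test_hand_computed_mixture(self):
        st = _hand_state()
        assert biterm_probability(st, (0, 1)) == pytest.approx(0.186)

    def test_uniform_single_topic(self):
        st = _hand_state()
        st.theta = np.array([1.0, 0.0])
        assert biterm_probability(st, (0, 0)) == pytest.approx(0.25)

    def test_normalises_over_ordered_pairs(self):
        st = _hand_state()
        total = sum(biterm_probability(st, (i, j)) for i in range(2) for j in range(2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_unknown_event_id_rejected(self):
        with pytest.raises(KeyError):
            biterm_probability(_hand_state(), (0, 5))


class TestLikelihoodAndInference:
    def test_single_biterm_likelihood(self):
        st = _hand_state()
        assert corpus_log_likelihood(st, [(0, 1)]) == \
            pytest.approx(np.log(0.186))

    def test_duplicate_biterm_doubles_contribution(self):
        st = _hand_state()
        one = corpus_log_likelihood(st, [(0, 1)])
        two = corpus_log_likelihood(st, [(0, 1), (0, 1)])
        assert two == pytest.approx(2 * one)

    def test_single_biterm_document_equals_posterior(self):
        st = _hand_state()
        dist = infer_document_topics(st, [(0, 1)])
        joint = st.theta * st.phi[:, 0] * st.phi[:, 1]
        np.testing.assert_allclose(dist, joint / joint.sum())

    def test_document_distribution_is_simplex(self):
        st = _hand_state()
        dist = infer_document_topics(st, [(0, 1), (0, 0), (1, 1)])
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dist >= 0)

    def test_empty_document_rejected(self):
        with pytest.raises(ValueError, match="no biterms"):
            infer_document_topics(_hand_state(), [])


class TestTopEvents:
    def test_rank_one_is_argmax(self):
        st = _hand_state()
        [(key, prob, terms)] = top_events(st, 1, 1)
        assert key == "e1" and prob == pytest.approx(0.9)

    def test_probabilities_non_increasing(self):
        st = _hand_state()
        out = top_events(st, 0, 2)
        assert out[0][1] >= out[1][1]

    def test_overlong_request_truncated(self):
        st = _hand_state()
        assert len(top_events(st, 0, 10)) == 2

    def test_event_keys_expand_to_terms(self, role_table):
        bset = build_biterms({"d": [
            _deduce_event(role_table), _deduce_event(role_table, trigger="finds"),
        ]})
        st = gibbs_fit(bset, 1, iterations=4, burn_in=2, seed=0)
        key, _, terms = top_events(st, 0, 1)[0]
        assert "DeduceResult" in terms
        assert "bold_respons" in terms and "task_difficulti" in terms


class TestParameterRecovery:
    def test_two_planted_topics_recovered(self):
        """End-to-end: planted disjoint topics over gold events are
        recovered by the sampler up to label switching."""
        from eventbtm import synthetic

        bundle = synthetic.generate(synthetic.GeneratorConfig(n_docs=80, seed=21))
        bset = build_biterms(bundle.events_by_doc)
        st = gibbs_fit(bset, 2, iterations=200, burn_in=100, seed=21)
        key2id = {k: i for i, k in enumerate(bset.vocabulary)}
        true_phi = np.zeros((2, bset.n_events))
        for s, key in enumerate(bundle.species_keys):
            if key in key2id:
                true_phi[:, key2id[key]] = bundle.true_phi[:, s]
        true_phi /= true_phi.sum(axis=1, keepdims=True)
        best = max(
            itertools.permutations(range(2)),
            key=lambda perm: sum(
                float(true_phi[k] @ st.phi[perm[k]])
                / (np.linalg.norm(true_phi[k]) * np.linalg.norm(st.phi[perm[k]]))
                for k in range(2)
            ),
        )
        cos = np.mean([
            float(true_phi[k] @ st.phi[best[k]])
            / (np.linalg.norm(true_phi[k]) * np.linalg.norm(st.phi[best[k]]))
            for k in range(2)
        ])
        assert cos > 0.9


class TestModelDump:
    def test_round_trip(self, tmp_path):
        st = _hand_state()
        p = tmp_path / "model.txt"
        write_model(st, p)
        back = read_model(p)
        assert back.K == 2 and back.vocabulary == ["e1", "e2"]
        np.testing.assert_array_equal(back.theta, st.theta)
        np.testing.assert_array_equal(back.phi, st.phi)
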