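"""Topic evaluation: document co-occurrence coherence and pairwise KL.

Coherence scores a topic's ranked unit list by summing, over ranked pairs
(v_i ranked above v_j), log((D(v_i, v_j) + eps) / D(v_j)) where D counts
*documents* containing the unit(s) — the UMass convention.  Higher is more
coherent (units that co-occur in the corpus score near 0; units that never
co-occur score increasingly negative).

Topic distinctness is the mean Kullback-Leibler divergence
KL(p||q) = sum_x p(x) log(p(x) / q(x)) over all ordered pairs of topic
distributions on a shared support, with tiny additive smoothing of q to
keep the sum finite.  KL is non-negative by Gibbs' inequality; the
implementation enforces this.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from eventbtm.corpus_io import Corpus
from eventbtm.stemming import porter_stem


class CorpusStats:
    """Document-frequency counts over stems, computed once per corpus."""

    def __init__(self, corpus: Corpus):
        self._doc_stems: list[frozenset[str]] = []
        for doc in corpus.documents:
            stems = {
                t.stem for sent in doc.sentences for t in sent.tokens
            }
            self._doc_stems.append(frozenset(stems))
        self.n_documents = len(self._doc_stems)

    @staticmethod
    def _normalise(unit: str) -> list[frozenset[str]]:
        # a unit may be a multi-word term; each word counts as present when
        # the document contains its stem, or the word itself when the word
        # is already a stem (stemming is not idempotent)
        return [
            frozenset({w.lower(), porter_stem(w)})
            for w in unit.replace("_", " ").split()
        ]

    def doc_frequency(self, *units: str) -> int:
        """D(v) or D(v_i, v_j): documents containing every given unit."""
        needed = [alts for u in units for alts in self._normalise(u)]
        return sum(
            1 for stems in self._doc_stems
            if all(alts & stems for alts in needed)
        )


def doc_frequency(corpus: Corpus, *units: str) -> int:
    return CorpusStats(corpus).doc_frequency(*units)


def topic_coherence(units: Sequence[str], stats: CorpusStats, eps: float = 1.0) -> float:
    """Sum of log((D(v_i, v_j) + eps) / D(v_j)) over ranked pairs i > j.

    ``units`` must be ranked most-probable first.  A single-unit topic has
    no pairs and scores 0.  D(v_j) = 0 for a needed denominator is an
    error naming the unit.
    """
    score = 0.0
    for a in range(1, len(units)):
        for b in range(a):
            # units[b] ranks above units[a]; denominator is the lower-ranked
            d_j = stats.doc_frequency(units[a])
            if d_j == 0:
                raise ValueError(
                    f"unit {units[a]!r} appears in no document; "
                    "coherence denominator undefined"
                )
            d_ij = stats.doc_frequency(units[b], units[a])
            score += float(np.log((d_ij + eps) / d_j))
    return score


def kl_divergence(p: Sequence[float], q: Sequence[float],
                  smoothing: float = 1e-12) -> float:
    """KL(p||q) with additive smoothing of q (then renormalised); natural
    log; the 0 * log(0/q) terms contribute 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"distributions differ in length: {p.shape} vs {q.shape}")
    q = q + smoothing
    q = q / q.sum()
    mask = p > 0
    val = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    return max(val, 0.0)


def mean_pairwise_kl(topics: Sequence[Sequence[float]],
                     smoothing: float = 1e-12) -> float:
    """Mean of KL(p||q) over all ordered pairs of distinct topics."""
    K = len(topics)
    if K < 2:
        raise ValueError("mean pairwise KL needs at least 2 topics")
    total = 0.0
    for a in range(K):
        for b in range(K):
            if a != b:
                total += kl_divergence(topics[a], topics[b], smoothing)
    return total / (K * (K - 1))


def evaluation_report(rows: Sequence[tuple[str, str, float]]) -> str:
    """Tab-separated (model, metric, value) table."""
    return "\n".join(f"{m}\t{metric}\t{v:.5f}" for m, metric, v in rows) + "\n"
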