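"""The event biterm topic model (Event-BTM).

Short, sparse event sequences per paper make document-level topic mixtures
hard to estimate, so the model follows the biterm formulation: every
unordered pair of events co-occurring in one document (a *biterm*) is
generated by first drawing a topic z from a single corpus-level topic
distribution theta ~ Dir(alpha) and then drawing both events independently
from the per-topic event distribution phi_z ~ Dir(beta).

Events are discretised into vocabulary units by ``canonicalize_event``
(meta-event type + stemmed trigger + sorted stemmed argument phrases); the
distributed event vectors are kept only for reporting and similarity, not
for inference.

Fitting integrates theta and phi out and runs collapsed Gibbs sampling over
the per-biterm topic assignments with the exact conditional

    P(z_b = k | z_-b, B) ∝ (n_k + alpha)
        * (n_{i|k} + beta) (n_{j|k} + beta + [i = j])
        / ((n_{.|k} + W beta) (n_{.|k} + 1 + W beta)),

where n_k counts biterms on topic k and n_{e|k} event occurrences (each
biterm contributes two).  Point estimates use post-burn-in averaged counts:
theta_k = (n_k + alpha) / (|B| + K alpha) and
phi_{e|k} = (n_{e|k} + beta) / (n_{.|k} + W beta).

Per-document topic distributions mix the posterior over biterm topics with
the document's empirical biterm frequencies:
P(z|d) = sum_b p(z|b) p(b|d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from eventbtm.corpus_io import tokenize
from eventbtm.schema import EventMention
from eventbtm.stemming import porter_stem

logger = logging.getLogger(__name__)

KEY_SEPARATOR = "|"


def _stem_phrase(text: str) -> str:
    return "_".join(porter_stem(t) for t in tokenize(text) if t.isalnum())


def canonicalize_event(event: EventMention, granularity: str = "full") -> str:
    """Deterministic vocabulary key for an event mention.

    ``full`` keys are meta-event | stemmed trigger | sorted stemmed argument
    phrases joined by '+'; ``type+trigger`` drops the arguments and ``type``
    keeps only the meta-event name.  Sentence/document provenance never
    enters the key, so repeated mentions collapse onto one unit.
    """
    if granularity not in {"type", "type+trigger", "full"}:
        raise ValueError(f"unknown granularity {granularity!r}")
    parts = [event.meta_event.value]
    if granularity in {"type+trigger", "full"}:
        parts.append(_stem_phrase(event.trigger.text))
    if granularity == "full":
        args = sorted(_stem_phrase(a.span.text) for a in event.arguments)
        parts.append("+".join(args))
    return KEY_SEPARATOR.join(parts)


@dataclass
class BitermSet:
    """The corpus-level biterm pool B plus per-document biterm lists.

    Biterms are stored as canonically ordered vocabulary-id pairs (i <= j);
    the same pair from two documents appears twice (multiset semantics).
    """

    vocabulary: list[str]
    biterms: list[tuple[int, int]]
    doc_ids: list[str]
    by_document: dict[str, list[tuple[int, int]]]

    @property
    def n_events(self) -> int:
        return len(self.vocabulary)

    def __len__(self) -> int:
        return len(self.biterms)


def build_biterms(
    events_by_doc: dict[str, Sequence[EventMention]] | Iterable[tuple[str, Sequence[EventMention]]],
    window: int | None = None,
    granularity: str = "full",
) -> BitermSet:
    """All unordered event pairs per document (or per sliding window of
    ``window`` consecutive events for very long documents)."""
    items = list(events_by_doc.items()) if isinstance(events_by_doc, dict) else list(events_by_doc)
    vocab_index: dict[str, int] = {}
    vocabulary: list[str] = []
    biterms: list[tuple[int, int]] = []
    doc_ids: list[str] = []
    by_document: dict[str, list[tuple[int, int]]] = {}
    for doc_id, events in items:
        ids = []
        for ev in events:
            key = canonicalize_event(ev, granularity)
            if key not in vocab_index:
                vocab_index[key] = len(vocabulary)
                vocabulary.append(key)
            ids.append(vocab_index[key])
        if len(ids) < 2:
            logger.warning("document %s has %d event(s); contributes no biterms",
                           doc_id, len(ids))
            by_document.setdefault(doc_id, [])
            continue
        pairs: list[tuple[int, int]] = []
        if window is None or window >= len(ids):
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    pairs.append((min(ids[a], ids[b]), max(ids[a], ids[b])))
        else:
            seen = set()
            for start in range(len(ids) - window + 1):
                chunk = ids[start : start + window]
                for a in range(len(chunk)):
                    for b in range(a + 1, len(chunk)):
                        key = (start + a, start + b)
                        if key not in seen:
                            seen.add(key)
                            pairs.append((min(chunk[a], chunk[b]), max(chunk[a], chunk[b])))
        by_document.setdefault(doc_id, []).extend(pairs)
        biterms.extend(pairs)
        doc_ids.extend([doc_id] * len(pairs))
    if not biterms:
        raise ValueError("no biterms in the corpus; the model is undefined")
    return BitermSet(vocabulary, biterms, doc_ids, by_document)


@dataclass
class TopicModelState:
    """A fitted Event-BTM: hyperparameters, assignments, counts, estimates."""

    K: int
    alpha: float
    beta: float
    vocabulary: list[str]
    z: np.ndarray                    # final topic assignment per biterm
    n_k: np.ndarray                  # averaged biterm counts per topic
    n_ek: np.ndarray                 # averaged event counts per topic (K, W)
    theta: np.ndarray                # topic distribution of B
    phi: np.ndarray                  # per-topic event distributions (K, W)
    seed: int
    iterations: int
    burn_in: int
    assignment_marginals: np.ndarray  # (|B|, K) post-burn-in frequencies
    samples: np.ndarray | None = None  # optional thinned z snapshots
    biterms: list[tuple[int, int]] = field(default_factory=list)

    def event_id(self, key: str) -> int:
        try:
            return self.vocabulary.index(key)
        except ValueError:
            raise KeyError(f"unknown event key {key!r}") from None


def gibbs_fit(
    bset: BitermSet,
    K: int,
    alpha: float | None = None,
    beta: float = 0.01,
    iterations: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
    keep_samples: bool = False,
    thin: int = 1,
) -> TopicModelState:
    """Collapsed Gibbs sampling over per-biterm topic assignments."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    n_b = len(bset)
    W = bset.n_events
    if K > n_b:
        logger.warning("K=%d exceeds |B|=%d; the model is degenerate", K, n_b)
    pairs = np.asarray(bset.biterms, dtype=np.int64)
    rng = np.random.default_rng(seed)

    z = rng.integers(0, K, size=n_b)
    n_k = np.zeros(K)
    n_ek = np.zeros((K, W))
    for b in range(n_b):
        i, j = pairs[b]
        n_k[z[b]] += 1
        n_ek[z[b], i] += 1
        n_ek[z[b], j] += 1

    marg = np.zeros((n_b, K))
    sum_nk = np.zeros(K)
    sum_nek = np.zeros((K, W))
    snapshots: list[np.ndarray] = []
    n_kept = 0
    wb = W * beta

    for it in range(iterations):
        for b in range(n_b):
            i, j = pairs[b]
            k_old = z[b]
            n_k[k_old] -= 1
            n_ek[k_old, i] -= 1
            n_ek[k_old, j] -= 1
            tot = n_ek.sum(axis=1)
            same = 1.0 if i == j else 0.0
            p = (n_k + alpha) * (n_ek[:, i] + beta) * (n_ek[:, j] + beta + same) \
                / ((tot + wb) * (tot + 1.0 + wb))
            p /= p.sum()
            k_new = int(rng.choice(K, p=p))
            z[b] = k_new
            n_k[k_new] += 1
            n_ek[k_new, i] += 1
            n_ek[k_new, j] += 1
        if it >= burn_in:
            n_kept += 1
            sum_nk += n_k
            sum_nek += n_ek
            marg[np.arange(n_b), z] += 1
            if keep_samples and (it - burn_in) % thin == 0:
                snapshots.append(z.copy())

    mean_nk = sum_nk / n_kept
    mean_nek = sum_nek / n_kept
    theta = (mean_nk + alpha) / (n_b + K * alpha)
    phi = (mean_nek + beta) / (mean_nek.sum(axis=1, keepdims=True) + wb)
    return TopicModelState(
        K=K, alpha=alpha, beta=beta, vocabulary=list(bset.vocabulary),
        z=z.copy(), n_k=mean_nk, n_ek=mean_nek, theta=theta, phi=phi,
        seed=seed, iterations=iterations, burn_in=burn_in,
        assignment_marginals=marg / n_kept,
        samples=np.asarray(snapshots) if keep_samples else None,
        biterms=list(bset.biterms),
    )


def biterm_probability(state: TopicModelState, biterm: tuple[int, int]) -> float:
    """Marginal ordered-pair probability P(b) = sum_z theta_z phi_i|z phi_j|z."""
    i, j = biterm
    W = len(state.vocabulary)
    if not (0 <= i < W and 0 <= j < W):
        raise KeyError(f"event id out of range in biterm {biterm}")
    return float(np.sum(state.theta * state.phi[:, i] * state.phi[:, j]))


def corpus_log_likelihood(state: TopicModelState,
                          biterms: Sequence[tuple[int, int]]) -> float:
    """Log-likelihood of a biterm multiset: sum_b log P(b)."""
    return float(sum(np.log(biterm_probability(state, b)) for b in biterms))


def infer_document_topics(state: TopicModelState,
                          doc_biterms: Sequence[tuple[int, int]]) -> np.ndarray:
    """P(z|d) = sum_b p(z|b) p(b|d) with empirical biterm frequencies."""
    if not doc_biterms:
        raise ValueError("document has no biterms; its topic distribution is undefined")
    out = np.zeros(state.K)
    for i, j in doc_biterms:
        joint = state.theta * state.phi[:, i] * state.phi[:, j]
        out += joint / joint.sum()
    return out / len(doc_biterms)


def top_events(state: TopicModelState, k: int, n: int) -> list[tuple[str, float, list[str]]]:
    """The n most probable event units of topic k with their constituent
    terms (ties broken lexicographically on the key)."""
    W = len(state.vocabulary)
    if not 0 <= k < state.K:
        raise ValueError(f"topic {k} out of range for K={state.K}")
    if n > W:
        logger.warning("requested %d events but vocabulary has %d", n, W)
        n = W
    order = sorted(range(W), key=lambda e: (-state.phi[k, e], state.vocabulary[e]))
    out = []
    for e in order[:n]:
        key = state.vocabulary[e]
        terms = [t for part in key.split(KEY_SEPARATOR) for t in part.split("+") if t]
        out.append((key, float(state.phi[k, e]), terms))
    return out


# -- model dump -------------------------------------------------------------


def write_model(state: TopicModelState, path: str | Path) -> None:
    lines = [
        f"K\t{state.K}",
        f"alpha\t{state.alpha!r}",
        f"beta\t{state.beta!r}",
        f"seed\t{state.seed}",
        f"iterations\t{state.iterations}",
        f"burn_in\t{state.burn_in}",
        "vocabulary\t" + "\t".join(state.vocabulary),
        "theta\t" + "\t".join(repr(float(x)) for x in state.theta),
    ]
    for k in range(state.K):
        lines.append(f"phi_{k}\t" + "\t".join(repr(float(x)) for x in state.phi[k]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_model(path: str | Path) -> TopicModelState:
    fields: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.split("\t")
        fields[parts[0]] = parts[1:]
    K = int(fields["K"][0])
    vocab = fields["vocabulary"]
    theta = np.asarray([float(x) for x in fields["theta"]])
    phi = np.asarray([[float(x) for x in fields[f"phi_{k}"]] for k in range(K)])
    W = len(vocab)
    return TopicModelState(
        K=K, alpha=float(fields["alpha"][0]), beta=float(fields["beta"][0]),
        vocabulary=vocab, z=np.zeros(0, dtype=int), n_k=np.zeros(K),
        n_ek=np.zeros((K, W)), theta=theta, phi=phi,
        seed=int(fields["seed"][0]), iterations=int(fields["iterations"][0]),
        burn_in=int(fields["burn_in"][0]),
        assignment_marginals=np.zeros((0, K)),
    )
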