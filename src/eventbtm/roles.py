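"""Argument-role classification and event assembly.

For every candidate trigger–argument pair inside one sentence the
classifier combines two feature blocks:

* a lexical-level vector: the word vectors of the trigger and the argument
  (multi-token spans are averaged), the words immediately before and after
  each of them, and the candidate role index ``r``.  A neighbour slot is
  the all-zero NULL vector when the position falls outside the sentence or
  inside the other span of the pair;
* a sentence-level vector: for each token, its word vector concatenated
  with two trainable distance embeddings (signed token offset to the
  trigger and to the argument, clipped to ±30), fed through a width-3
  convolution, max-pooled over positions, then a tanh hidden transform.

A softmax over the global role inventory (all role indices of the
event-role table plus a "none" class) scores the pair.  Because the
feature vector is conditioned on ``r``, inference evaluates the classifier
once per candidate role of the trigger's meta-event and renormalises the
per-role scores.

Assembled events keep, for each trigger, the arguments whose best role is
not "none" and whose category the event-role table admits; combinations
that would violate a cardinality are dropped with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from eventbtm import nn
from eventbtm.corpus_io import Sentence
from eventbtm.schema import (
    EventArgument,
    EventMention,
    EventRoleTable,
    NONE_ROLE,
    RoleType,
    Span,
    TriggerCategory,
    ArgumentCategory,
    validate_event,
)

logger = logging.getLogger(__name__)


class WordVectorTable:
    """Fixed word-vector lookup with zero-vector fallback for OOV words."""

    def __init__(self, table: dict[str, np.ndarray], dim: int | None = None):
        self.table = {w.lower(): np.asarray(v, dtype=float) for w, v in table.items()}
        if dim is None:
            if not self.table:
                raise ValueError("empty table needs an explicit dimension")
            dim = next(iter(self.table.values())).size
        self.dim = dim

    def vec(self, word: str) -> np.ndarray:
        return self.table.get(word.lower(), np.zeros(self.dim))

    def span_vec(self, sentence: Sentence, span: Span) -> np.ndarray:
        vecs = [self.vec(t.surface) for t in sentence.tokens[span.start : span.end + 1]]
        return np.mean(vecs, axis=0) if vecs else np.zeros(self.dim)

    @classmethod
    def random(cls, words: Sequence[str], dim: int, seed: int = 0,
               scale: float = 0.5) -> "WordVectorTable":
        rng = np.random.default_rng(seed)
        return cls({w: rng.uniform(-scale, scale, dim) for w in words}, dim)


def position_distances(target: Span, trigger: Span, argument: Span) -> tuple[int, int]:
    """Signed token offsets from the target span's first token to the
    trigger's and the argument's first tokens.  Overlapping spans give 0
    in the corresponding slot."""
    d_pft = 0 if target.overlaps(trigger) else target.start - trigger.start
    d_pfa = 0 if target.overlaps(argument) else target.start - argument.start
    return d_pft, d_pfa


def lexical_features(
    sentence: Sentence,
    trigger: Span,
    argument: Span,
    role_index: int,
    vectors: WordVectorTable,
) -> np.ndarray:
    """The lexical-level feature vector [E_1t, E_2t, E_1tf, E_1tb, E_2tf,
    E_2tb, r] of dimension 6 * d_w + 1."""
    n = len(sentence.tokens)

    def neighbour(pos: int, other: Span) -> np.ndarray:
        if pos < 0 or pos >= n:
            return np.zeros(vectors.dim)  # outside the sentence -> NULL
        if other.start <= pos <= other.end:
            return np.zeros(vectors.dim)  # inside the paired span -> NULL
        return vectors.vec(sentence.tokens[pos].surface)

    parts = [
        vectors.span_vec(sentence, trigger),          # E_1t
        vectors.span_vec(sentence, argument),         # E_2t
        neighbour(trigger.start - 1, argument),       # E_1tf
        neighbour(trigger.end + 1, argument),         # E_1tb
        neighbour(argument.start - 1, trigger),       # E_2tf
        neighbour(argument.end + 1, trigger),         # E_2tb
        np.array([float(role_index)]),                # r
    ]
    return np.concatenate(parts)


@dataclass
class RoleConfig:
    word_dim: int = 100
    pos_dim: int = 5
    pos_clip: int = 30
    conv_width: int = 3
    conv_out: int = 30
    hidden: int = 30
    lr: float = 1e-3
    clip_norm: float = 5.0
    epochs: int = 25
    seed: int = 0


@dataclass(frozen=True)
class RolePrediction:
    role: RoleType
    probability: float


class RoleClassifier:
    """Softmax role classifier over lexical + sentence-level CNN features."""

    def __init__(self, vectors: WordVectorTable, role_table: EventRoleTable,
                 config: RoleConfig | None = None):
        self.vectors = vectors
        self.role_table = role_table
        self.config = cfg = config or RoleConfig()
        if vectors.dim != cfg.word_dim:
            raise ValueError(
                f"word vectors have dimension {vectors.dim}, config says {cfg.word_dim}"
            )
        self.n_classes = max(r.index for r in role_table.roles()) + 1
        rng = np.random.default_rng(cfg.seed)
        n_pos = 2 * cfg.pos_clip + 1
        self.pos_trig = nn.Embedding(n_pos, cfg.pos_dim, rng, scale=0.5)
        self.pos_arg = nn.Embedding(n_pos, cfg.pos_dim, rng, scale=0.5)
        self.conv = nn.ConvMaxPool(cfg.word_dim + 2 * cfg.pos_dim, cfg.conv_width,
                                   cfg.conv_out, rng)
        self.hidden = nn.Dense(cfg.conv_out, cfg.hidden, rng)
        lf_dim = 6 * cfg.word_dim + 1
        self.out = nn.Dense(lf_dim + cfg.hidden, self.n_classes, rng)
        self.loss_history: list[float] = []

    def _layers(self) -> list[nn.Layer]:
        return [self.pos_trig, self.pos_arg, self.conv, self.hidden, self.out]

    def _pos_ids(self, sentence: Sentence, trigger: Span, argument: Span):
        clip = self.config.pos_clip
        ids_t, ids_a = [], []
        for i, _ in enumerate(sentence.tokens):
            tok = Span(i, i)
            d_pft, d_pfa = position_distances(tok, trigger, argument)
            ids_t.append(int(np.clip(d_pft, -clip, clip)) + clip)
            ids_a.append(int(np.clip(d_pfa, -clip, clip)) + clip)
        return ids_t, ids_a

    def sentence_features(self, sentence: Sentence, trigger: Span, argument: Span,
                          keep_cache: bool = False) -> np.ndarray:
        """V_sf = tanh(W2 . maxpool(conv(v_wp sequence))); coordinates in (-1, 1)."""
        ids_t, ids_a = self._pos_ids(sentence, trigger, argument)
        Vw = np.stack([self.vectors.vec(t.surface) for t in sentence.tokens]) \
            if sentence.tokens else np.zeros((0, self.config.word_dim))
        Pt = self.pos_trig.forward(ids_t)
        Pa = self.pos_arg.forward(ids_a)
        Vwp = np.concatenate([Vw, Pt, Pa], axis=1) if len(sentence.tokens) else \
            np.zeros((0, self.config.word_dim + 2 * self.config.pos_dim))
        pooled = self.conv.forward(Vwp)
        pre = self.hidden.forward(pooled)
        vsf = np.tanh(pre)
        if keep_cache:
            self._vsf_cache = (vsf, len(sentence.tokens))
        else:
            self.conv._cache.pop()
            self.hidden._x.pop()
            self.pos_trig._ids.pop()
            self.pos_arg._ids.pop()
        return vsf

    def _backward_sentence(self, d_vsf: np.ndarray) -> None:
        vsf, n_tokens = self._vsf_cache
        d_pre = d_vsf * (1.0 - vsf * vsf)
        d_pooled = self.hidden.backward(d_pre)
        d_vwp = self.conv.backward(d_pooled)
        if n_tokens:
            dw = self.config.word_dim
            pd = self.config.pos_dim
            self.pos_arg.backward(d_vwp[:, dw + pd :])
            self.pos_trig.backward(d_vwp[:, dw : dw + pd])
        else:
            self.pos_arg._ids.pop()
            self.pos_trig._ids.pop()

    def classify(self, sentence: Sentence, trigger: Span, argument: Span,
                 role_index: int, keep_cache: bool = False) -> np.ndarray:
        """Probability distribution over the global role inventory."""
        vlf = lexical_features(sentence, trigger, argument, role_index, self.vectors)
        vsf = self.sentence_features(sentence, trigger, argument, keep_cache)
        v = np.concatenate([vlf, vsf])
        logits = self.out.forward(v) if keep_cache else \
            v @ self.out.W.value + self.out.b.value
        if keep_cache:
            self._v_dim_lf = vlf.size
        return nn.softmax(logits)

    def predict_roles(self, sentence: Sentence, trigger: Span, argument: Span,
                      meta_event) -> list[RolePrediction]:
        """Role-conditioned inference: score each candidate role (plus the
        none class at r = 0) and renormalise."""
        slots = self.role_table.slots(meta_event)
        candidates = [NONE_ROLE] + [s.role for s in slots]
        scores = []
        for role in candidates:
            probs = self.classify(sentence, trigger, argument, role.index)
            scores.append(probs[role.index])
        scores = np.asarray(scores)
        total = scores.sum()
        scores = scores / total if total > 0 else np.full(len(scores), 1 / len(scores))
        preds = [RolePrediction(r, float(p)) for r, p in zip(candidates, scores)]
        return sorted(preds, key=lambda p: -p.probability)

    # -- training -----------------------------------------------------------

    def train(self, examples: Sequence[tuple[Sentence, Span, Span, int, int]],
              epochs: int | None = None) -> list[float]:
        """Cross-entropy training on (sentence, trigger, argument,
        feature-role-index r, target-class) tuples."""
        if not examples:
            raise ValueError("no role training examples")
        epochs = self.config.epochs if epochs is None else epochs
        params = [p for layer in self._layers() for p in layer.params()]
        opt = nn.Adam(params, lr=self.config.lr, clip_norm=self.config.clip_norm)
        rng = np.random.default_rng(self.config.seed + 1)
        for _ in range(epochs):
            order = rng.permutation(len(examples))
            total = 0.0
            for idx in order:
                sent, trig, arg, r, target = examples[idx]
                opt.zero_grad()
                probs = self.classify(sent, trig, arg, r, keep_cache=True)
                logp = np.log(np.maximum(probs, 1e-300))[None, :]
                loss, d_logits = nn.nll_loss_and_grad(logp, [target])
                d_v = self.out.backward(d_logits[0])
                self._backward_sentence(d_v[self._v_dim_lf :])
                opt.step()
                total += loss
            self.loss_history.append(total / len(examples))
        return self.loss_history


    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        import json

        arrays = {
            f"p{i}": p.value
            for i, p in enumerate(
                q for layer in self._layers() for q in layer.params()
            )
        }
        meta = {"config": asdict(self.config)}
        np.savez(Path(path),
                 __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path, vectors: WordVectorTable,
             role_table: EventRoleTable) -> "RoleClassifier":
        import json

        p = str(path)
        data = np.load(p if p.endswith(".npz") else p + ".npz")
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(vectors, role_table, RoleConfig(**meta["config"]))
        params = [q for layer in model._layers() for q in layer.params()]
        for i, q in enumerate(params):
            q.value[...] = data[f"p{i}"]
        return model


def write_events(events: Sequence[EventMention], path) -> None:
    """Tab-separated event records: document id, sentence id, meta-event,
    trigger span and text, then one 'start:end:CAT:role_index:prob' field
    per argument."""
    from pathlib import Path as _P

    lines = []
    for ev in events:
        args = ";".join(
            f"{a.span.start}:{a.span.end}:{a.category.abbreviation}:"
            f"{a.role.index}:{a.probability:.4f}|{a.span.text}"
            for a in ev.arguments
        )
        lines.append("\t".join([
            ev.document_id, str(ev.sentence_id), ev.meta_event.value,
            str(ev.trigger.start), str(ev.trigger.end), ev.trigger.text, args,
        ]))
    _P(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_events(path, role_table: EventRoleTable) -> list[EventMention]:
    from pathlib import Path as _P

    from eventbtm.schema import MetaEventType

    events = []
    for line in _P(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        doc_id, sent_id, meta, ts, te, ttext, args = line.split("\t")
        arguments = []
        if args:
            for rec in args.split(";"):
                head, text = rec.split("|", 1)
                s, e, cat, ridx, prob = head.split(":")
                arguments.append(EventArgument(
                    Span(int(s), int(e), text),
                    ArgumentCategory.from_abbreviation(cat),
                    role_table.role_by_index(int(ridx)),
                    float(prob),
                ))
        events.append(EventMention(
            MetaEventType(meta), Span(int(ts), int(te), ttext), arguments,
            int(sent_id), doc_id,
        ))
    return events


def make_training_examples(
    sentence: Sentence,
    gold_events: Sequence[EventMention],
    candidate_pairs: Sequence[tuple[Span, TriggerCategory, Span]],
    role_table: EventRoleTable,
) -> list[tuple[Sentence, Span, Span, int, int]]:
    """Role training tuples for one sentence.

    A gold pair yields a positive example conditioned on its gold role and
    one none-target example per wrong candidate role; a pair with no gold
    relation yields none-target examples for every candidate role.
    """
    gold: dict[tuple[int, int, int, int], int] = {}
    for ev in gold_events:
        for arg in ev.arguments:
            key = (ev.trigger.start, ev.trigger.end, arg.span.start, arg.span.end)
            gold[key] = arg.role.index
    examples = []
    for trig, cat, arg in candidate_pairs:
        slots = role_table.slots(cat.meta_event)
        key = (trig.start, trig.end, arg.start, arg.end)
        g = gold.get(key)
        for slot in slots:
            r = slot.role.index
            if g is not None and r == g:
                examples.append((sentence, trig, arg, r, g))
            else:
                examples.append((sentence, trig, arg, r, NONE_ROLE.index))
        examples.append((sentence, trig, arg, NONE_ROLE.index, NONE_ROLE.index
                         if g is None else g))
    return examples


def assemble_events(
    sentence: Sentence,
    triggers: Sequence[tuple[Span, TriggerCategory]],
    arguments: Sequence[tuple[Span, ArgumentCategory]],
    predict: Callable[[Sentence, Span, Span, object], list[RolePrediction]],
    role_table: EventRoleTable,
    sentence_id: int = 0,
    document_id: str = "",
) -> list[EventMention]:
    """Attach role-classified arguments to each trigger and validate.

    Arguments are attached best-probability first; one that would violate
    the role table (inadmissible category or exceeded cardinality) is
    dropped and logged.  Every returned event passes validation.
    """
    events = []
    for trig, cat in triggers:
        meta = cat.meta_event
        slots = {s.role.index: s for s in role_table.slots(meta)}
        scored: list[tuple[float, Span, ArgumentCategory, RolePrediction]] = []
        for arg_span, arg_cat in arguments:
            if arg_span.overlaps(trig):
                continue
            preds = predict(sentence, trig, arg_span, meta)
            best = preds[0]
            if best.role.index == NONE_ROLE.index:
                continue
            scored.append((best.probability, arg_span, arg_cat, best))
        event = EventMention(meta, trig, [], sentence_id, document_id)
        for prob, arg_span, arg_cat, pred in sorted(scored, key=lambda t: -t[0]):
            slot = slots.get(pred.role.index)
            if slot is None or arg_cat not in slot.categories:
                logger.info(
                    "dropped argument %r: category %s not admissible for role %r",
                    arg_span.text, arg_cat.abbreviation, pred.role.name,
                )
                continue
            candidate = EventArgument(arg_span, arg_cat, pred.role, prob)
            event.arguments.append(candidate)
            if validate_event(event, role_table):
                event.arguments.pop()
                logger.info(
                    "dropped argument %r: role %r already filled",
                    arg_span.text, pred.role.name,
                )
        assert not validate_event(event, role_table)
        events.append(event)
    return events
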