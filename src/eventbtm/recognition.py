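"""Event-element recognition: text vectorization and the BiLSTM-CNN tagger.

Each token is encoded as the concatenation of four parts, in this order:

1. a word embedding (pretrained table or seeded random fallback, with a
   shared trainable unknown vector),
2. a one-hot case vector over the categories numeric / allLower / allUpper /
   initialUpper / mainly_numeric / contains_digit / other (first match in
   that order),
3. a one-dimensional terminology-dictionary scalar: the 1-based index of
   the argument-category dictionary whose matched term covers the token,
   0 outside any match,
4. a character-level feature from a width-3 convolution with max pooling
   over 25-dimensional character embeddings initialised uniformly on
   [-0.5, 0.5].

A bidirectional LSTM reads the combined vectors; per-token log-softmax over
the BIO tag inventory (B-/I- for each of the nine trigger and nine argument
categories, plus O — 37 tags) scores triggers and arguments jointly.
Decoding takes the argmax tag per token, repairs illegal I- transitions,
and groups tokens into typed spans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from eventbtm import nn
from eventbtm.corpus_io import (
    Sentence,
    TermDictionary,
    bio_spans,
    repair_bio,
)
from eventbtm.schema import (
    DEFAULT_CATEGORY_PRIORITY,
    ArgumentCategory,
    Span,
    TriggerCategory,
)

CASE_CATEGORIES = (
    "numeric",
    "allLower",
    "allUpper",
    "initialUpper",
    "mainly_numeric",
    "contains_digit",
    "other",
)

TRIGGER_ABBRS = tuple(c.abbreviation for c in TriggerCategory)
ARGUMENT_ABBRS = tuple(c.abbreviation for c in ArgumentCategory)

#: the joint tag inventory: O + B/I per trigger and argument category
TAG_INVENTORY: tuple[str, ...] = ("O",) + tuple(
    f"{p}-{a}" for a in TRIGGER_ABBRS + ARGUMENT_ABBRS for p in ("B", "I")
)


def case_category(token: str) -> str:
    """Classify a token's capitalisation shape (first matching category)."""
    if not token:
        raise ValueError("empty token has no case category")
    n_digit = sum(ch.isdigit() for ch in token)
    if n_digit == len(token):
        return "numeric"
    if token.isalpha() and token.islower():
        return "allLower"
    if token.isalpha() and token.isupper():
        return "allUpper"
    if token[0].isupper() and token[1:].islower():
        return "initialUpper"
    if n_digit > len(token) / 2:
        return "mainly_numeric"
    if n_digit > 0:
        return "contains_digit"
    return "other"


def case_vector(token: str) -> np.ndarray:
    v = np.zeros(len(CASE_CATEGORIES))
    v[CASE_CATEGORIES.index(case_category(token))] = 1.0
    return v


def dict_scalars(
    sentence: Sentence,
    dictionaries: Sequence[TermDictionary],
    priority: Sequence[ArgumentCategory] = DEFAULT_CATEGORY_PRIORITY,
) -> np.ndarray:
    """Terminology-dictionary scalar per token: the dictionary index of the
    longest match covering the token, 0 for tokens outside any term."""
    rank = {cat: i for i, cat in enumerate(priority)}
    lowered = [t.surface.lower() for t in sentence.tokens]
    out = np.zeros(len(lowered), dtype=np.float64)
    i = 0
    while i < len(lowered):
        candidates = [
            (d.match_at(lowered, i), d.category) for d in dictionaries
        ]
        candidates = [(ln, c) for ln, c in candidates if ln > 0]
        if not candidates:
            i += 1
            continue
        best = max(ln for ln, _ in candidates)
        cat = min(
            (c for ln, c in candidates if ln == best),
            key=lambda c: rank.get(c, len(rank)),
        )
        out[i : i + best] = cat.dictionary_index
        i += best
    return out


@dataclass
class TaggerConfig:
    word_dim: int = 100
    char_dim: int = 25
    conv_width: int = 3
    char_out: int = 30
    hidden: int = 200          # per direction; h_i has 2 * hidden dims
    epochs: int = 50
    lr: float = 1e-3
    clip_norm: float = 5.0
    seed: int = 0

    @property
    def input_dim(self) -> int:
        return self.word_dim + len(CASE_CATEGORIES) + 1 + self.char_out


@dataclass
class RecognizedSpans:
    triggers: list[tuple[Span, TriggerCategory]] = field(default_factory=list)
    arguments: list[tuple[Span, ArgumentCategory]] = field(default_factory=list)


class Tagger:
    """Joint trigger/argument BIO tagger (BiLSTM over combined word vectors).

    One network covers trigger recognition, trigger typing and argument
    recognition through the shared 37-tag inventory; pass separate
    ``tags`` subsets to train dedicated trigger-only / argument-only
    taggers instead.
    """

    def __init__(
        self,
        word_vocab: dict[str, int],
        dictionaries: Sequence[TermDictionary] = (),
        config: TaggerConfig | None = None,
        pretrained: dict[str, np.ndarray] | None = None,
        tags: Sequence[str] = TAG_INVENTORY,
    ):
        self.config = config or TaggerConfig()
        self.tags = tuple(tags)
        unknown = set(self.tags) - set(TAG_INVENTORY)
        if unknown:
            raise ValueError(f"tags outside the schema inventory: {sorted(unknown)}")
        self.word_vocab = dict(word_vocab)  # word -> id >= 1; 0 is <unk>
        self.dictionaries = list(dictionaries)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.word_emb = nn.Embedding(len(self.word_vocab) + 1, cfg.word_dim, rng, scale=0.5)
        if pretrained:
            for w, idx in self.word_vocab.items():
                vec = pretrained.get(w)
                if vec is not None:
                    if vec.size != cfg.word_dim:
                        raise ValueError(
                            f"pretrained vector for {w!r} has dimension "
                            f"{vec.size}, expected {cfg.word_dim}"
                        )
                    self.word_emb.table.value[idx] = vec
        chars = sorted({ch for w in self.word_vocab for ch in w})
        self.char_vocab = {ch: i + 1 for i, ch in enumerate(chars)}  # 0 = unk
        self.char_emb = nn.Embedding(len(self.char_vocab) + 1, cfg.char_dim, rng, scale=0.5)
        self.char_cnn = nn.ConvMaxPool(cfg.char_dim, cfg.conv_width, cfg.char_out, rng)
        self.bilstm = nn.BiLSTM(cfg.input_dim, cfg.hidden, rng)
        self.out = nn.Dense(2 * cfg.hidden, len(self.tags), rng)
        self._rng = rng
        self.loss_history: list[float] = []

    # -- feature construction ----------------------------------------------

    def word_id(self, surface: str) -> int:
        return self.word_vocab.get(surface.lower(), 0)

    def char_features(self, token: str) -> np.ndarray:
        """Char-CNN feature for a single token (inference path)."""
        ids = [self.char_vocab.get(ch, 0) for ch in token]
        emb = self.char_emb.forward(ids if ids else [0])
        out = self.char_cnn.forward(emb)
        # inference only: discard the caches this created
        self.char_cnn._cache.pop()
        self.char_emb._ids.pop()
        return out

    def vectorize_sentence(self, sentence: Sentence) -> np.ndarray:
        """Combined word vectors, concatenated as (word, case, dict, char)."""
        X, _ = self._forward_features(sentence, keep_cache=False)
        return X

    def _forward_features(self, sentence: Sentence, keep_cache: bool = True):
        cfg = self.config
        n = len(sentence.tokens)
        if n == 0:
            return np.zeros((0, cfg.input_dim)), []
        word_ids = [self.word_id(t.surface) for t in sentence.tokens]
        Vw = self.word_emb.forward(word_ids)
        Vc = np.stack([case_vector(t.surface) for t in sentence.tokens])
        Vt = dict_scalars(sentence, self.dictionaries)[:, None]
        chars = []
        for t in sentence.tokens:
            ids = [self.char_vocab.get(ch, 0) for ch in t.surface] or [0]
            emb = self.char_emb.forward(ids)
            chars.append(self.char_cnn.forward(emb))
        Vchar = np.stack(chars)
        X = np.concatenate([Vw, Vc, Vt, Vchar], axis=1)
        if not keep_cache:
            for _ in range(n):
                self.char_cnn._cache.pop()
                self.char_emb._ids.pop()
            self.word_emb._ids.pop()
        return X, word_ids

    # -- forward / backward -------------------------------------------------

    def encode(self, sentence: Sentence) -> tuple[np.ndarray, np.ndarray]:
        """BiLSTM states h_i and per-token log-probabilities over the tags."""
        X, _ = self._forward_features(sentence, keep_cache=False)
        if X.shape[0] == 0:
            return np.zeros((0, 2 * self.config.hidden)), np.zeros((0, len(self.tags)))
        H = self.bilstm.forward(X)
        self._discard_bilstm_cache()
        logits = H @ self.out.W.value + self.out.b.value
        return H, nn.log_softmax(logits)

    def _discard_bilstm_cache(self) -> None:
        self.bilstm.fwd._cache.pop()
        self.bilstm.bwd._cache.pop()

    def _layers(self) -> list[nn.Layer]:
        return [self.word_emb, self.char_emb, self.char_cnn, self.bilstm, self.out]

    def _train_step(self, sentence: Sentence, targets: Sequence[int]) -> float:
        X, _ = self._forward_features(sentence, keep_cache=True)
        H = self.bilstm.forward(X)
        logits = self.out.forward(H)
        logp = nn.log_softmax(logits)
        loss, d_logits = nn.nll_loss_and_grad(logp, targets)
        dH = self.out.backward(d_logits)
        dX = self.bilstm.backward(dH)
        cfg = self.config
        dw = cfg.word_dim
        off_char = dw + len(CASE_CATEGORIES) + 1
        d_char = dX[:, off_char:]
        for t in range(len(sentence.tokens) - 1, -1, -1):
            d_emb = self.char_cnn.backward(d_char[t])
            self.char_emb.backward(d_emb)
        self.word_emb.backward(dX[:, :dw])
        return loss

    def train(self, sentences: Sequence[Sentence], epochs: int | None = None,
              log_every: int = 1) -> list[float]:
        """Minimise per-token NLL with Adam; returns per-epoch mean loss."""
        labelled = [s for s in sentences if s.labels is not None and len(s) > 0]
        if not labelled:
            raise ValueError("no labelled sentences to train on")
        tag_index = {t: i for i, t in enumerate(self.tags)}
        for s in labelled:
            bad = set(s.labels) - set(tag_index)
            if bad:
                raise ValueError(
                    f"sentence {s.id} uses labels outside the model tag set: "
                    f"{sorted(bad)}"
                )
        epochs = self.config.epochs if epochs is None else epochs
        params = [p for layer in self._layers() for p in layer.params()]
        opt = nn.Adam(params, lr=self.config.lr, clip_norm=self.config.clip_norm)
        order_rng = np.random.default_rng(self.config.seed + 1)
        for epoch in range(epochs):
            order = order_rng.permutation(len(labelled))
            total = 0.0
            for idx in order:
                s = labelled[idx]
                targets = [tag_index[lab] for lab in s.labels]
                opt.zero_grad()
                total += self._train_step(s, targets)
                opt.step()
            mean_loss = total / len(labelled)
            self.loss_history.append(mean_loss)
        return self.loss_history

    # -- decoding -----------------------------------------------------------

    def predict_labels(self, sentence: Sentence) -> list[str]:
        _, logp = self.encode(sentence)
        if logp.shape[0] == 0:
            return []
        pred = [self.tags[i] for i in logp.argmax(axis=1)]
        return repair_bio(pred, warn=False)

    def recognize(self, sentence: Sentence) -> RecognizedSpans:
        """Decode argmax tags into typed trigger and argument spans."""
        labels = self.predict_labels(sentence)
        out = RecognizedSpans()
        for start, end, abbr in bio_spans(labels):
            text = " ".join(t.surface for t in sentence.tokens[start : end + 1])
            span = Span(start, end, text)
            if abbr in TRIGGER_ABBRS:
                cat = next(c for c in TriggerCategory if c.abbreviation == abbr)
                out.triggers.append((span, cat))
            else:
                out.arguments.append((span, ArgumentCategory.from_abbreviation(abbr)))
        return out

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {
            f"p{i}": p.value
            for i, p in enumerate(
                q for layer in self._layers() for q in layer.params()
            )
        }
        meta = {
            "config": asdict(self.config),
            "tags": list(self.tags),
            "word_vocab": self.word_vocab,
            "char_vocab": self.char_vocab,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path,
             dictionaries: Sequence[TermDictionary] = ()) -> "Tagger":
        data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(
            meta["word_vocab"],
            dictionaries,
            TaggerConfig(**meta["config"]),
            tags=meta["tags"],
        )
        model.char_vocab = meta["char_vocab"]
        params = [p for layer in model._layers() for p in layer.params()]
        for i, p in enumerate(params):
            p.value[...] = data[f"p{i}"]
        return model


def build_vocab(sentences: Sequence[Sentence],
                pretrained: dict[str, np.ndarray] | None = None) -> dict[str, int]:
    """Word vocabulary (lower-cased) from a corpus, ids starting at 1."""
    words = sorted({t.surface.lower() for s in sentences for t in s.tokens})
    if pretrained:
        words = sorted(set(words) | set(pretrained))
    return {w: i + 1 for i, w in enumerate(words)}


def token_f1(gold: Sequence[Sequence[str]], pred: Sequence[Sequence[str]]) -> float:
    """Micro-averaged token-level F1 over non-O labels."""
    tp = fp = fn = 0
    for g_labels, p_labels in zip(gold, pred, strict=True):
        for g, p in zip(g_labels, p_labels, strict=True):
            if p != "O" and p == g:
                tp += 1
            elif p != "O" and p != g:
                fp += 1
                if g != "O":
                    fn += 1
            elif p == "O" and g != "O":
                fn += 1
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)
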