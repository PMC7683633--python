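"""Corpus containers, file formats, and distant-supervision annotation.

File formats handled here:

* documents — UTF-8 plain text, either one sentence per line or raw prose
  (rule-based sentence splitting);
* BIO files — CoNLL-style two columns (token, tab, label), blank line
  between sentences;
* role files — five whitespace-separated integers per line (role index,
  trigger start, trigger end, argument start, argument end), blank-line
  blocks parallel to the sentence sequence;
* term dictionaries — one term per line, matched case-insensitively;
* word embeddings — text format, token followed by its vector values.

Token spans are 0-based and inclusive throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from eventbtm.schema import (
    DEFAULT_CATEGORY_PRIORITY,
    ArgumentCategory,
    TriggerCategory,
)
from eventbtm.stemming import porter_stem

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+(?:[-/]\w+)*|[^\w\s]")
_SENT_RE = re.compile(r"(?<=[.!?])\s+")

#: every legal BIO label: O plus B-/I- per trigger and argument abbreviation
VALID_CATEGORY_ABBRS: tuple[str, ...] = tuple(
    c.abbreviation for c in TriggerCategory
) + tuple(c.abbreviation for c in ArgumentCategory)

VALID_BIO_LABELS: frozenset[str] = frozenset(
    {"O"}
    | {f"{p}-{a}" for p in "BI" for a in VALID_CATEGORY_ABBRS}
)


@dataclass(frozen=True)
class Token:
    """A surface token with its stem and the residual affix."""

    surface: str
    stem: str
    affix: str
    index: int

    @classmethod
    def make(cls, surface: str, index: int) -> "Token":
        stem = porter_stem(surface)
        low = surface.lower()
        affix = low[len(stem):] if low.startswith(stem) else ""
        return cls(surface, stem, affix, index)


@dataclass(frozen=True)
class RoleAnnotation:
    """Gold role tuple: role index plus trigger and argument spans."""

    role_index: int
    e1_start: int
    e1_end: int
    e2_start: int
    e2_end: int

    def __post_init__(self):
        if self.e1_start > self.e1_end:
            raise ValueError(
                f"trigger span start {self.e1_start} > end {self.e1_end}"
            )
        if self.e2_start > self.e2_end:
            raise ValueError(
                f"argument span start {self.e2_start} > end {self.e2_end}"
            )
        if min(self.e1_start, self.e2_start) < 0:
            raise ValueError("negative span position")


@dataclass
class Sentence:
    id: int
    tokens: list[Token]
    labels: list[str] | None = None
    roles: list[RoleAnnotation] = field(default_factory=list)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Document:
    id: str
    sentences: list[Sentence]


@dataclass
class Corpus:
    documents: list[Document]
    split: str = ""

    def __len__(self) -> int:
        return len(self.documents)

    def sentences(self) -> Iterator[tuple[Document, Sentence]]:
        for doc in self.documents:
            for sent in doc.sentences:
                yield doc, sent


def tokenize(text: str) -> list[str]:
    """Rule-based word tokenizer: splits on whitespace and punctuation,
    keeps hyphen/slash compounds together, preserves case."""
    return _TOKEN_RE.findall(text)


def make_sentence(surfaces: Sequence[str], sent_id: int = 0) -> Sentence:
    return Sentence(sent_id, [Token.make(s, i) for i, s in enumerate(surfaces)])


def sentence_from_text(text: str, sent_id: int = 0) -> Sentence:
    return make_sentence(tokenize(text), sent_id)


def read_documents(path: str | Path, mode: str = "sentence_per_line") -> Corpus:
    """Read a document file or a directory of document files.

    ``sentence_per_line`` treats each non-empty line as one sentence; ``raw``
    splits prose into sentences on terminal punctuation first.
    """
    if mode not in {"raw", "sentence_per_line"}:
        raise ValueError(f"unknown mode {mode!r}")
    p = Path(path)
    files = sorted(p.glob("*.txt")) if p.is_dir() else [p]
    documents = []
    for f in files:
        text = f.read_text(encoding="utf-8")  # undecodable bytes raise
        if mode == "raw":
            lines = [s for s in _SENT_RE.split(text.strip()) if s.strip()]
        else:
            lines = [ln for ln in text.splitlines() if ln.strip()]
        sentences = [sentence_from_text(ln, i) for i, ln in enumerate(lines)]
        if not sentences:
            logger.warning("document %s is empty", f.name)
        documents.append(Document(f.stem, sentences))
    return Corpus(documents)


# -- BIO files --------------------------------------------------------------


def repair_bio(labels: Sequence[str], warn: bool = True) -> list[str]:
    """Fix illegal I- transitions (I after O, after a different category, or
    sentence-initial) by promoting them to B-."""
    out: list[str] = []
    prev_cat = None
    for i, lab in enumerate(labels):
        if lab.startswith("I-"):
            cat = lab[2:]
            if prev_cat != cat:
                if warn:
                    logger.warning(
                        "illegal %s at position %d repaired to B-%s", lab, i, cat
                    )
                lab = "B-" + cat
        out.append(lab)
        prev_cat = lab[2:] if lab != "O" else None
    return out


def write_bio(sentences: Iterable[Sentence], path: str | Path) -> None:
    lines: list[str] = []
    for sent in sentences:
        if sent.labels is None or len(sent.labels) != len(sent.tokens):
            raise ValueError(f"sentence {sent.id} has no complete BIO labels")
        for tok, lab in zip(sent.tokens, sent.labels):
            if lab not in VALID_BIO_LABELS:
                raise ValueError(
                    f"unknown BIO label {lab!r}; valid category tags: "
                    f"{', '.join(VALID_CATEGORY_ABBRS)}"
                )
            lines.append(f"{tok.surface}\t{lab}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_bio(path: str | Path) -> list[Sentence]:
    sentences: list[Sentence] = []
    surfaces: list[str] = []
    labels: list[str] = []

    def flush():
        if surfaces:
            sent = make_sentence(surfaces, len(sentences))
            sent.labels = repair_bio(labels)
            sentences.append(sent)
            surfaces.clear()
            labels.clear()

    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'token<TAB>label'")
        tok, lab = parts
        if lab not in VALID_BIO_LABELS:
            raise ValueError(
                f"{path}:{lineno}: unknown BIO label {lab!r}; valid category "
                f"tags: {', '.join(VALID_CATEGORY_ABBRS)}"
            )
        surfaces.append(tok)
        labels.append(lab)
    flush()
    return sentences


def bio_spans(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """Group repaired BIO labels into (start, end, category) spans."""
    spans: list[tuple[int, int, str]] = []
    start, cat = None, None
    for i, lab in enumerate(repair_bio(labels, warn=False)):
        if lab.startswith("B-"):
            if start is not None:
                spans.append((start, i - 1, cat))
            start, cat = i, lab[2:]
        elif lab.startswith("I-"):
            pass  # continuation of current span (repair guarantees legality)
        else:
            if start is not None:
                spans.append((start, i - 1, cat))
            start, cat = None, None
    if start is not None:
        spans.append((start, len(labels) - 1, cat))
    return spans


def spans_to_bio(n_tokens: int, spans: Iterable[tuple[int, int, str]]) -> list[str]:
    labels = ["O"] * n_tokens
    for start, end, cat in spans:
        labels[start] = f"B-{cat}"
        for i in range(start + 1, end + 1):
            labels[i] = f"I-{cat}"
    return labels


# -- role files -------------------------------------------------------------


def parse_role_line(line: str, lineno: int = 0) -> RoleAnnotation:
    """Parse one five-integer role annotation line."""
    parts = line.split()
    if len(parts) != 5:
        raise ValueError(
            f"line {lineno}: role annotation needs 5 fields, got {len(parts)}"
        )
    try:
        vals = [int(p) for p in parts]
    except ValueError:
        raise ValueError(f"line {lineno}: non-integer field in {line!r}") from None
    return RoleAnnotation(*vals)


def read_roles(path: str | Path) -> list[list[RoleAnnotation]]:
    """Read blank-line-separated blocks of role lines, one block per
    sentence (empty blocks allowed)."""
    blocks: list[list[RoleAnnotation]] = []
    current: list[RoleAnnotation] = []
    seen_any = False
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip():
            blocks.append(current)
            current = []
            continue
        seen_any = True
        current.append(parse_role_line(line, lineno))
    if current or not seen_any and not blocks:
        blocks.append(current)
    return blocks


def write_roles(blocks: Iterable[Sequence[RoleAnnotation]], path: str | Path) -> None:
    lines: list[str] = []
    for block in blocks:
        for r in block:
            lines.append(
                f"{r.role_index} {r.e1_start} {r.e1_end} {r.e2_start} {r.e2_end}"
            )
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- term dictionaries ------------------------------------------------------


@dataclass
class TermDictionary:
    """Lower-cased term set for one argument category."""

    category: ArgumentCategory
    terms: set[str]

    def __post_init__(self):
        self.terms = {t.lower() for t in self.terms if t.strip()}
        # tokenized forms for longest-match scanning
        self._token_terms = {tuple(tokenize(t)) for t in self.terms}
        self.max_len = max((len(t) for t in self._token_terms), default=0)

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def match_at(self, lowered: Sequence[str], i: int) -> int:
        """Length of the longest term starting at token i, 0 if none."""
        best = 0
        for ln in range(min(self.max_len, len(lowered) - i), 0, -1):
            if tuple(lowered[i : i + ln]) in self._token_terms:
                best = ln
                break
        return best


def load_term_dictionary(path: str | Path, category: ArgumentCategory) -> TermDictionary:
    terms = {
        line.strip().lower()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }
    if not terms:
        logger.warning("term dictionary %s (%s) is empty", path, category.abbreviation)
    d = TermDictionary(category, terms)
    logger.info("loaded %d %s terms from %s", len(d), category.abbreviation, path)
    return d


def distant_annotate(
    corpus: Corpus,
    dictionaries: Sequence[TermDictionary],
    priority: Sequence[ArgumentCategory] = DEFAULT_CATEGORY_PRIORITY,
) -> Corpus:
    """Dictionary-based distant supervision: label argument spans in place.

    Scans each sentence left to right; at each position the longest
    dictionary match wins, with equal lengths broken by the fixed category
    priority order.  Matched spans get B-/I- labels with the category
    abbreviation; spans never overlap.
    """
    rank = {cat: i for i, cat in enumerate(priority)}
    for _, sent in corpus.sentences():
        lowered = [t.surface.lower() for t in sent.tokens]
        spans: list[tuple[int, int, str]] = []
        i = 0
        while i < len(lowered):
            candidates = [
                (d.match_at(lowered, i), d.category) for d in dictionaries
            ]
            candidates = [(ln, cat) for ln, cat in candidates if ln > 0]
            if not candidates:
                i += 1
                continue
            best_len = max(ln for ln, _ in candidates)
            tied = sorted(
                (cat for ln, cat in candidates if ln == best_len),
                key=lambda c: rank.get(c, len(rank)),
            )
            if len(tied) > 1:
                logger.warning(
                    "equal-length dictionary overlap at sentence %d token %d; "
                    "resolved to %s by priority",
                    sent.id, i, tied[0].abbreviation,
                )
            spans.append((i, i + best_len - 1, tied[0].abbreviation))
            i += best_len
        sent.labels = spans_to_bio(len(sent.tokens), spans)
    return corpus


# -- corpus split -----------------------------------------------------------


def split_corpus(corpus: Corpus, ratio: float = 0.9, seed: int = 0) -> tuple[Corpus, Corpus]:
    """Document-level random split; train size is round-half-up(ratio * M)."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0,1), got {ratio}")
    m = len(corpus)
    if m < 2:
        raise ValueError("need at least 2 documents to split")
    n_train = int(np.floor(ratio * m + 0.5))
    n_train = min(max(n_train, 1), m - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return (
        Corpus([corpus.documents[i] for i in train_idx], split="train"),
        Corpus([corpus.documents[i] for i in test_idx], split="test"),
    )


# -- embeddings -------------------------------------------------------------


def read_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    """Read a text embedding file: token then space-separated values."""
    table: dict[str, np.ndarray] = {}
    dim = None
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        parts = line.rstrip().split(" ")
        if len(parts) < 2:
            continue
        vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(f"{path}:{lineno}: dimension {vec.size} != {dim}")
        table[parts[0]] = vec
    return table


def write_embeddings(table: dict[str, np.ndarray], path: str | Path) -> None:
    lines = [
        w + " " + " ".join(f"{v:.6f}" for v in vec) for w, vec in table.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
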