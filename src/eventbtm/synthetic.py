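"""Seeded synthetic corpora with gold annotations for every pipeline stage.

The generator plants a known topic-over-events mixture and realises each
event as a templated sentence whose trigger and argument spans come from
small per-category lexicons (terms taken from the taxonomy's printed
examples).  Every gold layer is emitted consistently: tokens, BIO labels,
role annotations, event mentions, and per-document topic mixtures, in
exactly the formats the corpus I/O layer reads, so the pipeline runs on
generated data unmodified.

What it emulates: dictionary-term arguments arranged into trigger+argument
mentions, documents drawn from a mixture over topics that own disjoint
event inventories, and a configurable fraction of event-free filler
sentences.  What it does not emulate: real scientific prose statistics,
ambiguous triggers, nested or cross-sentence events — passing tests on
this corpus show the machinery is correct, not that real-literature
accuracy matches.

Templates deliberately include a sentence-initial argument directly
adjacent to the trigger so the NULL-vector logic of the lexical role
features is exercised by construction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from eventbtm.corpus_io import (
    Corpus,
    Document,
    RoleAnnotation,
    Sentence,
    TermDictionary,
    make_sentence,
    write_bio,
    write_embeddings,
    write_roles,
)
from eventbtm.btm import canonicalize_event
from eventbtm.schema import (
    ArgumentCategory,
    EventArgument,
    EventMention,
    EventRoleTable,
    MetaEventType,
    Span,
    TriggerCategory,
    default_role_table,
)

#: five example terms per argument category (from the taxonomy's printed
#: example terms); lexicons are disjoint across categories
ARGUMENT_LEXICONS: dict[ArgumentCategory, tuple[str, ...]] = {
    ArgumentCategory.GrossBrainAnatomy: (
        "auditory cortex", "frontal gyri", "basic ganglia", "limbic", "visual cortex"),
    ArgumentCategory.CognitiveFunction: (
        "attention", "visual perception", "language", "episodic memory",
        "cognitive dissonance"),
    ArgumentCategory.Subject: (
        "patient", "adults", "children", "students", "participants"),
    ArgumentCategory.MedicalProblem: (
        "hypertension", "depression", "schizophrenia", "epilepsy", "autism"),
    ArgumentCategory.SensoryStimuliOrResponse: (
        "visual stimuli", "auditory sense", "emotional stimuli",
        "tactile stimuli", "olfactory stimuli"),
    ArgumentCategory.ExperimentalTask: (
        "delayed memory task", "motion discrimination task", "abstract task",
        "working memory task", "reading task"),
    ArgumentCategory.ExperimentalMeasurement: (
        "functional magnetic resonance imaging", "magnetoencephalography",
        "MRI", "MEG", "diffusion optical imaging"),
    ArgumentCategory.AnalyticalToolAndMethod: (
        "multivariate analysis", "independent component analysis",
        "regression analysis", "clustering", "support vector machine"),
    ArgumentCategory.BrainNetwork: (
        "visual network", "sensory motor network", "auditory network",
        "cerebellar network", "executive control network"),
}

#: trigger terms per category, disjoint across categories
TRIGGER_LEXICONS: dict[TriggerCategory, tuple[str, ...]] = {
    TriggerCategory.Activate: ("activation", "activates", "hyperactivity"),
    TriggerCategory.Deactivate: ("deactivation", "suppresses", "deactivates"),
    TriggerCategory.Include: ("includes", "contains", "comprises"),
    TriggerCategory.Affect: ("influences", "affects", "modulates"),
    TriggerCategory.DesignCognitiveTask: ("designed", "presented", "recorded"),
    TriggerCategory.PerformCognitiveTask: ("completed", "performed", "implemented"),
    TriggerCategory.AcquireData: ("examined", "assessed", "scanned"),
    TriggerCategory.AnalyzeData: ("analyzed", "applied", "computed"),
    TriggerCategory.DeduceResult: ("reveals", "indicates", "demonstrates"),
}

_FILLERS = (
    "The results were consistent with previous findings .",
    "Further work is needed to confirm this observation .",
    "These considerations motivated the present investigation .",
    "No additional exclusion criteria were applied here .",
)


@dataclass(frozen=True)
class EventSpecies:
    """A fixed lexical realisation of one meta-event: the trigger term and
    one term per role slot, hence one canonical vocabulary key."""

    trigger_category: TriggerCategory
    trigger: str
    arg1: str
    arg1_category: ArgumentCategory
    arg2: str
    arg2_category: ArgumentCategory

    @property
    def meta_event(self) -> MetaEventType:
        return self.trigger_category.meta_event


@dataclass
class GeneratorConfig:
    n_docs: int = 200
    sentences_per_doc: int = 6
    K_true: int = 2
    noise_rate: float = 0.2      # probability a sentence carries no event
    dominant_weight: float = 0.9  # mass of a document's own topic
    seed: int = 0
    role_table: EventRoleTable = field(default_factory=default_role_table)

    def __post_init__(self):
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if not 1.0 / self.K_true <= self.dominant_weight <= 1.0:
            raise ValueError("dominant_weight must be at least 1/K_true")


def default_species(role_table: EventRoleTable,
                    per_meta: int = 1) -> list[EventSpecies]:
    """One (or more) fixed realisations per extractable meta-event, built
    from the first admissible lexicon entries of each role slot."""
    species = []
    for cat in TriggerCategory:
        slots = role_table.slots(cat.meta_event)
        s1, s2 = slots[0], slots[1]
        for v in range(per_meta):
            c1 = sorted(s1.categories, key=lambda c: c.abbreviation)[0]
            c2 = sorted(s2.categories, key=lambda c: c.abbreviation)[-1]
            trig = TRIGGER_LEXICONS[cat][v % len(TRIGGER_LEXICONS[cat])]
            a1 = ARGUMENT_LEXICONS[c1][v % len(ARGUMENT_LEXICONS[c1])]
            a2 = ARGUMENT_LEXICONS[c2][(v + 1) % len(ARGUMENT_LEXICONS[c2])]
            species.append(EventSpecies(cat, trig, a1, c1, a2, c2))
    return species


@dataclass
class GoldBundle:
    corpus: Corpus
    events_by_doc: dict[str, list[EventMention]]
    doc_topics: np.ndarray          # (n_docs, K_true) generating mixtures
    true_topic: np.ndarray          # (n_docs,) dominant topic per document
    species: list[EventSpecies]
    true_phi: np.ndarray            # (K_true, n_species)
    species_keys: list[str]         # canonical key per species
    config: GeneratorConfig

    def dictionaries(self) -> list[TermDictionary]:
        return [
            TermDictionary(cat, set(terms))
            for cat, terms in ARGUMENT_LEXICONS.items()
        ]

    def all_sentences(self) -> list[Sentence]:
        return [s for doc in self.corpus.documents for s in doc.sentences]


def _realise(species: EventSpecies, variant: int, sent_id: int,
             doc_id: str, role_table: EventRoleTable
             ) -> tuple[Sentence, EventMention]:
    a1 = species.arg1.split()
    a2 = species.arg2.split()
    tr = species.trigger.split()
    if variant == 0:
        # sentence-initial argument, trigger adjacent to both arguments
        tokens = a1 + tr + a2 + ["."]
        off1, off_t, off2 = 0, len(a1), len(a1) + len(tr)
    elif variant == 1:
        tokens = ["The"] + a1 + tr + ["the"] + a2 + ["."]
        off1, off_t = 1, 1 + len(a1)
        off2 = off_t + len(tr) + 1
    else:
        tokens = ["In", "this", "study"] + a1 + tr + a2 + ["again", "."]
        off1, off_t = 3, 3 + len(a1)
        off2 = off_t + len(tr)
    sent = make_sentence(tokens, sent_id)
    trig_span = Span(off_t, off_t + len(tr) - 1, species.trigger)
    a1_span = Span(off1, off1 + len(a1) - 1, species.arg1)
    a2_span = Span(off2, off2 + len(a2) - 1, species.arg2)
    slots = role_table.slots(species.meta_event)
    event = EventMention(
        species.meta_event, trig_span,
        [
            EventArgument(a1_span, species.arg1_category, slots[0].role),
            EventArgument(a2_span, species.arg2_category, slots[1].role),
        ],
        sentence_id=sent_id, document_id=doc_id,
    )
    labels = ["O"] * len(tokens)
    tabbr = species.trigger_category.abbreviation
    labels[off_t] = f"B-{tabbr}"
    for i in range(off_t + 1, off_t + len(tr)):
        labels[i] = f"I-{tabbr}"
    for span, cat in ((a1_span, species.arg1_category), (a2_span, species.arg2_category)):
        labels[span.start] = f"B-{cat.abbreviation}"
        for i in range(span.start + 1, span.end + 1):
            labels[i] = f"I-{cat.abbreviation}"
    sent.labels = labels
    sent.roles = [
        RoleAnnotation(slots[0].role.index, trig_span.start, trig_span.end,
                       a1_span.start, a1_span.end),
        RoleAnnotation(slots[1].role.index, trig_span.start, trig_span.end,
                       a2_span.start, a2_span.end),
    ]
    return sent, event


def generate(config: GeneratorConfig | None = None) -> GoldBundle:
    """Generate a gold bundle; byte-identical for a fixed config and seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    species = default_species(cfg.role_table)
    S = len(species)
    K = cfg.K_true
    # partition the species round-robin across topics: disjoint supports
    true_phi = np.zeros((K, S))
    for s in range(S):
        true_phi[s % K, s] = 1.0
    true_phi /= true_phi.sum(axis=1, keepdims=True)
    for k in range(K):
        if not true_phi[k].any():
            raise ValueError(f"topic {k} owns no event species; too few species")

    documents: list[Document] = []
    events_by_doc: dict[str, list[EventMention]] = {}
    doc_topics = np.zeros((cfg.n_docs, K))
    true_topic = np.zeros(cfg.n_docs, dtype=int)
    for d in range(cfg.n_docs):
        k_dom = d % K
        theta_d = np.full(K, (1.0 - cfg.dominant_weight) / max(K - 1, 1))
        theta_d[k_dom] = cfg.dominant_weight if K > 1 else 1.0
        doc_id = f"doc{d:04d}"
        sentences: list[Sentence] = []
        events: list[EventMention] = []
        for s in range(cfg.sentences_per_doc):
            if rng.random() < cfg.noise_rate:
                text = _FILLERS[rng.integers(len(_FILLERS))]
                sent = make_sentence(text.split(), s)
                sent.labels = ["O"] * len(sent.tokens)
                sentences.append(sent)
                continue
            k = int(rng.choice(K, p=theta_d))
            sp = species[int(rng.choice(S, p=true_phi[k]))]
            sent, event = _realise(sp, int(rng.integers(3)), s, doc_id,
                                   cfg.role_table)
            sentences.append(sent)
            events.append(event)
        documents.append(Document(doc_id, sentences))
        events_by_doc[doc_id] = events
        doc_topics[d] = theta_d
        true_topic[d] = k_dom
    bundle = GoldBundle(
        Corpus(documents), events_by_doc, doc_topics, true_topic,
        species, true_phi,
        [canonicalize_event(_realise(sp, 0, 0, "", cfg.role_table)[1])
         for sp in species],
        cfg,
    )
    return bundle


def corrupt(bundle: GoldBundle, swap_rate: float, seed: int = 0) -> GoldBundle:
    """Flip a ``swap_rate`` fraction of non-O BIO labels to O (label noise
    for robustness experiments); the original bundle is left untouched."""
    if not 0 <= swap_rate < 1:
        raise ValueError("swap_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(bundle)
    for doc in out.corpus.documents:
        for sent in doc.sentences:
            if sent.labels is None:
                continue
            sent.labels = [
                "O" if lab != "O" and rng.random() < swap_rate else lab
                for lab in sent.labels
            ]
    return out


def write_bundle(bundle: GoldBundle, out_dir: str | Path,
                 embedding_dim: int = 100) -> None:
    """Emit the bundle in the pipeline's on-disk formats: one text file per
    document, a BIO file and a role file per document, the term
    dictionaries, and a seeded random embedding file over the vocabulary."""
    out = Path(out_dir)
    (out / "documents").mkdir(parents=True, exist_ok=True)
    (out / "bio").mkdir(exist_ok=True)
    (out / "roles").mkdir(exist_ok=True)
    (out / "dictionaries").mkdir(exist_ok=True)
    vocab: set[str] = set()
    for doc in bundle.corpus.documents:
        lines = [" ".join(s.surfaces) for s in doc.sentences]
        (out / "documents" / f"{doc.id}.txt").write_text(
            "\n".join(lines) + "\n", encoding="utf-8")
        write_bio(doc.sentences, out / "bio" / f"{doc.id}.bio")
        write_roles([s.roles for s in doc.sentences], out / "roles" / f"{doc.id}.roles")
        vocab |= {t.surface.lower() for s in doc.sentences for t in s.tokens}
    for cat, terms in ARGUMENT_LEXICONS.items():
        (out / "dictionaries" / f"{cat.abbreviation}.txt").write_text(
            "\n".join(terms) + "\n", encoding="utf-8")
    rng = np.random.default_rng(bundle.config.seed + 99)
    table = {w: rng.uniform(-0.5, 0.5, embedding_dim) for w in sorted(vocab)}
    write_embeddings(table, out / "embeddings.txt")
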