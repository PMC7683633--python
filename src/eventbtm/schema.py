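"""The fixed neuroimaging event taxonomy and the event-role table.

Neuroimaging research is described by three *topic events* — the cognitive
response a study reports, the experiment it ran, and the analysis it
performed — each realised in text as one of ten finer *meta-events*
(activate, deactivate, affect, co-occur, include, design cognitive task,
perform cognitive task, acquire data, analyze data, deduce result).  A
meta-event mention is a trigger word plus zero or more argument spans, each
argument filling a role drawn from the event-role table.  Nine trigger
categories and nine argument categories cover the mentions; the co-occur
meta-event has no trigger category of its own and is therefore not
extracted from text.

An event's distributed representation is the elementwise (Hadamard) product
of the trigger vector and the argument vectors, all in the word-embedding
space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml


class TopicEventType(enum.Enum):
    """The three coarse research-topic events."""

    CognitiveResponse = "CognitiveResponse"
    Experiment = "Experiment"
    Analysis = "Analysis"


class MetaEventType(enum.Enum):
    """The ten meta-events, each belonging to one topic event."""

    Activate = "Activate"
    Deactivate = "Deactivate"
    Affect = "Affect"
    CoOccur = "CoOccur"
    Include = "Include"
    DesignCognitiveTask = "DesignCognitiveTask"
    PerformCognitiveTask = "PerformCognitiveTask"
    AcquireData = "AcquireData"
    AnalyzeData = "AnalyzeData"
    DeduceResult = "DeduceResult"

    @property
    def parent(self) -> TopicEventType:
        return _META_PARENT[self]


_META_PARENT = {
    MetaEventType.Activate: TopicEventType.CognitiveResponse,
    MetaEventType.Deactivate: TopicEventType.CognitiveResponse,
    MetaEventType.Affect: TopicEventType.CognitiveResponse,
    MetaEventType.CoOccur: TopicEventType.CognitiveResponse,
    MetaEventType.Include: TopicEventType.CognitiveResponse,
    MetaEventType.DesignCognitiveTask: TopicEventType.Experiment,
    MetaEventType.PerformCognitiveTask: TopicEventType.Experiment,
    MetaEventType.AcquireData: TopicEventType.Experiment,
    MetaEventType.AnalyzeData: TopicEventType.Analysis,
    MetaEventType.DeduceResult: TopicEventType.Analysis,
}


class TriggerCategory(enum.Enum):
    """The nine trigger categories (co-occur has none)."""

    Activate = "ACT"
    Deactivate = "DEA"
    Include = "INC"
    Affect = "AFF"
    DesignCognitiveTask = "DES"
    PerformCognitiveTask = "PER"
    AcquireData = "ACQ"
    AnalyzeData = "ANA"
    DeduceResult = "DED"

    @property
    def abbreviation(self) -> str:
        return self.value

    @property
    def meta_event(self) -> MetaEventType:
        return MetaEventType[self.name]


class ArgumentCategory(enum.Enum):
    """The nine argument categories with their dictionary abbreviations.

    ``dictionary_index`` is the 1-based position of the category's term
    dictionary, used as the terminology-dictionary scalar feature of the
    tagger (0 is reserved for "not in any dictionary").
    """

    GrossBrainAnatomy = ("GRO", 1)
    CognitiveFunction = ("COG", 2)
    Subject = ("SUB", 3)
    MedicalProblem = ("MDI", 4)
    SensoryStimuliOrResponse = ("SEN", 5)
    ExperimentalTask = ("TSK", 6)
    ExperimentalMeasurement = ("MEA", 7)
    AnalyticalToolAndMethod = ("TOL", 8)
    BrainNetwork = ("RLT", 9)

    def __init__(self, abbr: str, dict_index: int):
        self.abbreviation = abbr
        self.dictionary_index = dict_index

    @classmethod
    def from_abbreviation(cls, abbr: str) -> "ArgumentCategory":
        for cat in cls:
            if cat.abbreviation == abbr:
                return cat
        raise KeyError(f"unknown argument category abbreviation {abbr!r}")


#: Tie-break priority when equal-length dictionary matches overlap
#: (first wins).  Configurable at call sites that accept a priority list.
DEFAULT_CATEGORY_PRIORITY: tuple[ArgumentCategory, ...] = (
    ArgumentCategory.GrossBrainAnatomy,
    ArgumentCategory.CognitiveFunction,
    ArgumentCategory.MedicalProblem,
    ArgumentCategory.ExperimentalTask,
    ArgumentCategory.BrainNetwork,
    ArgumentCategory.SensoryStimuliOrResponse,
    ArgumentCategory.Subject,
    ArgumentCategory.ExperimentalMeasurement,
    ArgumentCategory.AnalyticalToolAndMethod,
)


class SchemaError(ValueError):
    """Raised when an object violates the fixed taxonomy."""


@dataclass(frozen=True)
class RoleType:
    """A named argument role with its global index in the event-role table.

    The index is the scalar ``r`` appended to the lexical feature vector of
    the role classifier, so it must be total and unique across the table.
    Index 0 is reserved for the "none" (no-relation) class.
    """

    name: str
    index: int

    def __post_init__(self):
        if self.index < 0:
            raise SchemaError(f"role index must be >= 0, got {self.index}")


NONE_ROLE = RoleType("none", 0)


@dataclass(frozen=True)
class RoleSlot:
    """One row of the event-role table: a role, its admissible argument
    categories, and its cardinality ("0..1", "1" or "0..n")."""

    role: RoleType
    categories: frozenset[ArgumentCategory]
    cardinality: str = "0..1"

    def __post_init__(self):
        if self.cardinality not in {"0..1", "1", "0..n"}:
            raise SchemaError(f"bad cardinality {self.cardinality!r}")


@dataclass(frozen=True)
class Span:
    """Inclusive 0-based token span [start, end] with its surface text."""

    start: int
    end: int
    text: str = ""

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise SchemaError(f"invalid span ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Span") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class EventArgument:
    span: Span
    category: ArgumentCategory
    role: RoleType
    probability: float = 1.0


@dataclass
class EventMention:
    """A recognised meta-event: trigger span plus role-labelled arguments."""

    meta_event: MetaEventType
    trigger: Span
    arguments: list[EventArgument] = field(default_factory=list)
    sentence_id: int = 0
    document_id: str = ""

    def __post_init__(self):
        if len(self.trigger) < 1:
            raise SchemaError("trigger span must be non-empty")


class EventRoleTable:
    """Mapping from meta-event type to its admissible role slots.

    Role indices are globally unique so that the scalar ``r`` used by the
    role classifier resolves unambiguously.
    """

    def __init__(self, entries: dict[MetaEventType, list[RoleSlot]]):
        self.entries = dict(entries)
        seen: dict[int, str] = {}
        for slots in self.entries.values():
            for slot in slots:
                prev = seen.get(slot.role.index)
                if prev is not None and prev != slot.role.name:
                    raise SchemaError(
                        f"role index {slot.role.index} used by both "
                        f"{prev!r} and {slot.role.name!r}"
                    )
                seen[slot.role.index] = slot.role.name

    def slots(self, meta: MetaEventType) -> list[RoleSlot]:
        try:
            return self.entries[meta]
        except KeyError:
            raise SchemaError(f"meta-event {meta} not in role table") from None

    def roles(self) -> list[RoleType]:
        """All roles in the table, sorted by index (excludes the none role)."""
        out = {s.role for slots in self.entries.values() for s in slots}
        return sorted(out, key=lambda r: r.index)

    def role_by_index(self, index: int) -> RoleType:
        if index == NONE_ROLE.index:
            return NONE_ROLE
        for role in self.roles():
            if role.index == index:
                return role
        raise SchemaError(f"no role with index {index}")

    # -- serialization (human-editable YAML) --------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            meta.value: [
                {
                    "role": s.role.name,
                    "index": s.role.index,
                    "categories": sorted(c.abbreviation for c in s.categories),
                    "cardinality": s.cardinality,
                }
                for s in slots
            ]
            for meta, slots in self.entries.items()
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EventRoleTable":
        doc = yaml.safe_load(Path(path).read_text())
        entries: dict[MetaEventType, list[RoleSlot]] = {}
        for meta_name, rows in doc.items():
            meta = MetaEventType(meta_name)
            entries[meta] = [
                RoleSlot(
                    RoleType(row["role"], int(row["index"])),
                    frozenset(
                        ArgumentCategory.from_abbreviation(a)
                        for a in row["categories"]
                    ),
                    row.get("cardinality", "0..1"),
                )
                for row in rows
            ]
        return cls(entries)


def default_role_table() -> EventRoleTable:
    """The shipped event-role table.

    Only the deduce-result entry is fully prescribed by the event
    definitions (role "research object" over experimental task / cognitive
    function / medical problem, role "biological mechanism" over the
    physiological-feature categories, both optional).  The remaining
    meta-events get one agent/object-style pair each; co-occur and include
    relate two members of the same span category.
    """
    A = ArgumentCategory
    r = _RoleFactory()
    resp_agent = frozenset({A.ExperimentalTask, A.CognitiveFunction})
    resp_obj = frozenset({A.GrossBrainAnatomy, A.BrainNetwork})
    pair_cats = frozenset(
        {A.GrossBrainAnatomy, A.BrainNetwork, A.ExperimentalTask, A.CognitiveFunction}
    )
    entries = {
        MetaEventType.Activate: [
            RoleSlot(r("activation agent"), resp_agent),
            RoleSlot(r("activated region"), resp_obj),
        ],
        MetaEventType.Deactivate: [
            RoleSlot(r("deactivation agent"), resp_agent),
            RoleSlot(r("deactivated region"), resp_obj),
        ],
        MetaEventType.Affect: [
            RoleSlot(r("affecting agent"), resp_agent),
            RoleSlot(r("affected region"), resp_obj),
        ],
        MetaEventType.CoOccur: [
            RoleSlot(r("member 1"), pair_cats),
            RoleSlot(r("member 2"), pair_cats),
        ],
        MetaEventType.Include: [
            RoleSlot(r("container"), pair_cats),
            RoleSlot(r("containee"), pair_cats),
        ],
        MetaEventType.DesignCognitiveTask: [
            RoleSlot(r("designed task"), frozenset({A.ExperimentalTask})),
            RoleSlot(r("design stimulus"), frozenset({A.SensoryStimuliOrResponse})),
        ],
        MetaEventType.PerformCognitiveTask: [
            RoleSlot(r("performer"), frozenset({A.Subject})),
            RoleSlot(r("performed task"), frozenset({A.ExperimentalTask})),
        ],
        MetaEventType.AcquireData: [
            RoleSlot(r("recorded subject"), frozenset({A.Subject, A.MedicalProblem})),
            RoleSlot(r("instrument"), frozenset({A.ExperimentalMeasurement})),
        ],
        MetaEventType.AnalyzeData: [
            RoleSlot(r("analysis tool"), frozenset({A.AnalyticalToolAndMethod})),
            RoleSlot(r("analysed signal"), resp_obj),
        ],
        MetaEventType.DeduceResult: [
            RoleSlot(
                r("research object"),
                frozenset({A.ExperimentalTask, A.CognitiveFunction, A.MedicalProblem}),
            ),
            # "features of physiology and psychology" resolves to the gross
            # anatomy / brain-network categories in the taxonomy.
            RoleSlot(r("biological mechanism"), resp_obj),
        ],
    }
    return EventRoleTable(entries)


class _RoleFactory:
    """Hands out RoleTypes with consecutive indices starting at 1."""

    def __init__(self):
        self._next = 1

    def __call__(self, name: str) -> RoleType:
        role = RoleType(name, self._next)
        self._next += 1
        return role


def validate_event(event: EventMention, table: EventRoleTable) -> list[str]:
    """Check an event mention against the role table.

    Returns a list of human-readable violations; empty means valid.  The
    check is order-independent over arguments: role admissibility, category
    admissibility per role, and role cardinalities.
    """
    slots = table.slots(event.meta_event)  # raises SchemaError if unknown
    by_role = {s.role.index: s for s in slots}
    violations: list[str] = []
    counts: dict[int, int] = {}
    for arg in sorted(event.arguments, key=lambda a: (a.span.start, a.span.end)):
        slot = by_role.get(arg.role.index)
        if slot is None:
            violations.append(
                f"role {arg.role.name!r} not allowed for {event.meta_event.value}"
            )
            continue
        if arg.category not in slot.categories:
            violations.append(
                f"category {arg.category.abbreviation} not allowed in role "
                f"{arg.role.name!r} of {event.meta_event.value}"
            )
        counts[slot.role.index] = counts.get(slot.role.index, 0) + 1
    for idx, n in sorted(counts.items()):
        slot = by_role[idx]
        if slot.cardinality in {"0..1", "1"} and n > 1:
            violations.append(
                f"role {slot.role.name!r} filled {n} times but allows at most 1"
            )
    for slot in slots:
        if slot.cardinality == "1" and counts.get(slot.role.index, 0) == 0:
            violations.append(f"required role {slot.role.name!r} missing")
    return violations


def compose_event_vector(
    v_trigger: np.ndarray, v_args: Iterable[np.ndarray] = ()
) -> np.ndarray:
    """Distributed event representation: elementwise product of the trigger
    vector with every argument vector.  With no arguments the trigger vector
    is returned unchanged (the identity of the Hadamard product)."""
    v = np.asarray(v_trigger, dtype=float)
    for i, va in enumerate(v_args, start=1):
        va = np.asarray(va, dtype=float)
        if va.shape != v.shape:
            raise ValueError(
                f"argument vector {i} has dimension {va.shape} but the "
                f"trigger vector has {v.shape}"
            )
        v = v * va
    return v


def span_vector(token_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Vector of a multi-token span: the mean of its token vectors, which
    keeps the embedding dimension fixed for event composition."""
    if not len(token_vectors):
        raise ValueError("empty span has no vector")
    return np.mean(np.asarray(token_vectors, dtype=float), axis=0)
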