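"""Domain types and the phase-stratified, time-ordered study-lineage DAG.

A research program is modelled as a directed acyclic graph whose nodes are
individual studies (in vitro experiments, animal studies, clinical trials)
and whose directed edges record intellectual lineage: an arrow from a
"parent" study to a "child" study that built on its evidence.  Nodes carry
a research phase (the y-stratum), a publication year (the x-position) and
an outcome coding the direction of the result with respect to further
research: ``positive`` (supports), ``negative`` (argues against) or
``inconclusive`` (ambivalent).  Proposed-but-unexecuted studies are carried
as ``contemplated`` nodes without an outcome, so that "what next" scenarios
can be explored on the same structure.

Lineage may descend in phase (a later-phase result informing a subsequent
earlier-phase experiment); only time must be respected.  Two studies
published in the same report are linked by a ``same_report`` edge, which is
kept in the lineage for reachability but is exempt from strict temporal
precedence and is drawn without an arrowhead.
"""

from __future__ import annotations

import heapq
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from enum import Enum

import networkx as nx

__all__ = [
    "Outcome",
    "Status",
    "PhaseSchema",
    "Study",
    "LineageEdge",
    "AeroGraph",
    "AeroGraphError",
    "SchemaError",
    "DuplicateStudyError",
    "UnknownStudyError",
    "CycleError",
    "TemporalOrderError",
    "ValidationError",
    "YEAR_MIN",
    "YEAR_MAX",
]

YEAR_MIN = 1800
YEAR_MAX = 2100


class AeroGraphError(ValueError):
    """Base class for all graph-construction and validation errors."""


class SchemaError(AeroGraphError):
    """Phase schema is malformed or a study names an unknown phase."""


class DuplicateStudyError(AeroGraphError):
    """A study id or a (parent, child) edge pair was added twice."""


class UnknownStudyError(AeroGraphError):
    """An operation referenced a study id not present in the graph."""


class CycleError(AeroGraphError):
    """An edge would create a directed cycle through the lineage."""


class TemporalOrderError(AeroGraphError):
    """Lineage contradicts the temporal order (child precedes parent)."""


class ValidationError(AeroGraphError):
    """A study record violates its own invariants."""


class Outcome(str, Enum):
    """Direction of a study result with respect to further research."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    INCONCLUSIVE = "inconclusive"

    @classmethod
    def parse(cls, text: str) -> "Outcome":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown outcome {text!r}; expected one of "
                f"{[o.value for o in cls]}"
            ) from None


class Status(str, Enum):
    """Whether a study has been executed or is merely proposed."""

    COMPLETED = "completed"
    CONTEMPLATED = "contemplated"

    @classmethod
    def parse(cls, text: str) -> "Status":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown status {text!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


@dataclass(frozen=True)
class PhaseSchema:
    """Ordered research phases, rank 0 being the earliest.

    The default schema is the canonical drug-development ladder:
    ``in_vitro < in_vivo < phase1 < phase2 < phase3``.
    """

    names: tuple[str, ...] = ("in_vitro", "in_vivo", "phase1", "phase2", "phase3")
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.names:
            raise SchemaError("phase schema needs at least one phase")
        if len(set(self.names)) != len(self.names):
            raise SchemaError(f"duplicate phase names in {self.names}")
        for name in self.names:
            if not name or name.split() != [name]:
                raise SchemaError(f"phase name {name!r} must be a non-empty token")
        unknown = set(self.labels) - set(self.names)
        if unknown:
            raise SchemaError(f"labels given for unknown phases {sorted(unknown)}")

    @classmethod
    def default(cls) -> "PhaseSchema":
        return cls()

    def rank(self, phase: str) -> int:
        try:
            return self.names.index(phase)
        except ValueError:
            raise SchemaError(
                f"unknown phase {phase!r}; schema has {list(self.names)}"
            ) from None

    def label(self, phase: str) -> str:
        self.rank(phase)
        if phase in self.labels:
            return self.labels[phase]
        return phase.replace("_", " ")

    def __contains__(self, phase: object) -> bool:
        return phase in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class Study:
    """One research report: a node of the graph.

    ``id`` is a short, case-sensitive, whitespace-free key (``u1``, ``δ3``);
    any Greek/subscripted rendering lives in ``label``.  ``seq`` is a
    within-year ordinal used only to break ties in the temporal order.
    ``extra`` carries unrecognised study-table columns through a round-trip.
    """

    id: str
    phase: str
    year: int
    label: str = ""
    seq: int = 0
    outcome: Outcome | None = None
    status: Status = Status.COMPLETED
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id or self.id.split() != [self.id]:
            raise ValidationError(f"study id {self.id!r} must be a non-empty token")
        if not isinstance(self.year, int) or not YEAR_MIN <= self.year <= YEAR_MAX:
            raise ValidationError(
                f"study {self.id!r}: year {self.year!r} outside "
                f"[{YEAR_MIN}, {YEAR_MAX}]"
            )
        if self.status is Status.COMPLETED and self.outcome is None:
            raise ValidationError(f"completed study {self.id!r} has no outcome")
        if self.status is Status.CONTEMPLATED and self.outcome is not None:
            raise ValidationError(
                f"contemplated study {self.id!r} must not carry an outcome"
            )

    @property
    def completed(self) -> bool:
        return self.status is Status.COMPLETED


@dataclass(frozen=True)
class LineageEdge:
    """Directed parent→child intellectual-lineage link.

    ``same_report=True`` marks two studies published in one report; such an
    edge requires equal years and is rendered without an arrowhead.
    """

    parent: str
    child: str
    same_report: bool = False

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise ValidationError(f"self-loop on {self.parent!r} is not allowed")

    @property
    def key(self) -> tuple[str, str]:
        return (self.parent, self.child)


class AeroGraph:
    """The validated DAG plus its phase schema.

    Single source of truth for all analytics and rendering.  Mutating
    operations (:meth:`add_study`, :meth:`add_edge`, …) return a new graph
    and leave the receiver untouched, which keeps what-if exploration safe.
    """

    def __init__(
        self,
        phase_schema: PhaseSchema | None = None,
        studies: Iterable[Study] = (),
        edges: Iterable[LineageEdge] = (),
    ) -> None:
        self.phase_schema = phase_schema or PhaseSchema.default()
        self._studies: dict[str, Study] = {}
        self._edges: dict[tuple[str, str], LineageEdge] = {}
        for s in studies:
            self._insert_study(s)
        for e in edges:
            self._insert_edge(e)
        self._check_global()

    # -- construction -----------------------------------------------------

    def _insert_study(self, study: Study) -> None:
        if study.id in self._studies:
            raise DuplicateStudyError(f"duplicate study id {study.id!r}")
        if study.phase not in self.phase_schema:
            raise SchemaError(
                f"study {study.id!r}: unknown phase {study.phase!r}; "
                f"schema has {list(self.phase_schema.names)}"
            )
        self._studies[study.id] = study

    def _insert_edge(self, edge: LineageEdge) -> None:
        for endpoint in edge.key:
            if endpoint not in self._studies:
                raise UnknownStudyError(f"edge references unknown study {endpoint!r}")
        if edge.key in self._edges:
            raise DuplicateStudyError(
                f"duplicate edge {edge.parent!r}→{edge.child!r}"
            )
        parent, child = self._studies[edge.parent], self._studies[edge.child]
        if edge.same_report:
            if parent.year != child.year:
                raise TemporalOrderError(
                    f"same-report edge {edge.parent!r}–{edge.child!r} requires "
                    f"equal years (got {parent.year} and {child.year})"
                )
        elif child.year < parent.year:
            raise TemporalOrderError(
                f"edge {edge.parent!r}→{edge.child!r} runs backwards in time "
                f"({parent.year} → {child.year})"
            )
        self._edges[edge.key] = edge

    def _check_global(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " → ".join(str(u) for u, _ in cycle) + f" → {cycle[0][0]}"
            raise CycleError(f"lineage contains a directed cycle: {path}")
        # materialising the temporal order surfaces within-year seq conflicts
        self.temporal_order()

    # -- basic accessors ---------------------------------------------------

    @property
    def studies(self) -> dict[str, Study]:
        return dict(self._studies)

    @property
    def edges(self) -> list[LineageEdge]:
        return list(self._edges.values())

    def study(self, study_id: str) -> Study:
        try:
            return self._studies[study_id]
        except KeyError:
            raise UnknownStudyError(f"unknown study id {study_id!r}") from None

    def has_edge(self, parent: str, child: str) -> bool:
        return (parent, child) in self._edges

    def edge(self, parent: str, child: str) -> LineageEdge:
        try:
            return self._edges[(parent, child)]
        except KeyError:
            raise UnknownStudyError(f"no edge {parent!r}→{child!r}") from None

    @property
    def n_studies(self) -> int:
        return len(self._studies)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def completed_studies(self) -> list[Study]:
        return [s for s in self._studies.values() if s.completed]

    def contemplated_studies(self) -> list[Study]:
        return [s for s in self._studies.values() if not s.completed]

    def __contains__(self, study_id: object) -> bool:
        return study_id in self._studies

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AeroGraph):
            return NotImplemented
        return (
            self.phase_schema == other.phase_schema
            and self._studies == other._studies
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return (
            f"AeroGraph({self.n_studies} studies, {self.n_edges} edges, "
            f"{len(self.contemplated_studies())} contemplated)"
        )

    # -- mutation (functional) ---------------------------------------------

    def _copy(self) -> "AeroGraph":
        new = object.__new__(AeroGraph)
        new.phase_schema = self.phase_schema
        new._studies = dict(self._studies)
        new._edges = dict(self._edges)
        return new

    def add_study(self, study: Study) -> "AeroGraph":
        """Return a new graph with ``study`` added."""
        new = self._copy()
        new._insert_study(study)
        return new

    def add_edge(
        self, parent: str, child: str, same_report: bool = False
    ) -> "AeroGraph":
        """Return a new graph with a lineage edge added.

        Acyclicity and temporal precedence are re-checked; a violation
        raises and leaves the receiver unchanged.
        """
        new = self._copy()
        new._insert_edge(LineageEdge(parent, child, same_report))
        new._check_global()
        return new

    def with_outcome(self, study_id: str, outcome: Outcome) -> "AeroGraph":
        """Return a new graph where a contemplated study is completed
        with the given outcome (the what-if primitive)."""
        study = self.study(study_id)
        if study.completed:
            raise ValidationError(
                f"study {study_id!r} is already completed; "
                "outcomes can only be assigned to contemplated studies"
            )
        new = self._copy()
        new._studies[study_id] = replace(
            study, status=Status.COMPLETED, outcome=outcome
        )
        return new

    # -- graph views -------------------------------------------------------

    def to_networkx(self, include_same_report: bool = True) -> nx.DiGraph:
        """Directed view of the lineage with study/edge attributes."""
        g = nx.DiGraph()
        for s in self._studies.values():
            g.add_node(
                s.id,
                phase=s.phase,
                year=s.year,
                seq=s.seq,
                outcome=s.outcome.value if s.outcome else "",
                status=s.status.value,
                label=s.label,
            )
        for e in self._edges.values():
            if e.same_report and not include_same_report:
                continue
            g.add_edge(e.parent, e.child, same_report=e.same_report)
        return g

    # -- ordering ----------------------------------------------------------

    def temporal_order(self) -> list[str]:
        """Total order of study ids along the time axis.

        Studies sort by year; within a year every lineage parent comes
        before its children (same-report parents included), remaining ties
        break on ``seq`` then id.  The result is a linear extension of the
        DAG restricted to non-same-report edges.  An explicit ``seq``
        assignment that contradicts within-year lineage raises
        :class:`TemporalOrderError` rather than being silently reordered.
        """
        by_year: dict[int, list[Study]] = {}
        for s in self._studies.values():
            by_year.setdefault(s.year, []).append(s)

        order: list[str] = []
        for year in sorted(by_year):
            members = {s.id for s in by_year[year]}
            succ: dict[str, list[str]] = {s.id: [] for s in by_year[year]}
            indeg: dict[str, int] = {s.id: 0 for s in by_year[year]}
            for e in self._edges.values():
                if e.parent in members and e.child in members:
                    p, c = self._studies[e.parent], self._studies[e.child]
                    if c.seq < p.seq:
                        raise TemporalOrderError(
                            f"in {year}, lineage {e.parent!r}→{e.child!r} "
                            f"contradicts seq ({p.seq} vs {c.seq})"
                        )
                    succ[e.parent].append(e.child)
                    indeg[e.child] += 1

            def key(sid: str) -> tuple[int, str]:
                return (self._studies[sid].seq, sid)

            heap = [key(sid) for sid in members if indeg[sid] == 0]
            heapq.heapify(heap)
            while heap:
                _, sid = heapq.heappop(heap)
                order.append(sid)
                for nxt in succ[sid]:
                    indeg[nxt] -= 1
                    if indeg[nxt] == 0:
                        heapq.heappush(heap, key(nxt))
        if len(order) != len(self._studies):  # pragma: no cover - guarded upstream
            raise CycleError("within-year lineage contains a cycle")
        return order

    def year_span(self) -> tuple[int, int] | None:
        """(min, max) publication year over all studies, or None if empty."""
        if not self._studies:
            return None
        years = [s.year for s in self._studies.values()]
        return (min(years), max(years))

    # -- reachability ------------------------------------------------------

    def ancestors(self, study_id: str) -> set[str]:
        """All studies upstream of ``study_id`` in the lineage."""
        self.study(study_id)
        return set(nx.ancestors(self.to_networkx(), study_id))

    def descendants(self, study_id: str) -> set[str]:
        """All studies downstream of ``study_id`` in the lineage."""
        self.study(study_id)
        return set(nx.descendants(self.to_networkx(), study_id))

    def all_paths(self, source: str, target: str) -> list[list[str]]:
        """Every simple directed lineage path from source to target."""
        self.study(source)
        self.study(target)
        return sorted(nx.all_simple_paths(self.to_networkx(), source, target))

    # -- reduction ---------------------------------------------------------

    def transitive_reduction(self) -> "AeroGraph":
        """The unique minimal edge set with the same reachability.

        Distils a full citation network into direct intellectual lineage.
        Same-report edges are always retained, even when implied by a
        longer path.
        """
        g = self.to_networkx()
        reduced = nx.transitive_reduction(g)
        keep: dict[tuple[str, str], LineageEdge] = {}
        for e in self._edges.values():
            if e.same_report or reduced.has_edge(e.parent, e.child):
                keep[e.key] = e
        new = self._copy()
        new._edges = keep
        return new
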