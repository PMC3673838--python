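"""Robustness analytics over a study-lineage graph.

Two dimensions of evidential robustness are quantified:

* **consistency** — agreement among studies within one phase, i.e. with an
  identical or similar outcome metric.  Consistency requires at least two
  completed studies sharing an outcome; a phase holding one of each outcome
  is maximally inconsistent.
* **concordance** — agreement in the direction of result along a directed
  lineage path, across studies with qualitatively different outcome
  metrics (e.g. a surrogate endpoint feeding a clinical endpoint).

On top of these sit the de-facto phase-transition thresholds (how many
positive studies a phase had accumulated before the next phase began),
orphan detection (studies with no incoming lineage, not justified by prior
evidence inside the program), maximal same-outcome sub-trajectories
("robustly negative" or "robustly positive" regions), the overall
positive:negative trend, and what-if re-analysis for contemplated studies.

Contemplated studies carry no outcome and are excluded from every count,
ratio and threshold until a what-if assignment completes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import gcd
from typing import Mapping

import networkx as nx

from .core import (
    AeroGraph,
    AeroGraphError,
    Outcome,
    SchemaError,
    UnknownStudyError,
    ValidationError,
)

__all__ = [
    "PhaseSummary",
    "PhaseConsistency",
    "ConsistencyReport",
    "ConcordanceReport",
    "ThresholdEstimate",
    "SubTrajectory",
    "TrendSummary",
    "RobustnessReport",
    "phase_counts",
    "assess_consistency",
    "classify_path",
    "de_facto_threshold",
    "detect_orphans",
    "monochromatic_subtrajectories",
    "trend_ratio",
    "whatif",
    "analyze",
]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PhaseSummary:
    """Completed-study outcome tallies for one phase."""

    phase: str
    n_completed: int
    n_positive: int
    n_negative: int
    n_inconclusive: int

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "n_completed": self.n_completed,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_inconclusive": self.n_inconclusive,
        }


@dataclass(frozen=True)
class PhaseConsistency:
    """Consistency flags for one phase.

    ``has_consistency`` — at least two completed studies share an outcome.
    ``is_fully_consistent`` — at least two completed studies and all of
    them share one outcome (a single study cannot verify itself).
    """

    phase: str
    has_consistency: bool
    consistent_outcomes: tuple[Outcome, ...]
    is_fully_consistent: bool

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "has_consistency": self.has_consistency,
            "consistent_outcomes": [o.value for o in self.consistent_outcomes],
            "is_fully_consistent": self.is_fully_consistent,
        }


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-phase consistency, in phase-schema order."""

    phases: tuple[PhaseConsistency, ...]

    def for_phase(self, phase: str) -> PhaseConsistency:
        for p in self.phases:
            if p.phase == phase:
                return p
        raise SchemaError(f"unknown phase {phase!r} in consistency report")

    def to_dict(self) -> dict:
        return {"phases": [p.to_dict() for p in self.phases]}


@dataclass(frozen=True)
class ConcordanceReport:
    """Classification of one directed lineage path.

    A path is perfectly concordant iff every study on it shares one
    outcome; each adjacent pair with differing outcomes is a discordant
    step (inconclusive differs from both positive and negative).
    """

    path: tuple[str, ...]
    classification: str  # "perfectly_concordant" | "discordant"
    discordant_steps: tuple[tuple[str, str], ...]

    @property
    def perfectly_concordant(self) -> bool:
        return self.classification == "perfectly_concordant"

    def to_dict(self) -> dict:
        return {
            "path": list(self.path),
            "classification": self.classification,
            "discordant_steps": [list(s) for s in self.discordant_steps],
        }


@dataclass(frozen=True)
class ThresholdEstimate:
    """De-facto evidential bar for one phase transition.

    ``n_positive_before`` counts positive completed studies of
    ``source_phase`` strictly preceding the first study of the next-rank
    phase in the temporal order.  Undefined (``defined=False``) while the
    target phase has no studies.
    """

    source_phase: str
    target_phase: str
    defined: bool
    first_target_study: str | None = None
    n_positive_before: int | None = None

    def to_dict(self) -> dict:
        return {
            "source_phase": self.source_phase,
            "target_phase": self.target_phase,
            "defined": self.defined,
            "first_target_study": self.first_target_study,
            "n_positive_before": self.n_positive_before,
        }


@dataclass(frozen=True)
class SubTrajectory:
    """Maximal weakly-connected same-outcome sub-structure (≥2 studies)."""

    outcome: Outcome
    studies: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome.value,
            "studies": list(self.studies),
            "edges": [list(e) for e in self.edges],
        }


@dataclass(frozen=True)
class TrendSummary:
    """Whole-program outcome tallies and positive:negative ratio."""

    n_positive: int
    n_negative: int
    n_inconclusive: int
    pos_neg_ratio: float | None

    @property
    def ratio_string(self) -> str | None:
        """Reduced integer ratio for display, e.g. ``'3:1'``."""
        if self.n_negative == 0:
            return None
        d = gcd(self.n_positive, self.n_negative)
        return f"{self.n_positive // d}:{self.n_negative // d}"

    def to_dict(self) -> dict:
        return {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_inconclusive": self.n_inconclusive,
            "pos_neg_ratio": self.pos_neg_ratio,
            "ratio_string": self.ratio_string,
        }


@dataclass(frozen=True)
class RobustnessReport:
    """Aggregate of every analytic over one graph state."""

    n_studies: int
    n_completed: int
    n_contemplated: int
    year_span: tuple[int, int] | None
    phase_summaries: tuple[PhaseSummary, ...]
    consistency: ConsistencyReport
    thresholds: tuple[ThresholdEstimate, ...]
    orphans: tuple[str, ...]
    subtrajectories: tuple[SubTrajectory, ...]
    trend: TrendSummary

    def to_dict(self) -> dict:
        span = list(self.year_span) if self.year_span else None
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_studies": self.n_studies,
            "n_completed": self.n_completed,
            "n_contemplated": self.n_contemplated,
            "year_span": span,
            "phase_summaries": [p.to_dict() for p in self.phase_summaries],
            "consistency": self.consistency.to_dict(),
            "thresholds": [t.to_dict() for t in self.thresholds],
            "orphans": list(self.orphans),
            "subtrajectories": [s.to_dict() for s in self.subtrajectories],
            "trend": self.trend.to_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, ensure_ascii=False)


# ---------------------------------------------------------------------------


def phase_counts(graph: AeroGraph) -> list[PhaseSummary]:
    """Outcome tallies per phase, contemplated studies excluded.

    Every schema phase appears, zero-filled when empty, in rank order.
    """
    tallies = {
        phase: {o: 0 for o in Outcome} for phase in graph.phase_schema.names
    }
    for s in graph.completed_studies():
        tallies[s.phase][s.outcome] += 1
    out = []
    for phase in graph.phase_schema.names:
        t = tallies[phase]
        out.append(
            PhaseSummary(
                phase=phase,
                n_completed=sum(t.values()),
                n_positive=t[Outcome.POSITIVE],
                n_negative=t[Outcome.NEGATIVE],
                n_inconclusive=t[Outcome.INCONCLUSIVE],
            )
        )
    return out


def assess_consistency(graph: AeroGraph) -> ConsistencyReport:
    """Within-phase consistency flags for every schema phase."""
    per_phase = []
    for summary in phase_counts(graph):
        counts = {
            Outcome.POSITIVE: summary.n_positive,
            Outcome.NEGATIVE: summary.n_negative,
            Outcome.INCONCLUSIVE: summary.n_inconclusive,
        }
        consistent = tuple(o for o in Outcome if counts[o] >= 2)
        per_phase.append(
            PhaseConsistency(
                phase=summary.phase,
                has_consistency=bool(consistent),
                consistent_outcomes=consistent,
                is_fully_consistent=(
                    summary.n_completed >= 2
                    and max(counts.values()) == summary.n_completed
                ),
            )
        )
    return ConsistencyReport(phases=tuple(per_phase))


def classify_path(graph: AeroGraph, path: list[str] | tuple[str, ...]) -> ConcordanceReport:
    """Classify a directed lineage path as concordant or discordant.

    Every consecutive pair must be a lineage edge (same-report edges
    qualify) and every study on the path must be completed.
    """
    if not path:
        raise AeroGraphError("cannot classify an empty path")
    studies = [graph.study(sid) for sid in path]
    for s in studies:
        if not s.completed:
            raise ValidationError(
                f"contemplated study {s.id!r} on path; concordance is "
                "defined over completed studies only"
            )
    for parent, child in zip(path, path[1:]):
        if not graph.has_edge(parent, child):
            raise AeroGraphError(
                f"{parent!r}→{child!r} is not a lineage edge; "
                "input is not a directed path"
            )
    discordant = tuple(
        (a.id, b.id)
        for a, b in zip(studies, studies[1:])
        if a.outcome != b.outcome
    )
    return ConcordanceReport(
        path=tuple(path),
        classification="discordant" if discordant else "perfectly_concordant",
        discordant_steps=discordant,
    )


def de_facto_threshold(
    graph: AeroGraph, source_phase: str
) -> ThresholdEstimate | None:
    """Positive studies a phase accumulated before the next phase began.

    Counts positive completed ``source_phase`` studies strictly preceding
    (in the temporal order) the earliest study of the next-rank phase.
    Inconclusive studies never count.  Returns ``None`` while the target
    phase is empty; raises for the top-rank phase.
    """
    rank = graph.phase_schema.rank(source_phase)
    if rank == len(graph.phase_schema) - 1:
        raise SchemaError(
            f"{source_phase!r} is the top-rank phase; no next phase exists"
        )
    target_phase = graph.phase_schema.names[rank + 1]
    order = graph.temporal_order()
    first_target = next(
        (sid for sid in order if graph.study(sid).phase == target_phase), None
    )
    if first_target is None:
        return None
    cutoff = order.index(first_target)
    n = sum(
        1
        for sid in order[:cutoff]
        if (s := graph.study(sid)).phase == source_phase
        and s.completed
        and s.outcome is Outcome.POSITIVE
    )
    return ThresholdEstimate(
        source_phase=source_phase,
        target_phase=target_phase,
        defined=True,
        first_target_study=first_target,
        n_positive_before=n,
    )


def detect_orphans(graph: AeroGraph) -> set[str]:
    """Studies with no incoming lineage beyond the lowest phase present.

    An orphan is not directly justified by prior evidence within the
    program.  Parentless studies in the lowest-rank phase present are the
    program's natural roots and are exempt.
    """
    if graph.n_studies == 0:
        return set()
    lowest = min(graph.phase_schema.rank(s.phase) for s in graph.studies.values())
    with_parents = {e.child for e in graph.edges}
    return {
        s.id
        for s in graph.studies.values()
        if s.id not in with_parents
        and graph.phase_schema.rank(s.phase) > lowest
    }


def monochromatic_subtrajectories(graph: AeroGraph) -> list[SubTrajectory]:
    """Maximal same-outcome weakly-connected sub-structures (≥2 studies).

    For each outcome, the lineage subgraph induced on completed studies
    with that outcome is split into weak components; components of at
    least two studies are reported, with their internal edges.  Weak
    connectivity groups siblings that share a parent of the same outcome
    into one sub-trajectory.
    """
    g = graph.to_networkx()
    found: list[SubTrajectory] = []
    order = graph.temporal_order()
    pos = {sid: i for i, sid in enumerate(order)}
    for outcome in Outcome:
        members = [s.id for s in graph.completed_studies() if s.outcome is outcome]
        sub = g.subgraph(members)
        for component in nx.weakly_connected_components(sub):
            if len(component) < 2:
                continue
            comp = sorted(component, key=pos.__getitem__)
            edges = sorted(
                (u, v) for u, v in sub.edges if u in component and v in component
            )
            found.append(
                SubTrajectory(
                    outcome=outcome,
                    studies=tuple(comp),
                    edges=tuple(edges),
                )
            )
    found.sort(key=lambda t: (t.outcome.value, t.studies))
    return found


def trend_ratio(graph: AeroGraph) -> TrendSummary:
    """Whole-program tallies; the ratio is absent when nothing is negative."""
    n = {o: 0 for o in Outcome}
    for s in graph.completed_studies():
        n[s.outcome] += 1
    ratio = (
        n[Outcome.POSITIVE] / n[Outcome.NEGATIVE] if n[Outcome.NEGATIVE] else None
    )
    return TrendSummary(
        n_positive=n[Outcome.POSITIVE],
        n_negative=n[Outcome.NEGATIVE],
        n_inconclusive=n[Outcome.INCONCLUSIVE],
        pos_neg_ratio=ratio,
    )


def whatif(
    graph: AeroGraph, assignments: Mapping[str, Outcome | str]
) -> tuple[AeroGraph, RobustnessReport]:
    """Complete contemplated studies with hypothetical outcomes and re-analyze.

    Returns the updated copy and its report; the input graph is untouched.
    Assigning to a completed study or an unknown id raises.
    """
    new = graph
    for sid, outcome in assignments.items():
        if sid not in graph:
            raise UnknownStudyError(f"unknown study id {sid!r} in assignment")
        if isinstance(outcome, str):
            outcome = Outcome.parse(outcome)
        new = new.with_outcome(sid, outcome)
    return new, analyze(new)


def analyze(graph: AeroGraph) -> RobustnessReport:
    """Run every analytic and aggregate into one serializable report.

    A threshold entry is present for every adjacent phase pair of the
    schema; pairs whose target phase is empty are marked undefined.
    """
    thresholds = []
    for source, target in zip(
        graph.phase_schema.names, graph.phase_schema.names[1:]
    ):
        est = de_facto_threshold(graph, source)
        if est is None:
            est = ThresholdEstimate(
                source_phase=source, target_phase=target, defined=False
            )
        thresholds.append(est)
    return RobustnessReport(
        n_studies=graph.n_studies,
        n_completed=len(graph.completed_studies()),
        n_contemplated=len(graph.contemplated_studies()),
        year_span=graph.year_span(),
        phase_summaries=tuple(phase_counts(graph)),
        consistency=assess_consistency(graph),
        thresholds=tuple(thresholds),
        orphans=tuple(sorted(detect_orphans(graph))),
        subtrajectories=tuple(monochromatic_subtrajectories(graph)),
        trend=trend_ratio(graph),
    )
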