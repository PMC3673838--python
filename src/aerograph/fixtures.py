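"""Packaged example programs and a seeded synthetic-program generator.

Two example research programs ship with the package:

* the **moxifloxacin** program — 19 studies (1998–2009) evaluating
  moxifloxacin for drug-susceptible tuberculosis, from in-vitro work
  through five phase 2 trials, optionally extended with the four
  contemplated follow-up options A–D;
* a small **toy** program in three stages (nodes only; nodes plus lineage;
  plus a failed phase 3 and two contemplated follow-ups) used throughout
  the documentation.

Both are built programmatically here; serialized CSV/JSON copies live in
``aerograph/data`` for command-line use and are tested for equality with
these builders.  :func:`generate` produces arbitrary valid programs from a
seed, for property testing and simulation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .core import (
    AeroGraph,
    AeroGraphError,
    LineageEdge,
    Outcome,
    PhaseSchema,
    Status,
    Study,
)

__all__ = [
    "fixture_moxifloxacin",
    "fixture_toy",
    "fixture_path",
    "GeneratorConfig",
    "generate",
]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture table.

    ``name`` is e.g. ``"moxifloxacin.csv"``, ``"moxifloxacin_figure4.json"``,
    ``"toy_figure2.csv"`` or ``"toy_figure3.json"``.
    """
    from importlib.resources import files

    path = files("aerograph").joinpath("data", name)
    if not path.is_file():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path

_P = Outcome.POSITIVE
_N = Outcome.NEGATIVE
_I = Outcome.INCONCLUSIVE

# id, phase, year, outcome, citation, children (same-report children marked "~")
_MOXIFLOXACIN_TABLE = [
    ("u1", "in_vitro", 1998, _P, "Ji et al. 1998", ["~v1"]),
    ("u2", "in_vitro", 1999, _P, "Gillespie et al. 1999", ["w1", "w2"]),
    ("u3", "in_vitro", 2007, _P, "Shandil et al. 2007", ["w5", "w6"]),
    ("v1", "in_vivo", 1998, _P, "Ji et al. 1998", ["v2"]),
    ("v2", "in_vivo", 1999, _P, "Miyazaki et al. 1999", ["v3", "w1"]),
    ("v3", "in_vivo", 2001, _P, "Lounis et al. 2001", ["v4"]),
    ("v4", "in_vivo", 2002, _I, "Yoshimatsu et al. 2002", ["v5"]),
    ("v5", "in_vivo", 2004, _I, "Nuermberger et al. 2004", ["u3", "w3", "w4"]),
    ("w1", "phase1", 2003, _P, "Gosling et al. 2003", ["v5"]),
    ("w2", "phase1", 2004, _P, "Pletz et al. 2004", ["v5"]),
    ("w3", "phase1", 2005, _N, "Gillespie et al. 2005", ["x1"]),
    ("w4", "phase1", 2006, _P, "Johnson et al. 2006", ["x1", "x2"]),
    ("w5", "phase1", 2007, _N, "Nijland et al. 2007", []),
    ("w6", "phase1", 2008, _I, "Peloquin et al. 2008", ["x4"]),
    ("x1", "phase2", 2006, _N, "Burman et al. 2006", ["w5", "w6", "x3", "x4"]),
    ("x2", "phase2", 2007, _P, "Rustomjee et al. 2007", ["x3"]),
    ("x3", "phase2", 2009, _P, "Conde et al. 2009", ["x5"]),
    ("x4", "phase2", 2009, _N, "Dorman et al. 2009", []),
    ("x5", "phase2", 2009, _P, "Wang et al. 2009", []),
]

# Contemplated follow-up options.  The program's arguments tie each option
# to the sub-trajectories ending at the listed parents: A (another in-vivo
# study) follows the negative x4; B (another phase 1) follows w5 and x4;
# C (another phase 2) follows x4 and x5; D (a phase 3) follows x5.
_MOXIFLOXACIN_CONTEMPLATED = [
    ("A", "in_vivo", 2010, "Option A: in vivo discordance mechanisms", ["x4"]),
    ("B", "phase1", 2010, "Option B: drug-interaction pharmacokinetics", ["w5", "x4"]),
    ("C", "phase2", 2010, "Option C: further phase 2 efficacy", ["x4", "x5"]),
    ("D", "phase3", 2010, "Option D: decisive phase 3 effectiveness", ["x5"]),
]


def fixture_moxifloxacin(state: str = "completed_only") -> AeroGraph:
    """The moxifloxacin–tuberculosis program.

    ``state="completed_only"`` gives exactly the 19 published studies and
    their children links (the u1–v1 pair shares one report).
    ``state="figure4"`` adds the four contemplated options A–D.
    """
    if state not in ("completed_only", "figure4"):
        raise ValueError(f"unknown state {state!r}")
    studies = [
        Study(id=sid, phase=phase, year=year, outcome=out, label=label)
        for sid, phase, year, out, label, _ in _MOXIFLOXACIN_TABLE
    ]
    edges = [
        LineageEdge(sid, child.lstrip("~"), same_report=child.startswith("~"))
        for sid, *_, children in _MOXIFLOXACIN_TABLE
        for child in children
    ]
    if state == "figure4":
        for sid, phase, year, label, parents in _MOXIFLOXACIN_CONTEMPLATED:
            studies.append(
                Study(
                    id=sid,
                    phase=phase,
                    year=year,
                    label=label,
                    status=Status.CONTEMPLATED,
                )
            )
            edges.extend(LineageEdge(p, sid) for p in parents)
    return AeroGraph(PhaseSchema.default(), studies, edges)


# id, phase, year, seq, outcome
_TOY_STUDIES = [
    ("α1", "in_vitro", 2000, 0, _P),
    ("α2", "in_vitro", 2000, 1, _P),
    ("β1", "in_vivo", 2001, 0, _N),
    ("β2", "in_vivo", 2002, 0, _P),
    ("β3", "in_vivo", 2002, 1, _P),
    ("γ1", "phase1", 2003, 0, _P),
    ("γ2", "phase1", 2003, 1, _I),
    ("γ3", "phase1", 2004, 1, _P),
]
_TOY_STUDIES_FIG2 = [
    ("δ1", "phase2", 2004, 0, _N),
    ("δ2", "phase2", 2005, 0, _P),
    ("δ3", "phase2", 2005, 1, _I),
]
_TOY_STUDIES_FIG3 = [
    ("ε1", "phase3", 2005, 2, _N),
]
_TOY_EDGES_FIG2 = [
    ("α1", "α2"),
    ("α2", "β2"),
    ("α2", "β3"),
    ("α1", "β1"),
    ("β2", "γ1"),
    ("β3", "γ2"),
    ("β3", "γ3"),
    ("γ1", "δ1"),
    ("δ1", "γ3"),  # phase backtrack: a failed phase 2 informs a later phase 1
    ("β3", "δ2"),
    ("γ3", "δ2"),
]
_TOY_EDGES_FIG3 = [("δ2", "ε1")]
_TOY_CONTEMPLATED_FIG3 = [
    ("δ4", "phase2", 2006, "a fourth phase 2 trial"),
    ("ε2", "phase3", 2006, "a second phase 3 trial"),
]


def fixture_toy(stage: str = "figure3") -> AeroGraph:
    """The three-stage toy program used in the documentation.

    ``figure1`` — eight studies across five years (2000–2004) in three
    phases, no lineage drawn yet.  ``figure2`` — eleven studies across six
    years with the full lineage; δ3 is the orphan.  ``figure3`` — adds the
    negative phase 3 study ε1 and the contemplated δ4 and ε2.
    """
    if stage not in ("figure1", "figure2", "figure3"):
        raise ValueError(f"unknown stage {stage!r}")
    rows = list(_TOY_STUDIES)
    edges: list[LineageEdge] = []
    contemplated: list[tuple[str, str, int, str]] = []
    if stage in ("figure2", "figure3"):
        rows += _TOY_STUDIES_FIG2
        edges += [LineageEdge(p, c) for p, c in _TOY_EDGES_FIG2]
    if stage == "figure3":
        rows += _TOY_STUDIES_FIG3
        edges += [LineageEdge(p, c) for p, c in _TOY_EDGES_FIG3]
        contemplated = _TOY_CONTEMPLATED_FIG3
    studies = [
        Study(id=sid, phase=phase, year=year, seq=seq, outcome=out, label=sid)
        for sid, phase, year, seq, out in rows
    ]
    studies += [
        Study(
            id=sid,
            phase=phase,
            year=year,
            label=label,
            status=Status.CONTEMPLATED,
        )
        for sid, phase, year, label in contemplated
    ]
    return AeroGraph(PhaseSchema.default(), studies, edges)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-program generator.

    Defaults emulate the scale and shape of a small translational program:
    a handful of studies per phase over a six-year window, a largely
    positive outcome mix (60/20/20), up to three parents per study with a
    preference for the immediately preceding phase, occasional
    phase-backtracking edges and rare orphans.
    """

    phase_schema: PhaseSchema = field(default_factory=PhaseSchema.default)
    studies_per_phase: tuple[int, ...] = (2, 3, 3, 3, 1)
    year_range: tuple[int, int] = (2000, 2005)
    p_positive: float = 0.6
    p_negative: float = 0.2
    p_inconclusive: float = 0.2
    max_parents: int = 3
    p_backtrack: float = 0.1
    p_orphan: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_positive, self.p_negative, self.p_inconclusive)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("outcome probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities sum to {sum(probs)}, not 1")
        if len(self.studies_per_phase) != len(self.phase_schema):
            raise ValueError(
                f"studies_per_phase has {len(self.studies_per_phase)} entries "
                f"for {len(self.phase_schema)} phases"
            )
        if any(n < 0 for n in self.studies_per_phase):
            raise ValueError("studies_per_phase entries must be non-negative")
        if self.max_parents < 1:
            raise ValueError("max_parents must be at least 1")
        if not 0.0 <= self.p_backtrack <= 1.0 or not 0.0 <= self.p_orphan <= 1.0:
            raise ValueError("p_backtrack and p_orphan must lie in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError(f"empty year range {self.year_range}")


def generate(config: GeneratorConfig | None = None, **overrides) -> AeroGraph:
    """Generate a random valid research program; the seed fixes the output.

    Studies are laid out phase by phase: later phases start later in the
    year window.  Each study beyond the temporally first draws 1..k
    parents from strictly earlier studies, weighted toward the adjacent
    lower phase; candidates from higher phases (backtracking) are only
    admitted with probability ``p_backtrack``.  Non-lowest-phase studies
    are left parentless (orphaned) with probability ``p_orphan``.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    counts = config.studies_per_phase
    total = sum(counts)
    nonzero = [i for i, n in enumerate(counts) if n > 0]
    if total and config.p_backtrack == 0 and counts[0] == 0:
        raise AeroGraphError(
            "infeasible config: no studies in the lowest phase and "
            "backtracking disabled leaves later phases without lineage roots"
        )

    rng = random.Random(config.seed)
    y0, y1 = config.year_range
    span = y1 - y0
    nphases = len(config.phase_schema)
    outcomes = list(Outcome)
    weights = [config.p_positive, config.p_negative, config.p_inconclusive]

    studies: list[Study] = []
    for rank, phase in enumerate(config.phase_schema.names):
        # later phases begin later in the window, as real programs do
        base = y0 + round(rank * span / max(nphases, 2))
        for j in range(counts[rank]):
            year = rng.randint(base, y1)
            studies.append(
                Study(
                    id=f"{phase}_{j}",
                    phase=phase,
                    year=year,
                    seq=0,
                    outcome=rng.choices(outcomes, weights=weights)[0],
                    label=f"synthetic {phase} study {j}",
                )
            )

    # a strict total order; seq records it so lineage can never contradict it
    studies.sort(key=lambda s: (s.year, s.id))
    studies = [
        Study(
            id=s.id, phase=s.phase, year=s.year, seq=i,
            outcome=s.outcome, label=s.label,
        )
        for i, s in enumerate(studies)
    ]

    lowest = nonzero[0] if nonzero else 0
    schema = config.phase_schema
    edges: list[LineageEdge] = []
    for i, s in enumerate(studies):
        earlier = studies[:i]
        rank = schema.rank(s.phase)
        if not earlier:
            continue
        if rank > lowest and rng.random() < config.p_orphan:
            continue
        candidates: list[Study] = []
        cweights: list[float] = []
        for cand in earlier:
            crank = schema.rank(cand.phase)
            if crank > rank and rng.random() >= config.p_backtrack:
                continue
            if crank == rank - 1:
                w = 4.0  # adjacent-phase preference
            elif crank == rank:
                w = 2.0
            else:
                w = 1.0
            candidates.append(cand)
            cweights.append(w)
        if not candidates:
            continue
        k = rng.randint(1, min(config.max_parents, len(candidates)))
        chosen = {
            c.id for c in rng.choices(candidates, weights=cweights, k=k)
        }
        edges.extend(LineageEdge(p, s.id) for p in sorted(chosen))

    return AeroGraph(schema, studies, edges)
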