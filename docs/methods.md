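# Methods

## The model

A research program is a directed acyclic graph `G = (V, E)` over studies.
Each study carries a phase from an ordered schema (default
`in_vitro < in_vivo < phase1 < phase2 < phase3`), an integer publication
year, a within-year ordinal `seq`, a status (`completed` or
`contemplated`) and — for completed studies only — an outcome in
`{positive, negative, inconclusive}`. A directed edge `p → c` asserts
that study `c` built on evidence from study `p` ("intellectual lineage").
Acyclicity is the only structural constraint besides time: an edge may
descend in phase (phase backtracking — e.g. a clinical result motivating
a later in-vitro experiment, as with v5 → u3 in the moxifloxacin
program), but a child may never precede its parent in time. Two studies
published in one report are joined by a `same_report` edge; it requires
equal years, stays in the lineage for reachability, and is drawn without
an arrowhead.

### Temporal order

Analytics need a total order along the time axis, but publication years
give only a partial one. Studies sort by year; within a year, every
lineage parent (same-report parents included) precedes its children,
remaining ties break on `seq` and then on the id. The result is a linear
extension of the DAG restricted to non-same-report edges. This within-year
rule matters: in the moxifloxacin program, w4 and x1 are both from 2006,
and only the parent-precedes-child rule places the positive phase 1 study
w4 before the first phase 2 trial x1 — which is what makes the phase 1→2
threshold three rather than two. An explicit `seq` assignment that
contradicts within-year lineage is reported as an error, never silently
reordered; `seq` is this package's mechanism for sub-year resolution, not
something source tables usually record.

### Analytics

- **Phase counts / consistency.** Contemplated studies are excluded from
  every count. A phase *has consistency* when ≥ 2 completed studies share
  an outcome; it is *fully consistent* when it has ≥ 2 completed studies
  and all of them agree (one study cannot verify itself). Inconclusive
  studies count toward neither agreeing side but do make a phase
  inconsistent: a phase holding one positive, one negative and one
  inconclusive study has no consistency at all.
- **Concordance** is evaluated on directed lineage paths only (arguments
  about a trajectory follow the arrows). A path is perfectly concordant
  iff all its studies share one outcome; every adjacent pair that differs
  (inconclusive differs from both poles) is a discordant step. All
  studies on a classified path must be completed.
- **De-facto thresholds.** For a source phase of rank `r`, the threshold
  is the number of *positive* completed studies of that phase strictly
  preceding — in the temporal order — the earliest study of the rank
  `r+1` phase. Only the immediately preceding phase is counted (not the
  union of all lower phases): this is the reading under which the
  moxifloxacin program shows three positives (v1, v2, v3) before the
  first phase 1 study w1 in 2003. Whether positives from still-lower
  phases should also count is a genuinely open modelling question; the
  package exposes the per-pair estimate and leaves aggregation to the
  user. The estimate is undefined while the target phase is empty, and
  inconclusive studies never contribute.
- **Orphans** are studies with in-degree 0 whose phase is not the
  lowest-rank phase *present in the graph*. The exemption reflects that a
  program's earliest-phase roots cannot have internal justification,
  whereas a parentless later-phase study (like the toy program's δ3)
  signals reliance on evidence external to the program.
- **Monochromatic sub-trajectories** are the weakly connected components,
  per outcome, of the lineage subgraph induced on completed studies with
  that outcome; components with ≥ 2 studies are reported together with
  their internal edges. Weak (not directed) connectivity is used so that
  siblings fed by one same-outcome parent — w5 and x4, both negative
  children of the negative x1 — are grouped into a single robustly
  negative region. Singletons are omitted from the listing but are still
  covered by the partition property the tests check.
- **Trend** is the completed-study tally and the ratio
  `n_positive / n_negative`, reported as a float plus a reduced integer
  string ("3:1"); absent when nothing is negative.
- **What-if** completes contemplated studies with hypothetical outcomes
  on a copy and re-runs the full report; the original graph is never
  mutated, and an empty assignment reproduces the plain report exactly.

### Transitive reduction

Children lists extracted from citation networks often contain shortcut
edges implied by longer chains. `transitive_reduction` computes the
unique minimal edge set of the DAG with the same reachability (delegating
to networkx) while always retaining same-report edges. On the packaged
moxifloxacin table it removes exactly one edge, x1 → x4, which is implied
by the two-step path x1 → w6 → x4; the analytics operate on the table as
published, and reduction is offered as an explicit operation.

## Fixtures

The moxifloxacin table is transcribed row-for-row from the published
program summary: 19 studies, 25 lineage links (24 arrows plus the u1–v1
same-report pair). The four contemplated options A–D (another in-vivo
study, phase 1, phase 2, phase 3) have no published children lists; their
parents are reconstructed from the sub-trajectory arguments made for each
option (A ← x4; B ← w5, x4; C ← x4, x5; D ← x5) and assigned the year
2010. These links affect only rendering and what-if lineage, never the
counts.

The toy program's years are not fully specified by its source, which
states only the spans (five, then six years) and a handful of relative
orderings (β2 after α2, γ1 after β3, γ3 subsequent to δ1). The packaged
assignment — α1, α2 2000; β1 2001; β2, β3 2002; γ1, γ2 2003; γ3, δ1 2004
with δ1 first; δ2, δ3, ε1 2005 — is the minimal one satisfying every
stated constraint. The δ2 node is given both β3 and γ3 as parents; the
description ("in conjunction with") is ambiguous about whether β3 → δ2
is a distinct edge, and both are included.

## The synthetic generator

`generate(GeneratorConfig(...))` emulates the *shape* of a small
translational program: studies per phase (default `(2, 3, 3, 3, 1)`, the
toy-program scale), a six-year window in which later phases start later,
a largely positive outcome mix (`p_pos=0.6, p_neg=0.2, p_inc=0.2`,
matching the roughly 12:4:3 mix of the real program), up to three parents
per study drawn from strictly earlier studies with a 4:2:1 weighting for
(adjacent lower phase : same phase : other), backtracking edges admitted
with probability 0.1 and orphans with probability 0.05. The seed fully
determines the output. Because parents are always drawn from strictly
earlier studies in the (year, id) order that also defines `seq`, every
generated graph is acyclic and free of seq contradictions by
construction — which is what makes 500-seed validation fuzzing cheap.

What the generator does **not** emulate: outcome dependence on parent
outcomes (no causal model of study success), same-report pairs,
contemplated nodes, realistic citation-network density, or publication
bias. Passing tests on generated programs therefore demonstrate
structural correctness of the algorithms, not calibration against any
real research portfolio.

## Rendering

Layout is deterministic: x = year plus a fixed within-year offset
(0.8 / k for k co-located studies, following the temporal order), y =
phase rank with the lowest phase at the bottom. Colors are
`#2ca25f` (positive), `#de2d26` (negative), `#fec44f` (inconclusive),
with contemplated nodes white-filled and `#3182bd`-bordered — the named
colors of the visual convention pinned to fixed hex values. Same-report
edges are drawn without arrowheads (DOT: `dir=none`). Edge routing is
straight-line (SVG) or left to Graphviz (DOT); hand-shaped splines for
aesthetic parity with hand-drawn figures are out of scope. Rendering is a
pure function of (graph, style): repeated calls are byte-identical.

## Numerical and interface conventions

- Outcome and status labels parse case-insensitively, stored lowercase;
  study ids are case-sensitive whitespace-free tokens; Greek display
  forms are labels, not ids.
- CSV/TSV children cells use ";" as the list separator (commas collide
  with CSV); an empty cell or dash means no children. Unknown columns
  round-trip untouched. Years must lie in [1800, 2100].
- Reports serialize to JSON with a fixed key order and
  `schema_version: 1`.
- The test suite sizes were chosen to keep the full run in seconds:
  500-seed generator fuzzing, 200 random ≤ 12-node DAGs against a
  brute-force closure oracle, 100 synthetic round-trips, and one
  2000-study draw for the ±0.03 binomial check on outcome frequencies.

## Limitations

- One outcome dimension per node; no effect sizes, no ordinal or
  probabilistic gradings, no weighted edges.
- No automated recommendation among contemplated options: the package
  computes the evidential state; choosing the next study is judgment.
- Lineage must be supplied (hand-curated children lists); no citation
  database parsing.
- Sub-year ordering beyond lineage and `seq` is unmodelled; two unlinked
  same-year studies order lexicographically, which is a convention, not
  a claim about history.
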