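# aerograph

Phase-stratified study-lineage graphs for representing, analyzing and
planning translational research programs.

A drug-development program is a sequence of discrete studies — in-vitro
experiments, animal models, phase 1–3 clinical trials — each building on
evidence from earlier ones. `aerograph` models such a program as a
**directed acyclic graph**: each study is a node placed by publication
year (x) and research phase (y), colored by the direction of its result
(*positive* = supports further research, *negative* = argues against,
*inconclusive* = ambivalent), with directed edges recording intellectual
lineage from "parent" studies to the "children" that built on them.
Edges may descend in phase (a clinical result informing a later animal
experiment); only time must be respected. Proposed future studies ride
along as outcome-free *contemplated* nodes for what-if planning.

On this structure the package computes the robustness analytics that
evidence-synthesis and research-policy groups ask of a program:

- **consistency** — per phase, do ≥ 2 studies agree in outcome?
- **concordance** — along a directed lineage path, do studies with
  qualitatively different endpoints agree in direction?
- **de-facto phase thresholds** — how many positive studies had a phase
  accumulated before the first study of the next phase began? (the
  implicit evidential bar for each phase transition)
- **orphaned studies** — nodes with no incoming lineage, i.e. not
  directly justified by prior evidence inside the program;
- **monochromatic sub-trajectories** — maximal connected same-outcome
  regions ("robustly negative" clusters and their positive counterparts);
- **trend** — overall positive:negative ratio;
- **what-if** — complete contemplated studies with hypothetical outcomes
  and re-run the whole report on a copy.

It ships a validated in-memory model (`AeroGraph`), CSV/TSV/JSON study
tables, DOT/GraphML/SVG export, a deterministic layered visualization, a
seeded synthetic-program generator, and the `aero` command line. Two
example programs are packaged: the moxifloxacin-for-tuberculosis
trajectory (19 studies, 1998–2009, plus four contemplated options A–D)
and a small three-stage toy program.

## Worked example

```python
import aerograph as ag

g = ag.fixture_moxifloxacin("completed_only")
report = ag.analyze(g)

t = report.trend
print("trend:", t.n_positive, t.n_negative, t.n_inconclusive, t.ratio_string)
for est in report.thresholds:
    print(est.source_phase, "→", est.target_phase, ":", est.n_positive_before)
neg = [s for s in report.subtrajectories if s.outcome.value == "negative"][0]
print("negative sub-trajectory:", neg.studies)
```

prints

```
trend: 12 4 3 3:1
in_vitro → in_vivo : 1
in_vivo → phase1 : 3
phase1 → phase2 : 3
phase2 → phase3 : None
negative sub-trajectory: ('w3', 'x1', 'w5', 'x4')
```

Reading: of the 19 completed moxifloxacin studies, 12 were positive,
4 negative and 3 inconclusive — a 3:1 positive-to-negative trend. Both
the animal-to-human and the phase 1-to-phase 2 transitions happened after
three positive studies in the preceding phase (the de-facto thresholds),
while the first in-vivo study appeared after a single positive in-vitro
result. The phase 2→3 threshold is undefined because no phase 3 study
exists yet. Finally there is a robustly negative sub-trajectory — the
negative phase 1 study w3 feeding the negative phase 2 trial x1 and its
negative descendants w5 and x4 — the cluster that made the case for
re-examining the animal models before a phase 3 commitment.

The same pipeline from the shell:

```sh
aero validate src/aerograph/data/moxifloxacin.csv
# 19 studies, 25 edges (1 same-report), acyclic
aero analyze src/aerograph/data/moxifloxacin.csv            # JSON report
aero render src/aerograph/data/moxifloxacin_figure4.csv --to svg --out mox.svg
aero whatif src/aerograph/data/moxifloxacin_figure4.csv \
    --set A=positive --set C=positive                       # updated report
aero simulate --seed 7 --out program.csv                    # synthetic program
```

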