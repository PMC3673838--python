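"""Robustness analytics: counts, consistency, concordance, thresholds,
orphans, sub-trajectories, trend and what-if."""

import pytest
from hypothesis import given, settings

from aerograph import (
    AeroGraph,
    AeroGraphError,
    LineageEdge,
    Outcome,
    SchemaError,
    Status,
    Study,
    UnknownStudyError,
    ValidationError,
    analyze,
    assess_consistency,
    classify_path,
    de_facto_threshold,
    detect_orphans,
    generate,
    monochromatic_subtrajectories,
    phase_counts,
    trend_ratio,
    whatif,
)
from test_core import small_dags

P, N, I = Outcome.POSITIVE, Outcome.NEGATIVE, Outcome.INCONCLUSIVE


# -- phase counts --------------------------------------------------------------


def test_moxifloxacin_phase_counts(mox):
    by_phase = {s.phase: s for s in phase_counts(mox)}
    expect = {
        "in_vitro": (3, 3, 0, 0),
        "in_vivo": (5, 3, 0, 2),
        "phase1": (6, 3, 2, 1),
        "phase2": (5, 3, 2, 0),
        "phase3": (0, 0, 0, 0),
    }
    for phase, (nc, np_, nn, ni) in expect.items():
        s = by_phase[phase]
        assert (s.n_completed, s.n_positive, s.n_negative, s.n_inconclusive) == (
            nc, np_, nn, ni,
        )


def test_toy_figure1_phase_counts(toy_fig1):
    by_phase = {s.phase: s for s in phase_counts(toy_fig1)}
    assert (by_phase["in_vitro"].n_completed, by_phase["in_vitro"].n_positive) == (2, 2)
    assert (by_phase["in_vivo"].n_completed, by_phase["in_vivo"].n_positive) == (3, 2)
    assert (by_phase["phase1"].n_completed, by_phase["phase1"].n_positive) == (3, 2)


def test_contemplated_studies_excluded_from_counts(mox, mox_fig4):
    assert phase_counts(mox) == phase_counts(mox_fig4)


def test_empty_graph_counts_are_zero():
    for s in phase_counts(AeroGraph()):
        assert s.n_completed == 0


# -- consistency ---------------------------------------------------------------


def test_moxifloxacin_has_consistency_at_every_occupied_phase(mox):
    report = assess_consistency(mox)
    for phase in ("in_vitro", "in_vivo", "phase1", "phase2"):
        assert report.for_phase(phase).has_consistency
    assert not report.for_phase("phase3").has_consistency
    assert report.for_phase("in_vitro").is_fully_consistent  # 3/3 positive


def test_one_of_each_outcome_is_maximally_inconsistent(toy_fig2):
    phase2 = assess_consistency(toy_fig2).for_phase("phase2")
    assert not phase2.has_consistency
    assert phase2.consistent_outcomes == ()
    assert not phase2.is_fully_consistent


def test_single_study_phase_cannot_show_consistency():
    g = AeroGraph(studies=[Study(id="a", phase="phase1", year=2000, outcome=P)])
    flags = assess_consistency(g).for_phase("phase1")
    assert not flags.has_consistency and not flags.is_fully_consistent


# -- concordance ---------------------------------------------------------------


def test_perfectly_concordant_trajectory(toy_fig2):
    report = classify_path(toy_fig2, ["α1", "α2", "β3", "γ3", "δ2"])
    assert report.perfectly_concordant and report.discordant_steps == ()


def test_discordant_step_located(toy_fig2):
    report = classify_path(toy_fig2, ["α1", "β1"])
    assert report.classification == "discordant"
    assert report.discordant_steps == (("α1", "β1"),)


def test_single_node_path_is_concordant(toy_fig2):
    assert classify_path(toy_fig2, ["α1"]).perfectly_concordant


def test_classify_path_rejects_non_paths_and_contemplated(mox_fig4):
    with pytest.raises(AeroGraphError):
        classify_path(mox_fig4, ["u1", "x5"])  # not an edge
    with pytest.raises(ValidationError):
        classify_path(mox_fig4, ["x5", "D"])  # D is contemplated
    with pytest.raises(AeroGraphError):
        classify_path(mox_fig4, [])


@settings(max_examples=50, derandomize=True)
@given(small_dags())
def test_classification_agrees_with_all_outcomes_equal_check(g):
    import networkx as nx

    nxg = g.to_networkx()
    nodes = list(g.studies)
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            for path in nx.all_simple_paths(nxg, src, dst):
                expected = len({g.study(s).outcome for s in path}) == 1
                got = classify_path(g, path)
                assert got.perfectly_concordant == expected
                assert (got.discordant_steps == ()) == expected


# -- thresholds ----------------------------------------------------------------


def test_moxifloxacin_thresholds_are_three_positive_studies(mox):
    pre_clinical = de_facto_threshold(mox, "in_vivo")
    assert pre_clinical.first_target_study == "w1"
    assert pre_clinical.n_positive_before == 3  # v1, v2, v3
    clinical = de_facto_threshold(mox, "phase1")
    assert clinical.first_target_study == "x1"
    assert clinical.n_positive_before == 3  # w1, w2 and w4 (before x1 in 2006)


def test_toy_figure2_low_threshold_into_phase2(toy_fig2):
    est = de_facto_threshold(toy_fig2, "phase1")
    assert est.first_target_study == "δ1"
    assert est.n_positive_before == 1  # only γ1; γ3 follows δ1


def test_toy_figure1_two_positive_studies_per_transition(toy_fig1):
    assert de_facto_threshold(toy_fig1, "in_vitro").n_positive_before == 2
    assert de_facto_threshold(toy_fig1, "in_vivo").n_positive_before == 2


def test_threshold_edge_cases(mox):
    assert de_facto_threshold(mox, "phase2") is None  # phase3 empty
    with pytest.raises(SchemaError):
        de_facto_threshold(mox, "phase3")  # top rank
    with pytest.raises(SchemaError):
        de_facto_threshold(mox, "phase9")


def test_threshold_monotone_under_an_extra_early_positive(mox):
    extra = Study(id="v0", phase="in_vivo", year=2000, outcome=P)
    bumped = mox.add_study(extra)
    assert (
        de_facto_threshold(bumped, "in_vivo").n_positive_before
        == de_facto_threshold(mox, "in_vivo").n_positive_before + 1
    )


# -- orphans -------------------------------------------------------------------


def test_toy_figure2_orphan_is_delta3(toy_fig2):
    assert detect_orphans(toy_fig2) == {"δ3"}


def test_moxifloxacin_has_no_orphans(mox):
    # u1 and u2 are parentless but sit in the lowest phase present
    assert detect_orphans(mox) == set()


def test_empty_graph_has_no_orphans():
    assert detect_orphans(AeroGraph()) == set()


def test_lowest_phase_present_sets_the_exemption():
    # with no in-vitro work at all, parentless in-vivo studies are roots
    g = AeroGraph(
        studies=[
            Study(id="b1", phase="in_vivo", year=2000, outcome=P),
            Study(id="c1", phase="phase1", year=2001, outcome=P),
        ]
    )
    assert detect_orphans(g) == {"c1"}


# -- monochromatic sub-trajectories --------------------------------------------


def test_robustly_negative_subtrajectory(mox):
    negative = [
        t for t in monochromatic_subtrajectories(mox) if t.outcome is N
    ]
    assert len(negative) == 1
    assert set(negative[0].studies) == {"w3", "x1", "w5", "x4"}
    assert set(negative[0].edges) == {("w3", "x1"), ("x1", "w5"), ("x1", "x4")}


def test_all_positive_chain_is_one_subtrajectory():
    g = AeroGraph(
        studies=[
            Study(id=s, phase="in_vitro", year=2000 + i, outcome=P)
            for i, s in enumerate("abc")
        ],
        edges=[LineageEdge("a", "b"), LineageEdge("b", "c")],
    )
    trajectories = monochromatic_subtrajectories(g)
    assert len(trajectories) == 1
    assert trajectories[0].studies == ("a", "b", "c")


def test_toy_positive_component_groups_siblings(toy_fig2):
    positive = [
        t
        for t in monochromatic_subtrajectories(toy_fig2)
        if t.outcome is P and "α1" in t.studies
    ]
    assert len(positive) == 1
    assert set(positive[0].studies) == {"α1", "α2", "β2", "β3", "γ1", "γ3", "δ2"}


@pytest.mark.parametrize("seed", range(30))
def test_subtrajectories_partition_each_outcome_class(seed):
    import networkx as nx

    g = generate(seed=seed, studies_per_phase=(3, 3, 3, 3, 2))
    trajectories = monochromatic_subtrajectories(g)
    for outcome in Outcome:
        members = {s.id for s in g.completed_studies() if s.outcome is outcome}
        listed = [set(t.studies) for t in trajectories if t.outcome is outcome]
        # listed components are disjoint ≥2-study sets of this outcome
        assert all(len(c) >= 2 and c <= members for c in listed)
        assert sum(len(c) for c in listed) == len(set().union(*listed, set()))
        # together with singleton components they partition the class
        comps = list(
            nx.weakly_connected_components(g.to_networkx().subgraph(members))
        )
        assert sorted(map(sorted, (c for c in comps if len(c) >= 2))) == sorted(
            map(sorted, listed)
        )


# -- trend ---------------------------------------------------------------------


def test_moxifloxacin_trend_is_three_to_one(mox):
    trend = trend_ratio(mox)
    assert (trend.n_positive, trend.n_negative, trend.n_inconclusive) == (12, 4, 3)
    assert trend.pos_neg_ratio == pytest.approx(3.0)
    assert trend.ratio_string == "3:1"


def test_toy_figure3_trend_seven_of_twelve(toy_fig3):
    trend = trend_ratio(toy_fig3)
    assert trend.n_positive == 7
    assert trend.n_positive + trend.n_negative + trend.n_inconclusive == 12


def test_ratio_absent_without_negatives():
    g = AeroGraph(studies=[Study(id="a", phase="in_vitro", year=2000, outcome=P)])
    trend = trend_ratio(g)
    assert trend.pos_neg_ratio is None and trend.ratio_string is None


# -- what-if -------------------------------------------------------------------


def test_whatif_options_a_and_c_positive(mox_fig4):
    updated, report = whatif(mox_fig4, {"A": P, "C": P})
    by_phase = {s.phase: s for s in report.phase_summaries}
    assert by_phase["in_vivo"].n_positive == 4  # was 3
    assert by_phase["phase2"].n_positive == 4  # was 3
    assert report.n_completed == 21 and report.n_contemplated == 2
    # original untouched
    assert len(mox_fig4.contemplated_studies()) == 4


def test_whatif_empty_assignment_is_identity(mox_fig4):
    _, report = whatif(mox_fig4, {})
    assert report == analyze(mox_fig4)


def test_whatif_rejects_completed_and_unknown(mox_fig4):
    with pytest.raises(ValidationError):
        whatif(mox_fig4, {"u1": P})
    with pytest.raises(UnknownStudyError):
        whatif(mox_fig4, {"zz9": P})


def test_whatif_accepts_outcome_names(mox_fig4):
    _, report = whatif(mox_fig4, {"D": "Negative"})
    by_phase = {s.phase: s for s in report.phase_summaries}
    assert by_phase["phase3"].n_negative == 1


# -- aggregate report ----------------------------------------------------------


def test_analyze_moxifloxacin_states(mox, mox_fig4):
    assert analyze(mox).n_completed == 19
    report = analyze(mox_fig4)
    assert (report.n_completed, report.n_contemplated) == (19, 4)
    assert report.year_span[0] == 1998


def test_analyze_empty_graph():
    report = analyze(AeroGraph())
    assert report.n_studies == 0 and report.year_span is None
    assert all(not t.defined for t in report.thresholds)


def test_report_round_trips_through_json(mox_fig4):
    import json

    doc = json.loads(analyze(mox_fig4).to_json())
    assert doc["schema_version"] == 1
    assert doc["trend"]["ratio_string"] == "3:1"
    assert doc["n_completed"] == 19


@pytest.mark.parametrize("seed", range(20))
def test_conservation_of_counts(seed):
    g = generate(seed=seed, studies_per_phase=(2, 3, 4, 3, 2))
    report = analyze(g)
    assert sum(p.n_completed for p in report.phase_summaries) == report.n_completed
    assert (
        sum(p.n_positive for p in report.phase_summaries) == report.trend.n_positive
    )
    assert (
        sum(p.n_negative for p in report.phase_summaries) == report.trend.n_negative
    )
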