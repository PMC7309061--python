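"""Task point rules, Jaro-Winkler matching, and error-counter replays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nits.sage_scoring import (
    AnswerKey,
    jaro,
    jaro_winkler,
    score_clock,
    score_construction_3d,
    score_memory,
    score_orientation,
    score_picture_naming,
    score_problem_solving,
    score_similarities_calculation,
    score_trails,
    score_verbal_fluency,
    encode_insights,
)
from nits.session_io import (
    GraphAction,
    GraphActionLog,
    TouchEvent,
    TouchTrajectory,
    graph_layout,
)
from nits.synthetic import cube_layout, cube_reference


# ---------------------------------------------------------------------------
# Jaro / Jaro-Winkler (independent reference implementation as oracle)


def jaro_reference(s, t):
    """Straightforward textbook Jaro similarity, written independently."""
    if s == t:
        return 1.0
    if not s or not t:
        return 0.0
    match_dist = max(len(s), len(t)) // 2 - 1
    s_matches, t_matches = [], []
    t_used = [False] * len(t)
    for i, c in enumerate(s):
        for j in range(max(0, i - match_dist), min(len(t), i + match_dist + 1)):
            if not t_used[j] and t[j] == c:
                t_used[j] = True
                s_matches.append(c)
                break
    t_matches = [c for j, c in enumerate(t) if t_used[j]]
    m = len(s_matches)
    if m == 0:
        return 0.0
    trans = sum(1 for x, y in zip(s_matches, t_matches) if x != y) // 2
    return (m / len(s) + m / len(t) + (m - trans) / m) / 3


def jw_reference(s, t, p=0.1):
    j = jaro_reference(s, t)
    ell = 0
    while ell < min(4, len(s), len(t)) and s[ell] == t[ell]:
        ell += 1
    return j + ell * p * (1 - j) if j > 0 else 0.0


class TestJaroWinkler:
    def test_perfect_match_is_one(self):
        assert jaro("martha", "martha") == 1.0
        assert jaro_winkler("martha", "martha") == 1.0

    def test_disjoint_strings_are_zero(self):
        assert jaro("abc", "xyz") == 0.0
        assert jaro_winkler("abc", "xyz") == 0.0

    def test_published_martha_example(self):
        assert jaro("martha", "marhta") == pytest.approx(0.9444, abs=1e-4)
        assert jaro_winkler("martha", "marhta") == pytest.approx(0.9611, abs=1e-4)

    def test_empty_strings_are_identical_by_convention(self):
        assert jaro("", "") == 1.0

    @given(st.text(alphabet="abcdef", max_size=10), st.text(alphabet="abcdef", max_size=10))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_reference_implementation(self, s, t):
        assert jaro(s, t) == pytest.approx(jaro_reference(s, t), abs=1e-12)
        assert jaro_winkler(s, t) == pytest.approx(jw_reference(s, t), abs=1e-12)

    @given(st.text(alphabet="abcdef", max_size=10), st.text(alphabet="abcdef", max_size=10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_winkler_boost_bounds_and_symmetry(self, s, t):
        j, jw = jaro(s, t), jaro_winkler(s, t)
        assert jw >= j
        assert 0.0 <= jw <= 1.0
        assert jaro(s, t) == pytest.approx(jaro(t, s))
        assert jaro_winkler(s, t) == pytest.approx(jaro_winkler(t, s))


# ---------------------------------------------------------------------------
# Text / numeric task scorers


class TestTextScorers:
    key = AnswerKey()

    @pytest.mark.parametrize("answer,expected", [
        ((2019, 5, 7), 3), ((1999, 1, 1), 0), ((2019, 5, 9), 2),
    ])
    def test_orientation_points(self, answer, expected):
        assert score_orientation(answer, (2019, 5, 7)).points == expected

    def test_orientation_rejects_invalid_date(self):
        with pytest.raises(ValueError):
            score_orientation((2019, 13, 7), (2019, 5, 7))

    def test_picture_naming_exact_and_misspelled(self):
        full = score_picture_naming(["elephant", "volcano"], self.key)
        assert full.points == 2 and full.auxiliaries["jw_average"] == 1.0
        typo = score_picture_naming(["elefant", "volcano"], self.key)
        assert typo.points == 2  # spelling tolerance credits the answer
        assert 0.85 <= typo.auxiliaries["jw_0"] < 1.0
        blank = score_picture_naming(["", ""], self.key)
        assert blank.points == 0

    def test_similarities_calculation_rules(self):
        abstract = score_similarities_calculation("tools", 6.55, 20.0, self.key)
        assert abstract.auxiliaries["q3_points"] == 2
        concrete = score_similarities_calculation("metal", 6.55, 20.0, self.key)
        assert concrete.auxiliaries["q3_points"] == 1
        assert abstract.points == 4  # 2 + 1 (Q4 = B - M) + 1 (Q5 exact)
        wrong_q4 = score_similarities_calculation("tools", 6.60, 20.0, self.key)
        assert wrong_q4.auxiliaries["q4_points"] == 0.0
        none_numeric = score_similarities_calculation("tools", None, None, self.key)
        assert none_numeric.points == 2

    @pytest.mark.parametrize("answer,expected", [
        ("Have you finished?", 2), ("I am done now", 1), ("hello", 0),
        ("are you done", 2), ("FINISHED!", 1),
    ])
    def test_memory_phrase(self, answer, expected):
        assert score_memory(answer, self.key).points == expected

    def test_verbal_fluency_rules(self):
        words = list(self.key.fluency_dictionary[:12])
        full = score_verbal_fluency(words, self.key.fluency_dictionary)
        assert full.points == 2
        assert full.auxiliaries["jw_average"] == pytest.approx(1.0)
        ten = score_verbal_fluency(words[:10] + ["", ""], self.key.fluency_dictionary)
        assert ten.points == 1
        five = score_verbal_fluency(words[:5] + [""] * 7, self.key.fluency_dictionary)
        assert five.points == 0

    def test_verbal_fluency_duplicates_count_once(self):
        words = [self.key.fluency_dictionary[0]] * 12
        assert score_verbal_fluency(words, self.key.fluency_dictionary).points == 0

    def test_verbal_fluency_needs_twelve_slots(self):
        with pytest.raises(ValueError):
            score_verbal_fluency(["dog"] * 11, self.key.fluency_dictionary)

    def test_insights_encoding_deterministic(self):
        schema = [("memory_problems", ("no", "sometimes", "often")),
                  ("depression", ("no", "yes"))]
        q = {"memory_problems": "no", "depression": "no"}
        assert encode_insights(q, schema) == [0.0, 0.0]
        q2 = {"memory_problems": "often", "depression": "yes"}
        assert encode_insights(q2, schema) == [2.0, 1.0]
        with pytest.raises(ValueError):
            encode_insights({"depression": "yes"}, schema)


# ---------------------------------------------------------------------------
# Graph-task replays


def _stroke_between(p, q, t0=0, n=12):
    pts = np.linspace(p, q, n)
    return TouchTrajectory(events=tuple(
        TouchEvent(t_ms=t0 + 20 * i, x_px=float(x), y_px=float(y))
        for i, (x, y) in enumerate(pts)))


def _log_of_edges(layout, pairs, t0=0):
    pos = layout.positions()
    actions = []
    t = t0
    for a, b in pairs:
        s = _stroke_between(pos[a], pos[b], t0=t)
        actions.append(GraphAction("stroke", t, stroke=s))
        t = s.events[-1].t_ms + 300
    return GraphActionLog(actions=tuple(actions))


class TestConstruction3D:
    def test_perfect_replay_no_errors_similarity_one(self):
        layout, ref = cube_layout(), cube_reference()
        edges = sorted(tuple(sorted(e)) for e in ref.edges)
        score = score_construction_3d(_log_of_edges(layout, edges), ref, layout)
        aux = score.auxiliaries
        assert aux["similarity"] == pytest.approx(1.0)
        for k in ("err_wrong_connection", "err_too_few", "err_too_many", "err_existing"):
            assert aux[k] == 0.0
        assert score.points == 2

    def test_single_node_stroke_counts_too_few(self):
        layout, ref = cube_layout(), cube_reference()
        pos = layout.positions()
        dab = _stroke_between(pos["A"], pos["A"], n=4)
        log = GraphActionLog(actions=(GraphAction("stroke", 0, stroke=dab),))
        score = score_construction_3d(log, ref, layout)
        assert score.auxiliaries["err_too_few"] == 1.0

    def test_repeated_connection_counts_existing(self):
        layout, ref = cube_layout(), cube_reference()
        log = _log_of_edges(layout, [("A", "B"), ("A", "B")])
        score = score_construction_3d(log, ref, layout)
        assert score.auxiliaries["err_existing"] == 1.0

    def test_error_counters_monotone_in_log_prefix(self):
        layout, ref = cube_layout(), cube_reference()
        pairs = [("A", "B"), ("A", "B"), ("A", "C"), ("B", "C"), ("B", "C")]
        full_log = _log_of_edges(layout, pairs)
        keys = ("err_wrong_connection", "err_too_few", "err_too_many", "err_existing")
        prev = {k: 0.0 for k in keys}
        for n in range(1, len(full_log.actions) + 1):
            prefix = GraphActionLog(actions=full_log.actions[:n])
            aux = score_construction_3d(prefix, ref, layout).auxiliaries
            for k in keys:
                assert aux[k] >= prev[k]
                prev[k] = aux[k]


class TestClock:
    square = np.array([(0, 0), (100, 0), (100, 100), (0, 100)], float)

    def test_all_inside_no_errors(self):
        strokes = [_stroke_between((10, 10), (90, 90))]
        score = score_clock(strokes, self.square)
        assert score.auxiliaries["boundary_errors"] == 0.0

    def test_outside_points_counted(self):
        pts = [(50, 50)] * 3 + [(150, 50)] * 5
        stroke = TouchTrajectory(events=tuple(
            TouchEvent(t_ms=10 * i, x_px=float(x), y_px=float(y))
            for i, (x, y) in enumerate(pts)))
        score = score_clock([stroke], self.square)
        assert score.auxiliaries["boundary_errors"] == 5.0

    def test_supervisor_score_passes_through(self):
        score = score_clock([_stroke_between((10, 10), (20, 20))], self.square,
                            supervisor_score=4)
        assert score.points == 4


class TestTrails:
    def _fixture(self):
        labels = ["1", "A", "2", "B"]
        layout = graph_layout([(l, 100 + 150 * i, 100, l) for i, l in enumerate(labels)],
                              node_radius_px=30.0)
        ref = layout.with_edges([("1", "A"), ("A", "2"), ("2", "B")])
        return layout, ref

    def test_straight_paths_zero_frechet_and_similarity_one(self):
        layout, ref = self._fixture()
        log = _log_of_edges(layout, [("1", "A"), ("A", "2"), ("2", "B")])
        score = score_trails(log, layout, ref)
        assert score.auxiliaries["similarity"] == pytest.approx(1.0)
        assert score.auxiliaries["mean_frechet"] == pytest.approx(0.0, abs=1e-9)
        assert score.auxiliaries["err_wrong_connection"] == 0.0

    def test_three_node_stroke_is_wrong_connection_not_path(self):
        layout, ref = self._fixture()
        pos = layout.positions()
        pts = list(np.linspace(pos["1"], pos["2"], 30))  # passes through A
        stroke = TouchTrajectory(events=tuple(
            TouchEvent(t_ms=10 * i, x_px=float(x), y_px=float(y))
            for i, (x, y) in enumerate(pts)))
        log = GraphActionLog(actions=(GraphAction("stroke", 0, stroke=stroke),))
        score = score_trails(log, layout, ref)
        assert score.auxiliaries["n_paths"] == 0.0
        assert score.auxiliaries["err_wrong_connection"] == 1.0


class TestProblemSolving:
    def _fixture(self):
        nodes = [("a", 0, 0), ("b", 100, 0), ("c", 0, 100)]
        start = graph_layout(nodes, edges=[("a", "b")], node_radius_px=20.0)
        goal = graph_layout(nodes, edges=[("a", "c")], node_radius_px=20.0)
        return start, goal

    def _touch_log(self, seq, t0=0):
        return GraphActionLog(actions=tuple(
            GraphAction("node_touch", t0 + 100 * i, node_id=n) for i, n in enumerate(seq)))

    def test_reaching_goal_scores_full(self):
        start, goal = self._fixture()
        log = self._touch_log(["a", "b", "a", "c"])  # remove a-b, insert a-c
        score = score_problem_solving(log, start, goal, ops_budget=2)
        assert score.auxiliaries["similarity"] == pytest.approx(1.0)
        assert score.auxiliaries["goal_reached"] == 1.0
        assert score.points == 2

    def test_disallowed_insert_counts_rule_violation(self):
        start, goal = self._fixture()
        log = self._touch_log(["a", "c"])  # a-c absent -> insert, but only remove allowed
        score = score_problem_solving(log, start, goal, ops_budget=2,
                                      allowed_ops=("remove",))
        assert score.auxiliaries["err_rule_violation"] == 1.0
        assert score.auxiliaries["ops_used"] == 0.0

    def test_same_node_twice_counted(self):
        start, goal = self._fixture()
        log = self._touch_log(["a", "a"])
        score = score_problem_solving(log, start, goal, ops_budget=2)
        assert score.auxiliaries["err_same_node"] == 1.0

    def test_budget_exhaustion_stops_execution(self):
        start, goal = self._fixture()
        log = self._touch_log(["a", "b", "a", "c", "b", "c"])
        score = score_problem_solving(log, start, goal, ops_budget=1)
        assert score.auxiliaries["ops_used"] == 1.0
        assert score.auxiliaries["ops_remaining"] == 0.0
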