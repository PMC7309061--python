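"""Point scoring for the digitized cognitive tasks.

Implements the per-task point rules of the self-administered battery
(orientation, picture naming, similarities/calculation, 3D-figure
construction, clock drawing, verbal fluency, modified trails, problem
solving, delayed memory), Jaro and Jaro-Winkler inexact string matching
for spelling tolerance, and the error-taxonomy counters replayed from the
graph-construction action logs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

from nits.geometry import (
    discrete_frechet,
    fit_line_slope,
    neighbor_matching_similarity,
    parallel_pairs_score,
    resample_by_arc_length,
    resolve_stroke_nodes,
)
from nits.session_io import GraphActionLog, GraphLayout, TouchTrajectory

#: default Jaro-Winkler similarity above which a misspelled answer still
#: earns credit ("knows the name but makes a spelling error")
DEFAULT_JW_THRESHOLD = 0.85


@dataclass
class TaskScore:
    task_id: str
    points: int
    max_points: int
    auxiliaries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.points <= self.max_points:
            raise ValueError("points must satisfy 0 <= points <= max_points")


@dataclass
class AnswerKey:
    """Ground truth for the scored text/numeric tasks."""

    today: tuple[int, int, int] = (2019, 5, 7)
    picture_names: tuple[tuple[str, ...], ...] = (("elephant",), ("volcano",))
    q3_abstract: tuple[str, ...] = ("tools", "instruments", "measuring tools")
    q3_concrete: tuple[str, ...] = ("metal", "long", "hard")
    q4_bill: float = 20.0
    q4_price: float = 13.45
    q5_sum: float = 1.0
    q5_coin: float = 0.05
    fluency_dictionary: tuple[str, ...] = (
        "dog", "cat", "horse", "cow", "sheep", "pig", "goat", "rabbit",
        "lion", "tiger", "bear", "wolf", "fox", "deer", "mouse", "rat",
        "eagle", "owl", "duck", "goose", "hen", "frog", "snake", "fish",
    )
    memory_phrases: tuple[str, ...] = ("have you finished", "are you done")
    memory_keywords: tuple[str, ...] = ("finished", "done")


# ---------------------------------------------------------------------------
# Jaro / Jaro-Winkler


def canonicalize(s: str) -> str:
    """Casefold, trim and collapse whitespace; strip punctuation."""
    s = re.sub(r"[^\w\s]", "", s.casefold())
    return re.sub(r"\s+", " ", s).strip()


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity from character matches and transpositions."""
    if s1 == s2:
        return 1.0
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return 0.0
    window = max(n1, n2) // 2 - 1
    m1 = [False] * n1
    m2 = [False] * n2
    matches = 0
    for i, ch in enumerate(s1):
        lo = max(0, i - window)
        hi = min(n2, i + window + 1)
        for j in range(lo, hi):
            if not m2[j] and s2[j] == ch:
                m1[i] = m2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    a = [c for c, f in zip(s1, m1) if f]
    b = [c for c, f in zip(s2, m2) if f]
    transpositions = sum(x != y for x, y in zip(a, b)) // 2
    m = matches
    return (m / n1 + m / n2 + (m - transpositions) / m) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity boosted for a shared prefix (Winkler modification)."""
    j = jaro(s1, s2)
    if j == 0.0:
        return 0.0
    ell = 0
    for a, b in zip(s1[:max_prefix], s2[:max_prefix]):
        if a != b:
            break
        ell += 1
    return j + ell * prefix_scale * (1.0 - j)


def best_jw(answer: str, candidates: Sequence[str]) -> tuple[float, Optional[str]]:
    """Best Jaro-Winkler match of a canonicalized answer against candidates."""
    a = canonicalize(answer)
    if not a or not candidates:
        return 0.0, None
    scores = [(jaro_winkler(a, canonicalize(c)), c) for c in candidates]
    s, c = max(scores, key=lambda t: t[0])
    return s, c


# ---------------------------------------------------------------------------
# Simple text/numeric scorers


def score_orientation(answer: tuple[int, int, int], today: tuple[int, int, int]) -> TaskScore:
    """One point per correct component of the current date (Y, M, D)."""
    y, m, d = (int(v) for v in answer)
    if not (1 <= m <= 12 and 1 <= d <= 31):
        raise ValueError("unparsable date answer")
    pts = int(y == today[0]) + int(m == today[1]) + int(d == today[2])
    return TaskScore(task_id="T6", points=pts, max_points=3)


def score_picture_naming(
    answers: Sequence[str], key: AnswerKey, jw_threshold: float = DEFAULT_JW_THRESHOLD
) -> TaskScore:
    """One point per picture named correctly, with spelling tolerance.

    Exact (canonicalized) matches earn the point directly; otherwise the
    best Jaro-Winkler similarity against the accepted alternates earns the
    point when it reaches the threshold.  Raw similarities are kept as
    auxiliaries for the spelling feature group.
    """
    if len(answers) != len(key.picture_names):
        raise ValueError(f"expected {len(key.picture_names)} answers")
    pts = 0
    jws = []
    for ans, alternates in zip(answers, key.picture_names):
        a = canonicalize(ans)
        if a in {canonicalize(x) for x in alternates}:
            pts += 1
            jws.append(1.0)
        else:
            jw, _ = best_jw(ans, alternates)
            jws.append(jw)
            if jw >= jw_threshold:
                pts += 1
    aux = {f"jw_{i}": v for i, v in enumerate(jws)}
    aux["jw_average"] = float(np.mean(jws))
    return TaskScore(task_id="T7", points=pts, max_points=len(answers), auxiliaries=aux)


def score_similarities_calculation(
    q3_answer: str,
    q4_answer: Optional[float],
    q5_answer: Optional[float],
    key: AnswerKey,
    jw_threshold: float = DEFAULT_JW_THRESHOLD,
) -> TaskScore:
    """Similarities (abstract 2 / concrete 1) plus two arithmetic questions.

    Q4 asks for the change B - M (tolerance 0.005, currency rounding); Q5
    asks for the exact integer count S / D.
    """
    jw_abs, _ = best_jw(q3_answer, key.q3_abstract)
    jw_con, _ = best_jw(q3_answer, key.q3_concrete)
    if jw_abs >= jw_threshold:  # abstract beats concrete on a double match
        q3_pts = 2
    elif jw_con >= jw_threshold:
        q3_pts = 1
    else:
        q3_pts = 0
    q4_ok = q4_answer is not None and abs(float(q4_answer) - (key.q4_bill - key.q4_price)) <= 0.005
    expected_coins = key.q5_sum / key.q5_coin
    q5_ok = (
        q5_answer is not None
        and float(q5_answer) == float(int(round(expected_coins)))
    )
    pts = q3_pts + int(q4_ok) + int(q5_ok)
    return TaskScore(
        task_id="T8",
        points=pts,
        max_points=4,
        auxiliaries={
            "q3_points": float(q3_pts),
            "q4_points": float(q4_ok),
            "q5_points": float(q5_ok),
            "jw_average": float(max(jw_abs, jw_con)),
        },
    )


def score_memory(answer: str, key: AnswerKey) -> TaskScore:
    """Delayed-recall phrase: 2 for exact wording, 1 for a keyword, else 0."""
    a = canonicalize(answer)
    if a in {canonicalize(p) for p in key.memory_phrases}:
        pts = 2
    elif any(k in a.split() for k in key.memory_keywords):
        pts = 1
    else:
        pts = 0
    return TaskScore(task_id="T0", points=pts, max_points=2)


def score_verbal_fluency(
    items: Sequence[str],
    dictionary: Sequence[str],
    jw_threshold: float = DEFAULT_JW_THRESHOLD,
) -> TaskScore:
    """Category fluency: 12 slots scored against a category word list.

    2 points for 12 distinct valid items, 1 point for 10 or 11, else 0.
    The auxiliary is the mean of the 12 per-item Jaro-Winkler similarities
    to the closest dictionary entry (blank slots contribute 0).
    """
    if len(items) != 12:
        raise ValueError("verbal fluency expects exactly 12 slots")
    canon_dict = [canonicalize(w) for w in dictionary]
    seen: set[str] = set()
    n_correct = 0
    jws = []
    for raw in items:
        a = canonicalize(raw)
        if not a:
            jws.append(0.0)
            continue
        if len(a.split()) > 3:
            jws.append(0.0)  # invalid slot: more than three words
            continue
        if a in canon_dict:
            jw, match = 1.0, a
        else:
            jw = 0.0
            match = None
            for w in canon_dict:
                s = jaro_winkler(a, w)
                if s > jw:
                    jw, match = s, w
        jws.append(jw)
        if jw >= jw_threshold and match is not None and match not in seen:
            seen.add(match)
            n_correct += 1
    if n_correct >= 12:
        pts = 2
    elif n_correct >= 10:
        pts = 1
    else:
        pts = 0
    return TaskScore(
        task_id="T11",
        points=pts,
        max_points=2,
        auxiliaries={"jw_average": float(np.mean(jws)), "n_correct": float(n_correct)},
    )


def encode_insights(questionnaire: dict[str, Any], schema: Sequence[tuple[str, Sequence[str]]]) -> list[float]:
    """Deterministic ordinal encoding of the non-scored insight questionnaire.

    ``schema`` fixes the field order and the admissible categorical levels;
    each field is encoded as its level index (0-based).
    """
    out = []
    for name, levels in schema:
        if name not in questionnaire:
            raise ValueError(f"missing mandatory questionnaire field {name!r}")
        val = questionnaire[name]
        if val not in levels:
            raise ValueError(f"field {name!r}: unknown level {val!r}")
        out.append(float(list(levels).index(val)))
    return out


# ---------------------------------------------------------------------------
# Graph-task replays (construction / trails / problem solving)


@dataclass
class GraphReplay:
    """Outcome of replaying a construction/trails action log."""

    edges: list[tuple[str, str]]
    error_counts: dict[str, int]
    per_stroke_nodes: list[list[str]]
    formed_paths: list[tuple[TouchTrajectory, tuple[str, str]]]


def _replay_strokes(
    log: GraphActionLog, layout: GraphLayout, counters: dict[str, int]
) -> GraphReplay:
    edges: list[tuple[str, str]] = []
    edge_set: set[frozenset[str]] = set()
    per_stroke = []
    formed = []
    for action in log.actions:
        if action.kind != "stroke":
            continue
        nodes = resolve_stroke_nodes(action.stroke, layout)
        per_stroke.append(nodes)
        if len(nodes) == 0:
            counters["outside"] = counters.get("outside", 0) + 1
        elif len(nodes) == 1:
            counters["too_few"] = counters.get("too_few", 0) + 1
        elif len(nodes) > 2:
            counters["too_many"] = counters.get("too_many", 0) + 1
        else:
            a, b = nodes
            fs = frozenset((a, b))
            if fs in edge_set:
                counters["existing"] = counters.get("existing", 0) + 1
            else:
                edge_set.add(fs)
                edges.append((a, b))
                formed.append((action.stroke, (a, b)))
    return GraphReplay(edges=edges, error_counts=counters, per_stroke_nodes=per_stroke, formed_paths=formed)


def _similarity_points(similarity: float, errors: int) -> int:
    """Map replay quality to battery points (max 2): documented convention."""
    if similarity >= 0.95 and errors == 0:
        return 2
    if similarity >= 0.8:
        return 1
    return 0


def score_construction_3d(
    log: GraphActionLog,
    reference: GraphLayout,
    layout: GraphLayout,
    parallel_pairs: Optional[Sequence[tuple[int, int]]] = None,
    angle_tol_deg: float = 10.0,
    match_pct: float = 0.5,
) -> TaskScore:
    """Replay the 3D-figure construction and count the four error kinds.

    Errors: wrongly connected nodes (an edge absent from the reference),
    too few nodes in a stroke, too many nodes in a stroke, and re-drawing
    an already existing connection.  Auxiliaries carry the
    neighbor-matching similarity against the reference figure and the
    parallel-pairs score over the designated (default 9) edge pairs.
    """
    counters = {"wrong_connection": 0, "too_few": 0, "too_many": 0, "existing": 0, "outside": 0}
    replay = _replay_strokes(log, layout, counters)
    ref_edges = {frozenset(e) for e in reference.edges}
    for a, b in replay.edges:
        if frozenset((a, b)) not in ref_edges:
            counters["wrong_connection"] += 1
    drawn = layout.with_edges(replay.edges)
    sim = neighbor_matching_similarity(drawn, reference)

    aux: dict[str, float] = {"similarity": sim, "n_edges": float(len(replay.edges))}
    # parallel check over the designated reference pairs that were drawn
    if parallel_pairs:
        slopes = [fit_line_slope(stroke.xy()) for stroke, _ in replay.formed_paths]
        edge_index = {frozenset(e): i for i, (_, e) in enumerate(replay.formed_paths)}
        ref_edge_list = sorted(tuple(sorted(e)) for e in reference.edges)
        usable = []
        for i, j in parallel_pairs:
            ei = frozenset(ref_edge_list[i])
            ej = frozenset(ref_edge_list[j])
            if ei in edge_index and ej in edge_index:
                usable.append((edge_index[ei], edge_index[ej]))
        if usable:
            frac, ok = parallel_pairs_score(slopes, usable, angle_tol_deg, match_pct)
        else:
            frac, ok = 0.0, False
        aux["parallel_fraction"] = frac
        aux["parallel_pass"] = float(ok)
    total_errors = sum(
        counters[k] for k in ("wrong_connection", "too_few", "too_many", "existing")
    )
    aux.update({f"err_{k}": float(v) for k, v in counters.items()})
    pts = _similarity_points(sim, total_errors)
    return TaskScore(task_id="T9", points=pts, max_points=2, auxiliaries=aux)


def _point_in_polygon(pt: np.ndarray, poly: np.ndarray) -> bool:
    # ray casting
    x, y = pt
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
            if x < xin:
                inside = not inside
    return inside


def score_clock(
    strokes: Sequence[TouchTrajectory],
    active_contour: np.ndarray,
    supervisor_score: Optional[int] = None,
) -> TaskScore:
    """Clock-drawing: automatic boundary-error counter.

    Counts stroke points falling outside the active drawing contour.  The
    clinical clock score proper is supervised; when supplied it is stored
    unchanged, otherwise a coarse automatic surrogate from the boundary
    error count is used (2 / 1 / 0 for 0 / <5 / >=5 errors).
    """
    poly = np.asarray(active_contour, dtype=float)
    n_outside = 0
    for s in strokes:
        for pt in s.xy():
            if not _point_in_polygon(pt, poly):
                n_outside += 1
    if supervisor_score is not None:
        pts, mx = int(supervisor_score), max(int(supervisor_score), 2)
    else:
        pts, mx = (2 if n_outside == 0 else 1 if n_outside < 5 else 0), 2
    return TaskScore(
        task_id="T10",
        points=pts,
        max_points=mx,
        auxiliaries={
            "boundary_errors": float(n_outside),
            "supervisor_score": float(supervisor_score) if supervisor_score is not None else float("nan"),
        },
    )


def score_trails(log: GraphActionLog, layout: GraphLayout, reference: GraphLayout) -> TaskScore:
    """Modified trails: alternate numbers and letters by free-drawn paths.

    A stroke forms a path only when exactly two nodes are touched.  Error
    counters: wrongly connected nodes, clicking the same node, clicks
    outside a node.  Auxiliaries: neighbor-matching similarity against the
    reference chain and the mean discrete Frechet distance between each
    formed path and the straight segment joining its node centers.
    """
    counters = {"wrong_connection": 0, "same_node": 0, "outside": 0, "too_few": 0,
                "too_many": 0, "existing": 0}
    replay = _replay_strokes(log, layout, counters)
    # strokes that started and ended on one node = "same node" clicks
    counters["same_node"] += counters.pop("too_few")
    # >2 nodes or an unknown pairing = wrong connection
    counters["wrong_connection"] += counters.pop("too_many") + counters.pop("existing")
    ref_edges = {frozenset(e) for e in reference.edges}
    for a, b in replay.edges:
        if frozenset((a, b)) not in ref_edges:
            counters["wrong_connection"] += 1
    pos = layout.positions()
    frechets = []
    for stroke, (a, b) in replay.formed_paths:
        # both curves on a common 64-point arc-length grid: the ideal
        # straight path is the linear interpolation between the node centers
        seg = np.linspace(pos[a], pos[b], 64)
        frechets.append(discrete_frechet(resample_by_arc_length(stroke.xy(), 64), seg))
    drawn = layout.with_edges(replay.edges)
    sim = neighbor_matching_similarity(drawn, reference)
    n_err = counters["wrong_connection"] + counters["same_node"] + counters["outside"]
    aux = {
        "similarity": sim,
        "n_paths": float(len(replay.formed_paths)),
        "mean_frechet": float(np.mean(frechets)) if frechets else 0.0,
        "max_frechet": float(np.max(frechets)) if frechets else 0.0,
    }
    aux.update({f"err_{k}": float(v) for k, v in counters.items()})
    return TaskScore(task_id="T12", points=_similarity_points(sim, n_err), max_points=2, auxiliaries=aux)


def score_problem_solving(
    log: GraphActionLog,
    start: GraphLayout,
    goal: GraphLayout,
    ops_budget: int,
    allowed_ops: tuple[str, ...] = ("insert", "remove"),
) -> TaskScore:
    """Match-moving puzzle: sequential node touches insert/remove edges.

    Two consecutive in-zone touches of distinct nodes execute an insert
    (edge absent) or remove (edge present), when that operation is allowed
    for the puzzle; execution stops when the operation budget is spent.
    Errors: touching the same node twice, touching outside any node zone,
    and violating the allowed-operation rules.
    """
    if ops_budget < 0:
        raise ValueError("ops_budget must be >= 0")
    counters = {"same_node": 0, "outside_zone": 0, "rule_violation": 0}
    edges = {frozenset(e) for e in start.edges}
    pos = start.positions()
    radius = start.node_radius_px
    pending: Optional[str] = None
    ops_left = ops_budget
    n_ops = 0
    for action in log.actions:
        if ops_left <= 0:
            break
        if action.kind == "node_touch":
            touched = action.node_id
        else:
            pts = action.stroke.xy()
            touched = None
            for nid, c in pos.items():
                if np.linalg.norm(pts[0] - c) <= radius:
                    touched = nid
                    break
        if touched is None:
            counters["outside_zone"] += 1
            continue
        if pending is None:
            pending = touched
            continue
        if touched == pending:
            counters["same_node"] += 1
            pending = None
            continue
        fs = frozenset((pending, touched))
        op = "remove" if fs in edges else "insert"
        if op not in allowed_ops:
            counters["rule_violation"] += 1
        else:
            if op == "insert":
                edges.add(fs)
            else:
                edges.discard(fs)
            n_ops += 1
            ops_left -= 1
        pending = None
    final = start.with_edges(tuple(tuple(sorted(e)) for e in edges))
    sim = neighbor_matching_similarity(final, goal)
    goal_reached = {frozenset(e) for e in goal.edges} == edges
    n_err = sum(counters.values())
    aux = {
        "similarity": sim,
        "ops_used": float(n_ops),
        "ops_remaining": float(ops_left),
        "goal_reached": float(goal_reached),
    }
    aux.update({f"err_{k}": float(v) for k, v in counters.items()})
    pts = 2 if goal_reached and n_err == 0 else (1 if sim >= 0.8 else 0)
    return TaskScore(task_id="T13", points=pts, max_points=2, auxiliaries=aux)
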