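"""Synthetic subjects, sessions, voices and cohorts.

The study population the battery targets (a small cohort of healthy
controls and patients with central-nervous-system disorders, each visited
five times) is emulated with class-conditional generators: impaired
sessions carry larger 4-8 Hz hand tremor, longer response latencies, more
typos and task errors, perturbed voice (jitter/shimmer, lower
harmonics-to-noise ratio), and a negative daily calorie balance.  Every
generator is a pure function of its parameters and a seed, and setting the
impaired parameters equal to the healthy ones yields exchangeable classes
(the null used to guard against label leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from nits.feature_table import FeatureVector, extract_features
from nits.geometry import SpiralSpec, generate_spiral
from nits.sage_scoring import AnswerKey
from nits.session_io import (
    AudioClip,
    GraphAction,
    GraphActionLog,
    GraphLayout,
    SessionRecord,
    SubjectProfile,
    TouchTrajectory,
    graph_layout,
    trajectory_from_arrays,
)

SCREEN_W, SCREEN_H = 1280.0, 800.0  # 10" tablet, the recommended device


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional generator parameters (one per diagnosis class)."""

    tremor_amp_px: float = 1.0       # lateral 4-8 Hz tremor amplitude
    tremor_freq_hz: float = 5.0      # within the pathological 4-8 Hz band
    jitter_px: float = 0.5           # white positional jitter, sd
    latency_ms: float = 500.0        # mean response latency
    speed_px_s: float = 400.0        # drawing speed
    typo_rate: float = 0.02          # per-character typo probability
    error_rate: float = 0.02         # per-action graph-task error probability
    blank_rate: float = 0.0          # fluency slots left empty
    voice_jitter_pct: float = 0.5    # cycle-to-cycle f0 perturbation
    voice_shimmer_pct: float = 3.0   # cycle-to-cycle amplitude perturbation
    voice_hnr_db: float = 25.0       # harmonics-to-noise ratio
    calorie_balance_kcal: float = 100.0  # mean daily balance


HEALTHY_PROFILE = ClassProfile()
IMPAIRED_PROFILE = ClassProfile(
    tremor_amp_px=6.0,
    tremor_freq_hz=6.0,
    jitter_px=2.0,
    latency_ms=900.0,
    speed_px_s=250.0,
    typo_rate=0.20,
    error_rate=0.25,
    blank_rate=0.15,
    voice_jitter_pct=3.0,
    voice_shimmer_pct=10.0,
    voice_hnr_db=10.0,
    calorie_balance_kcal=-400.0,
)


@dataclass(frozen=True)
class CohortProfile:
    """Cohort composition and the two class-conditional parameter sets."""

    n_healthy: int = 89
    n_impaired: int = 61
    n_healthy_subjects: int = 8
    n_impaired_subjects: int = 7
    healthy: ClassProfile = HEALTHY_PROFILE
    impaired: ClassProfile = IMPAIRED_PROFILE
    seed: int = 0

    def null(self) -> "CohortProfile":
        """Zero-effect variant: impaired parameters equal the healthy ones."""
        return replace(self, impaired=self.healthy)


# ---------------------------------------------------------------------------
# Trajectories and voices


def simulate_trajectory(
    reference: np.ndarray, profile: ClassProfile, seed: int, t0_ms: float = 0.0
) -> TouchTrajectory:
    """Reference path + sinusoidal tremor + white jitter, timed at drawing speed.

    With zero tremor amplitude and zero jitter the points equal the
    reference exactly; timestamps are always strictly increasing.
    """
    rng = np.random.default_rng(seed)
    ref = np.asarray(reference, dtype=float)
    n = len(ref)
    seg = np.linalg.norm(np.diff(ref, axis=0), axis=1) if n > 1 else np.array([0.0])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = t0_ms + 1000.0 * s / profile.speed_px_s + np.arange(n) * 1e-3
    # unit normals to the path for lateral tremor
    if n > 1:
        tang = np.gradient(ref, axis=0)
        norm = np.column_stack([-tang[:, 1], tang[:, 0]])
        ln = np.linalg.norm(norm, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        norm = norm / ln
    else:
        norm = np.zeros((1, 2))
    phase = rng.uniform(0, 2 * np.pi)
    tremor = profile.tremor_amp_px * np.sin(
        2 * np.pi * profile.tremor_freq_hz * (t - t0_ms) / 1000.0 + phase)
    jitter = rng.normal(0.0, profile.jitter_px, size=(n, 2)) if profile.jitter_px > 0 else 0.0
    xy = ref + norm * tremor[:, None] + jitter
    return trajectory_from_arrays(np.round(t).astype(int), xy)


def simulate_voice(
    profile: ClassProfile, duration_s: float = 2.0, f0_hz: float = 150.0,
    seed: int = 0, rate_hz: int = 48000,
) -> AudioClip:
    """Glottal-style impulse train with jitter, shimmer and additive noise.

    Cycle periods are perturbed by ``voice_jitter_pct`` and cycle
    amplitudes by ``voice_shimmer_pct``; the pulse train is colored by two
    vocal-tract-like resonances and mixed with white noise at the target
    harmonics-to-noise ratio.
    """
    if duration_s < 1.0:
        raise ValueError("duration must be >= 1 s")
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate_hz)
    x = np.zeros(n)
    pos = 0.0
    while pos < n:
        period = rate_hz / f0_hz
        period *= 1.0 + rng.normal(0.0, profile.voice_jitter_pct / 100.0)
        amp = 1.0 + rng.normal(0.0, profile.voice_shimmer_pct / 100.0)
        i = int(round(pos))
        if i < n:
            x[i] = amp
        pos += max(period, 2.0)
    # two damped resonances shape the harmonic spectrum
    from scipy.signal import lfilter

    for fc, bw in ((500.0, 80.0), (1500.0, 120.0)):
        r = np.exp(-np.pi * bw / rate_hz)
        theta = 2 * np.pi * fc / rate_hz
        a = [1.0, -2 * r * np.cos(theta), r * r]
        x = lfilter([1.0], a, x)
    x /= np.max(np.abs(x)) + 1e-12
    p_sig = float(np.mean(x ** 2))
    p_noise = p_sig / (10.0 ** (profile.voice_hnr_db / 10.0))
    x = x + rng.normal(0.0, np.sqrt(p_noise), size=n)
    x /= np.max(np.abs(x)) + 1e-12
    return AudioClip(samples=x, rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# Text helpers


def _typo(word: str, rate: float, rng: np.random.Generator) -> str:
    """Per-character substitution/transposition typo model."""
    chars = list(word)
    i = 0
    while i < len(chars):
        if chars[i].isalpha() and rng.random() < rate:
            if rng.random() < 0.5 and i + 1 < len(chars):
                chars[i], chars[i + 1] = chars[i + 1], chars[i]
                i += 1
            else:
                chars[i] = chr(ord("a") + rng.integers(26))
        i += 1
    return "".join(chars)


# ---------------------------------------------------------------------------
# Graph-layout fixtures


def cube_layout() -> GraphLayout:
    """Eight nodes positioned as the 2D projection of a cube (no edges)."""
    pts = {
        "A": (400, 500), "B": (700, 500), "C": (700, 250), "D": (400, 250),
        "E": (520, 420), "F": (820, 420), "G": (820, 170), "H": (520, 170),
    }
    return graph_layout([(k, x, y) for k, (x, y) in pts.items()], node_radius_px=36.0)


def cube_reference() -> GraphLayout:
    edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"),
             ("E", "F"), ("F", "G"), ("G", "H"), ("H", "E"),
             ("A", "E"), ("B", "F"), ("C", "G"), ("D", "H")]
    return cube_layout().with_edges(edges)


#: the 9 designated parallel edge pairs of the cube reference (indices into
#: the sorted edge list), a configured convention
CUBE_PARALLEL_PAIRS = ((0, 2), (0, 6), (2, 6), (1, 3), (1, 7), (3, 7), (4, 5), (4, 8), (5, 8))


def trails_layout() -> tuple[GraphLayout, GraphLayout]:
    """1-A-2-B-3-C-4-D alternating layout and its reference chain."""
    labels = ["1", "A", "2", "B", "3", "C", "4", "D"]
    rng = np.random.default_rng(7)  # fixed decorative placement
    nodes = []
    for i, lab in enumerate(labels):
        x = 180 + 130 * i + rng.uniform(-20, 20)
        y = 400 + 220 * np.sin(i * 2.2)
        nodes.append((lab, x, y, lab))
    layout = graph_layout(nodes, node_radius_px=36.0)
    ref = layout.with_edges([(labels[i], labels[i + 1]) for i in range(len(labels) - 1)])
    return layout, ref


def matches_puzzle() -> tuple[GraphLayout, GraphLayout, int]:
    """A small match-moving puzzle: start shape, goal shape, op budget."""
    nodes = [("N1", 300, 300), ("N2", 450, 300), ("N3", 600, 300),
             ("N4", 300, 450), ("N5", 450, 450), ("N6", 600, 450)]
    start = graph_layout(nodes, edges=[("N1", "N2"), ("N2", "N3"), ("N4", "N5"),
                                       ("N5", "N6"), ("N1", "N4"), ("N2", "N5")],
                         node_radius_px=36.0)
    goal = start.with_edges([("N1", "N2"), ("N2", "N3"), ("N4", "N5"),
                             ("N5", "N6"), ("N2", "N5"), ("N3", "N6")])
    return start, goal, 4


# ---------------------------------------------------------------------------
# Session generator


def _edge_stroke(layout: GraphLayout, a: str, b: str, profile: ClassProfile,
                 seed: int, t0: float, n_pts: int = 24) -> TouchTrajectory:
    pos = layout.positions()
    line = np.linspace(pos[a], pos[b], n_pts)
    return simulate_trajectory(line, profile, seed, t0_ms=t0)


def _graph_log_for_edges(
    layout: GraphLayout, edges: list[tuple[str, str]], profile: ClassProfile,
    rng: np.random.Generator,
) -> GraphActionLog:
    """Draw the reference edges, injecting error strokes at the class rate."""
    actions = []
    t = 0.0
    node_ids = list(layout.node_ids)
    drawn: set[frozenset] = set()
    for a, b in edges:
        t += profile.latency_ms * (1.0 + rng.uniform(-0.2, 0.2))
        if rng.random() < profile.error_rate:
            kind = rng.integers(3)
            if kind == 0:  # wrong connection
                c, d = rng.choice(node_ids, size=2, replace=False)
                if frozenset((c, d)) not in drawn and frozenset((c, d)) != frozenset((a, b)):
                    s = _edge_stroke(layout, c, d, profile, int(rng.integers(2**31)), t)
                    actions.append(GraphAction("stroke", int(s.t()[0]), stroke=s))
                    drawn.add(frozenset((c, d)))
                    t = s.t()[-1]
            elif kind == 1:  # too few nodes: a short dab on one node
                c = rng.choice(node_ids)
                p = layout.positions()[c]
                dab = np.tile(p, (4, 1))
                s = simulate_trajectory(dab, profile, int(rng.integers(2**31)), t0_ms=t)
                actions.append(GraphAction("stroke", int(s.t()[0]), stroke=s))
                t = s.t()[-1]
            else:  # repeat an existing connection
                if drawn:
                    prior = sorted(tuple(sorted(e)) for e in drawn)
                    c, d = prior[int(rng.integers(len(prior)))]
                    s = _edge_stroke(layout, c, d, profile, int(rng.integers(2**31)), t)
                    actions.append(GraphAction("stroke", int(s.t()[0]), stroke=s))
                    t = s.t()[-1]
        s = _edge_stroke(layout, a, b, profile, int(rng.integers(2**31)), t)
        actions.append(GraphAction("stroke", int(s.t()[0]), stroke=s))
        drawn.add(frozenset((a, b)))
        t = s.t()[-1]
    return GraphActionLog(actions=tuple(actions))


def _clock_payload(profile: ClassProfile, rng: np.random.Generator) -> dict:
    cx, cy, R = SCREEN_W / 2, SCREEN_H / 2, 260.0
    th = np.linspace(0, 2 * np.pi, 48)
    contour = np.column_stack([cx + R * np.cos(th), cy + R * np.sin(th)])
    face_r = R - 10.0  # drawing margin inside the active contour
    th2 = np.linspace(0, 2 * np.pi, 80)
    face = np.column_stack([cx + face_r * np.cos(th2), cy + face_r * np.sin(th2)])
    strokes = [simulate_trajectory(face, profile, int(rng.integers(2**31)))]
    for ang, ln in ((rng.uniform(0, 2 * np.pi), 0.45 * R), (rng.uniform(0, 2 * np.pi), 0.7 * R)):
        hand = np.linspace([cx, cy], [cx + ln * np.cos(ang), cy + ln * np.sin(ang)], 20)
        t0 = strokes[-1].t()[-1] + profile.latency_ms
        strokes.append(simulate_trajectory(hand, profile, int(rng.integers(2**31)), t0_ms=t0))
    return {"strokes": strokes, "contour": contour.tolist()}


def simulate_session(
    profile: ClassProfile,
    subject: SubjectProfile,
    seed: int,
    round_index: int = 1,
    keys: Optional[AnswerKey] = None,
    include_audio: bool = False,
) -> SessionRecord:
    """Generate all 16 task payloads for one visit of one subject."""
    rng = np.random.default_rng(seed)
    keys = keys or AnswerKey()
    tasks: dict = {}

    # T1: sequential touch on 2/3/5 circles
    layouts = []
    for k in (2, 3, 5):
        targets = rng.uniform([100, 100], [SCREEN_W - 100, SCREEN_H - 100], size=(k, 2))
        taps = []
        t = 0.0
        for tx, ty in targets:
            t += profile.latency_ms * (1.0 + rng.uniform(-0.2, 0.4))
            off = rng.normal(0, profile.tremor_amp_px + profile.jitter_px + 2.0, 2)
            if rng.random() < profile.error_rate:
                off = off + rng.uniform(60, 120, 2) * rng.choice([-1, 1], 2)
            taps.append([t, tx + off[0], ty + off[1]])
        layouts.append({"n_circles": k, "radius_px": 60.0,
                        "targets": targets.tolist(), "taps": taps})
    tasks["T1"] = {"layouts": layouts}

    # T2: rainbow color touch, 5 redraws
    trials = []
    t = 0.0
    for _ in range(5):
        target = rng.uniform([100, 100], [SCREEN_W - 100, SCREEN_H - 100])
        rt = profile.latency_ms * (1.0 + abs(rng.normal(0, 0.3)))
        off = rng.normal(0, profile.tremor_amp_px + profile.jitter_px + 2.0, 2)
        trials.append({"t_shown_ms": t, "tap": [t + rt, target[0] + off[0], target[1] + off[1]],
                       "target": target.tolist()})
        t += rt + 400.0
    tasks["T2"] = {"trials": trials}

    # T3: multi-touch, 7 objects
    objects = []
    for _ in range(7):
        target = rng.uniform([100, 100], [SCREEN_W - 100, SCREEN_H - 100])
        off = rng.normal(0, profile.tremor_amp_px + profile.jitter_px + 2.0, 2)
        objects.append({
            "target": target.tolist(),
            "tap": [0.0, target[0] + off[0], target[1] + off[1]],
            "reaction_ms": profile.latency_ms * (1.0 + abs(rng.normal(0, 0.3))),
            "hold_ms": 120.0 + abs(rng.normal(0, 40.0)) + 0.2 * profile.latency_ms,
            "missed": bool(rng.random() < profile.error_rate),
        })
    tasks["T3"] = {"objects": objects}

    # T4: spiral follow + draw
    spec = SpiralSpec(center=(SCREEN_W / 2, SCREEN_H / 2),
                      spacing_px=0.4 * SCREEN_H / 3.0, turns=3.0, n_points=200)
    ref = generate_spiral(spec)
    tasks["T4"] = {
        "follow": {"reference": ref.tolist(),
                   "trajectory": simulate_trajectory(ref, profile, int(rng.integers(2**31)))},
        "draw": {"reference": ref.tolist(),
                 "trajectory": simulate_trajectory(ref, _drawing_profile(profile), int(rng.integers(2**31)))},
    }

    # T5: insights questionnaire (non-scored)
    tasks["T5"] = {"questionnaire": {
        "memory_problems": str(rng.choice(["no", "sometimes", "often"])),
        "depression": str(rng.choice(["no", "yes"])),
        "motor_symptoms": str(rng.choice(["no", "yes"])),
    }}

    # T6: orientation (date)
    y0, m0, d0 = keys.today
    ans = [y0, m0, d0]
    for i, span in enumerate((1, 2, 3)):
        if rng.random() < profile.error_rate:
            ans[i] += int(rng.integers(1, span + 1))
    tasks["T6"] = {"answer": ans}

    # T7: picture naming with typos
    answers = []
    for alternates in keys.picture_names:
        if rng.random() < profile.error_rate:
            answers.append("unknown")
        else:
            answers.append(_typo(alternates[0], profile.typo_rate, rng))
    tasks["T7"] = {"answers": answers}

    # T8: similarities + calculation
    if rng.random() < profile.error_rate:
        q3 = "something"
    elif rng.random() < 0.7:
        q3 = _typo(keys.q3_abstract[0], profile.typo_rate, rng)
    else:
        q3 = _typo(keys.q3_concrete[0], profile.typo_rate, rng)
    q4 = keys.q4_bill - keys.q4_price + (0.0 if rng.random() > profile.error_rate
                                         else round(rng.uniform(0.5, 3.0), 2))
    q5 = keys.q5_sum / keys.q5_coin + (0 if rng.random() > profile.error_rate
                                       else int(rng.integers(1, 5)))
    tasks["T8"] = {"q3": q3, "q4": float(q4), "q5": float(q5)}

    # T9: cube construction
    layout = cube_layout()
    reference = cube_reference()
    edges = [tuple(sorted(e)) for e in sorted(tuple(sorted(x)) for x in reference.edges)]
    tasks["T9"] = {
        "layout": layout, "reference": reference,
        "log": _graph_log_for_edges(layout, edges, profile, rng),
        "parallel_pairs": [list(p) for p in CUBE_PARALLEL_PAIRS],
    }

    # T10: clock drawing
    tasks["T10"] = _clock_payload(profile, rng)

    # T11: verbal fluency
    words = list(rng.choice(keys.fluency_dictionary, size=12, replace=False))
    items = []
    for w in words:
        if rng.random() < profile.blank_rate:
            items.append("")
        else:
            items.append(_typo(str(w), profile.typo_rate, rng))
    tasks["T11"] = {"items": items, "category": "animals"}

    # T12: modified trails
    tlay, tref = trails_layout()
    tedges = [tuple(sorted(e)) for e in sorted(tuple(sorted(x)) for x in tref.edges)]
    seq_edges = [("1", "A"), ("A", "2"), ("2", "B"), ("B", "3"),
                 ("3", "C"), ("C", "4"), ("4", "D")]
    tasks["T12"] = {
        "layout": tlay, "reference": tref,
        "log": _graph_log_for_edges(tlay, seq_edges, profile, rng),
    }

    # T13: problem solving (insert/remove to reach the goal)
    start, goal, budget = matches_puzzle()
    start_e = {frozenset(e) for e in start.edges}
    goal_e = {frozenset(e) for e in goal.edges}
    moves = [tuple(sorted(e)) for e in (start_e - goal_e)] + \
            [tuple(sorted(e)) for e in (goal_e - start_e)]
    actions = []
    t = 0.0
    for a, b in moves:
        for nid in (a, b):
            t += profile.latency_ms * (1.0 + rng.uniform(-0.2, 0.2))
            if rng.random() < profile.error_rate:
                actions.append(GraphAction("node_touch", int(t), node_id=nid))
                t += 150.0  # double touch = same-node error
            actions.append(GraphAction("node_touch", int(t), node_id=nid))
    tasks["T13"] = {"start": start, "goal": goal, "ops_budget": budget,
                    "log": GraphActionLog(actions=tuple(actions))}

    # T14: voice recordings (optional, heavy)
    if include_audio:
        f0 = 120.0 if subject.gender == "man" else 200.0
        tasks["T14"] = {"clips": [
            simulate_voice(profile, 2.0, f0, int(rng.integers(2**31))),
            simulate_voice(profile, 2.0, f0, int(rng.integers(2**31))),
        ]}

    # T15: food/activity diary tuned to the class calorie balance
    from nits.energy import bmr as bmr_fn, tdee as tdee_fn

    target_balance = profile.calorie_balance_kcal + rng.normal(0, 60.0)
    burned_target = 250.0 + abs(rng.normal(0, 80.0))
    met = 3.5
    minutes = burned_target / (met * subject.weight_kg / 60.0)
    gained_target = target_balance + met * subject.weight_kg * minutes / 60.0
    gained_target = max(gained_target, 50.0)
    n_items = 3
    tasks["T15"] = {
        "products": [
            {"name": f"item{i}", "grams": 100.0 * gained_target / n_items / 250.0,
             "kcal_per_100g": 250.0, "mealtime": mt}
            for i, mt in enumerate(("breakfast", "dinner", "supper"))
        ],
        "activities": [
            {"name": "walking", "met": met, "minutes": float(minutes), "time_of_day": "day"},
        ],
    }

    # T0: delayed memory phrase
    r = rng.random()
    if r < profile.error_rate:
        answer = "hello"
    elif r < 2 * profile.error_rate:
        answer = "i am done now"
    else:
        answer = keys.memory_phrases[0]
    tasks["T0"] = {"answer": answer}

    base_durations = {
        "T0": 10, "T1": 20, "T2": 25, "T3": 20, "T4": 30, "T5": 60, "T6": 20,
        "T7": 40, "T8": 90, "T9": 120, "T10": 90, "T11": 120, "T12": 90,
        "T13": 90, "T14": 60, "T15": 180,
    }
    scale = profile.latency_ms / 500.0
    durations = {k: float(v * scale * (1.0 + abs(rng.normal(0, 0.15))))
                 for k, v in base_durations.items()}
    return SessionRecord(profile=subject, round_index=round_index,
                         tasks=tasks, durations_s=durations)


def _drawing_profile(profile: ClassProfile) -> ClassProfile:
    """Memory-drawing variant: same tremor, looser reproduction."""
    return replace(profile, jitter_px=profile.jitter_px + 2.0)


def random_subject(subject_id: str, label: int, rng: np.random.Generator) -> SubjectProfile:
    """Demographics drawn identically for both classes (no label leakage)."""
    gender = str(rng.choice(["man", "woman"]))
    return SubjectProfile(
        subject_id=subject_id,
        gender=gender,
        age_years=int(rng.integers(20, 76)),
        height_m=float(rng.normal(1.75 if gender == "man" else 1.63, 0.07)),
        weight_kg=float(rng.normal(80.0 if gender == "man" else 66.0, 10.0)),
        pal=str(rng.choice(["sedentary", "light", "moderate"])),
        label=label,
    )


def simulate_cohort(
    cohort: CohortProfile = CohortProfile(),
    keys: Optional[AnswerKey] = None,
    include_audio: bool = False,
) -> list[FeatureVector]:
    """Generate sessions for the whole cohort and extract the feature table.

    Records are distributed round-robin over the subjects of each class
    (five visit rounds cycling), every session is scored through the full
    extraction pipeline, and the labeled 238-feature vectors are returned.
    """
    rng = np.random.default_rng(cohort.seed)
    keys = keys or AnswerKey()
    subjects = {
        0: [random_subject(f"H{i+1:02d}", 0, rng) for i in range(cohort.n_healthy_subjects)],
        1: [random_subject(f"S{i+1:02d}", 1, rng) for i in range(cohort.n_impaired_subjects)],
    }
    plan = [(0, i) for i in range(cohort.n_healthy)] + [(1, i) for i in range(cohort.n_impaired)]
    vectors = []
    for label, i in plan:
        subs = subjects[label]
        subject = subs[i % len(subs)]
        profile = cohort.healthy if label == 0 else cohort.impaired
        session = simulate_session(
            profile, subject, seed=int(rng.integers(2**31)),
            round_index=(i // len(subs)) % 5 + 1, keys=keys,
            include_audio=include_audio,
        )
        vectors.append(extract_features(session, keys=keys))
    return vectors
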