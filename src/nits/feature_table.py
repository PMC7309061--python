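"""Canonical 238-feature schema and session-to-vector extraction.

The battery summarizes one session into 238 features across 14 groups:

====================  ====
group                 size
====================  ====
T1 (sequential tap)      9
T2 (rainbow tap)        10
T3 (multi-touch)        28
T4 spiral follow        22
T4 spiral draw          22
T9 3D construction      30
T10 clock drawing       24
T11 verbal fluency       2
T12 modified trails     33
T13 problem solving     25
T15 energy balance       4
Spelling (JW)            3
SAGE points             10
Duration (all tasks)    16
====================  ====

The published methodology fixes the group sizes; the concrete per-group
feature lists below are this package's documented realization of those
sizes.  Speech features live on a separate sequence path and are not part
of this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from nits import energy as energy_mod
from nits import sage_scoring as sage
from nits.geometry import discrete_frechet, percentage_match, resample_by_arc_length
from nits.sage_scoring import AnswerKey
from nits.session_io import SessionRecord, TouchTrajectory, TASK_IDS

# ---------------------------------------------------------------------------
# Schema


def _kinematic_names(prefix: str) -> list[str]:
    return [f"{prefix}_{n}" for n in (
        "frechet", "pct_match", "mean_speed", "sd_speed",
        "mean_radial_err", "sd_radial_err", "max_radial_err",
        "tremor_band_power", "tremor_peak_freq", "tremor_peak_amp",
        "duration_s", "path_len_ratio", "mean_curvature", "sd_curvature",
        "n_pauses", "mean_jerk", "sd_jerk", "start_offset", "end_offset",
        "n_points", "mean_dev", "sd_dev",
    )]


_T9_NAMES = [f"t9_{n}" for n in (
    "err_wrong_connection", "err_too_few", "err_too_many", "err_existing",
    "similarity", "parallel_fraction", "parallel_pass", "n_strokes",
    "n_edges", "n_correct_edges", "n_missing_edges", "n_extra_edges",
    "mean_stroke_len", "sd_stroke_len", "mean_stroke_dur", "sd_stroke_dur",
    "mean_speed", "sd_speed", "mean_frechet_line", "sd_frechet_line",
    "max_frechet_line", "mean_tremor_power", "sd_tremor_power",
    "total_duration_s", "mean_node_offset", "sd_node_offset",
    "total_path_len", "points", "err_outside", "mean_straightness",
)]

_T10_NAMES = [f"t10_{n}" for n in (
    "boundary_errors", "supervisor_score", "points", "n_strokes", "n_points",
    "total_path_len", "total_duration_s", "mean_speed", "sd_speed",
    "frac_outside", "mean_stroke_len", "sd_stroke_len", "mean_stroke_dur",
    "sd_stroke_dur", "mean_tremor_power", "sd_tremor_power",
    "mean_curvature", "sd_curvature", "mean_jerk", "sd_jerk",
    "mean_gap_ms", "sd_gap_ms", "width_px", "height_px",
)]

_T12_NAMES = [f"t12_{n}" for n in (
    "err_wrong_connection", "err_same_node", "err_outside", "similarity",
    "points", "n_paths", "n_correct_edges", "frac_sequence_completed",
    "mean_frechet", "sd_frechet", "max_frechet", "min_frechet",
    "mean_path_len", "sd_path_len", "mean_path_dur", "sd_path_dur",
    "mean_speed", "sd_speed", "total_duration_s", "mean_straightness",
    "sd_straightness", "mean_tremor_power", "sd_tremor_power",
    "mean_jerk", "sd_jerk", "mean_node_offset", "sd_node_offset",
    "total_path_len", "n_strokes", "mean_inter_path_ms", "sd_inter_path_ms",
    "mean_curvature", "sd_curvature",
)]

_T13_NAMES = [f"t13_{n}" for n in (
    "err_same_node", "err_outside_zone", "err_rule_violation", "similarity",
    "points", "ops_used", "ops_remaining", "goal_reached", "n_insert",
    "n_remove", "edge_diff", "mean_op_interval_ms", "sd_op_interval_ms",
    "total_duration_s", "mean_touch_offset", "sd_touch_offset",
    "max_touch_offset", "n_touches", "frac_ops_valid", "n_errors_total",
    "mean_touch_gap_ms", "sd_touch_gap_ms", "n_unpaired", "start_goal_diff",
    "final_goal_diff",
)]

_SAGE_NAMES = [
    "sage_t6", "sage_t7", "sage_t8", "sage_t9", "sage_t10",
    "sage_t11", "sage_t12", "sage_t13", "sage_t0", "sage_total",
]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature groups; the single source of truth for the table."""

    groups: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def names(self) -> list[str]:
        return [n for _, ns in self.groups for n in ns]

    @property
    def size(self) -> int:
        return len(self.names)

    def group_sizes(self) -> dict[str, int]:
        return {g: len(ns) for g, ns in self.groups}

    def group_slice(self, group: str) -> slice:
        start = 0
        for g, ns in self.groups:
            if g == group:
                return slice(start, start + len(ns))
            start += len(ns)
        raise KeyError(group)


def default_schema() -> FeatureSchema:
    groups: list[tuple[str, tuple[str, ...]]] = []
    groups.append(("T1", tuple(
        f"t1_{k}_{n}" for k in (2, 3, 5) for n in ("mean_tap_interval_ms", "miss_count", "mean_offset_px")
    )))
    groups.append(("T2", tuple(
        f"t2_trial{i}_{n}" for i in range(1, 6) for n in ("reaction_ms", "offset_px")
    )))
    groups.append(("T3", tuple(
        f"t3_obj{i}_{n}" for i in range(1, 8) for n in ("reaction_ms", "offset_px", "hold_ms", "miss")
    )))
    groups.append(("T4_follow", tuple(_kinematic_names("t4f"))))
    groups.append(("T4_draw", tuple(_kinematic_names("t4d"))))
    groups.append(("T9", tuple(_T9_NAMES)))
    groups.append(("T10", tuple(_T10_NAMES)))
    groups.append(("T11", ("t11_points", "t11_jw_average")))
    groups.append(("T12", tuple(_T12_NAMES)))
    groups.append(("T13", tuple(_T13_NAMES)))
    groups.append(("T15", ("t15_bmr", "t15_tdee", "t15_p_gained", "t15_p_balance")))
    groups.append(("Spelling", ("spell_jw_t7", "spell_jw_t8", "spell_jw_t11")))
    groups.append(("SAGE", tuple(_SAGE_NAMES)))
    groups.append(("Duration", tuple(f"duration_{t}" for t in TASK_IDS)))
    schema = FeatureSchema(groups=tuple(groups))
    assert schema.size == 238, f"schema size {schema.size} != 238"
    return schema


@dataclass
class FeatureVector:
    values: np.ndarray
    label: Optional[int]
    subject_id: str
    round_index: int
    missing_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)


# ---------------------------------------------------------------------------
# Kinematic helpers


def _uniform_resample_t(t_ms: np.ndarray, v: np.ndarray, rate_hz: float = 100.0):
    if t_ms[-1] <= t_ms[0]:
        return np.array([v[0]])
    tt = np.arange(t_ms[0], t_ms[-1], 1000.0 / rate_hz)
    return np.interp(tt, t_ms, v)


def _tremor_spectrum(traj: TouchTrajectory, band=(4.0, 8.0)) -> tuple[float, float, float]:
    """Band power / peak frequency / peak amplitude of the lateral deviation.

    The deviation signal is the distance of each sample from a 0.3 s
    moving-average smoothing of the path (the voluntary movement), sampled
    uniformly at 100 Hz.  Pathological rest/action hand tremor concentrates
    in the 4-8 Hz band.
    """
    xy = traj.xy()
    t = traj.t()
    if len(xy) < 8 or t[-1] - t[0] < 200:
        return 0.0, 0.0, 0.0
    fs = 100.0
    x = _uniform_resample_t(t, xy[:, 0], fs)
    y = _uniform_resample_t(t, xy[:, 1], fs)
    if len(x) < 8:
        return 0.0, 0.0, 0.0
    w = max(3, int(0.3 * fs) | 1)
    kernel = np.ones(w) / w
    pad = w // 2
    xs = np.convolve(np.pad(x, pad, mode="edge"), kernel, mode="valid")
    ys = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")
    dev = np.hypot(x - xs, y - ys)
    dev = dev - dev.mean()
    n = len(dev)
    spec = np.abs(np.fft.rfft(dev * np.hanning(n))) ** 2 / n
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        return 0.0, 0.0, 0.0
    power = float(spec[sel].sum())
    i = int(np.argmax(spec[sel]))
    return power, float(freqs[sel][i]), float(np.sqrt(spec[sel][i]))


def _stroke_stats(traj: TouchTrajectory) -> dict[str, float]:
    xy = traj.xy()
    t = traj.t()
    d = np.diff(xy, axis=0)
    seg = np.linalg.norm(d, axis=1)
    dt = np.maximum(np.diff(t), 1.0) / 1000.0
    speed = seg / dt
    path_len = float(seg.sum())
    chord = float(np.linalg.norm(xy[-1] - xy[0]))
    # turning angle per point
    if len(d) >= 2:
        ang = np.arctan2(d[:, 1], d[:, 0])
        dang = np.abs(np.diff(np.unwrap(ang)))
        curv_mean, curv_sd = float(dang.mean()), float(dang.std())
    else:
        curv_mean = curv_sd = 0.0
    if len(speed) >= 2:
        acc = np.diff(speed) / dt[1:]
        jerk = np.abs(np.diff(acc)) if len(acc) >= 2 else np.array([0.0])
        jerk_mean, jerk_sd = float(np.mean(jerk)), float(np.std(jerk))
    else:
        jerk_mean = jerk_sd = 0.0
    power, pf, pa = _tremor_spectrum(traj)
    return {
        "path_len": path_len,
        "duration_s": float((t[-1] - t[0]) / 1000.0),
        "mean_speed": float(speed.mean()) if len(speed) else 0.0,
        "sd_speed": float(speed.std()) if len(speed) else 0.0,
        "straightness": chord / path_len if path_len > 0 else 1.0,
        "mean_curvature": curv_mean,
        "sd_curvature": curv_sd,
        "mean_jerk": jerk_mean,
        "sd_jerk": jerk_sd,
        "tremor_band_power": power,
        "tremor_peak_freq": pf,
        "tremor_peak_amp": pa,
        "n_points": float(len(xy)),
        "n_pauses": float(int((speed < 5.0).sum())) if len(speed) else 0.0,
    }


def spiral_features(traj: TouchTrajectory, reference: np.ndarray,
                    match_radius_px: float) -> list[float]:
    """The 22 spiral-task features for one trajectory vs its reference."""
    xy = traj.xy()
    st = _stroke_stats(traj)
    fre = discrete_frechet(xy, reference)
    pct = percentage_match(xy, reference, match_radius_px)
    diff = xy[:, None, :] - reference[None, :, :]
    nearest = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
    ref_res = resample_by_arc_length(reference, len(xy))
    dev = np.linalg.norm(xy - ref_res, axis=1)
    ref_len = float(np.linalg.norm(np.diff(reference, axis=0), axis=1).sum())
    return [
        fre, pct, st["mean_speed"], st["sd_speed"],
        float(nearest.mean()), float(nearest.std()), float(nearest.max()),
        st["tremor_band_power"], st["tremor_peak_freq"], st["tremor_peak_amp"],
        st["duration_s"], st["path_len"] / ref_len if ref_len > 0 else 0.0,
        st["mean_curvature"], st["sd_curvature"], st["n_pauses"],
        st["mean_jerk"], st["sd_jerk"],
        float(np.linalg.norm(xy[0] - reference[0])),
        float(np.linalg.norm(xy[-1] - reference[-1])),
        st["n_points"], float(dev.mean()), float(dev.std()),
    ]


def _mean_sd(vals: Sequence[float]) -> tuple[float, float]:
    if not vals:
        return 0.0, 0.0
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# Per-group extractors (each consumes the task payload dialect)


def _extract_t1(payload: dict) -> list[float]:
    out = []
    for layout in payload["layouts"]:
        taps = np.asarray(layout["taps"], dtype=float)  # (n, 3): t, x, y
        targets = np.asarray(layout["targets"], dtype=float)
        radius = float(layout.get("radius_px", 60.0))
        offsets = np.linalg.norm(taps[:, 1:3] - targets, axis=1)
        misses = float((offsets > radius).sum())
        intervals = np.diff(taps[:, 0])
        out += [float(intervals.mean()) if len(intervals) else 0.0, misses, float(offsets.mean())]
    return out


def _extract_t2(payload: dict) -> list[float]:
    out = []
    for trial in payload["trials"]:
        t0 = float(trial["t_shown_ms"])
        t, x, y = (float(v) for v in trial["tap"])
        tx, ty = (float(v) for v in trial["target"])
        out += [t - t0, float(np.hypot(x - tx, y - ty))]
    return out


def _extract_t3(payload: dict) -> list[float]:
    out = []
    for obj in payload["objects"]:
        t, x, y = (float(v) for v in obj["tap"])
        tx, ty = (float(v) for v in obj["target"])
        out += [
            float(obj["reaction_ms"]),
            float(np.hypot(x - tx, y - ty)),
            float(obj["hold_ms"]),
            float(bool(obj.get("missed", False))),
        ]
    return out


def _extract_t4_part(part: dict, match_radius_px: float) -> list[float]:
    traj: TouchTrajectory = part["trajectory"]
    ref = np.asarray(part["reference"], dtype=float)
    return spiral_features(traj, ref, match_radius_px)


def _extract_t9(payload: dict) -> tuple[list[float], sage.TaskScore]:
    score = sage.score_construction_3d(
        payload["log"], payload["reference"], payload["layout"],
        parallel_pairs=payload.get("parallel_pairs"),
    )
    aux = score.auxiliaries
    layout = payload["layout"]
    reference = payload["reference"]
    pos = layout.positions()
    replay_strokes = [a.stroke for a in payload["log"].actions if a.kind == "stroke"]
    stats = [_stroke_stats(s) for s in replay_strokes]
    lens = [s["path_len"] for s in stats]
    durs = [s["duration_s"] for s in stats]
    speeds = [s["mean_speed"] for s in stats]
    trem = [s["tremor_band_power"] for s in stats]
    straight = [s["straightness"] for s in stats]
    from nits.geometry import resolve_stroke_nodes

    frechets = []
    node_offsets = []
    drawn_edges = set()
    for s in replay_strokes:
        nodes = resolve_stroke_nodes(s, layout)
        if len(nodes) == 2:
            a, b = nodes
            drawn_edges.add(frozenset((a, b)))
            seg = np.linspace(pos[a], pos[b], 64)
            frechets.append(discrete_frechet(resample_by_arc_length(s.xy(), 64), seg))
            node_offsets.append(float(np.linalg.norm(s.xy()[0] - pos[a])))
            node_offsets.append(float(np.linalg.norm(s.xy()[-1] - pos[b])))
    ref_edges = {frozenset(e) for e in reference.edges}
    n_correct = len(drawn_edges & ref_edges)
    mfre, sfre = _mean_sd(frechets)
    mlen, slen = _mean_sd(lens)
    mdur, sdur = _mean_sd(durs)
    msp, ssp = _mean_sd(speeds)
    mtr, str_ = _mean_sd(trem)
    mno, sno = _mean_sd(node_offsets)
    times = [a.t_ms for a in payload["log"].actions]
    total_dur = (times[-1] - times[0]) / 1000.0 if len(times) >= 2 else 0.0
    vals = [
        aux["err_wrong_connection"], aux["err_too_few"], aux["err_too_many"],
        aux["err_existing"], aux["similarity"],
        aux.get("parallel_fraction", 0.0), aux.get("parallel_pass", 0.0),
        float(len(replay_strokes)), aux["n_edges"], float(n_correct),
        float(len(ref_edges) - n_correct), float(len(drawn_edges) - n_correct),
        mlen, slen, mdur, sdur, msp, ssp,
        mfre, sfre, float(np.max(frechets)) if frechets else 0.0,
        mtr, str_, float(total_dur), mno, sno, float(np.sum(lens)),
        float(score.points), aux.get("err_outside", 0.0),
        float(np.mean(straight)) if straight else 0.0,
    ]
    return vals, score


def _extract_t10(payload: dict) -> tuple[list[float], sage.TaskScore]:
    strokes: list[TouchTrajectory] = payload["strokes"]
    contour = np.asarray(payload["contour"], dtype=float)
    score = sage.score_clock(strokes, contour, payload.get("supervisor_score"))
    stats = [_stroke_stats(s) for s in strokes]
    all_xy = np.vstack([s.xy() for s in strokes]) if strokes else np.zeros((1, 2))
    n_pts = sum(int(s_["n_points"]) for s_ in stats)
    lens = [s_["path_len"] for s_ in stats]
    durs = [s_["duration_s"] for s_ in stats]
    gaps = []
    for a, b in zip(strokes, strokes[1:]):
        gaps.append(b.t()[0] - a.t()[-1])
    mlen, slen = _mean_sd(lens)
    mdur, sdur = _mean_sd(durs)
    msp, ssp = _mean_sd([s_["mean_speed"] for s_ in stats])
    mtr, str_ = _mean_sd([s_["tremor_band_power"] for s_ in stats])
    mcv, scv = _mean_sd([s_["mean_curvature"] for s_ in stats])
    mjk, sjk = _mean_sd([s_["mean_jerk"] for s_ in stats])
    mgap, sgap = _mean_sd(gaps)
    n_out = score.auxiliaries["boundary_errors"]
    sup = score.auxiliaries["supervisor_score"]
    vals = [
        n_out, sup if np.isfinite(sup) else float(score.points), float(score.points),
        float(len(strokes)), float(n_pts), float(np.sum(lens)),
        float(np.sum(durs)), msp, ssp,
        n_out / max(n_pts, 1), mlen, slen, mdur, sdur, mtr, str_,
        mcv, scv, mjk, sjk, mgap, sgap,
        float(all_xy[:, 0].max() - all_xy[:, 0].min()),
        float(all_xy[:, 1].max() - all_xy[:, 1].min()),
    ]
    return vals, score


def _extract_t12(payload: dict) -> tuple[list[float], sage.TaskScore]:
    score = sage.score_trails(payload["log"], payload["layout"], payload["reference"])
    aux = score.auxiliaries
    layout = payload["layout"]
    pos = layout.positions()
    strokes = [a.stroke for a in payload["log"].actions if a.kind == "stroke"]
    stats = [_stroke_stats(s) for s in strokes]
    from nits.geometry import resolve_stroke_nodes

    frechets, node_offsets, path_lens, path_durs = [], [], [], []
    drawn_edges = set()
    path_end_times, path_start_times = [], []
    for s in strokes:
        nodes = resolve_stroke_nodes(s, layout)
        if len(nodes) == 2:
            a, b = nodes
            drawn_edges.add(frozenset((a, b)))
            seg = np.linspace(pos[a], pos[b], 64)
            frechets.append(discrete_frechet(resample_by_arc_length(s.xy(), 64), seg))
            node_offsets.append(float(np.linalg.norm(s.xy()[0] - pos[a])))
            node_offsets.append(float(np.linalg.norm(s.xy()[-1] - pos[b])))
            st = _stroke_stats(s)
            path_lens.append(st["path_len"])
            path_durs.append(st["duration_s"])
            path_start_times.append(s.t()[0])
            path_end_times.append(s.t()[-1])
    ref_edges = {frozenset(e) for e in payload["reference"].edges}
    n_correct = len(drawn_edges & ref_edges)
    inter = [s - e for s, e in zip(path_start_times[1:], path_end_times[:-1])]
    mfre, sfre = _mean_sd(frechets)
    mpl, spl = _mean_sd(path_lens)
    mpd, spd = _mean_sd(path_durs)
    msp, ssp = _mean_sd([s_["mean_speed"] for s_ in stats])
    mst, sst = _mean_sd([s_["straightness"] for s_ in stats])
    mtr, str_ = _mean_sd([s_["tremor_band_power"] for s_ in stats])
    mjk, sjk = _mean_sd([s_["mean_jerk"] for s_ in stats])
    mno, sno = _mean_sd(node_offsets)
    mip, sip = _mean_sd(inter)
    mcv, scv = _mean_sd([s_["mean_curvature"] for s_ in stats])
    times = [a.t_ms for a in payload["log"].actions]
    total_dur = (times[-1] - times[0]) / 1000.0 if len(times) >= 2 else 0.0
    vals = [
        aux["err_wrong_connection"], aux["err_same_node"], aux["err_outside"],
        aux["similarity"], float(score.points), aux["n_paths"],
        float(n_correct), n_correct / max(len(ref_edges), 1),
        mfre, sfre,
        float(np.max(frechets)) if frechets else 0.0,
        float(np.min(frechets)) if frechets else 0.0,
        mpl, spl, mpd, spd, msp, ssp, float(total_dur), mst, sst,
        mtr, str_, mjk, sjk, mno, sno,
        float(np.sum(path_lens)), float(len(strokes)), mip, sip, mcv, scv,
    ]
    return vals, score


def _extract_t13(payload: dict) -> tuple[list[float], sage.TaskScore]:
    score = sage.score_problem_solving(
        payload["log"], payload["start"], payload["goal"],
        payload["ops_budget"], tuple(payload.get("allowed_ops", ("insert", "remove"))),
    )
    aux = score.auxiliaries
    start = payload["start"]
    pos = start.positions()
    radius = start.node_radius_px
    touch_times, offsets = [], []
    n_insert = n_remove = 0
    edges = {frozenset(e) for e in start.edges}
    pending = None
    for a in payload["log"].actions:
        touch_times.append(a.t_ms)
        if a.kind == "node_touch":
            nid = a.node_id
            if nid in pos:
                offsets.append(0.0)
        else:
            p0 = a.stroke.xy()[0]
            best = min((float(np.linalg.norm(p0 - c)) for c in pos.values()), default=0.0)
            offsets.append(best)
            nid = None
            for k, c in pos.items():
                if np.linalg.norm(p0 - c) <= radius:
                    nid = k
                    break
        if nid is None or nid not in pos:
            pending = None
            continue
        if pending is None:
            pending = nid
        elif nid != pending:
            fs = frozenset((pending, nid))
            if fs in edges:
                n_remove += 1
                edges.discard(fs)
            else:
                n_insert += 1
                edges.add(fs)
            pending = None
        else:
            pending = None
    goal_edges = {frozenset(e) for e in payload["goal"].edges}
    start_edges = {frozenset(e) for e in start.edges}
    gaps = np.diff(touch_times) if len(touch_times) >= 2 else np.array([0.0])
    op_gaps = gaps[::2] if len(gaps) else np.array([0.0])
    moff, soff = _mean_sd(offsets)
    n_err = aux["err_same_node"] + aux["err_outside_zone"] + aux["err_rule_violation"]
    final_diff = float(len(edges ^ goal_edges))
    vals = [
        aux["err_same_node"], aux["err_outside_zone"], aux["err_rule_violation"],
        aux["similarity"], float(score.points), aux["ops_used"],
        aux["ops_remaining"], aux["goal_reached"], float(n_insert), float(n_remove),
        final_diff, float(np.mean(op_gaps)), float(np.std(op_gaps)),
        float((touch_times[-1] - touch_times[0]) / 1000.0) if len(touch_times) >= 2 else 0.0,
        moff, soff, float(np.max(offsets)) if offsets else 0.0,
        float(len(touch_times)),
        aux["ops_used"] / max(aux["ops_used"] + n_err, 1.0),
        float(n_err), float(np.mean(gaps)), float(np.std(gaps)),
        float(pending is not None),
        float(len(start_edges ^ goal_edges)), final_diff,
    ]
    return vals, score


# ---------------------------------------------------------------------------
# Orchestration


def extract_features(
    session: SessionRecord,
    schema: Optional[FeatureSchema] = None,
    keys: Optional[AnswerKey] = None,
    match_radius_px: float = 44.0,
) -> FeatureVector:
    """Score every task payload in a session into the 238-feature vector.

    Groups whose task payload is missing are filled with NaN and flagged;
    the table-level imputation replaces them with training-column medians.
    """
    schema = schema or default_schema()
    keys = keys or AnswerKey()
    tasks = session.tasks
    values: dict[str, list[float]] = {}
    missing: list[str] = []
    scores: dict[str, sage.TaskScore] = {}
    jw_aux = {"t7": np.nan, "t8": np.nan, "t11": np.nan}

    def put(group: str, vals: Optional[list[float]]) -> None:
        size = schema.group_sizes()[group]
        if vals is None:
            missing.append(group)
            values[group] = [np.nan] * size
        else:
            if len(vals) != size:
                raise ValueError(f"group {group}: got {len(vals)} features, expected {size}")
            values[group] = [float(v) for v in vals]

    put("T1", _extract_t1(tasks["T1"]) if "T1" in tasks else None)
    put("T2", _extract_t2(tasks["T2"]) if "T2" in tasks else None)
    put("T3", _extract_t3(tasks["T3"]) if "T3" in tasks else None)
    t4 = tasks.get("T4", {})
    put("T4_follow", _extract_t4_part(t4["follow"], match_radius_px) if "follow" in t4 else None)
    put("T4_draw", _extract_t4_part(t4["draw"], match_radius_px) if "draw" in t4 else None)

    if "T9" in tasks:
        vals, scores["T9"] = _extract_t9(tasks["T9"])
        put("T9", vals)
    else:
        put("T9", None)
    if "T10" in tasks:
        vals, scores["T10"] = _extract_t10(tasks["T10"])
        put("T10", vals)
    else:
        put("T10", None)
    if "T11" in tasks:
        sc = sage.score_verbal_fluency(tasks["T11"]["items"], tasks["T11"].get(
            "dictionary", keys.fluency_dictionary))
        scores["T11"] = sc
        jw_aux["t11"] = sc.auxiliaries["jw_average"]
        put("T11", [float(sc.points), sc.auxiliaries["jw_average"]])
    else:
        put("T11", None)
    if "T12" in tasks:
        vals, scores["T12"] = _extract_t12(tasks["T12"])
        put("T12", vals)
    else:
        put("T12", None)
    if "T13" in tasks:
        vals, scores["T13"] = _extract_t13(tasks["T13"])
        put("T13", vals)
    else:
        put("T13", None)

    if "T15" in tasks:
        t15 = tasks["T15"]
        products = [energy_mod.ProductItem(**p) for p in t15.get("products", [])]
        activities = [energy_mod.ActivityItem(**a) for a in t15.get("activities", [])]
        rep = energy_mod.energy_report(session.profile, products, activities)
        put("T15", [rep.bmr, rep.tdee, rep.p_gained, rep.p_balance])
    else:
        put("T15", None)

    # text tasks
    if "T6" in tasks:
        scores["T6"] = sage.score_orientation(tuple(tasks["T6"]["answer"]), keys.today)
    if "T7" in tasks:
        scores["T7"] = sage.score_picture_naming(tasks["T7"]["answers"], keys)
        jw_aux["t7"] = scores["T7"].auxiliaries["jw_average"]
    if "T8" in tasks:
        t8 = tasks["T8"]
        scores["T8"] = sage.score_similarities_calculation(
            t8.get("q3", ""), t8.get("q4"), t8.get("q5"), keys)
        jw_aux["t8"] = scores["T8"].auxiliaries["jw_average"]
    if "T0" in tasks:
        scores["T0"] = sage.score_memory(tasks["T0"]["answer"], keys)

    put("Spelling", [jw_aux["t7"], jw_aux["t8"], jw_aux["t11"]]
        if any(np.isfinite(v) for v in jw_aux.values()) else None)

    sage_tasks = ("T6", "T7", "T8", "T9", "T10", "T11", "T12", "T13", "T0")
    if any(t in scores for t in sage_tasks):
        pts = [float(scores[t].points) if t in scores else np.nan for t in sage_tasks]
        total = float(np.nansum(pts))
        put("SAGE", pts + [total])
    else:
        put("SAGE", None)

    put("Duration", [float(session.durations_s.get(t, np.nan)) for t in TASK_IDS])

    vec = np.concatenate([values[g] for g, _ in schema.groups])
    return FeatureVector(
        values=vec,
        label=session.profile.label,
        subject_id=session.profile.subject_id,
        round_index=session.round_index,
        missing_groups=tuple(missing),
    )


# ---------------------------------------------------------------------------
# Table I/O


def vectors_to_frame(vectors: Sequence[FeatureVector],
                     schema: Optional[FeatureSchema] = None) -> pd.DataFrame:
    schema = schema or default_schema()
    rows = []
    for v in vectors:
        if len(v.values) != schema.size:
            raise ValueError("vector length does not match schema")
        row = {"subject_id": v.subject_id, "round_index": v.round_index}
        row.update(dict(zip(schema.names, v.values)))
        row["label"] = v.label if v.label is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "round_index", *schema.names, "label"])


def frame_to_vectors(df: pd.DataFrame, schema: Optional[FeatureSchema] = None) -> list[FeatureVector]:
    schema = schema or default_schema()
    miss = [c for c in schema.names if c not in df.columns]
    if miss:
        raise ValueError(f"feature table missing columns, e.g. {miss[0]!r}")
    out = []
    for _, row in df.iterrows():
        lbl = row.get("label")
        out.append(FeatureVector(
            values=row[list(schema.names)].to_numpy(dtype=float),
            label=None if pd.isna(lbl) else int(lbl),
            subject_id=str(row.get("subject_id", "")),
            round_index=int(row.get("round_index", 1)),
        ))
    return out


def write_feature_table(vectors: Sequence[FeatureVector], path: str | Path,
                        schema: Optional[FeatureSchema] = None) -> None:
    vectors_to_frame(vectors, schema).to_csv(path, index=False)


def read_feature_table(path: str | Path, schema: Optional[FeatureSchema] = None) -> list[FeatureVector]:
    return frame_to_vectors(pd.read_csv(path), schema)


def impute_missing(df: pd.DataFrame, schema: Optional[FeatureSchema] = None) -> pd.DataFrame:
    """Replace NaN feature cells by the column median over labeled rows."""
    schema = schema or default_schema()
    out = df.copy()
    for c in schema.names:
        med = out[c].median()
        out[c] = out[c].fillna(0.0 if pd.isna(med) else med)
    return out
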