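"""Session data model and serialization.

One *session* is one visit of one subject: demographic profile, the
payloads captured by each of the 16 tasks (T0..T15), and per-task
durations.  Sessions are stored as JSON (schema tag ``nits-session/1``);
audio is stored separately as PCM WAV and referenced by file name.

Coordinate convention: screen pixels, origin top-left, y increasing
downward (the native touchscreen convention).  Timestamps are integer
milliseconds since the start of the task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np
from scipy.io import wavfile

SCHEMA_VERSION = "nits-session/1"

TASK_IDS = tuple(f"T{i}" for i in range(16))

PAL_LEVELS = ("sedentary", "light", "moderate", "heavy", "athlete")


class Label(IntEnum):
    HEALTHY = 0
    IMPAIRED = 1


class SessionFormatError(ValueError):
    """Raised when a session file violates the documented JSON dialect."""


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics used by the energy-expenditure task and bookkeeping.

    Height is in metres, weight in kilograms, matching the basal metabolic
    rate formula's units.  ``label`` is the ground-truth class when known
    (0 healthy, 1 impaired).
    """

    subject_id: str
    gender: str  # "man" | "woman"
    age_years: int
    height_m: float
    weight_kg: float
    pal: str = "sedentary"
    body_fat_pct: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gender not in ("man", "woman"):
            raise SessionFormatError(f"gender must be man|woman, got {self.gender!r}")
        if self.age_years <= 0:
            raise SessionFormatError("age_years must be positive")
        if not 0.5 < self.height_m < 2.5:
            raise SessionFormatError(f"height_m {self.height_m} outside (0.5, 2.5)")
        if self.weight_kg <= 0:
            raise SessionFormatError("weight_kg must be positive")
        if self.pal not in PAL_LEVELS:
            raise SessionFormatError(f"unknown PAL {self.pal!r}")
        if self.label is not None and self.label not in (0, 1):
            raise SessionFormatError("label must be 0 (healthy) or 1 (impaired)")


@dataclass(frozen=True)
class TouchEvent:
    t_ms: int
    x_px: float
    y_px: float
    pointer_id: int = 0
    pressure: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_ms < 0:
            raise SessionFormatError("t_ms must be >= 0")


@dataclass(frozen=True)
class TouchTrajectory:
    """One continuous finger stroke: a time-ordered list of touch events."""

    events: tuple[TouchEvent, ...]

    def __post_init__(self) -> None:
        if len(self.events) < 1:
            raise SessionFormatError("trajectory needs at least one event")
        ts = [e.t_ms for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise SessionFormatError("trajectory timestamps must be non-decreasing")

    def xy(self) -> np.ndarray:
        """(n, 2) array of point coordinates."""
        return np.array([[e.x_px, e.y_px] for e in self.events], dtype=float)

    def t(self) -> np.ndarray:
        return np.array([e.t_ms for e in self.events], dtype=float)

    def __len__(self) -> int:
        return len(self.events)


def trajectory_from_arrays(
    t_ms: Iterable[float], xy: np.ndarray, pointer_id: int = 0
) -> TouchTrajectory:
    events = tuple(
        TouchEvent(t_ms=int(round(t)), x_px=float(x), y_px=float(y), pointer_id=pointer_id)
        for t, (x, y) in zip(t_ms, np.asarray(xy, dtype=float))
    )
    return TouchTrajectory(events=events)


@dataclass(frozen=True)
class GraphLayout:
    """Node positions (and optional text labels) plus undirected edges."""

    nodes: tuple[tuple[str, float, float, Optional[str]], ...]
    edges: frozenset[frozenset[str]] = field(default_factory=frozenset)
    node_radius_px: float = 40.0

    def __post_init__(self) -> None:
        ids = [n[0] for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SessionFormatError("node ids must be unique")
        for e in self.edges:
            if len(e) != 2:
                raise SessionFormatError("self-loop or malformed edge")
            if not e <= set(ids):
                raise SessionFormatError(f"edge {sorted(e)} references unknown node")

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n[0] for n in self.nodes)

    def positions(self) -> dict[str, np.ndarray]:
        return {n[0]: np.array([n[1], n[2]], dtype=float) for n in self.nodes}

    def labels(self) -> dict[str, Optional[str]]:
        return {n[0]: n[3] for n in self.nodes}

    def with_edges(self, edges: Iterable[tuple[str, str]]) -> "GraphLayout":
        es = frozenset(frozenset(e) for e in edges)
        return GraphLayout(nodes=self.nodes, edges=es, node_radius_px=self.node_radius_px)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {nid: set() for nid in self.node_ids}
        for e in self.edges:
            a, b = sorted(e)
            adj[a].add(b)
            adj[b].add(a)
        return adj


def graph_layout(
    nodes: Sequence[tuple[str, float, float] | tuple[str, float, float, Optional[str]]],
    edges: Iterable[tuple[str, str]] = (),
    node_radius_px: float = 40.0,
) -> GraphLayout:
    """Convenience constructor accepting 3- or 4-tuples for nodes."""
    full = tuple((n[0], float(n[1]), float(n[2]), n[3] if len(n) > 3 else None) for n in nodes)
    return GraphLayout(
        nodes=full,
        edges=frozenset(frozenset(e) for e in edges),
        node_radius_px=node_radius_px,
    )


@dataclass(frozen=True)
class GraphAction:
    kind: str  # "stroke" | "node_touch"
    t_ms: int
    stroke: Optional[TouchTrajectory] = None
    node_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("stroke", "node_touch"):
            raise SessionFormatError(f"unknown action kind {self.kind!r}")
        if self.kind == "stroke" and self.stroke is None:
            raise SessionFormatError("stroke action needs a trajectory")
        if self.kind == "node_touch" and self.node_id is None:
            raise SessionFormatError("node_touch action needs a node_id")


@dataclass(frozen=True)
class GraphActionLog:
    """Time-ordered actions taken against a displayed node layout."""

    actions: tuple[GraphAction, ...]

    def __post_init__(self) -> None:
        ts = [a.t_ms for a in self.actions]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise SessionFormatError("action timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.actions)


@dataclass
class AudioClip:
    samples: np.ndarray  # float in [-1, 1], mono
    rate_hz: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if self.rate_hz <= 0:
            raise SessionFormatError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass
class SessionRecord:
    """One subject visit: profile, per-task payloads, per-task durations (s)."""

    profile: SubjectProfile
    round_index: int = 1
    tasks: dict[str, Any] = field(default_factory=dict)
    durations_s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.round_index <= 5:
            raise SessionFormatError("round_index must be in 1..5")
        for k in self.tasks:
            if k not in TASK_IDS:
                raise SessionFormatError(f"unknown task key {k!r}")
        for k, v in self.durations_s.items():
            if k not in TASK_IDS:
                raise SessionFormatError(f"unknown duration key {k!r}")
            if v < 0:
                raise SessionFormatError("durations must be >= 0")


# ---------------------------------------------------------------------------
# JSON serialization


def _traj_to_json(tr: TouchTrajectory) -> dict:
    return {
        "events": [
            {
                "t_ms": e.t_ms,
                "x_px": e.x_px,
                "y_px": e.y_px,
                "pointer_id": e.pointer_id,
                **({"pressure": e.pressure} if e.pressure is not None else {}),
            }
            for e in tr.events
        ]
    }


def _traj_from_json(d: dict) -> TouchTrajectory:
    return TouchTrajectory(
        events=tuple(
            TouchEvent(
                t_ms=int(e["t_ms"]),
                x_px=float(e["x_px"]),
                y_px=float(e["y_px"]),
                pointer_id=int(e.get("pointer_id", 0)),
                pressure=e.get("pressure"),
            )
            for e in d["events"]
        )
    )


def _layout_to_json(g: GraphLayout) -> dict:
    return {
        "nodes": [[n[0], n[1], n[2], n[3]] for n in g.nodes],
        "edges": sorted(sorted(e) for e in g.edges),
        "node_radius_px": g.node_radius_px,
    }


def _layout_from_json(d: dict) -> GraphLayout:
    return GraphLayout(
        nodes=tuple((n[0], float(n[1]), float(n[2]), n[3]) for n in d["nodes"]),
        edges=frozenset(frozenset(e) for e in d.get("edges", [])),
        node_radius_px=float(d.get("node_radius_px", 40.0)),
    )


def _log_to_json(log: GraphActionLog) -> dict:
    out = []
    for a in log.actions:
        rec: dict[str, Any] = {"kind": a.kind, "t_ms": a.t_ms}
        if a.kind == "stroke":
            rec["stroke"] = _traj_to_json(a.stroke)
        else:
            rec["node_id"] = a.node_id
        out.append(rec)
    return {"actions": out}


def _log_from_json(d: dict) -> GraphActionLog:
    actions = []
    for rec in d["actions"]:
        if rec["kind"] == "stroke":
            actions.append(
                GraphAction(kind="stroke", t_ms=int(rec["t_ms"]), stroke=_traj_from_json(rec["stroke"]))
            )
        else:
            actions.append(
                GraphAction(kind="node_touch", t_ms=int(rec["t_ms"]), node_id=rec["node_id"])
            )
    return GraphActionLog(actions=tuple(actions))


def _payload_to_json(value: Any) -> Any:
    if isinstance(value, AudioClip):
        raise SessionFormatError(
            "audio clips are stored as separate WAV files (write_audio) and "
            "referenced by path in the session, not embedded")
    if isinstance(value, TouchTrajectory):
        return {"__type__": "trajectory", **_traj_to_json(value)}
    if isinstance(value, GraphLayout):
        return {"__type__": "layout", **_layout_to_json(value)}
    if isinstance(value, GraphActionLog):
        return {"__type__": "action_log", **_log_to_json(value)}
    if isinstance(value, dict):
        return {k: _payload_to_json(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_payload_to_json(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def _payload_from_json(value: Any) -> Any:
    if isinstance(value, dict):
        t = value.get("__type__")
        if t == "trajectory":
            return _traj_from_json(value)
        if t == "layout":
            return _layout_from_json(value)
        if t == "action_log":
            return _log_from_json(value)
        return {k: _payload_from_json(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_payload_from_json(v) for v in value]
    return value


def session_to_dict(session: SessionRecord) -> dict:
    p = session.profile
    return {
        "schema": SCHEMA_VERSION,
        "profile": {
            "subject_id": p.subject_id,
            "gender": p.gender,
            "age_years": p.age_years,
            "height_m": p.height_m,
            "weight_kg": p.weight_kg,
            "pal": p.pal,
            "body_fat_pct": p.body_fat_pct,
            "label": p.label,
        },
        "round_index": session.round_index,
        "tasks": {k: _payload_to_json(v) for k, v in session.tasks.items()},
        "durations_s": dict(session.durations_s),
    }


def session_from_dict(d: dict) -> SessionRecord:
    if d.get("schema") != SCHEMA_VERSION:
        raise SessionFormatError(f"unsupported schema {d.get('schema')!r} (field 'schema')")
    try:
        prof = d["profile"]
        profile = SubjectProfile(
            subject_id=prof["subject_id"],
            gender=prof["gender"],
            age_years=int(prof["age_years"]),
            height_m=float(prof["height_m"]),
            weight_kg=float(prof["weight_kg"]),
            pal=prof.get("pal", "sedentary"),
            body_fat_pct=prof.get("body_fat_pct"),
            label=prof.get("label"),
        )
    except KeyError as exc:  # pragma: no cover - error path
        raise SessionFormatError(f"missing profile field {exc.args[0]!r}") from exc
    return SessionRecord(
        profile=profile,
        round_index=int(d.get("round_index", 1)),
        tasks={k: _payload_from_json(v) for k, v in d.get("tasks", {}).items()},
        durations_s={k: float(v) for k, v in d.get("durations_s", {}).items()},
    )


def read_session(path: str | Path) -> SessionRecord:
    """Read one session from the documented JSON dialect."""
    text = Path(path).read_text()
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    return session_from_dict(d)


def write_session(session: SessionRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(session_to_dict(session), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Audio I/O (PCM WAV only)


def read_audio(path: str | Path) -> AudioClip:
    """Read a PCM WAV file; stereo is averaged to mono, samples in [-1, 1]."""
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise SessionFormatError(f"unsupported audio container: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.int16:
        x = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    else:
        x = data.astype(float)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioClip(samples=np.clip(x, -1.0, 1.0), rate_hz=int(rate))


def write_audio(clip: AudioClip, path: str | Path) -> None:
    """Write 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    # symmetric 2^15 scaling (clipped at int16 max) keeps the round-trip
    # error within half a quantization step
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), clip.rate_hz, pcm)
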