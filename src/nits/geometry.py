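"""Geometric scoring primitives for the touchscreen tasks.

Covers the reference Archimedean spiral shown in the tremor task, the
discrete Frechet distance used to compare a drawn curve against the
reference, a radius-based percentage match, parallel-line angle checks for
the 3D-figure construction task, node-hit resolution for free-drawn graph
edges, and a neighbor-matching graph similarity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from nits.session_io import GraphLayout, TouchTrajectory

try:  # optional JIT for the O(n*m) dynamic program
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


Curve2D = np.ndarray  # (n, 2) float array


def as_curve(points) -> Curve2D:
    c = np.asarray(points, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 1:
        raise ValueError("a curve is a non-empty (n, 2) array")
    if not np.all(np.isfinite(c)):
        raise ValueError("curve coordinates must be finite")
    return c


@dataclass(frozen=True)
class SpiralSpec:
    """Parameters of the displayed Archimedean spiral.

    ``spacing_px`` is the radial gap between consecutive turns, so the
    polar form is r = (spacing / 2*pi) * theta.  ``direction`` selects
    clockwise/counter-clockwise winding on a y-down screen.
    """

    center: tuple[float, float] = (0.0, 0.0)
    spacing_px: float = 100.0
    turns: float = 3.0
    direction: str = "cw"
    n_points: int = 256

    def __post_init__(self) -> None:
        if self.spacing_px <= 0 or self.turns <= 0:
            raise ValueError("spacing_px and turns must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.direction not in ("cw", "ccw"):
            raise ValueError("direction must be 'cw' or 'ccw'")


def spiral_spec_for_screen(width_px: float, height_px: float, turns: float = 3.0,
                           n_points: int = 256, direction: str = "cw") -> SpiralSpec:
    """Spiral spanning 80% of the shorter screen dimension, centered."""
    short = min(width_px, height_px)
    r_max = 0.4 * short  # radius = half of the 80% span
    return SpiralSpec(
        center=(width_px / 2.0, height_px / 2.0),
        spacing_px=r_max / turns,
        turns=turns,
        direction=direction,
        n_points=n_points,
    )


def generate_spiral(spec: SpiralSpec) -> Curve2D:
    """Sample r = (spacing/2*pi)*theta uniformly in theta; first point at center."""
    theta = np.linspace(0.0, 2.0 * np.pi * spec.turns, spec.n_points)
    r = spec.spacing_px / (2.0 * np.pi) * theta
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    if spec.direction == "ccw":
        x = -x  # mirror about the vertical axis through the center
    cx, cy = spec.center
    return np.column_stack([cx + x, cy + y])


# ---------------------------------------------------------------------------
# Discrete Frechet distance


def resample_by_arc_length(curve: Curve2D, n: int) -> Curve2D:
    """Resample a polyline to n points uniformly spaced along its arc length."""
    c = as_curve(curve)
    if len(c) == 1:
        return np.repeat(c, n, axis=0)
    seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(c[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    x = np.interp(target, s, c[:, 0])
    y = np.interp(target, s, c[:, 1])
    return np.column_stack([x, y])


def _frechet_dp_python(d: np.ndarray) -> float:
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[n - 1, m - 1])


if _HAVE_NUMBA:
    _frechet_dp = njit(cache=True)(_frechet_dp_python)
else:  # pragma: no cover
    _frechet_dp = _frechet_dp_python


def discrete_frechet(a, b, max_points: int = 512) -> float:
    """Discrete Frechet distance between two point sequences.

    The standard O(n*m) dynamic program over monotone couplings with the
    Euclidean ground metric.  Inputs longer than ``max_points`` are first
    resampled by arc length to bound the cost.
    """
    ca = as_curve(a)
    cb = as_curve(b)
    if len(ca) > max_points:
        ca = resample_by_arc_length(ca, max_points)
    if len(cb) > max_points:
        cb = resample_by_arc_length(cb, max_points)
    diff = ca[:, None, :] - cb[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return float(_frechet_dp(d))


def percentage_match(drawn, reference, radius_px: float) -> float:
    """Fraction of drawn points whose nearest reference point is within radius."""
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    cd = as_curve(drawn)
    cr = as_curve(reference)
    diff = cd[:, None, :] - cr[None, :, :]
    dmin = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
    return float(np.mean(dmin <= radius_px))


# ---------------------------------------------------------------------------
# Parallel-line angles (3D-figure construction)


def parallel_angle(m1: Optional[float], m2: Optional[float]) -> float:
    """Acute angle (degrees) between two lines given by slope; None = vertical."""
    if m1 is None and m2 is None:
        return 0.0
    if m1 is None or m2 is None:
        m = m2 if m1 is None else m1
        # angle between a vertical line and slope m
        return float(np.degrees(np.arctan(1.0 / abs(m)))) if m != 0 else 90.0
    denom = 1.0 + m1 * m2
    if denom == 0.0:
        return 90.0
    return float(np.degrees(np.arctan(abs(m1 - m2) / abs(denom))))


def fit_line_slope(points) -> Optional[float]:
    """Total-least-squares slope of a point cloud; None when near-vertical."""
    c = as_curve(points)
    centered = c - c.mean(axis=0)
    if len(c) < 2 or np.allclose(centered, 0.0):
        return 0.0
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    dx, dy = vt[0]
    if abs(dx) < 1e-9 * max(1.0, abs(dy)):
        return None  # vertical
    return float(dy / dx)


def parallel_pairs_score(
    slopes: Sequence[Optional[float]],
    pairs: Sequence[tuple[int, int]],
    angle_tol_deg: float = 10.0,
    match_pct: float = 0.5,
) -> tuple[float, bool]:
    """Fraction of designated edge pairs within the parallel tolerance.

    The construction task checks whether edge pairs that should be parallel
    in the reference figure were drawn within ``angle_tol_deg`` of each
    other; the task passes when at least ``match_pct`` of the pairs are.
    """
    if len(pairs) == 0:
        raise ValueError("pair list must be non-empty")
    n_ok = 0
    for i, j in pairs:
        if parallel_angle(slopes[i], slopes[j]) < angle_tol_deg:
            n_ok += 1
    frac = n_ok / len(pairs)
    return frac, frac >= match_pct


# ---------------------------------------------------------------------------
# Node-hit resolution


def resolve_stroke_nodes(
    stroke: TouchTrajectory | Curve2D, layout: GraphLayout, hit_radius_px: Optional[float] = None
) -> list[str]:
    """Node ids whose centers come within the hit radius of the stroke.

    Returned in first-touch order, deduplicated.  The default hit radius is
    the layout's drawn node-circle radius.
    """
    if hit_radius_px is None:
        hit_radius_px = layout.node_radius_px
    if hit_radius_px <= 0:
        raise ValueError("hit_radius_px must be positive")
    pts = stroke.xy() if isinstance(stroke, TouchTrajectory) else as_curve(stroke)
    pos = layout.positions()
    ids = list(pos)
    centers = np.array([pos[i] for i in ids])
    diff = pts[:, None, :] - centers[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))  # (n_pts, n_nodes)
    hit: list[str] = []
    for k in range(len(pts)):
        for j in np.nonzero(d[k] <= hit_radius_px)[0]:
            nid = ids[j]
            if nid not in hit:
                hit.append(nid)
    return hit


# ---------------------------------------------------------------------------
# Neighbor-matching graph similarity


def _neighbor_matching_matrix(
    adj1: dict[str, set[str]], adj2: dict[str, set[str]], eps: float, max_iter: int
) -> np.ndarray:
    ids1 = sorted(adj1)
    ids2 = sorted(adj2)
    n1, n2 = len(ids1), len(ids2)
    nbr1 = [sorted(adj1[i]) for i in ids1]
    nbr2 = [sorted(adj2[j]) for j in ids2]
    idx1 = {v: k for k, v in enumerate(ids1)}
    idx2 = {v: k for k, v in enumerate(ids2)}
    sim = np.ones((n1, n2))
    for _ in range(max_iter):
        new = np.empty_like(sim)
        for i in range(n1):
            for j in range(n2):
                a, b = nbr1[i], nbr2[j]
                if not a and not b:
                    new[i, j] = 1.0
                    continue
                if not a or not b:
                    new[i, j] = 0.0
                    continue
                sub = sim[np.ix_([idx1[x] for x in a], [idx2[x] for x in b])]
                r, c = linear_sum_assignment(-sub)
                # optimal assignment of neighbor similarities, normalized by
                # the larger neighborhood so missing neighbors count as 0
                new[i, j] = sub[r, c].sum() / max(len(a), len(b))
        delta = np.abs(new - sim).max()
        sim = new
        if delta < eps:
            break
    return sim


def neighbor_matching_similarity(
    g1: GraphLayout | dict[str, set[str]],
    g2: GraphLayout | dict[str, set[str]],
    eps: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """Whole-graph similarity in [0, 1] by iterative neighbor matching.

    Node-pair similarities are refined to a fixed point: the similarity of
    two nodes is the optimally assigned mean similarity of their neighbor
    sets (undirected edges treated as symmetric arcs).  The graph score is
    the mean similarity of the optimal node assignment, normalized by the
    larger node count, so identical (or isomorphic) graphs score 1.
    """
    adj1 = g1.adjacency() if isinstance(g1, GraphLayout) else {k: set(v) for k, v in g1.items()}
    adj2 = g2.adjacency() if isinstance(g2, GraphLayout) else {k: set(v) for k, v in g2.items()}
    if not adj1 or not adj2:
        raise ValueError("graphs must be non-empty")
    sim = _neighbor_matching_matrix(adj1, adj2, eps, max_iter)
    r, c = linear_sum_assignment(-sim)
    return float(sim[r, c].sum() / max(len(adj1), len(adj2)))
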