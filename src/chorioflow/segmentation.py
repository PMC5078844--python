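"""Separatrices and the tessellation into functional vascular segments.

Each saddle of the physical field has two stable and two unstable
eigendirections.  The two unstable branches flow forward into venular
openings: together they form a separation surface joining two venules
through the saddle, across which no fluid passes.  The closed chains of
such separatrices bound the drainage territory of each arteriolar opening,
the *functional vascular segment*.  A segment with ``n`` venular vertices
and straight (prism) sides satisfies the shape/ratio relation

    ``N_a / N_v = 2 / (n - 2)``

(one arteriole per segment; venule ``k`` shared between adjacent segments
in proportion to its interior angle ``alpha_k / 2 pi``, with
``sum_k alpha_k = (n - 2) pi`` for a prism).  The same angles partition the
arteriolar flow among the venules, giving ``Q_a / <Q_v> = sum_k alpha_k / 2 pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import polygonize, unary_union

from chorioflow.flow import (
    StagnationPoint,
    find_stagnation_points,
    trace_ensemble,
)
from chorioflow.geometry import OpeningConfiguration

__all__ = [
    "Separatrix",
    "FunctionalSegment",
    "FlowPartition",
    "saddle_eigendirections",
    "trace_separatrices",
    "build_segments",
    "interior_angles",
    "ratio_from_shape",
    "flow_rate_ratio_from_angles",
    "flow_partition",
    "segments_to_geojson",
]


@dataclass(frozen=True)
class Separatrix:
    """One traced branch of a saddle's invariant manifold.

    ``branch`` is one of ``unstable+ / unstable- / stable+ / stable-``;
    unstable branches are traced forward (they terminate at venular
    openings or infinity), stable branches backward (toward arterioles).
    ``terminal`` is ``("opening", id)``, ``("infinity", None)`` or
    ``("truncated", None)`` when the step cap was hit.
    """

    saddle_index: int
    branch: str
    polyline: np.ndarray  # (n, 2)
    terminal: tuple

    @property
    def is_boundary(self) -> bool:
        return self.branch.startswith("unstable")


def saddle_eigendirections(config: OpeningConfiguration,
                           saddle: StagnationPoint):
    """Unit eigendirections of the linearised physical field at a saddle.

    Returns ``(unstable, stable)``, each a pair of opposite unit vectors.
    The Jacobian of ``conj(w)`` is symmetric, so the directions are two
    orthogonal axes; eigenvalue ``+|w'|`` is unstable, ``-|w'|`` stable.
    """
    if saddle.multiplicity != 1:
        raise ValueError(
            "degenerate (multiplicity > 1) saddle: jitter the configuration "
            "or handle the symmetric case manually"
        )
    J = saddle.jacobian
    evals, evecs = np.linalg.eigh(J)  # ascending: [-m, +m]
    stable = evecs[:, 0] / np.linalg.norm(evecs[:, 0])
    unstable = evecs[:, 1] / np.linalg.norm(evecs[:, 1])
    return (np.array([unstable, -unstable]), np.array([stable, -stable]))


def _trace_branch(
    config: OpeningConfiguration,
    z_start: complex,
    direction: float,
    bound_radius: float,
    max_arc: float,
    rtol: float,
    max_step: float = 0.05,
):
    """Integrate one streamline with scipy's adaptive RK; arclength-limited."""
    zi, ki, ai = config.positions, config.strengths * direction, config.radii

    def rhs(t, y):
        z = complex(y[0], y[1])
        w = (ki / (z - zi)).sum()
        u = np.conj(w)
        s = abs(u)
        if s == 0.0:
            return [0.0, 0.0]
        return [u.real / s, u.imag / s]  # unit speed: t is arclength

    def capture(t, y):
        d = np.abs(complex(y[0], y[1]) - zi) - ai
        return d.min()

    capture.terminal = True  # type: ignore[attr-defined]

    def escape(t, y):
        return bound_radius - math.hypot(y[0], y[1])

    escape.terminal = True  # type: ignore[attr-defined]
    escape.direction = -1  # type: ignore[attr-defined]  # outward only

    sol = solve_ivp(
        rhs,
        (0.0, max_arc),
        [z_start.real, z_start.imag],
        events=[capture, escape],
        rtol=rtol,
        atol=1e-12,
        max_step=max_step,
        dense_output=False,
    )
    pts = sol.y.T
    if sol.t_events[0].size:
        zf = complex(pts[-1, 0], pts[-1, 1])
        idx = int(np.argmin(np.abs(zf - zi) - ai))
        terminal = ("opening", int(config.openings[idx].id))
    elif sol.t_events[1].size:
        terminal = ("infinity", None)
    else:
        terminal = ("truncated", None)
    return pts, terminal


def trace_separatrices(
    config: OpeningConfiguration,
    stagnation_points: list[StagnationPoint] | None = None,
    eps: float = 1e-6,
    bound_radius: float | None = None,
    max_arc: float = 200.0,
    rtol: float = 1e-10,
    max_step: float = 0.05,
) -> list[Separatrix]:
    """Trace all four separatrix branches from every simple saddle.

    Each branch is seeded ``eps`` along an eigendirection and integrated at
    unit speed (arclength parametrisation, so the infinite travel *time*
    into the saddle does not stall the tracer) until it enters an opening's
    capture disc — the disc of the opening radius, inside which the
    continuum model is invalid anyway — or leaves the bounding circle.
    Unstable branches are followed forward, stable branches backward.
    The saddle position is prepended and the terminal opening centre
    appended, so separatrix polylines form an exactly noded arrangement.
    """
    if stagnation_points is None:
        stagnation_points = find_stagnation_points(config)
    if bound_radius is None:
        bound_radius = 3.0 * max(config.cloud_radius(), 1.0)
    out: list[Separatrix] = []
    for s_idx, sp in enumerate(stagnation_points):
        if sp.multiplicity != 1:
            continue
        unstable, stable = saddle_eigendirections(config, sp)
        for dirs, label, sign in ((unstable, "unstable", 1.0),
                                  (stable, "stable", -1.0)):
            for d, suffix in zip(dirs, ("+", "-")):
                z0 = sp.position + eps * complex(d[0], d[1])
                pts, terminal = _trace_branch(
                    config, z0, sign, bound_radius, max_arc, rtol, max_step
                )
                poly = np.vstack(
                    [[sp.position.real, sp.position.imag], pts]
                )
                if terminal[0] == "opening":
                    o = config.opening(terminal[1])
                    poly = np.vstack([poly, [o.x, o.y]])
                out.append(
                    Separatrix(
                        saddle_index=s_idx,
                        branch=label + suffix,
                        polyline=poly,
                        terminal=terminal,
                    )
                )
    return out


@dataclass
class FunctionalSegment:
    """The drainage territory of one arteriolar opening.

    ``area`` is the perfused area ``(1 - phi) * area_0``, with ``area_0``
    the geometric polygon area of the traced boundary (the model field is
    computed without discrete posts, so the traced polygon measures the
    post-free area).  ``vertices`` lists the venular opening ids at the
    polygon corners in boundary order.
    """

    arteriole_id: int
    polygon: Polygon | None
    vertices: list[int] = field(default_factory=list)
    vertex_positions: np.ndarray | None = None  # (n, 2), same order as vertices
    bounded: bool = True

    @property
    def n_sides(self) -> int:
        return len(self.vertices)

    @property
    def area_0(self) -> float:
        return float(self.polygon.area) if self.polygon is not None else math.inf

    def area(self, phi: float) -> float:
        return (1.0 - phi) * self.area_0


def build_segments(
    config: OpeningConfiguration,
    separatrices: list[Separatrix] | None = None,
    clip_radius: float | None = None,
    vertex_tol: float = 1e-6,
) -> list[FunctionalSegment]:
    """Assemble functional vascular segments from the boundary separatrices.

    The unstable (boundary) separatrix polylines are noded and polygonised;
    each bounded face is assigned to the arteriole it contains.  A single
    arteriole with no saddles (e.g. a dipole) yields one segment covering
    the whole domain (``bounded=False`` unless ``clip_radius`` closes it).
    ``clip_radius`` optionally adds a bounding circle to the arrangement so
    that otherwise-unbounded outer segments acquire finite polygons.
    """
    if separatrices is None:
        separatrices = trace_separatrices(config)
    lines = [LineString(s.polyline) for s in separatrices if s.is_boundary]
    if clip_radius is not None:
        t = np.linspace(0, 2 * np.pi, 720)
        circ = np.column_stack([clip_radius * np.cos(t), clip_radius * np.sin(t)])
        circ[-1] = circ[0]  # close the ring exactly
        lines.append(LineString(circ))
    segments: list[FunctionalSegment] = []
    faces: list[Polygon] = []
    if lines:
        merged = unary_union(lines)
        faces = list(polygonize(merged))
    venules = config.venules()
    # a face legitimately belongs to at most one arteriole; shared claims
    # mean a boundary piece is not a finite-saddle manifold (e.g. it runs
    # through a saddle at infinity) and the territories stay unresolved
    claims: dict[int, int] = {}
    for art in config.arterioles():
        p = Point(art.x, art.y)
        fidx = next((i for i, f in enumerate(faces) if f.contains(p)), None)
        if fidx is not None:
            claims[fidx] = claims.get(fidx, 0) + 1
    for art in config.arterioles():
        p = Point(art.x, art.y)
        poly = next((f for i, f in enumerate(faces)
                     if f.contains(p) and claims[i] == 1), None)
        if poly is None:
            segments.append(
                FunctionalSegment(art.id, None, vertices=[], bounded=False)
            )
            continue
        ring = np.asarray(poly.exterior.coords)
        verts = []
        for v in venules:
            d = np.hypot(ring[:, 0] - v.x, ring[:, 1] - v.y)
            if d.min() < vertex_tol:
                verts.append((int(np.argmin(d)), v.id, (v.x, v.y)))
        verts.sort()
        segments.append(
            FunctionalSegment(
                art.id,
                poly,
                vertices=[vid for _, vid, _ in verts],
                vertex_positions=np.array([xy for _, _, xy in verts])
                if verts else np.empty((0, 2)),
                bounded=True,
            )
        )
    return segments


def _tangent(ring: np.ndarray, idx: int, step: int, n_avg: int = 5) -> np.ndarray:
    """Average unit direction from ring[idx] toward nearby boundary points.

    Averaging over the last few separatrix points suppresses both
    integration noise and single-point discretisation error; residual bias
    scales with the local boundary curvature.
    """
    n = len(ring) - 1  # closed ring: last point repeats the first
    dirs = []
    for k in range(1, n_avg + 1):
        p = ring[(idx + step * k) % n]
        d = p - ring[idx % n]
        norm = np.hypot(*d)
        if norm > 0:
            dirs.append(d / norm)
    v = np.mean(dirs, axis=0)
    return v / np.hypot(*v)


def interior_angles(segment: FunctionalSegment, n_avg: int = 5) -> np.ndarray:
    """Interior angle ``alpha_k`` at each venular vertex of a segment.

    Measured between the tangents of the two incident boundary
    separatrices, each averaged over the last ``n_avg`` polyline points to
    suppress discretisation noise.  For a prism (straight-sided) segment
    the angles sum to ``(n - 2) pi``.
    """
    if segment.polygon is None:
        raise ValueError("segment has no closed boundary")
    ring = np.asarray(segment.polygon.exterior.coords)
    ccw = _ring_is_ccw(ring)
    angles = []
    for v_ring_idx, vid in _vertex_ring_indices(segment):
        fwd = _tangent(ring, v_ring_idx, +1, n_avg)
        back = _tangent(ring, v_ring_idx, -1, n_avg)
        a_f = math.atan2(fwd[1], fwd[0])
        a_b = math.atan2(back[1], back[0])
        ang = (a_b - a_f) % (2 * math.pi) if ccw else (a_f - a_b) % (2 * math.pi)
        angles.append(ang)
    return np.array(angles)


def _ring_is_ccw(ring: np.ndarray) -> bool:
    x, y = ring[:-1, 0], ring[:-1, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) > 0


def _vertex_ring_indices(segment: FunctionalSegment):
    """Pairs ``(ring_index, venule_id)`` for the segment's venular vertices."""
    ring = np.asarray(segment.polygon.exterior.coords)
    out = []
    for vid, (vx, vy) in zip(segment.vertices, segment.vertex_positions):
        d = np.hypot(ring[:, 0] - vx, ring[:, 1] - vy)
        out.append((int(np.argmin(d)), vid))
    out.sort()
    return out


def ratio_from_shape(n_sides: int | float) -> float:
    """Opening-count ratio ``N_a/N_v = 2/(n - 2)`` for prism segments.

    A square tessellation (``n = 4``) gives 1, a honeycomb (``n = 6``)
    gives 1/2.
    """
    if n_sides < 3:
        raise ValueError("a prism segment needs at least 3 sides")
    return 2.0 / (n_sides - 2.0)


def flow_rate_ratio_from_angles(alpha: np.ndarray) -> float:
    """``Q_a/<Q_v> = sum_k alpha_k / (2 pi)`` (equal venular contributions)."""
    return float(np.asarray(alpha).sum() / (2.0 * math.pi))


@dataclass(frozen=True)
class FlowPartition:
    """Monte-Carlo partition of one arteriole's flow among venular vertices."""

    arteriole_id: int
    venule_ids: np.ndarray
    fractions: np.ndarray          # Q_{a,k}/Q_a from ray tracing
    angle_fractions: np.ndarray    # alpha_k / sum(alpha): the angle prediction
    q_ratio_mc: float              # Q_a/<Q_v> from the traced fractions
    q_ratio_angles: float          # sum(alpha)/2 pi
    n_rays: int
    unresolved: int

    @property
    def q_a(self) -> float:
        return 1.0  # fractions are normalised to the arteriolar flow


def flow_partition(
    config: OpeningConfiguration,
    segment: FunctionalSegment,
    n_rays: int = 2000,
    seed: int | None = 0,
    t_max: float | None = None,
) -> FlowPartition:
    """Partition ``Q_a`` among the venular vertices by flux-weighted rays.

    ``n_rays`` corpuscles are released uniformly in angle from the
    arteriolar rim (the inflow is axisymmetric, so uniform angle is
    flux-weighted) and each is assigned to the venule whose capture disc
    its streamline reaches.  Reported alongside is the interior-angle
    prediction ``alpha_k / sum alpha`` and both estimates of the
    arteriolar-to-mean-venular flow-rate ratio.
    """
    if n_rays < max(segment.n_sides, 1):
        raise ValueError("n_rays must be at least the number of sides")
    art = config.opening(segment.arteriole_id)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_rays)
    z0 = art.z + art.radius * 1.0001 * np.exp(1j * theta)
    if t_max is None:
        area = segment.area_0 if segment.polygon is not None else 10.0
        t_max = 50.0 * area / (2.0 * math.pi * art.strength)
    src_idx = int(np.nonzero(config.ids == art.id)[0][0])
    T, terminal, _ = trace_ensemble(
        config, z0, t_max=t_max, source_index=src_idx
    )
    vids = segment.vertices or [o.id for o in config.venules()]
    counts = np.zeros(len(vids))
    unresolved = 0
    id_by_index = config.ids
    for term in terminal:
        if term < 0:
            unresolved += 1
            continue
        oid = int(id_by_index[term])
        if oid in vids:
            counts[vids.index(oid)] += 1
        else:
            unresolved += 1
    if unresolved > 0.01 * n_rays:
        import warnings

        warnings.warn(
            f"{unresolved}/{n_rays} rays unresolved within the step cap",
            stacklevel=2,
        )
    fractions = counts / n_rays
    if segment.polygon is not None and segment.n_sides >= 2:
        alpha = interior_angles(segment)
        angle_fr = alpha / alpha.sum()
        q_ratio_angles = flow_rate_ratio_from_angles(alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            qv_est = fractions * 2.0 * math.pi / alpha
        good = qv_est > 0
        q_ratio_mc = 1.0 / qv_est[good].mean() if good.any() else math.nan
    else:
        alpha = np.array([])
        angle_fr = np.full(len(vids), np.nan)
        q_ratio_angles = math.nan
        q_ratio_mc = math.nan
    return FlowPartition(
        arteriole_id=art.id,
        venule_ids=np.array(vids, dtype=int),
        fractions=fractions,
        angle_fractions=angle_fr,
        q_ratio_mc=float(q_ratio_mc),
        q_ratio_angles=float(q_ratio_angles),
        n_rays=n_rays,
        unresolved=unresolved,
    )


def segments_to_geojson(config: OpeningConfiguration,
                        segments: list[FunctionalSegment]) -> dict:
    """GeoJSON FeatureCollection of segment polygons with shape properties."""
    feats = []
    for s in segments:
        if s.polygon is None:
            continue
        alpha = interior_angles(s).tolist() if s.n_sides >= 2 else []
        feats.append(
            {
                "type": "Feature",
                "geometry": s.polygon.__geo_interface__,
                "properties": {
                    "arteriole_id": s.arteriole_id,
                    "n_sides": s.n_sides,
                    "area_0": s.area_0,
                    "alpha_k": alpha,
                    "vertex_venule_ids": list(s.vertices),
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
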