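"""Multipole Hele-Shaw flow field, stagnation points and topology.

The depth-averaged (lubrication) velocity obeys ``u_h = -(K/mu) grad p``
with ``K = h^2/12``, so the flow is a potential flow whose complex velocity
is the rational function

    ``w(z) = sum_i k_i / (z - z_i)``.

``w`` is holomorphic; the *physical* velocity vector is its complex
conjugate, ``u_h = conj(w)``.  With this convention sources repel, sinks
attract, and every simple zero of ``w`` is a hyperbolic saddle of the
physical field (Poincare index -1).  On the Riemann sphere the nodes
(openings, plus the point at infinity when the net flux is unbalanced) and
saddles satisfy the Euler-characteristic identity

    ``N_a + N_v = N_s + 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from chorioflow.geometry import OpeningConfiguration

__all__ = [
    "ProximityWarning",
    "StagnationPoint",
    "TopologyReport",
    "complex_velocity",
    "velocity",
    "velocity_jacobian",
    "pressure",
    "opening_flux",
    "numerator_coefficients",
    "find_stagnation_points",
    "verify_euler_relation",
]


class ProximityWarning(UserWarning):
    """Field evaluated inside an opening disc, where the continuum model fails."""


def _as_complex(z) -> np.ndarray:
    z = np.asarray(z)
    if z.dtype.kind != "c":
        z = z.astype(complex)
    return z


def complex_velocity(config: OpeningConfiguration, z, warn: bool = True):
    """Holomorphic complex velocity ``w(z) = sum_i k_i/(z - z_i)``.

    The physical velocity vector is ``conj(w)``.  Evaluation inside an
    opening disc emits :class:`ProximityWarning` naming the opening (the
    value is still returned); the lubrication model only holds a short
    distance away from the openings.
    """
    z = _as_complex(z)
    zi = config.positions
    ki = config.strengths
    dz = z[..., None] - zi
    if warn:
        inside = np.abs(dz) < config.radii
        if inside.any():
            bad = config.ids[np.unique(np.nonzero(inside)[-1])]
            warnings.warn(
                f"field evaluated inside opening disc(s) {bad.tolist()}",
                ProximityWarning,
                stacklevel=2,
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (ki / dz).sum(axis=-1)
    return w


def velocity(config: OpeningConfiguration, z, warn: bool = False):
    """Physical planar velocity ``u_h = conj(w(z))`` as a complex number."""
    return np.conj(complex_velocity(config, z, warn=warn))


def velocity_jacobian(config: OpeningConfiguration, z) -> np.ndarray:
    """Jacobian of the physical field ``u_h = conj(w)`` at a point.

    For ``w'(z) = a + i b`` the Jacobian is ``[[a, -b], [-b, -a]]``:
    symmetric and trace-free, as expected for the gradient of a harmonic
    potential; its determinant is ``-|w'|^2 <= 0``.
    """
    z = complex(z)
    dw = -(config.strengths / (z - config.positions) ** 2).sum()
    a, b = dw.real, dw.imag
    return np.array([[a, -b], [-b, -a]])


def pressure(config: OpeningConfiguration, z, warn: bool = True):
    """Pressure (up to an additive constant) consistent with ``u_h``.

    ``p(z) = -(mu/K) sum_i k_i ln|z - z_i|`` so that ``-(K/mu) grad p``
    reproduces the physical velocity exactly.
    """
    z = _as_complex(z)
    if warn:  # reuse proximity check
        complex_velocity(config, z, warn=True)
    mu_over_K = config.params.mu / config.params.K
    with np.errstate(divide="ignore"):
        r = np.abs(z[..., None] - config.positions)
        return -mu_over_K * (config.strengths * np.log(r)).sum(axis=-1)


def opening_flux(config: OpeningConfiguration, opening_id: int,
                 n_quad: int = 720) -> float:
    """Outward flux of ``u_h`` through a circle just outside opening *i*.

    By the residue of ``w``, this equals ``2*pi*k_i``; computed by
    trapezoidal quadrature as an independent consistency check.
    """
    o = config.opening(opening_id)
    r = 1.5 * o.radius
    t = np.linspace(0.0, 2.0 * np.pi, n_quad, endpoint=False)
    ring = o.z + r * np.exp(1j * t)
    u = velocity(config, ring, warn=False)
    n_hat = np.exp(1j * t)
    un = (u * np.conj(n_hat)).real
    return float(un.mean() * 2.0 * np.pi * r)


# ---------------------------------------------------------------------------
# stagnation points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StagnationPoint:
    """A zero of the velocity field (hyperbolic saddle when simple)."""

    position: complex
    jacobian: np.ndarray
    multiplicity: int = 1
    residual: float = 0.0
    index: int = -1

    @property
    def is_degenerate(self) -> bool:
        return self.multiplicity > 1

    def to_dict(self) -> dict:
        return {
            "x": float(self.position.real),
            "y": float(self.position.imag),
            "multiplicity": int(self.multiplicity),
            "residual": float(self.residual),
        }


def numerator_coefficients(config: OpeningConfiguration,
                           centre: complex = 0.0,
                           scale: float = 1.0) -> np.ndarray:
    """Coefficients (descending) of ``P(z) = w(z) * prod_j (z - z_j)``.

    ``P = sum_i k_i prod_{j != i} (z - z_j)`` has degree ``N - 1`` in
    general and ``N - 2`` for a flux-balanced configuration, so a generic
    balanced set of ``N`` openings has exactly ``N - 2`` finite saddles.
    ``centre``/``scale`` build the polynomial in the shifted coordinate
    ``(z - centre)/scale``, which conditions the companion matrix for
    large clouds.
    """
    zi = (config.positions - centre) / scale
    ki = config.strengths
    n = len(zi)
    coeffs = np.zeros(n, dtype=complex)
    for i in range(n):
        poly = np.array([1.0 + 0j])
        for j in range(n):
            if j != i:
                poly = np.convolve(poly, np.array([1.0, -zi[j]]))
        coeffs += ki[i] * np.pad(poly, (n - len(poly), 0))
    return coeffs


def _conditioning_frame(config: OpeningConfiguration) -> tuple[complex, float]:
    """Centroid and radius used to condition the numerator polynomial."""
    z = config.positions
    c = complex(z.mean())
    s = float(np.abs(z - c).max())
    return c, max(s, 1.0)


def _trimmed_numerator(config: OpeningConfiguration,
                       centre: complex = 0.0,
                       scale: float = 1.0) -> np.ndarray:
    """Numerator coefficients with (numerically) vanishing leads dropped.

    Flux balance zeroes the leading coefficient; additional symmetries
    (vanishing dipole/quadrupole moments, as on perfect lattices) zero
    further leads, each sending one saddle to infinity.
    """
    coeffs = numerator_coefficients(config, centre, scale)
    mag = np.abs(coeffs).max()
    if mag == 0.0:
        return coeffs[:0]
    lead = np.nonzero(np.abs(coeffs) > 1e-12 * mag)[0]
    if len(lead) == 0:
        return coeffs[:0]
    return coeffs[lead[0]:]


def find_stagnation_points(
    config: OpeningConfiguration,
    merge_tol: float = 1e-9,
    residual_tol: float = 1e-10,
    jitter: float = 0.0,
    seed: int | None = None,
) -> list[StagnationPoint]:
    """All finite zeros of ``w``, as polished roots of its numerator.

    Roots come from the companion matrix of the numerator polynomial
    (``numpy.roots``), are polished by Newton iteration on ``w`` itself,
    and are merged within ``merge_tol`` into multiple zeros, which are
    reported with their multiplicity rather than silently split.  Symmetric
    degeneracies can be broken by a small seeded ``jitter`` of the opening
    positions (off by default).
    """
    if len(config.openings) < 2 and config.is_balanced:
        raise ValueError("need at least two openings or an unbalanced set")
    work = config
    if jitter > 0.0:
        from dataclasses import replace

        rng = np.random.default_rng(seed)
        moved = tuple(
            replace(o, x=o.x + jitter * rng.standard_normal(),
                    y=o.y + jitter * rng.standard_normal())
            for o in config.openings
        )
        work = replace(config, openings=moved)

    centre, cond_scale = _conditioning_frame(work)
    coeffs = _trimmed_numerator(work, centre, cond_scale)
    if len(coeffs) <= 1:
        return []
    roots = centre + cond_scale * np.roots(coeffs)

    zi, ki = work.positions, work.strengths

    def w_and_dw(z):
        d = z - zi
        return (ki / d).sum(), -(ki / d**2).sum()

    polished = []
    for r in roots:
        z = complex(r)
        for _ in range(50):
            wv, dwv = w_and_dw(z)
            if abs(wv) < residual_tol or dwv == 0:
                break
            step = wv / dwv
            z -= step
            if abs(step) < 1e-16:
                break
        wv, _ = w_and_dw(z)
        polished.append((z, abs(wv)))

    # merge clusters within tolerance -> multiplicity
    used = [False] * len(polished)
    points: list[StagnationPoint] = []
    for i, (z, res) in enumerate(polished):
        if used[i]:
            continue
        cluster = [i]
        for j in range(i + 1, len(polished)):
            if not used[j] and abs(polished[j][0] - z) < merge_tol:
                cluster.append(j)
        for j in cluster:
            used[j] = True
        zc = np.mean([polished[j][0] for j in cluster])
        resc = max(polished[j][1] for j in cluster)
        mult = len(cluster)
        if mult == 1 and resc > residual_tol * max(1.0, np.abs(ki).sum()):
            raise ArithmeticError(
                f"stagnation-point polish did not converge at {zc}: "
                f"|w| = {resc:.3e}"
            )
        points.append(
            StagnationPoint(
                position=complex(zc),
                jacobian=velocity_jacobian(work, zc),
                multiplicity=mult,
                residual=float(resc),
            )
        )
    return points


@dataclass(frozen=True)
class TopologyReport:
    """Node/saddle bookkeeping on the sphere.

    The Euler characteristic of the sphere is 2 regardless of the number of
    collagenous-post holes ``n_d`` (each hole contributes two
    half-crosspoints that cancel its Euler deficit), so posts never change
    the count.  With node index ``sigma_n = +1`` and saddle index
    ``sigma_s = -1`` the identity is ``N_a + N_v = N_s + 2``, where an
    unbalanced configuration counts the node at infinity in ``N_a`` or
    ``N_v`` according to its sign.
    """

    n_a: int
    n_v: int
    n_s: int
    chi: int = 2
    n_d: int = 0
    sigma_n: int = 1
    sigma_s: int = -1
    infinity_node: str | None = None
    n_s_infinity: int = 0
    satisfied: bool = False

    def to_dict(self) -> dict:
        return {
            "N_a": self.n_a,
            "N_v": self.n_v,
            "N_s": self.n_s,
            "chi": self.chi,
            "n_d": self.n_d,
            "infinity_node": self.infinity_node,
            "N_s_infinity": self.n_s_infinity,
            "satisfied": bool(self.satisfied),
        }


def verify_euler_relation(
    config: OpeningConfiguration,
    stagnation_points: list[StagnationPoint] | None = None,
    n_d: int = 0,
) -> TopologyReport:
    """Check ``N_a + N_v = N_s + 2`` with explicit infinity-node bookkeeping.

    Saddle multiplicities are counted with weight (a double zero counts
    twice).  ``n_d`` records post holes for bookkeeping only; they do not
    enter the identity.
    """
    if stagnation_points is None:
        stagnation_points = find_stagnation_points(config)
    n_finite = sum(p.multiplicity for p in stagnation_points)
    n_a, n_v = config.n_a, config.n_v
    infinity = None
    n_s_inf = 0
    if not config.is_balanced:
        infinity = VENULAR_AT_INF if config.net_flux > 0 else ARTERIOLAR_AT_INF
        if config.net_flux > 0:
            n_v += 1
        else:
            n_a += 1
    else:
        # a balanced configuration whose low multipole moments vanish by
        # symmetry carries a saddle of the spherical field at infinity:
        # w ~ c/z^(2+p) there, a saddle of multiplicity p, and the finite
        # numerator degree drops to N - 2 - p
        centre, cond_scale = _conditioning_frame(config)
        degree = max(len(_trimmed_numerator(config, centre, cond_scale)) - 1, 0)
        n_s_inf = max(len(config.openings) - 2 - degree, 0)
    n_s = n_finite + n_s_inf
    satisfied = (n_a + n_v) == (n_s + 2)
    return TopologyReport(
        n_a=n_a, n_v=n_v, n_s=n_s, n_d=n_d,
        infinity_node=infinity, n_s_infinity=n_s_inf, satisfied=satisfied,
    )


VENULAR_AT_INF = "venular"
ARTERIOLAR_AT_INF = "arteriolar"


# ---------------------------------------------------------------------------
# vectorised Lagrangian ensemble advection
# ---------------------------------------------------------------------------

TERMINAL_NONE = -1
TERMINAL_ESCAPED = -2


def trace_ensemble(
    config: OpeningConfiguration,
    z0: np.ndarray,
    t_max: float,
    direction: float = 1.0,
    cfl: float = 0.1,
    bound_radius: float | None = None,
    source_index: int | None = None,
    max_steps: int = 200_000,
):
    """Advect an ensemble of corpuscles in the analytic field ``conj(w)``.

    Classical RK4 with a per-particle adaptive step clamped to ``cfl`` times
    the distance to the nearest opening centre, so trajectories slow down
    (rather than overshoot) as they approach the singular openings.
    Integration of particle *p* stops when it enters the capture disc of an
    opening (other than ``source_index``, whose disc it was released from),
    leaves ``bound_radius``, or accumulates ``t_max`` of travel time.

    Returns ``(T, terminal, z_final)`` where ``terminal[p]`` is the index
    of the capturing opening in ``config.openings``, ``TERMINAL_ESCAPED``
    for particles leaving the bounding circle, or ``TERMINAL_NONE`` for
    particles truncated at ``t_max``.
    """
    zi = config.positions
    ki = config.strengths * direction
    ai = config.radii
    if bound_radius is None:
        bound_radius = 4.0 * max(config.cloud_radius(), 1.0)

    z = np.array(z0, dtype=complex).ravel().copy()
    n = z.size
    T = np.zeros(n)
    terminal = np.full(n, TERMINAL_NONE, dtype=int)
    active = np.ones(n, dtype=bool)

    def u(zz):
        return np.conj((ki / (zz[:, None] - zi)).sum(axis=1))

    def strain(zz):
        # |w'(z)|: the local velocity-gradient scale, which bounds the
        # stable step near saddles where the speed itself is small
        return np.abs((ki / (zz[:, None] - zi) ** 2).sum(axis=1))

    for _ in range(max_steps):
        if not active.any():
            break
        za = z[active]
        dist = np.abs(za[:, None] - zi)
        # capture: inside an opening disc (ignoring the release opening)
        inside = dist <= ai
        if source_index is not None:
            inside[:, source_index] = False
        cap = inside.any(axis=1)
        esc = np.abs(za) > bound_radius
        if cap.any() or esc.any():
            idx_active = np.nonzero(active)[0]
            if cap.any():
                which = np.argmax(inside[cap], axis=1)
                terminal[idx_active[cap]] = which
                active[idx_active[cap]] = False
            if esc.any():
                rem = esc & ~cap
                terminal[idx_active[rem]] = TERMINAL_ESCAPED
                active[idx_active[rem]] = False
            if not active.any():
                break
            za = z[active]
            dist = np.abs(za[:, None] - zi)
        # step length scales with the gap to the nearest opening, floored at
        # half its radius so trajectories actually cross into capture discs;
        # the bounding circle limits the step the same way
        gap = np.maximum(dist - ai, 0.5 * ai).min(axis=1)
        to_bound = np.maximum(bound_radius - np.abs(za), 0.01 * bound_radius)
        gap = np.minimum(gap, to_bound)
        u1 = u(za)
        speed = np.maximum(np.abs(u1), 1e-300)
        dt = np.minimum(cfl * gap / speed, cfl / np.maximum(strain(za), 1e-300))
        dt = np.minimum(dt, t_max - T[active])
        dt = np.maximum(dt, 1e-14)
        k1 = u1
        k2 = u(za + 0.5 * dt * k1)
        k3 = u(za + 0.5 * dt * k2)
        k4 = u(za + dt * k3)
        z[active] = za + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        T[active] += dt
        done = T[active] >= t_max * (1.0 - 1e-12)
        if done.any():
            idx_active = np.nonzero(active)[0]
            active[idx_active[done]] = False
    return T, terminal, z
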