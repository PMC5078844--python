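"""Lagrangian corpuscle travel times and first-order mass extraction.

Corpuscles advect at the mean bulk velocity; the dimensionless travel time
along a streamline from an arteriolar to a venular opening is
``T = integral ds/|u_h|`` (lengths scaled by L, velocities by U).  Exchange
with the outer retina is a first-order process: along a path the blood
concentration decays as ``C(T) = exp(-T/tau)`` with ``1/tau`` the mass
transfer coefficient, so the extraction from a segment is the flux-weighted
average over release angles,

    ``eta = 1 - <exp(-T/tau)>``.

A second-order expansion for ``1/tau << 1`` gives
``eta ~ <T>/tau - <T^2>/(2 tau^2)``; the first term is the mean travel
time, the second measures the mechanical dispersion of travel times.  For
a closed segment the flux-weighted mean travel time equals the perfused
volume over the inflow, ``<T> = (1 - phi) A_0 h / Q_a``, which links
extraction to segment shape: ``eta ~ (1 - phi) A_0 h / (Q_a tau)``.

The shape dependence is scanned over prism segments decomposed into
isosceles triangular portions of apex angle ``omega`` (a regular ``n``-gon
has ``omega = 2 pi / n``); the flow inside a portion is obtained exactly by
a Schwarz-Christoffel map of the triangle onto the upper half-plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import beta as beta_fn

from chorioflow.flow import TERMINAL_NONE, trace_ensemble
from chorioflow.geometry import (
    ARTERIOLAR,
    DEFAULT_RADIUS,
    OpeningConfiguration,
)
from chorioflow.segmentation import FunctionalSegment

__all__ = [
    "StreamlinePath",
    "TravelTimeDistribution",
    "ExtractionResult",
    "ShapeExtractionCurve",
    "TauEstimate",
    "integrate_streamline",
    "travel_time_distribution",
    "mass_extraction",
    "apex_angle_regular",
    "triangular_portion_travel_times",
    "shape_extraction_scan",
    "estimate_tau",
]


# ---------------------------------------------------------------------------
# single-streamline integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StreamlinePath:
    """A traced corpuscle path with its physical (dimensionless) travel time."""

    path: np.ndarray  # (n, 2)
    travel_time: float
    terminal: tuple   # ("opening", id) | ("radius", r) | ("truncated", None)
    truncated: bool


def integrate_streamline(
    config: OpeningConfiguration,
    opening_id: int,
    theta: float,
    t_max: float = 100.0,
    r_stop: float | None = None,
    rtol: float = 1e-10,
) -> StreamlinePath:
    """Integrate one corpuscle path released at angle ``theta`` from a rim.

    The corpuscle starts on the rim (radius ``a``) of the arteriolar
    opening and is advected by ``u_h = conj(w)`` until it enters another
    opening's capture disc, reaches distance ``r_stop`` from the release
    opening (if given), or exhausts ``t_max`` — the latter is expected for
    releases aimed along a separatrix, where the travel time diverges.
    """
    o = config.opening(opening_id)
    if o.kind != ARTERIOLAR:
        raise ValueError("corpuscles are released at arteriolar openings")
    zi, ki, ai = config.positions, config.strengths, config.radii
    self_idx = int(np.nonzero(config.ids == opening_id)[0][0])

    z0 = o.z + o.radius * 1.0001 * np.exp(1j * (theta % (2 * math.pi)))

    def rhs(t, y):
        z = complex(y[0], y[1])
        u = np.conj((ki / (z - zi)).sum())
        return [u.real, u.imag]

    events = []

    def capture(t, y):
        z = complex(y[0], y[1])
        d = np.abs(z - zi) - ai
        d[self_idx] = np.inf
        return d.min()

    capture.terminal = True  # type: ignore[attr-defined]
    events.append(capture)
    if r_stop is not None:
        def ring(t, y):
            return r_stop - abs(complex(y[0], y[1]) - o.z)

        ring.terminal = True  # type: ignore[attr-defined]
        events.append(ring)

    sol = solve_ivp(rhs, (0.0, t_max), [z0.real, z0.imag],
                    events=events, rtol=rtol, atol=1e-12)
    path = sol.y.T
    if sol.t_events[0].size:
        zf = complex(path[-1, 0], path[-1, 1])
        d = np.abs(zf - zi) - ai
        d[self_idx] = np.inf
        terminal = ("opening", int(config.openings[int(np.argmin(d))].id))
        truncated = False
    elif r_stop is not None and sol.t_events[1].size:
        terminal = ("radius", r_stop)
        truncated = False
    else:
        terminal = ("truncated", None)
        truncated = True
    return StreamlinePath(path=path, travel_time=float(sol.t[-1]),
                          terminal=terminal, truncated=truncated)


# ---------------------------------------------------------------------------
# travel-time distributions
# ---------------------------------------------------------------------------


@dataclass
class TravelTimeDistribution:
    """Flux-weighted Lagrangian travel times within one segment.

    ``travel_times`` are the post-free (geometric) times ``T_0``; the
    posts rescale every travel time by the perfused fraction,
    ``T = (1 - phi) T_0``, which :func:`mass_extraction` applies.
    Uniform-in-angle release at an axisymmetric arteriolar rim is
    flux-weighted by construction, so plain sample means are the
    flux-weighted averages.
    """

    arteriole_id: int
    theta: np.ndarray
    travel_times: np.ndarray
    terminal_ids: np.ndarray  # venular opening id, or -1 for truncated
    t_max: float
    q_a: float                # dimensionless arteriolar flow, 2 pi k_a
    weights: np.ndarray | None = None  # rim-flux weights, sum to 1

    @property
    def n(self) -> int:
        return self.travel_times.size

    @property
    def w(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n, 1.0 / self.n)
        return self.weights

    @property
    def cap_hits(self) -> int:
        return int((self.terminal_ids < 0).sum())

    @property
    def mean(self) -> float:
        """Flux-weighted mean post-free travel time ``<T>_0``."""
        return float(self.w @ self.travel_times)

    @property
    def dispersion(self) -> float:
        """Second central moment of the travel time (mechanical dispersion)."""
        return float(self.w @ (self.travel_times - self.mean) ** 2)

    @property
    def se_mean(self) -> float:
        w = self.w
        return float(math.sqrt((w**2 * (self.travel_times - self.mean) ** 2).sum()))

    def mean_with_posts(self, phi: float) -> float:
        return (1.0 - phi) * self.mean


def travel_time_distribution(
    config: OpeningConfiguration,
    segment: FunctionalSegment,
    n_particles: int = 10_000,
    seed: int | None = 0,
    t_max: float | None = None,
) -> TravelTimeDistribution:
    """Monte-Carlo travel-time distribution of one functional segment.

    ``n_particles`` corpuscles are released uniformly in angle from the
    arteriolar rim and advected to venular capture.  ``t_max`` defaults to
    50x the residence-time estimate ``A_0/Q_a``; trajectories still in
    flight at ``t_max`` (separatrix-adjacent releases) are kept at the cap
    value and flagged by ``terminal_ids == -1``.  Identical seeds give
    identical samples.
    """
    if n_particles < 100:
        raise ValueError("n_particles must be at least 100")
    art = config.opening(segment.arteriole_id)
    q_a = 2.0 * math.pi * art.strength
    if t_max is None:
        if segment.polygon is None:
            raise ValueError("open segment: pass t_max explicitly")
        t_max = 50.0 * segment.area_0 / q_a
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_particles)
    z0 = art.z + art.radius * 1.0001 * np.exp(1j * theta)
    # the source term dominates at the rim but the background field of the
    # other openings modulates the local outward flux by O(a); weighting
    # each release by the radial rim velocity makes the averages exactly
    # flux-weighted
    from chorioflow.flow import velocity as _velocity

    u_rim = _velocity(config, z0, warn=False)
    u_r = np.maximum((u_rim * np.exp(-1j * theta)).real, 0.0)
    weights = u_r / u_r.sum()
    src_idx = int(np.nonzero(config.ids == art.id)[0][0])
    T, terminal, _ = trace_ensemble(config, z0, t_max=t_max,
                                    source_index=src_idx)
    term_ids = np.where(terminal >= 0, config.ids[np.maximum(terminal, 0)], -1)
    dist = TravelTimeDistribution(
        arteriole_id=art.id, theta=theta, travel_times=T,
        terminal_ids=term_ids, t_max=float(t_max), q_a=q_a, weights=weights,
    )
    if dist.cap_hits > 0.01 * n_particles:
        warnings.warn(
            f"{dist.cap_hits}/{n_particles} trajectories truncated at "
            f"t_max={t_max:.3g}; consider a larger t_max",
            stacklevel=2,
        )
    return dist


# ---------------------------------------------------------------------------
# mass extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionResult:
    """Exact and asymptotic mass extraction for one travel-time sample.

    ``eta_exact = 1 - <exp(-T/tau)>`` with ``T = (1 - phi) T_0``;
    ``eta_leading = <T>/tau``; ``eta_asymptotic`` additionally subtracts
    the mechanical-dispersion term ``<T^2>/(2 tau^2)``.
    """

    eta_exact: float
    eta_asymptotic: float
    eta_leading: float
    dispersion_term: float
    tau: float
    phi: float
    mean_travel_time: float     # <T> including posts
    mean_travel_time_0: float   # <T>_0 post-free

    def lambda_rate(self, time_scale: float) -> float:
        """Dimensional exchange rate ``lambda = 1/(tau * L/U)`` (1/s)."""
        return 1.0 / (self.tau * time_scale)


def mass_extraction(
    dist: TravelTimeDistribution,
    tau: float,
    phi: float = 0.0,
) -> ExtractionResult:
    """First-order mass extraction from a travel-time distribution.

    Truncated samples enter with the cap value (their true contribution to
    ``<exp(-T/tau)>`` is smaller than ``exp(-t_max/tau)``, a negligible
    bias at the default 50x cap).  Posts enter only through the perfused
    fraction: every travel time is multiplied by ``1 - phi``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must lie in [0, 1)")
    if dist.n == 0:
        raise ValueError("empty travel-time distribution")
    if dist.cap_hits == dist.n:
        raise ValueError("all trajectories truncated: distribution unusable")
    T = (1.0 - phi) * dist.travel_times
    w = dist.w
    eta_exact = float(1.0 - w @ np.exp(-T / tau))
    mean_T = float(w @ T)
    mean_T2 = float(w @ T**2)
    eta_leading = mean_T / tau
    disp = mean_T2 / (2.0 * tau**2)
    return ExtractionResult(
        eta_exact=eta_exact,
        eta_asymptotic=eta_leading - disp,
        eta_leading=eta_leading,
        dispersion_term=disp,
        tau=float(tau),
        phi=float(phi),
        mean_travel_time=mean_T,
        mean_travel_time_0=dist.mean,
    )


# ---------------------------------------------------------------------------
# shape of the segment vs extraction
# ---------------------------------------------------------------------------


def apex_angle_regular(n_sides: int | float) -> float:
    """Apex angle ``omega = 2 pi / n`` of a regular ``n``-gon's portions.

    ``omega = pi/2`` characterises a square, ``2 pi/3`` a triangle,
    ``pi/3`` a hexagon.  Strictly decreasing in ``n``.
    """
    if n_sides < 3:
        raise ValueError("a regular polygonal segment needs >= 3 sides")
    return 2.0 * math.pi / float(n_sides)


def _triangle_map_constants(omega: float):
    """Schwarz-Christoffel data for the unit-leg isosceles triangle.

    The triangle has apex angle ``omega`` at the arteriole and base angles
    ``delta = (pi - omega)/2`` at the two venules; legs (apex to base
    corner) have length 1, the arteriole-venule distance.  Prevertices are
    ``0`` (apex) and ``+/-1`` (corners) on the real axis of the upper
    half-plane; the derivative of the map is

        ``f'(z) = C (z+1)^(d-1) z^(w-1) (z-1)^(d-1)``

    with ``w = omega/pi``, ``d = delta/pi`` and the Beta-function
    normalisation ``C = 2 / B(omega/(2 pi), delta/pi)`` fixing unit legs.
    """
    if not 0.0 < omega < math.pi:
        raise ValueError("omega must lie in (0, pi)")
    delta = 0.5 * (math.pi - omega)
    w_exp = omega / math.pi
    d_exp = delta / math.pi
    C = 2.0 / beta_fn(omega / (2.0 * math.pi), d_exp)
    return delta, w_exp, d_exp, C


def triangular_portion_travel_times(
    omega: float,
    n_particles: int = 400,
    seed: int | None = 0,
    q: float = 2.0 * math.pi,
    opening_radius: float = DEFAULT_RADIUS,
    t_max: float | None = None,
    cfl: float = 0.08,
    max_steps: int = 400_000,
) -> TravelTimeDistribution:
    """Travel times inside one isosceles triangular portion of apex ``omega``.

    The portion is the unit-leg isosceles triangle with the arteriole at
    the apex (inflow ``q`` through the wedge), half-venules at the two base
    corners and no-flux walls elsewhere; its two legs are streamlines of
    the prism segment and its base is the separatrix shared with the
    neighbouring segment.  The flow is computed exactly in the upper
    half-plane through the Schwarz-Christoffel map ``f``: trajectories are
    advected by the half-plane potential

        ``W(z) = (q/pi) ln z - (q/2 pi) ln(z-1) - (q/2 pi) ln(z+1)``

    and physical time accumulates with the Jacobian ``|f'(z)|^2``.  The
    saddle of the prism flow is the image of ``z = infinity`` (the
    mid-base point); releases aimed at it are truncated at ``t_max``.
    """
    delta, w_exp, d_exp, C = _triangle_map_constants(omega)
    area = 0.5 * math.sin(omega)
    if t_max is None:
        t_max = 50.0 * area / q
    # release/capture radii in the half-plane from the local map behaviour;
    # sharp base corners make the map so compressive that the preimage of
    # the physical capture disc can fall below machine precision, so the
    # capture radius is floored and the analytic corner-sink remainder
    # (radial flow q/2 through the corner angle delta) added on capture
    corner_scale = C * 2.0 ** (d_exp - 1.0) / d_exp  # |dz| = scale*|zeta-+1|^d
    rho_cap_exact = (opening_radius / corner_scale) ** (1.0 / d_exp)
    rho_cap = max(rho_cap_exact, 1e-11)
    rho_rel = (opening_radius * w_exp / C) ** (1.0 / w_exp)

    # stratified flux-weighted release: one jittered sample per angular
    # stratum (equal flux per stratum), which sharply reduces the variance
    # of flux-weighted means while staying deterministic under the seed
    rng = np.random.default_rng(seed)
    phi_rel = (np.arange(n_particles) + rng.uniform(size=n_particles)) \
        / n_particles * math.pi
    z = rho_rel * np.exp(1j * phi_rel)
    theta = omega * phi_rel / math.pi  # physical release angle from one leg

    T = np.zeros(n_particles)
    terminal = np.full(n_particles, TERMINAL_NONE, dtype=int)
    active = np.ones(n_particles, dtype=bool)

    qpi = q / math.pi

    def zeta_velocity(zz):
        return np.conj(-qpi / (zz * (zz * zz - 1.0)))

    def jac(zz):
        return (C * C
                * np.abs(zz + 1.0) ** (2.0 * (d_exp - 1.0))
                * np.abs(zz) ** (2.0 * (w_exp - 1.0))
                * np.abs(zz - 1.0) ** (2.0 * (d_exp - 1.0)))

    for _ in range(max_steps):
        if not active.any():
            break
        za = z[active]
        d_m = np.abs(za - 1.0)
        d_p = np.abs(za + 1.0)
        cap = (d_m <= rho_cap) | (d_p <= rho_cap)
        if cap.any():
            idx = np.nonzero(active)[0]
            hit = idx[cap]
            terminal[hit] = np.where(d_m[cap] <= rho_cap, 1, 2)
            # analytic remainder from the stopping radius down to the rim
            r_phys = corner_scale * np.minimum(d_m[cap], d_p[cap]) ** d_exp
            extra = delta * np.maximum(r_phys**2 - opening_radius**2, 0.0) / q
            T[hit] += extra
            active[hit] = False
            if not active.any():
                break
            za = z[active]
            d_m = np.abs(za - 1.0)
            d_p = np.abs(za + 1.0)
        gap = np.minimum(np.minimum(d_m, d_p), np.abs(za))
        v = zeta_velocity(za)
        speed = np.maximum(np.abs(v), 1e-300)
        J = jac(za)
        # step limited both in map distance and in accrued physical time
        ds = cfl * gap / speed
        ds = np.minimum(ds, (t_max - T[active]) / np.maximum(J, 1e-300))
        ds = np.maximum(ds, 1e-300)
        k1 = v
        k2 = zeta_velocity(za + 0.5 * ds * k1)
        k3 = zeta_velocity(za + 0.5 * ds * k2)
        k4 = zeta_velocity(za + ds * k3)
        z_new = za + (ds / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        # physical time: trapezoid of |f'|^2 along the sub-step
        T[active] += 0.5 * (J + jac(z_new)) * ds
        z[active] = z_new
        done = T[active] >= t_max
        if done.any():
            idx = np.nonzero(active)[0]
            active[idx[done]] = False
    T = np.minimum(T, t_max)
    term_ids = np.where(terminal > 0, terminal, -1)
    return TravelTimeDistribution(
        arteriole_id=0, theta=theta, travel_times=T,
        terminal_ids=term_ids, t_max=float(t_max), q_a=q,
    )


@dataclass(frozen=True)
class ShapeExtractionCurve:
    """Extraction ``eta`` versus apex angle ``omega`` at fixed flow and tau."""

    omegas: np.ndarray
    eta: np.ndarray
    mean_travel_times: np.ndarray
    tau: float
    phi: float
    q_a: float

    @property
    def argmax_omega(self) -> float:
        return float(self.omegas[int(np.argmax(self.eta))])


def shape_extraction_scan(
    omega_grid,
    tau: float,
    q_a: float = 2.0 * math.pi,
    phi: float = 0.0,
    n_particles: int = 400,
    seed: int | None = 0,
    t_max: float | None = None,
) -> ShapeExtractionCurve:
    """Scan mass extraction over segment shapes at fixed flow rate and tau.

    For each apex angle ``omega`` the flow through the unit-leg triangular
    portion is held at ``q_a`` and venular pressures are equal (zero), so
    the portion geometry alone varies.  At leading order
    ``eta ~ (1 - phi) A_0 / (q_a tau)`` with ``A_0 = sin(omega)/2``: the
    extraction is maximal for ``omega = pi/2``, the square segment.
    """
    omegas = np.asarray(omega_grid, dtype=float)
    if np.any((omegas <= 0.0) | (omegas >= math.pi)):
        raise ValueError("omega values must lie in (0, pi)")
    etas = np.empty_like(omegas)
    means = np.empty_like(omegas)
    for i, om in enumerate(omegas):
        # common random numbers across omegas: the shape comparison is
        # paired, so release-angle noise largely cancels in the argmax
        dist = triangular_portion_travel_times(
            om, n_particles=n_particles, seed=seed, q=q_a, t_max=t_max
        )
        res = mass_extraction(dist, tau=tau, phi=phi)
        etas[i] = res.eta_exact
        means[i] = res.mean_travel_time
    return ShapeExtractionCurve(
        omegas=omegas, eta=etas, mean_travel_times=means,
        tau=float(tau), phi=float(phi), q_a=float(q_a),
    )


# ---------------------------------------------------------------------------
# tau estimation from in-vivo measurements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TauEstimate:
    """Range of the mass-transfer time implied by measured extraction."""

    tau_seconds: tuple[float, float]
    tau_dimensionless: tuple[float, float]
    eta_range: tuple[float, float]
    travel_time_seconds: float


def estimate_tau(
    eta_measured: tuple[float, float],
    T_measured: float,
    U: float = 1.0e-3,
    L: float = 600e-6,
) -> TauEstimate:
    """Invert the leading-order extraction relation for ``tau``.

    From ``eta ~ <T>/tau``, a measured extraction fraction and mean
    angiographic travel time give ``tau = <T>_measured / eta_measured``;
    the range follows from the extraction range (larger extraction means a
    faster exchange, hence smaller ``tau`` — the estimate is inversely
    proportional to ``eta``).  Returned both in seconds and nondimensional
    (scaled by ``L/U``).
    """
    lo, hi = sorted(eta_measured)
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError("measured extraction must lie strictly in (0, 1)")
    if T_measured <= 0 or U <= 0 or L <= 0:
        raise ValueError("T_measured, U and L must be positive")
    tau_s = (T_measured / hi, T_measured / lo)
    ts = L / U
    return TauEstimate(
        tau_seconds=tau_s,
        tau_dimensionless=(tau_s[0] / ts, tau_s[1] / ts),
        eta_range=(lo, hi),
        travel_time_seconds=float(T_measured),
    )
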