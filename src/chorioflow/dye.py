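"""Simulated fluorescent-dye angiography: 2-D passive-scalar transport.

The dye concentration obeys the advection-diffusion equation
``dC/dt + u_h . grad C = D lap C`` with the analytic multipole velocity
field, a no-flux condition on a circle enclosing the openings, zero initial
concentration, and a double-Heaviside inlet schedule: every arteriolar
opening is held at ``C = C0`` between ``t_on`` and ``t_off`` (filling) and
at ``C = 0`` afterwards (flushing).  Venular openings remove dye
advectively with no diffusive re-entry.

Discretisation: conservative finite-volume donor-cell upwinding for
advection plus explicit central differences for diffusion, operator-split,
with the time step set by the CFL and diffusive stability limits.  Speeds
are capped at the rim speed of the smallest opening (the continuum model is
invalid inside the rim anyway), which keeps the CFL limit finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from chorioflow.geometry import ARTERIOLAR, OpeningConfiguration

__all__ = [
    "DyeSimulation",
    "ArrivalTimeMap",
    "simulate_dye",
    "arrival_time_map",
]

UNREACHED = np.inf  # sentinel for cells that never cross the threshold


@dataclass
class DyeSimulation:
    """Space-time concentration field of the simulated angiogram."""

    x: np.ndarray            # cell-centre coordinates, shape (nx,)
    y: np.ndarray            # shape (ny,)
    times: np.ndarray        # output times, shape (nt,)
    frames: np.ndarray       # concentrations, shape (nt, ny, nx)
    mask: np.ndarray         # True inside the flow domain (circle)
    c0: float
    schedule: tuple[float, float]
    diffusivity: float
    total_mass: np.ndarray   # mass inside the domain at each output time
    peclet: float

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def sample(self, t: float, xy: tuple[float, float]) -> float:
        """Concentration at the output frame nearest ``t``, cell of ``xy``."""
        it = int(np.argmin(np.abs(self.times - t)))
        ix = int(np.argmin(np.abs(self.x - xy[0])))
        iy = int(np.argmin(np.abs(self.y - xy[1])))
        return float(self.frames[it, iy, ix])


def _face_velocities(config: OpeningConfiguration, x: np.ndarray,
                     y: np.ndarray, u_cap: float):
    """Donor-cell face-normal velocities of ``conj(w)`` with speed capped."""
    dx = x[1] - x[0]
    xf = np.concatenate([x - dx / 2, [x[-1] + dx / 2]])
    yf = np.concatenate([y - dx / 2, [y[-1] + dx / 2]])
    zi, ki = config.positions, config.strengths

    def vel(zz):
        w = (ki / (zz[..., None] - zi)).sum(axis=-1)
        u = np.conj(w)
        s = np.abs(u)
        over = s > u_cap
        u = np.where(over, u * (u_cap / np.where(s == 0, 1.0, s)), u)
        return u

    zx = xf[None, :] + 1j * y[:, None]        # x-faces: (ny, nx+1)
    zy = x[None, :] + 1j * yf[:, None]        # y-faces: (ny+1, nx)
    return vel(zx).real, vel(zy).imag


def simulate_dye(
    config: OpeningConfiguration | None,
    grid_n: int = 128,
    extent: float | None = None,
    D: float = 2e-3,
    schedule: tuple[float, float] = (0.0, 2.0),
    t_end: float = 4.0,
    c0: float = 1.0,
    output_stride: int = 20,
    bound_radius: float | None = None,
    cfl: float = 0.4,
    initial_condition: np.ndarray | None = None,
) -> DyeSimulation:
    """Run the filling/flushing simulation on a ``grid_n`` x ``grid_n`` mesh.

    ``extent`` is the half-width of the square mesh (defaults to the
    bounding circle radius); ``schedule = (t_on, t_off)`` is the double
    Heaviside.  ``D`` is the dimensionless diffusivity ``1/Pe``.  Raises
    if the grid does not resolve the smallest opening with at least four
    cells across its diameter.  With ``config=None`` the run is pure
    diffusion of ``initial_condition`` in the no-flux circle (the analytic
    heat-kernel / mass-conservation reference mode).
    """
    t_on, t_off = schedule
    if not (0.0 <= t_on < t_off):
        raise ValueError("schedule times must satisfy 0 <= t_on < t_off")
    if D <= 0:
        raise ValueError("diffusivity must be positive")
    if bound_radius is None:
        bound_radius = max(3.0 * config.cloud_radius(), 1.5) if config else 1.5
    if extent is None:
        extent = 1.02 * bound_radius
    dx = 2.0 * extent / grid_n
    if config is not None:
        a_min = float(config.radii.min())
        if dx > a_min / 2.0:
            raise ValueError(
                f"grid too coarse: dx={dx:.4g} but openings of radius "
                f"{a_min:.4g} need at least 4 cells across "
                f"(dx <= {a_min / 2:.4g})"
            )
    x = np.linspace(-extent + dx / 2, extent - dx / 2, grid_n)
    y = x.copy()
    X, Y = np.meshgrid(x, y)
    R = np.hypot(X, Y)
    mask = R <= bound_radius

    art_cells = np.zeros_like(mask)
    ven_cells = np.zeros_like(mask)
    if config is not None:
        for o in config.openings:
            disc = np.hypot(X - o.x, Y - o.y) <= o.radius
            if o.kind == ARTERIOLAR:
                art_cells |= disc
            else:
                ven_cells |= disc
        if not art_cells.any() and config.n_a:
            raise ValueError("grid does not resolve any arteriolar opening cell")

    if config is not None and len(config.openings):
        u_cap = float((np.abs(config.strengths) / config.radii).max())
        ux, uy = _face_velocities(config, x, y, u_cap)
    else:
        ux = np.zeros((grid_n, grid_n + 1))
        uy = np.zeros((grid_n + 1, grid_n))

    # zero advective flux through faces leaving the domain mask
    open_x = np.zeros_like(ux, dtype=bool)
    open_x[:, 1:-1] = mask[:, 1:] & mask[:, :-1]
    open_y = np.zeros_like(uy, dtype=bool)
    open_y[1:-1, :] = mask[1:, :] & mask[:-1, :]
    ux = np.where(open_x, ux, 0.0)
    uy = np.where(open_y, uy, 0.0)

    # diffusion acts through interior faces, but not into venular sink
    # cells (advective removal only, no diffusive re-entry)
    diff_x = open_x.copy()
    diff_x[:, 1:-1] &= ~(ven_cells[:, 1:] | ven_cells[:, :-1])
    diff_y = open_y.copy()
    diff_y[1:-1, :] &= ~(ven_cells[1:, :] | ven_cells[:-1, :])

    umax = max(np.abs(ux).max(), np.abs(uy).max(), 1e-12)
    dt = cfl * min(dx / umax, dx * dx / (4.0 * D))
    n_steps = int(math.ceil(t_end / dt))
    dt = t_end / n_steps

    C = np.zeros_like(X)
    if initial_condition is not None:
        C[:] = initial_condition
        C[~mask] = 0.0
    frames, times, mass = [], [], []

    def record(t):
        frames.append(C.astype(np.float32))
        times.append(t)
        mass.append(float(C[mask].sum() * dx * dx))

    record(0.0)
    lam = D * dt / (dx * dx)
    for step in range(1, n_steps + 1):
        t = step * dt
        inlet_on = t_on <= t < t_off
        # inlet enforcement (Dirichlet over the opening disc)
        C[art_cells] = c0 if inlet_on else 0.0
        # advection: donor-cell upwind fluxes
        Fx = np.where(ux[:, 1:-1] > 0, C[:, :-1], C[:, 1:]) * ux[:, 1:-1]
        Fy = np.where(uy[1:-1, :] > 0, C[:-1, :], C[1:, :]) * uy[1:-1, :]
        div = np.zeros_like(C)
        div[:, :-1] += Fx
        div[:, 1:] -= Fx
        div[:-1, :] += Fy
        div[1:, :] -= Fy
        C -= dt / dx * div
        # diffusion: explicit, through permitted faces only
        Gx = np.where(diff_x[:, 1:-1], C[:, 1:] - C[:, :-1], 0.0)
        Gy = np.where(diff_y[1:-1, :], C[1:, :] - C[:-1, :], 0.0)
        dC = np.zeros_like(C)
        dC[:, :-1] += Gx
        dC[:, 1:] -= Gx
        dC[:-1, :] += Gy
        dC[1:, :] -= Gy
        C += lam * dC
        # venular cells drain: dye entering them is removed
        C[ven_cells] = 0.0
        C[art_cells] = c0 if inlet_on else 0.0
        np.clip(C, 0.0, None, out=C)
        if step % output_stride == 0 or step == n_steps:
            record(t)

    peclet = 1.0 / D
    return DyeSimulation(
        x=x, y=y, times=np.array(times), frames=np.array(frames),
        mask=mask, c0=c0, schedule=(t_on, t_off), diffusivity=D,
        total_mass=np.array(mass), peclet=peclet,
    )


@dataclass
class ArrivalTimeMap:
    """First time each cell's concentration crosses a threshold."""

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray      # (ny, nx); UNREACHED where never crossed
    threshold: float

    def at(self, xy: tuple[float, float]) -> float:
        ix = int(np.argmin(np.abs(self.x - xy[0])))
        iy = int(np.argmin(np.abs(self.y - xy[1])))
        return float(self.times[iy, ix])


def arrival_time_map(sim: DyeSimulation, threshold: float = 0.5) -> ArrivalTimeMap:
    """Per-cell first-crossing times of ``threshold * C0`` during filling.

    Cells never reaching the threshold carry the ``UNREACHED`` sentinel.
    Arrival times are weakly increasing in the threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    level = threshold * sim.c0
    nt, ny, nx = sim.frames.shape
    arrived = sim.frames >= level
    never = ~arrived.any(axis=0)
    times = sim.times[np.argmax(arrived, axis=0)]
    times = np.where(never, UNREACHED, times)
    times = np.where(sim.mask, times, UNREACHED)
    return ArrivalTimeMap(x=sim.x, y=sim.y, times=times, threshold=threshold)
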