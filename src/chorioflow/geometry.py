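"""Opening configurations: the boundary data of the choriocapillaris model.

The choriocapillaris is fed by arterioles and drained by venules inserting
approximately perpendicular to the capillary plane.  In the planar model an
arteriolar opening is a point source of strength ``k > 0`` and a venular
opening a point sink (``k < 0``); ``k`` is a flux per unit slab depth, so the
volumetric flow rate of opening *i* is ``Q_i = 2*pi*k_i*h``.

All geometry is nondimensional: lengths are scaled by ``L``, the
characteristic arteriole-venule distance, and velocities by ``U``.
Dimensional values are restored only at reporting time via
:class:`PhysicalParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

__all__ = [
    "ARTERIOLAR",
    "VENULAR",
    "DEFAULT_RADIUS",
    "Opening",
    "OpeningConfiguration",
    "PhysicalParams",
    "PackingError",
    "BalanceError",
    "FormatError",
    "generate_random_openings",
    "generate_lattice_openings",
    "read_openings",
    "write_openings",
    "balance_fluxes",
]

ARTERIOLAR = "arteriolar"
VENULAR = "venular"
_KINDS = (ARTERIOLAR, VENULAR)

#: Default opening radius, nondimensional: openings are typically 10-25 um in
#: diameter while the arteriole-venule spacing L is ~600 um, so a ~ 10/600.
DEFAULT_RADIUS = 10e-6 / 600e-6


class PackingError(RuntimeError):
    """Rejection sampling could not place openings at the requested separation."""


class BalanceError(ValueError):
    """Flux balance is impossible (no venular openings in a bounded domain)."""


class FormatError(ValueError):
    """An opening-map file is malformed; the message names the offending line."""


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional scales of the slab.

    Parameters
    ----------
    L : characteristic arteriole-venule distance (m).
    h : slab (choriocapillaris) thickness (m).
    phi : volume fraction occupied by intercapillary collagenous posts,
        ``0 <= phi < 1``; anatomical range is roughly 0.25-0.5.
    mu : blood viscosity (Pa s).
    U : characteristic in-plane blood speed (m/s), from in vivo angiography.
    D : tracer diffusivity (m^2/s) used by the dye simulation.
    """

    L: float = 600e-6
    h: float = 15e-6
    phi: float = 0.3
    mu: float = 3e-3
    U: float = 1.0e-3
    D: float = 1.0e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")
        for name in ("L", "h", "mu", "U", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def K(self) -> float:
        """Hele-Shaw permeability between parallel plates, ``h**2/12`` (m^2)."""
        return self.h**2 / 12.0

    @property
    def time_scale(self) -> float:
        """Advective time scale ``L/U`` (s) converting dimensionless times."""
        return self.L / self.U

    def to_dict(self) -> dict:
        return {"L": self.L, "h": self.h, "phi": self.phi, "mu": self.mu,
                "U": self.U, "D": self.D}

    @classmethod
    def from_dict(cls, block: dict) -> "PhysicalParams":
        known = {"L", "h", "phi", "mu", "U", "D"}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown physical parameter(s): {sorted(unknown)}")
        return cls(**block)


@dataclass(frozen=True)
class Opening:
    """A single arteriolar or venular opening.

    ``strength`` is the source strength per unit depth; its sign must match
    ``kind`` (positive for arteriolar, negative for venular).
    """

    id: int
    kind: str
    x: float
    y: float
    strength: float
    radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("opening radius must be positive")
        if self.strength == 0:
            raise ValueError("opening strength must be nonzero")
        if self.kind == ARTERIOLAR and self.strength < 0:
            raise ValueError("arteriolar opening must have positive strength")
        if self.kind == VENULAR and self.strength > 0:
            raise ValueError("venular opening must have negative strength")

    @property
    def z(self) -> complex:
        return complex(self.x, self.y)


@dataclass(frozen=True)
class OpeningConfiguration:
    """A set of openings plus the physical scales of the slab.

    ``domain`` is ``"bounded_disc"`` for a flux-balanced set viewed in a
    bounded region, or ``"plane_with_infinity"`` where a net source/sink
    imbalance is legal and the point at infinity is bookkept as a single
    node of the opposite sign (the extended plane is the Riemann sphere).
    """

    openings: tuple[Opening, ...]
    domain: str = "bounded_disc"
    params: PhysicalParams = field(default_factory=PhysicalParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "openings", tuple(self.openings))
        if self.domain not in ("bounded_disc", "plane_with_infinity"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.n_a < 1:
            raise ValueError("a configuration needs at least one arteriolar opening")
        if self.n_v == 0 and self.domain == "bounded_disc":
            raise BalanceError(
                "no venular openings: only legal in plane_with_infinity, "
                "where the point at infinity acts as the sink"
            )
        ids = [o.id for o in self.openings]
        if len(set(ids)) != len(ids):
            raise ValueError("opening ids must be unique")
        z = self.positions
        a = self.radii
        if len(z) > 1:
            d = np.abs(z[:, None] - z[None, :])
            limit = a[:, None] + a[None, :]
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d - limit), d.shape)
            if d[i, j] <= limit[i, j]:
                raise ValueError(
                    f"openings {self.openings[i].id} and {self.openings[j].id} overlap"
                )

    # -- derived arrays -------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return np.array([o.z for o in self.openings], dtype=complex)

    @property
    def strengths(self) -> np.ndarray:
        return np.array([o.strength for o in self.openings], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([o.radius for o in self.openings], dtype=float)

    @property
    def ids(self) -> np.ndarray:
        return np.array([o.id for o in self.openings], dtype=int)

    @property
    def n_a(self) -> int:
        return sum(1 for o in self.openings if o.kind == ARTERIOLAR)

    @property
    def n_v(self) -> int:
        return sum(1 for o in self.openings if o.kind == VENULAR)

    @property
    def net_flux(self) -> float:
        """Net strength ``sum(k_i)``; zero for a balanced configuration."""
        return float(self.strengths.sum())

    @property
    def is_balanced(self) -> bool:
        tot = np.abs(self.strengths).sum()
        return abs(self.net_flux) < 1e-12 * max(tot, 1.0)

    def opening(self, opening_id: int) -> Opening:
        for o in self.openings:
            if o.id == opening_id:
                return o
        raise KeyError(f"no opening with id {opening_id}")

    def arterioles(self) -> list[Opening]:
        return [o for o in self.openings if o.kind == ARTERIOLAR]

    def venules(self) -> list[Opening]:
        return [o for o in self.openings if o.kind == VENULAR]

    def cloud_radius(self) -> float:
        return float(np.abs(self.positions).max()) if self.openings else 0.0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_random_openings(
    n_a: int,
    n_v: int,
    domain_radius: float = 2.5,
    min_separation: float = 0.4,
    seed: int | None = 0,
    strength_mode: str = "equal",
    radius: float = DEFAULT_RADIUS,
    params: PhysicalParams | None = None,
    max_attempts: int = 20_000,
) -> OpeningConfiguration:
    """Scatter ``n_a`` arteriolar and ``n_v`` venular openings in a disc.

    Positions are drawn uniformly in the disc of ``domain_radius`` by
    rejection sampling with pairwise centre separation >= ``min_separation``.
    Strengths: ``"equal"`` gives every arteriole ``k = +1``; ``"random"``
    draws arteriolar strengths uniformly in [0.5, 1.5].  Venular strengths
    are set by flux balance in either mode.  Identical seeds give identical
    configurations.
    """
    if n_a < 1:
        raise ValueError("n_a must be at least 1")
    if n_v < 0:
        raise ValueError("n_v must be nonnegative")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    if strength_mode not in ("equal", "random"):
        raise ValueError(f"unknown strength_mode {strength_mode!r}")
    rng = np.random.default_rng(seed)
    n = n_a + n_v
    pts: list[complex] = []
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n} openings with separation "
                f"{min_separation} in a disc of radius {domain_radius} "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        r = domain_radius * math.sqrt(rng.uniform())
        t = rng.uniform(0.0, 2.0 * math.pi)
        z = r * complex(math.cos(t), math.sin(t))
        if all(abs(z - q) >= min_separation for q in pts):
            pts.append(z)

    if strength_mode == "equal":
        ka = np.ones(n_a)
    else:
        ka = rng.uniform(0.5, 1.5, size=n_a)
    openings = [
        Opening(i, ARTERIOLAR, pts[i].real, pts[i].imag, float(ka[i]), radius)
        for i in range(n_a)
    ]
    if n_v > 0:
        kv = -np.ones(n_v) if strength_mode == "equal" else -rng.uniform(0.5, 1.5, size=n_v)
        kv *= ka.sum() / (-kv.sum())  # flux balance
        openings += [
            Opening(n_a + j, VENULAR, pts[n_a + j].real, pts[n_a + j].imag,
                    float(kv[j]), radius)
            for j in range(n_v)
        ]
        domain = "bounded_disc"
    else:
        domain = "plane_with_infinity"
    return OpeningConfiguration(tuple(openings), domain,
                                params or PhysicalParams())


def generate_lattice_openings(
    lattice: str,
    n_cells: int,
    radius: float = DEFAULT_RADIUS,
    params: PhysicalParams | None = None,
) -> OpeningConfiguration:
    """Regular lattice of openings: the idealised, shape-controlled fixture.

    ``"square"``: arterioles at the centres of an ``n x n`` grid of square
    cells, venules at the cell corners; interior segments are squares
    (4 venular vertices).  ``"honeycomb"``: arterioles on an ``n x n``
    rhombus of a triangular lattice, venules at the surrounding honeycomb
    vertices; interior segments are regular hexagons.  Venular strengths are
    weighted by the number of cells sharing each vertex so that the finite
    patch reproduces the infinite-lattice flow in its interior, and the
    whole configuration is exactly flux balanced.

    The arteriole-venule distance is 1 (the length unit).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if lattice == "square":
        s = math.sqrt(2.0)  # cell side so that centre-corner distance is 1
        openings: list[Opening] = []
        oid = 0
        for i in range(n_cells):
            for j in range(n_cells):
                openings.append(Opening(oid, ARTERIOLAR, (i + 0.5) * s,
                                        (j + 0.5) * s, 1.0, radius))
                oid += 1
        for i in range(n_cells + 1):
            for j in range(n_cells + 1):
                # number of adjacent cells: interior 4, edge 2, corner 1
                adj = (2 if 0 < i < n_cells else 1) * (2 if 0 < j < n_cells else 1)
                openings.append(Opening(oid, VENULAR, i * s, j * s,
                                        -adj / 4.0, radius))
                oid += 1
        return OpeningConfiguration(tuple(openings), "bounded_disc",
                                    params or PhysicalParams())
    if lattice == "honeycomb":
        # hexagon centres on a triangular lattice with centre-vertex distance 1
        a1 = complex(math.sqrt(3.0), 0.0)
        a2 = complex(math.sqrt(3.0) / 2.0, 1.5)
        centres = [i * a1 + j * a2 for i in range(n_cells) for j in range(n_cells)]
        hex_angles = [math.pi / 2 + k * math.pi / 3 for k in range(6)]
        verts: dict[tuple[int, int], list[complex]] = {}
        adj_count: dict[tuple[int, int], int] = {}
        for c in centres:
            for t in hex_angles:
                v = c + complex(math.cos(t), math.sin(t))
                key = (round(v.real * 1e6), round(v.imag * 1e6))
                verts.setdefault(key, []).append(v)
                adj_count[key] = adj_count.get(key, 0) + 1
        openings = []
        oid = 0
        for c in centres:
            openings.append(Opening(oid, ARTERIOLAR, c.real, c.imag, 1.0, radius))
            oid += 1
        total_w = sum(adj_count.values()) / 3.0  # == 2 * n_cells**2
        scale = len(centres) / total_w
        for key, copies in verts.items():
            v = copies[0]
            w = adj_count[key] / 3.0 * scale
            openings.append(Opening(oid, VENULAR, v.real, v.imag, -w, radius))
            oid += 1
        return OpeningConfiguration(tuple(openings), "bounded_disc",
                                    params or PhysicalParams())
    raise ValueError(f"unknown lattice {lattice!r}; expected 'square' or 'honeycomb'")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_COLUMNS = ["id", "kind", "x", "y", "strength", "radius"]


def write_openings(config: OpeningConfiguration, path) -> None:
    """Write an opening map as CSV with header id,kind,x,y,strength,radius."""
    df = pd.DataFrame(
        [{"id": o.id, "kind": o.kind, "x": repr(o.x), "y": repr(o.y),
          "strength": repr(o.strength), "radius": repr(o.radius)}
         for o in config.openings],
        columns=_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_openings(
    path,
    domain: str = "bounded_disc",
    params: PhysicalParams | None = None,
) -> OpeningConfiguration:
    """Read an opening map written by :func:`write_openings`.

    Counts ``N_a``/``N_v`` are recomputed from the records.  Malformed rows
    raise :class:`FormatError` naming the (1-based, header included) line.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    openings = []
    seen: set[int] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        kind = str(row["kind"]).strip()
        if kind not in _KINDS:
            raise FormatError(f"line {line}: unknown kind {kind!r}")
        try:
            oid = int(row["id"])
            x, y = float(row["x"]), float(row["y"])
            k = float(row["strength"])
            a = float(row["radius"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"line {line}: non-numeric field ({exc})") from exc
        if oid in seen:
            raise FormatError(f"line {line}: duplicate id {oid}")
        seen.add(oid)
        try:
            openings.append(Opening(oid, kind, x, y, k, a))
        except ValueError as exc:
            raise FormatError(f"line {line}: {exc}") from exc
    return OpeningConfiguration(tuple(openings), domain, params or PhysicalParams())


def bulk_opening_ratio(config: OpeningConfiguration) -> float:
    """Boundary-corrected arteriolar-to-venular opening ratio.

    Venules are counted by their drainage share relative to a bulk
    (interior) venule — on a lattice a boundary venule only serves the
    cells that exist, and its strength encodes that share — so the finite
    patch reports the infinite-lattice ratio: 1 for the square lattice,
    1/2 for the honeycomb.  For equal-strength scatters this reduces to
    ``N_a / N_v``.
    """
    kv = np.array([abs(o.strength) for o in config.openings if o.kind == VENULAR])
    if kv.size == 0:
        raise ValueError("configuration has no venular openings")
    return config.n_a / float(kv.sum() / kv.max())


def balance_fluxes(config: OpeningConfiguration) -> OpeningConfiguration:
    """Rescale venular strengths by a common factor so that ``sum(k_i) = 0``.

    Arteriolar strengths are untouched.  Required before the closed-surface
    (sphere) bookkeeping applies: a balanced set has no node at infinity.
    """
    ka = sum(o.strength for o in config.openings if o.kind == ARTERIOLAR)
    kv = sum(o.strength for o in config.openings if o.kind == VENULAR)
    if kv == 0.0:
        if config.domain == "plane_with_infinity":
            return config
        raise BalanceError("cannot balance: no venular openings in a bounded domain")
    factor = ka / (-kv)
    new = tuple(
        o if o.kind == ARTERIOLAR else replace(o, strength=o.strength * factor)
        for o in config.openings
    )
    return replace(config, openings=new)
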