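"""Analytic free-energy landscapes used as the sampling targets.

These differentiable surfaces stand in for the molecular system: a Brownian
walker sampling ``exp(-U/kT)`` on one of them plays the role of the biased
simulation engine, and the exact surface doubles as the reference the
unbiasing machinery is tested against.

Families
--------
``harmonic``
    Separable quadratic well; ``k = 0`` gives a flat landscape.
``double_well``
    1D symmetric quartic with an exactly specified barrier height.
``permeation_map``
    2D valley of wells joined by cosine saddles along an arbitrary direction,
    with harmonic confinement transverse to the valley.  The default presets
    mimic the topology of ion-occupancy free-energy maps of a K+ channel
    selectivity filter: a chain of occupancy states (wells) connected through
    saddles, either low (open-like, 2-3 kcal/mol) or high (closed-like,
    > 6 kcal/mol).
``gated_ridge``
    2D ridge of fixed height across the domain, optionally fading away along
    the other axis ("gated"), giving maps whose sub-threshold region is
    disconnected or connected through a gap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import thermal_energy
from .grids import AnalysisGrid, PMFGrid

__all__ = [
    "DomainError",
    "AnalyticLandscape",
    "Harmonic",
    "DoubleWell",
    "PermeationMap",
    "GatedRidge",
    "boltzmann_pmf",
    "load_landscape",
    "landscape_preset",
]


class DomainError(ValueError):
    """A coordinate fell outside the landscape domain."""


@dataclass
class AnalyticLandscape:
    """Base class: a differentiable potential on a closed rectangular domain.

    ``bounds`` is a sequence of per-axis ``(lo, hi)`` pairs in angstrom.
    Subclasses implement ``_energy`` and ``_gradient`` on arrays of shape
    (n, ndim); the public ``potential`` / ``gradient`` accept scalars, 1D
    points or stacks of points and validate the domain.
    """

    bounds: tuple[tuple[float, float], ...]
    family = "abstract"

    def __post_init__(self):
        b = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        for ax, (lo, hi) in enumerate(b):
            if hi <= lo:
                raise ValueError(f"axis {ax}: invalid bounds ({lo}, {hi})")
        self.bounds = b

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    # -- public API ---------------------------------------------------------
    def potential(self, z) -> float | np.ndarray:
        """Potential energy (kcal/mol) at one or many points."""
        pts, squeeze = self._as_points(z)
        self._check_domain(pts)
        e = self._energy(pts)
        return float(e[0]) if squeeze else e

    def gradient(self, z) -> np.ndarray:
        """Analytic gradient (kcal/mol/A) at one or many points."""
        pts, squeeze = self._as_points(z)
        self._check_domain(pts)
        g = self._gradient(pts)
        return g[0] if squeeze else g

    def force(self, pts: np.ndarray) -> np.ndarray:
        """Unchecked vectorized -grad(U) used by the integrator hot loop."""
        return -self._gradient(pts)

    def contains(self, z) -> bool:
        pts, _ = self._as_points(z)
        for ax, (lo, hi) in enumerate(self.bounds):
            if ((pts[:, ax] < lo) | (pts[:, ax] > hi)).any():
                return False
        return True

    # -- helpers ------------------------------------------------------------
    def _as_points(self, z) -> tuple[np.ndarray, bool]:
        arr = np.asarray(z, dtype=float)
        if arr.ndim == 0:
            arr = arr.reshape(1, 1)
            squeeze = True
        elif arr.ndim == 1:
            if self.ndim == 1 and arr.shape[0] != 1:
                # a batch of 1D points
                arr = arr.reshape(-1, 1)
                squeeze = False
            else:
                arr = arr.reshape(1, -1)
                squeeze = True
        else:
            squeeze = False
        if arr.shape[1] != self.ndim:
            raise DomainError(
                f"points have dimension {arr.shape[1]}, landscape has {self.ndim}"
            )
        return arr, squeeze

    def _check_domain(self, pts: np.ndarray) -> None:
        for ax, (lo, hi) in enumerate(self.bounds):
            bad = (pts[:, ax] < lo) | (pts[:, ax] > hi)
            if bad.any():
                z = pts[bad, ax][0]
                raise DomainError(
                    f"coordinate {z:g} on axis {ax} outside domain [{lo}, {hi}]"
                )

    def _energy(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _gradient(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass
class Harmonic(AnalyticLandscape):
    """Separable quadratic well: ``U = sum_i k_i/2 (z_i - c_i)^2``."""

    center: tuple[float, ...] = (0.0,)
    k: tuple[float, ...] = (1.0,)
    family = "harmonic"

    def __post_init__(self):
        super().__post_init__()
        self.center = tuple(
            float(x) for x in np.broadcast_to(np.asarray(self.center, float), (self.ndim,))
        )
        self.k = tuple(
            float(x) for x in np.broadcast_to(np.asarray(self.k, float), (self.ndim,))
        )

    def _energy(self, pts):
        d = pts - np.asarray(self.center)
        return 0.5 * (np.asarray(self.k) * d * d).sum(axis=1)

    def _gradient(self, pts):
        return np.asarray(self.k) * (pts - np.asarray(self.center))

    def to_dict(self):
        return {
            "family": self.family,
            "params": {"center": list(self.center), "k": list(self.k)},
            "bounds": [list(b) for b in self.bounds],
        }


@dataclass
class DoubleWell(AnalyticLandscape):
    """1D quartic double well ``U = h ((z - c)^2/a^2 - 1)^2``.

    Wells sit at ``c +/- a`` with energy 0 and the central barrier height is
    exactly ``h`` (kcal/mol).
    """

    barrier: float = 6.0
    half_separation: float = 1.0
    center: float = 0.0
    family = "double_well"

    def __post_init__(self):
        super().__post_init__()
        if self.ndim != 1:
            raise ValueError("double_well is one-dimensional")
        if self.barrier <= 0 or self.half_separation <= 0:
            raise ValueError("barrier and half_separation must be positive")

    def _energy(self, pts):
        u = (pts[:, 0] - self.center) / self.half_separation
        return self.barrier * (u * u - 1.0) ** 2

    def _gradient(self, pts):
        u = (pts[:, 0] - self.center) / self.half_separation
        g = self.barrier * 4.0 * u * (u * u - 1.0) / self.half_separation
        return g[:, None]

    @property
    def well_centers(self):
        return (self.center - self.half_separation, self.center + self.half_separation)

    def to_dict(self):
        return {
            "family": self.family,
            "params": {
                "barrier": self.barrier,
                "half_separation": self.half_separation,
                "center": self.center,
            },
            "bounds": [list(b) for b in self.bounds],
        }


@dataclass
class PermeationMap(AnalyticLandscape):
    """2D chain of wells along a valley with transverse harmonic confinement.

    The potential separates into a 1D profile along the valley coordinate
    ``s = (z - anchor) . u`` and a quadratic term in the transverse
    coordinate ``d``:

    ``U = profile(s) + k_perp/2 d^2``

    The profile holds wells at ``well_s`` (energies ``well_energies``) joined
    by cosine saddles whose peak lies ``barriers[j]`` above the higher of the
    two adjacent wells, so the minimax barrier between adjacent wells equals
    the requested value exactly.  Beyond the terminal wells the profile is
    flat (``k_wall = 0``) or rises harmonically.

    Transverse confinement is either harmonic (``perp_style="harmonic"``,
    strength ``k_perp``) or a flat-bottomed cosine channel
    (``perp_style="cosine"``): zero up the channel axis, rising as
    ``perp_height (1 - cos(pi d / perp_width))/2`` and plateauing at
    ``perp_height`` for ``|d| >= perp_width``.
    """

    anchor: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (1.0, 1.0)
    well_s: tuple[float, ...] = (-2.0, 0.0, 2.0)
    well_energies: tuple[float, ...] | None = None
    barriers: tuple[float, ...] = (2.5, 2.5)
    perp_style: str = "harmonic"
    k_perp: float = 14.0
    perp_height: float = 16.0
    perp_width: float = 1.0
    k_wall: float = 0.0
    family = "permeation_map"

    def __post_init__(self):
        super().__post_init__()
        if self.ndim != 2:
            raise ValueError("permeation_map is two-dimensional")
        u = np.asarray(self.direction, dtype=float)
        u = u / np.linalg.norm(u)
        self._u = u
        self._v = np.array([-u[1], u[0]])
        self.well_s = tuple(float(s) for s in self.well_s)
        if any(b <= a for a, b in zip(self.well_s, self.well_s[1:])):
            raise ValueError("well_s must be strictly increasing")
        if self.well_energies is None:
            self.well_energies = tuple(0.0 for _ in self.well_s)
        self.well_energies = tuple(float(e) for e in self.well_energies)
        if len(self.barriers) != len(self.well_s) - 1:
            raise ValueError("need one barrier per pair of adjacent wells")
        if any(b <= 0 for b in self.barriers):
            raise ValueError("barriers must be positive")
        if self.perp_style not in ("harmonic", "cosine"):
            raise ValueError("perp_style must be 'harmonic' or 'cosine'")
        # knot positions and peak values of the cosine profile
        self._peaks = tuple(
            b + max(e0, e1)
            for b, e0, e1 in zip(self.barriers, self.well_energies, self.well_energies[1:])
        )
        self._build_segments()

    def _build_segments(self) -> None:
        """Precompute a segment table so the profile is one gather away.

        Segment i covers edges[i-1] <= s < edges[i]; each half-saddle is the
        unified form  E_b + A (1 - cos(w (s - r)))/2  and the two outer walls
        are harmonic in (s - r).
        """
        ws, we = self.well_s, self.well_energies
        edges, kind, eb, amp, om, ref = [], [0], [we[0]], [0.0], [0.0], [ws[0]]
        for j in range(len(ws) - 1):
            mid = 0.5 * (ws[j] + ws[j + 1])
            h = mid - ws[j]
            edges += [ws[j], mid]
            kind += [1, 1]
            eb += [we[j], we[j + 1]]
            amp += [self._peaks[j] - we[j], self._peaks[j] - we[j + 1]]
            om += [np.pi / h, np.pi / h]
            ref += [ws[j], ws[j + 1]]
        edges.append(ws[-1])
        kind.append(0)
        eb.append(we[-1])
        amp.append(0.0)
        om.append(0.0)
        ref.append(ws[-1])
        self._edges = np.asarray(edges)
        self._seg_cos = np.asarray(kind, dtype=bool)
        # rows: E_b, A/2, omega, r -- gathered in one take() per call
        self._segtab = np.stack([
            np.asarray(eb), 0.5 * np.asarray(amp), np.asarray(om), np.asarray(ref)
        ])
        # with flat outer walls (k_wall = 0) the unified cosine form
        # (A = 0, omega = 0) covers the wall segments exactly
        self._pure_cos = self.k_wall == 0.0
        u = self._u
        self._axis = None
        if abs(abs(u[0]) - 1.0) < 1e-15:
            self._axis = 0
        elif abs(abs(u[1]) - 1.0) < 1e-15:
            self._axis = 1

    def _perp(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Transverse energy and derivative dE/dd, vectorized."""
        if self.perp_style == "harmonic":
            return 0.5 * self.k_perp * d * d, self.k_perp * d
        # clipping gives the flat plateau for free: cos(+-pi) = -1, sin = 0
        t = np.clip(d / self.perp_width, -1.0, 1.0) * np.pi
        e = self.perp_height * 0.5 * (1.0 - np.cos(t))
        de = self.perp_height * 0.5 * np.pi / self.perp_width * np.sin(t)
        return e, de

    @property
    def well_centers(self) -> np.ndarray:
        """(m, 2) array of well positions in the plane."""
        return np.asarray(self.anchor) + np.outer(self.well_s, self._u)

    def _profile(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Valley profile energy and derivative dE/ds, vectorized."""
        s = np.asarray(s, dtype=float)
        idx = self._edges.searchsorted(s, side="right")
        eb, half, om, ref = self._segtab.take(idx, axis=1)
        x = om * (s - ref)
        e_cos = eb + half * (1.0 - np.cos(x))
        de_cos = half * om * np.sin(x)
        if self._pure_cos:
            return e_cos, de_cos
        cos = self._seg_cos[idx]
        dw = s - ref
        e_wall = eb + 0.5 * self.k_wall * dw * dw
        de_wall = self.k_wall * dw
        return np.where(cos, e_cos, e_wall), np.where(cos, de_cos, de_wall)

    def _coords(self, pts):
        rel = pts - np.asarray(self.anchor)
        if self._axis is not None:  # axis-aligned valley: skip the matmuls
            su = 1.0 if self._u[self._axis] > 0 else -1.0
            sv = 1.0 if self._v[1 - self._axis] > 0 else -1.0
            return su * rel[:, self._axis], sv * rel[:, 1 - self._axis]
        return rel @ self._u, rel @ self._v

    def _energy(self, pts):
        s, d = self._coords(pts)
        e, _ = self._profile(s)
        ep, _ = self._perp(d)
        return e + ep

    def _gradient(self, pts):
        s, d = self._coords(pts)
        _, de = self._profile(s)
        _, dep = self._perp(d)
        return de[:, None] * self._u + dep[:, None] * self._v

    def to_dict(self):
        return {
            "family": self.family,
            "params": {
                "anchor": list(self.anchor),
                "direction": list(self.direction),
                "well_s": list(self.well_s),
                "well_energies": list(self.well_energies),
                "barriers": list(self.barriers),
                "perp_style": self.perp_style,
                "k_perp": self.k_perp,
                "perp_height": self.perp_height,
                "perp_width": self.perp_width,
                "k_wall": self.k_wall,
            },
            "bounds": [list(b) for b in self.bounds],
        }


@dataclass
class GatedRidge(AnalyticLandscape):
    """2D cosine ridge across ``x = x0``, optionally gated open along y.

    ``U(x, y) = height * bump(x) * gate(y)`` with
    ``bump(x) = (1 + cos(pi (x - x0)/width))/2`` for ``|x - x0| <= width``
    (0 elsewhere).  Without a gate the ridge blocks the whole domain; with
    ``gate_start`` set, the ridge fades in smoothly over ``gate_width`` along
    y (0 below ``gate_start``, 1 above ``gate_start + gate_width``), leaving
    a passage between the two half-planes.
    """

    height: float = 16.0
    x0: float = 0.0
    width: float = 1.0
    gate_start: float | None = None
    gate_width: float = 1.0
    family = "gated_ridge"

    def __post_init__(self):
        super().__post_init__()
        if self.ndim != 2:
            raise ValueError("gated_ridge is two-dimensional")
        if self.height <= 0 or self.width <= 0 or self.gate_width <= 0:
            raise ValueError("height, width and gate_width must be positive")

    def _bump(self, x):
        # clipping gives the zero tails for free: cos(+-pi) = -1, sin = 0
        t = np.clip((x - self.x0) / self.width, -1.0, 1.0) * np.pi
        b = 0.5 * (1.0 + np.cos(t))
        db = -0.5 * np.pi / self.width * np.sin(t)
        return b, db

    def _gate(self, y):
        if self.gate_start is None:
            y = np.asarray(y, dtype=float)
            return np.ones_like(y), np.zeros_like(y)
        t = np.clip((y - self.gate_start) / self.gate_width, 0.0, 1.0) * np.pi
        g = 0.5 * (1.0 - np.cos(t))
        dg = 0.5 * np.pi / self.gate_width * np.sin(t)
        return g, dg

    def _energy(self, pts):
        b, _ = self._bump(pts[:, 0])
        g, _ = self._gate(pts[:, 1])
        return self.height * b * g

    def _gradient(self, pts):
        b, db = self._bump(pts[:, 0])
        g, dg = self._gate(pts[:, 1])
        return self.height * np.stack([db * g, b * dg], axis=1)

    def to_dict(self):
        params = {"height": self.height, "x0": self.x0, "width": self.width,
                  "gate_width": self.gate_width}
        if self.gate_start is not None:
            params["gate_start"] = self.gate_start
        return {
            "family": self.family,
            "params": params,
            "bounds": [list(b) for b in self.bounds],
        }


# ---------------------------------------------------------------------------

def boltzmann_pmf(
    landscape: AnalyticLandscape, grid: AnalysisGrid, temperature: float
) -> PMFGrid:
    """Exact PMF of a landscape on a grid: ``F(b) = U(center_b) - min U``.

    For these reaction-coordinate-space landscapes the Boltzmann-weighted
    marginal over a bin reduces to the potential at the bin center (up to the
    sub-bin variation), so this is the analytic reference every estimator in
    the package is compared against.  The result is independent of
    ``temperature``; it is stored only as metadata.
    """
    if grid.ndim != landscape.ndim:
        raise DomainError("grid and landscape dimensions differ")
    mesh = grid.center_mesh()
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    u = landscape.potential(pts).reshape(grid.shape)
    thermal_energy(temperature)  # validate
    return PMFGrid.from_energies(grid, u, temperature=temperature)


_FAMILIES = {
    "harmonic": Harmonic,
    "double_well": DoubleWell,
    "permeation_map": PermeationMap,
    "gated_ridge": GatedRidge,
}


def load_landscape(source) -> AnalyticLandscape:
    """Build a landscape from a config mapping or a YAML file path.

    The mapping uses keys ``family``, ``params`` and ``bounds``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    cfg = dict(source)
    family = cfg["family"]
    if family not in _FAMILIES:
        raise ValueError(f"unknown landscape family {family!r}")
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in dict(cfg.get("params", {})).items()}
    bounds = tuple(tuple(b) for b in cfg["bounds"])
    return _FAMILIES[family](bounds=bounds, **params)


def landscape_preset(name: str) -> AnalyticLandscape:
    """Named 2D toy maps with well-separated sub-/super-threshold regions.

    ``open_valley``
        Three wells along the x axis joined by 2.5 kcal/mol saddles
        (open-like: every saddle far below the 12 kcal/mol window-creation
        limit) inside a flat-bottomed cosine channel whose walls plateau at
        16 kcal/mol.
    ``open_basin``
        The same three wells and 2.5 kcal/mol saddles with soft harmonic
        confinement (k_perp = 10 kcal/mol/A^2) and gentle end walls: an
        open-like map whose slopes stay small enough that bin-center
        discretization is negligible, used for quantitative PMF-accuracy
        comparisons.
    ``blocking_ridge``
        A 16 kcal/mol ridge along x = 0 splitting the domain in two
        (closed-like: the two basins connect only above the limit).
    ``gated_ridge``
        The same ridge fading out for y < 0, leaving a sub-limit passage.

    All three are engineered so that, on the default 0.5 A window lattice
    anchored at a well or ridge-flank node, every lattice node sits well
    clear (>= ~1.5 kcal/mol) of the 12 kcal/mol creation limit -- the
    property that makes exact coverage comparisons against a flood fill of
    the exact surface meaningful despite sampling noise.
    """
    if name == "open_valley":
        return PermeationMap(
            bounds=((-2.5, 2.5), (-0.4, 0.4)),
            anchor=(0.0, 0.0),
            direction=(1.0, 0.0),
            well_s=(-1.5, 0.0, 1.5),
            barriers=(2.5, 2.5),
            perp_style="cosine",
            perp_height=16.0,
            perp_width=1.0,
            k_wall=0.0,
        )
    if name == "open_basin":
        return PermeationMap(
            bounds=((-2.5, 2.5), (-1.5, 1.5)),
            anchor=(0.0, 0.0),
            direction=(1.0, 0.0),
            well_s=(-1.5, 0.0, 1.5),
            barriers=(2.5, 2.5),
            perp_style="harmonic",
            k_perp=10.0,
            k_wall=5.0,
        )
    if name == "blocking_ridge":
        return GatedRidge(
            bounds=((-2.0, 2.0), (-2.0, 2.0)), height=16.0, x0=0.0, width=1.0
        )
    if name == "gated_ridge":
        return GatedRidge(
            bounds=((-2.0, 2.0), (-2.0, 2.0)),
            height=16.0,
            x0=0.0,
            width=1.0,
            gate_start=-0.5,
            gate_width=1.0,
        )
    raise ValueError(f"unknown preset {name!r}")
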