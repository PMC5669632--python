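"""Analysis grids and gridded free-energy surfaces (PMFs).

An :class:`AnalysisGrid` tiles a rectangular reaction-coordinate domain with
half-open bins ``[lo, hi)`` identified by their centers.  A :class:`PMFGrid`
holds one free energy per bin, referenced so that the minimum over sampled
bins is exactly zero; unsampled bins are NaN and excluded from every
computation via the boolean mask.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnalysisGrid", "PMFGrid", "GridError"]

#: Relative tolerance used when snapping coordinates to bin edges. A sample
#: lying exactly on an edge is assigned to the upper bin.
_EDGE_EPS = 1e-9


class GridError(ValueError):
    """Raised for inconsistent grid definitions or grid/domain mismatches."""


@dataclass(frozen=True)
class AnalysisGrid:
    """Rectangular histogram grid with uniform spacing on every axis.

    Parameters
    ----------
    lo, hi :
        Per-axis bounds in angstrom. ``(hi - lo) / spacing`` must be an
        integer (within 1e-9) on every axis so bins tile the range exactly.
    spacing :
        Bin width in angstrom, shared by all axes (0.1 by default, matching
        the resolution used for the reference PMF maps).
    """

    lo: tuple[float, ...]
    hi: tuple[float, ...]
    spacing: float = 0.1

    def __post_init__(self):
        lo = tuple(float(x) for x in np.atleast_1d(np.asarray(self.lo, dtype=float)))
        hi = tuple(float(x) for x in np.atleast_1d(np.asarray(self.hi, dtype=float)))
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if len(lo) != len(hi):
            raise GridError("lo and hi must have the same length")
        if self.spacing <= 0:
            raise GridError(f"spacing must be positive, got {self.spacing}")
        for axis, (a, b) in enumerate(zip(lo, hi)):
            if b <= a:
                raise GridError(f"axis {axis}: hi must exceed lo")
            n = (b - a) / self.spacing
            if abs(n - round(n)) > 1e-9:
                raise GridError(
                    f"axis {axis}: range {b - a} is not an integer multiple "
                    f"of spacing {self.spacing}"
                )

    @property
    def ndim(self) -> int:
        return len(self.lo)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(
            int(round((b - a) / self.spacing)) for a, b in zip(self.lo, self.hi)
        )

    def centers(self, axis: int) -> np.ndarray:
        """Bin centers along one axis."""
        n = self.shape[axis]
        return self.lo[axis] + self.spacing * (np.arange(n) + 0.5)

    def center_mesh(self) -> list[np.ndarray]:
        """Bin-center coordinate arrays of shape ``self.shape`` (ij indexing)."""
        return list(
            np.meshgrid(*[self.centers(ax) for ax in range(self.ndim)], indexing="ij")
        )

    def bin_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points of shape (n, ndim) to flat bin indices.

        Returns ``(flat_index, inside)`` where ``inside`` flags points that
        fall within the grid.  Samples exactly on a bin edge go to the upper
        bin (half-open convention).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.ndim:
            raise GridError(
                f"points have dimension {pts.shape[1]}, grid has {self.ndim}"
            )
        idx = np.empty(pts.shape, dtype=np.int64)
        inside = np.ones(len(pts), dtype=bool)
        for ax in range(self.ndim):
            t = (pts[:, ax] - self.lo[ax]) / self.spacing
            k = np.floor(t + _EDGE_EPS).astype(np.int64)
            inside &= (k >= 0) & (k < self.shape[ax])
            idx[:, ax] = np.clip(k, 0, self.shape[ax] - 1)
        flat = np.ravel_multi_index(tuple(idx.T), self.shape)
        return flat, inside

    def is_compatible(self, other: "AnalysisGrid") -> bool:
        return (
            self.ndim == other.ndim
            and np.allclose(self.lo, other.lo)
            and np.allclose(self.hi, other.hi)
            and np.isclose(self.spacing, other.spacing)
        )


@dataclass
class PMFGrid:
    """Gridded potential of mean force.

    ``free_energy`` has the grid's shape; undefined (unsampled) bins are NaN
    and ``mask`` is False there.  The minimum over sampled bins is exactly 0.
    """

    grid: AnalysisGrid
    free_energy: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    temperature: float = 0.0

    def __post_init__(self):
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.free_energy.shape != self.grid.shape:
            raise GridError(
                f"free energy shape {self.free_energy.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.free_energy)
        self.mask = np.asarray(self.mask, dtype=bool)

    @classmethod
    def from_energies(
        cls, grid: AnalysisGrid, energies: np.ndarray, temperature: float = 0.0
    ) -> "PMFGrid":
        """Build a PMF from raw bin energies, re-referencing the minimum to 0."""
        f = np.asarray(energies, dtype=float).copy()
        mask = np.isfinite(f)
        if not mask.any():
            raise GridError("PMF has no defined bins")
        f[mask] -= f[mask].min()
        f[~mask] = np.nan
        return cls(grid=grid, free_energy=f, mask=mask, temperature=temperature)

    def value_at(self, point) -> float:
        """Free energy of the bin containing ``point`` (NaN if undefined)."""
        flat, inside = self.grid.bin_index(np.atleast_2d(point))
        if not inside[0]:
            return float("nan")
        return float(self.free_energy.ravel()[flat[0]])

    def interpolate(self, point) -> float:
        """Multilinear interpolation at ``point``.

        Returns NaN when any of the ``2**ndim`` surrounding bin centers is
        undefined or outside the grid.
        """
        p = np.atleast_1d(np.asarray(point, dtype=float))
        ndim = self.grid.ndim
        # index of the lower bin-center corner
        t = [(p[ax] - self.grid.lo[ax]) / self.grid.spacing - 0.5 for ax in range(ndim)]
        base = [int(np.floor(ti)) for ti in t]
        frac = [ti - bi for ti, bi in zip(t, base)]
        val = 0.0
        for corner in range(1 << ndim):
            w = 1.0
            idx = []
            for ax in range(ndim):
                bit = (corner >> ax) & 1
                i = base[ax] + bit
                if i < 0 or i >= self.grid.shape[ax]:
                    return float("nan")
                w *= frac[ax] if bit else 1.0 - frac[ax]
                idx.append(i)
            f = self.free_energy[tuple(idx)]
            if not np.isfinite(f):
                return float("nan")
            val += w * f
        return float(val)
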