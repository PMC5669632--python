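"""Weighted histogram analysis method (WHAM) on 1D/2D grids.

Umbrella windows are histogrammed on a shared :class:`~permeon.grids.AnalysisGrid`
and unbiased by the standard self-consistent WHAM equations

    P(b)  proportional to  sum_i n_i(b) / sum_i N_i exp[(f_i - w_i(b)) / kT]
    f_i = -kT ln sum_b P(b) exp(-w_i(b) / kT)

iterated until ``max_i |delta f_i| < tolerance``.  Bias energies are
evaluated at bin centers.  All exponentials are handled in log space so
windows far apart in free energy cannot overflow.

The default solver first minimizes the equivalent convex likelihood

    Phi(g) = sum_b M_b ln sum_i N_i exp(g_i - w_i(b)/kT) - sum_i N_i g_i

with L-BFGS (whose stationary point is exactly the WHAM fixed point) and
then polishes with the self-consistent iteration until the tolerance is met,
so convergence is always certified by the fixed-point residual itself.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .brownian import BiasSpec, RCTrajectory
from .constants import thermal_energy
from .grids import AnalysisGrid, PMFGrid

__all__ = [
    "EmptyWindowError",
    "DisconnectedSamplingError",
    "WindowData",
    "WhamSolution",
    "bin_samples",
    "wham_solve",
]


class EmptyWindowError(ValueError):
    """A window retained no in-grid samples after the equilibration discard."""


class DisconnectedSamplingError(RuntimeError):
    """The windows' histograms split into non-overlapping groups."""

    def __init__(self, components: list[list[int]]):
        self.components = components
        super().__init__(
            "window histograms form "
            f"{len(components)} disconnected groups: {components}"
        )


@dataclass
class WindowData:
    """One umbrella window ready for WHAM: bias + histogram.

    ``counts`` has the grid's shape; ``n_retained`` is its total.  Samples
    earlier than ``discard`` (equilibration, 100 ps in the reference
    protocol) are dropped; retained samples falling outside the grid are
    tallied in ``n_overflow`` and excluded.
    """

    bias: BiasSpec
    counts: np.ndarray
    grid: AnalysisGrid
    n_retained: int
    discard: float
    n_overflow: int = 0
    trajectory: RCTrajectory | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid shape")
        if self.n_retained != int(self.counts.sum()):
            raise ValueError("n_retained must equal the sum of counts")


def bin_samples(
    traj: RCTrajectory,
    grid: AnalysisGrid,
    discard: float = 100.0,
    t_max: float | None = None,
) -> WindowData:
    """Histogram a window's trajectory on the analysis grid.

    Samples with ``time >= discard`` (and ``time < t_max`` if given) are
    retained; each increments exactly one bin, samples on a bin edge going to
    the upper bin.  Raises :class:`EmptyWindowError` when nothing usable
    remains.
    """
    if traj.ndim != grid.ndim:
        raise ValueError("trajectory and grid dimensions differ")
    keep = traj.times >= discard
    if t_max is not None:
        keep &= traj.times < t_max
    pts = traj.coords[keep]
    if len(pts) == 0:
        raise EmptyWindowError(
            f"all samples discarded (discard={discard} ps, window of "
            f"{traj.duration} ps)"
        )
    flat, inside = grid.bin_index(pts)
    counts = np.bincount(flat[inside], minlength=int(np.prod(grid.shape)))
    counts = counts.reshape(grid.shape)
    n_retained = int(counts.sum())
    if n_retained == 0:
        raise EmptyWindowError("all retained samples fall outside the grid")
    return WindowData(
        bias=traj.bias,
        counts=counts,
        grid=grid,
        n_retained=n_retained,
        discard=discard,
        n_overflow=int((~inside).sum()),
        trajectory=traj,
    )


@dataclass
class WhamSolution:
    """Result of a WHAM solve: PMF, per-window offsets and diagnostics.

    ``offsets`` are the window free energies f_i (kcal/mol) anchored at
    ``f_0 = 0``; ``converged`` is True iff the final fixed-point residual
    (max_i |delta f_i| of the last sweep) fell below the tolerance.
    """

    pmf: PMFGrid
    offsets: np.ndarray
    iterations: int
    converged: bool
    residual: float


def _window_components(sampled_flat: list[np.ndarray], n_bins: int) -> list[list[int]]:
    """Connected components of windows linked by sharing a sampled bin."""
    owner = -np.ones(n_bins, dtype=np.int64)  # union-find over windows
    parent = np.arange(len(sampled_flat))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for w, bins in enumerate(sampled_flat):
        for b in bins:
            if owner[b] < 0:
                owner[b] = w
            else:
                ra, rb = find(w), find(int(owner[b]))
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for w in range(len(sampled_flat)):
        groups.setdefault(find(w), []).append(w)
    return sorted(groups.values())


def wham_solve(
    windows: list[WindowData],
    grid: AnalysisGrid,
    temperature: float,
    tolerance: float = 1e-7,
    max_iterations: int = 100_000,
    initial_offsets=None,
    method: str = "hybrid",
) -> WhamSolution:
    """Unbias a set of umbrella windows into a PMF.

    Parameters
    ----------
    tolerance :
        Convergence threshold (kcal/mol) on the largest change of any window
        offset in one self-consistent sweep.
    initial_offsets :
        Optional warm start for the f_i (kcal/mol); the solution is gauge
        invariant, so any uniform shift of the guess is irrelevant.
    method :
        ``"hybrid"`` (default) minimizes the convex WHAM likelihood first and
        then runs the self-consistent iteration; ``"iteration"`` uses the
        plain fixed point from the start.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    for w in windows:
        if not w.grid.is_compatible(grid):
            raise ValueError("all windows must share the analysis grid")
    kT = thermal_energy(temperature)
    n_bins = int(np.prod(grid.shape))
    counts = np.stack([w.counts.reshape(-1) for w in windows])  # (W, B)
    m_b = counts.sum(axis=0)
    sampled = m_b > 0
    if not sampled.any():
        raise EmptyWindowError("no bin holds any sample")

    comps = _window_components(
        [np.flatnonzero(c) for c in counts], n_bins
    )
    if len(comps) > 1:
        raise DisconnectedSamplingError(comps)

    n_i = counts.sum(axis=1).astype(float)  # (W,)
    log_n = np.log(n_i)
    log_m = np.log(m_b[sampled].astype(float))

    # bias energies at the centers of sampled bins, in kT units
    mesh = grid.center_mesh()
    centers = np.stack([m.ravel()[sampled] for m in mesh], axis=1)  # (B_s, d)
    logw = np.stack(
        [-w.bias.energy(centers) / kT for w in windows]
    )  # (W, B_s) = -w_i(b)/kT

    nw = len(windows)
    if initial_offsets is None:
        g = np.zeros(nw)
    else:
        g = np.asarray(initial_offsets, dtype=float) / kT
    g = g - g[0]

    def sweep(g):
        """One self-consistent update g -> g'; returns (g', logP)."""
        denom = logsumexp(log_n[:, None] + g[:, None] + logw, axis=0)
        log_p = log_m - denom
        g_new = -logsumexp(log_p[None, :] + logw, axis=1)
        return g_new - g_new[0], log_p

    iterations = 0
    residual = np.inf

    if method == "hybrid" and nw > 1:
        def phi(gfree):
            gg = np.concatenate([[0.0], gfree])
            a = log_n[:, None] + gg[:, None] + logw
            lse = logsumexp(a, axis=0)
            val = float((np.exp(log_m) * lse).sum() - (n_i * gg).sum())
            # gradient wrt g_i: sum_b M_b softmax_i(a) - N_i
            soft = np.exp(a - lse)
            grad = (np.exp(log_m) * soft).sum(axis=1) - n_i
            return val, grad[1:]

        res = minimize(phi, g[1:], jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        g = np.concatenate([[0.0], res.x])
    elif method not in ("hybrid", "iteration"):
        raise ValueError(f"unknown method {method!r}")

    for iterations in range(1, max_iterations + 1):
        g_new, log_p = sweep(g)
        residual = float(np.max(np.abs(g_new - g)) * kT)
        g = g_new
        if residual < tolerance:
            break
    converged = residual < tolerance

    f = np.full(n_bins, np.nan)
    f[sampled] = -kT * log_p
    pmf = PMFGrid.from_energies(grid, f.reshape(grid.shape), temperature=temperature)
    return WhamSolution(
        pmf=pmf,
        offsets=g * kT,
        iterations=iterations,
        converged=converged,
        residual=residual,
    )
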