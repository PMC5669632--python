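"""Post-processing of PMF maps and coordinate time series.

Covers the downstream analyses of a free-energy study: combining the
windows of independent runs into one PMF, interval-based statistical error
bars, locating occupancy-state minima, reading barrier heights via minimax
(widest) paths, and counting permeation events from ion-coordinate series.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .grids import AnalysisGrid, PMFGrid
from .wham import WhamSolution, WindowData, bin_samples, wham_solve

__all__ = [
    "CombinedPMF",
    "ErrorMap",
    "StatePoint",
    "PathResult",
    "OccupancySeries",
    "combine_runs",
    "interval_error",
    "find_states",
    "minimax_path",
    "classify_occupancy",
]


@dataclass
class CombinedPMF:
    """PMF from the pooled windows of several runs, with provenance."""

    pmf: PMFGrid
    provenance: list[tuple[str, int]]
    solution: WhamSolution


def combine_runs(
    window_sets: list[list[WindowData]],
    grid: AnalysisGrid,
    temperature: float,
    run_ids: list[str] | None = None,
    **wham_kwargs,
) -> CombinedPMF:
    """Combine >= 2 independent runs by one WHAM solve over pooled windows.

    Pooling the histograms and re-solving jointly weighs every window by its
    sampling, the same logic used to merge forward and backward perturbation
    runs; it is NOT an average of the per-run PMFs.  Passing one run split
    into halves therefore reproduces the unsplit PMF identically.
    """
    if len(window_sets) < 2:
        raise ValueError("need at least two window sets to combine")
    if run_ids is None:
        run_ids = [f"run{i}" for i in range(len(window_sets))]
    pooled: list[WindowData] = []
    for ws in window_sets:
        pooled.extend(ws)
    solution = wham_solve(pooled, grid, temperature, **wham_kwargs)
    provenance = [(rid, len(ws)) for rid, ws in zip(run_ids, window_sets)]
    return CombinedPMF(pmf=solution.pmf, provenance=provenance, solution=solution)


@dataclass
class ErrorMap:
    """Per-bin statistical uncertainty of a PMF from interval slicing."""

    sd: np.ndarray
    n_intervals: int
    slice_length: float
    fit_mask: np.ndarray
    grid: AnalysisGrid


def interval_offset(f_interval: np.ndarray, f_final: np.ndarray, mask: np.ndarray) -> float:
    """Least-squares constant aligning an interval PMF with the final PMF.

    Minimizing ``sum_mask (F_int + c - F_final)^2`` over ``c`` gives the
    closed form ``c* = mean_mask(F_final - F_int)``.
    """
    return float(np.mean(f_final[mask] - f_interval[mask]))


def interval_error(
    windows: list[WindowData],
    final: PMFGrid,
    slice_length: float = 100.0,
    n_last: int = 5,
    mask_level: float = 6.0,
    temperature: float = DEFAULT_TEMPERATURE,
    **wham_kwargs,
) -> ErrorMap:
    """Statistical error of a PMF by re-solving WHAM on sampling slices.

    The post-equilibration sampling of every window is cut into consecutive
    disjoint slices of ``slice_length`` ps; each slice is unbiased on its
    own, offset onto the final PMF by a least-squares constant fitted over
    the grid points with final free energy below ``mask_level`` (6 kcal/mol),
    and the per-bin standard deviation over the last ``n_last`` interval
    PMFs is reported.  With 600 ps windows and 100 ps equilibration there
    are exactly five such intervals.
    """
    if not windows:
        raise ValueError("need at least one window")
    fit_mask = final.mask & (final.free_energy < mask_level)
    if not fit_mask.any():
        raise ValueError(f"no bins with final free energy below {mask_level}")
    t_end = min(w.trajectory.duration for w in windows)
    discard = max(w.discard for w in windows)
    n_slices = int(np.floor((t_end - discard) / slice_length + 1e-9))
    if n_slices < n_last:
        raise ValueError(
            f"only {n_slices} slices of {slice_length} ps available after "
            f"equilibration; need {n_last}"
        )
    used = range(n_slices - n_last, n_slices)
    interval_pmfs = []
    for k in used:
        t0 = discard + k * slice_length
        t1 = discard + (k + 1) * slice_length
        slice_windows = []
        for w in windows:
            if w.trajectory is None:
                raise ValueError("window carries no trajectory to slice")
            slice_windows.append(
                bin_samples(w.trajectory, final.grid, discard=t0, t_max=t1)
            )
        sol = wham_solve(slice_windows, final.grid, temperature, **wham_kwargs)
        f_int = sol.pmf.free_energy
        if not np.isfinite(f_int[fit_mask]).all():
            raise ValueError(
                f"interval {k} ({t0:g}-{t1:g} ps) leaves fit-mask bins unsampled"
            )
        c = interval_offset(f_int, final.free_energy, fit_mask)
        interval_pmfs.append(f_int + c)
    stack = np.stack(interval_pmfs)
    defined = np.isfinite(stack).all(axis=0)
    sd = np.full(final.grid.shape, np.nan)
    sd[defined] = stack[:, defined].std(axis=0, ddof=0)
    return ErrorMap(
        sd=sd,
        n_intervals=n_last,
        slice_length=slice_length,
        fit_mask=fit_mask,
        grid=final.grid,
    )


@dataclass
class StatePoint:
    """A local PMF minimum interpreted as an ion-occupancy state."""

    label: str
    coords: tuple[float, ...]
    free_energy: float
    bin_index: tuple[int, ...] = field(default=None, repr=False)  # type: ignore


def _neighbor_indices(idx: tuple[int, ...], shape: tuple[int, ...]):
    if len(shape) == 1:
        offs = [(-1,), (1,)]
    else:
        offs = [
            (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
        ]
    for off in offs:
        n = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= ni < s for ni, s in zip(n, shape)):
            yield n


def find_states(
    pmf: PMFGrid, max_f: float = 6.0, merge_radius: float = 0.0
) -> list[StatePoint]:
    """Locate occupancy-state minima on a PMF map.

    Returns every defined bin that is a strict minimum over its (defined)
    8-neighborhood with free energy below ``max_f``, minima closer than
    ``merge_radius`` (angstrom) merged into the lower one, sorted by free
    energy.  Labels are ``state0, state1, ...`` in that order; callers may
    relabel with occupancy names such as ``S0-S2-S4``.
    """
    f = pmf.free_energy
    shape = pmf.grid.shape
    minima = []
    for idx in zip(*np.nonzero(pmf.mask & (f < max_f))):
        v = f[idx]
        if all(
            (not np.isfinite(f[n])) or v < f[n] for n in _neighbor_indices(idx, shape)
        ):
            minima.append(idx)
    minima.sort(key=lambda i: f[i])
    kept: list[tuple[int, ...]] = []
    for idx in minima:
        c = np.array([pmf.grid.centers(ax)[i] for ax, i in enumerate(idx)])
        ok = True
        for j in kept:
            cj = np.array([pmf.grid.centers(ax)[i] for ax, i in enumerate(j)])
            if np.linalg.norm(c - cj) < merge_radius:
                ok = False
                break
        if ok:
            kept.append(idx)
    return [
        StatePoint(
            label=f"state{n}",
            coords=tuple(float(pmf.grid.centers(ax)[i]) for ax, i in enumerate(idx)),
            free_energy=float(f[idx]),
            bin_index=idx,
        )
        for n, idx in enumerate(kept)
    ]


@dataclass
class PathResult:
    """Widest (minimax) path between two states on a PMF map."""

    bins: list[tuple[int, ...]]
    coords: np.ndarray
    barrier: float
    saddle: tuple[float, ...] | None


def _as_bin(pmf: PMFGrid, state) -> tuple[int, ...]:
    if isinstance(state, StatePoint):
        if state.bin_index is not None:
            return tuple(state.bin_index)
        state = state.coords
    flat, inside = pmf.grid.bin_index(np.atleast_2d(state))
    if not inside[0]:
        raise ValueError(f"state {state} outside the grid")
    return tuple(int(i) for i in np.unravel_index(flat[0], pmf.grid.shape))


def minimax_path(pmf: PMFGrid, state_a, state_b) -> PathResult:
    """Path from A to B minimizing the maximum free energy along the way.

    A modified Dijkstra over the 8-connected defined bins where the cost of
    a path is the largest bin value it visits; the barrier is that value
    minus F(A).  This is how saddle heights are read off a 2D map.  Raises
    if A and B are not connected through defined bins.
    """
    a = _as_bin(pmf, state_a)
    b = _as_bin(pmf, state_b)
    f = pmf.free_energy
    if not (np.isfinite(f[a]) and np.isfinite(f[b])):
        raise ValueError("both states must lie on defined bins")
    if a == b:
        return PathResult(bins=[], coords=np.empty((0, pmf.grid.ndim)), barrier=0.0,
                          saddle=None)
    shape = pmf.grid.shape
    best: dict[tuple[int, ...], float] = {a: float(f[a])}
    prev: dict[tuple[int, ...], tuple[int, ...]] = {}
    heap = [(float(f[a]), a)]
    while heap:
        cost, node = heapq.heappop(heap)
        if node == b:
            break
        if cost > best.get(node, np.inf):
            continue
        for n in _neighbor_indices(node, shape):
            if not np.isfinite(f[n]):
                continue
            c = max(cost, float(f[n]))
            if c < best.get(n, np.inf):
                best[n] = c
                prev[n] = node
                heapq.heappush(heap, (c, n))
    if b not in best:
        raise ValueError("states are not connected through defined bins")
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    path.reverse()
    coords = np.array(
        [[pmf.grid.centers(ax)[i] for ax, i in enumerate(idx)] for idx in path]
    )
    values = np.array([f[idx] for idx in path])
    k = int(np.argmax(values))
    return PathResult(
        bins=path,
        coords=coords,
        barrier=float(values.max() - f[a]),
        saddle=tuple(coords[k]),
    )


@dataclass
class OccupancySeries:
    """Per-frame site assignment, bound-ion count and permeation events."""

    sites: np.ndarray  # (n_frames, n_ions) indices into `labels`
    labels: list[str]
    bound_count: np.ndarray  # ions in filter sites per frame
    events_cumulative: np.ndarray  # non-decreasing, summed over ions
    n_events: int


#: Default site labels for seven boundaries along the pore axis, ordered
#: extracellular -> intracellular.
_DEFAULT_LABELS = ["extracellular", "S0", "S1", "S2", "S3", "S4", "Cav", "intracellular"]
_BOUND_SITES = {"S0", "S1", "S2", "S3", "S4"}


def classify_occupancy(
    ion_z: np.ndarray,
    site_boundaries,
    labels: list[str] | None = None,
    bound_sites=frozenset(_BOUND_SITES),
) -> OccupancySeries:
    """Assign ions to pore sites and count complete permeation events.

    ``ion_z`` is (n_frames, n_ions) pore-axis positions; ``site_boundaries``
    are strictly decreasing z cutoffs (extracellular side high).  ``m``
    cutoffs define ``m + 1`` intervals; with seven cutoffs the default
    labels are extracellular, S0..S4, Cav, intracellular.

    A permeation event is an ion crossing the whole filter in the conduction
    direction: it must first drop below the lowest cutoff (the cavity's
    intracellular edge) and subsequently rise above the highest cutoff (the
    extracellular edge of S0).  Both thresholds must be fully crossed, in
    that order -- oscillations across any single internal boundary count
    nothing (hysteresis).
    """
    z = np.atleast_2d(np.asarray(ion_z, dtype=float))
    bounds = np.asarray(site_boundaries, dtype=float)
    if bounds.ndim != 1 or len(bounds) < 1:
        raise ValueError("site_boundaries must be a 1D list of cutoffs")
    if np.any(np.diff(bounds) >= 0):
        raise ValueError("site boundaries must be strictly decreasing along z")
    if labels is None:
        if len(bounds) == len(_DEFAULT_LABELS) - 1:
            labels = list(_DEFAULT_LABELS)
        else:
            labels = [f"region{i}" for i in range(len(bounds) + 1)]
    if len(labels) != len(bounds) + 1:
        raise ValueError("need one label per interval (len(boundaries) + 1)")

    # interval index: 0 above the first cutoff ... m below the last
    sites = np.searchsorted(-bounds, -z, side="right")
    bound_idx = np.array([i for i, lab in enumerate(labels) if lab in bound_sites])
    bound_count = np.isin(sites, bound_idx).sum(axis=1)

    upper, lower = bounds[0], bounds[-1]
    n_frames, n_ions = z.shape
    armed = np.zeros(n_ions, dtype=bool)
    events = np.zeros(n_frames, dtype=np.int64)
    total = 0
    for t in range(n_frames):
        below = z[t] < lower
        above = z[t] > upper
        fired = armed & above
        total += int(fired.sum())
        armed = (armed | below) & ~above
        events[t] = total
    return OccupancySeries(
        sites=sites,
        labels=list(labels),
        bound_count=bound_count,
        events_cumulative=events,
        n_events=total,
    )
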