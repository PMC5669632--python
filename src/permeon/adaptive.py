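"""Self-learning adaptive umbrella sampling.

Starting from a single seed window, the loop alternates three steps --
simulate the newly proposed windows, re-unbias all windows jointly with
WHAM, propose lattice neighbors of the completed windows whose estimated
free energy lies below a creation limit -- until a round proposes nothing.
Window centers live on a lattice (0.5 A spacing by default) anchored at the
seed, and the creation limit (12 kcal/mol by default) confines the search to
the low-free-energy valleys of the map.

A candidate's free energy is estimated by multilinear interpolation of the
current PMF at the candidate center; where the interpolation is undefined
(some surrounding bin unsampled) the estimate falls back to the minimum
defined free energy among bins within half a lattice spacing of the
candidate.  A candidate with no defined bin that close is deferred: the
frontier never steps onto a node it has no evidence about, which is what
keeps the explored set equal to the sub-limit region actually reachable
through sub-limit corridors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .brownian import BiasSpec, BrownianParams, simulate_windows
from .constants import DEFAULT_TEMPERATURE
from .grids import AnalysisGrid
from .landscapes import AnalyticLandscape
from .wham import (
    DisconnectedSamplingError,
    WhamSolution,
    WindowData,
    bin_samples,
    wham_solve,
)

__all__ = [
    "AdaptiveConfig",
    "AdaptiveRound",
    "AdaptiveRun",
    "propose_new_windows",
    "seed_position_for",
    "run_adaptive",
]

_OFFSETS_2D_8 = [
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
]
_OFFSETS_2D_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass(frozen=True)
class AdaptiveConfig:
    """Knobs of the adaptive loop.

    The defaults reproduce the reference protocol: windows every 0.5 A,
    600 ps per window with the first 100 ps discarded, 20 kcal/mol/A^2
    harmonic biases, and a 12 kcal/mol upper free-energy limit for creating
    new windows.  ``window_duration`` is routinely scaled down in tests as
    long as enough retained samples remain per window.
    """

    spacing: float = 0.5
    creation_limit: float = 12.0
    window_duration: float = 600.0
    equilibration: float = 100.0
    force_constant: float = 20.0
    topology: int = 8  # 8- or 4-connected lattice neighborhood
    max_rounds: int = 60
    temperature: float = DEFAULT_TEMPERATURE
    frontier: str = "interpolate"  # or "nearest": skip interpolation

    def __post_init__(self):
        if self.creation_limit <= 0:
            raise ValueError("creation limit must be positive")
        if self.topology not in (4, 8):
            raise ValueError("topology must be 4 or 8")
        if self.frontier not in ("interpolate", "nearest"):
            raise ValueError("frontier must be 'interpolate' or 'nearest'")
        if self.equilibration >= self.window_duration:
            raise ValueError("equilibration must be shorter than the window")

    def neighbor_offsets(self, ndim: int):
        if ndim == 1:
            return [(-1,), (1,)]
        return _OFFSETS_2D_8 if self.topology == 8 else _OFFSETS_2D_4


@dataclass
class AdaptiveRound:
    """One round: the windows it created and the joint solution after it."""

    index: int
    new_nodes: list[tuple[int, ...]]
    new_centers: np.ndarray
    solution: WhamSolution
    seed: int


@dataclass
class AdaptiveRun:
    """Full transcript of an adaptive umbrella-sampling run."""

    landscape: AnalyticLandscape
    config: AdaptiveConfig
    seed_center: np.ndarray
    master_seed: int
    grid: AnalysisGrid
    rounds: list[AdaptiveRound] = field(default_factory=list)
    windows: list[WindowData] = field(default_factory=list)
    nodes: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def final_solution(self) -> WhamSolution:
        return self.rounds[-1].solution

    @property
    def centers(self) -> np.ndarray:
        """(n_windows, ndim) array of simulated window centers, in order."""
        return np.asarray(
            [self.seed_center + np.asarray(n) * self.config.spacing for n in self.nodes]
        )


def _node_center(seed_center: np.ndarray, node: tuple[int, ...], spacing: float):
    return seed_center + np.asarray(node, dtype=float) * spacing


def _estimate_free_energy(
    solution: WhamSolution | None, center: np.ndarray, config: AdaptiveConfig
) -> float:
    """Frontier estimate at a candidate center; NaN when no evidence exists."""
    if solution is None:
        return float("nan")
    pmf = solution.pmf
    if config.frontier == "interpolate":
        est = pmf.interpolate(center)
        if np.isfinite(est):
            return est
    # fall back: minimum defined free energy among bins lying within half a
    # lattice spacing of the candidate.  A bin counts as "within" if any
    # point of its cell does (per-axis slack of half a grid spacing):
    # lattice nodes sit on bin corners, so a center-to-center metric would
    # exclude the whole ring of bins that actually touch the disc.
    radius = config.spacing / 2.0
    grid = pmf.grid
    mesh = grid.center_mesh()
    sl = []
    for ax in range(grid.ndim):
        i0 = int(np.floor((center[ax] - radius - grid.lo[ax]) / grid.spacing)) - 1
        i1 = int(np.ceil((center[ax] + radius - grid.lo[ax]) / grid.spacing)) + 1
        sl.append(slice(max(i0, 0), min(i1, grid.shape[ax])))
    sl = tuple(sl)
    sub_f = pmf.free_energy[sl]
    dist2 = np.zeros_like(sub_f)
    for ax in range(grid.ndim):
        gap = np.abs(mesh[ax][sl] - center[ax]) - grid.spacing / 2.0
        dist2 = dist2 + np.maximum(gap, 0.0) ** 2
    near = (dist2 <= radius * radius + 1e-12) & np.isfinite(sub_f)
    if not near.any():
        return float("nan")
    return float(sub_f[near].min())


def propose_new_windows(
    solution: WhamSolution | None,
    completed: list[tuple[int, ...]],
    config: AdaptiveConfig,
    landscape: AnalyticLandscape,
    seed_center: np.ndarray,
) -> list[tuple[int, ...]]:
    """Lattice nodes to simulate next, in lexicographic order.

    With no completed window the proposal is exactly the seed node.
    Otherwise candidates are the not-yet-simulated lattice neighbors of
    completed nodes (inside the domain) whose estimated free energy is below
    the creation limit.
    """
    if not completed:
        return [tuple(0 for _ in range(landscape.ndim))]
    done = set(completed)
    candidates = set()
    for node in completed:
        for off in config.neighbor_offsets(landscape.ndim):
            cand = tuple(n + o for n, o in zip(node, off))
            if cand in done:
                continue
            center = _node_center(seed_center, cand, config.spacing)
            if not landscape.contains(center):
                continue
            candidates.add(cand)
    accepted = []
    for cand in sorted(candidates):
        center = _node_center(seed_center, cand, config.spacing)
        est = _estimate_free_energy(solution, center, config)
        if np.isfinite(est) and est < config.creation_limit:
            accepted.append(cand)
    return accepted


def seed_position_for(
    new_center: np.ndarray, neighbor_windows: list[WindowData]
) -> np.ndarray:
    """Starting configuration for a new window.

    Returns the retained sample, over all neighboring completed windows,
    closest in Euclidean distance to the new center.  Ties resolve to the
    lowest window index, then the earliest sample.
    """
    if not neighbor_windows:
        raise ValueError("need at least one completed neighbor window")
    best = None
    best_d = np.inf
    for win in neighbor_windows:
        traj = win.trajectory
        if traj is None:
            raise ValueError("neighbor window carries no trajectory")
        keep = traj.times >= win.discard
        pts = traj.coords[keep]
        d = np.linalg.norm(pts - np.asarray(new_center), axis=1)
        i = int(np.argmin(d))  # argmin returns the earliest minimum
        if d[i] < best_d:
            best_d = float(d[i])
            best = pts[i]
    return np.array(best)


def run_adaptive(
    landscape: AnalyticLandscape,
    seed_center,
    config: AdaptiveConfig,
    brownian: BrownianParams,
    master_seed: int = 0,
    grid: AnalysisGrid | None = None,
    wham_tolerance: float = 1e-7,
) -> AdaptiveRun:
    """Run the self-learning loop until no new window can be created.

    Everything (window order, trajectories, PMFs) is reproducible from
    ``master_seed``.  Raises whatever :func:`permeon.wham.wham_solve` raises;
    a disconnected-sampling error aborts the run with its round number.
    """
    seed_center = np.atleast_1d(np.asarray(seed_center, dtype=float))
    if not landscape.contains(seed_center):
        raise ValueError("seed center outside the landscape domain")
    if grid is None:
        grid = AnalysisGrid(
            tuple(b[0] for b in landscape.bounds),
            tuple(b[1] for b in landscape.bounds),
            0.1,
        )
    ratio = config.spacing / grid.spacing
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("lattice spacing must be a multiple of the grid spacing")

    ss = np.random.SeedSequence(master_seed)
    run = AdaptiveRun(
        landscape=landscape,
        config=config,
        seed_center=seed_center,
        master_seed=master_seed,
        grid=grid,
    )
    solution: WhamSolution | None = None
    offsets = None
    for round_index in range(config.max_rounds):
        proposal = propose_new_windows(
            solution, run.nodes, config, landscape, seed_center
        )
        if not proposal:
            break
        round_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        window_seeds = [
            int(s) for s in np.random.SeedSequence(round_seed).generate_state(len(proposal))
        ]
        biases, starts = [], []
        for node in proposal:
            center = _node_center(seed_center, node, config.spacing)
            biases.append(
                BiasSpec(tuple(center), tuple([config.force_constant] * landscape.ndim))
            )
            if not run.windows:
                starts.append(center)
            else:
                neigh_nodes = {
                    tuple(n + o for n, o in zip(node, off))
                    for off in config.neighbor_offsets(landscape.ndim)
                }
                neighbors = [
                    w for n, w in zip(run.nodes, run.windows) if n in neigh_nodes
                ]
                starts.append(seed_position_for(center, neighbors))
        trajs = simulate_windows(
            landscape, biases, brownian, config.window_duration,
            seeds=window_seeds, starts=starts,
        )
        for node, traj in zip(proposal, trajs):
            run.nodes.append(node)
            run.windows.append(bin_samples(traj, grid, discard=config.equilibration))
        if offsets is not None:
            offsets = np.concatenate([offsets, np.zeros(len(proposal))])
        try:
            solution = wham_solve(
                run.windows, grid, config.temperature,
                tolerance=wham_tolerance, initial_offsets=offsets,
            )
        except DisconnectedSamplingError as exc:
            exc.round_index = round_index  # which round broke connectivity
            raise
        offsets = solution.offsets
        run.rounds.append(
            AdaptiveRound(
                index=round_index,
                new_nodes=list(proposal),
                new_centers=np.asarray(
                    [_node_center(seed_center, n, config.spacing) for n in proposal]
                ),
                solution=solution,
                seed=round_seed,
            )
        )
    if not run.rounds:
        raise RuntimeError("adaptive run created no windows")
    return run
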