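"""Plain-text interchange formats.

Trajectories are whitespace-delimited text (time then coordinates, '#'
headers carrying the bias and seed); window sets are described by a CSV
metadata file listing per-window trajectory path, bias center and force
constant, following the conventions of community WHAM tools; PMFs and error
maps are one-row-per-bin tables (bin-center coordinates then the value,
``nan`` for undefined bins) with a JSON sidecar for offsets and diagnostics.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ErrorMap, OccupancySeries, PathResult, StatePoint
from .brownian import BiasSpec, RCTrajectory
from .grids import AnalysisGrid, PMFGrid
from .wham import WhamSolution

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_window_metadata",
    "read_window_metadata",
    "write_pmf",
    "read_pmf",
    "write_error_map",
    "states_to_csv",
    "path_to_csv",
    "occupancy_to_csv",
    "fit_report_json",
    "fit_report_text",
]


def write_trajectory(traj: RCTrajectory, path) -> None:
    header = (
        f"bias_center: {' '.join(repr(c) for c in traj.bias.center)}\n"
        f"force_constant: {' '.join(repr(k) for k in traj.bias.k)}\n"
        f"seed: {traj.seed if traj.seed is not None else 'none'}\n"
        f"duration_ps: {traj.duration!r}\n"
        "columns: time_ps " + " ".join(f"z{i+1}_A" for i in range(traj.ndim))
    )
    data = np.column_stack([traj.times, traj.coords])
    np.savetxt(path, data, header=header, fmt="%.10g")


def read_trajectory(path) -> RCTrajectory:
    center = k = duration = None
    seed = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, rest = line.lstrip("# ").partition(":")
            key = key.strip()
            if key == "bias_center":
                center = tuple(float(x) for x in rest.split())
            elif key == "force_constant":
                k = tuple(float(x) for x in rest.split())
            elif key == "duration_ps":
                duration = float(rest)
            elif key == "seed":
                rest = rest.strip()
                seed = None if rest == "none" else int(rest)
    if center is None or k is None:
        raise ValueError(f"{path}: missing bias header lines")
    data = np.loadtxt(path, ndmin=2)
    return RCTrajectory(
        times=data[:, 0], coords=data[:, 1:], bias=BiasSpec(center, k), seed=seed,
        duration=duration,
    )


def write_window_metadata(path, traj_paths, biases: list[BiasSpec]) -> None:
    ndim = biases[0].ndim
    rows = []
    for p, b in zip(traj_paths, biases):
        row = {"path": str(p)}
        for ax in range(ndim):
            row[f"center_{ax + 1}"] = b.center[ax]
            row[f"k_{ax + 1}"] = b.k[ax]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_window_metadata(path) -> list[RCTrajectory]:
    """Load every trajectory listed in a window metadata CSV.

    Relative trajectory paths are resolved against the CSV's directory.
    The bias stored in each trajectory header must match the metadata row.
    """
    base = Path(path).parent
    df = pd.read_csv(path)
    ndim = sum(c.startswith("center_") for c in df.columns)
    trajs = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        traj = read_trajectory(p)
        meta_bias = BiasSpec(
            tuple(row[f"center_{ax + 1}"] for ax in range(ndim)),
            tuple(row[f"k_{ax + 1}"] for ax in range(ndim)),
        )
        if not np.allclose(meta_bias.center, traj.bias.center) or not np.allclose(
            meta_bias.k, traj.bias.k
        ):
            raise ValueError(f"{p}: bias header disagrees with metadata")
        trajs.append(traj)
    return trajs


def _grid_table(grid: AnalysisGrid, values: np.ndarray) -> np.ndarray:
    mesh = grid.center_mesh()
    cols = [m.ravel() for m in mesh] + [values.ravel()]
    return np.column_stack(cols)


def write_pmf(pmf: PMFGrid, path, solution: WhamSolution | None = None) -> None:
    """Write a PMF table plus a JSON sidecar (<path>.json) of diagnostics."""
    header = (
        "potential of mean force (kcal/mol); nan = unsampled bin\n"
        f"grid_lo: {' '.join(repr(x) for x in pmf.grid.lo)}\n"
        f"grid_hi: {' '.join(repr(x) for x in pmf.grid.hi)}\n"
        f"spacing: {pmf.grid.spacing!r}\n"
        f"temperature_K: {pmf.temperature!r}\n"
        "columns: " + " ".join(f"z{i+1}_A" for i in range(pmf.grid.ndim)) + " F_kcal_mol"
    )
    np.savetxt(path, _grid_table(pmf.grid, pmf.free_energy), header=header, fmt="%.10g")
    side = {"temperature_K": pmf.temperature}
    if solution is not None:
        side.update(
            offsets_kcal_mol=[float(x) for x in solution.offsets],
            iterations=solution.iterations,
            converged=solution.converged,
            residual_kcal_mol=solution.residual,
        )
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh, indent=1)


def read_pmf(path) -> PMFGrid:
    lo = hi = spacing = None
    temperature = 0.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, rest = line.lstrip("# ").partition(":")
            key = key.strip()
            if key == "grid_lo":
                lo = tuple(float(x) for x in rest.split())
            elif key == "grid_hi":
                hi = tuple(float(x) for x in rest.split())
            elif key == "spacing":
                spacing = float(rest)
            elif key == "temperature_K":
                temperature = float(rest)
    if lo is None or hi is None or spacing is None:
        raise ValueError(f"{path}: missing grid header lines")
    grid = AnalysisGrid(lo, hi, spacing)
    data = np.loadtxt(path, ndmin=2)
    f = data[:, -1].reshape(grid.shape)
    return PMFGrid(grid=grid, free_energy=f, temperature=temperature)


def write_error_map(err: ErrorMap, path) -> None:
    header = (
        "per-bin PMF standard deviation (kcal/mol); nan = not defined in "
        "every interval\n"
        f"grid_lo: {' '.join(repr(x) for x in err.grid.lo)}\n"
        f"grid_hi: {' '.join(repr(x) for x in err.grid.hi)}\n"
        f"spacing: {err.grid.spacing!r}\n"
        f"n_intervals: {err.n_intervals}\n"
        f"slice_length_ps: {err.slice_length!r}"
    )
    np.savetxt(path, _grid_table(err.grid, err.sd), header=header, fmt="%.10g")


def states_to_csv(states: list[StatePoint], path) -> None:
    rows = [
        {"label": s.label,
         **{f"z{i+1}_A": c for i, c in enumerate(s.coords)},
         "F_kcal_mol": s.free_energy}
        for s in states
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def path_to_csv(result: PathResult, path) -> None:
    rows = [
        {**{f"z{i+1}_A": c for i, c in enumerate(coord)}}
        for coord in result.coords
    ]
    df = pd.DataFrame(rows)
    df.attrs["barrier"] = result.barrier
    df.to_csv(path, index=False)


def occupancy_to_csv(series: OccupancySeries, path) -> None:
    n_frames, n_ions = series.sites.shape
    data = {
        f"ion{i+1}_site": [series.labels[s] for s in series.sites[:, i]]
        for i in range(n_ions)
    }
    data["bound_count"] = series.bound_count
    data["events_cumulative"] = series.events_cumulative
    pd.DataFrame(data).to_csv(path, index_label="frame")


def fit_report_json(result, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)


def fit_report_text(result) -> str:
    """Human-readable fit summary in the conventional table layout:
    value (error), 'N/A' where a parameter was fixed or constrained."""
    lines = [f"model: {result.model}   converged: {result.converged}   "
             f"SSR: {result.ssr:.3e}"]
    for name, value in result.params.items():
        err = result.stderr.get(name)
        shown = f"{value:.4g}"
        shown += f" ({err:.2g})" if err is not None else " (N/A)"
        lines.append(f"  {name:>12s} = {shown}")
    if result.active_bounds:
        lines.append("  active constraints: " + "; ".join(result.active_bounds))
    if result.warnings:
        lines.append("  warnings: " + "; ".join(result.warnings))
    return "\n".join(lines)
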