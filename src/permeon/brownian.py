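"""Overdamped Brownian dynamics on analytic landscapes.

This is the sampling engine that stands in for the molecular-dynamics code:
an Euler-Maruyama integrator for the overdamped Langevin equation

    dz = -(D/kT) grad(U + w) dt + sqrt(2 D dt) dW

with reflecting walls at the domain boundary.  Only the stationary
(Boltzmann) distribution matters for free-energy recovery, so inertia is
dropped.  Trajectories are bit-reproducible for a fixed seed, and a batch of
windows integrated together is bit-identical to the same windows integrated
one at a time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .landscapes import AnalyticLandscape

__all__ = [
    "StabilityError",
    "BrownianParams",
    "BiasSpec",
    "RCTrajectory",
    "simulate",
    "simulate_windows",
    "reaction_coords",
]

_CHUNK_STEPS = 50_000


class StabilityError(RuntimeError):
    """The requested timestep is too large for the potential's forces."""


@dataclass(frozen=True)
class BrownianParams:
    """Integrator parameters.

    temperature : K (323.25 by default, the reference simulation temperature)
    diffusion   : A^2/ps, isotropic
    timestep    : ps
    sampling_interval : ps, must be an integer multiple of the timestep.
        The default (0.1 ps) is one to two relaxation times of a coordinate
        held by the default 20 kcal/mol/A^2 bias, so recorded samples are
        approximately independent -- which is what the histogram estimators
        downstream assume.
    metropolis : accept/reject each Euler-Maruyama step with the usual
        Langevin proposal ratio, making the sampled stationary distribution
        exactly Boltzmann at any timestep.  Plain (unadjusted) integration
        carries an O(a dt) density error (a the local relaxation rate),
        negligible on soft 1D landscapes but visible against tight error
        bounds on 2D maps with stiff confining walls; the adjusted sampler
        removes it at roughly twice the cost per step.
    seed : default RNG seed; an explicit seed passed to ``simulate`` wins
    """

    temperature: float = DEFAULT_TEMPERATURE
    diffusion: float = 0.5
    timestep: float = 0.002
    sampling_interval: float = 0.1
    metropolis: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.diffusion <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.sampling_interval < self.timestep:
            raise ValueError("sampling interval must be >= timestep")
        n = self.sampling_interval / self.timestep
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling interval must be a multiple of the timestep")

    @property
    def steps_per_sample(self) -> int:
        return int(round(self.sampling_interval / self.timestep))


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella bias ``w(z) = sum_i k_i/2 (z_i - c_i)^2``.

    The default force constant of 20 kcal/mol/A^2 matches the umbrella
    windows of the reference protocol.  The bias is exactly zero at its
    center.
    """

    center: tuple[float, ...]
    k: tuple[float, ...] = (20.0,)

    def __post_init__(self):
        c = tuple(float(x) for x in np.atleast_1d(np.asarray(self.center, float)))
        k = tuple(
            float(x) for x in np.broadcast_to(np.asarray(self.k, float), (len(c),))
        )
        if any(ki < 0 for ki in k):
            raise ValueError("force constants must be non-negative")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "k", k)

    @property
    def ndim(self) -> int:
        return len(self.center)

    def energy(self, z) -> np.ndarray:
        d = np.asarray(z, dtype=float) - np.asarray(self.center)
        return 0.5 * (np.asarray(self.k) * d * d).sum(axis=-1)

    def gradient(self, z) -> np.ndarray:
        return np.asarray(self.k) * (np.asarray(z, dtype=float) - np.asarray(self.center))


@dataclass
class RCTrajectory:
    """Reaction-coordinate time series from one umbrella window.

    Samples are recorded at ``t = 0, dt_s, 2 dt_s, ...`` (``dt_s`` the
    sampling interval), the first being the starting configuration, so a
    window of nominal ``duration`` holds ``floor(duration / dt_s)`` rows.
    """

    times: np.ndarray
    coords: np.ndarray
    bias: BiasSpec
    seed: int | None = None
    duration: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and coords must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.duration is None:
            # nominal span: one sampling interval past the last stamp
            step = self.times[1] - self.times[0] if len(self.times) > 1 else 0.0
            self.duration = float(self.times[-1] + step)

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return len(self.times)


def _check_stability(
    landscape: AnalyticLandscape, biases, params: BrownianParams, scan: int = 101
) -> None:
    """Scan the domain for drift steps exceeding half an angstrom."""
    axes = [np.linspace(lo, hi, scan) for lo, hi in landscape.bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    g = landscape.gradient(pts) if pts.shape[0] > 1 else landscape.gradient(pts)
    g = np.atleast_2d(g)
    mob = params.diffusion / thermal_energy(params.temperature)
    for bias in biases:
        total = g + bias.gradient(pts)
        step = mob * np.abs(total) * params.timestep
        if step.max() > 0.5:
            raise StabilityError(
                f"drift step {step.max():.2f} A exceeds 0.5 A for timestep "
                f"{params.timestep} ps; reduce the timestep"
            )


def _integrate(
    landscape: AnalyticLandscape,
    biases: list[BiasSpec],
    params: BrownianParams,
    n_samples: int,
    starts: np.ndarray,
    generators: list[np.random.Generator],
) -> np.ndarray:
    """Core batched Euler-Maruyama loop -> samples (n_samples, W, d)."""
    d = landscape.ndim
    nw = len(biases)
    kT = thermal_energy(params.temperature)
    mob_dt = params.diffusion / kT * params.timestep
    sigma = np.sqrt(2.0 * params.diffusion * params.timestep)
    lo = np.array([b[0] for b in landscape.bounds])
    hi = np.array([b[1] for b in landscape.bounds])
    centers = np.stack([np.asarray(b.center) for b in biases])  # (W, d)
    ks = np.stack([np.asarray(b.k) for b in biases])  # (W, d)

    z = np.array(starts, dtype=float).reshape(nw, d).copy()
    out = np.empty((n_samples, nw, d))
    out[0] = z  # first sample is the starting configuration (t = 0)
    sps = params.steps_per_sample
    n_steps = (n_samples - 1) * sps
    gradient = landscape._gradient  # hot loop: skip the validating wrapper
    energy = landscape._energy
    kT = thermal_energy(params.temperature)
    mh = params.metropolis
    if mh:
        u_cur = energy(z) + 0.5 * (ks * (z - centers) ** 2).sum(axis=1)
        g_cur = gradient(z) + ks * (z - centers)
    step = 0
    while step < n_steps:
        chunk = min(_CHUNK_STEPS, n_steps - step)
        # per-window noise streams keep batch == single bit-identical;
        # each window draws its normals, then (if adjusting) its uniforms
        noise = np.stack(
            [g.standard_normal((chunk, d)) for g in generators], axis=1
        )  # (chunk, W, d)
        if mh:
            logu = np.log(np.stack(
                [g.random(chunk) for g in generators], axis=1
            ))  # (chunk, W)
        for i in range(chunk):
            if mh:
                # Metropolis-adjusted Langevin step: propose, then accept
                # with the ratio of Boltzmann weights and proposal densities
                prop = z - mob_dt * g_cur + sigma * noise[i]
                inside = ((prop >= lo) & (prop <= hi)).all(axis=1)
                u_prop = energy(prop) + 0.5 * (ks * (prop - centers) ** 2).sum(axis=1)
                g_prop = gradient(prop) + ks * (prop - centers)
                fwd = prop - (z - mob_dt * g_cur)
                bwd = z - (prop - mob_dt * g_prop)
                log_q = ((fwd * fwd).sum(axis=1) - (bwd * bwd).sum(axis=1)) / (
                    2.0 * sigma * sigma
                )
                log_alpha = -(u_prop - u_cur) / kT + log_q
                accept = inside & (logu[i] < log_alpha)
                a = accept[:, None]
                z = np.where(a, prop, z)
                u_cur = np.where(accept, u_prop, u_cur)
                g_cur = np.where(a, g_prop, g_cur)
            else:
                grad = gradient(z) + ks * (z - centers)
                z = z - mob_dt * grad + sigma * noise[i]
                # reflecting walls; the stability check bounds one step well
                # below the domain size, so a single reflection pass suffices
                z = np.where(z < lo, 2.0 * lo - z, z)
                z = np.where(z > hi, 2.0 * hi - z, z)
            step += 1
            if step % sps == 0:
                out[step // sps] = z
                if ((z < lo) | (z > hi)).any():  # pragma: no cover
                    raise StabilityError("particle escaped the domain")
    return out


def simulate(
    landscape: AnalyticLandscape,
    bias: BiasSpec,
    params: BrownianParams,
    duration: float,
    seed: int | None = None,
    start=None,
) -> RCTrajectory:
    """Sample one umbrella window.

    ``duration`` (ps) must cover at least 10 sampling intervals.  The walk
    starts at ``start`` (bias center by default) and records the coordinate
    every ``params.sampling_interval`` ps, the first sample one interval in.
    """
    trajs = simulate_windows(
        landscape, [bias], params, duration,
        seeds=[seed if seed is not None else params.seed],
        starts=None if start is None else [start],
    )
    return trajs[0]


def simulate_windows(
    landscape: AnalyticLandscape,
    biases: list[BiasSpec],
    params: BrownianParams,
    duration: float,
    seeds: list[int | None],
    starts=None,
) -> list[RCTrajectory]:
    """Sample several windows on the same landscape in one batched sweep.

    Each window consumes its own RNG stream (from its own seed), so the
    result is bit-identical to calling :func:`simulate` per window; batching
    only amortizes the Python-level cost of the time loop.
    """
    if len(biases) == 0:
        return []
    if duration < 10 * params.sampling_interval:
        raise ValueError(
            f"duration {duration} ps too short: need at least 10 sampling "
            f"intervals ({10 * params.sampling_interval} ps)"
        )
    if len(seeds) != len(biases):
        raise ValueError("need one seed per window")
    for bias in biases:
        if bias.ndim != landscape.ndim:
            raise ValueError("bias and landscape dimensions differ")
    _check_stability(landscape, biases, params)

    n_samples = int(np.floor(duration / params.sampling_interval + 1e-9))
    if starts is None:
        starts = [b.center for b in biases]
    starts = np.asarray([np.atleast_1d(np.asarray(s, float)) for s in starts])
    for s in starts:
        if not landscape.contains(s):
            raise ValueError(f"start position {s} outside the landscape domain")
    gens = [np.random.default_rng(s) for s in seeds]
    samples = _integrate(landscape, biases, params, n_samples, starts, gens)
    times = params.sampling_interval * np.arange(n_samples)
    return [
        RCTrajectory(
            times=times, coords=samples[:, i, :], bias=biases[i], seed=seeds[i],
            duration=float(duration),
        )
        for i in range(len(biases))
    ]


def reaction_coords(ion_z, filter_com_z: float):
    """Reduced permeation coordinates (Z12, Z3) from three ion positions.

    ``ion_z`` holds the pore-axis positions of the three tracked ions ordered
    from extracellular to intracellular, either as a length-3 vector or as an
    (n, 3) array of frames.  Z12 is the center-of-mass of the two outermost
    (extracellular-side) ions and Z3 the innermost ion, both relative to the
    selectivity-filter center of mass ``filter_com_z``.
    """
    z = np.asarray(ion_z, dtype=float)
    squeeze = z.ndim == 1
    z = np.atleast_2d(z)
    if z.shape[1] != 3:
        raise ValueError(f"expected three ion positions per frame, got {z.shape[1]}")
    z12 = 0.5 * (z[:, 0] + z[:, 1]) - filter_com_z
    z3 = z[:, 2] - filter_com_z
    if squeeze:
        return float(z12[0]), float(z3[0])
    return z12, z3
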