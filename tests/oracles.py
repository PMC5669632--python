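"""Independent reference implementations used only by the test suite.

Each oracle deliberately takes a different route from the package code it
checks: binless MBAR instead of binned WHAM, exhaustive path enumeration
instead of Dijkstra, lattice flood fill on the exact surface instead of the
sampled frontier, and high-precision arithmetic instead of log-domain
doubles.
"""
from __future__ import annotations

from collections import deque

import numpy as np


def mbar_free_energies(samples, bias_fns, kT, n_iter=20_000, tol=1e-12):
    """Binless MBAR window free energies, anchored at f_0 = 0.

    ``samples`` is a list of (N_i, d) arrays, one per window; ``bias_fns``
    the matching bias energy callables.  Solves the standard MBAR
    self-consistency on the pooled samples by direct iteration -- slow and
    simple on purpose.
    """
    x = np.concatenate([np.atleast_2d(s) for s in samples], axis=0)
    n_i = np.array([len(np.atleast_2d(s)) for s in samples], dtype=float)
    u = np.stack([fn(x) / kT for fn in bias_fns])  # (K, N) reduced energies
    log_n = np.log(n_i)
    f = np.zeros(len(samples))
    for _ in range(n_iter):
        # log denominator per sample: logsumexp_k (log N_k + f_k - u_k(x))
        a = log_n[:, None] + f[:, None] - u
        amax = a.max(axis=0)
        logden = amax + np.log(np.exp(a - amax).sum(axis=0))
        b = -u - logden
        bmax = b.max(axis=1)
        f_new = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f * kT


def enumerate_minimax(f_grid: np.ndarray, a, b):
    """Minimax barrier by exhaustive enumeration of simple 8-connected paths.

    Exponential -- intended for grids of about 5x5.  Returns the minimal
    over paths of the maximal value visited (including both endpoints).
    """
    shape = f_grid.shape
    a, b = tuple(a), tuple(b)
    best = [np.inf]

    def neighbors(n):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                m = (n[0] + di, n[1] + dj)
                if 0 <= m[0] < shape[0] and 0 <= m[1] < shape[1]:
                    if np.isfinite(f_grid[m]):
                        yield m

    def dfs(node, visited, running_max):
        if running_max >= best[0]:
            return  # cannot improve
        if node == b:
            best[0] = running_max
            return
        for m in neighbors(node):
            if m not in visited:
                dfs(m, visited | {m}, max(running_max, float(f_grid[m])))

    dfs(a, {a}, float(f_grid[a]))
    return best[0]


def flood_fill_nodes(landscape, seed_center, spacing=0.5, limit=12.0,
                     topology=8):
    """Lattice nodes below ``limit`` reachable from the seed through
    sub-limit nodes, on the exact surface referenced to its global minimum
    (found on a fine scan)."""
    seed = np.atleast_1d(np.asarray(seed_center, dtype=float))
    axes = [np.linspace(lo, hi, 401) for lo, hi in landscape.bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    fmin = landscape.potential(
        np.stack([m.ravel() for m in mesh], axis=1)
    ).min()
    if landscape.ndim == 1:
        offs = [(-1,), (1,)]
    elif topology == 8:
        offs = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    start = tuple(0 for _ in range(landscape.ndim))
    seen = {start}
    out = set()
    q = deque([start])
    while q:
        n = q.popleft()
        out.add(n)
        for o in offs:
            m = tuple(ni + oi for ni, oi in zip(n, o))
            if m in seen:
                continue
            c = seed + np.asarray(m) * spacing
            if not landscape.contains(c):
                continue
            seen.add(m)
            if landscape.potential(c) - fmin < limit:
                q.append(m)
    return out


def mwc_po_highprec(lo, ph, pka1=None, pka2=None, dps=60):
    """Open probability of the two-sensor concerted model via mpmath.

    ``pka1``/``pka2`` are (closed, open) tuples or None for absent sensors.
    """
    import mpmath as mp

    with mp.workdps(dps):
        h = mp.mpf(10) ** (-mp.mpf(str(ph)))
        num = mp.mpf(str(lo))
        den = mp.mpf(1)
        for pka in (pka1, pka2):
            if pka is None:
                continue
            c, o = (mp.mpf(str(v)) for v in pka)
            ka_o = mp.mpf(10) ** (-o)
            ka_c = mp.mpf(10) ** (-c)
            num *= (1 + h / ka_o) ** 4
            den *= (1 + h / ka_c) ** 4
        return float(num / (num + den))
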