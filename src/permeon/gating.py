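"""pH-dependent gating models for single-channel open probability.

Two descriptions of Po(pH) for a proton-gated tetrameric K+ channel:

* the empirical Hill equation,
      Po = Pomax / (1 + 10^((pH - pH_1/2) * nH)),
  whose EC50 = 10^-pH_1/2 and Hill coefficient nH summarize potency and
  apparent cooperativity; and

* a concerted two-state (closed/open) allosteric model with four copies each
  of two proton sensors (H25 and E118 in KcsA), whose acid dissociation
  constants differ between the closed and open conformations:

      Po = Lo * Ao * Bo / (Lo * Ao * Bo + Ac * Bc),
      A_x = (1 + 10^(pKa1_x - pH))^4,   B_x = (1 + 10^(pKa2_x - pH))^4.

  Lo is the intrinsic open/closed equilibrium of the fully deprotonated
  channel; a mutated-away sensor contributes a factor of exactly 1.

Both curves are evaluated in the log domain so extreme Lo values and pKa-pH
gaps cannot overflow.  Fitting is unweighted nonlinear least squares on the
per-pH mean open probabilities, with the physical ordering
pKa_closed <= pKa_open available as a bound constraint, and Lo optimized as
log10(Lo) since it spans many decades.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "HillParams",
    "MWCParams",
    "PoDataset",
    "PoSyntheticConfig",
    "FitResult",
    "NoCrossingError",
    "hill_po",
    "mwc_po",
    "generate_po_dataset",
    "fit_hill",
    "fit_mwc",
    "two_stage_mwc_fit",
    "hill_summary_of_mwc",
    "KCSA_GATING",
]

_LN10 = np.log(10.0)
#: Subunit count of the homotetramer; a structural constant, not a fit knob.
N_SUBUNITS = 4


class NoCrossingError(ValueError):
    """The Po curve does not cross one half of Pomax on the given grid."""


def _log1p10(u):
    """log(1 + 10^u), overflow-safe for any u."""
    return np.logaddexp(0.0, np.asarray(u, dtype=float) * _LN10)


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: Po(pH_half) = Pomax/2 by construction."""

    pomax: float
    ph_half: float
    nh: float

    def __post_init__(self):
        if not (0.0 < self.pomax <= 1.0):
            raise ValueError(f"pomax must be in (0, 1], got {self.pomax}")
        if self.nh <= 0:
            raise ValueError(f"Hill coefficient must be positive, got {self.nh}")

    @property
    def ec50(self) -> float:
        """Half-activation proton concentration (M)."""
        return 10.0 ** (-self.ph_half)


def hill_po(params: HillParams, ph):
    """Open probability of the Hill dose-response at one or many pH values."""
    ph = np.asarray(ph, dtype=float)
    # Pomax / (1 + 10^((pH - pH_half) nH)) evaluated via log1p10 for safety
    out = params.pomax * np.exp(-_log1p10((ph - params.ph_half) * params.nh))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MWCParams:
    """Two-sensor concerted-gating parameters.

    A sensor is present when both of its pKa values are given; setting both
    to None removes it (its factor becomes exactly 1), which is how sensor
    point mutants such as H25R or E118A are encoded.
    """

    lo: float
    pka1_closed: float | None = None
    pka1_open: float | None = None
    pka2_closed: float | None = None
    pka2_open: float | None = None

    def __post_init__(self):
        if self.lo <= 0:
            raise ValueError(f"Lo must be positive, got {self.lo}")
        for name in ("pka1", "pka2"):
            c = getattr(self, f"{name}_closed")
            o = getattr(self, f"{name}_open")
            if (c is None) != (o is None):
                raise ValueError(
                    f"sensor {name}: give both pKa_closed and pKa_open or neither"
                )

    @property
    def sensor1_present(self) -> bool:
        return self.pka1_open is not None

    @property
    def sensor2_present(self) -> bool:
        return self.pka2_open is not None

    def replace(self, **kw) -> "MWCParams":
        d = {f: getattr(self, f) for f in
             ("lo", "pka1_closed", "pka1_open", "pka2_closed", "pka2_open")}
        d.update(kw)
        return MWCParams(**d)


def mwc_po(params: MWCParams, ph):
    """Open probability of the two-sensor concerted model.

    Log-domain evaluation: the open and closed partition factors are built
    as sums of log(1 + 10^x) terms and combined through a single logaddexp,
    so any Lo in (0, inf) and any pKa - pH gap is handled without overflow.
    """
    ph = np.asarray(ph, dtype=float)
    log_open = np.log(params.lo) + np.zeros_like(ph)
    log_closed = np.zeros_like(ph)
    if params.sensor1_present:
        log_open = log_open + N_SUBUNITS * _log1p10(params.pka1_open - ph)
        log_closed = log_closed + N_SUBUNITS * _log1p10(params.pka1_closed - ph)
    if params.sensor2_present:
        log_open = log_open + N_SUBUNITS * _log1p10(params.pka2_open - ph)
        log_closed = log_closed + N_SUBUNITS * _log1p10(params.pka2_closed - ph)
    out = np.exp(log_open - np.logaddexp(log_open, log_closed))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# datasets


@dataclass
class PoDataset:
    """Open probability vs pH with replicate (bilayer) structure."""

    ph: np.ndarray
    po: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    replicates: list[np.ndarray] | None = None

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.po = np.asarray(self.po, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.ph) == len(self.po) == len(self.sem) == len(self.n)):
            raise ValueError("ph, po, sem and n must have equal lengths")
        if len(np.unique(self.ph)) != len(self.ph):
            raise ValueError("pH values must be unique")
        if np.any((self.po < 0) | (self.po > 1)):
            raise ValueError("Po values must lie in [0, 1]")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")

    def __len__(self) -> int:
        return len(self.ph)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pH": self.ph, "po": self.po, "sem": self.sem,
                             "n": self.n})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PoDataset":
        df = pd.read_csv(path)
        return cls(ph=df["pH"], po=df["po"], sem=df["sem"], n=df["n"])

    @classmethod
    def from_curve(cls, params: MWCParams | HillParams, ph) -> "PoDataset":
        """Noiseless dataset evaluated directly on a model curve."""
        ph = np.asarray(ph, dtype=float)
        po = mwc_po(params, ph) if isinstance(params, MWCParams) else hill_po(params, ph)
        return cls(ph=ph, po=po, sem=np.zeros_like(ph), n=np.ones_like(ph, dtype=int))


@dataclass(frozen=True)
class PoSyntheticConfig:
    """Synthetic Po(pH) measurement design emulating bilayer recordings.

    Each pH point receives ``replicates`` independent bilayer measurements
    drawn around the model curve with Gaussian noise of ``noise_sd``
    (clipped to [0, 1], since Po is a probability); defaults mirror the
    4-5 bilayers and point scatter of the real dose-response data.
    """

    params: MWCParams
    ph_values: tuple[float, ...] = tuple(np.round(np.arange(4.0, 6.51, 0.25), 2))
    replicates: int = 5
    noise_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if any(not (0.0 <= p <= 14.0) for p in self.ph_values):
            raise ValueError("pH values must lie in [0, 14]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per pH")


def generate_po_dataset(config: PoSyntheticConfig) -> PoDataset:
    """Draw a replicate-structured synthetic dose-response dataset."""
    rng = np.random.default_rng(config.seed)
    ph = np.asarray(config.ph_values, dtype=float)
    truth = np.atleast_1d(mwc_po(config.params, ph))
    reps = []
    for mu in truth:
        r = np.clip(
            mu + config.noise_sd * rng.standard_normal(config.replicates), 0.0, 1.0
        )
        reps.append(r)
    means = np.array([r.mean() for r in reps])
    sems = np.array(
        [r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else 0.0 for r in reps]
    )
    return PoDataset(
        ph=ph,
        po=means,
        sem=sems,
        n=np.full(len(ph), config.replicates),
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a gating-model fit.

    ``stderr`` holds asymptotic standard errors for free parameters only;
    fixed or constrained parameters get no error, mirroring how constrained
    fits are conventionally reported.  ``active_bounds`` lists constraints
    that ended up binding at the optimum.
    """

    model: str
    params: dict
    stderr: dict
    fixed: list
    active_bounds: list
    ssr: float
    converged: bool
    ndata: int
    nfree: int
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: v for k, v in self.params.items()},
            "stderr": {k: v for k, v in self.stderr.items()},
            "fixed": list(self.fixed),
            "active_bounds": list(self.active_bounds),
            "ssr": self.ssr,
            "converged": self.converged,
            "ndata": self.ndata,
            "nfree": self.nfree,
            "warnings": list(self.warnings),
        }


def _default_hill_init(data: PoDataset) -> HillParams:
    pomax = float(np.clip(data.po.max(), 1e-3, 1.0))
    half = pomax / 2.0
    i = int(np.argmin(np.abs(data.po - half)))
    return HillParams(pomax=pomax, ph_half=float(data.ph[i]), nh=2.0)


def fit_hill(
    data: PoDataset,
    init: HillParams | None = None,
    fixed: dict | tuple = (),
    weighted: bool = False,
) -> FitResult:
    """Unweighted (default) nonlinear least-squares Hill fit to Po means.

    ``fixed`` pins parameters, either ``{"pomax": 1.0}`` or a tuple of names
    (values then come from ``init``).  With ``weighted=True`` residuals are
    divided by the sem where it is positive.
    """
    if init is None:
        init = _default_hill_init(data)
    fixed = dict(fixed) if isinstance(fixed, dict) else {
        name: getattr(init, name) for name in fixed
    }
    pars = lmfit.Parameters()
    pars.add("pomax", value=fixed.get("pomax", init.pomax), min=1e-6, max=1.0,
             vary="pomax" not in fixed)
    pars.add("ph_half", value=fixed.get("ph_half", init.ph_half),
             vary="ph_half" not in fixed)
    pars.add("nh", value=fixed.get("nh", init.nh), min=1e-6,
             vary="nh" not in fixed)
    nfree = sum(p.vary for p in pars.values())
    if nfree > len(data):
        raise ValueError(f"{nfree} free parameters but only {len(data)} pH points")
    warnings = []
    if np.ptp(data.po) < 1e-12:
        warnings.append("degenerate data: all Po values equal (rank-deficient fit)")
    w = None
    if weighted:
        w = np.where(data.sem > 0, data.sem, np.nan)
        w = np.where(np.isfinite(w), w, np.nanmin(w) if np.isfinite(w).any() else 1.0)

    def resid(p):
        model = p["pomax"].value * np.exp(
            -_log1p10((data.ph - p["ph_half"].value) * p["nh"].value)
        )
        r = model - data.po
        return r / w if w is not None else r

    out = lmfit.minimize(resid, pars, method="leastsq")
    params = {k: float(out.params[k].value) for k in out.params}
    stderr = {
        k: (float(out.params[k].stderr) if out.params[k].vary and
            out.params[k].stderr is not None else None)
        for k in out.params
    }
    active = [
        f"{k} at bound"
        for k, p in out.params.items()
        if p.vary and p.max is not None and np.isfinite(p.max)
        and abs(p.value - p.max) < 1e-8
    ]
    return FitResult(
        model="hill",
        params=params,
        stderr=stderr,
        fixed=sorted(fixed),
        active_bounds=active,
        ssr=float(np.sum(np.asarray(out.residual) ** 2)),
        converged=bool(out.success),
        ndata=len(data),
        nfree=nfree,
        warnings=warnings,
    )


_MWC_NAMES = ("lo", "pka1_closed", "pka1_open", "pka2_closed", "pka2_open")


def fit_mwc(
    data: PoDataset,
    init: MWCParams,
    free: tuple = ("lo",),
    enforce_order: bool = True,
    weighted: bool = False,
) -> FitResult:
    """Bounded nonlinear least-squares fit of the concerted gating model.

    ``free`` names the parameters allowed to vary (from ``lo``,
    ``pka1_closed``, ``pka1_open``, ``pka2_closed``, ``pka2_open``); all
    others stay at their ``init`` values.  Lo is optimized as log10(Lo).
    With ``enforce_order`` the physical constraint pKa_closed <= pKa_open is
    applied per present sensor; when it binds, the fit reports the active
    constraint -- the situation where a sensor's state-dependence has
    collapsed and the model should be refit with that pKa pinned (see
    :func:`two_stage_mwc_fit`).
    """
    free = tuple(free)
    for name in free:
        if name not in _MWC_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        if name != "lo" and getattr(init, name) is None:
            raise ValueError(f"cannot free {name}: sensor absent in init")
    pars = lmfit.Parameters()
    pars.add("log10_lo", value=np.log10(init.lo), min=-25.0, max=10.0,
             vary="lo" in free)
    delta_param = {}
    for s in ("1", "2"):
        o, c = getattr(init, f"pka{s}_open"), getattr(init, f"pka{s}_closed")
        if o is None:
            continue
        o_free = f"pka{s}_open" in free
        c_free = f"pka{s}_closed" in free
        pars.add(f"pka{s}_open", value=o, vary=o_free)
        if c_free and o_free and enforce_order:
            # both free: parametrize closed = open - delta, delta >= 0
            pars.add(f"delta{s}", value=max(o - c, 0.0), min=0.0, vary=True)
            pars.add(f"pka{s}_closed", expr=f"pka{s}_open - delta{s}")
            delta_param[s] = f"delta{s}"
        else:
            kw = {}
            if c_free and enforce_order:
                kw["max"] = o  # open fixed: simple upper bound
            if o_free and enforce_order and not c_free:
                pars[f"pka{s}_open"].min = c
            pars.add(f"pka{s}_closed", value=c, vary=c_free, **kw)
    nfree = sum(p.vary for p in pars.values())
    if nfree > len(data):
        raise ValueError(f"{nfree} free parameters but only {len(data)} pH points")
    warnings = []
    if np.ptp(data.po) < 1e-12:
        warnings.append("degenerate data: all Po values equal (rank-deficient fit)")
    w = None
    if weighted:
        w = np.where(data.sem > 0, data.sem, np.nan)
        w = np.where(np.isfinite(w), w, np.nanmin(w) if np.isfinite(w).any() else 1.0)

    def to_mwc(p) -> MWCParams:
        kw = {"lo": 10.0 ** p["log10_lo"].value}
        for s in ("1", "2"):
            if f"pka{s}_open" in p:
                kw[f"pka{s}_open"] = p[f"pka{s}_open"].value
                kw[f"pka{s}_closed"] = p[f"pka{s}_closed"].value
        return MWCParams(**kw)

    def resid(p):
        r = mwc_po(to_mwc(p), data.ph) - data.po
        return r / w if w is not None else r

    out = lmfit.minimize(resid, pars, method="leastsq")
    fitted = to_mwc(out.params)
    params = {"lo": fitted.lo, "log10_lo": float(out.params["log10_lo"].value)}
    stderr: dict = {}
    if "lo" in free and out.params["log10_lo"].stderr is not None:
        se = float(out.params["log10_lo"].stderr)
        stderr["log10_lo"] = se
        stderr["lo"] = fitted.lo * _LN10 * se  # delta method
    else:
        stderr["log10_lo"] = None
        stderr["lo"] = None
    for s in ("1", "2"):
        for side in ("open", "closed"):
            name = f"pka{s}_{side}"
            if getattr(fitted, name, None) is None:
                continue
            params[name] = float(getattr(fitted, name))
            if name in free:
                if side == "closed" and s in delta_param:
                    stderr[name] = _propagated_closed_stderr(out, s)
                else:
                    p = out.params[name]
                    stderr[name] = float(p.stderr) if p.stderr is not None else None
            else:
                stderr[name] = None
    active = []
    if enforce_order:
        for s in ("1", "2"):
            if s in delta_param:
                if abs(out.params[delta_param[s]].value) < 1e-6:
                    active.append(f"pka{s}_closed <= pka{s}_open")
            elif f"pka{s}_closed" in free and f"pka{s}_closed" in out.params:
                p = out.params[f"pka{s}_closed"]
                if p.max is not None and np.isfinite(p.max) and abs(p.value - p.max) < 1e-6:
                    active.append(f"pka{s}_closed <= pka{s}_open")
    fixed = sorted(set(_MWC_NAMES) - set(free) - {
        n for n in _MWC_NAMES if n != "lo" and getattr(init, n) is None
    })
    return FitResult(
        model="mwc",
        params=params,
        stderr=stderr,
        fixed=fixed,
        active_bounds=active,
        ssr=float(np.sum(np.asarray(out.residual) ** 2)),
        converged=bool(out.success),
        ndata=len(data),
        nfree=nfree,
        warnings=warnings,
    )


def _propagated_closed_stderr(out, s: str):
    """stderr of pKa_closed = pKa_open - delta from the fit covariance."""
    if out.covar is None:
        return None
    names = [n for n in out.params if out.params[n].vary]
    try:
        io = names.index(f"pka{s}_open")
        idx = names.index(f"delta{s}")
    except ValueError:
        p = out.params.get(f"delta{s}")
        return float(p.stderr) if p is not None and p.stderr is not None else None
    var = out.covar[io, io] + out.covar[idx, idx] - 2.0 * out.covar[io, idx]
    return float(np.sqrt(max(var, 0.0)))


def two_stage_mwc_fit(
    data: PoDataset, init: MWCParams, sensor: str = "1"
) -> tuple[FitResult, FitResult | None]:
    """The constrained fitting workflow for sensor-uncoupling mutants.

    Stage 1 frees Lo and the sensor's pKa_closed under the bound
    pKa_closed <= pKa_open.  If the bound binds (the sensor's
    state-dependence collapses), stage 2 pins pKa_closed = pKa_open and
    refits with Lo as the single free parameter.  Returns the stage-1
    result and the stage-2 result (None when the bound stayed inactive).
    """
    stage1 = fit_mwc(data, init, free=("lo", f"pka{sensor}_closed"))
    if not stage1.active_bounds:
        return stage1, None
    pinned = init.replace(
        **{f"pka{sensor}_closed": getattr(init, f"pka{sensor}_open")}
    )
    stage2 = fit_mwc(data, pinned, free=("lo",))
    return stage1, stage2


def hill_summary_of_mwc(
    params: MWCParams, ph_grid=None
) -> HillParams:
    """Summarize a concerted-model curve by its best-fit Hill parameters.

    Evaluates the model on ``ph_grid`` (pH 4.0-6.5 in steps of 0.05 by
    default, spanning the experimental dose-response range) and fits the
    Hill equation with Pomax, pH_half and nH all free.  Raises
    :class:`NoCrossingError` when the curve does not cross half-activation
    inside the grid (e.g. state-independent pKa values give a flat line).
    """
    if ph_grid is None:
        ph_grid = np.arange(4.0, 6.5 + 1e-9, 0.05)
    ph_grid = np.asarray(ph_grid, dtype=float)
    po = np.atleast_1d(mwc_po(params, ph_grid))
    half = po.max() / 2.0
    if po.max() <= 0 or not (po.min() < half < po.max()):
        raise NoCrossingError(
            "Po does not cross half-activation on the grid; cannot summarize"
        )
    data = PoDataset(ph=ph_grid, po=po, sem=np.zeros_like(po),
                     n=np.ones_like(po, dtype=int))
    i = int(np.argmin(np.abs(po - half)))
    init = HillParams(pomax=float(po.max()), ph_half=float(ph_grid[i]), nh=2.0)
    fit = fit_hill(data, init=init)
    return HillParams(
        pomax=fit.params["pomax"], ph_half=fit.params["ph_half"], nh=fit.params["nh"]
    )


# ---------------------------------------------------------------------------
# reference parameter sets

#: Concerted-model parameters of KcsA constructs from single-channel bilayer
#: dose-response measurements (all on the non-inactivating E71A background).
#: ``hill`` carries the published Hill-fit summaries of the same recordings
#: and ``free`` the parameters that were optimized for that construct (the
#: rest were constrained); sensor 1 is H25, sensor 2 is E118.
KCSA_GATING: dict[str, dict] = {
    "control": {
        "mwc": MWCParams(lo=2.5e-12, pka1_closed=4.8, pka1_open=7.6,
                         pka2_closed=5.0, pka2_open=6.2),
        "hill": {"ph_half": 5.3, "nh": 4.4},
        "free": ("lo",),
    },
    "L40A": {
        # outer-helix mutant: H25 state-dependence collapsed (pKa_closed
        # pinned to pKa_open) and intrinsic gating strongly increased
        "mwc": MWCParams(lo=6.2e-4, pka1_closed=7.6, pka1_open=7.6,
                         pka2_closed=5.0, pka2_open=6.2),
        "hill": {"ph_half": 5.2, "nh": 1.9},
        "free": ("lo",),
    },
    "H25R": {
        "mwc": MWCParams(lo=7e-4, pka2_closed=5.0, pka2_open=6.2),
        "hill": {"ph_half": 5.3, "nh": 1.9},
        "free": ("lo", "pka2_closed", "pka2_open"),
    },
    "E118A": {
        "mwc": MWCParams(lo=1.1e-8, pka1_closed=4.8, pka1_open=7.6),
        "hill": {"ph_half": 5.5, "nh": 4.5},
        "free": ("lo",),
    },
}
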