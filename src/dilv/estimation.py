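"""Breath-by-breath DILV parameter estimation.

The fitting problem is deliberately simple: minimize the mean squared error
between a simulated trace and the measured one over a chosen subset of free
parameters, under box bounds.  Because the model is nonlinear and
non-convex, a single local fit is not trusted; instead each breath is
fitted from many random initializations drawn uniformly from an interval
around a configured center, and the *distribution* of local optima is the
result.  A narrow distribution means the parameter is well determined; a
multimodal one flags competing solutions.  Point summaries are the
per-parameter median with its standard error of the mean over converged
starts.

The two sub-models are fitted sequentially: the respiratory frequency
``theta`` is estimated within the volume fit and then frozen for the
pressure fit (the only coupling the model asserts), unless configured
otherwise.  Parameters not being estimated are frozen at configured values
and returned unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DegenerateFitError,
    DILVError,
    EstimationFailureError,
    InvalidParameterError,
)
from .model import (
    PRESSURE_PARAM_NAMES,
    VOLUME_PARAM_NAMES,
    BreathRecord,
    PressureParams,
    VolumeParams,
    simulate_pressure,
    simulate_volume,
)
from .single_compartment import fit_sc

__all__ = [
    "FitSpec",
    "FitDistribution",
    "DEFAULT_BOUNDS",
    "DEFAULT_FREE_VOLUME",
    "DEFAULT_FREE_PRESSURE",
    "objective",
    "fit_breath",
    "compare_models",
    "summarize",
    "start_table",
]

log = logging.getLogger("dilv.estimation")

#: Sentinel objective value returned when a simulation inside the fit fails;
#: keeps the multistart loop alive instead of aborting it.
PENALTY_MSE = 1e12

#: Physically-motivated default box bounds per parameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "theta": (0.05, 3.0),
    "a1": (0.5, 500.0),
    "b1": (-0.95, 0.95),
    "phi1": (-np.pi, np.pi),
    "beta1": (1.0, 5000.0),
    "beta2": (1.0, 5000.0),
    "Av": (1e-3, 5000.0),
    "a2": (0.5, 500.0),
    "b2": (-0.95, 0.95),
    "phi2": (-np.pi, np.pi),
    "a3": (0.5, 500.0),
    "b3": (-2.0, 2.0),
    "phi3": (-np.pi, np.pi),
    "beta3": (1.0, 5000.0),
    "beta4": (1.0, 5000.0),
    "beta5": (1.0, 10.0),
    "beta6": (1.0, 10.0),
    "Ap1": (1e-3, 200.0),
    "Ap2": (0.0, 100.0),
    "Ap3": (0.0, 200.0),
    "Ap4": (-5.0, 60.0),
}

#: Default free sets: amplitudes, gradients, duty and phase. Drive sharpness
#: and the optional feature groups (low-volume knee, plateau peaks) stay
#: frozen unless explicitly requested, mirroring the practice of fixing
#: low-sensitivity parameters to keep the fit identifiable.
DEFAULT_FREE_VOLUME = ("b1", "phi1", "beta1", "beta2", "Av")
DEFAULT_FREE_PRESSURE = ("b2", "phi2", "beta3", "beta4", "Ap1", "Ap4")

_ALL_NAMES = ("theta",) + VOLUME_PARAM_NAMES + PRESSURE_PARAM_NAMES


@dataclass
class FitSpec:
    """Configuration of a multi-start breath fit.

    ``free_params`` are the names being estimated (``theta`` is governed by
    ``theta_mode`` instead); every other model parameter must have a value
    in ``fixed_params``.  Initializations are drawn uniformly from
    ``init_center ± init_halfwidth`` (clipped to ``bounds``), one draw per
    start, reproducibly from ``seed``.
    """

    free_params: tuple[str, ...]
    fixed_params: dict[str, float]
    init_center: dict[str, float]
    init_halfwidth: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 100
    seed: int = 0
    theta_mode: str = "from_volume"  # fixed | from_volume | joint
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_iter: int = 500
    mask_convention: str = "phase"

    def __post_init__(self) -> None:
        self.free_params = tuple(self.free_params)
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        self.bounds = merged
        self.validate()

    def validate(self) -> None:
        if self.theta_mode not in ("fixed", "from_volume", "joint"):
            raise InvalidParameterError(f"unknown theta_mode {self.theta_mode!r}")
        if self.n_starts < 1:
            raise InvalidParameterError("n_starts must be positive")
        for name in self.free_params:
            if name not in _ALL_NAMES:
                raise InvalidParameterError(f"unknown free parameter {name!r}")
            if name == "theta":
                raise InvalidParameterError(
                    "theta is governed by theta_mode, not free_params"
                )
            if name in self.fixed_params:
                raise InvalidParameterError(f"{name!r} is both free and frozen")
        theta_names = self.free_params
        if self.theta_mode != "fixed":
            theta_names = theta_names + ("theta",)
        elif "theta" not in self.fixed_params:
            raise InvalidParameterError("theta_mode='fixed' needs fixed_params['theta']")
        for name in theta_names:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InvalidParameterError(f"bounds for {name!r} must be finite, lo < hi")
            if name not in self.init_center or name not in self.init_halfwidth:
                raise InvalidParameterError(f"missing init interval for {name!r}")
            c, h = self.init_center[name], self.init_halfwidth[name]
            if h < 0 or not (lo <= c <= hi):
                raise InvalidParameterError(
                    f"init center {c} for {name!r} outside bounds [{lo}, {hi}]"
                )

    @classmethod
    def around(
        cls,
        center: dict[str, float],
        free_params: tuple[str, ...] = DEFAULT_FREE_VOLUME + DEFAULT_FREE_PRESSURE,
        rel_halfwidth: float = 0.3,
        **kwargs,
    ) -> "FitSpec":
        """Build a spec with init intervals ``value ± rel_halfwidth*|value|``.

        ``center`` must map every model parameter (including ``theta``) to a
        value; parameters not in ``free_params`` are frozen at it.  Centers
        are clipped into the default bounds.
        """
        bounds = dict(DEFAULT_BOUNDS)
        bounds.update(kwargs.pop("bounds", {}))
        init_center, init_halfwidth, fixed = {}, {}, {}
        for name, value in center.items():
            if name not in _ALL_NAMES:
                raise InvalidParameterError(f"unknown parameter {name!r}")
            lo, hi = bounds[name]
            c = float(np.clip(value, lo, hi))
            if name in free_params or name == "theta":
                init_center[name] = c
                init_halfwidth[name] = rel_halfwidth * abs(c)
            if name not in free_params and name != "theta":
                fixed[name] = float(value)
            elif name == "theta" and kwargs.get("theta_mode") == "fixed":
                fixed[name] = float(value)
        return cls(
            free_params=tuple(free_params),
            fixed_params=fixed,
            init_center=init_center,
            init_halfwidth=init_halfwidth,
            bounds=bounds,
            **kwargs,
        )


@dataclass
class FitDistribution:
    """Multi-start solution distribution for one trace of one breath."""

    which: str  # "volume" | "pressure"
    names: tuple[str, ...]  # free parameter names, in vector order
    params: np.ndarray  # (n_starts, n_free) local optima
    mse: np.ndarray  # (n_starts,)
    converged: np.ndarray  # (n_starts,) bool
    fixed: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    mse_at_median: float = np.nan

    @property
    def n_converged(self) -> int:
        return int(np.sum(self.converged))

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.mse))

    @property
    def mse_best(self) -> float:
        return float(self.mse[self.best_index])

    @property
    def best_params(self) -> dict[str, float]:
        out = dict(self.fixed)
        out.update(zip(self.names, self.params[self.best_index]))
        return out

    @property
    def median_params(self) -> dict[str, float]:
        if self.n_converged == 0:
            raise EstimationFailureError("no converged starts")
        sel = self.params[self.converged]
        out = dict(self.fixed)
        out.update(zip(self.names, np.median(sel, axis=0)))
        return out

    @property
    def sem_params(self) -> dict[str, float]:
        sel = self.params[self.converged]
        if sel.shape[0] < 2:
            sem = np.full(len(self.names), np.nan)
        else:
            sem = sel.std(axis=0, ddof=1) / np.sqrt(sel.shape[0])
        out = {name: 0.0 for name in self.fixed}
        out.update(zip(self.names, sem))
        return out


def _full_params(values: dict[str, float], which: str):
    theta = values["theta"]
    if which == "volume":
        kw = {k: values[k] for k in VOLUME_PARAM_NAMES}
        return VolumeParams(theta=theta, **kw)
    kw = {k: values[k] for k in PRESSURE_PARAM_NAMES}
    return PressureParams(theta=theta, **kw)


def objective(
    params: dict[str, float],
    breath: BreathRecord,
    which: str,
    mask_convention: str = "phase",
) -> float:
    """Mean squared error between the simulated and the measured trace.

    ``params`` maps every parameter of the chosen sub-model (plus
    ``theta``) to a value.  Simulation failures (degenerate normalization,
    invalid parameters) return the large penalty sentinel instead of
    raising, so a multistart optimizer simply moves on.
    """
    data = breath.volume.values if which == "volume" else breath.pressure.values
    try:
        model = _full_params(params, which)
        sim = (
            simulate_volume(model, breath.grid, mask_convention)
            if which == "volume"
            else simulate_pressure(model, breath.grid, mask_convention)
        )
    except DILVError as exc:
        log.debug("simulation failed in objective (%s): %s", which, exc)
        return PENALTY_MSE
    return float(np.mean((sim - data) ** 2))


def _make_residual_fn(breath, which, names, fixed, mask_convention):
    data = breath.volume.values if which == "volume" else breath.pressure.values
    # failed simulations yield exactly the penalty MSE, so such starts are
    # never mistaken for converged fits
    penalty_residual = float(np.sqrt(PENALTY_MSE))

    def residuals(x: np.ndarray) -> np.ndarray:
        values = dict(fixed)
        values.update(zip(names, x))
        try:
            model = _full_params(values, which)
            sim = (
                simulate_volume(model, breath.grid, mask_convention)
                if which == "volume"
                else simulate_pressure(model, breath.grid, mask_convention)
            )
        except DILVError as exc:
            log.debug("simulation failed in residuals (%s): %s", which, exc)
            return np.full(data.shape, penalty_residual)
        return sim - data

    return residuals


def _multistart(breath, which, names, fixed, spec: FitSpec, stage: int):
    """Run the multi-start bounded local optimization for one trace."""
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    center = np.array([spec.init_center[n] for n in names])
    halfwidth = np.array([spec.init_halfwidth[n] for n in names])
    fn = _make_residual_fn(breath, which, names, fixed, spec.mask_convention)
    x_scale = np.maximum(np.abs(center), 1e-3)

    n_free = len(names)
    params = np.empty((spec.n_starts, n_free))
    mse = np.empty(spec.n_starts)
    converged = np.zeros(spec.n_starts, dtype=bool)
    for k in range(spec.n_starts):
        # per-start stream: prefixes are identical across different n_starts
        rng = np.random.default_rng([spec.seed, stage, k])
        x0 = np.clip(center + halfwidth * rng.uniform(-1.0, 1.0, n_free), lo, hi)
        try:
            res = least_squares(
                fn,
                x0,
                bounds=(lo, hi),
                method="trf",
                x_scale=x_scale,
                ftol=spec.ftol,
                xtol=spec.xtol,
                max_nfev=spec.max_iter * (n_free + 1),
            )
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("start %d failed (%s): %s", k, which, exc)
            params[k] = x0
            mse[k] = PENALTY_MSE
            continue
        params[k] = res.x
        mse[k] = float(np.mean(res.fun**2))
        converged[k] = bool(res.status > 0) and mse[k] < PENALTY_MSE
    if not converged.any():
        raise EstimationFailureError(
            f"all {spec.n_starts} starts diverged for the {which} fit; "
            f"best penalty-free MSE {np.min(mse):.3e}"
        )
    return params, mse, converged


def _distribution(breath, which, names, fixed, spec, stage) -> FitDistribution:
    params, mse, converged = _multistart(breath, which, names, fixed, spec, stage)
    dist = FitDistribution(
        which=which,
        names=tuple(names),
        params=params,
        mse=mse,
        converged=converged,
        fixed=dict(fixed),
        bounds={n: spec.bounds[n] for n in names},
    )
    dist.mse_at_median = objective(
        dist.median_params, breath, which, spec.mask_convention
    )
    return dist


def fit_breath(breath: BreathRecord, spec: FitSpec) -> tuple[FitDistribution, FitDistribution]:
    """Fit the volume and pressure models to one breath.

    Returns the multi-start solution distributions ``(volume, pressure)``.
    With the default ``theta_mode='from_volume'`` the respiratory frequency
    is estimated in the volume fit and frozen at its best value for the
    pressure fit; ``'fixed'`` freezes it everywhere at the configured
    value; ``'joint'`` optimizes both traces simultaneously over the union
    of free parameters (stacked residuals).  Identical inputs and seed give
    identical outputs.
    """
    free_v = [n for n in spec.free_params if n in VOLUME_PARAM_NAMES]
    free_p = [n for n in spec.free_params if n in PRESSURE_PARAM_NAMES]
    fixed_all = dict(spec.fixed_params)

    if spec.theta_mode == "joint":
        names = ["theta"] + free_v + free_p
        data_scale = {
            "volume": max(float(np.ptp(breath.volume.values)), 1e-9),
            "pressure": max(float(np.ptp(breath.pressure.values)), 1e-9),
        }

        fn_v = _make_residual_fn(breath, "volume", names, fixed_all, spec.mask_convention)
        fn_p = _make_residual_fn(breath, "pressure", names, fixed_all, spec.mask_convention)

        def fn(x):
            # equalize trace scales so neither signal dominates the stack
            return np.concatenate(
                [fn_v(x) / data_scale["volume"], fn_p(x) / data_scale["pressure"]]
            )

        lo = np.array([spec.bounds[n][0] for n in names])
        hi = np.array([spec.bounds[n][1] for n in names])
        center = np.array([spec.init_center[n] for n in names])
        halfwidth = np.array([spec.init_halfwidth[n] for n in names])
        params = np.empty((spec.n_starts, len(names)))
        mse_v = np.empty(spec.n_starts)
        mse_p = np.empty(spec.n_starts)
        converged = np.zeros(spec.n_starts, dtype=bool)
        for k in range(spec.n_starts):
            rng = np.random.default_rng([spec.seed, 0, k])
            x0 = np.clip(center + halfwidth * rng.uniform(-1, 1, len(names)), lo, hi)
            res = least_squares(
                fn, x0, bounds=(lo, hi), method="trf",
                x_scale=np.maximum(np.abs(center), 1e-3),
                ftol=spec.ftol, xtol=spec.xtol,
                max_nfev=spec.max_iter * (len(names) + 1),
            )
            params[k] = res.x
            values = dict(fixed_all)
            values.update(zip(names, res.x))
            mse_v[k] = objective(values, breath, "volume", spec.mask_convention)
            mse_p[k] = objective(values, breath, "pressure", spec.mask_convention)
            converged[k] = bool(res.status > 0) and max(mse_v[k], mse_p[k]) < PENALTY_MSE
        if not converged.any():
            raise EstimationFailureError("all joint starts diverged")
        idx_v = [names.index(n) for n in ["theta"] + free_v]
        idx_p = [names.index(n) for n in ["theta"] + free_p]
        dists = []
        for which, idx, mse in (("volume", idx_v, mse_v), ("pressure", idx_p, mse_p)):
            sub_names = tuple(names[i] for i in idx)
            fixed = {
                n: fixed_all[n] for n in fixed_all
                if n in (("theta",) + (VOLUME_PARAM_NAMES if which == "volume" else PRESSURE_PARAM_NAMES))
            }
            d = FitDistribution(
                which=which, names=sub_names, params=params[:, idx], mse=mse,
                converged=converged, fixed=fixed,
                bounds={n: spec.bounds[n] for n in sub_names},
            )
            d.mse_at_median = objective(d.median_params, breath, which, spec.mask_convention)
            dists.append(d)
        return dists[0], dists[1]

    if spec.theta_mode == "from_volume":
        names_v = ["theta"] + free_v
        fixed_v = {k: v for k, v in fixed_all.items() if k in VOLUME_PARAM_NAMES}
    else:  # fixed
        names_v = list(free_v)
        fixed_v = {
            k: v for k, v in fixed_all.items()
            if k in VOLUME_PARAM_NAMES or k == "theta"
        }
    dist_v = _distribution(breath, "volume", names_v, fixed_v, spec, stage=0)

    theta = (
        dist_v.best_params["theta"]
        if spec.theta_mode == "from_volume"
        else fixed_all["theta"]
    )
    fixed_p = {k: v for k, v in fixed_all.items() if k in PRESSURE_PARAM_NAMES}
    fixed_p["theta"] = theta
    dist_p = _distribution(breath, "pressure", free_p, fixed_p, spec, stage=1)
    return dist_v, dist_p


def compare_models(
    breath: BreathRecord, spec: FitSpec, return_details: bool = False
):
    """Ratio of DILV to single-compartment mean squared error on one breath.

    Both MSEs are computed on the pressure trace — the signal the
    single-compartment model predicts — so the ratio is comparable across
    recording scales.  Values below one mean the DILV model represents the
    breath better; the volume-fit MSE (which has no single-compartment
    counterpart) is reported in the details.
    """
    dist_v, dist_p = fit_breath(breath, spec)
    dilv_mse = dist_p.mse_best
    sc, sc_mse = fit_sc(breath)
    if not sc_mse > 0:
        raise DegenerateFitError(
            "single-compartment MSE is zero; the ratio is undefined"
        )
    ratio = dilv_mse / sc_mse
    if return_details:
        return ratio, {
            "mse_dilv_volume": dist_v.mse_best,
            "mse_dilv_pressure": dist_p.mse_best,
            "mse_sc": sc_mse,
            "sc_params": sc,
            "dist_volume": dist_v,
            "dist_pressure": dist_p,
        }
    return ratio


def summarize(dist: FitDistribution, gap_fraction: float = 0.1) -> pd.DataFrame:
    """Per-parameter table: median ± SEM over converged starts, with flags.

    A parameter is flagged multimodal when its sorted converged solutions
    contain a gap larger than ``gap_fraction`` of the bound width —
    evidence of more than one cluster of local optima.  The table's
    ``attrs`` carry ``mse_best``, ``mse_at_median`` and ``n_converged``.
    """
    if dist.n_converged < 2:
        raise EstimationFailureError(
            f"need >= 2 converged starts to summarize, got {dist.n_converged}"
        )
    med = dist.median_params
    sem = dist.sem_params
    sel = dist.params[dist.converged]
    rows = []
    for j, name in enumerate(dist.names):
        lo, hi = dist.bounds[name]
        sols = np.sort(sel[:, j])
        gaps = np.diff(sols)
        multimodal = bool(gaps.size and gaps.max() > gap_fraction * (hi - lo))
        rows.append(
            dict(name=name, median=med[name], sem=sem[name],
                 lo_bound=lo, hi_bound=hi, frozen=False, multimodal=multimodal)
        )
    for name, value in dist.fixed.items():
        rows.append(
            dict(name=name, median=value, sem=0.0, lo_bound=np.nan,
                 hi_bound=np.nan, frozen=True, multimodal=False)
        )
    df = pd.DataFrame(rows)
    df.attrs.update(
        mse_best=dist.mse_best,
        mse_at_median=dist.mse_at_median,
        n_converged=dist.n_converged,
        which=dist.which,
    )
    return df


def start_table(dist: FitDistribution) -> pd.DataFrame:
    """Per-start table: start id, solution vector, MSE, convergence flag."""
    df = pd.DataFrame(dist.params, columns=list(dist.names))
    df.insert(0, "start_id", np.arange(len(df)))
    df["mse"] = dist.mse
    df["converged"] = dist.converged
    return df
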