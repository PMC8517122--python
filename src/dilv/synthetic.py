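"""Synthetic breath and cohort generation with known ground truth.

The generator emulates the study conditions under which the DILV model is
exercised: pressure-controlled mouse breaths in healthy and lavage-injured
lungs, a ventilated patient with dyssynchrony-like plateau peaks, and
breaths generated by the linear single-compartment model itself.  Each regime is a complete named
parameter set; per-breath variability is modelled as fractional Gaussian
jitter on the physiological parameters and measurement noise as additive
i.i.d. Gaussian noise scaled to a fraction of each trace's amplitude.

Generated breaths carry their generating parameters in ``meta['truth']``
and are bit-reproducible from ``(seed, index)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .model import (
    BreathRecord,
    PressureParams,
    VolumeParams,
    simulate_breath,
    simulate_volume,
)
from .single_compartment import SCParams, predict_pressure
from .waveforms import SampleGrid, Signal

__all__ = [
    "ScenarioSpec",
    "Cohort",
    "REGIMES",
    "scenario",
    "make_breath",
    "make_cohort",
]

# ---------------------------------------------------------------------------
# Reference parameter library.
#
# The demo sets are the canonical simulation examples used throughout the
# package documentation; the mouse and human sets are representative
# estimated breaths for a healthy and a lavage-injured mouse lung under PCV
# and a ventilated ICU patient with dyssynchronous plateau peaks.  Two
# conventions applied to the mouse sets (see docs/methods.md): the breath
# alignment phase is 0.3 rad for both regimes (alignment is a segmentation
# artifact, not lung state) and PEEP is the ventilation setting of
# 3 cmH2O.
# ---------------------------------------------------------------------------

DEMO_VOLUME = VolumeParams(
    theta=0.3, a1=200.0, b1=0.7, phi1=0.0, beta1=30.0, beta2=10.0, Av=1.0
)
DEMO_PRESSURE = PressureParams(
    theta=0.3, a2=200.0, b2=0.7, phi2=0.0, a3=10.0, b3=0.9, phi3=-0.6,
    beta3=5.0, beta4=5.0, beta5=1.001, beta6=1.1111,
    Ap1=1.0, Ap2=0.5, Ap3=0.5, Ap4=0.0,
)

_HEALTHY_V = VolumeParams(
    theta=0.66, a1=9.67, b1=0.59, phi1=0.3, beta1=112.97, beta2=28.35, Av=1.03
)
_HEALTHY_P = PressureParams(
    theta=0.66, a2=52.06, b2=0.80, phi2=0.3, a3=2.55, b3=1.00, phi3=0.0,
    beta3=50.00, beta4=18.54, Ap1=35.53, Ap2=0.0, Ap3=14.00, Ap4=3.0,
)
_INJURED_V = VolumeParams(
    theta=0.66, a1=15.41, b1=0.53, phi1=0.3, beta1=458.95, beta2=10.60, Av=0.70
)
_INJURED_P = PressureParams(
    theta=0.66, a2=32.11, b2=0.66, phi2=0.3, a3=5.11, b3=0.53, phi3=0.0,
    beta3=100.84, beta4=11.93, Ap1=35.02, Ap2=0.0, Ap3=9.60, Ap4=3.0,
)
_HUMAN_V = VolumeParams(
    theta=0.34, a1=7.51, b1=0.66, phi1=0.42, beta1=10.96, beta2=12.42, Av=402.61
)
_HUMAN_P = PressureParams(
    theta=0.34, a2=27.39, b2=0.67, phi2=0.35, a3=7.71, b3=0.91, phi3=0.15,
    beta3=7.25, beta4=1.95, beta5=1.0014, beta6=1.1262,
    Ap1=16.58, Ap2=3.80, Ap3=3.90, Ap4=19.98,
)
# Single-compartment generator: compliance close to the healthy mouse value
# (C = 1/E ~ 0.029 ml/cmH2O), a typical mouse airway resistance and PEEP 3.
_SC = SCParams(E=34.5, R=0.8, P0=3.0)

#: regime -> (VolumeParams, PressureParams, SCParams | None, default dt)
REGIMES: dict[str, tuple[VolumeParams, PressureParams, SCParams | None, float]] = {
    "demo": (DEMO_VOLUME, DEMO_PRESSURE, None, 0.005),
    "healthy": (_HEALTHY_V, _HEALTHY_P, None, 0.002),
    "injured": (_INJURED_V, _INJURED_P, None, 0.002),
    # dyssynchrony-like: the ventilated-patient parameter set, whose plateau
    # peaks (Ap2 > 0, beta5 near 1) the single-compartment model cannot fit
    "vd": (_HUMAN_V, _HUMAN_P, None, 0.005),
    "human": (_HUMAN_V, _HUMAN_P, None, 0.005),
    "sc": (_HEALTHY_V, _HEALTHY_P, _SC, 0.002),
}

#: Parameters receiving breath-to-breath jitter (physiology, not settings).
JITTERED = ("beta1", "beta2", "Av", "beta3", "beta4", "Ap1", "Ap3")


@dataclass
class ScenarioSpec:
    """A named generating scenario with noise, jitter and size."""

    regime: str
    vp: VolumeParams
    pp: PressureParams
    sc: SCParams | None = None
    noise_sd: float = 0.01  # fraction of each trace's amplitude
    n_breaths: int = 1
    seed: int = 0
    jitter: float = 0.0  # fractional SD of per-breath parameter perturbation
    dt: float = 0.005
    burn_in_periods: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not 0 <= self.jitter <= 0.5:
            raise InvalidParameterError("jitter fraction must lie in [0, 0.5]")
        if self.n_breaths < 1:
            raise InvalidParameterError("n_breaths must be >= 1")

    @property
    def grid(self) -> SampleGrid:
        n = int(round(1.0 / (self.vp.theta * self.dt)))
        return SampleGrid(dt=self.dt, n=n, burn_in_periods=self.burn_in_periods)


def scenario(
    regime: str,
    noise_sd: float = 0.01,
    n_breaths: int = 1,
    seed: int = 0,
    jitter: float = 0.0,
    dt: float | None = None,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from the named regime library."""
    if regime not in REGIMES:
        raise InvalidParameterError(
            f"unknown regime {regime!r}; choose from {sorted(REGIMES)}"
        )
    vp, pp, sc, default_dt = REGIMES[regime]
    return ScenarioSpec(
        regime=regime, vp=vp, pp=pp, sc=sc, noise_sd=noise_sd,
        n_breaths=n_breaths, seed=seed, jitter=jitter,
        dt=default_dt if dt is None else dt,
    )


def _jittered(params, rng: np.random.Generator, jitter: float):
    if jitter == 0:
        return params
    out = {}
    for name, value in params.as_dict().items():
        if name in JITTERED:
            value = value * (1.0 + jitter * rng.standard_normal())
            if name.startswith("beta"):
                value = max(value, 1.0)
            elif name in ("Av", "Ap1", "Ap3"):
                value = max(value, 1e-6)
        out[name] = value
    return type(params)(**out)


def make_breath(spec: ScenarioSpec, index: int = 0) -> tuple[BreathRecord, dict]:
    """One noisy breath plus its generating ground truth.

    Reproducible per ``(spec.seed, index)``: the jitter draw and the noise
    draw come from a generator seeded with both values.
    """
    rng = np.random.default_rng([spec.seed, index])
    vp = _jittered(spec.vp, rng, spec.jitter)
    pp = _jittered(spec.pp, rng, spec.jitter)
    grid = spec.grid

    if spec.sc is not None:
        v = simulate_volume(vp, grid)
        flow = np.gradient(v, grid.dt)
        pr = predict_pressure(spec.sc, v, flow)
    else:
        breath = simulate_breath(vp, pp, grid)
        v = breath.volume.values
        pr = breath.pressure.values

    truth: dict = {"regime": spec.regime, "index": index, "theta": vp.theta}
    truth.update({k: val for k, val in vp.as_dict().items() if k != "theta"})
    if spec.sc is not None:
        truth.update({"E": spec.sc.E, "R": spec.sc.R, "P0": spec.sc.P0})
    else:
        truth.update({k: val for k, val in pp.as_dict().items() if k != "theta"})

    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd * np.ptp(v), v.shape)
        pr = pr + rng.normal(0.0, spec.noise_sd * np.ptp(pr), pr.shape)
    flow = np.gradient(v, grid.dt)

    record = BreathRecord(
        grid=grid,
        pressure=Signal(pr, "cmH2O"),
        volume=Signal(v, "ml"),
        flow=Signal(flow, "ml/s"),
        meta={"regime": spec.regime, "seed": spec.seed, "index": index,
              "noise_sd": spec.noise_sd, "truth": truth},
    )
    return record, truth


@dataclass
class Cohort:
    """A generated breath sequence: per-breath records, truths, and the
    concatenated continuous record (for segmentation and batch fitting)."""

    breaths: list[BreathRecord]
    truths: pd.DataFrame
    continuous: BreathRecord


def make_cohort(spec: ScenarioSpec) -> Cohort:
    """Generate ``spec.n_breaths`` jittered breaths and their truth table."""
    breaths, rows = [], []
    for i in range(spec.n_breaths):
        record, truth = make_breath(spec, i)
        breaths.append(record)
        rows.append({"breath_id": i, **truth, "seed": spec.seed})
    truths = pd.DataFrame(rows)

    n = spec.grid.n
    cont_grid = SampleGrid(
        dt=spec.dt, n=n * spec.n_breaths, burn_in_periods=spec.burn_in_periods
    )
    v = np.concatenate([b.volume.values for b in breaths])
    pr = np.concatenate([b.pressure.values for b in breaths])
    flow = np.gradient(v, spec.dt)
    continuous = BreathRecord(
        grid=cont_grid,
        pressure=Signal(pr, "cmH2O"),
        volume=Signal(v, "ml"),
        flow=Signal(flow, "ml/s"),
        meta={"regime": spec.regime, "seed": spec.seed,
              "n_breaths": spec.n_breaths, "noise_sd": spec.noise_sd},
    )
    return Cohort(breaths=breaths, truths=truths, continuous=continuous)
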