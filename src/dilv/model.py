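"""The damage-informed lung-ventilator (DILV) waveform model.

The model mathematizes one breath of ventilator data as two independent,
feature-anchored signals that share only the respiratory frequency
``theta``:

* the **volume model** ``V = Av * (fv1 + fv2)`` — a rectangular drive
  smoothed separately on its rising (inspiration, ``beta1``) and falling
  (expiration, ``beta2``) phases, scaled to tidal amplitude ``Av`` (ml);
* the **pressure model** ``P = fp13 + fp24 + fp33 + Ap4`` — the same kind
  of rise/fall skeleton with amplitude ``Ap1`` (the plateau pressure above
  PEEP), plus two optional deformations: decaying peaks at the start and
  end of the plateau (``fp24``, amplitude ``Ap2``, shapes ``beta5``/
  ``beta6``; dyssynchrony-like features) and a low-volume knee in the
  inspiratory rise (``fp33``, amplitude ``Ap3``, pulse shape ``a3``/
  ``b3``/``phi3``).  ``Ap4`` is the baseline pressure (PEEP).

There is deliberately no mechanical coupling between the two signals beyond
the shared period; the model-derived lung compliance is the amplitude ratio
``Cd = Av / Ap1`` (ml/cmH2O).

Every recursive term is simulated with extra warm-up (burn-in) periods,
initialized at zero and discarded, so the returned traces are in periodic
steady state and independent of the arbitrary initial condition.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from .errors import (
    CouplingViolationError,
    DegenerateNormalizationError,
    InvalidParameterError,
)
from .waveforms import (
    SampleGrid,
    Signal,
    first_order_track,
    leaky_diff,
    mask_normalize,
    shifted_sine,
    squash,
)

__all__ = [
    "VolumeParams",
    "PressureParams",
    "BreathRecord",
    "ComplianceReport",
    "VOLUME_PARAM_NAMES",
    "PRESSURE_PARAM_NAMES",
    "simulate_volume",
    "simulate_pressure",
    "simulate_breath",
    "dilv_compliance",
]

#: Hard floor / soft target for time resolution of one breath.
MIN_SAMPLES_PER_PERIOD = 50
RECOMMENDED_SAMPLES_PER_PERIOD = 200


@dataclass
class VolumeParams:
    """Parameters of the volume model: shared ``theta`` plus six shape values.

    theta : respiratory frequency, breaths/s.
    a1 : sharpness of the rectangular drive (larger = squarer).
    b1 : duty offset; larger values shorten inspiration (|b1| < 1).
    phi1 : phase of the breath start within the cycle.
    beta1 : inspiratory smoothing >= 1 (larger = slower rise).
    beta2 : expiratory smoothing >= 1 (larger = slower fall).
    Av : tidal volume amplitude (ml).
    """

    theta: float
    a1: float
    b1: float
    phi1: float
    beta1: float
    beta2: float
    Av: float

    def validate(self) -> None:
        if not self.theta > 0:
            raise InvalidParameterError(f"theta must be > 0, got {self.theta}")
        if not self.a1 > 0:
            raise InvalidParameterError(f"a1 must be > 0, got {self.a1}")
        if not abs(self.b1) < 1:
            raise InvalidParameterError(
                f"|b1| must be < 1 (else the drive saturates), got {self.b1}"
            )
        for name in ("beta1", "beta2"):
            if not getattr(self, name) >= 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if not np.isfinite(self.Av):
            raise InvalidParameterError("Av must be finite")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PressureParams:
    """Parameters of the pressure model: shared ``theta`` plus fourteen values.

    The main drive (``a2``, ``b2``, ``phi2``) and rise/fall smoothings
    (``beta3``, ``beta4``) shape the plateau skeleton of amplitude ``Ap1``;
    ``beta5``/``beta6``/``Ap2`` shape the optional plateau peaks and
    ``a3``/``b3``/``phi3``/``Ap3`` the optional low-volume knee; ``Ap4`` is
    PEEP.  Setting ``Ap2 = 0`` or ``Ap3 = 0`` removes the respective
    feature exactly.
    """

    theta: float
    a2: float
    b2: float
    phi2: float
    beta3: float
    beta4: float
    Ap1: float
    Ap4: float = 0.0
    a3: float = 10.0
    b3: float = 0.9
    phi3: float = 0.0
    Ap3: float = 0.0
    beta5: float = 1.001
    beta6: float = 1.1111
    Ap2: float = 0.0

    def validate(self) -> None:
        if not self.theta > 0:
            raise InvalidParameterError(f"theta must be > 0, got {self.theta}")
        for name in ("a2", "a3"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not abs(self.b2) < 1:
            raise InvalidParameterError(
                f"|b2| must be < 1 (else the drive saturates), got {self.b2}"
            )
        for name in ("beta3", "beta4", "beta5", "beta6"):
            if not getattr(self, name) >= 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if self.Ap2 < 0 or self.Ap3 < 0:
            raise InvalidParameterError("Ap2 and Ap3 must be nonnegative")
        for name in ("Ap1", "Ap2", "Ap3", "Ap4", "b3", "phi2", "phi3"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def as_dict(self) -> dict:
        return asdict(self)


#: Registry of parameter names, beyond the shared respiratory frequency.
VOLUME_PARAM_NAMES = tuple(
    f.name for f in fields(VolumeParams) if f.name != "theta"
)
PRESSURE_PARAM_NAMES = tuple(
    f.name for f in fields(PressureParams) if f.name != "theta"
)


@dataclass
class BreathRecord:
    """One breath (or a continuous multi-breath record) of sampled traces."""

    grid: SampleGrid
    pressure: Signal
    volume: Signal
    flow: Signal | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pressure", "volume", "flow"):
            sig = getattr(self, name)
            if sig is None:
                continue
            if not isinstance(sig, Signal):
                sig = Signal(np.asarray(sig, dtype=float))
                setattr(self, name, sig)
            if len(sig) != self.grid.n:
                raise InvalidParameterError(
                    f"{name} trace length {len(sig)} does not match grid n={self.grid.n}"
                )

    def flow_values(self) -> np.ndarray:
        """Flow trace (ml/s); derived from volume by central differences when absent."""
        if self.flow is not None:
            return self.flow.values
        return np.gradient(self.volume.values, self.grid.dt)


@dataclass(frozen=True)
class ComplianceReport:
    """Model-derived lung compliance ``Cd = Av / Ap1`` (ml/cmH2O)."""

    Cd: float
    Av: float
    Ap1: float


def _sim_window(grid: SampleGrid, theta: float) -> tuple[SampleGrid, int, int]:
    """Extended grid for burn-in simulation.

    Returns ``(ext_grid, window_start, out_start)`` where the extended grid
    prepends ``burn_in_periods`` warm-up periods (plus enough samples that
    the normalization window covers at least one full period), samples from
    ``window_start`` on form the normalization window, and samples from
    ``out_start`` on map one-to-one onto the caller's grid.
    """
    n_period = max(1, int(round(1.0 / (theta * grid.dt))))
    if n_period < MIN_SAMPLES_PER_PERIOD:
        raise InvalidParameterError(
            f"only {n_period} samples per period at dt={grid.dt}, theta={theta}; "
            f"need at least {MIN_SAMPLES_PER_PERIOD}"
        )
    if n_period < RECOMMENDED_SAMPLES_PER_PERIOD:
        warnings.warn(
            f"{n_period} samples per period is below the recommended "
            f"{RECOMMENDED_SAMPLES_PER_PERIOD}; consider a smaller dt",
            stacklevel=3,
        )
    n_window = max(grid.n, n_period)
    n_pre = grid.burn_in_periods * n_period + (n_window - grid.n)
    n_total = n_pre + grid.n
    ext = SampleGrid(
        dt=grid.dt,
        n=n_total,
        t_start=grid.t_start - n_pre * grid.dt,
        burn_in_periods=0,
    )
    return ext, n_total - n_window, n_total - grid.n


def _norm(term: str, x: np.ndarray, mask: np.ndarray, window_start: int) -> np.ndarray:
    try:
        return mask_normalize(x, mask, window_start=window_start)
    except DegenerateNormalizationError as exc:
        raise DegenerateNormalizationError(term, exc.maximum) from None


def _norm_then_mask(
    term: str, x: np.ndarray, mask: np.ndarray, window_start: int
) -> np.ndarray:
    """``(x / max(x)) * mask`` with the max over the post-burn-in window.

    Used for the rise/fall tracking terms, whose normalization denominator
    is the raw recursion vector.  Because the rising and falling terms are
    each close to their maximum where the drive switches phase, the gated
    sum behaves as a convex combination there and the composed waveform
    peaks at its amplitude parameter instead of overshooting.
    """
    peak = float(np.max(x[window_start:]))
    if not peak > 1e-12:
        raise DegenerateNormalizationError(term, peak)
    return (x / peak) * mask


def _expiration_mask(fb: np.ndarray, mask_convention: str) -> np.ndarray:
    """Mask gating the expiratory (falling) smoothing term.

    ``"phase"`` (default) gates it to the expiration phase ``1 - fb`` so the
    falling-gradient parameter acts on expiration; ``"drive"`` applies the
    inspiration drive ``fb`` to every term, an alternative convention kept
    for comparison.
    """
    if mask_convention == "phase":
        return 1.0 - fb
    if mask_convention == "drive":
        return fb
    raise InvalidParameterError(
        f"mask_convention must be 'phase' or 'drive', got {mask_convention!r}"
    )


def simulate_volume(
    p: VolumeParams,
    grid: SampleGrid,
    mask_convention: str = "phase",
    return_components: bool = False,
):
    """Simulate the volume trace ``V = Av * (fv1 + fv2)`` on ``grid``.

    The trace is periodic with period ``1/theta`` and its post-burn-in
    maximum equals ``Av`` up to the mask overlap at phase transitions.
    With ``return_components=True`` also returns the named intermediate
    terms (post-burn-in window of the caller's grid).
    """
    p.validate()
    ext, w0, o0 = _sim_window(grid, p.theta)
    fs1 = shifted_sine(p.theta, p.phi1, p.b1, ext)
    fb1 = squash(fs1, p.a1)
    fv1 = _norm_then_mask("fv1", first_order_track(fb1, p.beta1), fb1, w0)
    fv2 = _norm_then_mask(
        "fv2",
        first_order_track(fb1, p.beta2),
        _expiration_mask(fb1, mask_convention),
        w0,
    )
    v = p.Av * (fv1 + fv2)
    if return_components:
        comps = {"fs1": fs1[o0:], "fb1": fb1[o0:], "fv1": fv1[o0:], "fv2": fv2[o0:]}
        return v[o0:], comps
    return v[o0:]


def simulate_pressure(
    p: PressureParams,
    grid: SampleGrid,
    mask_convention: str = "phase",
    return_components: bool = False,
):
    """Simulate the pressure trace ``P = fp13 + fp24 + fp33 + Ap4`` on ``grid``.

    ``fp13`` is the plateau skeleton (amplitude ``Ap1``), ``fp24`` the
    plateau peaks (amplitude ``Ap2``; identically zero when ``Ap2 = 0``)
    and ``fp33`` the low-volume knee (amplitude ``Ap3``; identically zero
    when ``Ap3 = 0``).
    """
    p.validate()
    ext, w0, o0 = _sim_window(grid, p.theta)
    fs2 = shifted_sine(p.theta, p.phi2, p.b2, ext)
    fb2 = squash(fs2, p.a2)
    fp11 = _norm_then_mask("fp11", first_order_track(fb2, p.beta3), fb2, w0)
    fp12 = _norm_then_mask(
        "fp12",
        first_order_track(fb2, p.beta4),
        _expiration_mask(fb2, mask_convention),
        w0,
    )
    fp13 = p.Ap1 * (fp11 + fp12)

    ones = np.ones_like(fb2)
    if p.Ap2 != 0.0:
        fp21 = leaky_diff(fb2, p.beta5)
        fp22 = fp21 * fb2
        fp23 = np.abs(leaky_diff(fp22, p.beta6))
        fp24 = p.Ap2 * _norm("fp23", fp23, ones, w0)
    else:
        fp21 = fp22 = fp23 = fp24 = np.zeros_like(fb2)

    if p.Ap3 != 0.0:
        fp31 = shifted_sine(p.theta, p.phi3, p.b3, ext)
        fp32 = squash(fp31, p.a3)
        low_volume = np.clip(1.0 - (fp11 + fp12), 0.0, 1.0)
        fp33 = p.Ap3 * _norm("fp33", fp32, low_volume, w0)
    else:
        fp31 = fp32 = fp33 = np.zeros_like(fb2)

    pr = fp13 + fp24 + fp33 + p.Ap4
    if return_components:
        comps = {
            name: arr[o0:]
            for name, arr in {
                "fs2": fs2, "fb2": fb2, "fp11": fp11, "fp12": fp12,
                "fp13": fp13, "fp21": fp21, "fp22": fp22, "fp23": fp23,
                "fp24": fp24, "fp31": fp31, "fp32": fp32, "fp33": fp33,
            }.items()
        }
        return pr[o0:], comps
    return pr[o0:]


def simulate_breath(
    vp: VolumeParams,
    pp: PressureParams,
    grid: SampleGrid,
    mask_convention: str = "phase",
    meta: dict | None = None,
) -> BreathRecord:
    """Simulate a combined breath: volume, pressure and finite-difference flow.

    The two sub-models are coupled only through the shared respiratory
    frequency; a mismatch is a coupling violation.
    """
    if vp.theta != pp.theta:
        raise CouplingViolationError(
            f"volume theta={vp.theta} != pressure theta={pp.theta}"
        )
    v = simulate_volume(vp, grid, mask_convention)
    pr = simulate_pressure(pp, grid, mask_convention)
    flow = np.gradient(v, grid.dt)
    return BreathRecord(
        grid=grid,
        pressure=Signal(pr, units="cmH2O"),
        volume=Signal(v, units="ml"),
        flow=Signal(flow, units="ml/s"),
        meta=dict(meta or {}),
    )


def dilv_compliance(Av: float, Ap1: float) -> ComplianceReport:
    """Model-derived lung compliance ``Cd = Av / Ap1`` (ml/cmH2O).

    ``Av`` is the fitted tidal volume amplitude and ``Ap1`` the fitted
    plateau pressure above PEEP; their ratio plays the role of the
    quasi-static compliance computed from tidal volume and driving
    pressure.
    """
    if Ap1 == 0:
        raise InvalidParameterError("Ap1 must be nonzero to define Cd = Av/Ap1")
    return ComplianceReport(Cd=Av / Ap1, Av=Av, Ap1=Ap1)
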