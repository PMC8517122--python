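"""Signal primitives for feature-anchored ventilator waveform models.

Both the volume and the pressure model are composed from the same small set
of discrete-time building blocks:

* a phase-shifted, offset sinusoid (the periodic clock of the breath),
* a tanh squashing step that turns the sinusoid into a soft rectangular
  drive whose duty cycle sets the inspiratory:expiratory ratio,
* a first-order recursive tracker that smooths the drive into rising /
  falling ramps (gradients of inspiration and expiration),
* a leaky differencer that turns drive transitions into decaying spikes
  (plateau-peak shapes), and
* masked normalization, which gates a term to the phase of the breath in
  which it is active and rescales its peak to one.

All primitives operate on plain ``numpy`` arrays sampled on a
:class:`SampleGrid`.  The smoothing factors ``beta`` act per sample, so
their physical meaning depends on the grid step ``dt``; ``dt`` is therefore
an explicit, logged configuration value throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import DegenerateNormalizationError, InvalidParameterError

__all__ = [
    "SampleGrid",
    "Signal",
    "shifted_sine",
    "squash",
    "first_order_track",
    "leaky_diff",
    "mask_normalize",
    "duty_fraction",
]


@dataclass(frozen=True)
class SampleGrid:
    """Uniform time discretization on which all signals live.

    Parameters
    ----------
    dt : float
        Seconds per sample, > 0.
    n : int
        Number of samples, > 0.
    t_start : float
        Time of the first sample (seconds).
    burn_in_periods : int
        Number of extra warm-up periods simulated before ``t_start`` and
        discarded, so recursive terms reach their periodic steady state
        before masking and normalization.
    """

    dt: float
    n: int
    t_start: float = 0.0
    burn_in_periods: int = 3

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise InvalidParameterError(f"n must be a positive integer, got {self.n}")
        if self.burn_in_periods < 0:
            raise InvalidParameterError("burn_in_periods must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t_start + i*dt`` for ``i = 0..n-1``."""
        return self.t_start + self.dt * np.arange(self.n)

    @property
    def span(self) -> float:
        """Total duration covered by the grid (seconds)."""
        return self.n * self.dt


@dataclass
class Signal:
    """A sampled trace aligned to a :class:`SampleGrid`."""

    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("Signal values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _values(x) -> np.ndarray:
    if isinstance(x, Signal):
        return x.values
    return np.asarray(x, dtype=float)


def shifted_sine(theta: float, phi: float, b: float, grid: SampleGrid) -> np.ndarray:
    """``sin(2*pi*theta*t - phi) - b`` sampled on ``grid``.

    ``theta`` is the respiratory frequency in breaths/s, ``phi`` shifts the
    starting point within the cycle and ``b`` offsets the sinusoid, which —
    after squashing — sets the duty cycle of the rectangular drive.
    """
    if not theta > 0:
        raise InvalidParameterError(f"theta must be > 0, got {theta}")
    return np.sin(2.0 * np.pi * theta * grid.times - phi) - b


def squash(x, a: float) -> np.ndarray:
    """Elementwise ``(tanh(a*x) + 1) / 2``; strictly inside (0, 1).

    Large ``a`` turns a thresholded sinusoid into a near-binary rectangular
    wave with zero base and unit amplitude.
    """
    if not a > 0:
        raise InvalidParameterError(f"sharpness a must be > 0, got {a}")
    return 0.5 * (np.tanh(a * _values(x)) + 1.0)


def first_order_track(drive, beta: float, init: float = 0.0) -> np.ndarray:
    """First-order recursive tracking of a drive signal.

    ``y[0] = init`` and ``y[i] = drive[i]/beta + (1 - 1/beta) * y[i-1]``.
    ``beta`` >= 1 is the per-sample smoothing factor: larger values give
    slower rise/fall toward the drive level.  The output never leaves the
    envelope spanned by ``init`` and the drive.
    """
    if not beta >= 1:
        raise InvalidParameterError(f"beta must be >= 1, got {beta}")
    x = _values(drive)
    if x.size == 0:
        return x.copy()
    r = 1.0 - 1.0 / beta
    out = np.empty_like(x)
    out[0] = init
    if x.size > 1:
        # y[i] = (1/beta) x[i] + r y[i-1]  ==  IIR filter with state r*init
        y, _ = lfilter([1.0 / beta], [1.0, -r], x[1:], zi=np.array([r * init]))
        out[1:] = y
    return out


def leaky_diff(drive, beta: float, init: float = 0.0) -> np.ndarray:
    """Leaky differencing of a drive signal.

    ``y[0] = init`` and ``y[i] = (y[i-1] + drive[i] - drive[i-1]) / beta``.
    Transitions of the drive appear as spikes that decay geometrically with
    ratio ``1/beta`` between transitions; ``beta = 1`` telescopes to
    ``drive - drive[0] + init``.
    """
    if not beta >= 1:
        raise InvalidParameterError(f"beta must be >= 1, got {beta}")
    x = _values(drive)
    if x.size == 0:
        return x.copy()
    out = np.empty_like(x)
    out[0] = init
    if x.size > 1:
        d = np.diff(x)
        # y[i] = (1/beta) d[i] + (1/beta) y[i-1]
        y, _ = lfilter([1.0 / beta], [1.0, -1.0 / beta], d, zi=np.array([init / beta]))
        out[1:] = y
    return out


def mask_normalize(x, mask, eps: float = 1e-12, window_start: int = 0) -> np.ndarray:
    """Gate ``x`` by ``mask`` and rescale so its windowed maximum is one.

    Returns ``(x * mask) / max(x * mask)`` where the maximum is taken over
    samples from ``window_start`` on (the post-burn-in window).  ``mask``
    entries must lie in [0, 1].

    Raises
    ------
    DegenerateNormalizationError
        If the windowed maximum does not exceed ``eps`` (e.g. the mask and
        the signal never overlap, or the drive saturated to a constant).
    """
    xv = _values(x)
    mv = _values(mask)
    if xv.shape != mv.shape:
        raise InvalidParameterError("signal and mask must share a grid length")
    if np.any(mv < -1e-12) or np.any(mv > 1.0 + 1e-12):
        raise InvalidParameterError("mask entries must lie in [0, 1]")
    masked = xv * mv
    peak = float(np.max(masked[window_start:]))
    if not peak > eps:
        raise DegenerateNormalizationError("masked signal", peak)
    return masked / peak


def duty_fraction(drive, threshold: float = 0.5, window_start: int = 0) -> float:
    """Fraction of samples (from ``window_start`` on) above ``threshold``.

    For a sharp rectangular drive this is the inspiratory fraction of the
    cycle; the inspiratory:expiratory ratio is ``f / (1 - f)``.
    """
    x = _values(drive)[window_start:]
    if x.size == 0:
        raise InvalidParameterError("empty window")
    return float(np.mean(x > threshold))
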