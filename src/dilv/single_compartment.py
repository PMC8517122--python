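"""Single-compartment comparator model of respiratory mechanics.

The linear equation of motion of the respiratory system lumps the lung into
a single elastance ``E`` and resistance ``R``:

    P(t) = E * V(t) + R * V'(t) + P0

with ``P0`` the baseline pressure.  It is fitted per breath by ordinary
least squares of pressure on volume, flow and an intercept; compliance is
``Cs = 1/E``.  The model is exact on data it generated itself and serves as
the comparator for the richer DILV waveform model, which can represent
features (plateau peaks, low-volume knees) this linear form cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InvalidParameterError
from .model import BreathRecord

__all__ = ["SCParams", "predict_pressure", "fit_sc"]


@dataclass(frozen=True)
class SCParams:
    """Single-compartment parameters: elastance, resistance, baseline.

    ``C`` is the derived compliance ``1/E`` (ml/cmH2O).
    """

    E: float  # cmH2O/ml
    R: float  # cmH2O*s/ml
    P0: float  # cmH2O

    @property
    def C(self) -> float:
        return 1.0 / self.E


def predict_pressure(sc: SCParams, volume, flow) -> np.ndarray:
    """Elementwise ``E*V + R*flow + P0`` on a shared grid."""
    v = np.asarray(getattr(volume, "values", volume), dtype=float)
    f = np.asarray(getattr(flow, "values", flow), dtype=float)
    if v.shape != f.shape:
        raise InvalidParameterError("volume and flow traces must share a grid")
    return sc.E * v + sc.R * f + sc.P0


def fit_sc(breath: BreathRecord) -> tuple[SCParams, float]:
    """Least-squares fit of the single-compartment model to one breath.

    Regresses measured pressure on [volume, flow, 1]; flow is derived from
    volume by central finite differences when not recorded.  Returns the
    parameter estimates and the mean squared pressure residual (cmH2O^2).

    Raises
    ------
    DegenerateFitError
        If the regressor matrix is rank deficient (e.g. constant volume
        with zero flow), so E, R, P0 are not separately identifiable.
    """
    p = breath.pressure.values
    v = breath.volume.values
    f = breath.flow_values()
    X = np.column_stack([v, f, np.ones_like(v)])
    rank = np.linalg.matrix_rank(X, tol=1e-10 * max(1.0, float(np.abs(X).max())))
    if rank < 3:
        raise DegenerateFitError(
            "regressors [volume, flow, 1] are rank deficient; cannot identify E, R, P0"
        )
    coef, _, _, _ = np.linalg.lstsq(X, p, rcond=None)
    resid = p - X @ coef
    mse = float(np.mean(resid**2))
    return SCParams(E=float(coef[0]), R=float(coef[1]), P0=float(coef[2])), mse
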