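"""Tests for the composed volume/pressure models and the compliance readout."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from dilv import (
    CouplingViolationError,
    InvalidParameterError,
    PRESSURE_PARAM_NAMES,
    VOLUME_PARAM_NAMES,
    PressureParams,
    SampleGrid,
    VolumeParams,
    dilv_compliance,
    simulate_breath,
    simulate_pressure,
    simulate_volume,
)
from dilv.synthetic import REGIMES

from dataclasses import replace


def rise_time_to_95(params: VolumeParams, dt: float = 0.001) -> float:
    """Time from inspiration onset to 95% of peak, by dense simulation."""
    n = int(round(3 / (params.theta * dt)))
    v = simulate_volume(params, SampleGrid(dt=dt, n=n))
    peak = v.max()
    i_peak = int(np.argmax(v))
    # walk back from the peak to the start of this rise
    below = np.nonzero(v[:i_peak] < 0.02 * peak)[0]
    i_start = below[-1] if below.size else 0
    i95 = i_start + int(np.argmax(v[i_start:i_peak + 1] >= 0.95 * peak))
    return (i95 - i_start) * dt


class TestVolumeModel:
    def test_demo_waveform_period_and_peak(self, demo_volume):
        grid = SampleGrid(dt=0.005, n=3 * 667)
        v = simulate_volume(demo_volume, grid)
        assert v.max() == pytest.approx(1.0, abs=1e-3)
        assert v.min() >= -1e-9
        peaks, _ = find_peaks(v, height=0.9)
        spacing = np.diff(peaks) * grid.dt
        assert np.allclose(spacing, 1 / 0.3, atol=2 * grid.dt)

    def test_zero_amplitude_gives_zero_trace(self, demo_volume, demo_grid):
        v = simulate_volume(replace(demo_volume, Av=0.0), demo_grid)
        assert np.all(v == 0.0)

    def test_peak_equals_amplitude(self, demo_volume, demo_grid):
        for av in (0.5, 1.0, 402.61):
            v = simulate_volume(replace(demo_volume, Av=av), demo_grid)
            assert v.max() == pytest.approx(av, rel=1e-3)

    def test_rise_time_monotone_in_beta1(self, demo_volume):
        t95 = [rise_time_to_95(replace(demo_volume, beta1=b))
               for b in np.linspace(30, 300, 10)]
        assert all(b > a for a, b in zip(t95, t95[1:]))

    def test_doubling_beta1_slows_rise(self, demo_volume):
        assert rise_time_to_95(replace(demo_volume, beta1=60.0)) > \
            rise_time_to_95(demo_volume)

    def test_fall_time_monotone_in_beta2(self, demo_volume, demo_grid):
        def fall_time(beta2):
            v = simulate_volume(replace(demo_volume, beta2=beta2), demo_grid)
            i_peak = int(np.argmax(v))
            below = np.nonzero(v[i_peak:] < 0.05)[0]
            return below[0] if below.size else len(v)
        times = [fall_time(b) for b in np.linspace(5, 100, 10)]
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_higher_b1_shortens_inspiration(self, demo_volume, demo_grid):
        def insp_fraction(b1):
            _, comps = simulate_volume(
                replace(demo_volume, b1=b1), demo_grid, return_components=True
            )
            return np.mean(comps["fb1"] > 0.5)
        fracs = [insp_fraction(b) for b in np.linspace(-0.5, 0.9, 8)]
        assert all(b < a for a, b in zip(fracs, fracs[1:]))

    def test_saturating_duty_offset_rejected(self, demo_volume, demo_grid):
        with pytest.raises(InvalidParameterError):
            simulate_volume(replace(demo_volume, b1=1.0), demo_grid)

    def test_periodicity_invariant(self, demo_volume, commensurate_grid):
        v = simulate_volume(replace(demo_volume, theta=0.25), commensurate_grid)
        assert np.abs(v[800:] - v[:800]).max() < 1e-4 * np.ptp(v)

    def test_mask_conventions_differ(self, demo_volume, demo_grid):
        v_phase = simulate_volume(demo_volume, demo_grid, mask_convention="phase")
        v_drive = simulate_volume(demo_volume, demo_grid, mask_convention="drive")
        # the drive convention gates expiration off, so the traces differ
        assert np.abs(v_phase - v_drive).max() > 0.1
        with pytest.raises(InvalidParameterError):
            simulate_volume(demo_volume, demo_grid, mask_convention="bogus")


class TestPressureModel:
    def test_demo_waveform_features(self, demo_pressure, demo_grid):
        p, comps = simulate_pressure(demo_pressure, demo_grid, return_components=True)
        amp = demo_pressure.Ap1 + demo_pressure.Ap2 + demo_pressure.Ap3
        assert p.min() >= demo_pressure.Ap4 - 0.02 * amp
        # the peak term spikes at both edges of the plateau
        bumps, _ = find_peaks(comps["fp24"], height=0.1 * demo_pressure.Ap2)
        assert len(bumps) >= 2

    def test_baseline_only(self, demo_pressure, demo_grid):
        p = simulate_pressure(
            replace(demo_pressure, Ap1=0.0, Ap2=0.0, Ap3=0.0, Ap4=7.5), demo_grid
        )
        assert np.allclose(p, 7.5)

    def test_feature_switches_are_exact(self, demo_pressure, demo_grid):
        _, c2 = simulate_pressure(
            replace(demo_pressure, Ap2=0.0), demo_grid, return_components=True
        )
        assert np.all(c2["fp24"] == 0.0)
        _, c3 = simulate_pressure(
            replace(demo_pressure, Ap3=0.0), demo_grid, return_components=True
        )
        assert np.all(c3["fp33"] == 0.0)

    def test_plateau_peak_amplitude_is_Ap2(self, demo_pressure, demo_grid):
        _, comps = simulate_pressure(demo_pressure, demo_grid, return_components=True)
        assert comps["fp24"].max() == pytest.approx(demo_pressure.Ap2, rel=1e-9)

    def test_skeleton_amplitude_is_Ap1(self, demo_pressure, demo_grid):
        _, comps = simulate_pressure(demo_pressure, demo_grid, return_components=True)
        assert comps["fp13"].max() == pytest.approx(demo_pressure.Ap1, rel=1e-3)

    def test_rise_and_fall_monotone_in_beta(self, demo_pressure, demo_grid):
        def times(beta3, beta4):
            p = simulate_pressure(
                replace(demo_pressure, beta3=beta3, beta4=beta4, Ap2=0.0, Ap3=0.0),
                demo_grid,
            )
            peak = p.max()
            i_peak = int(np.argmax(p))
            start = np.nonzero(p[:i_peak] < 0.05 * peak)[0]
            i_start = start[-1] if start.size else 0
            t_rise = int(np.argmax(p[i_start:] >= 0.95 * peak))
            i_top_end = int(np.nonzero(p >= 0.95 * peak)[0][-1])
            after = p[i_top_end:]
            low = np.nonzero(after < 0.05 * peak)[0]
            t_fall = low[0] if low.size else len(after)
            return t_rise, t_fall
        rises = [times(b, 5.0)[0] for b in np.linspace(2, 60, 10)]
        falls = [times(5.0, b)[1] for b in np.linspace(2, 60, 10)]
        assert all(b >= a for a, b in zip(rises, rises[1:]))
        assert all(b >= a for a, b in zip(falls, falls[1:]))

    def test_periodicity_invariant(self, demo_pressure):
        # the beta5 = 1.001 peak term decays with a ~5 s time constant, so
        # reaching periodic steady state needs a generous warm-up
        grid = SampleGrid(dt=0.005, n=1600, burn_in_periods=15)
        p = simulate_pressure(replace(demo_pressure, theta=0.25), grid)
        assert np.abs(p[800:] - p[:800]).max() < 1e-4 * np.ptp(p)


class TestBreathAndCompliance:
    def test_theta_mismatch_is_coupling_violation(self, demo_volume, demo_pressure,
                                                  demo_grid):
        with pytest.raises(CouplingViolationError):
            simulate_breath(demo_volume, replace(demo_pressure, theta=0.4), demo_grid)

    def test_flow_integrates_back_to_volume(self, demo_volume, demo_pressure):
        grid = SampleGrid(dt=0.001, n=3334)
        breath = simulate_breath(demo_volume, demo_pressure, grid)
        v = breath.volume.values
        reint = v[0] + cumulative_trapezoid(breath.flow.values, dx=grid.dt, initial=0.0)
        # central-difference flow re-integrates to O(dt^2) away from the
        # sharp drive transitions; compare in the bulk
        assert np.median(np.abs(reint - v)) < 1e-4 * np.ptp(v)
        assert np.abs(reint - v).max() < 2e-2 * np.ptp(v)

    def test_healthy_mouse_reference_breath(self):
        vp, pp, _, dt = REGIMES["healthy"]
        grid = SampleGrid(dt=dt, n=int(round(1 / (vp.theta * dt))))
        breath = simulate_breath(vp, pp, grid)
        assert breath.volume.values.max() == pytest.approx(1.03, rel=0.02)
        # plateau sits at Ap1 above PEEP
        assert breath.pressure.values.max() == pytest.approx(35.53 + pp.Ap4, rel=0.02)

    def test_parameter_registry_counts(self):
        assert len(VOLUME_PARAM_NAMES) == 6
        assert len(PRESSURE_PARAM_NAMES) == 14

    @pytest.mark.parametrize(
        "av, ap1, expected, digits",
        [
            (1.03, 35.53, 0.029, 3),
            (0.70, 35.02, 0.020, 3),
            (402.61, 16.58, 24.28, 2),
            (337.08, 11.64, 28.96, 2),
        ],
    )
    def test_compliance_values(self, av, ap1, expected, digits):
        report = dilv_compliance(av, ap1)
        assert round(report.Cd, digits) == expected

    def test_compliance_guards(self):
        assert dilv_compliance(0.0, 10.0).Cd == 0.0
        with pytest.raises(InvalidParameterError):
            dilv_compliance(1.0, 0.0)
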