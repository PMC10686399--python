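"""Fixed-period sine fitting, calibration, and deviation estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stare import (CalibrationModel, SimConfig, build_schedule, clean_trace,
                   deviation_to_pupil_offset, estimate_deviation,
                   fit_calibration, fit_refixation, simulate_trace)
from stare.exceptions import (CalibrationError, InsufficientDataError,
                              ParameterError)

from conftest import make_trace, square_wave_trace
from oracles import grid_search_sine_fit

PAPER_PRISM_GRID = [0, 1, 2, 3, 5, 6, 12, 15, 30, 40]


class TestFitRefixation:
    def test_flat_trace_has_zero_amplitude(self):
        t = np.arange(480) / 120.0
        fit = fit_refixation(make_trace(t, x_left=np.full(480, 1.5),
                                        x_right=np.full(480, -0.5)))
        assert fit.amplitude_left == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitude_right == pytest.approx(0.0, abs=1e-12)
        assert fit.offset_left == pytest.approx(1.5)

    def test_pure_sinusoid_recovered_exactly(self):
        t = np.arange(7200) / 120.0
        x = 0.7 + 3.0 * np.sin(2 * np.pi * t / 2.0 + 1.234)
        fit = fit_refixation(make_trace(t, x_left=x, x_right=x))
        assert fit.amplitude_left == pytest.approx(3.0, abs=1e-9)
        assert fit.offset_left == pytest.approx(0.7, abs=1e-9)
        assert fit.rms_residual_left == pytest.approx(0.0, abs=1e-9)

    def test_square_wave_fundamental(self):
        """An ideal square wave of peak-to-peak D fits amplitude 2D/pi."""
        D = 4.0
        fit = fit_refixation(square_wave_trace(height=D))
        expected = 2.0 * D / np.pi
        assert fit.amplitude_left == pytest.approx(expected, rel=5e-3)
        assert fit.amplitude_right == pytest.approx(expected, rel=5e-3)

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = 300
            t = np.sort(rng.uniform(0.0, 6.0, n))
            t += np.linspace(0, 1e-6, n)  # enforce strict monotonicity
            amp = rng.uniform(0.2, 3.0)
            x = (rng.normal() + amp * np.sin(np.pi * t + rng.uniform(0, 7))
                 + rng.normal(0, 0.2, n))
            fit = fit_refixation(make_trace(t, x_left=x, x_right=x))
            g_amp, _, g_sse, step = grid_search_sine_fit(t, x)
            assert abs(fit.amplitude_left - g_amp) <= step + 1e-9
            resid = x - (fit.offset_left + fit.amplitude_left *
                         np.sin(np.pi * t + fit.phase_left))
            assert float(resid @ resid) <= g_sse + 1e-9

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(-50.0, 50.0), st.integers(0, 2 ** 31 - 1))
    def test_amplitude_invariant_to_constant_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(600) / 120.0
        x = rng.normal(0, 1, 600)
        f0 = fit_refixation(make_trace(t, x_left=x, x_right=x))
        f1 = fit_refixation(make_trace(t, x_left=x + shift, x_right=x + shift))
        assert f1.amplitude_left == pytest.approx(f0.amplitude_left,
                                                  abs=1e-8)

    def test_window_keeps_whole_cycles_only(self):
        t = np.arange(7200) / 120.0
        trace = make_trace(t, x_left=np.sin(np.pi * t),
                           x_right=np.sin(np.pi * t))
        fit = fit_refixation(trace, window=2.0)
        assert fit.n_samples_left == 240  # one 2-s cycle at 120 Hz
        fit5 = fit_refixation(trace, window=5.0)
        assert fit5.n_samples_left == 480  # floor(5/2) = 2 cycles

    def test_less_than_one_cycle_raises(self):
        t = np.arange(120) / 120.0  # 1 s < one 2-s cycle
        with pytest.raises(InsufficientDataError):
            fit_refixation(make_trace(t))
        with pytest.raises(ParameterError):
            fit_refixation(make_trace(np.arange(480) / 120.0), window=1.0)

    def test_noise_floor_shrinks_with_more_data(self):
        """With zero true deviation, the fitted amplitude is a positive
        Rayleigh-type bias that decreases as samples accumulate."""
        amps_short, amps_long = [], []
        for seed in range(8):
            cfg = SimConfig(deviation_pd=0.0, blink_rate=0.0, seed=seed)
            trace = simulate_trace(cfg)
            amps_short.append(fit_refixation(trace, window=4.0)
                              .amplitude_left)
            amps_long.append(fit_refixation(trace).amplitude_left)
        assert min(amps_short) > 0
        assert np.mean(amps_long) < np.mean(amps_short)


class TestFitCalibration:
    def test_exact_linear_relation_recovered(self):
        runs = pd.DataFrame({"prism_pd": PAPER_PRISM_GRID,
                             "amplitude_mm": [0.08 * d for d in
                                              PAPER_PRISM_GRID]})
        model = fit_calibration(runs, "linear_through_origin")
        assert model.parameters["slope"] == pytest.approx(0.08, abs=1e-12)
        assert model.fit_residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_flat_amplitudes_rejected(self):
        runs = [(d, 1.0) for d in (0, 10, 20, 30)]
        with pytest.raises(CalibrationError):
            fit_calibration(runs)

    def test_too_few_strengths_rejected(self):
        with pytest.raises(ParameterError):
            fit_calibration([(0, 0.0), (10, 1.0)])

    def test_averages_across_controls(self):
        runs = pd.DataFrame({
            "control_id": ["a", "b"] * 3,
            "prism_pd": [0, 0, 10, 10, 20, 20],
            "amplitude_mm": [0.0, 0.0, 0.9, 1.1, 1.9, 2.1],
        })
        model = fit_calibration(runs)
        assert model.parameters["slope"] == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("form", ["linear_through_origin", "affine",
                                      "power"])
    def test_inverse_of_forward_is_identity(self, form):
        rng = np.random.default_rng(3)
        x = np.array(PAPER_PRISM_GRID, float)
        y = 0.07 * x ** 0.95 + rng.normal(0, 0.01, x.size)
        model = fit_calibration(pd.DataFrame({"prism_pd": x,
                                              "amplitude_mm":
                                                  np.abs(y)}), form)
        grid = np.linspace(0.5, 40.0, 50)
        np.testing.assert_allclose(model.inverse(model.forward(grid)), grid,
                                   atol=1e-9)

    def test_json_roundtrip(self, tmp_path):
        model = fit_calibration([(d, 0.07 * d) for d in PAPER_PRISM_GRID])
        p = tmp_path / "cal.json"
        model.to_json(p)
        back = CalibrationModel.from_json(p)
        assert back.model_form == model.model_form
        assert back.parameters == model.parameters
        assert back.inverse(1.4) == pytest.approx(model.inverse(1.4))

    def test_simulated_controls_recover_generative_slope(self):
        """The fitted mm/PD slope should match the generator's closed-form
        small-angle slope (2/pi) * eye_radius / 100 within 10%."""
        runs = []
        small_grid = [0, 1, 2, 3, 5, 6]
        for seed in range(1, 8):
            for d in small_grid:
                cfg = SimConfig(deviation_pd=float(d), seed=seed * 100 + d)
                schedule = build_schedule(60.0)
                trace = clean_trace(simulate_trace(cfg, schedule))
                fit = fit_refixation(trace, schedule)
                runs.append((float(d), fit.amplitude("mean_of_eyes")))
        model = fit_calibration(runs)
        expected = (2.0 / np.pi) * 11.0 / 100.0
        assert model.parameters["slope"] == pytest.approx(expected, rel=0.1)


class TestEstimateDeviation:
    @staticmethod
    def _fit_with_amplitudes(al, ar):
        from stare import RefixationFit
        return RefixationFit(amplitude_left=al, amplitude_right=ar,
                             phase_left=0.0, phase_right=0.0,
                             offset_left=0.0, offset_right=0.0, period=2.0,
                             rms_residual_left=0.0, rms_residual_right=0.0,
                             n_samples_left=7200, n_samples_right=7200)

    def test_zero_amplitude_maps_to_zero(self):
        model = fit_calibration([(d, 0.1 * d) for d in (0, 10, 20, 40)])
        est = estimate_deviation(self._fit_with_amplitudes(0.0, 0.0), model)
        assert est.deviation_pd == 0.0

    def test_linear_inverse(self):
        model = fit_calibration([(d, 0.1 * d) for d in (0, 10, 20, 40)])
        est = estimate_deviation(self._fit_with_amplitudes(2.0, 2.0), model)
        assert est.deviation_pd == pytest.approx(20.0, abs=1e-9)
        assert not est.extrapolated

    def test_eye_policies(self):
        model = fit_calibration([(d, 0.1 * d) for d in (0, 10, 20, 40)])
        fit = self._fit_with_amplitudes(1.0, 3.0)
        assert estimate_deviation(fit, model, "mean_of_eyes").deviation_pd \
            == pytest.approx(20.0)
        assert estimate_deviation(fit, model, "left").deviation_pd \
            == pytest.approx(10.0)
        assert estimate_deviation(fit, model, "max").deviation_pd \
            == pytest.approx(30.0)

    def test_extrapolation_flagged_not_fatal(self):
        model = fit_calibration([(d, 0.1 * d) for d in (0, 10, 20, 40)])
        est = estimate_deviation(self._fit_with_amplitudes(8.0, 8.0), model)
        assert est.extrapolated
        assert est.deviation_pd == pytest.approx(80.0)

    def test_end_to_end_recovery_of_known_deviation(self):
        """Calibrate on simulated controls, then recover a fresh 15-PD
        subject within +/- 3 PD."""
        runs = []
        for seed in range(1, 8):
            for d in PAPER_PRISM_GRID:
                cfg = SimConfig(deviation_pd=float(d), seed=seed * 1000 + d)
                schedule = build_schedule(60.0)
                trace = clean_trace(simulate_trace(cfg, schedule))
                runs.append((float(d),
                             fit_refixation(trace, schedule).amplitude()))
        model = fit_calibration(runs)
        cfg = SimConfig(deviation_pd=15.0, seed=3)
        schedule = build_schedule(60.0)
        trace = clean_trace(simulate_trace(cfg, schedule))
        est = estimate_deviation(fit_refixation(trace, schedule), model)
        assert est.deviation_pd == pytest.approx(15.0, abs=3.0)
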