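"""Refixation-amplitude measurement and amplitude-to-dioptre calibration.

The measurement at the heart of the screen is a fixed-period sinusoid fitted
to each eye's raw horizontal gaze trace.  Under 1-s alternate occlusion each
eye swings between fixation and its deviated position with a 2-s period, so
the trace is modelled as

    x(t) = a + b sin(2 pi t / T) + c cos(2 pi t / T),      T = 2 s fixed,

a linear least-squares problem whose amplitude sqrt(b^2 + c^2) captures the
fundamental of the square-wave-like refixation signal.  The fit is
closed-form, deterministic and indifferent to dropped samples.

Amplitudes (mm) are mapped to deviations (prism dioptres) through a
:class:`CalibrationModel` fitted on control runs with prisms of known
strength: per-strength mean amplitudes are regressed on prism strength and
the monotone fitted curve is inverted to score new subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (CalibrationError, InsufficientDataError,
                         ParameterError)
from .gaze_io import GazeTrace, OcclusionSchedule

__all__ = ["RefixationFit", "CalibrationModel", "DeviationEstimate",
           "fit_refixation", "fit_calibration", "estimate_deviation"]

MODEL_FORMS = ("linear_through_origin", "affine", "power")
EYE_POLICIES = ("mean_of_eyes", "left", "right", "max")


@dataclass(frozen=True)
class RefixationFit:
    """Per-eye fixed-period sine fit of the refixation movement."""

    amplitude_left: float
    amplitude_right: float
    phase_left: float
    phase_right: float
    offset_left: float
    offset_right: float
    period: float
    rms_residual_left: float
    rms_residual_right: float
    n_samples_left: int
    n_samples_right: int

    def amplitude(self, eye_policy: str = "mean_of_eyes") -> float:
        """Combine the two per-eye amplitudes into one response amplitude."""
        if eye_policy == "mean_of_eyes":
            return 0.5 * (self.amplitude_left + self.amplitude_right)
        if eye_policy == "left":
            return self.amplitude_left
        if eye_policy == "right":
            return self.amplitude_right
        if eye_policy == "max":
            return max(self.amplitude_left, self.amplitude_right)
        raise ParameterError(f"unknown eye_policy {eye_policy!r}")


def _fit_one_eye(t: np.ndarray, x: np.ndarray, period: float
                 ) -> tuple[float, float, float, float]:
    """Least squares of a + b sin + c cos; returns (amp, phase, offset, rms)."""
    w = 2.0 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    a, b, c = coef
    resid = x - design @ coef
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return float(np.hypot(b, c)), float(np.arctan2(c, b)), float(a), rms


def fit_refixation(trace: GazeTrace,
                   schedule: OcclusionSchedule | None = None,
                   window: float | None = None,
                   period: float | None = None) -> RefixationFit:
    """Fit the fixed-period sine to each eye of a (cleaned) trace.

    Parameters
    ----------
    trace : GazeTrace
        The gaze recording; only samples flagged valid for an eye enter that
        eye's fit.
    schedule : OcclusionSchedule, optional
        Supplies the cycle period (its ``cycle_period``); defaults to 2 s.
    window : float, optional
        Use only the first `window` seconds.  Truncation keeps whole cycles
        only — an N-second window keeps ``floor(N / period)`` cycles —
        because partial cycles bias the fixed-period fit.
    period : float, optional
        Override the sine period (s).

    Raises
    ------
    InsufficientDataError
        If an eye has less than one full cycle of valid data in the window.
    """
    if period is None:
        period = schedule.cycle_period if schedule is not None else 2.0
    if period <= 0:
        raise ParameterError("period must be positive")
    in_window = np.ones(len(trace), dtype=bool)
    if window is not None:
        if window < period:
            raise ParameterError(
                f"window {window} s is below one cycle ({period} s)")
        t_max = np.floor(window / period) * period
        in_window = trace.t < t_max
        extent = t_max
    else:
        extent = trace.duration
    # one whole cycle of regular samples spans period - 1/rate seconds
    if extent < period - 1.5 / trace.nominal_rate:
        raise InsufficientDataError(
            f"recording covers {extent} s, less than one {period}-s cycle")
    results = {}
    for eye, x, valid in (("left", trace.x_left, trace.valid_left),
                          ("right", trace.x_right, trace.valid_right)):
        sel = in_window & valid
        t_sel = trace.t[sel]
        if t_sel.size < 3:
            raise InsufficientDataError(
                f"{eye} eye: too few valid samples in the window")
        results[eye] = (*_fit_one_eye(t_sel, x[sel], period), int(t_sel.size))
    (al, pl, ol, rl, nl) = results["left"]
    (ar, pr, orr, rr, nr) = results["right"]
    return RefixationFit(amplitude_left=al, amplitude_right=ar,
                         phase_left=pl, phase_right=pr,
                         offset_left=ol, offset_right=orr, period=period,
                         rms_residual_left=rl, rms_residual_right=rr,
                         n_samples_left=nl, n_samples_right=nr)


@dataclass
class CalibrationModel:
    """Monotone mapping between response amplitude (mm) and deviation (PD).

    ``model_form`` is one of ``linear_through_origin`` (amplitude =
    slope * PD), ``affine`` (slope * PD + intercept) or ``power``
    (scale * PD^exponent).  The forward map must be strictly increasing on
    the calibrated range so it can be inverted to score new subjects.
    """

    model_form: str
    parameters: dict[str, float]
    fit_residual_rms: float
    source: pd.DataFrame = field(repr=False)
    pd_range: tuple[float, float] = (0.0, 40.0)

    def forward(self, deviation_pd):
        """Predicted amplitude (mm) at a deviation (PD)."""
        d = np.asarray(deviation_pd, dtype=float)
        p = self.parameters
        if self.model_form == "linear_through_origin":
            out = p["slope"] * d
        elif self.model_form == "affine":
            out = p["slope"] * d + p["intercept"]
        elif self.model_form == "power":
            out = p["scale"] * np.power(d, p["exponent"],
                                        where=d > 0, out=np.zeros_like(d))
        else:
            raise ParameterError(f"unknown model_form {self.model_form!r}")
        return out if out.ndim else float(out)

    def inverse(self, amplitude_mm):
        """Deviation (PD) whose predicted amplitude equals `amplitude_mm`."""
        a = np.asarray(amplitude_mm, dtype=float)
        p = self.parameters
        if self.model_form == "linear_through_origin":
            out = a / p["slope"]
        elif self.model_form == "affine":
            out = (a - p["intercept"]) / p["slope"]
        elif self.model_form == "power":
            out = np.power(np.maximum(a, 0.0) / p["scale"],
                           1.0 / p["exponent"])
        else:
            raise ParameterError(f"unknown model_form {self.model_form!r}")
        return out if out.ndim else float(out)

    @property
    def max_calibrated_amplitude(self) -> float:
        return float(self.forward(self.pd_range[1]))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_form": self.model_form,
            "parameters": self.parameters,
            "fit_residual_rms": self.fit_residual_rms,
            "pd_range": list(self.pd_range),
            "source": self.source.to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path_or_text: str | Path) -> "CalibrationModel":
        p = Path(path_or_text) if isinstance(path_or_text, Path) else None
        if p is None:
            try:
                if Path(path_or_text).exists():
                    p = Path(path_or_text)
            except OSError:
                p = None
        text = p.read_text() if p is not None else str(path_or_text)
        d = json.loads(text)
        return cls(model_form=d["model_form"], parameters=d["parameters"],
                   fit_residual_rms=d["fit_residual_rms"],
                   source=pd.DataFrame(d["source"]),
                   pd_range=tuple(d["pd_range"]))


def fit_calibration(runs: pd.DataFrame | Sequence[tuple[float, float]],
                    model_form: str = "linear_through_origin"
                    ) -> CalibrationModel:
    """Fit the amplitude-vs-prism-strength calibration curve.

    `runs` is a table with columns ``prism_pd`` and ``amplitude_mm`` (an
    optional ``control_id`` column is accepted and ignored beyond averaging).
    Amplitudes are first averaged per prism strength across controls, then
    the chosen model form is fitted by least squares.  A fitted curve that is
    not strictly increasing over the calibrated range is rejected.
    """
    if model_form not in MODEL_FORMS:
        raise ParameterError(f"model_form must be one of {MODEL_FORMS}")
    if not isinstance(runs, pd.DataFrame):
        runs = pd.DataFrame(runs, columns=["prism_pd", "amplitude_mm"])
    for col in ("prism_pd", "amplitude_mm"):
        if col not in runs.columns:
            raise ParameterError(f"runs table lacks column {col!r}")
    if (runs["amplitude_mm"] < 0).any():
        raise ParameterError("amplitudes must be >= 0")
    mean_tbl = (runs.groupby("prism_pd", as_index=False)["amplitude_mm"]
                .mean().sort_values("prism_pd").reset_index(drop=True))
    x = mean_tbl["prism_pd"].to_numpy(float)
    y = mean_tbl["amplitude_mm"].to_numpy(float)
    if x.size < 3:
        raise ParameterError("need at least 3 distinct prism strengths")
    if np.ptp(y) == 0:
        raise CalibrationError(
            "amplitudes do not vary with prism strength; flat curve "
            "cannot be inverted")
    pd_range = (0.0, float(x.max()))

    if model_form == "linear_through_origin":
        denom = float(np.sum(x * x))
        if denom == 0:
            raise CalibrationError("all prism strengths are zero")
        params = {"slope": float(np.sum(x * y) / denom)}
        monotone = params["slope"] > 0
    elif model_form == "affine":
        slope, intercept = np.polyfit(x, y, 1)
        params = {"slope": float(slope), "intercept": float(intercept)}
        monotone = slope > 0
    else:  # power: fit log-log on strictly positive pairs
        pos = (x > 0) & (y > 0)
        if pos.sum() < 3:
            raise CalibrationError("power fit needs >= 3 positive pairs")
        expn, logscale = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        params = {"scale": float(np.exp(logscale)), "exponent": float(expn)}
        monotone = params["scale"] > 0 and params["exponent"] > 0

    if not monotone:
        raise CalibrationError(
            "fitted calibration curve is not strictly increasing; the "
            "amplitude-deviation relationship is degenerate")
    model = CalibrationModel(model_form=model_form, parameters=params,
                             fit_residual_rms=0.0, source=mean_tbl,
                             pd_range=pd_range)
    resid = y - np.asarray(model.forward(x))
    model.fit_residual_rms = float(np.sqrt(np.mean(resid ** 2)))
    # invertibility check on the calibrated range
    grid = np.linspace(pd_range[0] + 1e-9, pd_range[1], 101)
    fwd = np.asarray(model.forward(grid))
    if not np.all(np.diff(fwd) > 0):
        raise CalibrationError("calibration curve not invertible on range")
    if not np.allclose(model.inverse(fwd), grid, atol=1e-9, rtol=1e-9):
        raise CalibrationError("inverse(forward(x)) != x on calibrated range")
    return model


@dataclass(frozen=True)
class DeviationEstimate:
    """A subject's estimated horizontal deviation.

    ``extrapolated`` flags amplitudes above the calibrated range — the
    estimate is still returned (large deviations are the ones a screen must
    not miss) but should be treated as a lower-confidence extrapolation.
    """

    deviation_pd: float
    amplitude_mm: float
    eye_policy: str
    extrapolated: bool = False


def estimate_deviation(fit: RefixationFit, calibration: CalibrationModel,
                       eye_policy: str = "mean_of_eyes") -> DeviationEstimate:
    """Map a refixation fit to prism dioptres through the calibration curve.

    The per-eye amplitudes are combined per `eye_policy` (default: mean of
    the two eyes), pushed through the calibration inverse and clamped at 0.
    """
    if eye_policy not in EYE_POLICIES:
        raise ParameterError(f"eye_policy must be one of {EYE_POLICIES}")
    amp = fit.amplitude(eye_policy)
    dev = max(0.0, float(calibration.inverse(amp)))
    extrapolated = amp > calibration.max_calibrated_amplitude
    return DeviationEstimate(deviation_pd=dev, amplitude_mm=amp,
                             eye_policy=eye_policy, extrapolated=extrapolated)
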