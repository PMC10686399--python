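"""Synthetic binocular gaze traces under alternate occlusion.

The generator emulates what an eye tracker inside a headset records during an
automated alternate cover test on a subject with a horizontal deviation of
known size.  Whichever eye is covered drifts to its deviated position; when
the cover swaps, the newly uncovered eye refixates the target with a saccade
after a short latency while the newly covered eye deviates.  Each eye's
horizontal trace is therefore a square-wave-like signal with the occlusion
cycle period, whose step height grows with the deviation.  Gaussian tracker
noise and blink dropouts are superimposed.

Deviation is expressed in prism dioptres (PD): a deviation of ``d`` PD
corresponds to a visual-axis rotation of ``arctan(d / 100)``.  The tracker
reports pupil position in millimetres, so a rotation by angle ``theta`` moves
the tracked pupil by ``eye_radius * sin(theta)`` where ``eye_radius`` is the
distance from the eye's rotation centre to the tracked pupil plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError
from .gaze_io import LEFT, NONE, RIGHT, GazeTrace, OcclusionSchedule, Segment

__all__ = ["SimConfig", "build_schedule", "deviation_to_pupil_offset",
           "simulate_trace"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic gaze generator.

    Attributes
    ----------
    deviation_pd : float
        True horizontal deviation in prism dioptres (>= 0).
    direction : str
        ``'eso'`` (convergent) or ``'exo'`` (divergent); only flips the sign
        of the deviated position, downstream analysis uses magnitude only.
    eye_radius : float
        Rotation-centre-to-pupil distance in mm; sets the mm-per-angle scale.
    saccade_latency : float
        Refixation latency after a cover change, seconds.
    latency_jitter_sd : float
        Per-saccade Gaussian jitter of the latency, seconds.
    saccade_duration_base, saccade_duration_slope : float
        Main-sequence duration model: duration = base + slope * amplitude_deg.
    noise_sd : float
        Per-sample Gaussian tracker noise, mm.
    blink_rate : float
        Blinks per minute; each blink blanks both validity flags for a
        uniformly random 100-300 ms.
    rate : float
        Sampling rate, Hz.
    duration : float
        Recording length, seconds.
    seed : int
        Seed for all randomness; identical seeds give identical traces.
    """

    deviation_pd: float = 0.0
    direction: str = "eso"
    eye_radius: float = 11.0
    saccade_latency: float = 0.2
    latency_jitter_sd: float = 0.02
    saccade_duration_base: float = 0.021
    saccade_duration_slope: float = 0.0022
    noise_sd: float = 0.3
    blink_rate: float = 4.0
    rate: float = 120.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deviation_pd < 0:
            raise ParameterError("deviation_pd must be >= 0")
        if self.direction not in ("eso", "exo"):
            raise ParameterError("direction must be 'eso' or 'exo'")
        if self.eye_radius <= 0:
            raise ParameterError("eye_radius must be positive")
        if self.rate <= 0 or self.duration <= 0:
            raise ParameterError("rate and duration must be positive")
        if self.noise_sd < 0 or self.blink_rate < 0:
            raise ParameterError("noise_sd and blink_rate must be >= 0")


def build_schedule(duration: float, occlusion_duration: float = 1.0,
                   first_covered: str = RIGHT,
                   lead_in: float = 0.0) -> OcclusionSchedule:
    """Alternating occlusion schedule truncated at `duration` seconds.

    The schedule starts with `first_covered` (right by default) occluded at
    ``t = lead_in``; an optional binocular lead-in precedes it.  The final
    segment is truncated at `duration`.
    """
    if duration <= 0 or occlusion_duration <= 0:
        raise ParameterError("duration and occlusion_duration must be > 0")
    if lead_in < 0 or lead_in >= duration:
        raise ParameterError("lead_in must lie in [0, duration)")
    other = LEFT if first_covered == RIGHT else RIGHT
    segs: list[Segment] = []
    if lead_in > 0:
        segs.append(Segment(0.0, lead_in, NONE))
    t, eye = lead_in, first_covered
    while t < duration:
        t_end = min(t + occlusion_duration, duration)
        segs.append(Segment(t, t_end, eye))
        t, eye = t_end, (other if eye == first_covered else first_covered)
    return OcclusionSchedule(segs, cycle_period=2.0 * occlusion_duration,
                             occlusion_duration=occlusion_duration)


def deviation_to_pupil_offset(deviation_pd: float,
                              eye_radius: float = 11.0) -> float:
    """Pupil-plane displacement (mm) for a deviation in prism dioptres.

    One prism dioptre deflects light 1 cm at 1 m, so the rotation angle is
    ``theta = arctan(deviation_pd / 100)`` and the tracked pupil moves by
    ``eye_radius * sin(theta)``.  Strictly increasing in ``deviation_pd``.
    """
    if deviation_pd < 0:
        raise ParameterError("deviation_pd must be >= 0")
    if eye_radius <= 0:
        raise ParameterError("eye_radius must be positive")
    return eye_radius * math.sin(math.atan(deviation_pd / 100.0))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Sigmoidal 0->1 ramp (cubic smoothstep) clipped to [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _eye_positions(t: np.ndarray, schedule: OcclusionSchedule, eye: str,
                   deviated_mm: float, cfg: SimConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Noise-free trace of one eye: fixation at 0, `deviated_mm` when covered,
    smooth saccadic transitions with latency after each cover change."""
    covered = schedule.covered_at(t)
    targets = np.where(covered == eye, deviated_mm, 0.0)
    # transition events: t=0 initialises, then every change of target
    amp_deg = math.degrees(math.atan(cfg.deviation_pd / 100.0))
    sac_dur = cfg.saccade_duration_base + cfg.saccade_duration_slope * amp_deg
    x = np.empty_like(t)
    prev = 0.0  # binocular fixation before the test
    starts = np.concatenate(([0], np.flatnonzero(np.diff(targets) != 0) + 1))
    for k, s in enumerate(starts):
        e = starts[k + 1] if k + 1 < len(starts) else len(t)
        new = targets[s]
        if new == prev or (k == 0 and new == 0.0):
            x[s:e] = new
            prev = new
            continue
        lat = cfg.saccade_latency
        if cfg.latency_jitter_sd > 0:
            lat = max(0.0, lat + rng.normal(0.0, cfg.latency_jitter_sd))
        t0 = t[s] + lat
        if sac_dur > 0:
            ramp = _smoothstep((t[s:e] - t0) / sac_dur)
        else:
            ramp = (t[s:e] >= t0).astype(float)
        x[s:e] = prev + (new - prev) * ramp
        prev = new
    return x


def simulate_trace(config: SimConfig,
                   schedule: OcclusionSchedule | None = None) -> GazeTrace:
    """Simulate a binocular gaze trace for one test run.

    The covered eye sits at its deviated position; on uncovering it
    refixates after the saccade latency with a main-sequence-duration smooth
    saccade; the viewing eye holds fixation at 0 mm.  Tracker noise and blink
    dropouts are then superimposed.  Deterministic under a fixed seed.
    """
    if schedule is None:
        schedule = build_schedule(config.duration)
    rng = np.random.default_rng(config.seed)
    n = int(round(config.rate * config.duration))
    t = np.arange(n) / config.rate
    off = deviation_to_pupil_offset(config.deviation_pd, config.eye_radius)
    sign = 1.0 if config.direction == "eso" else -1.0
    # nasal is rightward (+) for the left eye, leftward (-) for the right eye
    x_left = _eye_positions(t, schedule, LEFT, sign * off, config, rng)
    x_right = _eye_positions(t, schedule, RIGHT, -sign * off, config, rng)
    if config.noise_sd > 0:
        x_left = x_left + rng.normal(0.0, config.noise_sd, n)
        x_right = x_right + rng.normal(0.0, config.noise_sd, n)
    valid = np.ones(n, dtype=bool)
    if config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * config.duration / 60.0)
        for t_start in np.sort(rng.uniform(0.0, config.duration, n_blinks)):
            blink_len = rng.uniform(0.1, 0.3)
            valid &= ~((t >= t_start) & (t < t_start + blink_len))
    return GazeTrace(t=t, x_left=x_left, x_right=x_right,
                     valid_left=valid.copy(), valid_right=valid.copy(),
                     nominal_rate=config.rate, duration=config.duration)


def with_params(config: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of `config` with the given fields replaced."""
    return replace(config, **kwargs)
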