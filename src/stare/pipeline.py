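"""End-to-end screening-study orchestration.

`run_screening` composes the whole pipeline on a synthetic study: simulate
calibration runs on orthotropic controls across a prism-strength grid, fit
the amplitude-to-dioptre calibration, simulate a test cohort (controls,
vertical-only patients as additional negatives, horizontal-strabismus
patients), estimate every subject's deviation from its trace, and run the
full evaluation battery.  Every stochastic step derives its seed
deterministically from the global seed, so a report is fully regenerable
from its config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .deviation import (CalibrationModel, estimate_deviation, fit_calibration,
                        fit_refixation)
from .exceptions import ParameterError, StareError
from .gaze_io import GazeTrace, OcclusionSchedule, clean_trace
from .occlusion_sim import SimConfig, build_schedule, simulate_trace
from .screenstats import (CohortRecord, JitterConfig, bland_altman,
                          duration_auc_curve, jittered_roc, pearson_with_ci,
                          roc_auc)

logger = logging.getLogger("stare")

__all__ = ["RunConfig", "ScreeningReport", "run_screening",
           "simulate_calibration_runs", "simulate_cohort"]

PRISM_GRID = (0.0, 1.0, 2.0, 3.0, 5.0, 6.0, 12.0, 15.0, 30.0, 40.0)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a synthetic end-to-end screening study.

    The defaults mirror the study design the package models: 7 orthotropic
    controls calibrated over a 0-40 PD prism grid, then a validation cohort
    of the same controls plus patients with horizontal deviations and two
    vertical-only patients (negatives), each tested for 60 s at 120 Hz.
    """

    seed: int = 0
    n_controls: int = 7
    prism_grid: tuple[float, ...] = PRISM_GRID
    n_patients: int = 17
    patient_pd_range: tuple[float, float] = (5.0, 40.0)
    n_vertical_only: int = 2
    model_form: str = "linear_through_origin"
    eye_policy: str = "mean_of_eyes"
    duration_windows: tuple[float, ...] = tuple(float(w) for w
                                                in range(2, 61, 2))
    n_boot: int = 20000
    jitter_sims: int = 1000
    exclude: tuple[str, ...] = ()
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1:
            raise ParameterError("need >= 1 control and >= 1 patient")
        if len(self.prism_grid) < 3:
            raise ParameterError("prism grid needs >= 3 strengths")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from a global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def simulate_calibration_runs(config: RunConfig) -> pd.DataFrame:
    """Simulate each control at each prism strength and fit the amplitudes.

    Returns the calibration table ``control_id, prism_pd, amplitude_mm``.
    """
    seeds = iter(_child_seeds(config.seed,
                              config.n_controls * len(config.prism_grid)))
    rows = []
    for c in range(config.n_controls):
        for strength in config.prism_grid:
            sim = replace(config.sim, deviation_pd=float(strength),
                          seed=next(seeds))
            schedule = build_schedule(sim.duration)
            trace = clean_trace(simulate_trace(sim, schedule))
            fit = fit_refixation(trace, schedule)
            rows.append({"control_id": f"C{c + 1}",
                         "prism_pd": float(strength),
                         "amplitude_mm": fit.amplitude(config.eye_policy)})
    return pd.DataFrame(rows)


def simulate_cohort(config: RunConfig
                    ) -> list[tuple[str, float, bool, GazeTrace,
                                    OcclusionSchedule]]:
    """Simulate the validation cohort's test runs.

    Returns (subject_id, reference_pd, label, trace, schedule) per subject:
    controls and vertical-only patients at 0 PD horizontal (negatives), and
    patients with horizontal deviations drawn uniformly from the configured
    range, alternating eso/exo (positives).
    """
    n_neg = config.n_controls + config.n_vertical_only
    n_total = n_neg + config.n_patients
    seeds = _child_seeds(config.seed + 1, n_total + 1)
    rng = np.random.default_rng(seeds[-1])
    lo, hi = config.patient_pd_range
    true_pds = np.sort(rng.uniform(lo, hi, config.n_patients))
    subjects = []
    k = 0
    for c in range(config.n_controls):
        subjects.append((f"CTRL{c + 1}", 0.0, False, seeds[k]))
        k += 1
    for v in range(config.n_vertical_only):
        subjects.append((f"VERT{v + 1}", 0.0, False, seeds[k]))
        k += 1
    for p, true_pd in enumerate(true_pds):
        subjects.append((f"PAT{p + 1}", float(true_pd), True, seeds[k]))
        k += 1
    out = []
    for i, (sid, true_pd, label, seed) in enumerate(subjects):
        direction = "eso" if i % 2 == 0 else "exo"
        sim = replace(config.sim, deviation_pd=true_pd, direction=direction,
                      seed=seed)
        schedule = build_schedule(sim.duration)
        trace = clean_trace(simulate_trace(sim, schedule))
        out.append((sid, true_pd, label, trace, schedule))
    return out


@dataclass
class ScreeningReport:
    """Aggregated study results plus the provenance needed to regenerate them."""

    calibration: dict
    estimates: list[dict]
    roc: dict
    jitter: dict
    duration: dict
    agreement: dict
    correlation: dict
    min_specificity: dict
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_screening(config: RunConfig,
                  prevalence: float = 0.0193) -> ScreeningReport:
    """Run the full synthetic screening study and assemble the report.

    Stages: simulate + calibrate on controls, simulate the validation cohort,
    estimate each subject's deviation, then evaluate (ROC, jittered ROC,
    duration curve, Bland-Altman, Pearson correlation, minimum referral
    specificity at the given strabismus prevalence).
    """
    stage = "calibration"
    try:
        runs = simulate_calibration_runs(config)
        calibration = fit_calibration(runs, config.model_form)
        logger.info("calibration: %d runs, %s slope(s) %s",
                    len(runs), config.model_form, calibration.parameters)

        stage = "cohort simulation"
        cohort = simulate_cohort(config)
        logger.info("cohort: %d subjects simulated", len(cohort))

        stage = "estimation"
        records: list[CohortRecord] = []
        estimates = []
        for sid, true_pd, label, trace, schedule in cohort:
            fit = fit_refixation(trace, schedule)
            est = estimate_deviation(fit, calibration, config.eye_policy)
            records.append(CohortRecord(sid, true_pd, est.deviation_pd,
                                        label))
            estimates.append({"subject_id": sid, "reference_pd": true_pd,
                              "stare_pd": est.deviation_pd,
                              "amplitude_mm": est.amplitude_mm,
                              "label": bool(label),
                              "extrapolated": est.extrapolated})
            logger.debug("estimate %s: %.2f PD (true %.2f)", sid,
                         est.deviation_pd, true_pd)

        stage = "ROC"
        roc = roc_auc(records)

        stage = "jittered ROC"
        jit_seed, boot_seed = _child_seeds(config.seed + 2, 2)
        jitter = jittered_roc(records, JitterConfig(
            sigma=None, n_sims=config.jitter_sims, seed=jit_seed))

        stage = "duration analysis"
        duration = duration_auc_curve(
            [(tr, sch, lab) for _, _, lab, tr, sch in cohort],
            calibration, config.duration_windows, config.eye_policy)

        stage = "agreement"
        agreement = bland_altman(records, exclude=config.exclude,
                                 n_boot=config.n_boot, seed=boot_seed)
        r, r_ci = pearson_with_ci(records, n_boot=config.n_boot,
                                  seed=boot_seed)

        stage = "referral arithmetic"
        from .screenstats import min_specificity_for_prevalence
        s_min = min_specificity_for_prevalence(prevalence, 1.0)
    except StareError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    cfg_dict = asdict(config)
    report = ScreeningReport(
        calibration={"model_form": calibration.model_form,
                     "parameters": calibration.parameters,
                     "fit_residual_rms": calibration.fit_residual_rms,
                     "mean_amplitudes": calibration.source.to_dict("list")},
        estimates=estimates,
        roc={"auc": roc.auc,
             "sensitivity_at_full_specificity":
                 roc.sensitivity_at_full_specificity},
        jitter={"sigma_pd": jitter.sigma, "n_sims": jitter.n_sims,
                "mean_auc": jitter.mean_auc,
                "mean_sensitivity_at_full_specificity":
                    jitter.mean_sensitivity_at_full_specificity},
        duration={"window_seconds": duration.window_seconds.tolist(),
                  "auc_per_window": duration.auc_per_window.tolist()},
        agreement={"bias_pd": agreement.bias, "loa_low": agreement.loa_low,
                   "loa_high": agreement.loa_high, "cor_pd": agreement.cor,
                   "n": agreement.n, "n_boot": agreement.n_boot,
                   "ci": {k: list(v) for k, v in agreement.ci.items()},
                   "excluded_ids": list(agreement.excluded_ids)},
        correlation={"pearson_r": r, "ci": list(r_ci)},
        min_specificity={"prevalence": prevalence, "exact": s_min,
                         "percent_rounded": round(100.0 * s_min)},
        provenance={"package_version": __version__, "seed": config.seed,
                    "config": cfg_dict},
    )
    return report
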