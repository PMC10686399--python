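"""Cohort-level screening statistics.

Given per-subject deviation estimates, a clinical reference measurement
(alternate prism cover test, PD) and a binary horizontal-strabismus label,
this module computes the screening-evaluation battery: ROC/AUC with
sensitivity at full specificity, a jittered-ROC robustness simulation,
AUC as a function of test duration, Bland-Altman agreement with bootstrap
confidence intervals, Pearson correlation, and the prevalence-based minimum
referral specificity.

Labelling convention: positives are subjects with a horizontal deviation;
orthotropic controls and subjects with purely vertical deviations are
negatives.  The agreement sign convention is estimate minus reference, so a
positive bias means the automated test overestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .deviation import CalibrationModel, estimate_deviation, fit_refixation
from .exceptions import ParameterError
from .gaze_io import GazeTrace, OcclusionSchedule

__all__ = ["CohortRecord", "ROCResult", "JitterConfig", "JitterResult",
           "AgreementResult", "DurationCurve", "roc_auc", "jittered_roc",
           "duration_auc_curve", "bland_altman", "pearson_with_ci",
           "min_specificity_for_prevalence"]


@dataclass(frozen=True)
class CohortRecord:
    """One subject: reference deviation, automated estimate, and label."""

    subject_id: str
    reference_pd: float
    stare_pd: float
    has_horizontal_strabismus: bool

    def __post_init__(self) -> None:
        if self.stare_pd < 0:
            raise ParameterError("stare_pd must be >= 0")


def _scores_labels(records: Sequence[CohortRecord]
                   ) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([r.stare_pd for r in records], dtype=float)
    labels = np.array([r.has_horizontal_strabismus for r in records],
                      dtype=bool)
    return scores, labels


@dataclass
class ROCResult:
    """ROC curve with AUC and the sensitivity achievable at 100% specificity.

    The 100%-specificity operating point uses the smallest threshold strictly
    above every negative score; subjects tied with the highest negative score
    are called negative (the conservative, deterministic convention).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    sensitivity_at_full_specificity: float


def roc_auc(records: Sequence[CohortRecord]) -> ROCResult:
    """ROC analysis of the estimate as a screening score.

    AUC equals the Mann-Whitney probability that a random positive scores
    above a random negative, ties counting one half.
    """
    scores, labels = _scores_labels(records)
    if labels.all() or not labels.any():
        raise ParameterError("need at least one positive and one negative")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    neg_max = scores[~labels].max()
    sens_full_spec = float(np.mean(scores[labels] > neg_max))
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                     auc=auc,
                     sensitivity_at_full_specificity=sens_full_spec)


@dataclass(frozen=True)
class JitterConfig:
    """Configuration of the jittered-ROC robustness simulation.

    sigma : float or None
        SD of the Gaussian jitter added to every estimate (PD).  When None it
        is taken from the data: the sample SD of the estimates among the
        negative (control) subjects — the spread one would see retesting
        deviation-free eyes.
    """

    sigma: float | None = None
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if self.n_sims < 1:
            raise ParameterError("n_sims must be >= 1")


@dataclass
class JitterResult:
    """Means across jitter simulations, plus the vertically averaged ROC."""

    sigma: float
    n_sims: int
    mean_auc: float
    mean_sensitivity_at_full_specificity: float
    aucs: np.ndarray = field(repr=False)
    fpr_grid: np.ndarray = field(repr=False)
    mean_tpr: np.ndarray = field(repr=False)

    @property
    def auc_mc_se(self) -> float:
        """Monte-Carlo standard error of the mean AUC."""
        if self.aucs.size < 2:
            return 0.0
        return float(np.std(self.aucs, ddof=1) / np.sqrt(self.aucs.size))


_FPR_GRID = np.linspace(0.0, 1.0, 1001)


def _tpr_on_grid(labels: np.ndarray, scores: np.ndarray,
                 grid: np.ndarray) -> np.ndarray:
    """Step-function TPR at each grid FPR (max TPR with FPR <= grid value)."""
    fpr, tpr, _ = roc_curve(labels, scores)
    idx = np.searchsorted(fpr, grid, side="right") - 1
    return tpr[np.clip(idx, 0, len(tpr) - 1)]


def jittered_roc(records: Sequence[CohortRecord],
                 config: JitterConfig = JitterConfig()) -> JitterResult:
    """Re-run the ROC analysis after Gaussian jitter of every estimate.

    Each simulation adds i.i.d. N(0, sigma) noise to every subject's
    estimate, clamps at 0 (estimates are non-negative by construction) and
    recomputes the ROC.  Reported are the mean AUC, the mean sensitivity at
    full specificity, and the mean ROC by vertical averaging of sensitivity
    on a fixed 1001-point false-positive-rate grid.
    """
    scores, labels = _scores_labels(records)
    if labels.all() or not labels.any():
        raise ParameterError("need at least one positive and one negative")
    sigma = config.sigma
    if sigma is None:
        neg = scores[~labels]
        if neg.size < 2:
            raise ParameterError("cannot infer sigma from < 2 negatives")
        sigma = float(np.std(neg, ddof=1))
    if sigma == 0:  # degenerate jitter: identical to the raw ROC
        raw = roc_auc(records)
        return JitterResult(sigma=0.0, n_sims=config.n_sims,
                            mean_auc=raw.auc,
                            mean_sensitivity_at_full_specificity=
                            raw.sensitivity_at_full_specificity,
                            aucs=np.full(config.n_sims, raw.auc),
                            fpr_grid=_FPR_GRID.copy(),
                            mean_tpr=_tpr_on_grid(labels, scores, _FPR_GRID))
    rng = np.random.default_rng(config.seed)
    aucs = np.empty(config.n_sims)
    sens = np.empty(config.n_sims)
    tprs = np.empty((config.n_sims, _FPR_GRID.size))
    for i in range(config.n_sims):
        jittered = np.maximum(scores + rng.normal(0.0, sigma, scores.size),
                              0.0)
        aucs[i] = roc_auc_score(labels, jittered)
        neg_max = jittered[~labels].max()
        sens[i] = np.mean(jittered[labels] > neg_max)
        tprs[i] = _tpr_on_grid(labels, jittered, _FPR_GRID)
    return JitterResult(sigma=sigma, n_sims=config.n_sims,
                        mean_auc=float(aucs.mean()),
                        mean_sensitivity_at_full_specificity=float(
                            sens.mean()),
                        aucs=aucs, fpr_grid=_FPR_GRID.copy(),
                        mean_tpr=tprs.mean(axis=0))


@dataclass
class DurationCurve:
    """Screening AUC as a function of the analysed test duration."""

    window_seconds: np.ndarray
    auc_per_window: np.ndarray


def duration_auc_curve(subjects: Iterable[tuple[GazeTrace, OcclusionSchedule,
                                                bool]],
                       calibration: CalibrationModel,
                       windows: Sequence[float] = tuple(range(2, 61, 2)),
                       eye_policy: str = "mean_of_eyes") -> DurationCurve:
    """Screening AUC when only the first N seconds of each trace are used.

    For each window the deviation of every subject is re-estimated from the
    truncated trace (whole occlusion cycles only) and the ROC recomputed.
    """
    subjects = list(subjects)
    windows = np.asarray(sorted(windows), dtype=float)
    if windows.size == 0:
        raise ParameterError("need at least one window")
    aucs = np.empty(windows.size)
    for j, w in enumerate(windows):
        recs = []
        for i, (trace, schedule, label) in enumerate(subjects):
            if w < schedule.cycle_period:
                raise ParameterError(
                    f"window {w} s is below one cycle "
                    f"({schedule.cycle_period} s)")
            fit = fit_refixation(trace, schedule, window=float(w))
            est = estimate_deviation(fit, calibration, eye_policy)
            recs.append(CohortRecord(str(i), np.nan, est.deviation_pd,
                                     bool(label)))
        aucs[j] = roc_auc(recs).auc
    return DurationCurve(window_seconds=windows, auc_per_window=aucs)


@dataclass
class AgreementResult:
    """Bland-Altman agreement between the automated and reference tests.

    ``bias`` is the mean of (estimate - reference); ``loa_low``/``loa_high``
    are bias -/+ 1.96 SD (the 95% limits of agreement); ``cor`` is the 95%
    coefficient of repeatability 1.96 SD.  ``ci`` maps each statistic name to
    its percentile-bootstrap 95% confidence interval.
    """

    bias: float
    loa_low: float
    loa_high: float
    cor: float
    n: int
    n_boot: int
    ci: dict[str, tuple[float, float]]
    excluded_ids: tuple[str, ...] = ()


def bland_altman(records: Sequence[CohortRecord],
                 exclude: Iterable[str] = (),
                 n_boot: int = 20000, seed: int = 0) -> AgreementResult:
    """Bland-Altman bias, limits of agreement and coefficient of repeatability.

    Differences are estimate minus reference.  95% CIs for every statistic
    come from a percentile bootstrap with `n_boot` resamples.  `exclude`
    names subjects dropped before analysis (outlier handling is manual and
    explicit; no automated rejection rule is applied).
    """
    exclude = tuple(exclude)
    kept = [r for r in records if r.subject_id not in exclude]
    if len(kept) < 3:
        raise ParameterError("need at least 3 pairs after exclusion")
    d = np.array([r.stare_pd - r.reference_pd for r in kept])
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    cor = 1.96 * sd
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = d[idx]
    b_bias = boots.mean(axis=1)
    b_sd = boots.std(ddof=1, axis=1)
    pct = lambda v: tuple(float(q) for q in np.percentile(v, [2.5, 97.5]))
    ci = {
        "bias": pct(b_bias),
        "loa_low": pct(b_bias - 1.96 * b_sd),
        "loa_high": pct(b_bias + 1.96 * b_sd),
        "cor": pct(1.96 * b_sd),
    }
    return AgreementResult(bias=bias, loa_low=bias - cor, loa_high=bias + cor,
                           cor=cor, n=n, n_boot=n_boot, ci=ci,
                           excluded_ids=exclude)


def pearson_with_ci(records: Sequence[CohortRecord],
                    n_boot: int = 20000, seed: int = 0
                    ) -> tuple[float, tuple[float, float]]:
    """Product-moment correlation between reference and estimate, with a
    percentile-bootstrap 95% CI."""
    if len(records) < 3:
        raise ParameterError("need at least 3 pairs")
    x = np.array([r.reference_pd for r in records])
    y = np.array([r.stare_pd for r in records])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    bx, by = x[idx], y[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((bx - bx.mean(axis=1, keepdims=True)) *
               (by - by.mean(axis=1, keepdims=True))).sum(axis=1)
        den = np.sqrt(((bx - bx.mean(axis=1, keepdims=True)) ** 2)
                      .sum(axis=1) *
                      ((by - by.mean(axis=1, keepdims=True)) ** 2)
                      .sum(axis=1))
        boot_r = num / den
    boot_r = boot_r[np.isfinite(boot_r)]
    lo, hi = np.percentile(boot_r, [2.5, 97.5])
    return r, (float(lo), float(hi))


def min_specificity_for_prevalence(prevalence: float,
                                   sensitivity: float = 1.0) -> float:
    """Minimum specificity for true-positive referrals to outnumber false
    positives at a given prevalence.

    Among N screened, expected true positives are sensitivity * prevalence *
    N and expected false positives (1 - specificity) * (1 - prevalence) * N;
    equating the two gives s* = 1 - sensitivity * p / (1 - p), clamped to
    [0, 1].  Below s*, false-positive referrals exceed true positives.
    """
    if not (0.0 < prevalence < 1.0):
        raise ParameterError("prevalence must lie in (0, 1)")
    if not (0.0 < sensitivity <= 1.0):
        raise ParameterError("sensitivity must lie in (0, 1]")
    s = 1.0 - sensitivity * prevalence / (1.0 - prevalence)
    return float(min(1.0, max(0.0, s)))
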