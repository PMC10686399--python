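"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: the sine-fit oracle is a
dense grid search over (amplitude, phase) with the offset profiled out, and
the AUC oracle is a direct pairwise Mann-Whitney count.
"""

import numpy as np


def grid_search_sine_fit(t, x, period=2.0, n_amp=401, n_phase=360,
                         amp_max=None):
    """Best (amplitude, phase) of a + A sin(2 pi t / period + phi) on a grid.

    For each phase the residual variance is quadratic in A, and the offset a
    is profiled out analytically (a = mean residual); the SSE is evaluated
    exactly on the full grid.  Returns (amplitude, phase, sse, amp_step).
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    n = t.size
    if amp_max is None:
        amp_max = 2.0 * max(np.ptp(x), 1e-6)
    amps = np.linspace(0.0, amp_max, n_amp)
    phases = np.linspace(0.0, 2.0 * np.pi, n_phase, endpoint=False)
    w = 2.0 * np.pi / period
    xc = x - x.mean()
    var_x = float(np.mean(xc ** 2))
    best = (0.0, 0.0, np.inf)
    for phi in phases:
        s = np.sin(w * t + phi)
        sc = s - s.mean()
        cov_xs = float(np.mean(xc * sc))
        var_s = float(np.mean(sc ** 2))
        # SSE(A)/n with offset profiled out: var_x - 2 A cov + A^2 var_s
        sse = n * (var_x - 2.0 * amps * cov_xs + amps ** 2 * var_s)
        k = int(np.argmin(sse))
        if sse[k] < best[2]:
            best = (float(amps[k]), float(phi), float(sse[k]))
    return (*best, float(amps[1] - amps[0]))


def pairwise_auc(pos, neg):
    """Mann-Whitney AUC by explicit pairwise comparison, ties count 1/2."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))
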