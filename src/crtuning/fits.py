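"""Difference-of-Gaussians frequency fits and Naka-Rushton contrast fits.

Frequency tuning (spatial or temporal) is fitted with
R(f) = a_exc exp(-f^2/(2 s_exc^2)) - a_inh exp(-f^2/(2 s_inh^2)),
a standard zero-centred DoG in linear frequency that produces low-pass and
band-pass shapes.  Half-maximum frequencies are interpolated on a dense log
grid of the fitted curve; a cell is low-pass when the fitted curve at the
lowest tested frequency stays above half the fitted maximum.

Contrast tuning is fitted with a Naka-Rushton curve
R(c) = baseline + r_max c^n/(c^n + c50^n) and C50 is the fitted c50
parameter.  Both fits use bounded trust-region least squares with a fixed
set of data-driven multi-starts.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import least_squares

log = logging.getLogger("crtuning")

N_STARTS = 5
_FIT_TOL = 1e-10
HALF_GRID_POINTS = 4000


@dataclasses.dataclass
class FrequencyFit:
    a_exc: float
    sigma_exc: float
    a_inh: float
    sigma_inh: float
    rss: float
    peak_freq: float
    peak_response: float
    halfmax_low: float        # nan when the curve never drops below half (low side)
    halfmax_high: float
    lowpass: bool
    ok: bool
    reason: str = ""


@dataclasses.dataclass
class ContrastFit:
    r_max: float
    exponent: float
    c50: float
    baseline: float
    rss: float
    ok: bool
    reason: str = ""


def dog(f, a_exc, sigma_exc, a_inh, sigma_inh):
    f = np.asarray(f, float)
    return (a_exc * np.exp(-f ** 2 / (2 * sigma_exc ** 2))
            - a_inh * np.exp(-f ** 2 / (2 * sigma_inh ** 2)))


def naka_rushton(c, r_max, n, c50, baseline=0.0):
    c = np.asarray(c, float)
    cn = c ** n
    return baseline + r_max * cn / (cn + c50 ** n)


def _best_fit(residual, starts, bounds):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            res = least_squares(residual, x0, bounds=bounds, method="trf",
                                xtol=_FIT_TOL, ftol=_FIT_TOL, gtol=_FIT_TOL)
        except Exception as e:     # pragma: no cover - optimizer edge
            log.debug("fit start failed: %s", e)
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_difference_of_gaussians(frequencies, mean_responses) -> FrequencyFit:
    """Fit the DoG and interpolate half-maximum frequencies.

    Requires >= 4 frequency levels.  The fitted curve is evaluated on a log
    grid over [min(f)/4, 4 max(f)]; halfmax_low/high are the outermost
    crossings of half the fitted maximum on either side of the peak, by
    linear interpolation.  lowpass is judged at the lowest *tested*
    frequency.
    """
    f = np.asarray(frequencies, float)
    y = np.asarray(mean_responses, float)
    if f.size < 4:
        raise ValueError("need at least 4 frequency levels")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.ptp(y) < 1e-12:
        return FrequencyFit(*[np.nan] * 9, lowpass=False, ok=False,
                            reason="flat responses")
    span = y.max() - y.min()
    fw = f[np.argmax(y)]
    starts = [
        [max(y.max(), 1e-6), max(fw, f.min()), 0.0, 4 * max(fw, f.min())],
        [max(y.max(), 1e-6) * 1.5, 2 * max(fw, f.min()),
         0.5 * max(y.max(), 1e-6), 6 * max(fw, f.min())],
        [max(y.max(), 1e-6), f.max(), 0.0, 8 * f.max()],
        [2 * max(y.max(), 1e-6), 0.5 * max(fw, f.min()),
         max(y.max(), 1e-6), max(fw, f.min())],
        [np.mean(np.abs(y)) + 1e-6, 100 * f.max(), 0.0, 200 * f.max()],  # ~constant
    ][:N_STARTS]
    hi_a = 10 * max(abs(y).max(), 1e-6)
    bounds = (np.array([0.0, f.min() / 100, 0.0, f.min() / 100]),
              np.array([hi_a, 1e3 * f.max(), hi_a, 1e3 * f.max()]))
    best = _best_fit(lambda p: dog(f, *p) - y, starts, bounds)
    if best is None:
        return FrequencyFit(*[np.nan] * 9, lowpass=False, ok=False,
                            reason="no start converged")
    a_e, s_e, a_i, s_i = best.x
    rss = float(2 * best.cost)
    grid = np.geomspace(f.min() / 4, f.max() * 4, HALF_GRID_POINTS)
    curve = dog(grid, *best.x)
    ipk = int(np.argmax(curve))
    peak_r = float(curve[ipk])
    if peak_r <= 0:
        return FrequencyFit(a_e, s_e, a_i, s_i, rss, np.nan, peak_r, np.nan,
                            np.nan, lowpass=False, ok=False,
                            reason="fitted maximum nonpositive")
    half = 0.5 * peak_r

    def _cross(idx_range, reverse):
        seq = idx_range[::-1] if reverse else idx_range
        for j in seq:
            lo_i, hi_i = (j, j + 1)
            if (curve[lo_i] - half) * (curve[hi_i] - half) <= 0 and curve[lo_i] != curve[hi_i]:
                t = (half - curve[lo_i]) / (curve[hi_i] - curve[lo_i])
                return float(grid[lo_i] + t * (grid[hi_i] - grid[lo_i]))
        return np.nan

    hm_low = _cross(range(0, ipk), reverse=True) if ipk > 0 else np.nan
    hm_high = _cross(range(ipk, len(grid) - 1), reverse=False)
    lowpass = bool(dog(f.min(), *best.x) > half)
    return FrequencyFit(a_e, s_e, a_i, s_i, rss, float(grid[ipk]), peak_r,
                        hm_low, hm_high, lowpass=lowpass, ok=True)


def fit_naka_rushton(contrasts, mean_responses, with_baseline=True) -> ContrastFit:
    """Bounded Naka-Rushton fit; c50 in (0, 100], exponent in (0.5, 6]."""
    c = np.asarray(contrasts, float)
    y = np.asarray(mean_responses, float)
    if c.size < 4:
        raise ValueError("need at least 4 contrast levels")
    if np.any((c <= 0) | (c > 100)):
        raise ValueError("contrasts must lie in (0, 100]")
    if np.ptp(y) < 1e-12:
        return ContrastFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False,
                           reason="flat responses (degenerate)")
    span = max(y.max() - y.min(), 1e-9)
    cmid = float(np.sqrt(c.min() * c.max()))
    starts = [
        [span, 2.0, cmid, y.min()],
        [span, 1.0, c.min() * 2, y.min()],
        [span, 4.0, c.max() / 2, y.min()],
        [2 * span, 2.0, cmid / 2, y.min() - 0.5 * span],
        [1e-9, 2.0, cmid, float(np.mean(y))],     # near-constant model
    ][:N_STARTS]
    lo_b = -10 * abs(y).max() - 1.0 if with_baseline else -1e-12
    hi_b = 10 * abs(y).max() + 1.0 if with_baseline else 1e-12
    bounds = (np.array([0.0, 0.5 + 1e-9, 1e-6, lo_b]),
              np.array([100 * span + 1.0, 6.0, 100.0, hi_b]))
    best = _best_fit(lambda p: naka_rushton(c, *p) - y, starts, bounds)
    if best is None:
        return ContrastFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False,
                           reason="no start converged")
    r_max, n, c50, base = best.x
    return ContrastFit(float(r_max), float(n), float(c50), float(base),
                       float(2 * best.cost), ok=True)
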