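"""Laminar-probe analysis: spike detection, rates, layers and laser effects.

Spikes are detected as negative threshold crossings at 3x a robust SD
estimate (median absolute value / 0.6745, resistant to spike contamination).
The trial rate is the mean firing rate over the full stimulus interval
(1.5 s batteries); the spontaneous rate is taken from the 0.5 s before
onset; "response" always means rate minus spontaneous rate.  Responses are
averaged over all directions; a unit is included when its maximum
condition-mean response reaches 2 Hz.  Recording sites split into layers by
depth order among visually responsive channels: lowest five deep, next
three middle, rest top.  Single- and multi-units are pooled.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import fits, stats, tuning

log = logging.getLogger("crtuning")

RATE_WINDOW_S = 1.5
SPONT_WINDOW_S = 0.5
MIN_RESPONSE_HZ = 2.0
SD_MULTIPLIER = 3.0
REFRACTORY_S = 1e-3
N_DEEP, N_MIDDLE = 5, 3


def robust_sd(x) -> float:
    """Median(|x|)/0.6745: robust Gaussian-noise SD in the presence of spikes."""
    return float(np.median(np.abs(np.asarray(x, float))) / 0.6745)


def detect_spikes(bandpassed_trace, sampling_rate_hz, sd_multiplier=SD_MULTIPLIER,
                  refractory_s=REFRACTORY_S) -> np.ndarray:
    """Negative threshold crossings at -k*SD with a refractory merge.

    One event per downward crossing of the threshold; crossings closer than
    the refractory interval merge into one event.
    """
    x = np.asarray(bandpassed_trace, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace must be finite")
    sd = robust_sd(x)
    if sd == 0:
        raise ValueError("zero-variance trace: no noise level to threshold")
    thr = -sd_multiplier * sd
    below = x < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if crossings.size == 0:
        return np.empty(0)
    t = crossings / sampling_rate_hz
    keep = np.concatenate([[True], np.diff(t) >= refractory_s])
    return t[keep]


def unit_responses(spike_times, protocol, rate_window_s: float | None = None,
                   spont_window_s: float = SPONT_WINDOW_S) -> pd.DataFrame:
    """Per-trial rate, spontaneous rate and response for one unit.

    rate = spikes in [onset, onset + stimulus duration) / duration;
    spontaneous = spikes in [onset - 0.5 s, onset) / 0.5 s;
    response = rate - spontaneous.
    """
    st = np.sort(np.asarray(spike_times, float))
    t = protocol.trials
    win = float(rate_window_s if rate_window_s is not None else protocol.stim_s)
    on = t["onset"].to_numpy(float)
    n_stim = np.searchsorted(st, on + win) - np.searchsorted(st, on)
    n_spont = np.searchsorted(st, on) - np.searchsorted(st, on - spont_window_s)
    out = t.loc[:, ["trial_index", "stimulus_id", "direction", "diameter",
                    "sf", "tf", "contrast", "laser_on"]].copy()
    out["rate"] = n_stim / win
    out["spontaneous_rate"] = n_spont / spont_window_s
    out["response"] = out["rate"] - out["spontaneous_rate"]
    return out


def condition_means(trials: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Mean response per (condition level, laser state), averaged over all
    directions and repetitions."""
    g = (trials.groupby([condition, "laser_on"])["response"]
         .mean().rename("response").reset_index())
    return g


def unit_included(trials: pd.DataFrame, condition: str) -> bool:
    """Inclusion: maximum condition-mean response >= 2 Hz."""
    cm = condition_means(trials, condition)
    return bool(cm["response"].max() >= MIN_RESPONSE_HZ)


def assign_layers(responsive_channel_indices, channel_depth_order=None) -> dict:
    """Label responsive channels deep/middle/top by depth order.

    Channels are ordered from the deepest site upward (channel index 0 =
    probe tip unless an explicit depth order is given); the five deepest
    responsive sites are 'deep', the next three 'middle', the rest 'top'.
    """
    idx = list(responsive_channel_indices)
    if not idx:
        raise ValueError("need at least one responsive channel")
    order = sorted(idx, key=(channel_depth_order.__getitem__
                             if channel_depth_order is not None else lambda c: c))
    labels = {}
    for pos, ch in enumerate(order):
        if pos < N_DEEP:
            labels[ch] = "deep"
        elif pos < N_DEEP + N_MIDDLE:
            labels[ch] = "middle"
        else:
            labels[ch] = "top"
    if len(order) < N_DEEP + N_MIDDLE + 1:
        log.warning("only %d responsive channels: top layer %s", len(order),
                    "empty" if len(order) <= N_DEEP + N_MIDDLE else "thin")
    return labels


def laser_modulation(unit_trials: dict, condition: str = "contrast"):
    """Population laser effect across units.

    Per unit: mean response per laser state over all condition levels;
    percent change = 100 (on - off)/off (units with nonpositive off response
    are excluded from the percentage but kept in the paired test); per-unit
    Friedman test blocks the condition levels against the two laser states.
    Population test: Wilcoxon signed rank on paired (on, off) means.

    Returns (per-unit DataFrame, population GroupTestResult, mean % change).
    """
    rows = []
    for uid, trials in unit_trials.items():
        cm = condition_means(trials, condition)
        piv = cm.pivot(index=condition, columns="laser_on", values="response")
        piv = piv.sort_index(axis=1)     # columns ordered [False, True]
        if list(piv.columns) != [False, True]:
            raise ValueError("laser_modulation needs interleaved laser on/off trials")
        off = float(piv[False].mean())
        onm = float(piv[True].mean())
        pct = 100.0 * (onm - off) / off if off > 0 else np.nan
        if off <= 0:
            log.info("unit %s: nonpositive laser-off response; excluded from "
                     "percent change (kept for the paired test)", uid)
        fr = stats.friedman_test(piv.to_numpy())
        rows.append(dict(unit_id=uid, mean_off=off, mean_on=onm,
                         percent_change=pct, friedman_p=fr.p_value,
                         modulated=fr.p_value < 0.05))
    per_unit = pd.DataFrame(rows)
    pop = stats.compare_two_groups(per_unit["mean_on"], per_unit["mean_off"],
                                   paired=True)
    mean_pct = float(per_unit["percent_change"].mean(skipna=True))
    return per_unit, pop, mean_pct


def tuning_under_laser(trials: pd.DataFrame, kind: str):
    """Per-laser-state C50 (contrast battery) or SI (size battery).

    Delegates to the contrast fit and the size-tuning rule on
    direction-averaged condition means, independently per laser state.
    Returns dict with keys c50_on/c50_off or si_on/si_off (nan on a
    degenerate fit).
    """
    out = {}
    for state, tag in ((False, "off"), (True, "on")):
        sub = trials[trials["laser_on"] == state]
        if kind == "contrast":
            cm = sub.groupby("contrast")["response"].mean()
            fit = fits.fit_naka_rushton(cm.index.to_numpy(), cm.to_numpy())
            out[f"c50_{tag}"] = fit.c50 if fit.ok else np.nan
        elif kind == "size":
            cm = sub.groupby("diameter")["response"].mean()
            curve = tuning.TuningCurve(cm.index.to_numpy(), cm.to_numpy(),
                                       np.zeros(len(cm)), np.ones(len(cm), int))
            si, *_ = tuning.size_tuning(curve)
            out[f"si_{tag}"] = si
        else:
            raise ValueError(f"unknown battery kind {kind!r}")
    return out
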