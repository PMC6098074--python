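"""ROI trace extraction, dF/F and trial responses for calcium sessions.

dF/F is computed per trial against the mean fluorescence in a window just
before stimulus onset; the trial response is the mean dF/F from 0.5 s after
onset to stimulus offset.  Cells pass the responsiveness gate when a
one-sided t-test of responses against pooled pre-onset baseline samples is
significant at the 0.1 level and the maximum stimulus-averaged response is
at least 5% dF/F.  No neuropil correction is applied anywhere.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("crtuning")

RESPONSE_DELAY_S = 0.5       # response window starts this long after onset
BASELINE_WINDOW_S = 1.0      # dF/F baseline: mean F over this window pre-onset


class BaselineError(ValueError):
    """Raised when a trial's baseline fluorescence is nonpositive."""


def extract_roi_traces(frame_stack: np.ndarray, roi_table: pd.DataFrame) -> np.ndarray:
    """Mean pixel value inside each circular ROI, per frame.

    A pixel belongs to the ROI when its centre lies within the circle.
    Returns an array (n_rois, n_frames).
    """
    frames = np.asarray(frame_stack)
    _, h, w = frames.shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.empty((len(roi_table), frames.shape[0]))
    for i, row in enumerate(roi_table.itertuples()):
        if not (0 <= row.y < h and 0 <= row.x < w):
            raise ValueError(f"ROI {row.cell_id} centre outside the image")
        mask = (yy - row.y) ** 2 + (xx - row.x) ** 2 <= row.radius ** 2
        if not mask.any():
            raise ValueError(f"ROI {row.cell_id} covers zero pixels")
        out[i] = frames[:, mask].mean(axis=1)
    return out


@dataclasses.dataclass
class TrialDff:
    trial_index: int
    stimulus_id: int
    baseline_f0: float
    baseline_dff: np.ndarray   # pre-onset frames, dF/F units
    times: np.ndarray          # frame start times relative to onset (stim part)
    dff: np.ndarray            # dF/F of frames with start time in [0, offset-onset)


def compute_dff(trace: np.ndarray, protocol, frame_rate: float,
                baseline_window_s: float = BASELINE_WINDOW_S) -> list[TrialDff]:
    """Per-trial dF/F segments.

    F0 is the mean raw fluorescence over frames whose start time falls in
    [onset - baseline_window, onset); dF/F = (F - F0)/F0.  Frames are
    assigned to windows by their start time (half-open intervals).  A trial
    with F0 <= 0 raises BaselineError so the caller can exclude the cell.
    """
    trace = np.asarray(trace, float)
    frame_t = np.arange(trace.size) / frame_rate
    out = []
    for row in protocol.trials.itertuples():
        base = (frame_t >= row.onset - baseline_window_s) & (frame_t < row.onset)
        if not base.any():
            raise ValueError("baseline window contains no frames; frame rate too low")
        f0 = float(trace[base].mean())
        if f0 <= 0:
            raise BaselineError(
                f"trial {row.trial_index}: nonpositive baseline F0={f0:.3g}")
        stim = (frame_t >= row.onset) & (frame_t < row.offset)
        out.append(TrialDff(
            trial_index=int(row.trial_index), stimulus_id=int(row.stimulus_id),
            baseline_f0=f0, baseline_dff=(trace[base] - f0) / f0,
            times=frame_t[stim] - row.onset, dff=(trace[stim] - f0) / f0))
    return out


def trial_responses(segments: list[TrialDff], protocol,
                    response_delay_s: float = RESPONSE_DELAY_S) -> pd.DataFrame:
    """ResponseTable rows for one cell: scalar response per trial.

    response = mean dF/F over frames with start time in
    [onset + delay, offset); raises if the window holds no frame.
    """
    stim_s = protocol.stim_s
    if stim_s <= response_delay_s:
        raise ValueError(f"stimulus duration {stim_s} s must exceed the "
                         f"{response_delay_s} s response delay")
    rows = []
    for seg in segments:
        sel = seg.times >= response_delay_s
        if not sel.any():
            raise ValueError(f"trial {seg.trial_index}: no frames in response window")
        assert seg.times[sel].min() >= response_delay_s  # never pre-onset frames
        rows.append((seg.trial_index, seg.stimulus_id, float(seg.dff[sel].mean()),
                     seg.baseline_f0))
    out = pd.DataFrame(rows, columns=["trial_index", "stimulus_id", "response",
                                      "baseline_f0"])
    t = protocol.trials.set_index("trial_index")
    for col in ("direction", "diameter", "sf", "tf", "contrast",
                "patch_x", "patch_y", "laser_on"):
        out[col] = t.loc[out["trial_index"], col].to_numpy()
    return out


def max_stimulus_response(table: pd.DataFrame) -> float:
    """Maximum over per-stimulus mean responses (the '5%' quantity)."""
    return float(table.groupby("stimulus_id")["response"].mean().max())


def responsiveness(table: pd.DataFrame, baseline_samples: np.ndarray,
                   alpha: float = 0.1, min_max_response: float = 0.05,
                   apply_max_gate: bool = True):
    """Responsiveness gate: one-sided Welch t-test of responses vs baseline.

    All trials of all stimuli are pooled against the pooled pre-onset
    baseline dF/F samples.  Returns (responsive, p_value, max_response).
    Zero variance in both samples with equal means yields p = 1.
    """
    resp = table["response"].to_numpy(float)
    base = np.asarray(baseline_samples, float)
    if resp.size < 2 or base.size < 2:
        raise ValueError("need at least 2 responses and 2 baseline samples")
    if np.var(resp) == 0 and np.var(base) == 0 and resp.mean() == base.mean():
        log.info("responsiveness: zero variance and equal means; p=1 by convention")
        p = 1.0
    else:
        p = float(sps.ttest_ind(resp, base, equal_var=False, alternative="greater").pvalue)
        if np.isnan(p):
            p = 1.0
    mx = max_stimulus_response(table)
    ok = p < alpha and (not apply_max_gate or mx >= min_max_response)
    return bool(ok), p, mx


def pooled_baseline(segments: list[TrialDff]) -> np.ndarray:
    return np.concatenate([s.baseline_dff for s in segments]) if segments else np.empty(0)
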