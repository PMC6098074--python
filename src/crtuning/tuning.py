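"""Selectivity and suppression metrics derived from tuning curves.

OSI is the length of the response-weighted resultant vector in doubled
stimulus angle divided by the summed response (equal to 1 - circular
variance); DSI is the same measure in undoubled angle.  The suppression
index follows the 95%-of-maximum rule: R_preferred is the response to the
smallest diameter reaching 95% of the maximum, SI = (R_pref - R_largest) /
R_pref.  Negative mean responses are clamped to zero before any of these
indices (dF/F can be negative; the index formulas presuppose nonnegative
mass), and each clamp is logged.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

log = logging.getLogger("crtuning")

PIX_PER_DEG = 10.0            # 100 px on the stimulus screen ~ 10 deg
SIZE_MAX_ORI_DIFF = 30.0      # deg, inclusion for size analyses (inclusive)
SIZE_MAX_RF_DIST = 10.0       # deg, RF centre to stimulus centre (inclusive)
SF_MAX_ORI_DIFF = 60.0        # deg, inclusion for SF analyses (inclusive)
PREF_THRESHOLD = 0.95         # fraction of max defining the preferred size


@dataclasses.dataclass
class TuningCurve:
    """Mean response per stimulus level, with SEM and trial counts."""
    values: np.ndarray         # stimulus levels (deg, deg diameter, cpd, Hz or %)
    mean: np.ndarray
    sem: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.mean = np.asarray(self.mean, float)
        if not (len(self.values) == len(self.mean) == len(self.sem) == len(self.n_trials)):
            raise ValueError("TuningCurve fields must have equal length")


def curve_from_table(table: pd.DataFrame, by: str) -> TuningCurve:
    """Aggregate a ResponseTable into a tuning curve over column `by`."""
    g = table.groupby(by)["response"]
    mean = g.mean()
    sem = g.sem().fillna(0.0)
    n = g.count()
    return TuningCurve(values=mean.index.to_numpy(float), mean=mean.to_numpy(),
                       sem=sem.to_numpy(), n_trials=n.to_numpy())


def _clamped(mean, cell_id=None):
    m = np.asarray(mean, float)
    if (m < 0).any():
        log.debug("clamping %d negative mean responses to 0%s",
                  int((m < 0).sum()), f" (cell {cell_id})" if cell_id is not None else "")
    return np.clip(m, 0.0, None)


def _resultant(curve: TuningCurve, angle_multiplier: float, cell_id=None) -> float:
    r = _clamped(curve.mean, cell_id)
    total = r.sum()
    if total <= 0:
        return np.nan
    phi = np.radians(curve.values) * angle_multiplier
    return float(np.abs(np.sum(r * np.exp(1j * phi))) / total)


def orientation_selectivity(curve: TuningCurve, cell_id=None) -> float:
    """OSI = |sum R(phi) e^{2i phi}| / sum R(phi); nan when all mass is zero."""
    if len(curve.values) < 2:
        raise ValueError("need at least 2 direction levels")
    return _resultant(curve, 2.0, cell_id)


def direction_selectivity(curve: TuningCurve, cell_id=None) -> float:
    """DSI = |sum R(phi) e^{i phi}| / sum R(phi)."""
    if len(curve.values) < 2:
        raise ValueError("need at least 2 direction levels")
    return _resultant(curve, 1.0, cell_id)


def preferred_stimulus(curve: TuningCurve):
    """(preferred direction, preferred orientation) by argmax of mean response.

    Ties break toward the lowest stimulus angle; orientation is direction
    mod 180.
    """
    if len(curve.values) == 0 or np.all(np.isnan(curve.mean)):
        raise ValueError("empty or all-missing tuning curve")
    order = np.argsort(curve.values, kind="stable")
    vals, means = curve.values[order], curve.mean[order]
    pref = float(vals[np.nanargmax(means)])
    return pref, pref % 180.0


def size_tuning(curve: TuningCurve, cell_id=None):
    """(SI, preferred diameter, R_preferred, R_largest) from a size curve.

    R_preferred is the mean response at the smallest diameter reaching 95%
    of the maximum mean response; R_largest the response at the largest
    diameter.  Returns nans when the maximum response is nonpositive.
    """
    d = np.asarray(curve.values, float)
    if len(d) < 3 or np.any(np.diff(d) <= 0):
        raise ValueError("size curve needs >= 3 strictly increasing diameters")
    r = _clamped(curve.mean, cell_id)
    mx = r.max()
    if mx <= 0:
        return np.nan, np.nan, np.nan, np.nan
    idx = int(np.argmax(r >= PREF_THRESHOLD * mx))
    r_pref, r_large = float(r[idx]), float(r[-1])
    si = (r_pref - r_large) / r_pref
    assert si <= 1.0 + 1e-12
    return float(si), float(d[idx]), r_pref, r_large


def rf_center(grid_responses, patch_centers):
    """Response-weighted centre of mass of patch locations (deg).

    Negative responses are clamped to zero; all-nonpositive responses give
    a flagged (nan, nan) centre.
    """
    r = _clamped(grid_responses)
    centers = np.asarray(patch_centers, float)
    if r.sum() <= 0:
        return np.nan, np.nan
    w = r / r.sum()
    return float(w @ centers[:, 0]), float(w @ centers[:, 1])


def orientation_difference(a: float, b: float) -> float:
    """Circular orientation difference on [0, 90] deg."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def select_cells(metrics: pd.DataFrame, presented_orientation: float,
                 stimulus_center, analysis_kind: str) -> pd.Series:
    """Inclusion flags for size or SF analyses (inclusive boundaries).

    size: preferred orientation within 30 deg of the presented orientation
    and RF centre within 10 deg of the stimulus centre.  sf: orientation
    within 60 deg.  Missing RF centres exclude a cell from size analyses.
    """
    dori = metrics["pref_orientation"].map(
        lambda o: orientation_difference(o, presented_orientation))
    if analysis_kind == "size":
        dist = np.hypot(metrics["rf_x"] - stimulus_center[0],
                        metrics["rf_y"] - stimulus_center[1])
        missing = dist.isna()
        if missing.any():
            log.info("select_cells(size): %d cells excluded for missing RF centre",
                     int(missing.sum()))
        return (dori <= SIZE_MAX_ORI_DIFF) & (dist <= SIZE_MAX_RF_DIST) & ~missing
    if analysis_kind == "sf":
        return dori <= SF_MAX_ORI_DIFF
    raise ValueError(f"unknown analysis kind {analysis_kind!r}")


def pixels_to_degrees(px: float, pix_per_deg: float = PIX_PER_DEG) -> float:
    """Screen pixels to visual degrees with the fixed 100 px ~ 10 deg factor."""
    return px / pix_per_deg
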