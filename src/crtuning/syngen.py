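"""Ground-truth simulator for two-photon and laminar-probe sessions.

Generates populations of model V1 neurons (a "marked" calretinin-like
subpopulation and an "unmarked" rest), drifting-grating stimulus protocols,
Poisson spike trains, calcium-indicator fluorescence traces, rendered movie
frames and 16-channel laminar ephys sessions.  Every observable the analysis
modules measure (OSI, DSI, surround suppression, SF/TF tuning, C50, laser
gain) has a generator-side ground-truth parameter here.

The forward rate model is factorised:

    rate = [baseline + rate_max * f_dir * f_size * f_sf * f_tf * f_contrast] * laser_gain

with a doubled-angle von Mises orientation factor, a smooth direction lobe,
an integrated excitatory-minus-inhibitory Gaussian size factor,
difference-of-Gaussians spatial/temporal frequency factors and a
Naka-Rushton contrast factor.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import erf, i0, i0e, i1, i1e

log = logging.getLogger("crtuning")

# --------------------------------------------------------------------------
# stimulus batteries and timing defaults
# --------------------------------------------------------------------------
FRAME_RATE_2P = 7.0                      # two-photon scan rate, frames/s
DIRECTIONS_CA = tuple(float(d) for d in range(0, 360, 30))    # 12 directions
DIRECTIONS_EPHYS = tuple(float(d) for d in range(0, 360, 45)) # 8 directions
SIZES_CA = (20.0, 40.0, 60.0, 80.0, 100.0)            # patch diameters, deg
SIZES_EPHYS = (10.0, 25.0, 40.0, 60.0, 90.0, 120.0)
SF_BATTERY = (0.01, 0.021, 0.044, 0.092, 0.191, 0.4)  # cpd
TF_BATTERY = (1.0, 3.0, 8.0, 12.0, 16.0, 20.0)        # Hz
CONTRASTS_CA = (2.5, 5.0, 10.0, 20.0, 40.0, 80.0)     # %
CONTRASTS_EPHYS = (10.0, 30.0, 50.0, 70.0, 90.0)      # %
STIM_S_CA, ITI_S_CA = 2.0, 3.0          # 2 s grating, 3 s grey
STIM_S_EPHYS, ITI_S_EPHYS = 1.5, 1.0
BASE_SF, BASE_TF, BASE_CONTRAST = 0.05, 2.0, 90.0     # defaults unless varied
FULLSCREEN = np.inf                      # diameter code for full-screen gratings
RF_GRID_SHAPE = (6, 3)                   # columns x rows of patch locations
RF_GRID_X = tuple(np.linspace(-37.5, 37.5, 6))        # deg
RF_GRID_Y = (-17.0, 0.0, 17.0)
RF_PATCH_DIAMETER = 15.0

PROTOCOL_KINDS = ("orientation", "size", "sf", "tf", "contrast", "rf_grid",
                  "ephys_contrast", "ephys_size")

# seed-derivation stage order (documented contract: one global seed expands
# into per-stage children via numpy SeedSequence.spawn in this fixed order)
_STAGES = ("population", "protocol", "spikes", "fluorescence", "movie", "ephys")


class ConfigError(ValueError):
    """Raised for unknown protocol kinds or invalid generator settings."""


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    if stage not in _STAGES:
        raise ConfigError(f"unknown seed stage {stage!r}")
    return np.random.SeedSequence(seed).spawn(len(_STAGES))[_STAGES.index(stage)]


# --------------------------------------------------------------------------
# ground-truth cells
# --------------------------------------------------------------------------
@dataclasses.dataclass(frozen=True)
class GroundTruthCell:
    """Generator-side tuning parameters of a single model neuron.

    The marked flag distinguishes the calretinin-like subpopulation; it is
    frozen together with the rest of the record.
    """
    cell_id: int
    marked: bool
    depth_um: float
    pref_direction: float      # deg in [0, 360)
    kappa_ori: float           # von Mises concentration (doubled angle), >= 0
    dir_bias: float            # opposite-lobe weight in [0, 1]
    rf_x: float                # receptive-field centre, screen deg
    rf_y: float
    sigma_exc: float           # excitatory Gaussian extent, deg
    sigma_inh: float           # inhibitory (surround) extent, deg
    inh_weight: float          # inhibitory weight in [0, 1)
    sf_sigma: float            # centre-Gaussian extent of the SF factor, cpd
    sf_inh_ratio: float        # surround amplitude ratio in [0, 1)
    sf_inh_scale: float        # surround/centre sigma ratio (< 1: cuts low f)
    tf_sigma: float            # Hz
    tf_inh_ratio: float
    tf_inh_scale: float
    c50_true: float            # % contrast in (0, 100)
    nr_exponent: float         # Naka-Rushton exponent, > 0
    rate_max: float            # Hz, >= 0
    rate_baseline: float       # Hz, >= 0
    laser_gain: float = 1.0    # multiplicative factor when laser on

    def __post_init__(self):
        if not (0.0 <= self.dir_bias <= 1.0):
            raise ValueError("dir_bias must lie in [0, 1]")
        if not (0.0 < self.c50_true < 100.0):
            raise ValueError("c50_true must lie in (0, 100)")
        if min(self.rate_max, self.rate_baseline, self.kappa_ori) < 0:
            raise ValueError("rates and kappa_ori must be nonnegative")
        if self.laser_gain <= 0:
            raise ValueError("laser_gain must be positive")


def osi_to_kappa(osi: float) -> float:
    """Invert the von Mises resultant I1(k)/I0(k) = OSI."""
    if osi <= 0:
        return 0.0
    osi = min(osi, 0.999)
    return brentq(lambda k: i1e(k) / i0e(k) - osi, 1e-12, 1e4, xtol=1e-10)


def dsi_to_bias(dsi_target: float, kappa: float) -> float:
    """Opposite-lobe weight b giving the requested continuous-curve DSI.

    With the smooth cosine lobe w(d) = b + (1-b)(1+cos d)/2 the circular
    moments give DSI = (1-b)(1+A)/(2(1+b)), A = I1(kappa)/I0(kappa); the
    formula inverts in closed form.  Targets above the b=0 maximum (1+A)/2
    are clamped to b = 0.
    """
    A = i1(kappa) / i0(kappa)
    t = 2.0 * dsi_target / (1.0 + A)
    if t >= 1.0:
        return 0.0
    return (1.0 - t) / (1.0 + t)


def _beta_from_moments(mean, sd, rng, size):
    """Beta draws with the requested mean and sd (variance clipped feasible)."""
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    var = min(sd ** 2, 0.9 * mean * (1 - mean))
    nu = mean * (1 - mean) / var - 1.0
    return rng.beta(mean * nu, (1 - mean) * nu, size=size)


# population defaults: group means follow the study conditions the analysis
# is meant to recover (marked cells less orientation selective and less
# surround suppressed; all other tuning parameters shared between groups).
POPULATION_DEFAULTS = dict(
    n_marked=65, n_unmarked=173,
    osi_mean_marked=0.18, osi_sd_marked=0.16,     # 0.02 * sqrt(65)
    osi_mean_unmarked=0.25, osi_sd_unmarked=0.13, # 0.01 * sqrt(173)
    si_mean_marked=0.27, si_sd_marked=0.22,       # 0.06 * sqrt(13)
    si_mean_unmarked=0.41, si_sd_unmarked=0.24,   # 0.04 * sqrt(36)
    dsi_mean=0.175, dsi_sd=0.14,
    depth_range_um=[120.0, 350.0],
    rf_scatter_deg=5.0,
    # frequency tuning: difference-of-Gaussians in linear frequency, narrow
    # surround (scale < 1) cutting the low frequencies of band-pass cells
    sf_sigma_median=0.10, sf_sigma_sigma=0.4,     # lognormal, cpd
    tf_sigma_median=5.0, tf_sigma_sigma=0.4,      # Hz
    freq_inh_ratio_range=[0.25, 0.95],
    freq_inh_scale_range=[0.15, 0.5],
    c50_median=15.0, c50_sigma=0.3,               # %
    nr_exponent_range=[1.5, 3.5],
    sigma_exc_median=9.0, sigma_exc_sigma=0.35,   # deg
    sigma_inh_factor_range=[2.0, 3.5],
    rate_max_median=8.0, rate_max_sigma=0.5,      # Hz
    rate_baseline_median=1.5, rate_baseline_sigma=0.6,
    laser_gain=1.0,
)


def _size_curve(diams, sigma_exc, sigma_inh, w):
    r = np.asarray(diams, float) / 2.0
    e = erf(r / (np.sqrt(2.0) * sigma_exc))
    i = erf(r / (np.sqrt(2.0) * sigma_inh))
    return np.clip(e - w * i, 0.0, None)


def _si_of_weight(w, sigma_exc, sigma_inh, sizes):
    resp = _size_curve(sizes, sigma_exc, sigma_inh, w)
    mx = resp.max()
    if mx <= 0:
        return 1.0
    pref_idx = int(np.argmax(resp >= 0.95 * mx))
    rp = resp[pref_idx]
    return (rp - resp[-1]) / rp


def _weight_for_si(si_target, sigma_exc, sigma_inh, sizes):
    lo, hi = 0.0, 0.995
    if _si_of_weight(lo, sigma_exc, sigma_inh, sizes) >= si_target:
        return lo
    if _si_of_weight(hi, sigma_exc, sigma_inh, sizes) <= si_target:
        return hi
    return brentq(lambda w: _si_of_weight(w, sigma_exc, sigma_inh, sizes) - si_target,
                  lo, hi, xtol=1e-6)


def generate_population(seed: int, params: Mapping | None = None) -> pd.DataFrame:
    """Draw a ground-truth population as a DataFrame (one row per cell).

    Group structure: the marked group has lower mean true OSI and lower mean
    true SI; DSI, SF, TF and C50 parameters are drawn from the same
    distributions in both groups.  The drawn parameters are asserted to
    respect that ordering.
    """
    p = dict(POPULATION_DEFAULTS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ConfigError(f"unknown population parameters: {sorted(unknown)}")
        p.update(params)
    rng = np.random.default_rng(stage_seed(seed, "population"))
    n_m, n_u = int(p["n_marked"]), int(p["n_unmarked"])
    n = n_m + n_u
    marked = np.zeros(n, bool)
    marked[:n_m] = True

    osi = np.empty(n)
    osi[:n_m] = _beta_from_moments(p["osi_mean_marked"], p["osi_sd_marked"], rng, n_m)
    osi[n_m:] = _beta_from_moments(p["osi_mean_unmarked"], p["osi_sd_unmarked"], rng, n_u)
    si = np.empty(n)
    si[:n_m] = _beta_from_moments(p["si_mean_marked"], p["si_sd_marked"], rng, n_m)
    si[n_m:] = _beta_from_moments(p["si_mean_unmarked"], p["si_sd_unmarked"], rng, n_u)
    dsi = _beta_from_moments(p["dsi_mean"], p["dsi_sd"], rng, n)

    kappa = np.array([osi_to_kappa(v) for v in osi])
    bias = np.array([dsi_to_bias(d, k) for d, k in zip(dsi, kappa)])
    depth = rng.uniform(*p["depth_range_um"], size=n)
    pref_dir = rng.uniform(0.0, 360.0, size=n)
    rf = rng.normal(0.0, p["rf_scatter_deg"], size=(n, 2))
    sf_sigma = p["sf_sigma_median"] * np.exp(rng.normal(0, p["sf_sigma_sigma"], n))
    tf_sigma = p["tf_sigma_median"] * np.exp(rng.normal(0, p["tf_sigma_sigma"], n))
    sf_ratio = rng.uniform(*p["freq_inh_ratio_range"], size=n)
    sf_scale = rng.uniform(*p["freq_inh_scale_range"], size=n)
    tf_ratio = rng.uniform(*p["freq_inh_ratio_range"], size=n)
    tf_scale = rng.uniform(*p["freq_inh_scale_range"], size=n)
    c50 = np.clip(p["c50_median"] * np.exp(rng.normal(0, p["c50_sigma"], n)), 2.0, 90.0)
    nr_n = rng.uniform(*p["nr_exponent_range"], size=n)
    # excitatory extents clipped so the size battery reaches its asymptote
    # and the suppression target stays reachable
    sig_e = np.clip(p["sigma_exc_median"] * np.exp(rng.normal(0, p["sigma_exc_sigma"], n)),
                    2.0, 16.0)
    sig_i = sig_e * rng.uniform(*p["sigma_inh_factor_range"], size=n)
    w = np.array([_weight_for_si(s, se, si_, np.array(SIZES_CA))
                  for s, se, si_ in zip(si, sig_e, sig_i)])
    # ground truth is the SI the model actually realises on the battery
    si = np.array([_si_of_weight(wi, se, si_, np.array(SIZES_CA))
                   for wi, se, si_ in zip(w, sig_e, sig_i)])
    rmax = p["rate_max_median"] * np.exp(rng.normal(0, p["rate_max_sigma"], n))
    rbase = p["rate_baseline_median"] * np.exp(rng.normal(0, p["rate_baseline_sigma"], n))

    sf_truth = np.array([freq_truth(s, r, sc, SF_BATTERY[0])
                         for s, r, sc in zip(sf_sigma, sf_ratio, sf_scale)],
                        dtype=object)
    tf_truth = np.array([freq_truth(s, r, sc, TF_BATTERY[0])
                         for s, r, sc in zip(tf_sigma, tf_ratio, tf_scale)],
                        dtype=object)
    df = pd.DataFrame(dict(
        cell_id=np.arange(n), marked=marked, depth_um=depth,
        pref_direction=pref_dir, kappa_ori=kappa, dir_bias=bias,
        rf_x=rf[:, 0], rf_y=rf[:, 1],
        sigma_exc=sig_e, sigma_inh=sig_i, inh_weight=w,
        sf_sigma=sf_sigma, sf_inh_ratio=sf_ratio, sf_inh_scale=sf_scale,
        tf_sigma=tf_sigma, tf_inh_ratio=tf_ratio, tf_inh_scale=tf_scale,
        c50_true=c50, nr_exponent=nr_n, rate_max=rmax, rate_baseline=rbase,
        laser_gain=np.full(n, float(p["laser_gain"])),
        osi_true=osi, dsi_true=dsi, si_true=si,
        sf_peak_true=[t[0] for t in sf_truth],
        sf_halfmax_true=[t[1] for t in sf_truth],
        sf_lowpass_true=[t[2] for t in sf_truth],
        tf_peak_true=[t[0] for t in tf_truth],
        tf_halfmax_true=[t[1] for t in tf_truth],
    ))
    if min(n_m, n_u) >= 30 and p["osi_mean_marked"] < p["osi_mean_unmarked"]:
        # group structure holds on the drawn parameters at study-scale sizes
        assert df.loc[df.marked, "osi_true"].mean() < df.loc[~df.marked, "osi_true"].mean()
        assert df.loc[df.marked, "si_true"].mean() < df.loc[~df.marked, "si_true"].mean()
    return df


def cell_from_row(row) -> GroundTruthCell:
    fields = [f.name for f in dataclasses.fields(GroundTruthCell)]
    return GroundTruthCell(**{f: row[f] if f != "cell_id" else int(row[f])
                              for f in fields if f != "marked"},
                           marked=bool(row["marked"]))


# --------------------------------------------------------------------------
# stimulus protocols
# --------------------------------------------------------------------------
@dataclasses.dataclass
class StimulusProtocol:
    """Ordered trial table for one stimulus battery.

    trials columns: trial_index, stimulus_id, direction, diameter, sf, tf,
    contrast, patch_x, patch_y, laser_on, onset, offset.  Trials are
    block-shuffled: within each block every unique stimulus appears exactly
    once, in seeded pseudorandom order.
    """
    kind: str
    trials: pd.DataFrame
    stim_s: float
    iti_s: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        return float(self.trials["offset"].iloc[-1]) if self.n_trials else 0.0

    def to_csv(self, path):
        self.trials.to_csv(path, index=False)


def _battery(kind: str, params: Mapping) -> pd.DataFrame:
    """Unique-stimulus table (one row per distinct stimulus in a block)."""
    d = dict(direction=np.nan, diameter=FULLSCREEN, sf=BASE_SF, tf=BASE_TF,
             contrast=BASE_CONTRAST, patch_x=np.nan, patch_y=np.nan, laser_on=False)
    d.update({k: v for k, v in params.items() if k in d})
    if kind == "orientation":
        rows = [dict(d, direction=a) for a in DIRECTIONS_CA]
    elif kind == "size":
        center = params.get("center", (0.0, 0.0))
        rows = [dict(d, diameter=s, direction=params.get("direction", 0.0),
                     patch_x=center[0], patch_y=center[1]) for s in SIZES_CA]
    elif kind == "sf":
        rows = [dict(d, sf=f, direction=params.get("direction", 0.0)) for f in SF_BATTERY]
    elif kind == "tf":
        rows = [dict(d, tf=f, direction=params.get("direction", 0.0)) for f in TF_BATTERY]
    elif kind == "contrast":
        rows = [dict(d, contrast=c, direction=params.get("direction", 0.0))
                for c in CONTRASTS_CA]
    elif kind == "rf_grid":
        rows = [dict(d, diameter=RF_PATCH_DIAMETER, direction=params.get("direction", 0.0),
                     patch_x=x, patch_y=y) for y in RF_GRID_Y for x in RF_GRID_X]
    elif kind == "ephys_contrast":
        rows = [dict(d, contrast=c, direction=a, laser_on=bool(l))
                for c in CONTRASTS_EPHYS for a in DIRECTIONS_EPHYS for l in (0, 1)]
    elif kind == "ephys_size":
        center = params.get("center", (0.0, 0.0))
        rows = [dict(d, diameter=s, direction=a, laser_on=bool(l),
                     patch_x=center[0], patch_y=center[1])
                for s in SIZES_EPHYS for a in DIRECTIONS_EPHYS for l in (0, 1)]
    else:
        raise ConfigError(f"unknown protocol kind {kind!r}; expected one of {PROTOCOL_KINDS}")
    out = pd.DataFrame(rows)
    out.insert(0, "stimulus_id", np.arange(len(out)))
    return out


def build_protocol(kind: str, total_duration_s: float, seed: int,
                   params: Mapping | None = None) -> StimulusProtocol:
    """Block-shuffled trial list for a named battery.

    Each trial occupies a slot of (iti + stim) seconds: grey screen then
    grating, so onset = slot_start + iti and offset - onset = stim duration.
    For ephys batteries laser-on and laser-off versions of every stimulus are
    part of the block, which interleaves them in a balanced way.
    """
    params = dict(params or {})
    if total_duration_s <= 0:
        raise ConfigError("total_duration_s must be positive")
    stim_s = params.pop("stim_s", STIM_S_EPHYS if kind.startswith("ephys") else STIM_S_CA)
    iti_s = params.pop("iti_s", ITI_S_EPHYS if kind.startswith("ephys") else ITI_S_CA)
    battery = _battery(kind, params)
    slot = stim_s + iti_s
    block_len = slot * len(battery)
    n_blocks = int(np.floor(total_duration_s / block_len))
    if n_blocks < 1:
        raise ConfigError(
            f"duration {total_duration_s} s too short for one {kind} block ({block_len} s)")
    rng = np.random.default_rng(seed)
    blocks = [battery.iloc[rng.permutation(len(battery))] for _ in range(n_blocks)]
    trials = pd.concat(blocks, ignore_index=True)
    trials.insert(0, "trial_index", np.arange(len(trials)))
    trials["onset"] = trials["trial_index"] * slot + iti_s
    trials["offset"] = trials["onset"] + stim_s
    return StimulusProtocol(kind=kind, trials=trials, stim_s=stim_s, iti_s=iti_s)


# --------------------------------------------------------------------------
# forward rate model
# --------------------------------------------------------------------------
def _dir_factor(cell, direction):
    d = np.radians(np.asarray(direction, float) - cell.pref_direction)
    vm = np.exp(cell.kappa_ori * (np.cos(2 * d) - 1.0))
    lobe = cell.dir_bias + (1.0 - cell.dir_bias) * (1.0 + np.cos(d)) / 2.0
    out = vm * lobe
    return np.where(np.isnan(d), 1.0, out)


def _size_factor(cell, diameter, patch_x, patch_y):
    diameter = np.asarray(diameter, float)
    full = ~np.isfinite(diameter)
    dense = np.linspace(1.0, 200.0, 400)
    peak = _size_curve(dense, cell.sigma_exc, cell.sigma_inh, cell.inh_weight).max()
    if peak <= 0:
        return np.zeros_like(diameter, float)
    resp = _size_curve(np.where(full, 200.0, diameter),
                       cell.sigma_exc, cell.sigma_inh, cell.inh_weight) / peak
    dx = np.asarray(patch_x, float) - cell.rf_x
    dy = np.asarray(patch_y, float) - cell.rf_y
    dist2 = dx ** 2 + dy ** 2
    sigma_rf = np.maximum(cell.sigma_exc, np.where(full, np.inf, diameter) / 4.0)
    att = np.where(np.isnan(dist2) | full, 1.0, np.exp(-dist2 / (2 * sigma_rf ** 2)))
    return resp * att


def _freq_curve(f, sigma, ratio, scale):
    f = np.asarray(f, float)
    g = (np.exp(-f ** 2 / (2.0 * sigma ** 2))
         - ratio * np.exp(-f ** 2 / (2.0 * (sigma * scale) ** 2)))
    return np.clip(g, 0.0, None)


def _freq_factor(f, sigma, ratio, scale):
    dense = np.geomspace(sigma / 100.0, sigma * 8.0, 400)
    peak = _freq_curve(dense, sigma, ratio, scale).max()
    if peak <= 0:
        return np.zeros_like(np.asarray(f, float))
    return _freq_curve(f, sigma, ratio, scale) / peak


def freq_truth(sigma, ratio, scale, f_lowest):
    """Realised (peak frequency, high half-max frequency, lowpass flag) of a
    generator frequency factor, from a dense grid."""
    dense = np.geomspace(min(sigma / 100.0, f_lowest / 4), sigma * 8.0, 4000)
    c = _freq_curve(dense, sigma, ratio, scale)
    ipk = int(np.argmax(c))
    half = 0.5 * c[ipk]
    hm = np.nan
    for j in range(ipk, len(dense) - 1):
        if (c[j] - half) * (c[j + 1] - half) <= 0 and c[j] != c[j + 1]:
            t = (half - c[j]) / (c[j + 1] - c[j])
            hm = float(dense[j] + t * (dense[j + 1] - dense[j]))
            break
    lowpass = bool(_freq_curve(np.array([f_lowest]), sigma, ratio, scale)[0] > half)
    return float(dense[ipk]), hm, lowpass


def _contrast_factor(cell, contrast):
    c = np.asarray(contrast, float)
    cn = c ** cell.nr_exponent
    return cn / (cn + cell.c50_true ** cell.nr_exponent)


def tuning_rate(cell: GroundTruthCell, direction=np.nan, diameter=FULLSCREEN,
                sf=BASE_SF, tf=BASE_TF, contrast=BASE_CONTRAST,
                patch_x=np.nan, patch_y=np.nan, laser_on=False):
    """Expected firing rate (Hz) of a cell for the given stimulus parameters.

    Any intermediate negative size factor (inhibition exceeding excitation at
    large sizes) is clamped to zero inside the size model.
    """
    drive = (_dir_factor(cell, direction)
             * _size_factor(cell, diameter, patch_x, patch_y)
             * _freq_factor(sf, cell.sf_sigma, cell.sf_inh_ratio, cell.sf_inh_scale)
             * _freq_factor(tf, cell.tf_sigma, cell.tf_inh_ratio, cell.tf_inh_scale)
             * _contrast_factor(cell, contrast))
    rate = cell.rate_baseline + cell.rate_max * drive
    gain = np.where(np.asarray(laser_on, bool), cell.laser_gain, 1.0)
    return np.maximum(rate * gain, 0.0)


def expected_rates(cell: GroundTruthCell, protocol: StimulusProtocol) -> np.ndarray:
    t = protocol.trials
    return tuning_rate(cell, direction=t["direction"].to_numpy(),
                       diameter=t["diameter"].to_numpy(), sf=t["sf"].to_numpy(),
                       tf=t["tf"].to_numpy(), contrast=t["contrast"].to_numpy(),
                       patch_x=t["patch_x"].to_numpy(), patch_y=t["patch_y"].to_numpy(),
                       laser_on=t["laser_on"].to_numpy())


# --------------------------------------------------------------------------
# spikes and fluorescence
# --------------------------------------------------------------------------
def simulate_spikes(cell: GroundTruthCell, protocol: StimulusProtocol, seed,
                    t_end: float | None = None) -> np.ndarray:
    """Homogeneous-Poisson spike times for one cell over a protocol.

    Within each trial the rate is the forward-model rate; between trials the
    cell fires at its spontaneous rate.  The grey period preceding a trial
    inherits that trial's laser state (the laser is on during the
    pre-stimulus interval of laser trials).
    """
    rng = np.random.default_rng(seed)
    t = protocol.trials
    t_end = float(t_end if t_end is not None else protocol.duration_s)
    rates = expected_rates(cell, protocol)
    edges, seg_rates = [], []
    prev = 0.0
    for i in range(len(t)):
        on, off = t["onset"].iloc[i], t["offset"].iloc[i]
        gain = cell.laser_gain if t["laser_on"].iloc[i] else 1.0
        if on > prev:
            edges.append((prev, on))
            seg_rates.append(cell.rate_baseline * gain)
        edges.append((on, off))
        seg_rates.append(rates[i])
        prev = off
    if t_end > prev:
        edges.append((prev, t_end))
        seg_rates.append(cell.rate_baseline)
    out = []
    for (a, b), r in zip(edges, seg_rates):
        if r <= 0 or b <= a:
            continue
        k = rng.poisson(r * (b - a))
        if k:
            out.append(a + (b - a) * np.sort(rng.random(k)))
    return np.sort(np.concatenate(out)) if out else np.empty(0)


def spikes_to_fluorescence(spike_times, duration_s, amplitude_per_spike,
                           decay_tau_s, baseline_f0, noise_sd, frame_rate=FRAME_RATE_2P,
                           seed=0, clamp=False) -> np.ndarray:
    """Linear indicator forward model: each spike adds an exponential transient.

    A spike at time s contributes amplitude * exp(-(t_f - s)/tau) to every
    frame time t_f >= s.  Gaussian noise of sd noise_sd is added per frame.
    """
    if decay_tau_s <= 0 or frame_rate <= 0 or baseline_f0 <= 0:
        raise ValueError("tau, frame_rate and baseline_f0 must be positive")
    n_frames = int(round(duration_s * frame_rate))
    frame_t = np.arange(n_frames) / frame_rate
    impulse = np.zeros(n_frames)
    st = np.asarray(spike_times, float)
    st = st[(st >= 0) & (st < duration_s)]
    if st.size:
        j0 = np.ceil(st * frame_rate - 1e-9).astype(int)
        ok = j0 < n_frames
        j0, stv = j0[ok], st[ok]
        init = amplitude_per_spike * np.exp(-(frame_t[j0] - stv) / decay_tau_s)
        np.add.at(impulse, j0, init)
    decay = np.exp(-1.0 / (frame_rate * decay_tau_s))
    transient = lfilter([1.0], [1.0, -decay], impulse)
    rng = np.random.default_rng(seed)
    trace = baseline_f0 + transient
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, n_frames)
    return np.clip(trace, 0.0, None) if clamp else trace


# --------------------------------------------------------------------------
# movie rendering
# --------------------------------------------------------------------------
def place_cells(n_cells, field_of_view_px, cell_radius_px, seed,
                max_attempts=1000) -> np.ndarray:
    """Non-overlapping cell centres (>= 2 radii apart), rejection-sampled."""
    rng = np.random.default_rng(seed)
    h, w = field_of_view_px
    r = cell_radius_px
    centers = []
    for _ in range(n_cells):
        for attempt in range(max_attempts):
            c = rng.uniform([r, r], [h - r, w - r])
            if all(np.hypot(*(c - o)) >= 2 * r for o in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError(f"could not place {n_cells} non-overlapping cells "
                               f"in {field_of_view_px} after {max_attempts} attempts")
    return np.array(centers)


def render_movie(traces: np.ndarray, marked: Sequence[bool], field_of_view_px,
                 cell_radius_px, seed, background=0.0):
    """Render traces as disks on a frame stack.

    Every frame is background plus, per cell, a filled disk whose pixels
    carry that cell's trace sample.  Returns (frames [T,H,W] float32, ROI
    table with centres/radii and the marked flag).
    """
    traces = np.asarray(traces, float)
    n_cells, n_frames = traces.shape
    centers = place_cells(n_cells, field_of_view_px, cell_radius_px, seed)
    h, w = field_of_view_px
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.full((n_frames, h, w), float(background), np.float32)
    for i, (cy, cx) in enumerate(centers):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px ** 2
        frames[:, mask] += traces[i][:, None].astype(np.float32)
    roi = pd.DataFrame(dict(cell_id=np.arange(n_cells), y=centers[:, 0],
                            x=centers[:, 1], radius=float(cell_radius_px),
                            marked=np.asarray(marked, bool)))
    return frames, roi


# --------------------------------------------------------------------------
# laminar ephys sessions
# --------------------------------------------------------------------------
def simulate_ephys_session(population: pd.DataFrame, protocol: StimulusProtocol,
                           seed, n_channels=16, channel_spacing_um=50.0,
                           tip_depth_um=800.0):
    """Poisson spiking of a unit population on a laminar probe.

    Units are assigned to channels round-robin (channel 0 = probe tip, the
    deepest site; depth from tip = index * spacing).  A unit's laser_gain
    multiplies its rate on laser-on trials (and the preceding grey period).
    Returns (spikes: dict unit_id -> times, units table, channels table).
    """
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    unit_ids = population["cell_id"].to_numpy()
    children = root.spawn(len(unit_ids))
    channel = np.arange(len(unit_ids)) % n_channels
    spikes = {}
    for row_i, (uid, ss) in enumerate(zip(unit_ids, children)):
        cell = cell_from_row(population.iloc[row_i])
        spikes[int(uid)] = simulate_spikes(cell, protocol, ss)
    units = pd.DataFrame(dict(unit_id=unit_ids, channel_index=channel,
                              laser_gain=population["laser_gain"].to_numpy()))
    idx = np.arange(n_channels)
    channels = pd.DataFrame(dict(channel_index=idx,
                                 depth_from_tip_um=idx * channel_spacing_um,
                                 depth_um=tip_depth_um - idx * channel_spacing_um))
    return spikes, units, channels


# --------------------------------------------------------------------------
# session container (HDF5)
# --------------------------------------------------------------------------
def _write_frame(group, name, df: pd.DataFrame):
    sub = group.create_group(name)
    sub.attrs["columns"] = list(df.columns)
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object:
            data = data.astype("S")
        sub.create_dataset(col, data=data, track_times=False)


def _read_frame(group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    out = {}
    for col in cols:
        v = group[col][()]
        if v.dtype.kind == "S":
            v = v.astype(str)
        out[col] = v
    return pd.DataFrame(out)


def write_session(path, *, seed, config_yaml="", ground_truth=None,
                  calcium=None, ephys=None, channels=None, frame_rate=FRAME_RATE_2P):
    """Write a session container.

    calcium: dict kind -> dict(traces=2D array cells x frames, cell_ids=…,
    protocol=StimulusProtocol).  ephys: dict kind -> dict(spikes=dict,
    units=DataFrame, protocol=StimulusProtocol).
    """
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["seed"] = int(seed)
        f.attrs["config_yaml"] = config_yaml
        f.attrs["frame_rate"] = float(frame_rate)
        if ground_truth is not None:
            _write_frame(f, "ground_truth", ground_truth)
        if channels is not None:
            _write_frame(f, "channels", channels)
        if calcium:
            g = f.create_group("calcium")
            for kind, d in calcium.items():
                gk = g.create_group(kind)
                gk.attrs["stim_s"] = d["protocol"].stim_s
                gk.attrs["iti_s"] = d["protocol"].iti_s
                gk.create_dataset("traces", data=np.asarray(d["traces"]),
                                  track_times=False)
                gk.create_dataset("cell_ids", data=np.asarray(d["cell_ids"], int),
                                  track_times=False)
                _write_frame(gk, "protocol", d["protocol"].trials)
        if ephys:
            g = f.create_group("ephys")
            for kind, d in ephys.items():
                gk = g.create_group(kind)
                gk.attrs["stim_s"] = d["protocol"].stim_s
                gk.attrs["iti_s"] = d["protocol"].iti_s
                sp = gk.create_group("spikes")
                for uid, times in d["spikes"].items():
                    sp.create_dataset(str(uid), data=np.asarray(times, float),
                                      track_times=False)
                _write_frame(gk, "units", d["units"])
                _write_frame(gk, "protocol", d["protocol"].trials)


def load_session(path) -> dict:
    out = dict(calcium={}, ephys={})
    with h5py.File(path, "r") as f:
        out["seed"] = int(f.attrs["seed"])
        out["config_yaml"] = str(f.attrs.get("config_yaml", ""))
        out["frame_rate"] = float(f.attrs["frame_rate"])
        if "ground_truth" in f:
            out["ground_truth"] = _read_frame(f["ground_truth"])
        if "channels" in f:
            out["channels"] = _read_frame(f["channels"])
        for kind, gk in f.get("calcium", {}).items():
            out["calcium"][kind] = dict(
                traces=gk["traces"][()], cell_ids=gk["cell_ids"][()],
                protocol=StimulusProtocol(kind=kind, trials=_read_frame(gk["protocol"]),
                                          stim_s=float(gk.attrs["stim_s"]),
                                          iti_s=float(gk.attrs["iti_s"])))
        for kind, gk in f.get("ephys", {}).items():
            spikes = {int(k): gk["spikes"][k][()] for k in gk["spikes"]}
            out["ephys"][kind] = dict(
                spikes=spikes, units=_read_frame(gk["units"]),
                protocol=StimulusProtocol(kind=kind, trials=_read_frame(gk["protocol"]),
                                          stim_s=float(gk.attrs["stim_s"]),
                                          iti_s=float(gk.attrs["iti_s"])))
    return out
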