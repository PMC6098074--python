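"""Pipeline orchestration: config, simulate, analyze, report.

The pipeline mirrors the experimental workflow: a ground-truth population
is simulated through the stimulus batteries (orientation, receptive-field
grid, size, spatial/temporal frequency, contrast, plus laminar-probe
optogenetic sessions); the analysis then recovers responsiveness, tuning
metrics, fits, group statistics, the cluster scan and the laser-gain
report.  Every output table carries the config hash, and all randomness
derives from the single config seed, so a rerun reproduces outputs exactly.
"""
from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ephys as ephys_mod
from . import fits, stats, syngen, traces, tuning

log = logging.getLogger("crtuning")

CONFIG_DEFAULTS = dict(
    seed=0,
    population=dict(syngen.POPULATION_DEFAULTS),
    protocols=dict(
        orientation=dict(enabled=True, duration_s=300.0),
        rf_grid=dict(enabled=True, duration_s=270.0),
        size=dict(enabled=True, duration_s=300.0),
        sf=dict(enabled=True, duration_s=300.0),
        tf=dict(enabled=True, duration_s=300.0),
        contrast=dict(enabled=True, duration_s=300.0),
    ),
    indicator=dict(amplitude_per_spike_frac=0.2, decay_tau_s=1.8,
                   baseline_f0=1000.0, noise_sd_frac=0.03),
    validation=dict(n_cells=4),
    movie=dict(render=False, field_of_view_px=[96, 96], cell_radius_px=4,
               n_cells=8, background=20.0),
    ephys=dict(enabled=True, n_units=64, n_channels=16, channel_spacing_um=50.0,
               laser_gain_mean=0.93, laser_gain_sd=0.05,
               contrast_duration_s=1600.0, size_duration_s=960.0),
    analysis=dict(responsive_alpha=0.1, min_max_response=0.05,
                  osi_threshold=0.33, cluster_n_boot=2000, n_perm=2000,
                  baseline_window_s=1.0),
)


class PipelineConfig:
    """Validated nested configuration; unknown keys are rejected."""

    def __init__(self, overrides=None):
        self.data = copy.deepcopy(CONFIG_DEFAULTS)
        if overrides:
            self._merge(self.data, overrides, path="")

    def _merge(self, base, over, path):
        bad = [f"{path}{k}" for k in over if k not in base]
        if bad:
            raise syngen.ConfigError(f"unknown config keys: {bad}")
        for k, v in over.items():
            if isinstance(base[k], dict):
                if not isinstance(v, dict):
                    raise syngen.ConfigError(f"config key {path}{k} must be a mapping")
                self._merge(base[k], v, f"{path}{k}.")
            else:
                base[k] = v

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def __getitem__(self, k):
        return self.data[k]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _dump_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------
def _snap(angle, step):
    return float((np.round(angle / step) * step) % 360)


def cmd_simulate(config: PipelineConfig, out_dir) -> Path:
    """Simulate a full session to out_dir/session.h5 (plus manifest/CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    pop = syngen.generate_population(seed, config["population"])

    # the experiment optimises later batteries for one chosen marked cell
    if pop["marked"].any():
        chosen = pop[pop.marked].sort_values("rate_max").iloc[-1]
    else:
        log.warning("no marked cells in the population; optimising for an "
                    "unmarked cell instead")
        chosen = pop.sort_values("rate_max").iloc[-1]
    presented_dir = _snap(chosen["pref_direction"], 30.0)
    stim_center = (float(chosen["rf_x"]), float(chosen["rf_y"]))

    proto_seed_root = syngen.stage_seed(seed, "protocol")
    spike_root = syngen.stage_seed(seed, "spikes")
    fluor_root = syngen.stage_seed(seed, "fluorescence")
    kinds = [k for k, p in config["protocols"].items() if p["enabled"]]
    proto_children = proto_seed_root.spawn(len(kinds) + 2)
    params_by_kind = dict(
        orientation={}, rf_grid=dict(direction=presented_dir),
        size=dict(direction=presented_dir, center=stim_center),
        sf=dict(direction=presented_dir), tf=dict(direction=presented_dir),
        contrast=dict(direction=presented_dir))

    ind = config["indicator"]
    f0 = float(ind["baseline_f0"])
    amp = float(ind["amplitude_per_spike_frac"]) * f0
    noise_sd = float(ind["noise_sd_frac"]) * f0
    # cells for the paired calcium/spiking validation: strongest responders,
    # mostly marked (mirrors the targeted cell-attached recordings)
    n_val = int(config["validation"]["n_cells"])
    n_val_m = max(n_val - 1, 0) if (~pop["marked"]).any() else n_val
    val_rows = (list(pop[pop.marked].sort_values("rate_max").index[-n_val_m:])
                + list(pop[~pop.marked].sort_values("rate_max")
                       .index[-(n_val - n_val_m):] if n_val > n_val_m else []))
    val_rows = set(val_rows[:n_val])

    calcium = {}
    spike_children = spike_root.spawn(len(kinds))
    fluor_children = fluor_root.spawn(len(kinds))
    for ki, kind in enumerate(kinds):
        protocol = syngen.build_protocol(
            kind, config["protocols"][kind]["duration_s"],
            proto_children[ki], params_by_kind[kind])
        cells_seeds = spike_children[ki].spawn(len(pop))
        noise_seeds = fluor_children[ki].spawn(len(pop))
        traces_arr = np.empty((len(pop), int(round(protocol.duration_s
                                                   * syngen.FRAME_RATE_2P))))
        val_spikes = {}
        for i in range(len(pop)):
            cell = syngen.cell_from_row(pop.iloc[i])
            st = syngen.simulate_spikes(cell, protocol, cells_seeds[i])
            if i in val_rows:
                val_spikes[int(pop["cell_id"].iloc[i])] = st
            traces_arr[i] = syngen.spikes_to_fluorescence(
                st, protocol.duration_s, amp, float(ind["decay_tau_s"]), f0,
                noise_sd, seed=noise_seeds[i])
        calcium[kind] = dict(traces=traces_arr, cell_ids=pop["cell_id"].to_numpy(),
                             protocol=protocol, spikes=val_spikes)
        protocol.to_csv(out / f"protocol_{kind}.csv")

    ephys_data = {}
    channels = None
    if config["ephys"]["enabled"]:
        e = config["ephys"]
        rng = np.random.default_rng(syngen.stage_seed(seed, "ephys"))
        # pooled single/multi-units: robust multiunit-scale rates
        epop = syngen.generate_population(
            seed + 1, dict(n_marked=0, n_unmarked=int(e["n_units"]),
                           c50_median=30.0, rate_max_median=25.0,
                           rate_max_sigma=0.4, rate_baseline_median=4.0))
        epop["laser_gain"] = np.clip(
            rng.normal(e["laser_gain_mean"], e["laser_gain_sd"], len(epop)),
            0.05, 2.0)
        eproto_children = proto_children[len(kinds):]
        for kind, dur, child in (("ephys_contrast", e["contrast_duration_s"],
                                  eproto_children[0]),
                                 ("ephys_size", e["size_duration_s"],
                                  eproto_children[1])):
            protocol = syngen.build_protocol(kind, dur, child,
                                             dict(center=(0.0, 0.0)))
            spikes, units, channels = syngen.simulate_ephys_session(
                epop, protocol, syngen.stage_seed(seed, "ephys").spawn(2)[
                    0 if kind == "ephys_contrast" else 1],
                n_channels=int(e["n_channels"]),
                channel_spacing_um=float(e["channel_spacing_um"]))
            ephys_data[kind] = dict(spikes=spikes, units=units, protocol=protocol)
            protocol.to_csv(out / f"protocol_{kind}.csv")

    session_path = out / "session.h5"
    _write_session_with_val(session_path, seed, config, pop, calcium,
                            ephys_data, channels)

    if config["movie"]["render"]:
        import tifffile
        m = config["movie"]
        kind0 = kinds[0]
        frames, roi = syngen.render_movie(
            calcium[kind0]["traces"][: int(m["n_cells"])],
            pop["marked"].to_numpy()[: int(m["n_cells"])],
            tuple(m["field_of_view_px"]), m["cell_radius_px"],
            syngen.stage_seed(seed, "movie"), background=m["background"])
        tifffile.imwrite(out / "movie.tiff", frames.astype(np.float32))
        roi.to_csv(out / "movie_rois.csv", index=False)

    _dump_json(dict(config_hash=config.hash, seed=seed, version=__version__,
                    presented_direction=presented_dir,
                    stimulus_center=list(stim_center)), out / "manifest.json")
    (out / "config.yaml").write_text(config.to_yaml())
    return session_path


def _write_session_with_val(path, seed, config, pop, calcium, ephys_data, channels):
    import h5py
    syngen.write_session(path, seed=seed, config_yaml=config.to_yaml(),
                         ground_truth=pop, calcium=calcium, ephys=ephys_data,
                         channels=channels)
    with h5py.File(path, "a") as f:
        for kind, d in calcium.items():
            if d.get("spikes"):
                g = f[f"calcium/{kind}"].create_group("spikes")
                for uid, times in d["spikes"].items():
                    g.create_dataset(str(uid), data=np.asarray(times, float),
                                     track_times=False)
        f.attrs["config_hash"] = config.hash


def _load_session_with_val(path):
    import h5py
    session = syngen.load_session(path)
    with h5py.File(path, "r") as f:
        for kind in session["calcium"]:
            g = f[f"calcium/{kind}"]
            if "spikes" in g:
                session["calcium"][kind]["spikes"] = {
                    int(k): g["spikes"][k][()] for k in g["spikes"]}
        session["config_hash"] = str(f.attrs.get("config_hash", ""))
    return session


# --------------------------------------------------------------------------
# analyze
# --------------------------------------------------------------------------
def _cell_tables(entry, frame_rate, baseline_window_s):
    """ResponseTables for every cell of one calcium battery (None when the
    baseline is unusable)."""
    protocol = entry["protocol"]
    tables = {}
    for i, cid in enumerate(entry["cell_ids"]):
        try:
            segs = traces.compute_dff(entry["traces"][i], protocol, frame_rate,
                                      baseline_window_s)
        except traces.BaselineError as e:
            log.warning("cell %s excluded: %s", cid, e)
            tables[int(cid)] = None
            continue
        tables[int(cid)] = (traces.trial_responses(segs, protocol),
                            traces.pooled_baseline(segs))
    return tables


def cmd_analyze(session_path, config: PipelineConfig, out_dir) -> Path:
    """Analyze a simulated session into metrics, statistics and reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = _load_session_with_val(session_path)
    fr = session["frame_rate"]
    ana = config["analysis"]
    gt = session["ground_truth"]
    cal = session["calcium"]
    metrics = gt.loc[:, ["cell_id", "marked", "depth_um"]].copy()
    metrics = metrics.set_index("cell_id")
    for col in ("responsive", "p_responsive", "max_response", "osi", "dsi",
                "pref_direction", "pref_orientation", "rf_x", "rf_y", "si",
                "pref_diameter", "r_preferred", "r_largest", "sf_halfmax_high",
                "sf_lowpass", "tf_halfmax_high", "c50", "include_size",
                "include_sf"):
        metrics[col] = np.nan
    skipped = []

    # 1. responsiveness + orientation/direction selectivity
    if "orientation" in cal:
        tables = _cell_tables(cal["orientation"], fr, ana["baseline_window_s"])
        for cid, tb in tables.items():
            if tb is None:
                metrics.loc[cid, "responsive"] = 0.0
                continue
            table, baseline = tb
            ok, p, mx = traces.responsiveness(
                table, baseline, alpha=ana["responsive_alpha"],
                min_max_response=ana["min_max_response"])
            metrics.loc[cid, ["responsive", "p_responsive", "max_response"]] = \
                (float(ok), p, mx)
            if not ok:
                continue
            curve = tuning.curve_from_table(table, "direction")
            metrics.loc[cid, "osi"] = tuning.orientation_selectivity(curve, cid)
            metrics.loc[cid, "dsi"] = tuning.direction_selectivity(curve, cid)
            pd_, po = tuning.preferred_stimulus(curve)
            metrics.loc[cid, ["pref_direction", "pref_orientation"]] = (pd_, po)
    else:
        skipped.append("orientation")

    # 2. receptive-field centres
    if "rf_grid" in cal:
        tables = _cell_tables(cal["rf_grid"], fr, ana["baseline_window_s"])
        for cid, tb in tables.items():
            if tb is None:
                continue
            table, _ = tb
            g = table.groupby("stimulus_id").agg(
                response=("response", "mean"), x=("patch_x", "first"),
                y=("patch_y", "first"))
            cx, cy = tuning.rf_center(g["response"].to_numpy(),
                                      g[["x", "y"]].to_numpy())
            metrics.loc[cid, ["rf_x", "rf_y"]] = (cx, cy)
    else:
        skipped.append("rf_grid")

    responsive = metrics["responsive"].fillna(0).astype(bool)

    # 3. size tuning with the selection rules
    if "size" in cal:
        protocol = cal["size"]["protocol"]
        presented = float(protocol.trials["direction"].iloc[0]) % 180.0
        center = (float(protocol.trials["patch_x"].iloc[0]),
                  float(protocol.trials["patch_y"].iloc[0]))
        include = tuning.select_cells(metrics, presented, center, "size")
        metrics["include_size"] = include & responsive
        tables = _cell_tables(cal["size"], fr, ana["baseline_window_s"])
        for cid, tb in tables.items():
            if tb is None or not metrics.loc[cid, "include_size"]:
                continue
            curve = tuning.curve_from_table(tb[0], "diameter")
            si, pref_d, rp, rl = tuning.size_tuning(curve, cid)
            metrics.loc[cid, ["si", "pref_diameter", "r_preferred", "r_largest"]] = \
                (si, pref_d, rp, rl)
    else:
        skipped.append("size")

    # 4. SF / TF fits (inclusion: orientation within 60 deg) and contrast fits
    if "sf" in cal:
        protocol = cal["sf"]["protocol"]
        presented = float(protocol.trials["direction"].iloc[0]) % 180.0
        include = tuning.select_cells(metrics, presented, None, "sf")
        metrics["include_sf"] = include & responsive
        tables = _cell_tables(cal["sf"], fr, ana["baseline_window_s"])
        for cid, tb in tables.items():
            if tb is None or not metrics.loc[cid, "include_sf"]:
                continue
            curve = tuning.curve_from_table(tb[0], "sf")
            fit = fits.fit_difference_of_gaussians(curve.values, curve.mean)
            if fit.ok:
                metrics.loc[cid, ["sf_halfmax_high", "sf_lowpass"]] = \
                    (fit.halfmax_high, float(fit.lowpass))
    else:
        skipped.append("sf")
    if "tf" in cal:
        protocol = cal["tf"]["protocol"]
        presented = float(protocol.trials["direction"].iloc[0]) % 180.0
        include = tuning.select_cells(metrics, presented, None, "sf") & responsive
        tables = _cell_tables(cal["tf"], fr, ana["baseline_window_s"])
        for cid, tb in tables.items():
            if tb is None or not include.loc[cid]:
                continue
            curve = tuning.curve_from_table(tb[0], "tf")
            fit = fits.fit_difference_of_gaussians(curve.values, curve.mean)
            if fit.ok:
                metrics.loc[cid, "tf_halfmax_high"] = fit.halfmax_high
    else:
        skipped.append("tf")
    if "contrast" in cal:
        tables = _cell_tables(cal["contrast"], fr, ana["baseline_window_s"])
        for cid, tb in tables.items():
            if tb is None or not responsive.loc[cid]:
                continue
            curve = tuning.curve_from_table(tb[0], "contrast")
            fit = fits.fit_naka_rushton(curve.values, curve.mean)
            if fit.ok:
                metrics.loc[cid, "c50"] = fit.c50
    else:
        skipped.append("contrast")

    metrics = metrics.reset_index()
    metrics.insert(0, "config_hash", session.get("config_hash", config.hash))
    metrics.to_csv(out / "cell_metrics.csv", index=False)

    group_stats = _group_statistics(metrics, ana, config.seed)
    group_stats["skipped_batteries"] = skipped
    _dump_json(group_stats, out / "group_stats.json")

    # cluster scan within the marked population
    cluster_rows = []
    marked_metrics = metrics[metrics["marked"].astype(bool)]
    scan_features = marked_metrics.rename(columns={"sf_halfmax_high": "sfh"})
    try:
        scan = stats.cluster_scan(
            marked_metrics.loc[:, ["depth_um", "osi", "dsi", "si",
                                   "sf_halfmax_high", "tf_halfmax_high", "c50"]],
            n_boot=int(ana["cluster_n_boot"]), seed=config.seed)
        cluster_rows = [r.as_dict() for r in scan]
    except ValueError as e:
        log.warning("cluster scan skipped: %s", e)
    pd.DataFrame(cluster_rows).to_csv(out / "cluster_scan.csv", index=False)

    # calcium-vs-spiking validation
    validation = _validation_stats(cal, fr, ana)
    _dump_json(validation, out / "validation.json")

    # ephys / laser analysis
    ephys_report = _ephys_analysis(session, config)
    _dump_json(ephys_report, out / "ephys_report.json")
    return out


def _mean_sem(x):
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return dict(n=0, mean=np.nan, sem=np.nan)
    return dict(n=int(x.size), mean=float(x.mean()),
                sem=float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan)


def _compare_metric(metrics, col, mask=None):
    sel = metrics if mask is None else metrics[mask]
    a = sel.loc[sel["marked"].astype(bool), col].dropna().to_numpy()
    b = sel.loc[~sel["marked"].astype(bool), col].dropna().to_numpy()
    entry = dict(marked=_mean_sem(a), unmarked=_mean_sem(b))
    if len(a) >= 3 and len(b) >= 3:
        entry["test"] = stats.compare_two_groups(a, b).as_dict()
    else:
        entry["test"] = None
        entry["note"] = "group empty or too small"
    return entry


def _group_statistics(metrics, ana, seed):
    out = dict(config_note="marked = CR-like subpopulation", comparisons={})
    resp = metrics["responsive"].fillna(0).astype(bool)
    m = metrics[resp]
    for col in ("osi", "dsi", "si", "pref_diameter", "sf_halfmax_high",
                "tf_halfmax_high", "c50"):
        out["comparisons"][col] = _compare_metric(m, col)
    thr = float(ana["osi_threshold"])
    mm = m[m["osi"].notna()]
    k1 = int((mm.loc[mm["marked"].astype(bool), "osi"] > thr).sum())
    n1 = int(mm["marked"].astype(bool).sum())
    k2 = int((mm.loc[~mm["marked"].astype(bool), "osi"] > thr).sum())
    n2 = int((~mm["marked"].astype(bool)).sum())
    if min(n1, n2) > 0 and 0 < k1 + k2 < n1 + n2:
        out["osi_above_threshold"] = dict(
            threshold=thr, marked=dict(k=k1, n=n1), unmarked=dict(k=k2, n=n2),
            test=stats.compare_proportions(k1, n1, k2, n2).as_dict())
    lp = m[m["sf_lowpass"].notna()]
    if len(lp):
        k1 = int(lp.loc[lp["marked"].astype(bool), "sf_lowpass"].sum())
        n1 = int(lp["marked"].astype(bool).sum())
        k2 = int(lp.loc[~lp["marked"].astype(bool), "sf_lowpass"].sum())
        n2 = int((~lp["marked"].astype(bool)).sum())
        if min(n1, n2) > 0 and 0 < k1 + k2 < n1 + n2:
            out["lowpass_fraction"] = dict(
                marked=dict(k=k1, n=n1), unmarked=dict(k=k2, n=n2),
                test=stats.compare_proportions(k1, n1, k2, n2).as_dict())
    # correlations (permutation p; the source analysis is ambiguous here)
    corr = {}
    sel = m[m["osi"].notna() & m["dsi"].notna()]
    if len(sel) >= 5:
        r, p = stats.permutation_correlation(sel["osi"], sel["dsi"],
                                             n_perm=int(ana["n_perm"]), seed=seed)
        corr["osi_vs_dsi"] = dict(r=r, p_permutation=p, n=len(sel))
    for col in ("osi", "dsi"):
        sel = m[m[col].notna()]
        if len(sel) >= 5:
            r, p = stats.permutation_correlation(sel[col], sel["depth_um"],
                                                 n_perm=int(ana["n_perm"]),
                                                 seed=seed + 1)
            corr[f"{col}_vs_depth"] = dict(r=r, p_permutation=p, n=len(sel))
    out["correlations"] = corr
    return out


def _validation_stats(cal, fr, ana):
    """Fig-2-style check: normalized calcium vs spiking responses."""
    pooled_c, pooled_s = [], []
    for kind, entry in cal.items():
        spikes = entry.get("spikes") or {}
        if not spikes:
            continue
        protocol = entry["protocol"]
        ids = list(entry["cell_ids"])
        for cid, st in spikes.items():
            i = ids.index(cid)
            segs = traces.compute_dff(entry["traces"][i], protocol, fr,
                                      ana["baseline_window_s"])
            table = traces.trial_responses(segs, protocol)
            cmeans = table.groupby("stimulus_id")["response"].mean()
            on = protocol.trials["onset"].to_numpy()
            off = protocol.trials["offset"].to_numpy()
            st_sorted = np.sort(st)
            counts = (np.searchsorted(st_sorted, off)
                      - np.searchsorted(st_sorted, on)) / protocol.stim_s
            smeans = (pd.Series(counts, index=protocol.trials["stimulus_id"])
                      .groupby(level=0).mean())
            if cmeans.abs().max() <= 0 or smeans.abs().max() <= 0:
                continue
            pooled_c.append((cmeans / cmeans.max()).to_numpy())
            pooled_s.append((smeans / smeans.max()).to_numpy())
    if not pooled_c:
        return dict(available=False)
    x = np.concatenate(pooled_c)
    y = np.concatenate(pooled_s)
    r, slope_p = stats.calcium_spike_correlation(x, y)
    return dict(available=True, n_measurements=int(x.size),
                pearson_r=r, slope_p=slope_p)


def _ephys_analysis(session, config):
    out = {}
    for kind, entry in session["ephys"].items():
        protocol = entry["protocol"]
        condition = "contrast" if kind == "ephys_contrast" else "diameter"
        units = entry["units"]
        unit_trials = {}
        included_channels = set()
        for row in units.itertuples():
            tr = ephys_mod.unit_responses(entry["spikes"][int(row.unit_id)],
                                          protocol)
            if ephys_mod.unit_included(tr, condition):
                unit_trials[int(row.unit_id)] = tr
                included_channels.add(int(row.channel_index))
        section = dict(n_units=len(units), n_included=len(unit_trials))
        if not unit_trials:
            section["note"] = "no unit reached the 2 Hz inclusion threshold"
            out[kind] = section
            continue
        layers = ephys_mod.assign_layers(sorted(included_channels))
        chan_of = dict(zip(units["unit_id"].astype(int),
                           units["channel_index"].astype(int)))
        layer_of = {uid: layers[chan_of[uid]] for uid in unit_trials}
        section["layer_counts"] = {
            lab: sum(1 for v in layer_of.values() if v == lab)
            for lab in ("deep", "middle", "top")}
        per_unit, pop, mean_pct = ephys_mod.laser_modulation(unit_trials,
                                                             condition)
        per_unit["layer"] = per_unit["unit_id"].map(layer_of)
        sem = per_unit["percent_change"].std(ddof=1) / np.sqrt(
            per_unit["percent_change"].notna().sum())
        section["laser"] = dict(
            mean_percent_change=mean_pct, sem_percent_change=float(sem),
            population_wilcoxon=pop.as_dict(),
            n_modulated=int(per_unit["modulated"].sum()))
        top = per_unit[per_unit["layer"] == "top"]
        if len(top) >= 3:
            section["laser"]["top_layer"] = dict(
                n=len(top),
                mean_percent_change=float(top["percent_change"].mean(skipna=True)))
        tkind = "contrast" if condition == "contrast" else "size"
        pairs = {f"{'c50' if tkind=='contrast' else 'si'}_{s}": []
                 for s in ("off", "on")}
        for uid, tr in unit_trials.items():
            vals = ephys_mod.tuning_under_laser(tr, tkind)
            if all(np.isfinite(v) for v in vals.values()):
                for k, v in vals.items():
                    pairs[k].append(v)
        key = "c50" if tkind == "contrast" else "si"
        if len(pairs[f"{key}_off"]) >= 3:
            test = stats.compare_two_groups(pairs[f"{key}_on"],
                                            pairs[f"{key}_off"], paired=True)
            section[f"{key}_laser"] = dict(
                off=_mean_sem(pairs[f"{key}_off"]), on=_mean_sem(pairs[f"{key}_on"]),
                wilcoxon=test.as_dict())
        out[kind] = section
    return out


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------
def cmd_report(results_dir) -> Path:
    """Condense the analysis outputs into report.json / report.txt."""
    rd = Path(results_dir)
    if not rd.exists() or not (rd / "group_stats.json").exists():
        raise FileNotFoundError(f"no analysis results in {results_dir}")
    report = {}
    gaps = []
    for name in ("group_stats", "validation", "ephys_report"):
        p = rd / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
        else:
            gaps.append(name)
    metrics_p = rd / "cell_metrics.csv"
    if metrics_p.exists():
        m = pd.read_csv(metrics_p)
        report["counts"] = dict(
            n_cells=len(m), n_marked=int(m["marked"].sum()),
            n_responsive=int(m["responsive"].fillna(0).astype(bool).sum()))
    cluster_p = rd / "cluster_scan.csv"
    if cluster_p.exists() and cluster_p.stat().st_size > 1:
        c = pd.read_csv(cluster_p)
        report["cluster_scan"] = dict(
            n_tests=int(c["n_tests"].iloc[0]) if len(c) else 0,
            min_p_bonferroni=float(c["p_bonferroni"].min()) if len(c) else np.nan,
            n_significant=int((c["p_bonferroni"] < 0.05).sum()) if len(c) else 0)
    if gaps:
        report["gaps"] = gaps
    _dump_json(report, rd / "report.json")

    lines = ["tuning analysis report", "=" * 40]
    cc = report.get("counts", {})
    lines.append(f"cells: {cc.get('n_cells')} ({cc.get('n_marked')} marked), "
                 f"responsive: {cc.get('n_responsive')}")
    comps = report.get("group_stats", {}).get("comparisons", {})
    for name, c in comps.items():
        t = c.get("test")
        if t:
            lines.append(
                f"{name:18s} marked {c['marked']['mean']:.3g}+-{c['marked']['sem']:.2g}"
                f" (n={c['marked']['n']})  unmarked {c['unmarked']['mean']:.3g}"
                f"+-{c['unmarked']['sem']:.2g} (n={c['unmarked']['n']})"
                f"  {t['test_name']} p={t['p_value']:.3g}")
        else:
            lines.append(f"{name:18s} insufficient data")
    ot = report.get("group_stats", {}).get("osi_above_threshold")
    if ot:
        lines.append(f"OSI>{ot['threshold']}: marked {ot['marked']['k']}/{ot['marked']['n']}"
                     f" vs unmarked {ot['unmarked']['k']}/{ot['unmarked']['n']}"
                     f"  chi2 p={ot['test']['p_value']:.3g}")
    val = report.get("validation", {})
    if val.get("available"):
        lines.append(f"calcium-vs-spiking: r={val['pearson_r']:.3f} "
                     f"(n={val['n_measurements']}), slope p={val['slope_p']:.2g}")
    cs = report.get("cluster_scan")
    if cs:
        lines.append(f"cluster scan: {cs['n_tests']} subsets, min corrected "
                     f"p={cs['min_p_bonferroni']:.3g}, significant: {cs['n_significant']}")
    for kind, sec in report.get("ephys_report", {}).items():
        if "laser" in sec:
            las = sec["laser"]
            lines.append(
                f"{kind}: {sec['n_included']}/{sec['n_units']} units, laser "
                f"{las['mean_percent_change']:+.2f}%+-{las['sem_percent_change']:.2f}"
                f"  wilcoxon p={las['population_wilcoxon']['p_value']:.2g}")
    if gaps:
        lines.append(f"missing sections: {gaps}")
    (rd / "report.txt").write_text("\n".join(lines) + "\n")
    return rd / "report.json"
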