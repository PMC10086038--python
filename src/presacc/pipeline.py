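"""End-to-end orchestration: simulate -> detect -> epoch -> evoked -> GLM ->
surrogate -> group statistics, with content-hash caching and a report.

The participant-level chain is exposed as :func:`analyze_participant` so the
statistical simulation studies (effect recovery, type-I calibration) can run
it in memory without file round-trips; those studies take saccade onsets
from the generator's event table (the generator emulates the experiment's
online detection), while the full pipeline runs the velocity-threshold
detector on the gaze stream.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .epoching import (ScreenGeometry, dft_notch, downsample,
                       epoch_around, photodiode_trinary, relock_to_saccade,
                       select_fixation_trials, select_saccade_trials,
                       visual_onsets)
from .evoked import compute_evoked
from .eye_events import DetectorParams, align_clocks, classify_microsaccades, \
    detect_saccades
from .layout import SensorLayout
from .simulate import SimConfig, SimSession, simulate_session
from .stats import (AdjacencyGraph, cluster_onesample_test, duration_mask,
                    lateralization_timecourse, paired_hemisphere_ttest,
                    proportion_tests)
from .surrogate import fit_latency_kdes, median_residuals, sample_onsets, \
    surrogate_regressors

__all__ = [
    "AnalysisParams", "ParticipantResult", "GroupResult", "RunConfig",
    "analyze_participant", "simulate_cohort_residuals", "group_stats",
    "run_pipeline", "make_report", "test_scale_sim_config",
]

PRESACCADIC_WINDOWS = ((-0.112, -0.050), (-0.050, 0.0))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisParams:
    """Parameters of the per-participant analysis chain."""

    epoch_window: tuple = (-0.5, 1.5)     # s around S1 onset
    analysis_sfreq: float = 500.0
    relock_window: tuple = (-0.6, 0.0)
    baseline: tuple = (-0.6, -0.5)
    latency_bounds: tuple = (0.150, 0.500)
    n_draws: int = 1000
    eyelink_lag: float = 0.007
    apply_notch: bool = True
    notch_freqs: tuple = (50.0, 100.0, 150.0)
    use_truth_events: bool = False
    use_photodiode: bool = True
    seed: int = 0
    detector: DetectorParams = field(default_factory=DetectorParams)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)


@dataclass
class ParticipantResult:
    participant: int
    median_residual: np.ndarray     # (n_sites, n_samples)
    t: np.ndarray
    beta_saccade: np.ndarray        # (n_sites,) median over surrogate iterations
    beta_stimulus: np.ndarray
    r2: np.ndarray
    n_draws: int
    n_trials_used: dict
    rejection_logs: dict


@dataclass
class GroupResult:
    cluster_stats: object
    duration_sites: np.ndarray
    lateralization_diff: np.ndarray      # (n_participants, n_samples)
    lateralization_stats: object
    region_lateralization: dict
    r2_ttest: tuple                      # (t, df, p) left-minus-right medians
    beta_saccade_ttest: tuple
    beta_stimulus_ttest: tuple
    window_counts: list                  # per window: dict of counts + tests
    t: np.ndarray
    sfreq: float


def test_scale_sim_config(seed: int = 0, n_sites: int = 16,
                          residual_amplitude: float | None = None,
                          **overrides) -> SimConfig:
    """Desk-scale study conditions: fewer trials/sites, shorter trials, 500 Hz.

    Everything else (kernels, noise, latency distribution, geometry) keeps
    the generator defaults.
    """
    from .simulate import default_kernels
    kern = default_kernels() if residual_amplitude is None else \
        default_kernels(residual_amplitude)
    kw = dict(
        n_participants=8,
        trials_per_condition={"saccade_stimulus": 60, "saccade_only": 30,
                              "stimulus_only": 30},
        sfreq_meg=500.0, n_sites=n_sites, kernels=kern,
        iti=0.1, pre_cue_range=(0.6, 0.9), post_cue=0.7, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def _test_scale_params(seed: int = 0, **overrides) -> AnalysisParams:
    kw = {"epoch_window": (-0.5, 0.62), "n_draws": 50, "seed": seed}
    kw.update(overrides)
    return AnalysisParams(**kw)


# ---------------------------------------------------------------------------
# participant-level analysis
# ---------------------------------------------------------------------------

def _stimulus_onset_times(session: SimSession, params: AnalysisParams) -> pd.Series:
    """Per-trial S1 time: photodiode white-onset where available, else the cue."""
    ev = session.events
    t_cue = ev["t_cue"].copy()
    if not params.use_photodiode:
        return t_cue
    tri = photodiode_trinary(session.photodiode)
    onset_times = visual_onsets(tri, session.sfreq)
    # keep only transitions into white (+1)
    idx = np.round(onset_times * session.sfreq).astype(int)
    white = onset_times[tri[np.minimum(idx, len(tri) - 1)] == 1]
    for i, rec in enumerate(ev.itertuples()):
        if np.isfinite(rec.t_stim_on):
            in_trial = white[(white >= rec.t_start)
                             & (white < rec.t_start + rec.trial_len)]
            if len(in_trial):
                t_cue.iloc[i] = in_trial[0]
    return t_cue


def _events_relative(events, t_ref, t_max, t_min=-1.0):
    """Shift detected saccade events to epoch-relative time, keep those in range."""
    from dataclasses import replace as drep
    out = []
    for e in events:
        rel = e.onset_t - t_ref
        if t_min < rel <= t_max:
            out.append(drep(e, onset_t=rel, offset_t=e.offset_t - t_ref))
    return out


def analyze_participant(session: SimSession, params: AnalysisParams) -> ParticipantResult:
    """Run the full chain for one participant's session."""
    layout = session.layout
    sf_raw = session.sfreq
    ev = session.events
    meg = session.meg
    if params.apply_notch:
        meg = dft_notch(meg, sf_raw, params.notch_freqs)

    t_cue = _stimulus_onset_times(session, params)
    logs = {}

    # ----- eye events -----
    if params.use_truth_events:
        detected = None
    else:
        gaze = align_clocks(session.gaze, params.eyelink_lag) \
            if params.eyelink_lag else session.gaze
        detected = detect_saccades(gaze, params.detector)
        macro, _ = classify_microsaccades(detected, params.detector)

    # ----- epoch each condition around S1 -----
    cond_epochs = {}
    for cond in ("saccade_stimulus", "saccade_only", "stimulus_only"):
        rows = ev.index[ev["condition"] == cond].to_numpy()
        meta = ev.loc[rows].reset_index(drop=True)
        meta["t_cue_used"] = t_cue.loc[rows].to_numpy()
        eps = epoch_around(meg, sf_raw, meta["t_cue_used"].to_numpy(),
                           params.epoch_window, session.ch_names,
                           "stimulus_onset", meta)
        if sf_raw != params.analysis_sfreq:
            eps = downsample(eps, params.analysis_sfreq)
        cond_epochs[cond] = eps

    # ----- trial selection -----
    selected = {}
    for cond in ("saccade_stimulus", "saccade_only"):
        eps = cond_epochs[cond]
        if params.use_truth_events:
            lat = eps.meta["latency"].to_numpy()
            eps = eps.select(np.flatnonzero(np.isfinite(lat)))
            eps.meta["latency_boundary"] = False
            selected[cond] = eps
            logs[cond] = pd.DataFrame(columns=["trial", "reason"])
        else:
            # second stimulus appears ~80 ms after (online-detected) saccade onset
            eps.meta["t_second_stim"] = eps.meta["latency"] + 0.080
            per_trial = [
                _events_relative(macro, tc, eps.t[-1])
                for tc in eps.meta["t_cue_used"]]
            sel, log = select_saccade_trials(eps, per_trial, params.geometry,
                                            params.latency_bounds)
            selected[cond] = sel
            logs[cond] = log

    eps = cond_epochs["stimulus_only"]
    if params.use_truth_events:
        selected["stimulus_only"] = eps
        logs["stimulus_only"] = pd.DataFrame(columns=["trial", "reason"])
    else:
        gz = gaze
        win = params.epoch_window
        gaze_trials, ev_trials = [], []
        for tc in eps.meta["t_cue_used"]:
            i0 = int(round((tc + win[0]) * gz.sfreq))
            i1 = int(round((tc + win[1]) * gz.sfreq))
            gaze_trials.append(np.column_stack([gz.x[i0:i1], gz.y[i0:i1]]))
            ev_trials.append(_events_relative(detected, tc, win[1], t_min=win[0]))
        sel, log = select_fixation_trials(
            eps, gaze_trials, ev_trials,
            fixation_xy=(params.geometry.fixation_x, 0.0))
        selected["stimulus_only"] = sel
        logs["stimulus_only"] = log

    for cond in ("saccade_stimulus", "saccade_only", "stimulus_only"):
        if selected[cond].n_trials < 1:
            raise RuntimeError(f"no {cond} trials survived selection "
                               f"(participant {session.participant})")

    # ----- relock the saccade conditions, compute evoked gradients -----
    ss_locked, drop_ss = relock_to_saccade(selected["saccade_stimulus"],
                                           window=params.relock_window)
    so_locked, drop_so = relock_to_saccade(selected["saccade_only"],
                                           window=params.relock_window)
    logs["relock"] = pd.concat([drop_ss, drop_so], ignore_index=True)
    y_ev = compute_evoked(ss_locked, layout, params.baseline,
                          "saccade_stimulus", session.participant)
    xs_ev = compute_evoked(so_locked, layout, params.baseline,
                           "saccade_only", session.participant)

    # ----- surrogate stimulus-only regressors + GLM residual medians -----
    kdes = fit_latency_kdes(ss_locked.meta, params.latency_bounds,
                            session.participant)
    onsets = sample_onsets(kdes, selected["stimulus_only"].meta,
                           params.n_draws, params.seed, session.participant)
    regs, t_win, dropped = surrogate_regressors(
        selected["stimulus_only"], onsets, layout,
        params.relock_window, params.baseline)
    sur = median_residuals(y_ev.values, xs_ev.values, regs, t_win,
                           params.n_draws, params.seed, layout.site_ids,
                           keep_betas=True)
    return ParticipantResult(
        participant=session.participant,
        median_residual=sur.median_residual,
        t=t_win,
        beta_saccade=np.median(sur.betas[:, :, 0], axis=0),
        beta_stimulus=np.median(sur.betas[:, :, 1], axis=0),
        r2=np.median(sur.r2, axis=0),
        n_draws=params.n_draws,
        n_trials_used={c: selected[c].n_trials for c in selected},
        rejection_logs=logs)


def simulate_cohort_residuals(sim_cfg: SimConfig, params: AnalysisParams,
                              n_participants: int):
    """Simulate and analyze a cohort; returns stacked participant results.

    Used by the statistical simulation studies; saccade onsets come from the
    generator's event table (``use_truth_events=True`` by default in the
    passed params keeps the runtime linear in n_draws).
    """
    res = [analyze_participant(simulate_session(sim_cfg, p), params)
           for p in range(n_participants)]
    return {
        "residuals": np.stack([r.median_residual for r in res]),
        "beta_saccade": np.stack([r.beta_saccade for r in res]),
        "beta_stimulus": np.stack([r.beta_stimulus for r in res]),
        "r2": np.stack([r.r2 for r in res]),
        "t": res[0].t,
        "layout": sim_cfg.get_layout(),
    }


# ---------------------------------------------------------------------------
# group-level statistics
# ---------------------------------------------------------------------------

def group_stats(residuals: np.ndarray, t: np.ndarray, layout: SensorLayout,
                r2: np.ndarray | None = None,
                beta_saccade: np.ndarray | None = None,
                beta_stimulus: np.ndarray | None = None,
                alpha: float = 0.05, n_perm: int = 1000, seed: int = 0,
                windows=PRESACCADIC_WINDOWS) -> GroupResult:
    """Cluster test against zero, duration mask, lateralization contrasts and
    hemispheric proportion tests."""
    sfreq = 1.0 / float(np.mean(np.diff(t)))
    graph = AdjacencyGraph.from_layout(layout)
    cs = cluster_onesample_test(residuals, graph, alpha=alpha, n_perm=n_perm,
                                seed=seed, sfreq=sfreq)
    dmask = duration_mask(cs, sfreq)
    lat_diff, lat_cs = lateralization_timecourse(
        residuals, layout, alpha=alpha, n_perm=n_perm, seed=seed + 1, sfreq=sfreq)
    region_lat = {}
    for reg in ("occipital", "parietal"):
        idx = np.flatnonzero(np.asarray(layout.region) == reg)
        try:
            _, rcs = lateralization_timecourse(
                residuals, layout, site_subset=idx, alpha=alpha,
                n_perm=n_perm, seed=seed + 2, sfreq=sfreq)
            region_lat[reg] = rcs
        except ValueError:
            region_lat[reg] = None

    hemi = layout.hemisphere
    left = np.flatnonzero(hemi == "left")
    right = np.flatnonzero(hemi == "right")

    def _lat_ttest(maps):
        if maps is None:
            return None
        lm = np.median(maps[:, left], axis=1)
        rm = np.median(maps[:, right], axis=1)
        return paired_hemisphere_ttest(lm, rm)

    window_counts = []
    for w in windows:
        m = (t >= w[0] - 1e-9) & (t <= w[1] + 1e-9)
        sig_sites = cs.sig_mask[:, m].any(axis=1)
        kl = int(sig_sites[left].sum())
        kr = int(sig_sites[right].sum())
        tests = proportion_tests(kl, len(left), kr, len(right),
                                 n_windows=len(windows))
        window_counts.append({"window": w, "n_left_sig": kl, "n_right_sig": kr,
                              "n_left": len(left), "n_right": len(right),
                              **tests})
    return GroupResult(
        cluster_stats=cs, duration_sites=dmask,
        lateralization_diff=lat_diff, lateralization_stats=lat_cs,
        region_lateralization=region_lat,
        r2_ttest=_lat_ttest(r2),
        beta_saccade_ttest=_lat_ttest(beta_saccade),
        beta_stimulus_ttest=_lat_ttest(beta_stimulus),
        window_counts=window_counts, t=t, sfreq=sfreq)


# ---------------------------------------------------------------------------
# configured runs with caching
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    scale: str = "test"                 # "test" or "paper-like"
    n_participants: int | None = None
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    analysis: dict = field(default_factory=dict)   # AnalysisParams overrides
    alpha: float = 0.05
    n_perm: int | None = None

    _ALLOWED = {"seed", "scale", "n_participants", "sim", "analysis",
                "alpha", "n_perm"}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._ALLOWED
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.scale not in ("test", "paper-like"):
            raise ConfigError(f"unknown scale preset {cfg.scale!r}")
        sim_fields = {f.name for f in fields(SimConfig)}
        bad = set(cfg.sim) - sim_fields
        if bad:
            raise ConfigError(f"unknown sim keys: {sorted(bad)}")
        ana_fields = {f.name for f in fields(AnalysisParams)}
        bad = set(cfg.analysis) - ana_fields
        if bad:
            raise ConfigError(f"unknown analysis keys: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def build(self):
        if self.scale == "test":
            sim = test_scale_sim_config(seed=self.seed)
            ana = _test_scale_params(seed=self.seed)
            n_part = self.n_participants or 8
            n_perm = self.n_perm or 200
        else:
            sim = SimConfig(seed=self.seed)
            ana = AnalysisParams(seed=self.seed)
            n_part = self.n_participants or sim.n_participants
            n_perm = self.n_perm or 1000
        sim = replace(sim, **self.sim) if self.sim else sim
        ana = replace(ana, **self.analysis) if self.analysis else ana
        return sim, ana, n_part, n_perm


def _stage_key(name: str, payload) -> str:
    return hashlib.sha256(
        json.dumps([name, payload], sort_keys=True, default=str).encode()
    ).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, key: str) -> bool:
        from .io import content_hash
        entry = self.data.get(stage)
        if not entry or entry["key"] != key:
            return False
        for p, h in entry["outputs"].items():
            fp = Path(p)
            if not fp.exists():
                return False
            if content_hash(fp) != h:
                raise RuntimeError(f"checksum mismatch for cached output {p}")
        return True

    def record(self, stage: str, key: str, outputs) -> None:
        from .io import content_hash
        self.data[stage] = {
            "key": key,
            "outputs": {str(p): content_hash(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute all stages into ``outdir`` with content-hash caching.

    Re-running with an identical config is a no-op; a corrupted intermediate
    file raises a checksum-mismatch error naming the file.
    """
    from .io import content_hash, load_session, save_arrays, save_session

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json")
    sim_cfg, ana, n_part, n_perm = cfg.build()
    log_lines = []

    def log(msg):
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    # stage 1: simulate
    key = _stage_key("simulate", [asdict_safe(sim_cfg), n_part])
    sess_dir = outdir / "sessions"
    sess_paths = [sess_dir / f"session_p{p:03d}.h5" for p in range(n_part)]
    if manifest.fresh("simulate", key):
        log("simulate: cache hit")
    else:
        for p in range(n_part):
            save_session(simulate_session(sim_cfg, p), sess_dir)
        manifest.record("simulate", key, sess_paths + [sess_dir / "layout.json"])
        log(f"simulate: wrote {n_part} sessions")

    # stage 2: participant analyses
    key2 = _stage_key("participants", [asdict_safe(ana), key])
    res_path = outdir / "participants.h5"
    results = None
    if manifest.fresh("participants", key2):
        log("participants: cache hit")
    else:
        layout = sim_cfg.get_layout()
        results = []
        for p in range(n_part):
            session = load_session(sess_dir, p)
            session.layout = layout
            r = analyze_participant(session, ana)
            results.append(r)
            rej = {c: len(df) for c, df in r.rejection_logs.items()}
            log(f"participant {p}: trials used {r.n_trials_used}, rejected {rej}")
        save_arrays(res_path, {
            "median_residual": np.stack([r.median_residual for r in results]),
            "beta_saccade": np.stack([r.beta_saccade for r in results]),
            "beta_stimulus": np.stack([r.beta_stimulus for r in results]),
            "r2": np.stack([r.r2 for r in results]),
            "t": results[0].t,
        }, {"n_draws": ana.n_draws})
        manifest.record("participants", key2, [res_path])

    # stage 3: group statistics
    key3 = _stage_key("stats", [cfg.alpha, n_perm, cfg.seed, key2])
    stats_path = outdir / "group_stats.h5"
    summary_path = outdir / "group_summary.json"
    if manifest.fresh("stats", key3):
        log("stats: cache hit")
    else:
        from .io import load_arrays
        arrs, _ = load_arrays(res_path)
        layout = sim_cfg.get_layout()
        gr = group_stats(arrs["median_residual"], arrs["t"], layout,
                         r2=arrs["r2"], beta_saccade=arrs["beta_saccade"],
                         beta_stimulus=arrs["beta_stimulus"],
                         alpha=cfg.alpha, n_perm=n_perm, seed=cfg.seed)
        save_arrays(stats_path, {
            "t_obs": gr.cluster_stats.t_obs,
            "sig_mask": gr.cluster_stats.sig_mask.astype(np.int8),
            "duration_sites": gr.duration_sites.astype(np.int8),
            "lateralization_diff": gr.lateralization_diff,
            "t": gr.t,
        })
        summary = summarize_group(gr)
        summary_path.write_text(json.dumps(summary, indent=1))
        manifest.record("stats", key3, [stats_path, summary_path])
        log("stats: done")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    report = {
        "config_key": _stage_key("run", asdict_safe_cfg(cfg)),
        "stages": {s: manifest.data[s]["key"] for s in manifest.data},
        "outputs": {s: manifest.data[s]["outputs"] for s in manifest.data},
    }
    (outdir / "reproducibility.json").write_text(json.dumps(report, indent=1))
    return outdir


def asdict_safe(obj) -> dict:
    d = asdict(obj)
    d.pop("layout", None)
    return json.loads(json.dumps(d, default=str))


def asdict_safe_cfg(cfg: RunConfig) -> dict:
    return {k: v for k, v in asdict(cfg).items()}


def summarize_group(gr: GroupResult) -> dict:
    cs = gr.cluster_stats
    sig = [c for c in cs.clusters if c.p <= cs.alpha]
    onset_ms = None
    max_sites = 0
    if sig:
        first = min(gr.t[c.samples.min()] for c in sig)
        onset_ms = float(-first * 1000.0)
        max_sites = int(cs.sig_mask.any(axis=1).sum())
    lat_sig = [c for c in gr.lateralization_stats.clusters
               if c.p <= gr.lateralization_stats.alpha]
    return {
        "n_clusters": len(cs.clusters),
        "n_significant_clusters": len(sig),
        "cluster_table": [
            {"mass": float(c.mass), "p": float(c.p), "n_points": int(len(c.sites))}
            for c in cs.clusters[:20]],
        "min_cluster_p": min((c.p for c in cs.clusters), default=None),
        "residual_onset_ms_before_saccade": onset_ms,
        "n_sensors_significant": max_sites,
        "n_sensors_duration_mask": int(gr.duration_sites.sum()),
        "lateralization_any_significant": bool(lat_sig),
        "r2_ttest": gr.r2_ttest,
        "beta_saccade_ttest": gr.beta_saccade_ttest,
        "beta_stimulus_ttest": gr.beta_stimulus_ttest,
        "window_counts": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in wc.items()}
            for wc in gr.window_counts],
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def make_report(outdir) -> Path:
    """Markdown report with topographic maps and lateralization traces.

    Every figure gets a TSV sidecar with the exact plotted numbers.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .io import load_arrays

    outdir = Path(outdir)
    stats_path = outdir / "group_stats.h5"
    summary_path = outdir / "group_summary.json"
    res_path = outdir / "participants.h5"
    if not stats_path.exists() or not summary_path.exists():
        raise FileNotFoundError("stats outputs missing; run the pipeline first")
    summary = json.loads(summary_path.read_text())
    arrs, _ = load_arrays(stats_path)
    parts, _ = load_arrays(res_path)
    layout = SensorLayout.from_json(outdir / "sessions" / "layout.json")
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    def topomap(vals, name, title, mask=None):
        fig, ax = plt.subplots(figsize=(4, 4))
        sc = ax.scatter(layout.pos[:, 0], layout.pos[:, 1], c=vals, s=120,
                        cmap="RdBu_r")
        if mask is not None and mask.any():
            ax.scatter(layout.pos[mask, 0], layout.pos[mask, 1], c="white",
                       s=15, zorder=3)
        ax.set_title(title)
        ax.set_aspect("equal")
        fig.colorbar(sc, ax=ax, shrink=0.8)
        fig.savefig(figdir / f"{name}.png", dpi=110)
        plt.close(fig)
        pd.DataFrame({"site": layout.site_ids, "x": layout.pos[:, 0],
                      "y": layout.pos[:, 1], "value": vals}).to_csv(
            figdir / f"{name}.tsv", sep="\t", index=False)

    dur = arrs["duration_sites"].astype(bool)
    topomap(parts["beta_saccade"].mean(axis=0), "beta_saccade",
            "mean beta (saccade)")
    topomap(parts["beta_stimulus"].mean(axis=0), "beta_stimulus",
            "mean beta (stimulus)")
    topomap(parts["r2"].mean(axis=0), "r2", "mean R^2")
    topomap(parts["median_residual"].mean(axis=0).mean(axis=-1), "residual_mean",
            "mean residual (time-avg)", mask=dur)

    t = arrs["t"]
    diff = arrs["lateralization_diff"]
    fig, ax = plt.subplots(figsize=(5, 3))
    med = np.median(diff, axis=0)
    q1, q3 = np.percentile(diff, [25, 75], axis=0)
    ax.fill_between(t, q1, q3, alpha=0.3)
    ax.plot(t, med)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time from saccade onset (s)")
    ax.set_ylabel("left - right median residual")
    fig.tight_layout()
    fig.savefig(figdir / "lateralization.png", dpi=110)
    plt.close(fig)
    pd.DataFrame({"t": t, "median": med, "q1": q1, "q3": q3}).to_csv(
        figdir / "lateralization.tsv", sep="\t", index=False)

    lines = ["# Pre-saccadic residual gradient report", ""]
    if summary["n_significant_clusters"]:
        lines += [
            f"- {summary['n_significant_clusters']} significant cluster(s); "
            f"earliest significant residual "
            f"{summary['residual_onset_ms_before_saccade']:.0f} ms before "
            "saccade onset.",
            f"- {summary['n_sensors_significant']} sensors significant at any "
            f"time; {summary['n_sensors_duration_mask']} sensors exceed the "
            "12.5 ms duration criterion.",
        ]
        lines.append("")
        lines.append("| cluster | mass | points | p |")
        lines.append("|---|---|---|---|")
        for i, c in enumerate(summary.get("cluster_table", [])):
            lines.append(f"| {i} | {c['mass']:.1f} | {c['n_points']} | "
                         f"{c['p']:.4f} |")
    else:
        lines.append("- No significant clusters.")
    lines.append("")
    lines.append(
        "- Residual lateralization significant at any timepoint: "
        f"{summary['lateralization_any_significant']}")
    for wc in summary["window_counts"]:
        lines.append(
            f"- Window {wc['window']}: left {wc['n_left_sig']}/{wc['n_left']} vs "
            f"right {wc['n_right_sig']}/{wc['n_right']} significant sensors; "
            f"X2(1) = {wc['chi2']:.2f}, Bonferroni p = {wc['p_bonferroni']:.3f}, "
            f"BF10 = {wc['bf10']:.2f}")
    for name, lab in (("r2_ttest", "R^2"), ("beta_saccade_ttest", "beta_saccade"),
                      ("beta_stimulus_ttest", "beta_stimulus")):
        tt = summary.get(name)
        if tt:
            lines.append(f"- {lab} left-minus-right: t({tt[1]}) = {tt[0]:.2f}, "
                         f"p = {tt[2]:.4f}")
    lines += ["", "![beta saccade](figures/beta_saccade.png)",
              "![beta stimulus](figures/beta_stimulus.png)",
              "![R2](figures/r2.png)",
              "![residuals](figures/residual_mean.png)",
              "![lateralization](figures/lateralization.png)", ""]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
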