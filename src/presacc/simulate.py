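"""Synthetic MEG + gaze + photodiode sessions with known ground truth.

The generator emulates the three-condition saccadic-remapping design: a
Saccade+stimulus condition in which a left-hemifield grating appears
simultaneously with a fixation target 14 deg to the left and the participant
saccades to it, a Saccade-only condition without the grating, and a
Stimulus-only (fixation) condition without the saccade. Sensor activity is
built at the combined-gradiometer level: each evoked component has a time
course locked to either stimulus or saccade onset and a smooth spatial
weight map over sites; the per-site amplitude A(t) is split over the two
gradiometers of the pair as (A cos(theta), A sin(theta)) with a fixed
per-site angle, so the root-sum-of-squares combination recovers |A(t)|.

The Saccade+stimulus condition carries ``beta_true``-scaled copies of the
saccade and stimulus components plus an optional injected "residual"
component that exists in no other condition; this is the planted effect the
GLM residual analysis is supposed to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eye_events import GazeRecording
from .layout import SensorLayout, make_layout

__all__ = [
    "KernelSpec",
    "SimConfig",
    "SimSession",
    "simulate_session",
    "ground_truth_table",
    "default_kernels",
    "make_gaze_trace",
    "saccade_duration",
]

CONDITIONS = ("saccade_stimulus", "saccade_only", "stimulus_only")

ORIENTATIONS = (-30.0, 30.0)
SPATIAL_FREQS = (0.33, 1.33)
PHASES = (0.0, float(np.pi))


def saccade_duration(amplitude_deg: float) -> float:
    """Main-sequence duration: ~2.2 ms per degree plus a 21 ms intercept."""
    return 2.2e-3 * abs(amplitude_deg) + 0.021


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


# ---------------------------------------------------------------------------
# evoked components
# ---------------------------------------------------------------------------

@dataclass
class KernelSpec:
    """One evoked component: a time course locked to an event plus a spatial map.

    shape:
        "saccade_biphasic"  gamma-difference with a slow pre-movement build-up,
                            peaking 30 ms after saccade onset;
        "stim_gamma"        non-negative gamma peaking 120 ms post stimulus onset;
        "half_hann_ramp"    half-Hanning ramp rising over the final ``ramp_dur``
                            seconds before its lock event (the injected effect);
        "stim_gamma_nonneg" alias of "stim_gamma" (already non-negative).
    lock: "saccade" or "stimulus" onset.
    lateralization: "bilateral" (mirror-symmetric map), "left" or "right"
        (weights strictly zero outside the named hemisphere).
    """

    shape: str
    lock: str
    amplitude: float = 1.0
    center: tuple = (0.45, -0.45)
    width: float = 0.55
    lateralization: str = "bilateral"
    ramp_dur: float = 0.112
    nonneg: bool = False

    def support(self) -> tuple:
        if self.shape == "saccade_biphasic":
            return (-0.35, 0.45)
        if self.shape in ("stim_gamma", "stim_gamma_nonneg"):
            return (0.0, 0.45)
        if self.shape == "half_hann_ramp":
            return (-self.ramp_dur, 0.08)
        raise ValueError(f"unknown kernel shape {self.shape!r}")

    def timecourse(self, lags: np.ndarray) -> np.ndarray:
        """Evaluate the component at event-locked lags (s); peak value = amplitude."""
        lags = np.asarray(lags, dtype=float)
        if self.shape == "saccade_biphasic":
            u = lags + 0.35  # support starts 350 ms pre-onset (motor build-up)
            v = _gamma_shape(u, a=4.0, b=0.38 / 3.0) - 0.55 * _gamma_shape(u, a=7.0, b=0.50 / 6.0)
            if self.nonneg:
                v = np.maximum(v, 0.0)
        elif self.shape in ("stim_gamma", "stim_gamma_nonneg"):
            v = _gamma_shape(lags, a=6.0, b=0.12 / 5.0)
        elif self.shape == "half_hann_ramp":
            v = np.zeros_like(lags)
            rise = (lags >= -self.ramp_dur) & (lags <= 0)
            v[rise] = np.sin(0.5 * np.pi * (lags[rise] + self.ramp_dur) / self.ramp_dur) ** 2
            fall = (lags > 0) & (lags <= 0.08)
            v[fall] = np.cos(0.5 * np.pi * lags[fall] / 0.08) ** 2
        else:
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        return self.amplitude * v

    def spatial_weights(self, layout: SensorLayout) -> np.ndarray:
        """Per-site weights in [0, 1]; strictly zero outside the active hemisphere."""
        c = np.asarray(self.center, dtype=float)
        d2 = ((layout.pos - c) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2 * self.width**2))
        if self.lateralization == "bilateral":
            c2 = c * np.array([-1.0, 1.0])
            d2m = ((layout.pos - c2) ** 2).sum(axis=1)
            w = np.maximum(w, np.exp(-d2m / (2 * self.width**2)))
        else:
            hemi = layout.hemisphere
            w = np.where(hemi == self.lateralization, w, 0.0)
        return w


def _gamma_shape(u: np.ndarray, a: float, b: float) -> np.ndarray:
    """Gamma-density time course normalized to peak 1 at (a-1)*b; zero for u < 0."""
    u = np.asarray(u, dtype=float)
    up = (a - 1.0) * b
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = (u[pos] / up) ** (a - 1.0) * np.exp(-(u[pos] - up) / b)
    return out


def default_kernels(residual_amplitude: float = 0.4) -> dict:
    """The three default components.

    The stimulus response is right-lateralized (left-hemifield stimulus), the
    saccade response bilateral with a fronto-central bias, and the injected
    residual a bilateral occipito-parietal ramp beginning 112 ms pre-saccade.
    """
    return {
        "saccade": KernelSpec(shape="saccade_biphasic", lock="saccade",
                              amplitude=1.0, center=(0.35, 0.25), width=0.6,
                              lateralization="bilateral"),
        "stimulus": KernelSpec(shape="stim_gamma", lock="stimulus",
                               amplitude=1.0, center=(0.45, -0.5), width=0.5,
                               lateralization="right"),
        "residual": KernelSpec(shape="half_hann_ramp", lock="saccade",
                               amplitude=residual_amplitude,
                               center=(0.4, -0.35), width=0.7,
                               lateralization="bilateral"),
    }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design parameters of a simulated session.

    Trial counts, the saccade geometry (14 deg leftward, from fixation at
    +7 deg to a target at -7 deg), the stimulus feature grid and the latency
    support [0.15, 0.5] s follow the experimental design being emulated;
    kernel shapes, noise amplitudes and the latency distribution are
    generator choices documented in the methods note.
    """

    n_participants: int = 28
    trials_per_condition: dict = field(default_factory=lambda: {
        "saccade_stimulus": 416, "saccade_only": 208, "stimulus_only": 208})
    sfreq_meg: float = 1000.0
    sfreq_eye: float = 1000.0
    # truncated log-normal latency distribution on [0.15, 0.5] s
    latency_median: float = 0.230
    latency_sigma: float = 0.30        # log-scale sd
    latency_support: tuple = (0.150, 0.500)
    latency_participant_sd: float = 0.08  # log-scale jitter of the median
    saccade_amplitude: float = 14.0
    fixation_x: float = 7.0            # deg right of the vertical midline
    target_x: float = -7.0
    kernels: dict = field(default_factory=default_kernels)
    beta_true: tuple = (1.3, 0.7)
    noise_white_sd: float = 0.5
    noise_pink_sd: float = 0.5
    gaze_noise_sd: float = 0.010       # deg RMS, video-tracker-like
    eye_lag: float = 0.007             # s; gaze recorded late re MEG clock
    microsaccade_rate: float = 0.25    # per second during fixation
    microsaccade_amp: tuple = (0.05, 0.30)
    # trial timing (s)
    iti: float = 0.2
    pre_cue_range: tuple = (1.0, 1.5)
    post_cue: float = 1.6
    stim_duration_range: tuple = (0.5, 0.7)
    n_sites: int = 102
    layout: SensorLayout | None = None
    # snap cue and saccade times to the MEG sample grid (exact-recovery setups)
    snap_to_grid: bool = False
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.latency_support
        if not (0.0 < lo < hi):
            raise ValueError("invalid latency support")
        if not all(np.isfinite(self.beta_true)):
            raise ValueError("beta_true must be finite")
        unknown = set(self.trials_per_condition) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {unknown}")
        if self.post_cue < hi + 0.05:
            raise ValueError("post_cue must cover the latency support")

    def get_layout(self) -> SensorLayout:
        if self.layout is None:
            self.layout = make_layout(self.n_sites, symmetric=True, seed=self.seed)
        return self.layout


@dataclass
class SimSession:
    """One participant's continuous recording plus full ground truth."""

    meg: np.ndarray            # (n_channels, n_samples)
    sfreq: float
    ch_names: list
    gaze: GazeRecording
    photodiode: np.ndarray
    events: pd.DataFrame
    layout: SensorLayout
    truth: dict
    participant: int = 0

    @property
    def n_samples(self) -> int:
        return self.meg.shape[1]


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _draw_latencies(rng, n, median, sigma, support):
    """Truncated log-normal latencies; rejection keeps every draw in support."""
    mu = math.log(median)
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = np.exp(rng.normal(mu, sigma, size=2 * (n - filled) + 8))
        cand = cand[(cand >= support[0]) & (cand <= support[1])]
        take = min(len(cand), n - filled)
        out[filled:filled + take] = cand[:take]
        filled += take
    return out


def _pink_noise(rng, shape) -> np.ndarray:
    """Unit-variance 1/f-power noise along the last axis (spectral shaping)."""
    from scipy.fft import irfft, next_fast_len, rfft
    n = shape[-1]
    nfft = next_fast_len(n)
    white = rng.standard_normal(shape[:-1] + (nfft,))
    spec = rfft(white, axis=-1)
    f = np.fft.rfftfreq(nfft, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    # analytic normalization: Var(y) = (s0^2 + sN^2 + 2*sum interior s^2) / n
    s2 = scale**2
    var = (s2[0] + (s2[-1] if nfft % 2 == 0 else 2 * s2[-1]) + 2 * s2[1:-1].sum()) / nfft
    spec *= scale / math.sqrt(var)
    return irfft(spec, n=nfft, axis=-1)[..., :n]


def _add_minimum_jerk_step(x, y, sfreq, t0_idx, dur_s, dx, dy):
    ns = max(2, int(round(dur_s * sfreq)))
    idx = np.arange(ns + 1)
    prof = minimum_jerk(idx / ns)
    sl = slice(t0_idx, min(t0_idx + ns + 1, len(x)))
    m = sl.stop - sl.start
    x[sl] += dx * prof[:m]
    y[sl] += dy * prof[:m]
    if sl.stop < len(x):
        x[sl.stop:] += dx
        y[sl.stop:] += dy


def make_gaze_trace(saccades, duration, sfreq=1000.0, noise_sd=0.01,
                    start_xy=(0.0, 0.0), seed=0, microsaccades=()) -> GazeRecording:
    """Build a gaze trace with scripted saccades (for detector validation).

    ``saccades``: iterable of (onset_s, dx_deg, dy_deg); durations follow the
    main sequence. ``microsaccades`` uses the same format.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sfreq))
    t = np.arange(n) / sfreq
    x = np.full(n, float(start_xy[0]))
    y = np.full(n, float(start_xy[1]))
    for onset, dx, dy in list(saccades) + list(microsaccades):
        amp = math.hypot(dx, dy)
        _add_minimum_jerk_step(x, y, sfreq, int(round(onset * sfreq)),
                               saccade_duration(amp), dx, dy)
    if noise_sd:
        x = x + rng.normal(0, noise_sd, n)
        y = y + rng.normal(0, noise_sd, n)
    return GazeRecording(t=t, x=x, y=y, sfreq=sfreq)


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def _trial_schedule(cfg: SimConfig, participant: int) -> pd.DataFrame:
    rng = _rng(cfg.seed, participant, 3)
    rows = []
    for cond in CONDITIONS:
        for _ in range(cfg.trials_per_condition.get(cond, 0)):
            rows.append(cond)
    rng.shuffle(rows)

    feat_grid = [(o, s, p) for o in ORIENTATIONS for s in SPATIAL_FREQS for p in PHASES]
    lat_rng = _rng(cfg.seed, participant, 0)
    med = cfg.latency_median * math.exp(
        _rng(cfg.seed, participant, 5).normal(0.0, cfg.latency_participant_sd))

    recs = []
    t_cursor = 0.0
    feat_counters = {c: 0 for c in CONDITIONS}
    for tr, cond in enumerate(rows):
        pre = lat_rng.uniform(*cfg.pre_cue_range)
        trial_len = cfg.iti + pre + cfg.post_cue
        t_start = t_cursor
        t_cue = t_start + cfg.iti + pre
        if cfg.snap_to_grid:
            t_cue = round(t_cue * cfg.sfreq_meg) / cfg.sfreq_meg
        rec = {"trial": tr, "condition": cond, "t_start": t_start, "t_cue": t_cue,
               "trial_len": trial_len,
               "t_stim_on": np.nan, "stim_duration": np.nan,
               "orientation": np.nan, "spatial_frequency": np.nan, "phase": np.nan,
               "latency": np.nan, "t_sacc_on": np.nan, "t_sacc_off": np.nan,
               "sacc_amplitude": np.nan}
        if cond in ("saccade_stimulus", "stimulus_only"):
            # balanced features: cycle through the 8-cell factorial grid
            k = feat_counters[cond]
            o, s, p = feat_grid[k % 8]
            feat_counters[cond] += 1
            rec.update(orientation=o, spatial_frequency=s, phase=p,
                       t_stim_on=t_cue,
                       stim_duration=lat_rng.uniform(*cfg.stim_duration_range))
        if cond in ("saccade_stimulus", "saccade_only"):
            lat = float(_draw_latencies(lat_rng, 1, med, cfg.latency_sigma,
                                        cfg.latency_support)[0])
            if cfg.snap_to_grid:
                lat = round(lat * cfg.sfreq_meg) / cfg.sfreq_meg
            dur = saccade_duration(cfg.saccade_amplitude)
            rec.update(latency=lat, t_sacc_on=t_cue + lat,
                       t_sacc_off=t_cue + lat + dur,
                       sacc_amplitude=cfg.saccade_amplitude)
        recs.append(rec)
        t_cursor += trial_len
    df = pd.DataFrame(recs)
    df["total_duration"] = t_cursor
    return df


def simulate_session(cfg: SimConfig, participant: int = 0) -> SimSession:
    """Generate one participant's session; fully determined by (cfg, participant)."""
    cfg.validate()
    layout = cfg.get_layout()
    events = _trial_schedule(cfg, participant)
    sf = cfg.sfreq_meg
    total_dur = float(events["total_duration"].iloc[0])
    n = int(round(total_dur * sf))
    n_sites = layout.n_sites
    nch = 2 * n_sites

    theta = _rng(cfg.seed, 4).uniform(0.0, 2 * np.pi, n_sites)
    weights = {name: k.spatial_weights(layout) for name, k in cfg.kernels.items()}

    # scheduled per-site amplitude A(t)
    amp = np.zeros((n_sites, n), dtype=float)
    comp_coefs = {
        "saccade_stimulus": {"saccade": cfg.beta_true[0], "stimulus": cfg.beta_true[1],
                             "residual": 1.0},
        "saccade_only": {"saccade": 1.0},
        "stimulus_only": {"stimulus": 1.0},
    }
    for rec in events.itertuples():
        coefs = comp_coefs[rec.condition]
        for name, coef in coefs.items():
            k = cfg.kernels[name]
            if k.amplitude == 0 or coef == 0:
                continue
            t_lock = rec.t_sacc_on if k.lock == "saccade" else rec.t_stim_on
            if not np.isfinite(t_lock):
                continue
            lo, hi = k.support()
            i0 = max(0, int(round((t_lock + lo) * sf)))
            i1 = min(n, int(round((t_lock + hi) * sf)) + 1)
            if i1 <= i0:
                continue
            lags = np.arange(i0, i1) / sf - t_lock
            tc = coef * k.timecourse(lags)
            amp[:, i0:i1] += weights[name][:, None] * tc[None, :]

    meg = np.empty((nch, n), dtype=float)
    meg[0::2] = amp * np.cos(theta)[:, None]
    meg[1::2] = amp * np.sin(theta)[:, None]

    noise_rng = _rng(cfg.seed, participant, 1)
    if cfg.noise_white_sd > 0:
        meg += noise_rng.normal(0.0, cfg.noise_white_sd, meg.shape)
    if cfg.noise_pink_sd > 0:
        # one independent pink realization per channel per trial; generated
        # in one batch at the longest trial length and truncated per trial
        # (a truncated segment of a stationary pink process is still pink)
        bounds = np.round(np.r_[events["t_start"].to_numpy(), total_dur] * sf).astype(int)
        lens = np.minimum(bounds[1:], n) - bounds[:-1]
        pink = _pink_noise(noise_rng, (len(lens), nch, int(lens.max())))
        for k, (b0, ln) in enumerate(zip(bounds[:-1], lens)):
            if ln > 1:
                meg[:, b0:b0 + ln] += cfg.noise_pink_sd * pink[k, :, :ln]

    # ----- gaze -----
    sfe = cfg.sfreq_eye
    ne = int(round(total_dur * sfe))
    gx = np.full(ne, cfg.fixation_x)
    gy = np.zeros(ne)
    ms_rng = _rng(cfg.seed, participant, 2)
    for rec in events.itertuples():
        if np.isfinite(rec.t_sacc_on):
            _add_minimum_jerk_step(gx, gy, sfe, int(round(rec.t_sacc_on * sfe)),
                                   rec.t_sacc_off - rec.t_sacc_on,
                                   cfg.target_x - cfg.fixation_x, 0.0)
            # refixate at the end of the trial block for the next trial
            t_end = rec.t_start + rec.trial_len - 0.5 * cfg.iti
            _add_minimum_jerk_step(gx, gy, sfe, int(round(t_end * sfe)),
                                   saccade_duration(cfg.saccade_amplitude),
                                   cfg.fixation_x - cfg.target_x, 0.0)
        # microsaccades during the pre-cue fixation period
        span = rec.t_cue - rec.t_start - cfg.iti
        n_ms = ms_rng.poisson(cfg.microsaccade_rate * span)
        for _ in range(n_ms):
            t_ms = rec.t_start + cfg.iti + ms_rng.uniform(0.05, max(0.06, span - 0.1))
            a = ms_rng.uniform(*cfg.microsaccade_amp)
            ang = ms_rng.uniform(0, 2 * np.pi)
            i_ms = int(round(t_ms * sfe))
            _add_minimum_jerk_step(gx, gy, sfe, i_ms, 0.012,
                                   a * np.cos(ang), a * np.sin(ang))
            _add_minimum_jerk_step(gx, gy, sfe, i_ms + int(0.03 * sfe), 0.012,
                                   -a * np.cos(ang), -a * np.sin(ang))
    if cfg.eye_lag > 0:
        # digital-to-analog conversion lag: eye samples appear late on the
        # MEG clock; the analysis compensates with align_clocks
        sh = int(round(cfg.eye_lag * sfe))
        gx = np.concatenate([np.repeat(gx[0], sh), gx[:-sh]])
        gy = np.concatenate([np.repeat(gy[0], sh), gy[:-sh]])
    if cfg.gaze_noise_sd > 0:
        gx = gx + ms_rng.normal(0, cfg.gaze_noise_sd, ne)
        gy = gy + ms_rng.normal(0, cfg.gaze_noise_sd, ne)
    gaze = GazeRecording(t=np.arange(ne) / sfe, x=gx, y=gy, sfreq=sfe,
                         units_meta={"deg_per_px_x": 0.020292, "deg_per_px_y": 0.020161})

    # ----- photodiode: black between trials, grey at fixation, white at stimulus
    pd_sig = np.zeros(n)
    for rec in events.itertuples():
        i_fix = int(round((rec.t_start + cfg.iti) * sf))
        i_end = min(n, int(round((rec.t_start + rec.trial_len) * sf)))
        pd_sig[i_fix:i_end] = 0.5
        if np.isfinite(rec.t_stim_on):
            s0 = int(round(rec.t_stim_on * sf))
            s1 = min(n, int(round((rec.t_stim_on + rec.stim_duration) * sf)))
            pd_sig[s0:s1] = 1.0
    pd_sig += noise_rng.normal(0.0, 0.005, n)

    truth = {
        "theta": theta,
        "weights": weights,
        "kernels": cfg.kernels,
        "beta_true": tuple(cfg.beta_true),
        "residual_amplitude": cfg.kernels["residual"].amplitude,
        "scheduled_amplitude": None,  # filled on demand; see scheduled_amplitude()
    }
    ev = events.drop(columns=["total_duration"])
    return SimSession(meg=meg, sfreq=sf, ch_names=layout.ch_names, gaze=gaze,
                      photodiode=pd_sig, events=ev, layout=layout, truth=truth,
                      participant=participant)


def scheduled_amplitude(session: SimSession, cfg: SimConfig) -> np.ndarray:
    """Recompute the noise-free per-site amplitude |A(t)| for invariant checks."""
    noiseless = replace(cfg, noise_white_sd=0.0, noise_pink_sd=0.0, layout=session.layout)
    clean = simulate_session(noiseless, session.participant)
    g1, g2 = clean.meg[0::2], clean.meg[1::2]
    return np.hypot(g1, g2)


def ground_truth_table(session: SimSession) -> pd.DataFrame:
    """One row per trial: condition, true saccade onset/latency, features."""
    cols = ["trial", "condition", "t_cue", "t_stim_on", "latency",
            "t_sacc_on", "t_sacc_off", "sacc_amplitude",
            "orientation", "spatial_frequency", "phase"]
    return session.events[cols].copy()
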