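"""Continuous-to-epoch conversion, filtering, photodiode timing and trial selection.

Conventions: 0-based sample indices; epochs are stored as
(trials, channels, samples) with a shared time axis relative to the lock
event. Saccade-locked epochs span [-0.6, 0] s with the t = 0 sample included
(301 samples at 500 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin

__all__ = [
    "EpochSet",
    "ScreenGeometry",
    "dft_notch",
    "downsample_array",
    "downsample",
    "photodiode_trinary",
    "visual_onsets",
    "epoch_around",
    "select_saccade_trials",
    "select_fixation_trials",
    "relock_to_saccade",
]


@dataclass
class EpochSet:
    """Condition-labelled epochs locked to a named event."""

    data: np.ndarray        # (n_trials, n_channels, n_samples)
    t: np.ndarray           # seconds relative to the lock event
    sfreq: float
    ch_names: list
    lock: str               # "stimulus_onset" or "saccade_onset"
    meta: pd.DataFrame      # one row per trial

    def __post_init__(self):
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta row count must equal trial count")
        if self.data.shape[2] != len(self.t):
            raise ValueError("time axis length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.data[idx], self.t, self.sfreq, self.ch_names,
                        self.lock, self.meta.iloc[idx].reset_index(drop=True))


@dataclass
class ScreenGeometry:
    """Screen-frame landmarks in degrees (y positive = up)."""

    midline_x: float = 0.0
    horizontal_midline_y: float = 0.0
    fixation_x: float = 7.0
    target_x: float = -7.0
    stimulus_y: float = -6.0
    endpoint_min_past_midline: float = 4.0   # deg beyond the midline, far side
    endpoint_min_y: float = -2.0             # deg relative to horizontal midline

    @property
    def far_sign(self) -> float:
        """-1 if the saccade target lies left of fixation, else +1."""
        return -1.0 if self.target_x < self.fixation_x else 1.0


# ---------------------------------------------------------------------------
# filtering / timing primitives
# ---------------------------------------------------------------------------

def dft_notch(data: np.ndarray, sfreq: float, freqs=(50.0, 100.0, 150.0)) -> np.ndarray:
    """Attenuate line noise by least-squares sinusoid regression.

    A sine and cosine at each listed frequency are fit per channel over the
    whole window and subtracted; all other frequency content is preserved up
    to numerical error. Mirrors the classic DFT filter used for 50 Hz mains
    and its harmonics.
    """
    data = np.asarray(data, dtype=float)
    for f in freqs:
        if f >= sfreq / 2.0:
            raise ValueError(f"notch frequency {f} Hz >= Nyquist ({sfreq / 2} Hz)")
    n = data.shape[-1]
    t = np.arange(n) / sfreq
    design = np.column_stack(
        [fn(2 * np.pi * f * t) for f in freqs for fn in (np.sin, np.cos)])
    flat = data.reshape(-1, n)
    coef, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    return (flat - (design @ coef).T).reshape(data.shape)


def downsample_array(data: np.ndarray, sfreq: float, target: float) -> np.ndarray:
    """Anti-alias low-pass (zero-phase FIR, cutoff 0.4 * target) then decimate."""
    ratio = sfreq / target
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"target rate {target} must divide sfreq {sfreq}")
    if q == 1:
        return np.asarray(data, dtype=float).copy()
    n = data.shape[-1]
    numtaps = min(201, (max(31, n // 4)) | 1)
    h = firwin(numtaps, 0.4 * target, fs=sfreq)
    filtered = filtfilt(h, [1.0], data, axis=-1, padlen=min(3 * numtaps, n - 1))
    return filtered[..., ::q]


def downsample(epochs: EpochSet, target: float = 500.0) -> EpochSet:
    out = downsample_array(epochs.data, epochs.sfreq, target)
    q = int(round(epochs.sfreq / target))
    return EpochSet(out, epochs.t[::q], target, epochs.ch_names, epochs.lock,
                    epochs.meta.copy())


def photodiode_trinary(raw: np.ndarray, boundaries: str = "inclusive") -> np.ndarray:
    """Convert the raw photodiode trace to a trinary black/grey/white signal.

    Four linearly spaced boundary values span [min, max]; samples below the
    second boundary map to -1 (black), samples between the second and third
    (inclusive) to 0 (grey), samples above the third to +1 (white). With
    ``boundaries="interior"`` the four values are instead the interior points
    of a six-point grid.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 0:
        raise ValueError("photodiode signal has zero range")
    if boundaries == "inclusive":
        b = np.linspace(lo, hi, 4)
    elif boundaries == "interior":
        b = np.linspace(lo, hi, 6)[1:5]
    else:
        raise ValueError(f"unknown boundary convention {boundaries!r}")
    out = np.zeros(raw.shape, dtype=np.int8)
    out[raw < b[1]] = -1
    out[raw > b[2]] = 1
    return out


def visual_onsets(trinary: np.ndarray, sfreq: float) -> np.ndarray:
    """Times (s) of every luminance change: nonzero |diff| of the trinary trace.

    The onset index is the later sample of the changing pair.
    """
    idx = np.flatnonzero(np.abs(np.diff(trinary.astype(np.int16))) > 0) + 1
    return idx / sfreq


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_around(data: np.ndarray, sfreq: float, event_times, window,
                 ch_names, lock: str, meta: pd.DataFrame) -> EpochSet:
    """Cut (channels, samples) continuous data into epochs around event times.

    Trials whose window exceeds the recording are dropped (kept trials are
    recorded in the returned meta under their original row).
    """
    i0 = int(round(window[0] * sfreq))
    i1 = int(round(window[1] * sfreq))
    offs = np.arange(i0, i1 + 1)
    centers = np.round(np.asarray(event_times, dtype=float) * sfreq).astype(int)
    ok = (centers + i0 >= 0) & (centers + i1 < data.shape[-1])
    centers = centers[ok]
    cut = data[:, centers[:, None] + offs[None, :]]  # (ch, trials, samples)
    return EpochSet(np.ascontiguousarray(cut.transpose(1, 0, 2)),
                    offs / sfreq, sfreq, list(ch_names), lock,
                    meta.iloc[np.flatnonzero(ok)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# trial selection
# ---------------------------------------------------------------------------

def _log(entries) -> pd.DataFrame:
    return pd.DataFrame(entries, columns=["trial", "reason"])


def select_saccade_trials(epochs: EpochSet, events_per_trial,
                          geom: ScreenGeometry | None = None,
                          latency_bounds=(0.150, 0.500)):
    """Apply the saccade-condition inclusion rules.

    A trial survives iff (1) exactly one saccade falls between stimulus onset
    (t = 0) and the second-stimulus onset (meta column ``t_second_stim``, or
    the epoch end), (2) its endpoint is at least 4 deg past the vertical
    midline on the far side, (3) its endpoint is no lower than 2 deg below
    the horizontal midline, and (4) its latency lies in ``latency_bounds``
    (inclusive). Event times are epoch-relative (s). Returns the surviving
    EpochSet (meta gains ``latency`` and endpoint columns) and a rejection
    log with one reason per rejected trial; trials retained exactly at a
    latency bound are flagged in ``meta["latency_boundary"]``.
    """
    if events_per_trial is None:
        raise ValueError("per-trial saccade events are required")
    if geom is None:
        geom = ScreenGeometry()
    far = geom.far_sign
    keep, log = [], []
    lat_col, ex_col, ey_col, bnd_col = [], [], [], []
    t_end_default = float(epochs.t[-1])
    for i in range(epochs.n_trials):
        evs = events_per_trial[i]
        t_stop = epochs.meta["t_second_stim"].iloc[i] \
            if "t_second_stim" in epochs.meta.columns else t_end_default
        if not np.isfinite(t_stop):
            t_stop = t_end_default
        in_win = [e for e in evs if 0.0 < e.onset_t <= t_stop]
        if len(in_win) != 1:
            log.append((i, "multiple_saccades" if len(in_win) > 1 else "no_saccade"))
            continue
        e = in_win[0]
        end_x, end_y = e.end_xy
        if far * (end_x - geom.midline_x) < geom.endpoint_min_past_midline:
            log.append((i, "endpoint_x"))
            continue
        if end_y - geom.horizontal_midline_y < geom.endpoint_min_y:
            log.append((i, "endpoint_y"))
            continue
        lat = e.onset_t
        if lat < latency_bounds[0]:
            log.append((i, "latency_low"))
            continue
        if lat > latency_bounds[1]:
            log.append((i, "latency_high"))
            continue
        keep.append(i)
        lat_col.append(lat)
        ex_col.append(end_x)
        ey_col.append(end_y)
        bnd_col.append(lat in latency_bounds)
    out = epochs.select(keep)
    out.meta["latency"] = lat_col
    out.meta["endpoint_x"] = ex_col
    out.meta["endpoint_y"] = ey_col
    out.meta["latency_boundary"] = bnd_col
    return out, _log(log)


def select_fixation_trials(epochs: EpochSet, gaze_per_trial, events_per_trial,
                           fixation_xy=(7.0, 0.0), max_excursion: float = 2.0,
                           microsaccade_max_amp: float = 0.5):
    """Apply the fixation-condition inclusion rules.

    ``gaze_per_trial``: per-trial (n_samples, 2) gaze positions in degrees
    covering the whole epoch. A trial survives iff gaze stays within
    ``max_excursion`` degrees of the fixation point over the entire epoch and
    no detected saccadic event exceeds ``microsaccade_max_amp`` degrees.
    """
    if gaze_per_trial is None:
        raise ValueError("per-trial gaze is required")
    fx, fy = fixation_xy
    keep, log = [], []
    for i in range(epochs.n_trials):
        g = np.asarray(gaze_per_trial[i], dtype=float)
        dev = np.hypot(g[:, 0] - fx, g[:, 1] - fy)
        if np.nanmax(dev) > max_excursion:
            log.append((i, "gaze_excursion"))
            continue
        evs = events_per_trial[i] if events_per_trial is not None else []
        if any(e.amplitude > microsaccade_max_amp for e in evs):
            log.append((i, "microsaccade"))
            continue
        keep.append(i)
    return epochs.select(keep), _log(log)


def relock_to_saccade(epochs: EpochSet, onsets=None, window=(-0.6, 0.0)):
    """Re-epoch stimulus-locked trials to saccade onset.

    ``onsets``: per-trial saccade onset (s, relative to the current lock
    event); defaults to ``meta["latency"]``. The sample at t = 0 is the
    saccade-onset sample. Trials whose window is not fully covered are
    dropped and logged.
    """
    if onsets is None:
        onsets = epochs.meta["latency"].to_numpy()
    onsets = np.asarray(onsets, dtype=float)
    sf = epochs.sfreq
    i0 = int(round(window[0] * sf))
    i1 = int(round(window[1] * sf))
    offs = np.arange(i0, i1 + 1)
    base = int(round(epochs.t[0] * sf))
    centers = np.round(onsets * sf).astype(int) - base
    ns = epochs.data.shape[2]
    ok = (centers + i0 >= 0) & (centers + i1 < ns)
    log = _log([(i, "window_not_covered") for i in np.flatnonzero(~ok)])
    sel = np.flatnonzero(ok)
    idx = centers[sel][:, None] + offs[None, :]
    cut = epochs.data[sel[:, None, None],
                      np.arange(epochs.data.shape[1])[None, :, None],
                      idx[:, None, :]]
    meta = epochs.meta.iloc[sel].reset_index(drop=True)
    meta = meta.assign(saccade_onset=onsets[sel])
    return EpochSet(cut, offs / sf, sf, epochs.ch_names, "saccade_onset", meta), log
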