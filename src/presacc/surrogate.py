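"""Surrogate saccade onsets for fixation trials.

The Stimulus-only condition has no saccade, so its trials cannot be locked
to a real saccade onset. To scramble stimulus-evoked activity across trials
in the same way as in the saccade conditions, saccade-onset latencies are
resampled from per-participant, per-feature kernel density estimates (one
Gaussian KDE per combination of orientation x spatial frequency x phase,
eight cells). Each Stimulus-only trial receives ``n_draws`` (default 1000)
simulated onsets; iteration k relocks every trial to its k-th onset,
averages, combines and baseline-corrects exactly like the real conditions,
solves the GLM, and the element-wise median of the resulting residual traces
is the participant's statistic (median rather than mean, to be robust to
extreme iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epoching import EpochSet
from .evoked import baseline_correct
from .glm import fit_condition_glm_batch
from .layout import SensorLayout

__all__ = [
    "LatencyKde",
    "SurrogateResult",
    "fit_latency_kde",
    "fit_latency_kdes",
    "sample_onsets",
    "surrogate_regressors",
    "median_residuals",
    "feature_key",
]

MIN_CELL_N = 5
BANDWIDTH_FLOOR = 0.005  # s


def feature_key(orientation, spatial_frequency, phase) -> tuple:
    return (round(float(orientation), 3), round(float(spatial_frequency), 3),
            round(float(phase), 3))


@dataclass
class LatencyKde:
    """Gaussian-kernel latency density, truncated to the support by rejection."""

    latencies: np.ndarray
    bandwidth: float
    support: tuple = (0.150, 0.500)
    participant: int = -1
    key: tuple | None = None
    pooled_fallback: bool = False

    def pdf(self, grid: np.ndarray) -> np.ndarray:
        """Truncated-renormalized mixture density; integrates to 1 on support."""
        from scipy.stats import norm
        grid = np.asarray(grid, dtype=float)
        h, a, b = self.bandwidth, *self.support
        comp = norm.pdf((grid[:, None] - self.latencies[None, :]) / h) / h
        mass = (norm.cdf((b - self.latencies) / h)
                - norm.cdf((a - self.latencies) / h)).mean()
        dens = comp.mean(axis=1) / mass
        dens[(grid < a) | (grid > b)] = 0.0
        return dens

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Smoothed bootstrap with rejection outside the support."""
        a, b = self.support
        out = np.empty(n)
        filled = 0
        while filled < n:
            m = n - filled
            vals = rng.choice(self.latencies, size=2 * m + 8) \
                + rng.normal(0.0, self.bandwidth, size=2 * m + 8)
            vals = vals[(vals >= a) & (vals <= b)]
            take = min(len(vals), m)
            out[filled:filled + take] = vals[:take]
            filled += take
        return out


def _silverman(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return BANDWIDTH_FLOOR
    return max(BANDWIDTH_FLOOR, 0.9 * spread * n ** (-0.2))


def fit_latency_kde(latencies, support=(0.150, 0.500), participant=-1,
                    key=None, pooled_fallback=False) -> LatencyKde:
    """Gaussian KDE with Silverman's bandwidth, floored at 5 ms."""
    lat = np.asarray(latencies, dtype=float)
    if len(lat) < 1:
        raise ValueError("no latencies to fit")
    return LatencyKde(latencies=lat, bandwidth=_silverman(lat),
                      support=tuple(support), participant=participant, key=key,
                      pooled_fallback=pooled_fallback)


def fit_latency_kdes(saccade_meta: pd.DataFrame, support=(0.150, 0.500),
                     participant: int = -1) -> dict:
    """One KDE per stimulus-feature cell of a participant's saccade trials.

    ``saccade_meta`` needs columns latency / orientation / spatial_frequency
    / phase (the Saccade+stimulus condition). Cells with fewer than five
    latencies fall back to the participant's pooled distribution, with a
    warning.
    """
    pooled = saccade_meta["latency"].to_numpy()
    kdes = {}
    for (o, s, p), grp in saccade_meta.groupby(
            ["orientation", "spatial_frequency", "phase"]):
        k = feature_key(o, s, p)
        lat = grp["latency"].to_numpy()
        if len(lat) < MIN_CELL_N:
            warnings.warn(f"feature cell {k} has {len(lat)} latencies; "
                          "falling back to the pooled distribution")
            kdes[k] = fit_latency_kde(pooled, support, participant, k,
                                      pooled_fallback=True)
        else:
            kdes[k] = fit_latency_kde(lat, support, participant, k)
    return kdes


def sample_onsets(kdes: dict, trial_features: pd.DataFrame, n_draws: int = 1000,
                  seed: int = 0, participant: int = 0) -> np.ndarray:
    """Draw ``n_draws`` surrogate onsets per Stimulus-only trial.

    Returns (n_trials, n_draws); draw k of every trial belongs to surrogate
    iteration k. Per-trial substreams are derived from the master seed by
    counter-based key splitting, so the draws do not depend on execution
    order.
    """
    n_trials = len(trial_features)
    out = np.empty((n_trials, n_draws))
    for i in range(n_trials):
        row = trial_features.iloc[i]
        k = feature_key(row["orientation"], row["spatial_frequency"], row["phase"])
        if k not in kdes:
            raise KeyError(f"no latency KDE for feature cell {k}")
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), int(participant), 11, i]))
        out[i] = kdes[k].sample(n_draws, rng)
    return out


def surrogate_regressors(stimulus_epochs: EpochSet, onsets: np.ndarray,
                         layout: SensorLayout, window=(-0.6, 0.0),
                         baseline=(-0.6, -0.5)):
    """Build one surrogate Stimulus-only evoked gradient per iteration.

    For iteration k every Stimulus-only trial is relocked to its k-th
    simulated onset (stimulus onset = t 0 of ``stimulus_epochs``), then the
    trials are averaged, pair-combined and baseline-corrected exactly as the
    real conditions. Returns (regressors (n_draws, n_sites, n_win_samples),
    t_win, dropped_log).
    """
    data, t, sf = stimulus_epochs.data, stimulus_epochs.t, stimulus_epochs.sfreq
    n_trials, nch, ns = data.shape
    onsets = np.asarray(onsets, dtype=float)
    if onsets.shape[0] != n_trials:
        raise ValueError("one onset row per trial required")
    n_draws = onsets.shape[1]
    i0 = int(round(window[0] * sf))
    i1 = int(round(window[1] * sf))
    offs = np.arange(i0, i1 + 1)
    base = int(round(t[0] * sf))
    centers = np.round(onsets * sf).astype(int) - base  # (trials, draws)
    ok = (centers + i0 >= 0) & (centers + i1 < ns)
    dropped = [(int(tr), int(k)) for tr, k in zip(*np.nonzero(~ok))]
    t_win = offs / sf

    pair_index = _pair_rows(layout, stimulus_epochs.ch_names)
    nw = len(offs)
    out = np.empty((n_draws, layout.n_sites, nw))
    if not ok.all(axis=0).all():
        # rare path: some iteration misses a trial; go draw by draw
        trials = np.arange(n_trials)
        chans = np.arange(nch)
        for k in range(n_draws):
            use = ok[:, k]
            if not use.any():
                raise ValueError(f"iteration {k}: no trial covers the window")
            idx = centers[use, k][:, None] + offs[None, :]
            cut = data[trials[use][:, None, None], chans[None, :, None],
                       idx[:, None, :]]
            avg = cut.mean(axis=0)
            comb = np.hypot(avg[pair_index[:, 0]], avg[pair_index[:, 1]])
            out[k] = baseline_correct(comb, t_win, baseline)
        return out, t_win, dropped
    # fast path: gather draws in chunks and average over trials in one pass
    flat = data.transpose(1, 0, 2)  # (ch, trials, samples)
    chunk = max(1, int(4e6 // (n_trials * nw * nch)))
    for k0 in range(0, n_draws, chunk):
        k1 = min(n_draws, k0 + chunk)
        idx = centers[:, k0:k1, None] + offs[None, None, :]  # (trials, kc, nw)
        cut = flat[:, np.arange(n_trials)[:, None, None], idx]  # (ch, trials, kc, nw)
        avg = cut.mean(axis=1)                                  # (ch, kc, nw)
        comb = np.hypot(avg[pair_index[:, 0]], avg[pair_index[:, 1]])
        out[k0:k1] = np.moveaxis(
            baseline_correct(comb, t_win, baseline), 1, 0)
    return out, t_win, dropped


def _pair_rows(layout: SensorLayout, ch_names) -> np.ndarray:
    index = {c: i for i, c in enumerate(ch_names)}
    rows = np.empty((layout.n_sites, 2), dtype=int)
    for s, site in enumerate(layout.site_ids):
        c1, c2 = layout.pairs[site]
        rows[s] = (index[c1], index[c2])
    return rows


@dataclass
class SurrogateResult:
    """Element-wise median over the n_draws residual traces, per site."""

    median_residual: np.ndarray   # (n_sites, n_samples)
    t: np.ndarray
    site_ids: list
    n_draws: int
    seed: int
    betas: np.ndarray | None = None      # (n_draws, n_sites, 2) if retained
    r2: np.ndarray | None = None         # (n_draws, n_sites)


def median_residuals(y: np.ndarray, x_saccade: np.ndarray,
                     x_stimulus_draws: np.ndarray, t: np.ndarray,
                     n_draws: int, seed: int = 0, site_ids=None,
                     keep_betas: bool = False) -> SurrogateResult:
    """Solve the GLM once per surrogate iteration; take the element-wise median.

    y, x_saccade: (n_sites, n_samples); x_stimulus_draws:
    (n_draws, n_sites, n_samples).
    """
    if x_stimulus_draws.shape[0] != n_draws:
        raise ValueError(f"expected {n_draws} iterations, "
                         f"got {x_stimulus_draws.shape[0]}")
    n_sites, ns = y.shape
    resid = np.empty((n_draws, n_sites, ns))
    betas = np.empty((n_draws, n_sites, 2)) if keep_betas else None
    r2 = np.empty((n_draws, n_sites)) if keep_betas else None
    for k in range(n_draws):
        b, r, v = fit_condition_glm_batch(y, x_saccade, x_stimulus_draws[k])
        resid[k] = r
        if keep_betas:
            betas[k] = b
            r2[k] = v
    med = np.median(resid, axis=0)
    return SurrogateResult(median_residual=med, t=np.asarray(t), n_draws=n_draws,
                           seed=seed, site_ids=list(site_ids or []),
                           betas=betas, r2=r2)
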