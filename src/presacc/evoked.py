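"""Saccade-locked event-related combined planar gradients.

The order of operations is fixed: average over trials per gradiometer
channel first, then combine each gradiometer pair by root-sum-of-squares,
then subtract the mean of the [-0.6, -0.5] s baseline. No temporal filter is
applied anywhere in this chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epoching import EpochSet
from .layout import SensorLayout

__all__ = [
    "EvokedGradient",
    "average_evoked",
    "combine_planar",
    "baseline_correct",
    "compute_evoked",
    "baseline_indices",
]


@dataclass
class EvokedGradient:
    """Per-site combined planar gradient (averaged, combined, baseline-corrected)."""

    values: np.ndarray       # (n_sites, n_samples)
    t: np.ndarray
    site_ids: list
    baseline_window: tuple = (-0.6, -0.5)
    condition: str = ""
    participant: int = -1

    def to_tsv(self, path) -> None:
        """Long-format (site, t, value) table for inspection."""
        import pandas as pd
        n_sites, ns = self.values.shape
        pd.DataFrame({
            "site": np.repeat(self.site_ids, ns),
            "t": np.tile(self.t, n_sites),
            "value": self.values.ravel(),
        }).to_csv(path, sep="\t", index=False, float_format="%.8g")


def average_evoked(epochs: EpochSet) -> np.ndarray:
    """Arithmetic mean over trials, per channel and sample."""
    if epochs.n_trials < 1:
        raise ValueError("cannot average an empty epoch set")
    return epochs.data.mean(axis=0)


def combine_planar(avg: np.ndarray, layout: SensorLayout, ch_names=None) -> np.ndarray:
    """Root-sum-of-squares of each site's gradiometer pair: sqrt(g1^2 + g2^2)."""
    if ch_names is None:
        ch_names = layout.ch_names
    index = {c: i for i, c in enumerate(ch_names)}
    out = np.empty((layout.n_sites, avg.shape[-1]), dtype=float)
    for s, site in enumerate(layout.site_ids):
        c1, c2 = layout.pairs[site]
        if c1 not in index or c2 not in index:
            raise ValueError(f"gradiometer pair missing for site {site}")
        out[s] = np.hypot(avg[index[c1]], avg[index[c2]])
    return out


def baseline_indices(t: np.ndarray, window=(-0.6, -0.5)) -> np.ndarray:
    """Half-open sample selection: window[0] <= t < window[1]."""
    m = (t >= window[0] - 1e-12) & (t < window[1] - 1e-12)
    if not m.any():
        raise ValueError(f"baseline window {window} outside the time axis")
    return m


def baseline_correct(values: np.ndarray, t: np.ndarray,
                     window=(-0.6, -0.5)) -> np.ndarray:
    """Subtract each site's mean over the baseline window from its whole trace."""
    m = baseline_indices(t, window)
    return values - values[..., m].mean(axis=-1, keepdims=True)


def compute_evoked(epochs: EpochSet, layout: SensorLayout,
                   baseline=(-0.6, -0.5), condition: str = "",
                   participant: int = -1) -> EvokedGradient:
    """Average -> combine -> baseline-correct, in that order."""
    avg = average_evoked(epochs)
    comb = combine_planar(avg, layout, epochs.ch_names)
    vals = baseline_correct(comb, epochs.t, baseline)
    return EvokedGradient(values=vals, t=epochs.t.copy(), site_ids=list(layout.site_ids),
                          baseline_window=tuple(baseline), condition=condition,
                          participant=participant)
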