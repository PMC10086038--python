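"""Filtering, photodiode timing, epoching and the trial-inclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presacc.epoching import (EpochSet, ScreenGeometry, dft_notch, downsample,
                              downsample_array, epoch_around,
                              photodiode_trinary, relock_to_saccade,
                              select_fixation_trials, select_saccade_trials,
                              visual_onsets)
from presacc.eye_events import SaccadeEvent


def _sine(f, sfreq=1000.0, dur=2.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    return np.sin(2 * np.pi * f * t)


class TestDftNotch:
    def test_removes_50hz(self):
        x = _sine(50.0)[None, :]
        out = dft_notch(x, 1000.0)
        assert np.sqrt((out**2).mean()) < 1e-8 * np.sqrt((x**2).mean())

    def test_dc_unchanged(self):
        x = np.full((2, 1000), 3.7)
        assert np.allclose(dft_notch(x, 1000.0), x)

    def test_passband_preserved(self):
        x = _sine(10.0)[None, :]
        out = dft_notch(x, 1000.0)
        assert np.abs(out - x).max() < 1e-6

    def test_nyquist_error(self):
        with pytest.raises(ValueError):
            dft_notch(np.zeros((1, 100)), 100.0, freqs=(50.0,))


class TestDownsample:
    def test_sample_count(self):
        x = np.zeros((3, 4, 2000))
        assert downsample_array(x, 1000.0, 500.0).shape == (3, 4, 1000)

    def test_dc_identity(self):
        x = np.full((1, 2000), 2.5)
        assert np.allclose(downsample_array(x, 1000.0, 500.0), 2.5)

    def test_sine_amplitude(self):
        x = _sine(10.0)[None, :]
        out = downsample_array(x, 1000.0, 500.0)[0]
        assert out.max() == pytest.approx(1.0, abs=0.01)

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            downsample_array(np.zeros((1, 100)), 1000.0, 300.0)


class TestPhotodiode:
    def test_trinary_inclusive_boundaries(self):
        out = photodiode_trinary(np.array([0.0, 1.5, 3.0]))
        assert list(out) == [-1, 0, 1]

    def test_trinary_two_level(self):
        out = photodiode_trinary(np.array([0.0, 0.0, 3.0, 3.0]))
        assert list(out) == [-1, -1, 1, 1]

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            photodiode_trinary(np.full(10, 2.0))

    def test_interior_convention(self):
        # six-point grid on [0, 5]: boundaries at 1,2,3,4
        out = photodiode_trinary(np.array([0.0, 2.5, 5.0, 1.5]), "interior")
        assert list(out) == [-1, 0, 1, -1]

    def test_onsets_basic(self):
        t = visual_onsets(np.array([-1, -1, 1, 1]), 500.0)
        assert np.allclose(t, [2 / 500.0])

    def test_onsets_none(self):
        assert len(visual_onsets(np.zeros(10), 500.0)) == 0

    def test_onsets_double(self):
        t = visual_onsets(np.array([0, 1, 0]), 500.0)
        assert np.allclose(t, [1 / 500.0, 2 / 500.0])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=60))
    def test_trinary_values(self, vals):
        raw = np.asarray(vals)
        if raw.max() - raw.min() <= 0:
            return
        out = photodiode_trinary(raw)
        assert set(np.unique(out)) <= {-1, 0, 1}
        assert out[np.argmin(raw)] == -1 and out[np.argmax(raw)] == 1


def _toy_epochs(n_trials, n_samples=100, sfreq=100.0, t0=-0.2, meta=None):
    data = np.zeros((n_trials, 2, n_samples))
    t = t0 + np.arange(n_samples) / sfreq
    if meta is None:
        meta = pd.DataFrame({"trial": np.arange(n_trials)})
    return EpochSet(data, t, sfreq, ["a", "b"], "stimulus_onset", meta)


def _ev(onset, end_x=-7.0, end_y=0.0):
    return SaccadeEvent(onset, onset + 0.05, 0, 0, 14.0, 300.0, (7.0, 0.0),
                        (end_x, end_y))


class TestSelectSaccadeTrials:
    def test_toy_table_one_survivor(self):
        """Six constructed trials; each of five violates exactly one rule."""
        eps = _toy_epochs(6, 400, 500.0, t0=-0.2)
        events = [
            [_ev(0.2), _ev(0.4)],          # two saccades
            [_ev(0.2, end_x=-3.0)],        # endpoint only 3 deg past midline
            [_ev(0.2, end_y=-3.0)],        # endpoint too low
            [_ev(0.120)],                  # latency below 150 ms
            [_ev(0.550)],                  # latency above 500 ms
            [_ev(0.300)],                  # fully compliant
        ]
        sel, log = select_saccade_trials(eps, events, ScreenGeometry())
        assert sel.n_trials == 1
        assert sel.meta["trial"].tolist() == [5]
        reasons = dict(zip(log["trial"], log["reason"]))
        assert reasons == {0: "multiple_saccades", 1: "endpoint_x",
                           2: "endpoint_y", 3: "latency_low",
                           4: "latency_high"}

    def test_all_compliant_retained(self):
        eps = _toy_epochs(4, 400, 500.0)
        events = [[_ev(0.3)] for _ in range(4)]
        sel, log = select_saccade_trials(eps, events, ScreenGeometry())
        assert sel.n_trials == 4 and len(log) == 0

    def test_boundary_latencies_inclusive(self):
        eps = _toy_epochs(2, 400, 500.0)
        events = [[_ev(0.150)], [_ev(0.500)]]
        sel, log = select_saccade_trials(eps, events, ScreenGeometry())
        assert sel.n_trials == 2
        assert sel.meta["latency_boundary"].all()

    def test_conservation(self):
        eps = _toy_epochs(5, 400, 500.0)
        events = [[_ev(0.3)], [], [_ev(0.1)], [_ev(0.3), _ev(0.5)], [_ev(0.2)]]
        sel, log = select_saccade_trials(eps, events, ScreenGeometry())
        assert sel.n_trials + len(log) == 5
        assert set(log["trial"]) | set(sel.meta["trial"]) == set(range(5))

    def test_missing_events_error(self):
        with pytest.raises(ValueError):
            select_saccade_trials(_toy_epochs(1), None, ScreenGeometry())


class TestSelectFixationTrials:
    def test_rules(self):
        eps = _toy_epochs(3, 50, 100.0)
        good = np.full((50, 2), [7.0, 0.0])
        drift = good.copy()
        drift[30] = [9.6, 0.0]  # 2.6 deg excursion
        gaze = [drift, good, good]
        micro = SaccadeEvent(0.1, 0.12, 10, 12, 0.7, 30.0, (7, 0), (7.5, 0.5))
        events = [[], [micro], []]
        sel, log = select_fixation_trials(eps, gaze, events)
        assert sel.meta["trial"].tolist() == [2]
        reasons = dict(zip(log["trial"], log["reason"]))
        assert reasons == {0: "gaze_excursion", 1: "microsaccade"}

    def test_small_jitter_retained(self):
        eps = _toy_epochs(1, 50, 100.0)
        g = np.full((50, 2), [7.0, 0.0]) + 0.05
        micro = SaccadeEvent(0.1, 0.12, 10, 12, 0.3, 30.0, (7, 0), (7.3, 0))
        sel, log = select_fixation_trials(eps, [g], [[micro]])
        assert sel.n_trials == 1 and len(log) == 0

    def test_missing_gaze_error(self):
        with pytest.raises(ValueError):
            select_fixation_trials(_toy_epochs(1), None, [[]])


class TestRelock:
    def _epochs_with_marker(self, latencies, sfreq=500.0):
        n = len(latencies)
        ns = int(1.2 * sfreq)
        t0 = -0.5
        data = np.zeros((n, 1, ns))
        for i, lat in enumerate(latencies):
            j = int(round((lat - t0) * sfreq))
            data[i, 0, j] = 1.0  # marker at the saccade-onset sample
            k = int(round((0.0 - t0) * sfreq))
            data[i, 0, k] += 10.0  # marker at stimulus onset
        meta = pd.DataFrame({"latency": latencies})
        return EpochSet(data, t0 + np.arange(ns) / sfreq, sfreq, ["a"],
                        "stimulus_onset", meta)

    def test_marker_at_zero(self):
        eps = self._epochs_with_marker([0.300, 0.150])
        out, log = relock_to_saccade(eps)
        assert len(log) == 0
        assert out.t[0] == pytest.approx(-0.6)
        assert out.t[-1] == pytest.approx(0.0)
        i0 = np.argmin(np.abs(out.t - 0.0))
        assert (out.data[:, 0, i0] >= 1.0).all()

    def test_stimulus_marker_at_minus_latency(self):
        """Stimulus onset lands at t = -latency (within one sample)."""
        eps = self._epochs_with_marker([0.300, 0.450])
        out, _ = relock_to_saccade(eps)
        for i, lat in enumerate([0.300, 0.450]):
            j = int(np.argmax(out.data[i, 0] >= 10.0))
            assert out.t[j] == pytest.approx(-lat, abs=1.0 / out.sfreq)

    def test_uncovered_trial_dropped(self):
        eps = self._epochs_with_marker([0.050])  # window would start pre-epoch
        out, log = relock_to_saccade(eps)
        assert out.n_trials == 0
        assert log["reason"].tolist() == ["window_not_covered"]


class TestCommutation:
    def test_notch_downsample_commute_with_epoching(self):
        """Filtering the continuous trace then epoching matches epoch-wise
        filtering on deterministic band-limited data (integer line-noise
        cycles per window)."""
        sfreq = 1000.0
        n = 8000
        t = np.arange(n) / sfreq
        x = np.sin(2 * np.pi * 8 * t) + 0.5 * np.sin(2 * np.pi * 50 * t)
        data = x[None, :]
        events = [2.0, 3.5, 5.0]
        meta = pd.DataFrame({"trial": range(3)})
        # continuous: notch then epoch then downsample
        a = epoch_around(dft_notch(data, sfreq), sfreq, events, (-0.5, 1.0),
                         ["a"], "stimulus_onset", meta)
        a = downsample(a, 500.0)
        # epoch first, then notch per epoch, then downsample
        b = epoch_around(data, sfreq, events, (-0.5, 1.0), ["a"],
                         "stimulus_onset", meta)
        b_data = dft_notch(b.data, sfreq)
        b = EpochSet(b_data, b.t, sfreq, b.ch_names, b.lock, b.meta)
        b = downsample(b, 500.0)
        rms = np.sqrt((a.data**2).mean())
        # interior samples only: filtfilt edges differ by construction
        sl = slice(30, -30)
        assert np.abs(a.data[..., sl] - b.data[..., sl]).max() < 1e-6 * rms
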