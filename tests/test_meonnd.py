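"""MEONND: the exact neuron-weight identity, sampling-layer behaviour,
classifier and post-processing contracts, and detector invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgmeo import (
    MEONNDConfig,
    NetworkWeights,
    Signal,
    classify,
    conv_energy_layer,
    kteo,
    mask_to_events,
    meonnd_detect,
    meonnd_forward,
    postprocess_mask,
)
from emgmeo.meonnd import _sampling_layer
from emgmeo.signal import OFFSET, ONSET


class TestConvEnergyLayer:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 2**20), k=st.integers(1, 10))
    def test_identity_with_kteo(self, seed, k):
        """The fixed-weight neuron expansion equals the lag-k energy
        operator to machine precision (the cross terms cancel exactly)."""
        x = np.random.default_rng(seed).normal(size=50)
        sig = Signal(x, fs=1.0)
        got = conv_energy_layer(sig, k).values
        ref = kteo(sig, k).values
        np.testing.assert_allclose(got, ref, rtol=1e-12, atol=1e-12)

    def test_constant_signal_zero(self):
        out = conv_energy_layer(Signal(np.full(30, 2.0), fs=1.0), 3)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_ramp_example(self):
        out = conv_energy_layer(Signal([1, 2, 3, 4, 5], fs=1.0), 1)
        np.testing.assert_allclose(out.values, [0, 1, 1, 1, 0], atol=1e-12)

    def test_non_canonical_weights_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            NetworkWeights(W4=1.0)
        with pytest.raises(ValueError, match="non-canonical"):
            NetworkWeights(w33=0.5)


class TestSamplingLayer:
    def test_constant_input_all_zero(self):
        y = meonnd_forward(Signal(np.full(200, 3.0), fs=1.0), MEONNDConfig(k_max=4, median_len=5))
        np.testing.assert_array_equal(y, np.zeros(200))

    def test_output_in_unit_interval(self, rng):
        for norm in ("global", "running", "trailing"):
            x = rng.normal(size=300)
            y = meonnd_forward(
                Signal(x, fs=1.0), MEONNDConfig(k_max=5, median_len=5, norm=norm)
            )
            assert np.all(y >= 0.0) and np.all(y <= 1.0)

    def test_trailing_window_brute_force(self, rng):
        """Trailing mode equals a per-sample loop over the 2k-sample window
        (i-2k, i], truncated at the start of the series."""
        x = rng.normal(size=120)
        k = 4
        got = _sampling_layer(x, k, "trailing")
        w = 2 * k
        for i in range(len(x)):
            win = x[max(0, i - w + 1):i + 1]
            mn, mx = win.min(), win.max()
            expected = 0.0 if mx == mn else (x[i] - mn) / (mx - mn)
            assert got[i] == pytest.approx(expected)

    def test_strictly_increasing_trailing_is_one(self):
        x = np.arange(50.0)
        y = _sampling_layer(x, 3, "trailing")
        # every sample past the first is its window's max, with min < max
        assert np.all(y[1:] == 1.0)
        assert y[0] == 0.0  # degenerate single-sample window


class TestClassify:
    def test_sigmoid_of_zero_below_default_threshold(self):
        assert classify(np.array([0.0]), 0.506)[0] == 0

    def test_sigmoid_of_one_above_default_threshold(self):
        # 1/(1+e^-1) = 0.7311 >= 0.506
        assert classify(np.array([1.0]), 0.506)[0] == 1

    def test_threshold_below_half_activates_everything(self, rng):
        y = rng.uniform(0, 1, 100)  # sigmoid range on [0,1] is [0.5, 0.732]
        assert np.all(classify(y, 0.406) == 1)

    def test_monotone_in_threshold(self, rng):
        y = rng.uniform(0, 1, 500)
        prev = classify(y, 0.406)
        for T in (0.446, 0.486, 0.506, 0.514, 0.7):
            cur = classify(y, T)
            assert np.all(cur <= prev)
            prev = cur


class TestPostprocess:
    def test_short_run_removed_at_1024hz(self):
        mask = np.zeros(200, dtype=int)
        mask[50:70] = 1  # ~20 ms at 1024 Hz < round(30*1024/1000)=31 samples
        out = postprocess_mask(mask, 30.0, fs=1024.0)
        assert np.all(out == 0)

    def test_long_run_kept(self):
        mask = np.zeros(400, dtype=int)
        mask[100:203] = 1  # ~100 ms
        out = postprocess_mask(mask, 30.0, fs=1024.0)
        np.testing.assert_array_equal(out, mask)

    def test_all_zero_unchanged(self):
        out = postprocess_mask(np.zeros(64, dtype=int), 30.0, fs=1024.0)
        assert np.all(out == 0)

    def test_no_short_runs_survive(self, rng):
        mask = (rng.random(4096) > 0.5).astype(int)
        out = postprocess_mask(mask, 30.0, fs=1024.0)
        d = np.diff(np.concatenate(([0], out, [0])))
        runs = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
        assert np.all(runs >= 31)


class TestMaskToEvents:
    def test_edge_extraction_example(self):
        mask = np.zeros(20, dtype=int)
        mask[11:14] = 1  # ones at 11..13
        out = mask_to_events(mask, fs=1.0)
        assert [(e.kind, e.index) for e in out] == [(ONSET, 11), (OFFSET, 14)]

    def test_trailing_open_run_closed_at_last_sample(self):
        mask = np.zeros(20, dtype=int)
        mask[10:] = 1
        out = mask_to_events(mask, fs=1.0)
        assert [(e.kind, e.index) for e in out] == [(ONSET, 10), (OFFSET, 19)]


class TestMeonndDetect:
    def test_zero_signal_empty(self):
        out = meonnd_detect(Signal(np.zeros(2048), fs=1024.0))
        assert len(out) == 0

    def test_scale_invariance(self, short_recording):
        """The detector needs no baseline prior: output is invariant to
        global amplitude scaling (energies are degree-2 homogeneous and the
        sampling layer normalizes scale away)."""
        base = meonnd_detect(short_recording.signal)
        for c in (0.01, 3.0, 250.0):
            scaled = meonnd_detect(short_recording.signal.scaled(c))
            assert scaled == base

    def test_high_snr_onsets_recovered(self, short_recording):
        out = meonnd_detect(
            short_recording.signal, MEONNDConfig(k_max=15, median_len=15, threshold=0.506)
        )
        det_onsets = out.onsets
        for t in short_recording.truth.onsets:
            assert np.min(np.abs(det_onsets - t)) <= 0.1

    def test_raising_threshold_never_adds_active_samples(self, short_recording):
        y = meonnd_forward(short_recording.signal)
        prev = classify(y, 0.506)
        for T in (0.51, 0.6, 0.73):
            cur = classify(y, T)
            assert np.all(cur <= prev)
            prev = cur

    def test_alternation_invariant(self, short_recording):
        out = meonnd_detect(short_recording.signal)
        kinds = [e.kind for e in out]
        assert kinds == [ONSET, OFFSET] * (len(kinds) // 2)
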