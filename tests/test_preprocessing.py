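"""Filtering, epoching, cleaning, GFP normalisation and the CV/test split."""

import numpy as np
import pytest

from localglobal.epochs import EpochSet
from localglobal.preprocessing import (bandpass, baseline_correct, extract_epochs,
                                       gfp_normalize, reject_and_interpolate,
                                       split_cv_test)
from localglobal.synthetic import HeadModel


def _sine(freq, sfreq, dur):
    t = np.arange(int(dur * sfreq)) / sfreq
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    sfreq = 250.0

    def test_dc_removed(self):
        x = np.full((1, int(80 * self.sfreq)), 7.0)
        y = bandpass(x, self.sfreq)
        assert np.abs(y[0, 2000:-2000].mean()) < 0.05

    def test_passband_preserved(self):
        x = _sine(10.0, self.sfreq, 80)[None]
        y = bandpass(x, self.sfreq)
        mid = slice(5000, -5000)
        ratio = y[0, mid].std() / x[0, mid].std()
        assert abs(ratio - 1) < 0.05

    def test_stopband_attenuated(self):
        x = _sine(60.0, self.sfreq, 80)[None]
        y = bandpass(x, self.sfreq, 0.1, 40.0)
        mid = slice(5000, -5000)
        assert y[0, mid].std() < 0.1 * x[0, mid].std()

    def test_invalid_band(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(np.zeros((1, 1000)), 250.0, 40.0, 0.1)
        with pytest.raises(ValueError, match="band"):
            bandpass(np.zeros((1, 1000)), 250.0, 0.1, 200.0)


class TestExtractEpochs:
    def _continuous(self, sfreq, dur=30.0, n_ch=4, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n_ch, int(dur * sfreq)))

    @pytest.mark.parametrize("sfreq,n_expected", [(1200.0, 720), (500.0, 300)])
    def test_sample_count(self, sfreq, n_expected):
        cont = self._continuous(sfreq)
        ep, dropped = extract_epochs(cont, sfreq, [1.0, 5.0],
                                     ["standard", "deviant"],
                                     ["standard", "standard"])
        assert ep.n_samples == n_expected and dropped == 0

    def test_index_exact(self):
        sfreq = 500.0
        cont = self._continuous(sfreq)
        ep, _ = extract_epochs(cont, sfreq, [2.0], ["standard"], ["standard"])
        start = int(round(2.0 * sfreq)) + int(round(-0.1 * sfreq))
        np.testing.assert_array_equal(ep.data[0], cont[:, start:start + 300])

    def test_edge_events_dropped(self):
        sfreq = 500.0
        cont = self._continuous(sfreq, dur=10.0)
        with pytest.warns(UserWarning, match="dropped"):
            ep, dropped = extract_epochs(cont, sfreq, [0.05, 5.0, 9.9],
                                         ["standard"] * 3, ["standard"] * 3)
        assert dropped == 2 and ep.n_trials == 1


def _toy_epochs(n_trials=20, n_ch=8, n_samp=30, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    head = HeadModel.random(n_ch, seed=seed)
    labels = np.array(["standard"] * (n_trials - 5) + ["deviant"] * 5)
    return EpochSet(data=rng.normal(0, noise, (n_trials, n_ch, n_samp)),
                    times=-0.1 + np.arange(n_samp) / 50.0, sfreq=50.0,
                    labels_global=labels, labels_local=labels,
                    chan_pos=head.positions)


class TestRejectInterpolate:
    def test_clean_data_untouched(self):
        ep = _toy_epochs()
        cleaned, report = reject_and_interpolate(ep, amp_thresh=100.0)
        assert report["n_dropped"] == 0 and report["interpolated_channels"] == []
        np.testing.assert_array_equal(cleaned.data, ep.data)

    def test_bad_channel_interpolated(self):
        ep = _toy_epochs()
        ep.data[:, 3, :] *= 50.0  # persistently bad channel
        cleaned, report = reject_and_interpolate(ep, amp_thresh=20.0)
        assert report["interpolated_channels"] == [3]
        assert np.abs(cleaned.data[:, 3, :]).max() < 20.0
        assert cleaned.n_trials == ep.n_trials

    def test_spiky_epoch_dropped(self):
        ep = _toy_epochs()
        ep.data[7, 2, 5] = 500.0
        cleaned, report = reject_and_interpolate(ep, amp_thresh=100.0)
        assert report["dropped_epochs"] == [7]
        assert report["n_retained"] + report["n_dropped"] == report["n_input"]
        assert cleaned.n_trials == ep.n_trials - 1

    def test_all_rejected_raises(self):
        ep = _toy_epochs()
        with pytest.raises(ValueError, match="threshold"):
            reject_and_interpolate(ep, amp_thresh=1e-6, bad_channel_frac=2.0)


class TestGfpNormalize:
    def _one(self, topo):
        topo = np.asarray(topo, dtype=float)
        ep = EpochSet(data=topo[None, :, None], times=np.array([0.0]), sfreq=1.0,
                      labels_global=["standard"], labels_local=["standard"])
        return gfp_normalize(ep)

    def test_already_unit_gfp(self):
        out = self._one([1.0, -1.0])
        np.testing.assert_allclose(out.data[0, :, 0], [1.0, -1.0])
        assert out.gfp[0, 0] == pytest.approx(1.0)

    def test_average_reference_then_divide(self):
        out = self._one([2.0, 0.0])
        np.testing.assert_allclose(out.data[0, :, 0], [1.0, -1.0])

    def test_constant_topography_masked(self):
        out = self._one([5.0, 5.0])
        assert not out.mask[0, 0]
        np.testing.assert_array_equal(out.data[0, :, 0], [0.0, 0.0])

    def test_unit_gfp_invariant(self, rng):
        ep = _toy_epochs(seed=4)
        out = gfp_normalize(ep)
        ref = out.data - out.data.mean(axis=1, keepdims=True)
        gfp = ref.std(axis=1)
        np.testing.assert_allclose(gfp[out.mask], 1.0, atol=1e-9)

    def test_needs_two_channels(self):
        ep = EpochSet(data=np.zeros((1, 1, 3)), times=np.arange(3) / 10, sfreq=10.0,
                      labels_global=["standard"], labels_local=["standard"])
        with pytest.raises(ValueError):
            gfp_normalize(ep)


class TestSplit:
    def _labelled(self, n_std, n_dev):
        n = n_std + n_dev
        labels = np.array(["standard"] * n_std + ["deviant"] * n_dev)
        return EpochSet(data=np.zeros((n, 2, 3)), times=np.arange(3) / 10.0,
                        sfreq=10.0, labels_global=labels, labels_local=labels)

    def test_session_proportions(self):
        cv, test = split_cv_test(self._labelled(800, 160), seed=0)
        assert test.n_trials == 192
        assert (test.labels_global == "deviant").sum() == 32
        assert (cv.labels_global == "deviant").sum() == 128

    def test_exact_fifths(self):
        cv, test = split_cv_test(self._labelled(10, 10), seed=1)
        assert (test.labels_global == "deviant").sum() == 2
        assert (test.labels_global == "standard").sum() == 2

    def test_deterministic_and_disjoint(self):
        ep = self._labelled(40, 10)
        ep.data = np.random.default_rng(0).normal(size=ep.data.shape)
        cv1, te1 = split_cv_test(ep, seed=5)
        cv2, te2 = split_cv_test(ep, seed=5)
        np.testing.assert_array_equal(te1.data, te2.data)
        assert cv1.n_trials + te1.n_trials == ep.n_trials

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_cv_test(self._labelled(20, 4))


def test_baseline_correct():
    ep = _toy_epochs(seed=2)
    ep.data += 3.0
    out = baseline_correct(ep)
    pre = out.times < 0
    np.testing.assert_allclose(out.data[:, :, pre].mean(axis=2), 0.0, atol=1e-12)
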