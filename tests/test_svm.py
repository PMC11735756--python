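"""SVM decoding: features, grid selection, time-resolved decoding, sub-averages."""

import numpy as np
import pytest

from localglobal.epochs import EpochSet
from localglobal.pipeline import decode_once
from localglobal.preprocessing import split_cv_test
from localglobal.svm import (SubaverageSpec, SvmConfig, build_features_concat,
                             cv_select_svm, decode_test_svm, subaverage,
                             timepoint_decode)


def _epochs(data, labels):
    labels = np.asarray(labels)
    n, _, s = data.shape
    return EpochSet(data=data, times=np.arange(s) / 10.0, sfreq=10.0,
                    labels_global=labels, labels_local=labels)


class TestFeatures:
    def test_concat_order_channel_major(self):
        data = np.arange(2 * 2 * 3, dtype=float).reshape(2, 2, 3)
        ep = _epochs(data, ["standard", "deviant"])
        x = build_features_concat(ep)
        np.testing.assert_array_equal(x[0], [0, 1, 2, 3, 4, 5])
        np.testing.assert_array_equal(x[1], [6, 7, 8, 9, 10, 11])

    def test_dimension_product(self):
        data = np.zeros((2, 63, 720))
        x = build_features_concat(_epochs(data, ["standard", "deviant"]))
        assert x.shape == (2, 45360)

    def test_roundtrip(self, rng):
        data = rng.normal(size=(4, 3, 5))
        x = build_features_concat(_epochs(data, ["standard"] * 3 + ["deviant"]))
        np.testing.assert_array_equal(x.reshape(4, 3, 5), data)

    def test_nan_rejected(self):
        data = np.zeros((2, 2, 2))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            build_features_concat(_epochs(data, ["standard", "deviant"]))


def _separable(rng, n=60, d=10, gap=6.0):
    y = np.arange(n) % 2 == 1   # interleaved so any slice keeps both classes
    x = rng.normal(size=(n, d))
    x[y, 0] += gap
    return x, y


class TestSelection:
    def test_separable_reaches_auc_one(self, rng):
        x, y = _separable(rng)
        cfg = SvmConfig(kernels=("linear",), c_grid=(0.1, 1.0), n_folds=3, seed=0)
        params, cv_auc, ledger = cv_select_svm(x, y, cfg)
        assert cv_auc == pytest.approx(1.0)
        assert len(ledger) == 2

    def test_grid_of_one_returned_unchanged(self, rng):
        x, y = _separable(rng)
        cfg = SvmConfig(kernels=("rbf",), c_grid=(10.0,), gamma_grid=(0.1,),
                        n_folds=3, seed=0)
        params, _, ledger = cv_select_svm(x, y, cfg)
        assert params == {"kernel": "rbf", "C": 10.0, "gamma": 0.1}
        assert len(ledger) == 1

    def test_gamma_ignored_for_linear(self):
        cfg = SvmConfig(kernels=("linear",), c_grid=(1.0,), gamma_grid=(0.1, 1.0))
        assert len(cfg.grid) == 1

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            SvmConfig(c_grid=(0.0,))
        with pytest.raises(ValueError):
            SvmConfig(kernels=())

    def test_deterministic(self, rng):
        x = rng.normal(size=(60, 5))
        y = np.arange(60) % 2 == 0
        cfg = SvmConfig(kernels=("linear",), c_grid=(0.1, 1.0), n_folds=3, seed=4)
        assert cv_select_svm(x, y, cfg)[:2] == cv_select_svm(x, y, cfg)[:2]


class TestDecodeTest:
    def test_high_snr_pipeline(self, high_snr_epochs, reduced_cfg):
        import dataclasses
        cfg = dataclasses.replace(reduced_cfg, decoder="svm_concat")
        auc, details = decode_once(high_snr_epochs, "global", cfg, seed=2)
        assert auc > 0.9
        assert details["selected"]["kernel"] in ("linear", "rbf")

    def test_label_inversion_complements_auc(self, rng):
        """The fitted model's margins scored against inverted test labels
        give exactly the complementary AUC."""
        from localglobal.inference import compute_auc

        x, y = _separable(rng, gap=3.0)
        params = {"kernel": "linear", "C": 1.0, "gamma": "scale"}
        auc, margins = decode_test_svm(x[:40], y[:40], x[40:], y[40:], params)
        assert compute_auc(margins, ~y[40:]) == pytest.approx(1.0 - auc)

    def test_scaler_uses_cv_statistics_only(self, rng):
        """Test features far outside the CV distribution must produce large
        margins — they would be re-centred away if the scaler peeked at the
        test set."""
        x, y = _separable(rng, gap=4.0)
        params = {"kernel": "linear", "C": 1.0, "gamma": "scale"}
        x_test = x[40:].copy()
        x_test[:, 0] += 50.0
        _, margins = decode_test_svm(x[:40], y[:40], x_test, y[40:], params)
        assert margins.mean() > 1.0


class TestTimepoint:
    def test_planted_latency_found(self, high_snr_epochs, reduced_cfg):
        cv, test = split_cv_test(high_snr_epochs, "global", seed=1)
        times, aucs = timepoint_decode(cv, test, "global")
        peak_t = times[np.argmax(aucs)]
        assert 0.3 <= peak_t < 0.5
        baseline = aucs[times < 0]
        assert abs(baseline.mean() - 0.5) < 0.15


class TestSubaverage:
    def _labelled(self, rng, n_std=10, n_dev=7):
        labels = np.array(["standard"] * n_std + ["deviant"] * n_dev)
        data = rng.normal(size=(n_std + n_dev, 3, 4))
        return _epochs(data, labels)

    def test_counts_floor_and_leftover(self, rng):
        ep = self._labelled(rng, 10, 7)
        out = subaverage(ep, SubaverageSpec(3, seed=0), "global")
        # floor(10/3)=3 standards, floor(7/3)=2 deviants
        assert (out.labels_global == "standard").sum() == 3
        assert (out.labels_global == "deviant").sum() == 2

    def test_group_conservation(self, rng):
        ep = self._labelled(rng, 11, 8)
        out = subaverage(ep, SubaverageSpec(2, seed=0), "global")
        for cls, n_cls in (("standard", 11), ("deviant", 8)):
            kept = (out.labels_global == cls).sum()
            assert 2 * kept + (n_cls - 2 * kept) == n_cls
            assert n_cls - 2 * kept < 2

    def test_session_deviant_count(self, rng):
        ep = self._labelled(rng, 800, 160)
        out = subaverage(ep, SubaverageSpec(2, seed=1), "global")
        assert (out.labels_global == "deviant").sum() == 80

    def test_pseudo_trials_average_members(self, rng):
        ep = self._labelled(rng, 4, 4)
        out = subaverage(ep, SubaverageSpec(2, seed=0), "global")
        # each class's pseudo-trials together average all member trials
        for cls in ("standard", "deviant"):
            sel_in = ep.labels_global == cls
            sel_out = out.labels_global == cls
            np.testing.assert_allclose(out.data[sel_out].mean(axis=0),
                                       ep.data[sel_in].mean(axis=0), atol=1e-12)

    def test_noise_variance_scales_inverse_group(self, rng):
        """The SNR mechanism: averaging g iid trials divides noise variance
        by g while preserving any common signal."""
        ep = self._labelled(rng, 300, 300)
        out = subaverage(ep, SubaverageSpec(3, seed=2), "global")
        ratio = out.data.var() / ep.data.var()
        assert ratio == pytest.approx(1 / 3, rel=0.15)

    def test_invalid_group(self):
        with pytest.raises(ValueError):
            SubaverageSpec(4)

    def test_small_class_raises(self, rng):
        ep = self._labelled(rng, 10, 2)
        with pytest.raises(ValueError, match="fewer"):
            subaverage(ep, SubaverageSpec(3, seed=0), "global")
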