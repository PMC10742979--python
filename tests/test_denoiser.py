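"""Denoiser estimators, bundles, and stack-level inference."""

import numpy as np
import pytest
from sklearn.base import clone

from wunet.denoiser import (CAREDenoiser, DenoiserBundle, TrainConfig,
                            UNetConfig, WUNetDenoiser, denoise_patch,
                            denoise_stack, train)
from wunet.losses import LossSpec
from wunet.nn import UNet
from wunet.stack_io import TissueStack


def _identity_net(side, seed=0):
    cfg = UNetConfig(input_side=side, levels=2, base_channels=4,
                     n_convs_per_block=1)
    return UNet(cfg, seed=seed), cfg


@pytest.fixture
def identity_care_bundle():
    net, cfg = _identity_net(32)
    return DenoiserBundle(mode="care", networks={"single": net},
                          unet_config=cfg)


@pytest.fixture
def identity_wunet_bundle():
    net_cfg = [_identity_net(32, seed=i) for i in range(4)]
    nets = {b: net_cfg[i][0] for i, b in
            enumerate(("LL", "LH", "HL", "HH"))}
    return DenoiserBundle(mode="wunet", networks=nets,
                          unet_config=net_cfg[0][1])


class TestConfigs:
    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, plateau_patience=10)

    def test_bundle_key_validation(self):
        net, cfg = _identity_net(16)
        with pytest.raises(ValueError):
            DenoiserBundle(mode="care", networks={"LL": net},
                           unet_config=cfg)
        with pytest.raises(ValueError):
            DenoiserBundle(mode="wunet", networks={"single": net},
                           unet_config=cfg)


class TestIdentityContracts:
    def test_care_identity_patch(self, identity_care_bundle, rng):
        patch = rng.random((32, 32))
        out = denoise_patch(identity_care_bundle, patch)
        assert np.abs(out - patch).max() < 1e-10

    def test_wunet_identity_is_exact_round_trip(self, identity_wunet_bundle,
                                                rng):
        patch = rng.random((64, 64))
        out = denoise_patch(identity_wunet_bundle, patch)
        assert np.abs(out - patch).max() < 1e-10

    def test_patch_side_mismatch_rejected(self, identity_care_bundle, rng):
        with pytest.raises(ValueError):
            denoise_patch(identity_care_bundle, rng.random((64, 64)))

    def test_identity_stack_denoising(self, identity_wunet_bundle, rng):
        vox = rng.random((3, 1, 64, 64)) + 0.1
        stack = TissueStack(channel="FAD", voxels=vox,
                            provenance="raw_single")
        out = denoise_stack(identity_wunet_bundle, stack)
        assert out.provenance == "denoised"
        assert out.voxels.shape == vox.shape
        np.testing.assert_allclose(out.voxels, vox, atol=1e-9)

    def test_double_side_sections_use_patch_grid(self, identity_care_bundle,
                                                 rng):
        # 64-pixel sections over a 32-pixel bundle -> 2x2 patch route
        vox = rng.random((2, 1, 64, 64)) + 0.1
        stack = TissueStack(channel="NADPH", voxels=vox,
                            provenance="raw_single")
        out = denoise_stack(identity_care_bundle, stack)
        np.testing.assert_allclose(out.voxels, vox, atol=1e-9)

    def test_incompatible_geometry_rejected(self, identity_care_bundle, rng):
        stack = TissueStack(channel="NADPH",
                            voxels=rng.random((2, 1, 48, 48)),
                            provenance="raw_single")
        with pytest.raises(ValueError):
            denoise_stack(identity_care_bundle, stack)


@pytest.fixture(scope="module")
def tiny_training_data():
    rng = np.random.default_rng(5)
    clean = rng.random((40, 32, 32))
    noisy = clean + 0.2 * rng.standard_normal(clean.shape)
    return noisy, clean


class TestEstimators:
    def test_fit_predict_shapes_and_attributes(self, tiny_training_data):
        X, y = tiny_training_data
        est = CAREDenoiser(levels=2, base_channels=4, max_epochs=3,
                           plateau_patience=2, learning_rate=1e-3,
                           loss="mse", batch_size=8, seed=0)
        est.fit(X, y)
        assert est.input_side_ == 32
        assert est.n_epochs_ == 3
        assert est.bundle_.mode == "care"
        out = est.predict(X[:4])
        assert out.shape == (4, 32, 32) and np.isfinite(out).all()

    def test_history_best_val_monotone(self, tiny_training_data):
        X, y = tiny_training_data
        est = WUNetDenoiser(levels=2, base_channels=4, max_epochs=4,
                            plateau_patience=2, learning_rate=1e-3,
                            loss="mse", batch_size=8, seed=0)
        est.fit(X, y)
        for _, grp in est.history_.groupby("network"):
            best = grp["best_val_loss"].to_numpy()
            assert (np.diff(best) <= 1e-15).all()
        assert set(est.bundle_.networks) == {"LL", "LH", "HL", "HH"}

    def test_seeded_refit_bit_identical(self, tiny_training_data):
        X, y = tiny_training_data
        kw = dict(levels=2, base_channels=4, max_epochs=3,
                  plateau_patience=2, learning_rate=1e-3, loss="mse",
                  batch_size=8, seed=12)
        h1 = CAREDenoiser(**kw).fit(X, y).history_
        h2 = CAREDenoiser(**kw).fit(X, y).history_
        assert h1.equals(h2)

    def test_training_reduces_validation_loss(self, tiny_training_data):
        X, y = tiny_training_data
        est = CAREDenoiser(levels=2, base_channels=8, max_epochs=8,
                           plateau_patience=4, learning_rate=2e-3,
                           loss="mse", batch_size=8, seed=1)
        est.fit(X, y)
        hist = est.history_
        assert hist["val_loss"].iloc[-1] < hist["val_loss"].iloc[0]

    def test_sklearn_protocol(self):
        est = WUNetDenoiser(alpha=0.5, wavelet="db2")
        params = est.get_params()
        assert params["alpha"] == 0.5 and params["wavelet"] == "db2"
        est2 = clone(est).set_params(alpha=0.7)
        assert est2.get_params()["alpha"] == 0.7

    def test_unfitted_predict_rejected(self, rng):
        with pytest.raises(RuntimeError):
            CAREDenoiser().predict(rng.random((2, 32, 32)))

    def test_rr_loss_rejected_for_single_channel_training(
            self, tiny_training_data):
        X, y = tiny_training_data
        with pytest.raises(ValueError):
            CAREDenoiser(loss="rr", max_epochs=2,
                         plateau_patience=1).fit(X, y)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_non_finite_loss_aborts_with_diagnostic(self, tiny_training_data):
        X, y = tiny_training_data
        est = CAREDenoiser(levels=2, base_channels=4, max_epochs=3,
                           plateau_patience=2, learning_rate=1e12,
                           loss="mse", batch_size=8, seed=0)
        with pytest.raises(FloatingPointError):
            est.fit(X, y)


class TestBundlePersistence:
    def test_save_load_round_trip(self, tiny_training_data, tmp_path, rng):
        X, y = tiny_training_data
        est = WUNetDenoiser(levels=2, base_channels=4, max_epochs=2,
                            plateau_patience=1, learning_rate=1e-3,
                            loss="ssim_plus_r2", batch_size=8, seed=2)
        est.fit(X, y, channel="FAD")
        d = est.bundle_.save(tmp_path / "bundle")
        back = DenoiserBundle.load(d)
        assert back.mode == "wunet"
        assert back.trained_on_channel == "FAD"
        patch = rng.random((32, 32))
        np.testing.assert_allclose(denoise_patch(back, patch),
                                   denoise_patch(est.bundle_, patch),
                                   atol=1e-12)


class TestFunctionalTrain:
    def test_train_wrapper(self, tiny_training_data):
        X, y = tiny_training_data
        ucfg = UNetConfig(input_side=32, levels=2, base_channels=4,
                          n_convs_per_block=1)
        tc = TrainConfig(learning_rate=1e-3, max_epochs=2,
                         plateau_patience=1, batch_size=8, seed=0,
                         loss=LossSpec("mse"))
        bundle = train("care", ucfg, (X[:30], y[:30]), (X[30:], y[30:]),
                       tc, channel="NADPH")
        assert bundle.trained_on_channel == "NADPH"
        assert bundle.best_val_loss is not None

    def test_empty_sets_rejected(self, tiny_training_data):
        X, y = tiny_training_data
        ucfg = UNetConfig(input_side=32, levels=2, base_channels=4)
        tc = TrainConfig(learning_rate=1e-3, max_epochs=2,
                         plateau_patience=1, loss=LossSpec("mse"))
        with pytest.raises(ValueError):
            train("care", ucfg, (X[:0], y[:0]), (X[30:], y[30:]), tc)
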