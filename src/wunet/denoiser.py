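"""Residual U-Net denoisers: plain (CARE-style) and wavelet-routed (WU-Net).

Two scikit-learn-style estimators are provided.  ``CAREDenoiser`` trains a
single residual U-Net on (noisy, ground-truth) patch pairs.
``WUNetDenoiser`` first splits every patch into its four single-level
wavelet sub-bands and trains one network per band, each against its own
band of the ground truth; inference runs DWT -> per-band networks -> iDWT.
With identity sub-band networks WU-Net reduces to the DWT/iDWT round trip
and is the exact identity map.

Training uses Adam with reduce-on-plateau learning-rate scheduling, keeps
the best-validation-loss weights, and is reproducible bit-for-bit under a
fixed seed in single-threaded execution.  Patches are expected in
normalised intensity space (see :func:`wunet.stack_io.percentile_normalize`);
stack-level inference handles normalisation and returns output on the input
intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from . import stack_io
from .losses import LossSpec, loss_tensor
from .nn import Adam, ReduceLROnPlateau, Tensor, UNet, UNetConfig, no_grad
from .nn.unet import build_unet
from .stack_io import TissueStack, percentile_normalize, denormalize
from .wavelet import BAND_ORDER, DEFAULT_MODE, DEFAULT_WAVELET, \
    dwt_single, idwt_single, SubbandSet

__all__ = [
    "UNetConfig", "TrainConfig", "DenoiserBundle", "CAREDenoiser",
    "WUNetDenoiser", "build_unet", "train", "denoise_patch", "denoise_stack",
]


@dataclass
class TrainConfig:
    """Optimisation schedule for one (or four) denoising networks."""

    learning_rate: float = 1e-5
    max_epochs: int = 300
    plateau_patience: int = 20
    lr_factor: float = 0.5
    batch_size: int = 16
    seed: int = 0
    loss: LossSpec = field(default_factory=LossSpec)
    early_stopping: bool = False
    checkpoint_metric: str = "val_loss"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.plateau_patience < self.max_epochs:
            raise ValueError("plateau_patience must lie in (0, max_epochs)")
        if self.checkpoint_metric != "val_loss":
            raise ValueError("only val_loss checkpointing is supported")


@dataclass
class DenoiserBundle:
    """A trained denoiser: one network (care) or four keyed by sub-band."""

    mode: str                                  # "care" | "wunet"
    networks: dict[str, UNet]
    unet_config: UNetConfig
    train_config: TrainConfig | None = None
    wavelet_name: str = DEFAULT_WAVELET
    boundary_mode: str = DEFAULT_MODE
    norm_percentiles: tuple[float, float] = (0.1, 99.9)
    history: pd.DataFrame | None = None
    trained_on_channel: str | None = None
    best_val_loss: float | None = None

    def __post_init__(self):
        if self.mode == "care":
            if set(self.networks) != {"single"}:
                raise ValueError("care bundles hold one network keyed "
                                 "'single'")
        elif self.mode == "wunet":
            if set(self.networks) != set(BAND_ORDER):
                raise ValueError(f"wunet bundles hold four networks keyed "
                                 f"{BAND_ORDER}")
        else:
            raise ValueError("mode must be 'care' or 'wunet'")

    @property
    def patch_side(self) -> int:
        """Side length of the image-domain patches the bundle denoises."""
        side = self.unet_config.input_side
        return side if self.mode == "care" else 2 * side

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for key, net in self.networks.items():
            np.savez(directory / f"weights_{key}.npz",
                     *[p.data for p in net.params])
        meta = {
            "mode": self.mode,
            "wavelet_name": self.wavelet_name,
            "boundary_mode": self.boundary_mode,
            "norm_percentiles": list(self.norm_percentiles),
            "trained_on_channel": self.trained_on_channel,
            "best_val_loss": self.best_val_loss,
            "unet_config": asdict(self.unet_config),
            "train_config": (_train_config_dict(self.train_config)
                             if self.train_config else None),
        }
        (directory / "bundle.yaml").write_text(yaml.safe_dump(meta))
        if self.history is not None:
            self.history.to_csv(directory / "history.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory) -> "DenoiserBundle":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "bundle.yaml").read_text())
        ucfg = UNetConfig(**meta["unet_config"])
        tcfg = None
        if meta.get("train_config"):
            tc = dict(meta["train_config"])
            tc["loss"] = LossSpec(**tc["loss"])
            tcfg = TrainConfig(**tc)
        networks = {}
        keys = ["single"] if meta["mode"] == "care" else list(BAND_ORDER)
        for key in keys:
            net = UNet(ucfg, seed=0)
            with np.load(directory / f"weights_{key}.npz") as z:
                net.load_state([z[f] for f in z.files])
            networks[key] = net
        hist_path = directory / "history.csv"
        history = pd.read_csv(hist_path) if hist_path.exists() else None
        return cls(mode=meta["mode"], networks=networks, unet_config=ucfg,
                   train_config=tcfg, wavelet_name=meta["wavelet_name"],
                   boundary_mode=meta["boundary_mode"],
                   norm_percentiles=tuple(meta["norm_percentiles"]),
                   history=history,
                   trained_on_channel=meta.get("trained_on_channel"),
                   best_val_loss=meta.get("best_val_loss"))


def _train_config_dict(tc: TrainConfig) -> dict:
    d = asdict(tc)
    return d


# ---------------------------------------------------------------------------
# core training loop
# ---------------------------------------------------------------------------

def _batched_loss(net: UNet, X: np.ndarray, Y: np.ndarray, spec: LossSpec,
                  data_range: float, batch_size: int) -> float:
    total, n = 0.0, 0
    with no_grad():
        for i in range(0, len(X), batch_size):
            xb = Tensor(X[i:i + batch_size, None])
            yb = Tensor(Y[i:i + batch_size, None])
            out = net.forward(xb)
            val = float(loss_tensor(spec, out, yb,
                                    data_range=data_range).data)
            total += val * len(X[i:i + batch_size])
            n += len(X[i:i + batch_size])
    return total / n


def _fit_one_network(net: UNet, Xtr: np.ndarray, Ytr: np.ndarray,
                     Xval: np.ndarray, Yval: np.ndarray, tc: TrainConfig,
                     label: str = "single") -> tuple[pd.DataFrame, float]:
    """Train one network in place; restores best-validation weights."""
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("training and validation sets must be non-empty")
    spec = tc.loss
    data_range = float(Ytr.max() - Ytr.min()) or 1.0
    opt = Adam(net.params, lr=tc.learning_rate)
    sched = ReduceLROnPlateau(opt, patience=tc.plateau_patience,
                              factor=tc.lr_factor)
    rng = np.random.default_rng(tc.seed)
    best_val = np.inf
    best_state = net.state()
    rows = []
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(Xtr))
        ep_loss, n_seen = 0.0, 0
        for i in range(0, len(order), tc.batch_size):
            sel = order[i:i + tc.batch_size]
            xb = Tensor(Xtr[sel][:, None].astype(np.float32))
            yb = Tensor(Ytr[sel][:, None].astype(np.float32))
            out = net.forward(xb)
            loss = loss_tensor(spec, out, yb, data_range=data_range)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(network {label}); try a lower learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(sel)
            n_seen += len(sel)
        val_loss = _batched_loss(net, Xval.astype(np.float32),
                                 Yval.astype(np.float32), spec, data_range,
                                 tc.batch_size)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state()
        rows.append({"network": label, "epoch": epoch,
                     "train_loss": ep_loss / n_seen, "val_loss": val_loss,
                     "best_val_loss": best_val, "lr": opt.lr})
        sched.step(val_loss)
    net.load_state(best_state)
    return pd.DataFrame(rows), float(best_val)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _BaseDenoiser(BaseEstimator):
    """Shared fit/predict machinery of the patch denoisers.

    ``fit(X, y)`` expects congruent (n_patches, side, side) arrays of
    noisy inputs and ground-truth targets in normalised intensity space.
    An explicit validation set may be passed as fit parameters; otherwise
    a seeded tail fraction of the patches is held out (callers who need
    ROI-level splitting should pass explicit sets).
    """

    _mode = "care"

    def __init__(self, levels=3, base_channels=16, n_convs_per_block=1,
                 kernel_size=3, padding="reflect", residual_skips=True,
                 output_residual=True, loss="ssim_plus_r2", alpha=0.84,
                 ffl_exponent=1.0, learning_rate=1e-5, max_epochs=300,
                 plateau_patience=20, lr_factor=0.5, batch_size=16,
                 val_fraction=0.25, norm_percentiles=(0.1, 99.9), seed=0):
        self.levels = levels
        self.base_channels = base_channels
        self.n_convs_per_block = n_convs_per_block
        self.kernel_size = kernel_size
        self.padding = padding
        self.residual_skips = residual_skips
        self.output_residual = output_residual
        self.loss = loss
        self.alpha = alpha
        self.ffl_exponent = ffl_exponent
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.plateau_patience = plateau_patience
        self.lr_factor = lr_factor
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.norm_percentiles = norm_percentiles
        self.seed = seed

    # -- config assembly ----------------------------------------------
    def _loss_spec(self) -> LossSpec:
        return LossSpec(kind=self.loss, alpha=self.alpha,
                        ffl_exponent=self.ffl_exponent)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           max_epochs=self.max_epochs,
                           plateau_patience=self.plateau_patience,
                           lr_factor=self.lr_factor,
                           batch_size=self.batch_size, seed=self.seed,
                           loss=self._loss_spec())

    def _unet_config(self, net_side: int) -> UNetConfig:
        return UNetConfig(input_side=net_side, levels=self.levels,
                          base_channels=self.base_channels,
                          n_convs_per_block=self.n_convs_per_block,
                          kernel_size=self.kernel_size,
                          residual_skips=self.residual_skips,
                          output_residual=self.output_residual,
                          padding=self.padding)

    def _validate_pairs(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must be congruent "
                             "(n_patches, side, side) arrays")
        if X.shape[1] != X.shape[2]:
            raise ValueError("patches must be square")
        if self._loss_spec().needs_aux:
            raise ValueError("the redox-ratio loss needs paired counterpart "
                             "channels; train with a two-channel objective "
                             "is not supported by this estimator")
        return X, y

    def _split(self, X, y, X_val, y_val):
        if (X_val is None) != (y_val is None):
            raise ValueError("pass both X_val and y_val or neither")
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)
            return X, y, X_val, y_val
        n = len(X)
        n_val = max(1, int(round(self.val_fraction * n)))
        if n_val >= n:
            raise ValueError("too few patches to hold out validation data")
        order = np.random.default_rng(self.seed).permutation(n)
        tr, va = order[:-n_val], order[-n_val:]
        return X[tr], y[tr], X[va], y[va]

    # -- sklearn surface ----------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, channel: str | None = None):
        X, y = self._validate_pairs(X, y)
        Xtr, ytr, Xva, yva = self._split(X, y, X_val, y_val)
        self.input_side_ = int(X.shape[1])
        bundle, history, best = self._fit_impl(Xtr, ytr, Xva, yva)
        bundle.trained_on_channel = channel
        bundle.history = history
        bundle.best_val_loss = best
        self.bundle_ = bundle
        self.history_ = history
        self.best_val_loss_ = best
        self.n_epochs_ = int(history["epoch"].max()) + 1
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "bundle_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = _apply_networks_batch(self.bundle_, X)
        return out[0] if single else out

    transform = predict


class CAREDenoiser(_BaseDenoiser):
    """Single residual U-Net trained directly on image-domain patches."""

    _mode = "care"

    def _fit_impl(self, Xtr, ytr, Xva, yva):
        side = Xtr.shape[1]
        ucfg = self._unet_config(side)
        tc = self._train_config()
        net = UNet(ucfg, seed=self.seed)
        history, best = _fit_one_network(
            net, Xtr.astype(np.float32), ytr.astype(np.float32),
            Xva.astype(np.float32), yva.astype(np.float32), tc)
        bundle = DenoiserBundle(mode="care", networks={"single": net},
                                unet_config=ucfg, train_config=tc,
                                norm_percentiles=tuple(self.norm_percentiles))
        return bundle, history, best


class WUNetDenoiser(_BaseDenoiser):
    """Four per-sub-band residual U-Nets between a DWT and its inverse.

    Each network trains independently against its own wavelet band of the
    ground truth, with the same optimisation schedule, so high-frequency
    bands are denoised without mixing scales.
    """

    _mode = "wunet"

    def __init__(self, wavelet=DEFAULT_WAVELET, boundary_mode=DEFAULT_MODE,
                 levels=3, base_channels=16, n_convs_per_block=1,
                 kernel_size=3, padding="reflect", residual_skips=True,
                 output_residual=True, loss="ssim_plus_r2", alpha=0.84,
                 ffl_exponent=1.0, learning_rate=1e-5, max_epochs=300,
                 plateau_patience=20, lr_factor=0.5, batch_size=16,
                 val_fraction=0.25, norm_percentiles=(0.1, 99.9), seed=0):
        super().__init__(levels=levels, base_channels=base_channels,
                         n_convs_per_block=n_convs_per_block,
                         kernel_size=kernel_size, padding=padding,
                         residual_skips=residual_skips,
                         output_residual=output_residual, loss=loss,
                         alpha=alpha, ffl_exponent=ffl_exponent,
                         learning_rate=learning_rate, max_epochs=max_epochs,
                         plateau_patience=plateau_patience,
                         lr_factor=lr_factor, batch_size=batch_size,
                         val_fraction=val_fraction,
                         norm_percentiles=norm_percentiles, seed=seed)
        self.wavelet = wavelet
        self.boundary_mode = boundary_mode

    def _decompose(self, patches: np.ndarray) -> dict[str, np.ndarray]:
        bands = {b: [] for b in BAND_ORDER}
        for patch in patches:
            sb = dwt_single(patch, self.wavelet, self.boundary_mode)
            for name, arr in zip(BAND_ORDER, sb.bands):
                bands[name].append(arr)
        return {b: np.stack(v) for b, v in bands.items()}

    def _fit_impl(self, Xtr, ytr, Xva, yva):
        xb_tr = self._decompose(Xtr)
        yb_tr = self._decompose(ytr)
        xb_va = self._decompose(Xva)
        yb_va = self._decompose(yva)
        band_side = xb_tr["LL"].shape[1]
        if xb_tr["LL"].shape[1] != xb_tr["LL"].shape[2]:
            raise ValueError("wavelet sub-bands are not square; use even "
                             "patch sides")
        ucfg = self._unet_config(band_side)
        tc = self._train_config()
        networks, histories = {}, []
        best_total = 0.0
        for i, band in enumerate(BAND_ORDER):
            net = UNet(ucfg, seed=self.seed + 1000 * (i + 1))
            hist, best = _fit_one_network(
                net, xb_tr[band].astype(np.float32),
                yb_tr[band].astype(np.float32),
                xb_va[band].astype(np.float32),
                yb_va[band].astype(np.float32), tc, label=band)
            networks[band] = net
            histories.append(hist)
            best_total += best
        bundle = DenoiserBundle(mode="wunet", networks=networks,
                                unet_config=ucfg, train_config=tc,
                                wavelet_name=self.wavelet,
                                boundary_mode=self.boundary_mode,
                                norm_percentiles=tuple(self.norm_percentiles))
        return bundle, pd.concat(histories, ignore_index=True), best_total


# ---------------------------------------------------------------------------
# bundle-level operations
# ---------------------------------------------------------------------------

def _apply_networks_batch(bundle: DenoiserBundle,
                          patches: np.ndarray) -> np.ndarray:
    """Run a batch of normalised (n, side, side) patches through the
    bundle's network(s)."""
    if bundle.mode == "care":
        return bundle.networks["single"].predict(patches)
    bands = {b: [] for b in BAND_ORDER}
    for patch in patches:
        sb = dwt_single(patch, bundle.wavelet_name, bundle.boundary_mode)
        for name, arr in zip(BAND_ORDER, sb.bands):
            bands[name].append(arr)
    den = {name: bundle.networks[name].predict(np.stack(v))
           for name, v in bands.items()}
    out = np.empty_like(patches, dtype=float)
    for i in range(len(patches)):
        out[i] = idwt_single(SubbandSet(
            *(den[name][i] for name in BAND_ORDER),
            wavelet_name=bundle.wavelet_name,
            boundary_mode=bundle.boundary_mode))
    return out


def _apply_networks(bundle: DenoiserBundle, patch: np.ndarray) -> np.ndarray:
    """Run one normalised patch through the bundle's network(s)."""
    return _apply_networks_batch(bundle, patch[None])[0]


def train(mode: str, unet_config: UNetConfig, train_pairs, val_pairs,
          train_config: TrainConfig, wavelet_name: str = DEFAULT_WAVELET,
          channel: str | None = None) -> DenoiserBundle:
    """Functional training entry point over the estimator classes.

    ``train_pairs`` / ``val_pairs`` are (raw, gt) tuples of
    (n, side, side) arrays in normalised intensity space.
    """
    cls = {"care": CAREDenoiser, "wunet": WUNetDenoiser}.get(mode)
    if cls is None:
        raise ValueError("mode must be 'care' or 'wunet'")
    kwargs = dict(levels=unet_config.levels,
                  base_channels=unet_config.base_channels,
                  n_convs_per_block=unet_config.n_convs_per_block,
                  kernel_size=unet_config.kernel_size,
                  padding=unet_config.padding,
                  residual_skips=unet_config.residual_skips,
                  output_residual=unet_config.output_residual,
                  loss=train_config.loss.kind, alpha=train_config.loss.alpha,
                  ffl_exponent=train_config.loss.ffl_exponent,
                  learning_rate=train_config.learning_rate,
                  max_epochs=train_config.max_epochs,
                  plateau_patience=train_config.plateau_patience,
                  lr_factor=train_config.lr_factor,
                  batch_size=train_config.batch_size,
                  seed=train_config.seed)
    if mode == "wunet":
        kwargs["wavelet"] = wavelet_name
    est = cls(**kwargs)
    Xtr, ytr = train_pairs
    Xva, yva = val_pairs
    est.fit(np.asarray(Xtr), np.asarray(ytr), X_val=np.asarray(Xva),
            y_val=np.asarray(yva), channel=channel)
    return est.bundle_


def denoise_patch(bundle: DenoiserBundle, patch: np.ndarray) -> np.ndarray:
    """Denoise one patch, normalising and restoring its intensity scale."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (bundle.patch_side, bundle.patch_side):
        raise ValueError(
            f"patch side {patch.shape} does not match the bundle's "
            f"{bundle.patch_side}")
    p_low, p_high = bundle.norm_percentiles
    norm, params = percentile_normalize(patch, p_low, p_high)
    return denormalize(_apply_networks(bundle, norm), params)


def denoise_stack(bundle: DenoiserBundle, stack: TissueStack) -> TissueStack:
    """Denoise a whole stack section by section.

    Sections whose side equals twice the bundle's patch side are routed
    through 2x2 patching and stitched back; matching sides are denoised
    directly.  Normalisation parameters are computed per stack and
    inverted afterwards, so output is on the input intensity scale.
    Applicable to either channel regardless of the training channel
    (channel-transfer use).
    """
    sections = stack.sections()
    h, w = sections.shape[1:]
    side = bundle.patch_side
    if h != w:
        raise ValueError("sections must be square")
    if h not in (side, 2 * side):
        raise ValueError(f"section side {h} incompatible with patch side "
                         f"{side} (need equal or double)")
    p_low, p_high = bundle.norm_percentiles
    norm, params = percentile_normalize(sections, p_low, p_high)
    if h == side:
        out = _apply_networks_batch(bundle, norm)
    else:
        patches = np.concatenate([stack_io.patch_2x2(sec) for sec in norm])
        den = _apply_networks_batch(bundle, patches)
        out = np.stack([stack_io.stitch_2x2(den[4 * d:4 * d + 4])
                        for d in range(len(norm))])
    restored = denormalize(out, params)
    if not np.isfinite(restored).all():
        raise FloatingPointError("denoised stack contains non-finite values")
    from dataclasses import replace
    return replace(stack, voxels=restored[:, None], provenance="denoised")
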