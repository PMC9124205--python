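"""BS-CNN: encoder-decoder network mapping an HP frame to the high-frequency
product ``rho * I``.

Architecture (single-channel in and out): an encoder of 3x3 convolutions with
feature sizes 32, 64, 128 followed by elementwise ReLU and a 4x4-window
max-pool each (stride 2 by default, so successive windows overlap), a
512-feature 3x3 bottleneck convolution (ReLU, no pooling), a decoder of
nearest-neighbour upsampling + 3x3 convolution + ReLU stages with feature
sizes 128, 64, 32, and a final 1x1 convolution producing one channel.
Arbitrary input sizes are handled by padding inside each pooling stage and
cropping on the way back up, so the output always matches the input size.

Training minimizes ``1 - SSIM`` (Gaussian-weighted 11x11 windows, sigma 1.5)
with Adam (beta1 = 0.9, beta2 = 0.999, lr = 0.001, batch size 32, up to 120
epochs) and validation-based early stopping that restores the best weights.

The whole stack — im2col convolutions, pooling, the SSIM loss and its
analytic gradient, and the Adam update — is implemented directly on numpy
arrays, so training and inference run CPU-only with no framework dependency;
gradients are validated against finite differences in the test suite.

At inference the trained network is applied to every HP frame of a stack
independently and the outputs are ensemble-averaged into the reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import FrameStack, airy_psf, blur_image
from .phantoms import DensityMap
from .speckle import SpeckleParams, speckle_stack

__all__ = [
    "BSCNNConfig",
    "TrainingSample",
    "BSCNN",
    "build_model",
    "parameter_count",
    "make_dataset",
    "ssim_loss",
    "ssim_loss_grad",
    "train",
    "deconvolve",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BSCNNConfig:
    """Architecture and optimization settings.

    ``encoder_features`` lists the 3x3-conv feature sizes; all but the last
    are followed by a 4x4-window max-pool of stride ``pool_stride``, the
    last is the bottleneck.  ``decoder_features`` must have one entry per
    pooling stage; each decoder stage upsamples by the pool stride.  The
    stride-2 default keeps the pooling windows overlapping so an 11-d_PSF
    patch retains an informative bottleneck — stride 4 (non-overlapping)
    collapses it to a few pixels and the restoration cannot train.  Adam
    and schedule defaults follow the training protocol this package targets
    (beta1 0.9, beta2 0.999, lr 0.001, 120 epochs, batch 32).
    """

    encoder_features: tuple[int, ...] = (32, 64, 128, 512)
    decoder_features: tuple[int, ...] = (128, 64, 32)
    pool_stride: int = 2
    init: str = "identity"
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 120
    batch_size: int = 32
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.decoder_features) != len(self.encoder_features) - 1:
            raise ValueError(
                "decoder must have one stage per pooling stage "
                f"({len(self.encoder_features) - 1}), got {len(self.decoder_features)}"
            )
        if self.pool_stride not in (2, 4):
            raise ValueError("pool_stride must be 2 or 4")
        if self.init not in ("identity", "he"):
            raise ValueError("init must be 'identity' or 'he'")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @property
    def pool_factor(self) -> int:
        return self.pool_stride ** (len(self.encoder_features) - 1)


@dataclass(frozen=True)
class TrainingSample:
    """One (HP frame, rho*I target) pair with its provenance.

    ``provenance`` is ``(patch_id, illumination_id)``; each pair occurs at
    most once in a dataset.
    """

    input: np.ndarray
    target: np.ndarray
    provenance: tuple[int, int]

    def __post_init__(self) -> None:
        if self.input.shape != self.target.shape:
            raise ValueError("input/target shapes must match")


# ---------------------------------------------------------------------------
# layers (numpy, manual backprop)


class _Conv3x3:
    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator, identity_tap: bool = False
    ) -> None:
        std = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, std, size=(c_out, c_in * 9))
        if identity_tap:
            # pass-through channel: damp the random weights and put a unit
            # center tap on channel 0 <- 0, so the untrained network starts
            # near a (pool-dilated) identity instead of an amplified-noise map
            self.w *= 0.05
            self.w[0, 4] += 1.0
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(b, c, 3, 3, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
        )
        return cols.reshape(b, c * 9, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        out = np.matmul(self.w, self._cols) + self.b[None, :, None]
        return out.reshape(b, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, f, h, w = dout.shape
        d2 = dout.reshape(b, f, h * w)
        self.gw = np.einsum("bfp,bcp->fc", d2, self._cols)
        self.gb = d2.sum(axis=(0, 2))
        dcols = np.einsum("fc,bfp->bcp", self.w, d2)
        _, c, hh, ww = self._in_shape
        dcols = dcols.reshape(b, c, 3, 3, h, w)
        dxp = np.zeros((b, c, hh + 2, ww + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + hh, j : j + ww] += dcols[:, :, i, j]
        return dxp[:, :, 1 : 1 + hh, 1 : 1 + ww]


class _Conv1x1:
    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator, identity_tap: bool = False
    ) -> None:
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, size=(c_out, c_in))
        if identity_tap:
            self.w *= 0.05
            self.w[0, 0] += 1.0
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,bchw->bohw", self.w, x) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.gw = np.einsum("bohw,bchw->oc", dout, self._x)
        self.gb = dout.sum(axis=(0, 2, 3))
        return np.einsum("oc,bohw->bchw", self.w, dout)


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class _MaxPool4:
    """4x4-window max pooling with configurable stride.

    Inputs are padded with -inf on the bottom/right so every output window
    exists; with overlapping windows (stride < 4) the backward pass
    scatter-adds into the shared positions.
    """

    def __init__(self, stride: int = 2) -> None:
        self.window = 4
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._size = (h, w)
        s, k = self.stride, self.window
        oh = -(-h // s)
        ow = -(-w // s)
        hp = s * (oh - 1) + k
        wp = s * (ow - 1) + k
        xp = np.pad(
            x, ((0, 0), (0, 0), (0, hp - h), (0, wp - w)), constant_values=-np.inf
        )
        st = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp,
            shape=(b, c, oh, ow, k, k),
            strides=(st[0], st[1], st[2] * s, st[3] * s, st[2], st[3]),
        ).reshape(b, c, oh, ow, k * k)
        self._arg = np.argmax(windows, axis=-1)
        self._padded = (hp, wp)
        return np.take_along_axis(windows, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, oh, ow = dout.shape
        s, k = self.stride, self.window
        hp, wp = self._padded
        rows = s * np.arange(oh)[:, None] + self._arg // k
        cols = s * np.arange(ow)[None, :] + self._arg % k
        flat_idx = rows * wp + cols  # (b, c, oh, ow)
        dx = np.zeros((b, c, hp * wp))
        bi = np.arange(b)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dx, (bi, ci, flat_idx), dout)
        h, w = self._size
        return dx.reshape(b, c, hp, wp)[:, :, :h, :w]


class _Upsample4:
    """Nearest-neighbour upsampling by the pool stride, cropped to the
    matching pre-pool size."""

    def __init__(self, factor: int = 2) -> None:
        self.factor = factor
        self.target_size: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        up = np.repeat(np.repeat(x, f, axis=2), f, axis=3)
        assert self.target_size is not None
        h, w = self.target_size
        self._up_shape = up.shape
        return up[:, :, :h, :w]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f = self.factor
        b, c, uh, uw = self._up_shape
        full = np.zeros((b, c, uh, uw))
        full[:, :, : dout.shape[2], : dout.shape[3]] = dout
        return full.reshape(b, c, uh // f, f, uw // f, f).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# model


class BSCNN:
    """The encoder-decoder network with its weights and training history."""

    def __init__(self, config: BSCNNConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc = config.encoder_features
        dec = config.decoder_features
        self.enc_convs = []
        self.enc_relus = []
        self.pools = []
        tap = config.init == "identity"
        c_prev = 1
        for i, f in enumerate(enc):
            self.enc_convs.append(_Conv3x3(c_prev, f, rng, identity_tap=tap))
            self.enc_relus.append(_ReLU())
            if i < len(enc) - 1:
                self.pools.append(_MaxPool4(stride=config.pool_stride))
            c_prev = f
        self.ups = []
        self.dec_convs = []
        self.dec_relus = []
        for f in dec:
            self.ups.append(_Upsample4(factor=config.pool_stride))
            self.dec_convs.append(_Conv3x3(c_prev, f, rng, identity_tap=tap))
            self.dec_relus.append(_ReLU())
            c_prev = f
        self.head = _Conv1x1(c_prev, 1, rng, identity_tap=tap)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.data_fingerprint: str | None = None

    # -- parameter plumbing -------------------------------------------------

    def _layers_with_params(self):
        return [*self.enc_convs, *self.dec_convs, self.head]

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers_with_params():
            out.extend([layer.w, layer.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers_with_params():
            out.extend([layer.gw, layer.gb])
        return out

    def set_parameters(self, values: list[np.ndarray]) -> None:
        it = iter(values)
        for layer in self._layers_with_params():
            layer.w = next(it).copy()
            layer.b = next(it).copy()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, H, W) single-channel batch; returns (B, H, W)."""
        if x.ndim != 3:
            raise ValueError("expected a (B, H, W) batch")
        h = x[:, None, :, :]
        sizes = []
        n_pool = len(self.pools)
        for i, (conv, relu) in enumerate(zip(self.enc_convs, self.enc_relus)):
            h = relu.forward(conv.forward(h))
            if i < n_pool:
                sizes.append(h.shape[2:])
                h = self.pools[i].forward(h)
        for up, conv, relu in zip(self.ups, self.dec_convs, self.dec_relus):
            up.target_size = sizes.pop()
            h = relu.forward(conv.forward(up.forward(h)))
        out = self.head.forward(h)
        return out[:, 0, :, :]

    def backward(self, dout: np.ndarray) -> None:
        d = self.head.backward(dout[:, None, :, :])
        for up, conv, relu in zip(
            reversed(self.ups), reversed(self.dec_convs), reversed(self.dec_relus)
        ):
            d = up.backward(conv.backward(relu.backward(d)))
        n_pool = len(self.pools)
        for i in range(len(self.enc_convs) - 1, -1, -1):
            if i < n_pool:
                d = self.pools[i].backward(d)
            d = self.enc_convs[i].backward(self.enc_relus[i].backward(d))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference on (H, W) or (B, H, W); no state kept."""
        single = x.ndim == 2
        batch = x[None] if single else x
        out = self.forward(np.asarray(batch, dtype=np.float64))
        return out[0] if single else out


def build_model(config: BSCNNConfig | None = None) -> BSCNN:
    """Fresh (untrained) BS-CNN with seeded He-normal initialization."""
    return BSCNN(config or BSCNNConfig())


def parameter_count(config: BSCNNConfig) -> int:
    """Closed-form trainable parameter count (9*cin*cout + cout per 3x3
    stage, cin*cout + cout for the 1x1 head)."""
    total = 0
    c = 1
    for f in config.encoder_features:
        total += 9 * c * f + f
        c = f
    for f in config.decoder_features:
        total += 9 * c * f + f
        c = f
    total += c * 1 + 1
    return total


# ---------------------------------------------------------------------------
# SSIM loss (differentiable)

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius 5 px -> 11x11 window
_SSIM_PAD = 5


def _gfilt(x: np.ndarray) -> np.ndarray:
    # constant (zero) boundary makes the operator self-adjoint; the border
    # ring it affects is cropped out of the mean below
    return gaussian_filter(
        x, _SSIM_SIGMA, mode="constant", truncate=_SSIM_TRUNCATE, axes=(-2, -1)
    )


def _ssim_terms(x: np.ndarray, y: np.ndarray, data_range: float):
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    ux, uy = _gfilt(x), _gfilt(y)
    uxx, uyy, uxy = _gfilt(x * x), _gfilt(y * y), _gfilt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    a1 = 2 * ux * uy + c1
    a2 = 2 * vxy + c2
    b1 = ux**2 + uy**2 + c1
    b2 = vx + vy + c2
    s = (a1 * a2) / (b1 * b2)
    return s, (ux, uy, vxy, a1, a2, b1, b2)


def ssim_loss(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0) -> float:
    """``1 - SSIM(pred, target)`` with Gaussian 11x11 windows, sigma 1.5.

    The SSIM map's 5-pixel border (where the window hangs off the image) is
    excluded from the mean, matching the convention of the metrics module;
    batched inputs ``(B, H, W)`` return the mean loss over the batch.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    s, _ = _ssim_terms(pred, target, data_range)
    p = _SSIM_PAD
    core = s[..., p:-p, p:-p]
    if core.ndim == 2:
        return float(1.0 - core.mean())
    return float(1.0 - core.mean(axis=(-2, -1)).mean())


def ssim_loss_grad(
    pred: np.ndarray, target: np.ndarray, data_range: float = 1.0
) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to ``pred``."""
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    s, (ux, uy, vxy, a1, a2, b1, b2) = _ssim_terms(x, y, data_range)
    p = _SSIM_PAD
    core = s[..., p:-p, p:-p]
    if x.ndim == 2:
        loss = float(1.0 - core.mean())
        n_terms = core.shape[-1] * core.shape[-2]
    else:
        loss = float(1.0 - core.mean(axis=(-2, -1)).mean())
        n_terms = core.shape[-1] * core.shape[-2] * x.shape[0]
    # dL/dS: -1/n inside the cropped core, 0 on the border ring
    w = np.zeros_like(s)
    w[..., p:-p, p:-p] = -1.0 / n_terms
    ds_dmu = 2 * uy * a2 / (b1 * b2) - 2 * ux * a1 * a2 / (b1**2 * b2)
    ds_dvx = -a1 * a2 / (b1 * b2**2)  # via sigma_x^2 in b2
    ds_dvxy = 2 * a1 / (b1 * b2)
    # sigma_x^2 = uxx - ux^2 and sigma_xy = uxy - ux*uy couple back into mu_x
    dmu_total = ds_dmu - 2 * ux * ds_dvx - uy * ds_dvxy
    grad = (
        _gfilt(w * dmu_total)
        + 2 * x * _gfilt(w * ds_dvx)
        + y * _gfilt(w * ds_dvxy)
    )
    return loss, grad


# ---------------------------------------------------------------------------
# dataset generation


def make_dataset(
    gt_patches: list[DensityMap],
    d_sp: float,
    d_psf: float,
    seed: int = 0,
    split: tuple[float, float, float] = (0.75, 0.20, 0.05),
    m_aux: int = 64,
) -> tuple[list[TrainingSample], list[TrainingSample], list[TrainingSample]]:
    """Build (train, val, test) sample lists from ground-truth patches.

    Each patch gets one fresh speckle illumination (the target is
    ``rho * I``, the input the HP frame of the blurred product), so every
    ``(patch, illumination)`` pair occurs exactly once.  The ensemble-mean
    image subtracted before the positive cut is formed from ``m_aux``
    auxiliary speckle realizations shared across patches (their pixelwise
    mean times the patch, blurred — linearity makes the two orders equal).
    Inputs and targets are jointly normalized to the target's maximum.
    Deterministic given ``seed``.
    """
    if not gt_patches:
        raise ValueError("no patches given")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    d_sp = float(d_sp)
    psf = airy_psf(d_psf)
    shape = gt_patches[0].shape
    root = np.random.SeedSequence(seed)
    aux_seed, illum_seed = (int(s) for s in root.generate_state(2) % (2**31))
    aux = speckle_stack(
        SpeckleParams(d_sp=d_sp, seed=aux_seed), m_aux, shape
    )
    mean_illum = aux.frames.mean(axis=0)

    illum_seeds = np.random.SeedSequence(illum_seed).generate_state(len(gt_patches)) % (2**31)
    samples: list[TrainingSample] = []
    seen: set[tuple[int, int]] = set()
    for pid, patch in enumerate(gt_patches):
        if patch.shape != shape:
            raise ValueError("all patches must share one shape")
        illum = speckle_stack(
            SpeckleParams(d_sp=d_sp, seed=int(illum_seeds[pid])), 1, shape
        ).frames[0]
        target = patch.pixels * illum
        lr = blur_image(target, psf)
        lr_mean = blur_image(patch.pixels * mean_illum, psf)
        hp = np.clip(lr - lr_mean, 0.0, None)
        # each side normalized to its own unit maximum: the network sees
        # O(1) inputs (HP peaks are far dimmer than rho*I peaks) and
        # inference can apply the same self-normalization without a target
        peak_in = hp.max()
        if peak_in > 0:
            hp = hp / peak_in
        peak = target.max()
        if peak > 0:
            target = target / peak
        key = (pid, int(illum_seeds[pid]))
        if key in seen:
            raise ValueError(f"duplicate (patch, illumination) pair {key}")
        seen.add(key)
        samples.append(TrainingSample(input=hp, target=target, provenance=key))

    n = len(samples)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return (
        samples[:n_train],
        samples[n_train : n_train + n_val],
        samples[n_train + n_val :],
    )


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, b1: float, b2: float) -> None:
        self.lr, self.b1, self.b2 = lr, b1, b2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def _batch_arrays(samples: list[TrainingSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.input for s in samples])
    y = np.stack([s.target for s in samples])
    return x, y


def _dataset_loss(model: BSCNN, samples: list[TrainingSample], batch_size: int) -> float:
    total = 0.0
    for i in range(0, len(samples), batch_size):
        x, y = _batch_arrays(samples[i : i + batch_size])
        pred = model.forward(x)
        total += ssim_loss(pred, y) * len(x)
    return total / len(samples)


def train(
    model: BSCNN,
    datasets: tuple[list[TrainingSample], list[TrainingSample], list[TrainingSample]]
    | tuple[list[TrainingSample], list[TrainingSample]],
    config: BSCNNConfig | None = None,
) -> BSCNN:
    """Minimize the SSIM loss with Adam; early-stop on the validation loss.

    Stops when the validation loss has not improved for
    ``early_stop_patience`` epochs (or at ``epochs``), restoring the weights
    of the best validation epoch.  Per-epoch train/validation losses are
    recorded in ``model.history``.  Raises on divergence (NaN loss).
    """
    cfg = config or model.config
    train_set, val_set = datasets[0], datasets[1]
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    best_val = np.inf
    best_weights = [p.copy() for p in model.parameters()]
    since_best = 0
    model.history = {"train_loss": [], "val_loss": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_set[j] for j in order[i : i + cfg.batch_size]]
            x, y = _batch_arrays(batch)
            pred = model.forward(x)
            loss, grad = ssim_loss_grad(pred, y)
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: loss is not finite")
            model.backward(grad)
            opt.step(model.parameters(), model.gradients())
            epoch_loss += loss * len(batch)
        model.history["train_loss"].append(epoch_loss / len(train_set))
        val_loss = _dataset_loss(model, val_set, cfg.batch_size)
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = [p.copy() for p in model.parameters()]
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.early_stop_patience:
                break
    model.set_parameters(best_weights)
    return model


# ---------------------------------------------------------------------------
# inference


def deconvolve(
    model: BSCNN,
    hp_stack: FrameStack,
    pixel_pitch: float | None = None,
    batch_size: int = 16,
) -> DensityMap:
    """Apply the network to each HP frame and average the outputs.

    Each frame is normalized to unit maximum before inference (the network
    is trained on unit-scale data); the ensemble mean is clipped at zero.
    Permutation-invariant in frame order.
    """
    if hp_stack.n < 1:
        raise ValueError("empty stack")
    frames = hp_stack.frames
    peaks = frames.max(axis=(1, 2))
    peaks[peaks == 0] = 1.0
    normed = frames / peaks[:, None, None]
    acc = np.zeros(hp_stack.frame_shape)
    for i in range(0, hp_stack.n, batch_size):
        acc += model.forward(normed[i : i + batch_size]).sum(axis=0)
    out = np.clip(acc / hp_stack.n, 0.0, None)
    return DensityMap(pixels=out, pixel_pitch=pixel_pitch or 1.0)


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: BSCNN, path: str) -> None:
    """Single-file checkpoint: config + weights + history (npz container)."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    meta = {
        "config": asdict(model.config),
        "history": model.history,
        "data_fingerprint": model.data_fingerprint,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> BSCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["encoder_features"] = tuple(cfg_dict["encoder_features"])
        cfg_dict["decoder_features"] = tuple(cfg_dict["decoder_features"])
        config = BSCNNConfig(**cfg_dict)
        model = BSCNN(config)
        params = [data[f"param_{i}"] for i in range(len(model.parameters()))]
        model.set_parameters(params)
        model.history = meta["history"]
        model.data_fingerprint = meta["data_fingerprint"]
    return model
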