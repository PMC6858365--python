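"""Residual 3D U-Net segmenter.

Architecture: a strided entry convolution (kernel 7, stride 2) halves
each spatial dimension right after the input — trading a little compute
for a large reduction in feature-map memory — followed by a residual
encoder/decoder with additive skip connections at every resolution level
*except the highest*, and a transposed convolution (learned upsampling,
stride 2) restoring the input resolution before a single-channel sigmoid
output. Activations are leaky ReLU; normalization is group
normalization, which is stable at the small batch sizes 3D volumes
force.

Training minimizes the smoothed Dice loss (s = 1); evaluation uses the
hard Dice score (s = 0) on the 0.5-thresholded mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics
from .grids import NORMALIZED, LabelVolume, VolumeGrid
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv, ConvTranspose, GroupNorm, LeakyReLU, Module, Sequential, Sigmoid
from .nn.optim import Adam


@dataclass
class UNetConfig:
    input_shape: tuple[int, int, int] = (32, 32, 32)
    entry_stride: int = 2
    entry_kernel: int = 7
    base_channels: int = 8
    depth: int = 2  # resolution levels below the entry level
    groupnorm_groups: int = 4
    leaky_slope: float = 0.01
    batch_size: int = 2
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        div = self.entry_stride * 2**self.depth
        for n in self.input_shape:
            if n % div != 0:
                raise ValueError(
                    f"input_shape {self.input_shape} not divisible by "
                    f"entry_stride * 2^depth = {div}"
                )
        for level in range(self.depth + 1):
            ch = self.base_channels * 2**level
            if ch % self.groupnorm_groups != 0:
                raise ValueError(
                    f"groupnorm_groups={self.groupnorm_groups} does not divide "
                    f"channels={ch} at level {level}"
                )


class _ResBlock3d(Module):
    """Pre-activation residual block: (GN - LReLU - conv3)x2 + identity."""

    def __init__(self, channels, groups, slope, rng):
        super().__init__()
        self.body = self.add_module(
            Sequential(
                GroupNorm(channels, groups),
                LeakyReLU(slope),
                Conv(3, channels, channels, 3, rng=rng),
                GroupNorm(channels, groups),
                LeakyReLU(slope),
                Conv(3, channels, channels, 3, rng=rng),
            )
        )

    def forward(self, x):
        return x + self.body(x)


class UNet3d(Module):
    def __init__(self, config: UNetConfig, residual: bool = True):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c, g, s = config.base_channels, config.groupnorm_groups, config.leaky_slope
        block = _ResBlock3d if residual else _PlainBlock3d

        self.entry = self.add_module(
            Conv(3, 1, c, config.entry_kernel, stride=config.entry_stride, rng=rng)
        )
        self.enc_blocks, self.downs = [], []
        for level in range(config.depth):
            ch = c * 2**level
            self.enc_blocks.append(self.add_module(block(ch, g, s, rng)))
            self.downs.append(self.add_module(Conv(3, ch, ch * 2, 3, stride=2, rng=rng)))
        self.bottleneck = self.add_module(block(c * 2**config.depth, g, s, rng))
        self.ups, self.dec_blocks = [], []
        for level in reversed(range(config.depth)):
            ch = c * 2**level
            self.ups.append(self.add_module(ConvTranspose(3, ch * 2, ch, stride=2, rng=rng)))
            self.dec_blocks.append(self.add_module(block(ch, g, s, rng)))
        self.final_up = self.add_module(ConvTranspose(3, c, c, stride=config.entry_stride, rng=rng))
        self.head = self.add_module(Conv(3, c, 1, 1, rng=rng))
        self.act = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        x = self.entry(x)
        skips = []
        for blockm, down in zip(self.enc_blocks, self.downs):
            x = blockm(x)
            skips.append(x)
            x = down(x)
        x = self.bottleneck(x)
        for i, (up, blockm) in enumerate(zip(self.ups, self.dec_blocks)):
            x = up(x)
            level = self.config.depth - 1 - i
            if level > 0:  # no skip connection at the highest level
                x = x + skips[level]
            x = blockm(x)
        x = self.final_up(x)
        return self.act(self.head(x))


class _PlainBlock3d(Module):
    """Residual-ablated variant of :class:`_ResBlock3d` (for comparisons)."""

    def __init__(self, channels, groups, slope, rng):
        super().__init__()
        self.body = self.add_module(
            Sequential(
                GroupNorm(channels, groups),
                LeakyReLU(slope),
                Conv(3, channels, channels, 3, rng=rng),
            )
        )

    def forward(self, x):
        return self.body(x)


def build_unet3d(config: UNetConfig, residual: bool = True) -> UNet3d:
    return UNet3d(config, residual=residual)


def soft_dice_loss_tensor(pred: Tensor, target: np.ndarray, s: float = 1.0) -> Tensor:
    """Differentiable smoothed Dice loss, averaged over the batch."""
    n = pred.shape[0]
    x = pred.reshape(n, -1)
    y = Tensor(np.asarray(target, dtype=pred.data.dtype).reshape(n, -1))
    inter = (x * y).sum(axis=1)
    sums = x.sum(axis=1) + y.sum(axis=1)
    return (1.0 - (inter + s) * 2.0 / (sums + s)).mean()


@dataclass
class SegPrediction:
    probabilities: np.ndarray
    mask: LabelVolume
    case_id: str = ""


def predict_mask(model: UNet3d, volume: VolumeGrid, case_id: str = "",
                 threshold: float = 0.5) -> SegPrediction:
    if volume.intensity_kind != NORMALIZED:
        raise ValueError("predict_mask expects a clipped+normalized volume")
    x = Tensor(volume.values[None, None].astype(np.float32))
    probs = model(x).data[0, 0].astype(np.float64)
    return SegPrediction(
        probabilities=probs,
        mask=LabelVolume((probs >= threshold).astype(np.uint8)),
        case_id=case_id,
    )


class UNet3DSegmenter(BaseEstimator):
    """Organ segmenter wrapping the residual 3D U-Net, sklearn-style.

    ``fit`` consumes normalized volumes and binary masks; arbitrary
    per-iteration sampling (augmentation caches, domain swaps) goes
    through :meth:`fit_sampler`.
    """

    def __init__(self, input_shape=(32, 32, 32), base_channels=8, depth=2,
                 groupnorm_groups=4, leaky_slope=0.01, batch_size=2,
                 learning_rate=1e-3, max_iterations=300, patience_epochs=10,
                 steps_per_epoch=None, seed=0):
        self.input_shape = input_shape
        self.base_channels = base_channels
        self.depth = depth
        self.groupnorm_groups = groupnorm_groups
        self.leaky_slope = leaky_slope
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_iterations = max_iterations
        self.patience_epochs = patience_epochs
        self.steps_per_epoch = steps_per_epoch
        self.seed = seed

    def _config(self) -> UNetConfig:
        return UNetConfig(
            input_shape=tuple(self.input_shape),
            base_channels=self.base_channels,
            depth=self.depth,
            groupnorm_groups=self.groupnorm_groups,
            leaky_slope=self.leaky_slope,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )

    # -- training ------------------------------------------------------------
    def fit_sampler(self, sample_fn, val_pairs, n_train_samples: int | None = None):
        """Train with an arbitrary sampler.

        sample_fn(rng) must return one (image 3D float array, mask 3D binary
        array) training pair; ``val_pairs`` is a list of such pairs used for
        best-checkpoint selection with patience-based early stopping.
        """
        if not val_pairs:
            raise ValueError("validation set is empty; checkpoint selection undefined")
        config = self._config()
        model = build_unet3d(config)
        self.model_ = model
        self.history_ = []
        if self.max_iterations <= 0:
            warnings.warn("max_iterations <= 0: returning initialization")
            self.n_iterations_ = 0
            self.best_val_dice_ = self._val_dice(val_pairs)
            return self

        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 101]))
        opt = Adam(model.parameters(), lr=self.learning_rate)
        steps = self.steps_per_epoch
        if steps is None:
            base = n_train_samples if n_train_samples else 16
            steps = max(1, int(np.ceil(base / self.batch_size)))

        best_dice = -np.inf
        best_state = None
        epochs_without_improvement = 0
        it = 0
        while it < self.max_iterations:
            for _ in range(steps):
                if it >= self.max_iterations:
                    break
                imgs, masks = [], []
                for _ in range(self.batch_size):
                    img, msk = sample_fn(rng)
                    imgs.append(img)
                    masks.append(msk)
                x = Tensor(np.stack(imgs)[:, None].astype(np.float32))
                y = np.stack(masks)[:, None]
                model.zero_grad()
                loss = soft_dice_loss_tensor(model(x), y, s=1.0)
                loss.backward()
                opt.step()
                it += 1
            val_dice = self._val_dice(val_pairs)
            self.history_.append({"iteration": it, "val_dice": val_dice})
            if val_dice > best_dice:
                best_dice = val_dice
                best_state = [p.copy() for p in model.state_arrays()]
                epochs_without_improvement = 0
            else:
                epochs_without_improvement += 1
            if epochs_without_improvement >= self.patience_epochs:
                break
        if best_state is not None:
            model.load_state_arrays(best_state)
        self.best_val_dice_ = best_dice
        self.n_iterations_ = it
        return self

    def fit(self, X, y):
        """Fit on lists of normalized 3D arrays/VolumeGrids and binary masks."""
        pairs = [(_values(v), _values(m)) for v, m in zip(X, y)]

        def sample_fn(rng):
            return pairs[rng.integers(len(pairs))]

        # no held-out set supplied: select on the training pairs
        return self.fit_sampler(sample_fn, pairs, n_train_samples=len(pairs))

    # -- inference -----------------------------------------------------------
    def _val_dice(self, val_pairs) -> float:
        scores = []
        for img, msk in val_pairs:
            x = Tensor(np.asarray(img)[None, None].astype(np.float32))
            pred = (self.model_(x).data[0, 0] >= 0.5).astype(np.uint8)
            scores.append(metrics.dice_score_empty_as_zero(np.asarray(msk), pred))
        return float(np.mean(scores))

    def predict(self, volume: VolumeGrid, case_id: str = "") -> SegPrediction:
        return predict_mask(self.model_, volume, case_id=case_id)


def _values(x) -> np.ndarray:
    if isinstance(x, VolumeGrid):
        return x.values
    if isinstance(x, LabelVolume):
        return x.values
    return np.asarray(x)
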