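"""Unpaired two-domain slice translator (CycleGAN).

Two residual encoder/decoder generators translate axial CT slices
between the contrast (A) and non-contrast (B) domains; two patch
discriminators drive a least-squares adversarial objective. Training is
regularized by the cycle-consistency loss ||G_BtoA(G_AtoB(x)) - x||_1
(translate there and back must approximate identity — the property that
makes *unpaired* training possible) and an identity loss on
already-in-domain inputs.

Each generator carries a global residual connection:

    G(x) = x + delta_max * tanh(body(x))

so the output stays within ``delta_max`` of the input in normalized
intensity units and learning a near-identity translation is fast. With
``identity_init=True`` the final convolution of the body is
zero-initialized, making an untrained generator *exactly* the identity —
a deterministic oracle for :func:`translate_volume`. The training
objective pairs the least-squares adversarial terms with squared-error
cycle and identity penalties: unlike the absolute-error form, their
gradients vanish as the reconstruction approaches identity, which lets
the (comparatively weak) adversarial signal act within a desk-scale
iteration budget. Translation of a 3D volume is
slice-wise along the z axis, mirroring the memory constraints that make
3D GANs impractical; the resulting slice-to-slice inconsistency is
measurable with :func:`slice_consistency_sd`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom as nd_zoom
from sklearn.base import BaseEstimator

from .grids import NORMALIZED, VolumeGrid
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv, ConvTranspose, InstanceNorm, LeakyReLU, Module, Sequential, Tanh
from .nn.optim import Adam


@dataclass
class TranslatorConfig:
    slice_resolution: int = 32
    generator_width: int = 8
    discriminator_width: int = 8
    n_res_blocks: int = 3
    lambda_cycle: float = 2.0
    lambda_identity: float = 1.0  # 0.5 * lambda_cycle
    iterations: int = 500
    batch_size: int = 4
    learning_rate: float = 2e-3
    buffer_size: int = 50
    delta_max: float = 3.0  # max |output - input| in normalized units
    identity_init: bool = False  # zero residual path: exact identity mapping
    warmup_iterations: int = 50  # identity-pretraining phase (no adversarial)
    seed: int = 0

    def validate(self) -> None:
        r = self.slice_resolution
        if r < 16 or (r & (r - 1)) != 0:
            raise ValueError(f"slice_resolution must be a power of two >= 16, got {r}")
        if self.lambda_cycle <= 0:
            raise ValueError("lambda_cycle must be > 0")


class _ResBlock2d(Module):
    def __init__(self, ch, rng):
        super().__init__()
        self.body = self.add_module(
            Sequential(
                Conv(2, ch, ch, 3, rng=rng), InstanceNorm(ch), LeakyReLU(0.0),
                Conv(2, ch, ch, 3, rng=rng), InstanceNorm(ch),
            )
        )

    def forward(self, x):
        return x + self.body(x)


class Generator2d(Module):
    """Residual encoder/decoder slice generator with a global skip."""

    def __init__(self, config: TranslatorConfig, rng):
        super().__init__()
        w = config.generator_width
        self.delta_max = config.delta_max
        layers = [
            Conv(2, 1, w, 7, rng=rng), InstanceNorm(w), LeakyReLU(0.0),
            Conv(2, w, 2 * w, 3, stride=2, rng=rng), InstanceNorm(2 * w), LeakyReLU(0.0),
            Conv(2, 2 * w, 4 * w, 3, stride=2, rng=rng), InstanceNorm(4 * w), LeakyReLU(0.0),
        ]
        layers += [_ResBlock2d(4 * w, rng) for _ in range(config.n_res_blocks)]
        layers += [
            ConvTranspose(2, 4 * w, 2 * w, stride=2, rng=rng), InstanceNorm(2 * w), LeakyReLU(0.0),
            ConvTranspose(2, 2 * w, w, stride=2, rng=rng), InstanceNorm(w), LeakyReLU(0.0),
            # identity test mode zero-inits the final conv (exact identity);
            # for training, a moderate init keeps tanh unsaturated so the
            # identity-pretraining warmup converges quickly
            Conv(2, w, 1, 7, rng=rng, zero_init=config.identity_init, init_scale=0.3),
            Tanh(),
        ]
        self.body = self.add_module(Sequential(*layers))

    def forward(self, x):
        return x + self.body(x) * self.delta_max


class Discriminator2d(Module):
    """Patch discriminator: real/fake score per receptive-field patch."""

    def __init__(self, config: TranslatorConfig, rng):
        super().__init__()
        w = config.discriminator_width
        self.body = self.add_module(
            Sequential(
                Conv(2, 1, w, 4, stride=2, pad=1, rng=rng), LeakyReLU(0.2),
                Conv(2, w, 2 * w, 4, stride=2, pad=1, rng=rng), InstanceNorm(2 * w), LeakyReLU(0.2),
                Conv(2, 2 * w, 1, 3, rng=rng),
            )
        )

    def forward(self, x):
        return self.body(x)


# ---------------------------------------------------------------------------
# Losses (public, array-level contracts)


def adversarial_loss(discriminator_scores, target: str) -> float:
    """Least-squares adversarial objective: mean (score - t)^2, t=1 real / 0 fake."""
    scores = discriminator_scores.data if isinstance(discriminator_scores, Tensor) else np.asarray(
        discriminator_scores, dtype=np.float64
    )
    if target not in ("real", "fake"):
        raise ValueError("target must be 'real' or 'fake'")
    t = 1.0 if target == "real" else 0.0
    return float(np.mean((scores - t) ** 2))


def cycle_consistency_loss(x: np.ndarray, g_ab, g_ba) -> float:
    """Mean absolute reconstruction error ||G_BtoA(G_AtoB(x)) - x||_1."""
    x = np.asarray(x, dtype=np.float64)
    rec = np.asarray(g_ba(g_ab(x)), dtype=np.float64)
    if rec.shape != x.shape:
        raise ValueError(f"reconstruction shape {rec.shape} != input {x.shape}")
    return float(np.mean(np.abs(rec - x)))


def _adv_loss_t(scores: Tensor, target_value: float) -> Tensor:
    d = scores - target_value
    return (d * d).mean()


def _l2_t(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()


# ---------------------------------------------------------------------------
# Slice extraction


def extract_training_slices(pool: list[VolumeGrid], resolution: int,
                            rng: np.random.Generator | None = None,
                            body_fraction_min: float = 0.05) -> list[np.ndarray]:
    """Axial slices resampled to resolution^2; near-empty slices dropped.

    A voxel counts as body when it sits above the volume's intensity
    floor (the clip floor / air after normalization).
    """
    if not pool:
        raise ValueError("empty volume pool")
    slices: list[np.ndarray] = []
    for vol in pool:
        if vol.intensity_kind != NORMALIZED:
            raise ValueError("extract_training_slices expects clipped+normalized volumes")
        values = vol.values
        floor = values.min() + 1e-6 * max(np.ptp(values), 1e-12)
        for k in range(values.shape[2]):
            sl = values[:, :, k]
            if np.mean(sl > floor) < body_fraction_min:
                continue
            slices.append(_resample_slice(sl, (resolution, resolution)))
    if not slices:
        warnings.warn("no slices passed the body filter")
    if rng is not None:
        order = rng.permutation(len(slices))
        slices = [slices[i] for i in order]
    return slices


def _resample_slice(sl: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    factors = (shape[0] / sl.shape[0], shape[1] / sl.shape[1])
    if factors == (1.0, 1.0):
        return sl.astype(np.float32)
    return nd_zoom(sl, factors, order=1, mode="nearest").astype(np.float32)


# ---------------------------------------------------------------------------
# Training state


@dataclass
class TranslatorState:
    config: TranslatorConfig
    params_AtoB: list[np.ndarray]
    params_BtoA: list[np.ndarray]
    params_discA: list[np.ndarray]
    params_discB: list[np.ndarray]
    history: list[dict] = field(default_factory=list)
    iterations_done: int = 0

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {}
        for name in ("params_AtoB", "params_BtoA", "params_discA", "params_discB"):
            for i, a in enumerate(getattr(self, name)):
                arrays[f"{name}__{i}"] = a
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "config": asdict(self.config),
            "history": self.history,
            "iterations_done": self.iterations_done,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TranslatorState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        npz = np.load(path.with_suffix(".npz"))
        groups: dict[str, list] = {k: [] for k in
                                   ("params_AtoB", "params_BtoA", "params_discA", "params_discB")}
        for key in npz.files:
            name, idx = key.rsplit("__", 1)
            groups[name].append((int(idx), npz[key]))
        kwargs = {k: [a for _, a in sorted(v)] for k, v in groups.items()}
        cfg = TranslatorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in meta["config"].items()})
        return cls(config=cfg, history=meta["history"],
                   iterations_done=meta["iterations_done"], **kwargs)


class _ImageBuffer:
    """Pool of past generated slices shown to the discriminator (size 50)."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.items: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.items) < self.size:
                self.items.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                out.append(img)
            else:
                j = int(self.rng.integers(self.size))
                out.append(self.items[j].copy())
                self.items[j] = img.copy()
        return np.stack(out)


class CycleGANTranslator(BaseEstimator):
    """Contrast <-> non-contrast slice translator, sklearn-style estimator.

    ``fit(pool_a, pool_b)`` trains on unpaired normalized volumes (A =
    contrast, B = non-contrast); ``transform(volume)`` translates a
    volume slice-wise A->B (or B->A with ``direction="BtoA"``).
    """

    def __init__(self, slice_resolution=32, generator_width=8, discriminator_width=8,
                 n_res_blocks=3, lambda_cycle=2.0, lambda_identity=1.0,
                 iterations=500, batch_size=4, learning_rate=2e-3,
                 buffer_size=50, delta_max=3.0, identity_init=False,
                 warmup_iterations=50, seed=0):
        self.slice_resolution = slice_resolution
        self.generator_width = generator_width
        self.discriminator_width = discriminator_width
        self.n_res_blocks = n_res_blocks
        self.lambda_cycle = lambda_cycle
        self.lambda_identity = lambda_identity
        self.iterations = iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.buffer_size = buffer_size
        self.delta_max = delta_max
        self.identity_init = identity_init
        self.warmup_iterations = warmup_iterations
        self.seed = seed

    def _config(self) -> TranslatorConfig:
        return TranslatorConfig(
            slice_resolution=self.slice_resolution,
            generator_width=self.generator_width,
            discriminator_width=self.discriminator_width,
            n_res_blocks=self.n_res_blocks,
            lambda_cycle=self.lambda_cycle,
            lambda_identity=self.lambda_identity,
            iterations=self.iterations,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            buffer_size=self.buffer_size,
            delta_max=self.delta_max,
            identity_init=self.identity_init,
            warmup_iterations=self.warmup_iterations,
            seed=self.seed,
        )

    def _build(self, config: TranslatorConfig):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
        self.G_ab_ = Generator2d(config, rng)
        self.G_ba_ = Generator2d(config, rng)
        self.D_a_ = Discriminator2d(config, rng)
        self.D_b_ = Discriminator2d(config, rng)

    def fit(self, pool_a: list[VolumeGrid], pool_b: list[VolumeGrid]) -> "CycleGANTranslator":
        config = self._config()
        config.validate()
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 13]))
        slices_a = extract_training_slices(pool_a, config.slice_resolution, rng)
        slices_b = extract_training_slices(pool_b, config.slice_resolution, rng)
        if not slices_a or not slices_b:
            raise ValueError("a translator pool produced no usable slices")
        self._build(config)
        self.history_ = []
        if config.iterations <= 0:
            self.state_ = self._state(config)
            return self

        g_params = self.G_ab_.parameters() + self.G_ba_.parameters()
        opt_g = Adam(g_params, lr=config.learning_rate)
        opt_da = Adam(self.D_a_.parameters(), lr=config.learning_rate)
        opt_db = Adam(self.D_b_.parameters(), lr=config.learning_rate)
        buf_a = _ImageBuffer(config.buffer_size, np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 17])))
        buf_b = _ImageBuffer(config.buffer_size, np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 19])))

        A = np.stack(slices_a)[:, None]
        B = np.stack(slices_b)[:, None]
        lam_c, lam_i = config.lambda_cycle, config.lambda_identity
        warmup = 0 if config.identity_init else min(config.warmup_iterations,
                                                    config.iterations)
        for it in range(config.iterations):
            if it == warmup and warmup > 0:
                # identity pretraining over: restart the generator optimizer
                # so its moment estimates reflect the adversarial phase only
                opt_g = Adam(g_params, lr=config.learning_rate)
            for opt in (opt_g, opt_da, opt_db):
                opt.set_lr_linear_decay(it, config.iterations)
            real_a = Tensor(A[rng.integers(len(A), size=config.batch_size)])
            real_b = Tensor(B[rng.integers(len(B), size=config.batch_size)])

            # generator update
            for m in (self.G_ab_, self.G_ba_, self.D_a_, self.D_b_):
                m.zero_grad()
            fake_b = self.G_ab_(real_a)
            fake_a = self.G_ba_(real_b)
            rec_a = self.G_ba_(fake_b)
            rec_b = self.G_ab_(fake_a)
            adv = _adv_loss_t(self.D_b_(fake_b), 1.0) + _adv_loss_t(self.D_a_(fake_a), 1.0)
            cyc = _l2_t(rec_a, real_a) + _l2_t(rec_b, real_b)
            idt = _l2_t(self.G_ab_(real_b), real_b) + _l2_t(self.G_ba_(real_a), real_a)
            if it < warmup:
                loss_g = lam_c * cyc + lam_i * idt
            else:
                loss_g = adv + lam_c * cyc + lam_i * idt
            loss_g.backward()
            opt_g.step()

            # discriminator updates (on buffered fakes)
            fake_a_d = buf_a.query(fake_a.data)
            fake_b_d = buf_b.query(fake_b.data)
            self.D_a_.zero_grad()
            loss_da = (_adv_loss_t(self.D_a_(Tensor(A[rng.integers(len(A), size=config.batch_size)])), 1.0)
                       + _adv_loss_t(self.D_a_(Tensor(fake_a_d)), 0.0)) * 0.5
            loss_da.backward()
            opt_da.step()
            self.D_b_.zero_grad()
            loss_db = (_adv_loss_t(self.D_b_(Tensor(B[rng.integers(len(B), size=config.batch_size)])), 1.0)
                       + _adv_loss_t(self.D_b_(Tensor(fake_b_d)), 0.0)) * 0.5
            loss_db.backward()
            opt_db.step()

            rec = {
                "iteration": it,
                "loss_g_adv": float(adv.data),
                # canonical cycle-consistency metric (mean absolute error);
                # the optimized penalty is its squared-error surrogate
                "loss_cycle": float(np.mean(np.abs(rec_a.data - real_a.data))
                                    + np.mean(np.abs(rec_b.data - real_b.data))),
                "loss_cycle_sq": float(cyc.data),
                "loss_identity": float(idt.data),
                "loss_d_a": float(loss_da.data),
                "loss_d_b": float(loss_db.data),
            }
            if not all(np.isfinite(v) for v in rec.values()):
                raise FloatingPointError(f"training diverged at iteration {it}: {rec}")
            self.history_.append(rec)

        self.state_ = self._state(config)
        return self

    def _state(self, config: TranslatorConfig) -> TranslatorState:
        return TranslatorState(
            config=config,
            params_AtoB=[p.copy() for p in self.G_ab_.state_arrays()],
            params_BtoA=[p.copy() for p in self.G_ba_.state_arrays()],
            params_discA=[p.copy() for p in self.D_a_.state_arrays()],
            params_discB=[p.copy() for p in self.D_b_.state_arrays()],
            history=list(self.history_),
            iterations_done=len(self.history_),
        )

    @classmethod
    def from_state(cls, state: TranslatorState) -> "CycleGANTranslator":
        est = cls(**asdict(state.config))
        est._build(state.config)
        est.G_ab_.load_state_arrays(state.params_AtoB)
        est.G_ba_.load_state_arrays(state.params_BtoA)
        est.D_a_.load_state_arrays(state.params_discA)
        est.D_b_.load_state_arrays(state.params_discB)
        est.history_ = list(state.history)
        est.state_ = state
        return est

    # -- inference -----------------------------------------------------------
    def _generator(self, direction: str) -> Generator2d:
        if not hasattr(self, "G_ab_"):
            raise ValueError("translator is untrained; call fit() or from_state() first")
        if direction == "AtoB":
            return self.G_ab_
        if direction == "BtoA":
            return self.G_ba_
        raise ValueError(f"unknown direction {direction!r}")

    def translate_slices(self, slices: np.ndarray, direction: str = "AtoB",
                         batch: int = 16) -> np.ndarray:
        gen = self._generator(direction)
        out = []
        for i in range(0, len(slices), batch):
            x = Tensor(np.asarray(slices[i:i + batch], dtype=np.float32)[:, None])
            out.append(gen(x).data[:, 0])
        return np.concatenate(out)

    def transform(self, volume: VolumeGrid, direction: str = "AtoB") -> VolumeGrid:
        return translate_volume(self, volume, direction)


def translate_volume(translator: CycleGANTranslator, volume: VolumeGrid,
                     direction: str = "AtoB") -> VolumeGrid:
    """Slice-wise translation of a normalized volume; geometry unchanged."""
    if volume.intensity_kind != NORMALIZED:
        raise ValueError("translate_volume expects a clipped+normalized volume")
    res = translator._config().slice_resolution
    translator._generator(direction)  # untrained -> raises
    nx, ny, nz = volume.shape
    small = np.stack([_resample_slice(volume.values[:, :, k], (res, res)) for k in range(nz)])
    translated = translator.translate_slices(small, direction)
    out = np.empty_like(volume.values)
    for k in range(nz):
        out[:, :, k] = _resample_slice(translated[k], (nx, ny))
    result = volume.with_values(out.astype(np.float64))
    result.synthetic = True
    return result


def slice_consistency_sd(original: VolumeGrid, translated: VolumeGrid, mask) -> float:
    """SD across slices of the per-slice in-mask intensity shift.

    Quantifies the slice-to-slice inconsistency inherent to 2D slice-wise
    translation of a 3D volume.
    """
    m = mask.values.astype(bool) if hasattr(mask, "values") else np.asarray(mask, dtype=bool)
    shifts = []
    for k in range(original.shape[2]):
        mk = m[:, :, k]
        if mk.sum() == 0:
            continue
        shifts.append(translated.values[:, :, k][mk].mean() - original.values[:, :, k][mk].mean())
    if len(shifts) < 2:
        raise ValueError("need >= 2 organ-containing slices")
    return float(np.std(shifts, ddof=1))
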