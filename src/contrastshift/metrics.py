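"""Segmentation metrics: smoothed Dice loss, Dice score, relative volume error.

The training objective is the smoothed Dice loss

    Loss = 1 - 2 (<X, Y> + s) / (sum X + sum Y + s)

with smoothing ``s = 1`` during training (keeps the loss defined and its
gradient stable when a prediction or reference is empty) and ``s = 0``
for evaluation, where ``1 - Loss`` on binary masks is the ordinary Dice
score 2|X∩Y| / (|X| + |Y|). The soft intersection <X, Y> is the
elementwise product sum, so the loss is differentiable in a soft
prediction X ∈ [0, 1]^n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import LabelVolume


@dataclass
class DiceSpec:
    """Smoothing used by the Dice loss: s=1 for training, s=0 for evaluation."""

    s: float = 1.0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("smoothing s must be >= 0")


TRAIN_DICE = DiceSpec(s=1.0)
EVAL_DICE = DiceSpec(s=0.0)


def _as_array(x) -> np.ndarray:
    if isinstance(x, LabelVolume):
        return x.values.astype(np.float64)
    return np.asarray(x, dtype=np.float64)


def dice_loss(prediction, reference, spec: DiceSpec = TRAIN_DICE) -> float:
    """Smoothed Dice loss between a soft/binary prediction and a binary mask."""
    x = _as_array(prediction)
    y = _as_array(reference)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("prediction values must lie in [0, 1]")
    if not np.all(np.isin(np.unique(y), (0.0, 1.0))):
        raise ValueError("reference must be binary")
    denom = x.sum() + y.sum() + spec.s
    if denom == 0:
        raise ValueError("Dice loss undefined: both masks empty and s = 0")
    return float(1.0 - 2.0 * ((x * y).sum() + spec.s) / denom)


def dice_score(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two binary masks."""
    a = _as_array(mask_a)
    b = _as_array(mask_b)
    for arr, name in ((a, "A"), (b, "B")):
        if not np.all(np.isin(np.unique(arr), (0.0, 1.0))):
            raise ValueError(f"mask {name} must be binary")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Dice score undefined for two empty masks")
    return float(2.0 * (a * b).sum() / (a.sum() + b.sum()))


def dice_score_empty_as_zero(reference, predicted) -> float:
    """Dice with the empty-prediction-vs-nonempty-reference limit recorded as 0.

    Out-of-distribution failure cases routinely predict nothing; scoring
    them 0 keeps them finite and comparable across conditions.
    """
    p = _as_array(predicted)
    r = _as_array(reference)
    if p.sum() == 0 and r.sum() > 0:
        return 0.0
    return dice_score(reference, predicted)


def volume_error(expert: LabelVolume, predicted: LabelVolume,
                 spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Relative volume estimation error |V_expert - V_pred| / V_expert."""
    v_vox = float(np.prod(spacing_mm))
    v_expert = _as_array(expert).sum() * v_vox
    if v_expert == 0:
        raise ValueError("volume_error undefined: expert mask is empty")
    v_pred = _as_array(predicted).sum() * v_vox
    return float(abs(v_expert - v_pred) / v_expert)
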