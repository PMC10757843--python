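"""Soft Dice loss, CPS cross-supervision loss, and the lambda warm-up schedule.

The supervised and unsupervised objectives are both soft Dice losses

    DL(y, p) = 1 - (2 * sum(y*p) + eps) / (sum(y) + sum(p) + eps)

computed per sample and averaged over the batch. The cross pseudo
supervision (CPS) term lets two networks supervise each other through hard
pseudo-labels; gradients never flow back through the pseudo-label producer.
The CPS weight lambda follows a piecewise warm-up: a tiny plateau for the
first five epochs (pseudo-labels are still noise), a linear ramp over epochs
6-19, and 1 thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

EPSILON = 1e-6
PSEUDO_LABEL_THRESHOLD = 0.5

# warm-up schedule constants
WARMUP_PLATEAU = 0.00001
WARMUP_SLOPE = 0.067
WARMUP_INTERCEPT = -0.335
WARMUP_BREAK_LOW = 5    # last epoch of the plateau
WARMUP_BREAK_HIGH = 19  # last epoch of the linear ramp


@dataclass
class ConfidenceMap:
    values: object  # numpy array or Tensor, in [0, 1]
    grad_enabled: bool = False


@dataclass
class PseudoLabelMap:
    labels: np.ndarray
    derived_from: int = 0


@dataclass
class LossWeights:
    lambda_value: float
    epoch: int
    warmup_spec: dict = field(default_factory=lambda: {
        "plateau": WARMUP_PLATEAU, "slope": WARMUP_SLOPE,
        "intercept": WARMUP_INTERCEPT,
        "break_low": WARMUP_BREAK_LOW, "break_high": WARMUP_BREAK_HIGH,
    })

    @classmethod
    def at_epoch(cls, epoch: int) -> "LossWeights":
        return cls(lambda_value=lambda_warmup(epoch), epoch=epoch)


def _raw(x):
    if isinstance(x, ConfidenceMap):
        x = x.values
    if isinstance(x, PseudoLabelMap):
        x = x.labels
    return x


def _spatial_axes(x) -> tuple:
    ndim = x.ndim
    if ndim <= 1:
        return (0,) if ndim == 1 else ()
    return tuple(range(1, ndim))


def soft_dice_loss(y, p_hat, epsilon: float = EPSILON):
    """Soft Dice loss between a binary target and a confidence map.

    1D inputs are treated as a single sample; otherwise the first axis is
    the batch: Dice is computed per sample and averaged. Works on numpy
    arrays (returns float) and autodiff Tensors (returns a scalar Tensor).
    """
    y, p_hat = _raw(y), _raw(p_hat)
    y_arr = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64)
    if not np.all(np.isin(np.unique(y_arr), [0.0, 1.0])):
        raise ValueError("target must be binary")
    p_shape = p_hat.shape
    if tuple(p_shape) != y_arr.shape:
        raise ValueError(f"shape mismatch: target {y_arr.shape} vs prediction {tuple(p_shape)}")
    single = y_arr.ndim <= 1
    if single:
        y_arr = y_arr.reshape(1, -1)
        p_hat = p_hat.reshape(1, -1) if isinstance(p_hat, Tensor) \
            else np.asarray(p_hat, dtype=np.float64).reshape(1, -1)
    axes = _spatial_axes(y_arr)
    inter = (y_arr * p_hat).sum(axis=axes)
    denom = y_arr.sum(axis=axes) + p_hat.sum(axis=axes)
    loss = (1.0 - (2.0 * inter + epsilon) / (denom + epsilon)).mean()
    return loss


def lambda_warmup(epoch: int) -> float:
    """Piecewise CPS-weight schedule: 0.00001 (epochs <= 5), 0.067*epoch - 0.335
    (epochs 6-19), 1 afterwards."""
    if epoch < 0 or int(epoch) != epoch:
        raise ValueError("epoch must be a non-negative integer")
    epoch = int(epoch)
    if epoch <= WARMUP_BREAK_LOW:
        return WARMUP_PLATEAU
    if epoch <= WARMUP_BREAK_HIGH:
        return WARMUP_SLOPE * epoch + WARMUP_INTERCEPT
    return 1.0


def pseudo_label(p, threshold: float = PSEUDO_LABEL_THRESHOLD,
                 derived_from: int = 0) -> PseudoLabelMap:
    """Hard labels (p >= threshold) detached from the computation graph.

    Ties go to foreground. The returned map is a plain numpy array, so no
    gradient can flow back into the producing network through it.
    """
    p = _raw(p)
    data = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    return PseudoLabelMap(labels=(data >= threshold).astype(np.float64),
                          derived_from=derived_from)


def cps_loss(p1, p2, epsilon: float = EPSILON):
    """Cross pseudo supervision loss with the soft-Dice substitution.

    Each network's confidence map is scored against the *other* network's
    hard pseudo-labels; the two Dice terms are summed. Symmetric in its
    arguments.
    """
    y1 = pseudo_label(p1, derived_from=1)
    y2 = pseudo_label(p2, derived_from=2)
    return soft_dice_loss(y2.labels, p1, epsilon) + soft_dice_loss(y1.labels, p2, epsilon)


def total_loss(L_s, L_cps, lam: float):
    """Total objective: supervised loss plus lambda-weighted CPS loss."""
    for name, val in (("L_s", L_s), ("L_cps", L_cps), ("lam", lam)):
        v = val.data if isinstance(val, Tensor) else val
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite")
    return L_s + lam * L_cps
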