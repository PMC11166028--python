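"""Training objectives: Dice, BCE, CAM localization maps, cross-task loss.

The cross-task loss is the second information-interaction mechanism: the
classification head's class-activation maps (CAM) at three stages are
pulled toward the segmentation head's intermediate multi-scale maps with
a weighted MSE, so each task supervises the other's notion of "where the
lesions are".
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor, as_tensor
from .joint_model import ClsForwardState, MultiScaleSegMaps


@dataclasses.dataclass
class LossWeights:
    """beta weights the three total-loss terms; eta the three CAM scales."""

    beta: tuple = (1.0, 0.8, 1.0)
    eta: tuple = (0.25, 0.25, 0.5)

    def __post_init__(self):
        if len(self.beta) != 3 or len(self.eta) != 3:
            raise ValueError("beta and eta each need 3 entries")
        if any(b < 0 for b in self.beta) or any(e < 0 for e in self.eta):
            raise ValueError("loss weights must be non-negative")


def dice_loss(pred: Tensor | np.ndarray, truth: Tensor | np.ndarray,
              smooth: float = 1.0) -> Tensor:
    """Soft Dice loss 1 - (2|X.Y| + s) / (|X| + |Y| + s).

    ``smooth`` stabilizes empty masks (default 1.0); at smooth=0 the value
    is the exact 1 - DSC of the (binarized) inputs.
    """
    pred, truth = as_tensor(pred), as_tensor(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    inter = T.sum_(T.mul(pred, truth))
    total = T.add(T.sum_(pred), T.sum_(truth))
    dice = T.div(T.add(T.mul(inter, 2.0), smooth), T.add(total, smooth))
    return T.sub(1.0, dice)


def bce_loss(p_hat: Tensor | np.ndarray, y: np.ndarray,
             eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy on positive-class probabilities.

    Probabilities are clipped to [eps, 1-eps] before the log (guard, not
    an error).
    """
    clipped = T.clip(as_tensor(p_hat), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float32)
    pos = T.mul(y, T.log(clipped))
    negp = T.mul(1.0 - y, T.log(T.sub(1.0, clipped)))
    return T.neg(T.mean(T.add(pos, negp)))


def _minmax_normalize(x: Tensor) -> Tensor:
    """Map to [0, 1] per map; a constant map normalizes to all-zeros."""
    mn = T.reduce_min(x)
    mx = T.reduce_max(x)
    if float(mx.data) - float(mn.data) < 1e-12:
        return T.mul(x, 0.0)
    return T.div(T.sub(x, mn), T.sub(mx, mn))


def cam_maps(state: ClsForwardState, c: int | np.ndarray,
             normalize: bool = True) -> list:
    """Class-activation maps V_i = sum_k F_{i,k} * w_{i,k}^c per stage.

    ``c`` is the target class index (scalar) or a per-sample label vector.
    The final-layer weight matrix is split by stage along its input axis.
    Maps are min-max normalized to [0, 1] per map unless ``normalize`` is
    False (raw weighted sums).
    """
    W = state.fc_weights                      # (sum(C_i), 2)
    sizes = [f.shape[1] for f in state.stage_features]
    if sum(sizes) != W.shape[0]:
        raise ValueError("stage channels do not match FC weight rows")
    n = state.stage_features[0].shape[0]
    labels = np.full(n, c, dtype=int) if np.isscalar(c) else np.asarray(c, int)
    onehot = np.zeros((n, 2), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    maps = []
    offset = 0
    for F, size in zip(state.stage_features, sizes):
        w_stage = W[offset:offset + size]                 # (C_i, 2)
        offset += size
        w_sel = T.matmul(Tensor(onehot), T.transpose(w_stage, (1, 0)))  # (N, C_i)
        w_b = T.reshape(w_sel, (n, size, 1, 1, 1))
        V = T.sum_(T.mul(F, w_b), axis=1, keepdims=True)  # (N, 1, d, h, w)
        maps.append(_minmax_normalize(V) if normalize else V)
    return maps


def cross_task_loss(S: MultiScaleSegMaps | list, V: list,
                    eta: tuple = (0.25, 0.25, 0.5),
                    normalize: bool = True) -> Tensor:
    """sum_i eta_i * mean((S_i - V_i)^2) over the three paired scales.

    V_i is resampled (trilinear) to S_i's grid; both are min-max
    normalized per map before the MSE unless ``normalize`` is False. The
    mean (not sum) over voxels keeps the three scales commensurate.
    """
    s_maps = S.maps if isinstance(S, MultiScaleSegMaps) else list(S)
    if len(s_maps) != 3 or len(V) != 3:
        raise ValueError("cross-task loss pairs exactly three scales")
    total = None
    for eta_i, s_i, v_i in zip(eta, s_maps, V):
        s_i, v_i = as_tensor(s_i), as_tensor(v_i)
        if v_i.shape[2:] != s_i.shape[2:]:
            v_i = T.resize3d(v_i, s_i.shape[2:], "linear")
        if v_i.shape != s_i.shape:
            raise ValueError("scale pairing failed: "
                             f"{v_i.shape} vs {s_i.shape}")
        if normalize:
            s_i = _minmax_normalize(s_i)
            v_i = _minmax_normalize(v_i)
        term = T.mul(T.mean(T.pow_(T.sub(s_i, v_i), 2.0)), float(eta_i))
        total = term if total is None else T.add(total, term)
    return total


def total_loss(l_seg, l_cls, l_cross, beta: tuple = (1.0, 0.8, 1.0)) -> Tensor:
    """beta1*Lseg + beta2*Lcls + beta3*Lcross."""
    terms = [T.mul(as_tensor(l), float(b))
             for l, b in zip((l_seg, l_cls, l_cross), beta)]
    return T.add(T.add(terms[0], terms[1]), terms[2])
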