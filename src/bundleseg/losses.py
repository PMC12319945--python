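"""Training losses: focal loss and the NT-Xent contrastive loss.

Focal loss down-weights well-classified pixels, which matters here because
fiber bundles occupy a small fraction of a section, so the background class
dominates.  With weighting parameter ``alpha`` and focusing parameter
``gamma``::

    FL(p_t) = -alpha_t (1 - p_t)^gamma log(p_t)
    p_t = p        if y = 1
    p_t = 1 - p    if y = 0

where ``p`` is the predicted probability of the fiber class, ``alpha_t = alpha``
for positives and ``1 - alpha`` for negatives (the convention of the focal-loss
literature).

The contrastive loss is the normalized-temperature cross entropy (NT-Xent) of
SimCLR over a batch of N positive pairs (2N feature vectors).  For an ordered
pair (i, j)::

    l(i, j) = -log( exp(sim(f_i, f_j)/tau) / sum_{k != i} exp(sim(f_i, f_k)/tau) )

with cosine similarity ``sim`` and temperature ``tau``; the loss is the mean of
``l`` over all 2N ordered pairs.  Feature vectors are expected interleaved:
rows (2m, 2m+1) form the m-th positive pair.

Both losses also expose analytic gradients so the numpy trainer can backprop
through them; the gradients are validated against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FocalParams",
    "ContrastiveParams",
    "focal_loss",
    "focal_loss_grad",
    "contrastive_loss",
    "contrastive_loss_grad",
]

_EPS_P = 1e-7  # probability clamp for log stability
_EPS_NORM = 1e-12  # feature-norm clamp


@dataclass
class FocalParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class ContrastiveParams:
    tau: float = 0.5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def _pt_alphat(p: np.ndarray, y: np.ndarray, params: FocalParams):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    pc = np.clip(p, _EPS_P, 1.0 - _EPS_P)
    pos = y == 1
    p_t = np.where(pos, pc, 1.0 - pc)
    alpha_t = np.where(pos, params.alpha, 1.0 - params.alpha)
    return p_t, alpha_t, pos


def focal_loss(p: np.ndarray, y: np.ndarray, params: FocalParams = FocalParams()) -> float:
    """Mean focal loss of predicted fiber probabilities ``p`` against labels ``y``."""
    p_t, alpha_t, _ = _pt_alphat(p, y, params)
    return float(np.mean(-alpha_t * (1.0 - p_t) ** params.gamma * np.log(p_t)))


def focal_loss_grad(
    p: np.ndarray, y: np.ndarray, params: FocalParams = FocalParams()
) -> np.ndarray:
    """d(mean focal loss)/dp, elementwise, zero where p is clamped."""
    p_t, alpha_t, pos = _pt_alphat(p, y, params)
    g = params.gamma
    one_m = 1.0 - p_t
    # d/dp_t of -alpha_t (1-p_t)^g log(p_t)
    dl_dpt = alpha_t * (g * one_m ** (g - 1.0) * np.log(p_t) - one_m**g / p_t) if g > 0 else (
        -alpha_t / p_t
    )
    dpt_dp = np.where(pos, 1.0, -1.0)
    p_arr = np.asarray(p, dtype=np.float64)
    inside = (p_arr > _EPS_P) & (p_arr < 1.0 - _EPS_P)
    return (dl_dpt * dpt_dp * inside) / p_t.size


def _normalized(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 2 or f.shape[1] < 1:
        raise ValueError("features must be a 2N x D array with D >= 1")
    if f.shape[0] % 2 or f.shape[0] < 4:
        raise ValueError("features must contain N >= 2 positive pairs (even row count >= 4)")
    norms = np.maximum(np.linalg.norm(f, axis=1, keepdims=True), _EPS_NORM)
    return f / norms, norms


def _ntxent_terms(features: np.ndarray, tau: float):
    z, norms = _normalized(features)
    n2 = z.shape[0]
    s = (z @ z.T) / tau
    np.fill_diagonal(s, -np.inf)  # k != i
    partner = np.arange(n2) ^ 1  # interleaved pairs (2m, 2m+1)
    # softmax over each row excluding the diagonal
    smax = s.max(axis=1, keepdims=True)
    e = np.exp(s - smax)
    denom = e.sum(axis=1, keepdims=True)
    logprob = s - (smax + np.log(denom))
    losses = -logprob[np.arange(n2), partner]
    return z, norms, s, e / denom, partner, losses


def contrastive_loss(
    features: np.ndarray, params: ContrastiveParams = ContrastiveParams()
) -> float:
    """NT-Xent loss of interleaved positive pairs; mean over all 2N ordered pairs."""
    *_, losses = _ntxent_terms(features, params.tau)
    return float(losses.mean())


def contrastive_loss_grad(
    features: np.ndarray, params: ContrastiveParams = ContrastiveParams()
) -> np.ndarray:
    """d(mean NT-Xent)/d(features) for the interleaved-pair convention."""
    z, norms, s, soft, partner, _ = _ntxent_terms(features, params.tau)
    n2 = z.shape[0]
    # dL/ds[i,k] = (softmax[i,k] - [k == partner(i)]) / (2N)
    ds = soft.copy()
    ds[np.arange(n2), partner] -= 1.0
    ds /= n2
    ds[np.arange(n2), np.arange(n2)] = 0.0
    ds /= params.tau  # s includes 1/tau
    # dL/dz_i = sum_k ds[i,k] z_k + ds[k,i] z_k   (s is symmetric in z)
    dz = ds @ z + ds.T @ z
    # through the normalization z = f / ||f||
    proj = (dz * z).sum(axis=1, keepdims=True)
    return (dz - z * proj) / norms
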