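"""Model auditing: guided-backprop saliency volumes and attention overlays.

Saliency: the gradient of a region head's prediction with respect to the
input is computed under the guided-backpropagation rule (negative gradients
zeroed at every rectifier unit during the backward pass), then reduced to
a scalar per voxel by abs -> max over the two input channels -> min-max
normalization into [0, 1]. In 3D mode values below a clipping threshold
beta are zeroed; 2D mode performs no clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import Tensor, guided_backprop
from .scan_model import MultiTaskModel, ScanVolume, _encoding_to_voxels

__all__ = ["SaliencyVolume", "normalize_gradient", "compute_saliency", "project_attention"]


@dataclass
class SaliencyVolume:
    """Per-voxel saliency scores in [0, 1] (shape H x W x l)."""

    values: np.ndarray
    beta: float
    clipped: bool

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("saliency values must lie in [0, 1]")
        if self.clipped and np.any((self.values > 0) & (self.values < self.beta)):
            raise ValueError("clipped saliency has nonzero values below beta")


def normalize_gradient(grad: np.ndarray) -> np.ndarray:
    """abs -> max over channels -> subtract min, divide by max (0/0 -> zeros).

    grad: (2, H, W, l) input gradient; returns (H, W, l) in [0, 1].
    """
    scores = np.abs(grad).max(axis=0)
    scores = scores - scores.min()
    peak = scores.max()
    if peak == 0:
        return np.zeros_like(scores)
    return scores / peak


def compute_saliency(
    model: MultiTaskModel,
    scan: ScanVolume,
    region_id: str,
    mode: str = "3d-clipped",
    beta: Optional[float] = None,
) -> SaliencyVolume:
    """Guided-backprop saliency of one region head's prediction.

    beta defaults to the 95th percentile of the normalized saliency in
    3d-clipped mode; 2d-unclipped mode never clips.
    """
    if region_id not in model.heads:
        raise KeyError(f"no head for region {region_id!r}")
    if mode not in ("3d-clipped", "2d-unclipped"):
        raise ValueError(f"unknown saliency mode {mode!r}")
    x = Tensor(scan.data[None], requires_grad=True)
    with guided_backprop():
        voxels = _encoding_to_voxels(model.encoder(x))
        prob, _ = model.heads[region_id](voxels)
        prob.sum().backward()
    if x.grad is None or not np.any(x.grad):
        warnings.warn(
            f"zero input gradient for region {region_id!r}; model may be untrained "
            "or saturated",
            stacklevel=2,
        )
        grad = np.zeros_like(scan.data)
    else:
        grad = x.grad[0]
    normalized = normalize_gradient(grad)
    if mode == "2d-unclipped":
        return SaliencyVolume(values=normalized, beta=float(normalized.min()), clipped=False)
    if beta is None:
        beta = float(np.percentile(normalized, 95.0))
    values = np.where(normalized >= beta, normalized, 0.0)
    return SaliencyVolume(values=values, beta=float(beta), clipped=True)


def project_attention(alpha: np.ndarray, scan_shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbor upsampling of attention weights to the scan grid.

    alpha: (I, J, K) weights summing to 1; returns (H, W, l) overlay
    proportional to alpha and normalized so its maximum is 1.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if not np.isclose(alpha.sum(), 1.0, atol=1e-6):
        raise ValueError(f"attention weights must sum to 1, got {alpha.sum()}")
    out_idx = [
        np.minimum(
            (np.arange(n_out) * n_in) // n_out, n_in - 1
        )
        for n_out, n_in in zip(scan_shape, alpha.shape)
    ]
    overlay = alpha[np.ix_(*out_idx)]
    peak = overlay.max()
    return overlay / peak if peak > 0 else overlay
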