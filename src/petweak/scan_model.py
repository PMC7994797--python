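"""Multi-task 3D scan classifier with per-region soft spatial attention.

A shared strided-convolution encoder maps a 2-channel (PET, CT) volume
X (2 x H x W x l) to an encoding A (d x H' x W' x l') of voxel vectors
a_{ijk}. Each region head scores voxels by a dot product with a learned
attention vector, softmax-normalizes the scores jointly over all voxels,
pools the encoding by the attention weights, and applies a linear sigmoid
classifier. Training minimizes the mean soft-target cross-entropy across
heads against the propagated weak labels.

Two encoder configurations ship: a paper-scale one (d = 1024, spatial
reduction 32x, temporal reduction 6x with ceiling -> 7 x 7 x ceil(l/6) on
224 x 224 inputs) and a tiny desk-scale one (d = 32, reductions 8x / 2x)
used throughout the tests. Both honor the same declared shape contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from sklearn.metrics import roc_auc_score

from .nn import Adam, Conv3d, Module, Tensor, halved_lr, no_grad

__all__ = [
    "ScanVolume",
    "ScanEncoding",
    "EncoderSpec",
    "ScanEncoder",
    "TaskHead",
    "MultiTaskModel",
    "TrainConfig",
    "tiny_encoder_spec",
    "paper_encoder_spec",
    "bilinear_resize_slices",
    "preprocess_scan",
    "augment",
    "encode_scan",
    "attend",
    "predict_region",
    "multitask_loss",
    "train_multitask",
    "finetune_single_task",
]

_EPS = 1e-7

PET_CHANNEL = 0
CT_CHANNEL = 1


@dataclass
class ScanVolume:
    """2-channel volume, channel 0 = PET, channel 1 = CT, shape (2, H, W, l)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError(f"expected shape (2, H, W, l), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scan contains non-finite values")

    @property
    def n_slices(self) -> int:
        return self.data.shape[-1]


@dataclass
class ScanEncoding:
    """Encoder output of shape (d, H', W', l'); voxels are d-vectors."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected shape (d, H', W', l'), got {self.data.shape}")

    @property
    def d(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.data.shape[1:]))


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncoderSpec:
    """Declared architecture and shape-reduction contract of an encoder."""

    channels: tuple[int, ...]
    kernels: tuple[tuple[int, int, int], ...]
    strides: tuple[tuple[int, int, int], ...]
    in_channels: int = 2

    def __post_init__(self):
        if not (len(self.channels) == len(self.kernels) == len(self.strides)):
            raise ValueError("channels/kernels/strides must have equal length")

    @property
    def d(self) -> int:
        return self.channels[-1]

    @property
    def reduction(self) -> tuple[int, int, int]:
        """Per-axis total downsampling factors (spatial_h, spatial_w, temporal)."""
        r = [1, 1, 1]
        for stride in self.strides:
            for axis in range(3):
                r[axis] *= stride[axis]
        return tuple(r)

    @property
    def min_slices(self) -> int:
        return self.reduction[2]

    def output_shape(self, h: int, w: int, l: int) -> tuple[int, int, int, int]:
        rh, rw, rl = self.reduction
        return (self.d, math.ceil(h / rh), math.ceil(w / rw), math.ceil(l / rl))


def tiny_encoder_spec(d: int = 32) -> EncoderSpec:
    """Desk-scale encoder: spatial reduction 8x, temporal 2x."""
    return EncoderSpec(
        channels=(d // 4, d // 2, d),
        kernels=((3, 3, 3),) * 3,
        strides=((2, 2, 2), (2, 2, 1), (2, 2, 1)),
    )


def paper_encoder_spec() -> EncoderSpec:
    """Paper-scale encoder contract: d = 1024, spatial 32x, temporal 6x.

    On a 2 x 224 x 224 x l input the encoding is 1024 x 7 x 7 x ceil(l/6).
    """
    return EncoderSpec(
        channels=(64, 128, 256, 512, 1024),
        kernels=((3, 3, 3),) * 5,
        strides=((2, 2, 2), (2, 2, 3), (2, 2, 1), (2, 2, 1), (2, 2, 1)),
    )


class ScanEncoder(Module):
    """Strided 3D CNN honoring the EncoderSpec shape contract."""

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.layers = []
        cin = spec.in_channels
        for cout, kernel, stride in zip(spec.channels, spec.kernels, spec.strides):
            self.layers.append(Conv3d(cin, cout, kernel, stride, rng))
            cin = cout

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W, L) -> (N, d, H', W', L')."""
        if x.shape[-1] < self.spec.min_slices:
            raise ValueError(
                f"slice count {x.shape[-1]} below encoder minimum {self.spec.min_slices}"
            )
        for layer in self.layers:
            x = layer(x).relu()
        return x


def encode_scan(encoder: ScanEncoder, scan: ScanVolume) -> ScanEncoding:
    """Deterministic forward pass; output shape follows the declared contract."""
    with no_grad():
        out = encoder(Tensor(scan.data[None]))
    encoding = ScanEncoding(data=out.data[0])
    expected = encoder.spec.output_shape(*scan.data.shape[1:])
    if encoding.data.shape != expected:
        raise AssertionError(
            f"encoder violated its shape contract: {encoding.data.shape} != {expected}"
        )
    return encoding


# ---------------------------------------------------------------------------
# preprocessing / augmentation
# ---------------------------------------------------------------------------


def bilinear_resize_slices(volume: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Per-slice bilinear resample of (H, W, l) to (out_h, out_w, l).

    Sample positions follow the half-pixel-center convention:
    src = (dst + 0.5) * (in / out) - 0.5, clamped at the edges.
    """
    h, w, l = volume.shape
    oh, ow = out_hw
    ys = (np.arange(oh) + 0.5) * (h / oh) - 0.5
    xs = (np.arange(ow) + 0.5) * (w / ow) - 0.5
    zs = np.arange(l, dtype=float)
    coords = np.meshgrid(ys, xs, zs, indexing="ij")
    return map_coordinates(volume, coords, order=1, mode="nearest")


def preprocess_scan(pet: np.ndarray, ct: np.ndarray, out_size: int = 224) -> ScanVolume:
    """Resample native PET (128 x 128 x l) and CT (512 x 512 x l) slices to a
    common in-plane grid with bilinear interpolation and stack as 2 channels.
    Intensities pass through unchanged.
    """
    pet = np.asarray(pet, dtype=np.float64)
    ct = np.asarray(ct, dtype=np.float64)
    if pet.ndim != 3 or ct.ndim != 3:
        raise ValueError("pet and ct must be 3D arrays (H, W, l)")
    if pet.shape[-1] != ct.shape[-1]:
        raise ValueError(
            f"slice-count mismatch: PET has {pet.shape[-1]}, CT has {ct.shape[-1]}"
        )
    pet_rs = bilinear_resize_slices(pet, (out_size, out_size))
    ct_rs = bilinear_resize_slices(ct, (out_size, out_size))
    return ScanVolume(data=np.stack([pet_rs, ct_rs], axis=0))


def augment(
    scan: ScanVolume,
    rng: np.random.Generator,
    crop_size: int = 200,
    brightness_max: float = 0.25,
) -> ScanVolume:
    """Random crop (same window for all slices) + resize back + brightness jitter.

    The brightness factor gamma ~ Uniform(0, brightness_max) multiplies the
    whole sequence as (1 + s * gamma) with a random sign s, so jitter can
    both brighten and darken.
    """
    _, h, w, _ = scan.data.shape
    crop_h = min(crop_size, h)
    crop_w = min(crop_size, w)
    y0 = int(rng.integers(0, h - crop_h + 1))
    x0 = int(rng.integers(0, w - crop_w + 1))
    gamma = float(rng.uniform(0.0, brightness_max))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    out = np.empty_like(scan.data)
    for c in range(scan.data.shape[0]):
        cropped = scan.data[c, y0 : y0 + crop_h, x0 : x0 + crop_w, :]
        out[c] = bilinear_resize_slices(cropped, (h, w))
    out *= 1.0 + sign * gamma
    return ScanVolume(data=out)


# ---------------------------------------------------------------------------
# task heads
# ---------------------------------------------------------------------------


class TaskHead(Module):
    """Soft-attention pooling + linear sigmoid classifier for one region."""

    def __init__(self, d: int, region_id: str, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.region_id = region_id
        self.d = d
        # zero attention vector -> uniform attention at initialization, which
        # keeps the voxel softmax well-conditioned early in training
        self.attention = Tensor(np.zeros((d, 1)), requires_grad=True)
        self.classifier = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), (d, 1)), requires_grad=True)
        self.bias = Tensor(np.zeros(1), requires_grad=True)

    def attend(self, voxels: Tensor) -> tuple[Tensor, Tensor]:
        """voxels: (N, V, d) -> pooled (N, d), attention weights (N, V)."""
        n, v, d = voxels.shape
        if d != self.d:
            raise ValueError(f"head expects d={self.d}, encoding has d={d}")
        scores = (voxels @ self.attention).reshape(n, v)
        alpha = scores.softmax(axis=1)
        pooled = (alpha.reshape(n, v, 1) * voxels).sum(axis=1)
        return pooled, alpha

    def predict(self, pooled: Tensor) -> Tensor:
        """pooled: (N, d) -> probabilities (N,) in (0, 1)."""
        return ((pooled @ self.classifier).reshape(-1) + self.bias).sigmoid()

    def __call__(self, voxels: Tensor) -> tuple[Tensor, Tensor]:
        pooled, alpha = self.attend(voxels)
        return self.predict(pooled), alpha


def _encoding_to_voxels(encoding: Tensor) -> Tensor:
    """(N, d, I, J, K) -> (N, V, d)."""
    n, d = encoding.shape[0], encoding.shape[1]
    return encoding.reshape(n, d, -1).transpose(0, 2, 1)


def attend(head: TaskHead, encoding: ScanEncoding) -> tuple[np.ndarray, np.ndarray]:
    """Functional form on a single encoding: returns (pooled a, alpha grid)."""
    with no_grad():
        voxels = _encoding_to_voxels(Tensor(encoding.data[None]))
        pooled, alpha = head.attend(voxels)
    return pooled.data[0], alpha.data[0].reshape(encoding.data.shape[1:])


def predict_region(head: TaskHead, pooled: np.ndarray) -> float:
    """sigmoid(w^T a + b) for a single pooled vector."""
    with no_grad():
        return float(head.predict(Tensor(pooled[None])).item())


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def multitask_loss(targets, predictions) -> Tensor:
    """Mean over tasks (and batch) of soft-target binary cross-entropy.

    `targets`: array-like (T,) or (N, T) of probabilistic labels in [0, 1].
    `predictions`: Tensor/array of the same shape, or a list of T per-task
    Tensors of shape (N,). Predictions are clamped to [eps, 1 - eps].
    """
    if isinstance(predictions, (list, tuple)):
        targets = np.asarray(targets, dtype=np.float64)
        if targets.ndim == 1:
            # (T,) for a single example, or (N,) when there is a single task
            if len(targets) == len(predictions):
                targets = targets.reshape(1, -1)
            else:
                targets = targets.reshape(-1, 1)
        if np.any(targets < 0) or np.any(targets > 1):
            raise ValueError("targets must lie in [0, 1]")
        total = None
        for t, pred in enumerate(predictions):
            y = Tensor(targets[:, t])
            p = pred.clip(_EPS, 1.0 - _EPS)
            ce = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
            term = ce.mean()
            total = term if total is None else total + term
        return total * (1.0 / len(predictions))
    pred = predictions if isinstance(predictions, Tensor) else Tensor(predictions)
    y = Tensor(np.asarray(targets, dtype=np.float64))
    if y.shape != pred.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs predictions {pred.shape}")
    if np.any(y.data < 0) or np.any(y.data > 1):
        raise ValueError("targets must lie in [0, 1]")
    p = pred.clip(_EPS, 1.0 - _EPS)
    ce = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    return ce.mean()


# ---------------------------------------------------------------------------
# model + training
# ---------------------------------------------------------------------------


class MultiTaskModel(Module):
    """Shared encoder + one attention head per region."""

    def __init__(self, spec: EncoderSpec, regions: Sequence[str], seed: int = 0):
        if not regions:
            raise ValueError("need at least one region head")
        self.spec = spec
        self.seed = seed
        self.encoder = ScanEncoder(spec, seed=seed)
        self.heads = {
            rid: TaskHead(spec.d, rid, seed=seed + 1 + i)
            for i, rid in enumerate(regions)
        }

    @property
    def regions(self) -> list[str]:
        return list(self.heads)

    def forward(self, batch: Tensor) -> tuple[dict[str, Tensor], dict[str, Tensor]]:
        """batch (N, 2, H, W, L) -> ({region: probs (N,)}, {region: alpha (N, V)})."""
        voxels = _encoding_to_voxels(self.encoder(batch))
        probs, alphas = {}, {}
        for rid, head in self.heads.items():
            probs[rid], alphas[rid] = head(voxels)
        return probs, alphas

    def predict_proba(self, volumes: Sequence[np.ndarray], batch_size: int = 4) -> np.ndarray:
        """(n_exams, T) prediction matrix, head order = self.regions."""
        out = np.zeros((len(volumes), len(self.heads)))
        with no_grad():
            for start in range(0, len(volumes), batch_size):
                chunk = volumes[start : start + batch_size]
                batch = Tensor(np.stack(chunk))
                probs, _ = self.forward(batch)
                for t, rid in enumerate(self.heads):
                    out[start : start + len(chunk), t] = probs[rid].data
        return out


@dataclass
class TrainConfig:
    """Training schedule; defaults follow the published protocol, while tests
    pass desk-scale overrides (fewer samples per epoch, larger lr)."""

    epochs: int = 15
    samples_per_epoch: int = 2000
    batch_size: int = 2
    lr: float = 1e-4
    anneal_every: int = 16
    augment: bool = True
    crop_size: int = 200
    brightness_max: float = 0.25
    seed: int = 0
    select_best_epoch: bool = False
    finetune_epochs: int = 5


def _mean_val_auroc(model: MultiTaskModel, volumes, labels: np.ndarray, threshold=0.5) -> float:
    preds = model.predict_proba(volumes)
    hard = (labels >= threshold).astype(int)
    scores = []
    for t in range(labels.shape[1]):
        if len(np.unique(hard[:, t])) < 2:
            continue
        scores.append(roc_auc_score(hard[:, t], preds[:, t]))
    return float(np.mean(scores)) if scores else float("nan")


def train_multitask(
    model: MultiTaskModel,
    volumes: Sequence[np.ndarray],
    labels: np.ndarray,
    config: Optional[TrainConfig] = None,
    val_volumes: Optional[Sequence[np.ndarray]] = None,
    val_labels: Optional[np.ndarray] = None,
) -> list[dict]:
    """Optimize Eq-style multi-task soft-target cross-entropy.

    `labels` is (n_exams, T) with columns ordered as model.regions; the
    probabilistic weak labels are used directly as soft targets. Returns
    per-epoch metrics (loss, lr, optional validation AUROC).
    """
    config = config or TrainConfig()
    if len(volumes) == 0:
        raise ValueError("empty dataset")
    labels = np.asarray(labels, dtype=np.float64)
    if labels.shape != (len(volumes), len(model.heads)):
        raise ValueError(
            f"labels shape {labels.shape} != (n_exams={len(volumes)}, T={len(model.heads)})"
        )
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    optimizer = Adam(params, lr=config.lr)
    history: list[dict] = []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        optimizer.lr = halved_lr(config.lr, epoch, config.anneal_every)
        order = rng.integers(0, len(volumes), size=config.samples_per_epoch)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            arrays = []
            for i in idx:
                vol = volumes[i]
                if config.augment:
                    vol = augment(
                        ScanVolume(vol), rng, config.crop_size, config.brightness_max
                    ).data
                arrays.append(vol)
            batch = Tensor(np.stack(arrays))
            optimizer.zero_grad()
            probs, _ = model.forward(batch)
            loss = multitask_loss(labels[idx], [probs[rid] for rid in model.heads])
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item()
            n_batches += 1
        record = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "lr": optimizer.lr}
        if val_volumes is not None and val_labels is not None:
            record["val_auroc"] = _mean_val_auroc(model, val_volumes, val_labels)
            if config.select_best_epoch and record["val_auroc"] > best[0]:
                best = (record["val_auroc"], model.state())
        history.append(record)
    if config.select_best_epoch and best[1] is not None:
        model.load_state(best[1])
    return history


def finetune_single_task(
    model: MultiTaskModel,
    region_id: str,
    volumes: Sequence[np.ndarray],
    labels: np.ndarray,
    config: Optional[TrainConfig] = None,
    val_volumes: Optional[Sequence[np.ndarray]] = None,
    val_labels: Optional[np.ndarray] = None,
    reinit_head: bool = True,
) -> tuple[MultiTaskModel, list[dict]]:
    """Fine-tune a single-task copy of the model on one region (or an
    external binary task such as mortality).

    The encoder starts from the multi-task parameters; the head is freshly
    initialized by default. All parameters are optimized. Parameters come
    from the epoch with the highest validation AUROC when a validation set
    is given.
    """
    config = config or TrainConfig()
    single = MultiTaskModel(model.spec, [region_id], seed=config.seed)
    # copy over the shared encoder, and optionally the matching head
    single.encoder.load_state(model.encoder.state())
    if not reinit_head and region_id in model.heads:
        single.heads[region_id].load_state(model.heads[region_id].state())
    ft_config = replace(
        config, epochs=config.finetune_epochs, select_best_epoch=val_volumes is not None
    )
    labels = np.asarray(labels, dtype=np.float64).reshape(len(volumes), 1)
    if val_labels is not None:
        val_labels = np.asarray(val_labels, dtype=np.float64).reshape(-1, 1)
    history = train_multitask(
        single, volumes, labels, ft_config, val_volumes, val_labels
    )
    return single, history
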