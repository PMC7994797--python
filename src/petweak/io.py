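"""Checkpoint and volume I/O helpers.

Checkpoints are NPZ archives holding a JSON metadata record (architecture
config and seed) plus the flat parameter list, so a model can be rebuilt
exactly and its parameters restored in construction order. Volumes load
from NPZ (keys ``pet`` / ``ct``) or a pair of NIfTI files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .report_labeler import ReportModelConfig, TokenClassifierHead, TrainedReportModel
from .report_labeler.model import TinySelfAttentionEncoder
from .scan_model import EncoderSpec, MultiTaskModel

__all__ = [
    "save_scan_model",
    "load_scan_model",
    "save_report_model",
    "load_report_model",
    "load_volume_npz",
    "load_volume_nifti",
]


def _save_params(path, meta: dict, params: list[np.ndarray]) -> None:
    arrays = {f"p{i}": p for i, p in enumerate(params)}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def _load_params(path) -> tuple[dict, list[np.ndarray]]:
    with np.load(path) as archive:
        meta = json.loads(str(archive["meta"]))
        params = [archive[f"p{i}"] for i in range(len(archive.files) - 1)]
    return meta, params


def save_scan_model(path: str | Path, model: MultiTaskModel) -> None:
    meta = {
        "kind": "scan_model",
        "seed": model.seed,
        "regions": model.regions,
        "spec": {
            "channels": list(model.spec.channels),
            "kernels": [list(k) for k in model.spec.kernels],
            "strides": [list(s) for s in model.spec.strides],
            "in_channels": model.spec.in_channels,
        },
    }
    _save_params(path, meta, model.state())


def load_scan_model(path: str | Path) -> MultiTaskModel:
    meta, params = _load_params(path)
    if meta.get("kind") != "scan_model":
        raise ValueError(f"{path} is not a scan-model checkpoint")
    spec = EncoderSpec(
        channels=tuple(meta["spec"]["channels"]),
        kernels=tuple(tuple(k) for k in meta["spec"]["kernels"]),
        strides=tuple(tuple(s) for s in meta["spec"]["strides"]),
        in_channels=meta["spec"]["in_channels"],
    )
    model = MultiTaskModel(spec, meta["regions"], seed=meta["seed"])
    model.load_state(params)
    return model


def save_report_model(
    path: str | Path, trained: TrainedReportModel, config: ReportModelConfig, vocab_size: int
) -> None:
    meta = {
        "kind": "report_model",
        "vocab_size": vocab_size,
        "config": vars(config),
    }
    params = trained.encoder.state() + trained.head.state()
    _save_params(path, meta, params)


def load_report_model(path: str | Path) -> TrainedReportModel:
    meta, params = _load_params(path)
    if meta.get("kind") != "report_model":
        raise ValueError(f"{path} is not a report-model checkpoint")
    config = ReportModelConfig(**meta["config"])
    encoder = TinySelfAttentionEncoder(
        vocab_size=meta["vocab_size"],
        hidden=config.hidden,
        ffn=config.ffn,
        n_blocks=config.n_blocks,
        max_len=config.max_len,
        seed=config.seed,
    )
    head = TokenClassifierHead(hidden_size=config.hidden, seed=config.seed + 1)
    n_enc = len(encoder.parameters())
    encoder.load_state(params[:n_enc])
    head.load_state(params[n_enc:])
    return TrainedReportModel(encoder=encoder, head=head)


def load_volume_npz(path: str | Path) -> np.ndarray:
    """(2, H, W, l) array from an NPZ with `pet` and `ct` arrays."""
    with np.load(path) as archive:
        return np.stack([archive["pet"], archive["ct"]], axis=0)


def load_volume_nifti(pet_path: str | Path, ct_path: str | Path) -> np.ndarray:
    import nibabel as nib

    pet = np.asarray(nib.load(str(pet_path)).dataobj, dtype=np.float64)
    ct = np.asarray(nib.load(str(ct_path)).dataobj, dtype=np.float64)
    return np.stack([pet, ct], axis=0)
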