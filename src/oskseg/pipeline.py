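"""End-to-end orchestration: NIfTI I/O, dictionary sampling, overlap metrics
and file-level runs.

Volumes are read and written with nibabel; phantoms written by the CLI and
real multimodal slices (e.g. BraTS exports) travel through the same
:func:`read_volume` path.  Evaluation reports Dice, positive predictive
value, sensitivity and Jaccard per lesion region (necrosis, enhancing
tumour, edema and the whole-tumour composite) from confusion counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import LabeledImage

__all__ = [
    "read_volume",
    "write_label_map",
    "write_feature_volume",
    "sample_training",
    "default_regions",
    "region_metrics",
    "evaluate",
    "EvaluationReport",
    "RunConfig",
    "run_segmentation",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# NIfTI I/O
# --------------------------------------------------------------------------- #

def _load(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _as_slice(data: np.ndarray, path) -> np.ndarray:
    """Squeeze a stored slice to (H, W) or (H, W, L)."""
    data = np.squeeze(np.asarray(data))
    if data.ndim not in (2, 3):
        raise ValueError(f"{path}: expected a 2-D slice, got shape {data.shape}")
    return data


def write_label_map(path: str | Path, label_image: np.ndarray,
                    affine: np.ndarray | None = None) -> None:
    """Write an integer label image as NIfTI (background 0)."""
    arr = np.asarray(label_image, dtype=np.int16)
    nib.save(nib.Nifti1Image(arr, np.eye(4) if affine is None else affine),
             str(path))


def write_feature_volume(path: str | Path, image: LabeledImage,
                         affine: np.ndarray | None = None) -> None:
    """Write all modalities of a slice as one (H, W, 1, L) NIfTI."""
    h, w = image.shape
    vol = np.zeros((h, w, 1, image.n_modalities), dtype=np.float32)
    for c in range(image.n_modalities):
        vol[:, :, 0, c] = image.channel_image(c)
    nib.save(nib.Nifti1Image(vol, np.eye(4) if affine is None else affine),
             str(path))


def read_volume(
    modality_paths: str | Path | Sequence[str | Path],
    label_path: str | Path | None = None,
    mask_path: str | Path | None = None,
) -> tuple[LabeledImage, np.ndarray]:
    """Load co-registered modality slices (and optional labels/mask).

    ``modality_paths`` may be a single multi-channel file or one file per
    modality.  All grids and affines must agree; a mismatch raises with the
    offending shapes/affines listed.  The brain mask comes from
    ``mask_path`` if given, else from nonzero labels, else from pixels
    nonzero in any modality.  Returns the in-mask :class:`LabeledImage` and
    the affine (preserved for round-trip writing).
    """
    if isinstance(modality_paths, (str, Path)):
        modality_paths = [modality_paths]
    channels: list[np.ndarray] = []
    affines: list[np.ndarray] = []
    shapes: list[tuple] = []
    for p in modality_paths:
        data, aff = _load(p)
        data = _as_slice(data, p)
        if data.ndim == 3:  # multi-channel file
            channels.extend(data[..., c] for c in range(data.shape[-1]))
        else:
            channels.append(data)
        affines.append(aff)
        shapes.append(channels[-1].shape)
    base = channels[0].shape
    if any(c.shape != base for c in channels) or any(
        not np.allclose(a, affines[0]) for a in affines
    ):
        raise ValueError(
            "modality grids/affines disagree: shapes="
            f"{[c.shape for c in channels]}, affines={affines}"
        )
    stack = np.stack(channels, axis=-1).astype(float)  # (H, W, L)

    labels_img = None
    if label_path is not None:
        labels_img, laff = _load(label_path)
        labels_img = _as_slice(labels_img, label_path)
        if labels_img.shape != base or not np.allclose(laff, affines[0]):
            raise ValueError(
                f"label grid mismatch: {labels_img.shape} vs {base}"
            )
        labels_img = labels_img.astype(np.int64)

    if mask_path is not None:
        mask, maff = _load(mask_path)
        mask = _as_slice(mask, mask_path).astype(bool)
        if mask.shape != base or not np.allclose(maff, affines[0]):
            raise ValueError(f"mask grid mismatch: {mask.shape} vs {base}")
    elif labels_img is not None:
        mask = labels_img > 0
    else:
        mask = np.any(stack != 0, axis=-1)

    features = stack[mask]
    labels = labels_img[mask] if labels_img is not None else None
    return LabeledImage(features=features, labels=labels, mask=mask), affines[0]


# --------------------------------------------------------------------------- #
# dictionary sampling
# --------------------------------------------------------------------------- #

def sample_training(
    labels: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified dictionary sampling: per class, round(fraction·N_c) atoms
    with a floor of one; the remaining pixels form the test set.

    Returns (train_idx, test_idx, atom_labels), all deterministic per seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"class {c} has no pixels")
        k = max(1, int(round(fraction * idx.size)))
        train.append(rng.choice(idx, size=k, replace=False))
    train_idx = np.sort(np.concatenate(train))
    test_mask = np.ones(labels.size, dtype=bool)
    test_mask[train_idx] = False
    test_idx = np.flatnonzero(test_mask)
    if test_idx.size == 0:
        raise ValueError("training fraction leaves no test pixels")
    return train_idx, test_idx, labels[train_idx]


# --------------------------------------------------------------------------- #
# evaluation
# --------------------------------------------------------------------------- #

def default_regions(labels: np.ndarray) -> dict[str, tuple[int, ...]]:
    """Region spec from the label vocabulary.

    With the standard four classes this is necrosis (4), enhanced (3),
    edema (2) and the whole-tumour composite (2, 3, 4); otherwise one region
    per non-background class.
    """
    classes = sorted(int(c) for c in np.unique(labels) if c > 0)
    if classes == [1, 2, 3, 4]:
        return {
            "necrosis": (4,),
            "enhanced": (3,),
            "edema": (2,),
            "whole_tumour": (2, 3, 4),
        }
    return {f"class_{c}": (c,) for c in classes}


def region_metrics(tp: int, fp: int, fn: int) -> dict[str, float]:
    """Dice, PPV, sensitivity and Jaccard from confusion counts.

    A region absent from both prediction and reference scores 1 in all
    metrics (perfect agreement on absence).
    """
    if tp + fp + fn == 0:
        return {"dice": 1.0, "ppv": 1.0, "sensitivity": 1.0, "jaccard": 1.0}
    dice = 2 * tp / (2 * tp + fp + fn)
    ppv = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    jacc = tp / (tp + fp + fn)
    return {"dice": dice, "ppv": ppv, "sensitivity": sens, "jaccard": jacc}


@dataclass
class EvaluationReport:
    """Per-region overlap metrics plus raw confusion counts."""

    per_region: dict[str, dict[str, float]]
    confusion: dict[str, dict[str, int]]
    accuracy: float
    n_pixels: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_region).T[
            ["dice", "ppv", "sensitivity", "jaccard"]
        ]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_pixels": self.n_pixels,
            "per_region": self.per_region,
            "confusion": self.confusion,
        }


def evaluate(
    pred: np.ndarray,
    ref: np.ndarray,
    regions: Mapping[str, Sequence[int]] | None = None,
) -> EvaluationReport:
    """Score a predicted labelling against the reference on the same pixels."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference must cover the same pixels")
    vocab = set(np.unique(ref).tolist())
    extra = set(np.unique(pred).tolist()) - vocab
    if extra:
        raise ValueError(f"predicted labels {sorted(extra)} not in reference "
                         f"vocabulary {sorted(vocab)}")
    if regions is None:
        regions = default_regions(ref)

    per_region: dict[str, dict[str, float]] = {}
    confusion: dict[str, dict[str, int]] = {}
    for name, classes in regions.items():
        classes = tuple(classes)
        p = np.isin(pred, classes)
        r = np.isin(ref, classes)
        tp = int(np.sum(p & r))
        fp = int(np.sum(p & ~r))
        fn = int(np.sum(~p & r))
        if tp + fp + fn == 0:
            logger.info("region %s absent in both; metrics defined as 1", name)
        per_region[name] = region_metrics(tp, fp, fn)
        confusion[name] = {"tp": tp, "fp": fp, "fn": fn}
    return EvaluationReport(
        per_region=per_region,
        confusion=confusion,
        accuracy=float(np.mean(pred == ref)),
        n_pixels=int(pred.size),
    )


# --------------------------------------------------------------------------- #
# file-level runs
# --------------------------------------------------------------------------- #

@dataclass
class RunConfig:
    """Paths plus method configuration for a file-level segmentation run."""

    modality_paths: list[str]
    label_path: str
    out_prefix: str
    mask_path: str | None = None
    segmentation: "SegmentationConfig | None" = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .model import SegmentationConfig

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        return cls(segmentation=seg, **raw)


def run_segmentation(config: RunConfig):
    """Read inputs, fit the model, write label map and reports.

    Writes ``<prefix>_labels.nii.gz``, ``<prefix>_superpixels.nii.gz``,
    ``<prefix>_report.json`` and ``<prefix>_convergence.csv``; returns the
    :class:`~oskseg.model.SegmentationResults`.
    """
    from .model import OskKlrrSr, SegmentationConfig

    image, affine = read_volume(config.modality_paths, config.label_path,
                                config.mask_path)
    seg_cfg = config.segmentation or SegmentationConfig()
    model = OskKlrrSr(image, seg_cfg)
    results = model.fit()

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_label_map(f"{prefix}_labels.nii.gz", results.label_image(), affine)
    write_label_map(f"{prefix}_superpixels.nii.gz",
                    results.superpixel_image() + 1, affine)
    payload = results.report.to_dict()
    payload["mkl_weights"] = results.mkl_weights.tolist()
    payload["admm_converged"] = bool(results.admm.converged)
    payload["admm_iterations"] = int(results.admm.n_iter)
    payload["timings"] = results.model.timings_
    with open(f"{prefix}_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    results.convergence.to_csv(f"{prefix}_convergence.csv", index=False)
    logger.info("segmentation written to %s_*", prefix)
    return results
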