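"""Synthetic multimodal brain-tumour phantoms and toy classification fixtures.

The phantom emulates a single skull-stripped, co-registered multimodal MR
slice: an elliptical brain mask containing nested lesion compartments
(edema ⊃ enhancing tumour ⊃ necrotic core) over normal-appearing tissue.
Each tissue class has a characteristic mean intensity per modality
(T1, T1-c, T2, FLAIR by convention), corrupted by a smooth multiplicative
bias field and additive Gaussian noise — the two artefacts that make
intensity-only pixel classifiers fail on real MR data.

Pixels are flattened row-major over the 2-D grid; the in-mask subset is
indexed ``0..N-1`` in that order, and every downstream module works on that
in-mask ordering only (background never leaves this module).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "LabeledImage",
    "ToyProblem",
    "generate_phantom",
    "toy_problem",
    "DEFAULT_CLASS_MEANS",
    "CLASS_NAMES",
]

#: tissue classes, in label order 1..4 (0 is background)
CLASS_NAMES = ("normal", "edema", "enhanced", "necrosis")

#: per-class mean intensity in each modality (rows: normal, edema, enhanced,
#: necrosis; columns: T1, T1-c, T2, FLAIR), arbitrary units in [0, 1].
#: Chosen to mimic the usual contrast pattern of glioma imaging: edema bright
#: on T2/FLAIR, enhancing rim bright on post-contrast T1, necrotic core dark
#: on T1-c and intermediate on T2.
DEFAULT_CLASS_MEANS = np.array(
    [
        [0.50, 0.45, 0.40, 0.35],  # normal-appearing tissue
        [0.40, 0.35, 0.70, 0.75],  # edema
        [0.45, 0.80, 0.55, 0.60],  # enhancing tumour
        [0.25, 0.15, 0.65, 0.45],  # necrotic core
    ]
)


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (row, col centre; semi-axes)."""

    cy: float
    cx: float
    ry: float
    rx: float

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        return ((yy - self.cy) / self.ry) ** 2 + ((xx - self.cx) / self.rx) ** 2 <= 1.0


def _default_layout(height: int, width: int) -> tuple[Ellipse, ...]:
    """Nested brain ⊃ edema ⊃ enhancing ⊃ necrosis layout scaled to the grid."""
    h, w = float(height), float(width)
    return (
        Ellipse(0.50 * h, 0.50 * w, 0.44 * h, 0.41 * w),   # brain mask
        Ellipse(0.56 * h, 0.53 * w, 0.22 * h, 0.19 * w),   # edema
        Ellipse(0.59 * h, 0.56 * w, 0.14 * h, 0.125 * w),  # enhancing tumour
        Ellipse(0.59 * h, 0.56 * w, 0.08 * h, 0.06 * w),   # necrotic core
    )


@dataclass
class PhantomSpec:
    """Full description of a synthetic slice; ``generate_phantom`` realises it.

    Parameters
    ----------
    height, width : int
        Grid size in pixels (at least 8 each).
    n_modalities : int
        Number of co-registered channels (columns of ``class_means``).
    class_means : ndarray, shape (n_classes, n_modalities)
        Mean intensity of each tissue class in each modality, in [0, 1].
    noise_sigma : float
        Standard deviation of the additive Gaussian noise.
    bias_amplitude : float
        Maximum magnitude of the log bias field; the multiplicative field is
        ``exp(s)`` with a smooth random ``s`` scaled to ``±bias_amplitude``,
        so its mean is ≈ 1. One independent field per modality.
    seed : int
        RNG seed; outputs are bit-identical for equal specs and seeds.
    layout : sequence of Ellipse
        Nested regions, outermost (brain mask) first. Region k is assigned
        class k, the innermost region winning where they overlap.
    """

    height: int = 64
    width: int = 64
    n_modalities: int = 4
    class_means: np.ndarray = field(default_factory=lambda: DEFAULT_CLASS_MEANS.copy())
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.1
    seed: int = 0
    layout: Sequence[Ellipse] | None = None

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        if self.layout is None:
            self.layout = _default_layout(self.height, self.width)
        self.validate()

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom grid must be at least 8x8")
        if self.class_means.ndim != 2 or self.class_means.shape[1] != self.n_modalities:
            raise ValueError(
                f"class_means must be (n_classes, {self.n_modalities}), "
                f"got {self.class_means.shape}"
            )
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")
        if len(self.layout) != self.n_classes:
            raise ValueError("layout must provide one region per class")
        # class means must be distinguishable in at least one modality
        for a in range(self.n_classes):
            for b in range(a + 1, self.n_classes):
                if np.allclose(self.class_means[a], self.class_means[b]):
                    raise ValueError(f"classes {a} and {b} have identical means")
        # nesting: every inner region must lie inside its parent
        masks = [e.mask(self.height, self.width) for e in self.layout]
        for k in range(1, len(masks)):
            if not masks[k].any():
                raise ValueError(f"layout region {k} is empty on this grid")
            if (masks[k] & ~masks[k - 1]).any():
                raise ValueError(
                    f"layout region {k} is not nested inside region {k - 1}"
                )


@dataclass
class LabeledImage:
    """In-mask feature matrix with per-pixel class labels and 2-D geometry.

    ``features`` has one row per in-mask pixel (row-major grid order) and one
    column per modality; ``labels`` holds the class of each in-mask pixel in
    ``1..C``. Background pixels exist only in ``mask`` and never reach the
    feature matrix.
    """

    features: np.ndarray            # (N, L)
    labels: np.ndarray | None       # (N,) in 1..C, or None if unlabelled
    mask: np.ndarray                # (H, W) bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        if self.features.shape[0] != int(self.mask.sum()):
            raise ValueError("feature rows must match in-mask pixel count")
        if self.labels is not None and self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must be one per in-mask pixel")

    @property
    def n_pixels(self) -> int:
        return self.features.shape[0]

    @property
    def n_modalities(self) -> int:
        return self.features.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def label_image(self, values: np.ndarray | None = None) -> np.ndarray:
        """Paint per-pixel values (default: the labels) onto the full grid.

        Background is 0.
        """
        vals = self.labels if values is None else np.asarray(values)
        out = np.zeros(self.mask.shape, dtype=vals.dtype)
        out[self.mask] = vals
        return out

    def channel_image(self, channel: int) -> np.ndarray:
        """One modality painted on the full grid (background 0)."""
        out = np.zeros(self.mask.shape, dtype=float)
        out[self.mask] = self.features[:, channel]
        return out


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  amplitude: float) -> np.ndarray:
    """Zero-mean smooth random field scaled to max |value| = amplitude."""
    if amplitude == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=min(shape) / 8.0, mode="nearest")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    if peak == 0:  # degenerate but possible on tiny grids
        return np.zeros(shape)
    return smooth * (amplitude / peak)


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Realise a :class:`PhantomSpec` into a labelled multimodal slice.

    The clean image assigns every in-mask pixel its class-mean vector; each
    modality is then multiplied by ``exp(smooth field)`` and perturbed with
    i.i.d. Gaussian noise. With ``noise_sigma = 0`` and ``bias_amplitude = 0``
    the features equal the class means exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    masks = [e.mask(h, w) for e in spec.layout]
    label_img = np.zeros((h, w), dtype=np.int64)
    for k, m in enumerate(masks):  # innermost region painted last, wins
        label_img[m] = k + 1
    brain = masks[0]

    labels = label_img[brain]
    clean = spec.class_means[labels - 1]  # (N, L)

    features = np.empty_like(clean)
    for c in range(spec.n_modalities):
        bias = np.exp(_smooth_field(rng, (h, w), spec.bias_amplitude))
        chan = clean[:, c] * bias[brain]
        if spec.noise_sigma > 0:
            chan = chan + rng.normal(0.0, spec.noise_sigma, size=chan.shape)
        features[:, c] = chan

    return LabeledImage(features=features, labels=labels, mask=brain)


class ToyProblem(NamedTuple):
    """Gaussian-cluster fixture for solver and classifier tests."""

    dictionary: np.ndarray    # (T, dim) training samples
    dict_labels: np.ndarray   # (T,) in 1..n_classes
    test: np.ndarray          # (n_test, dim)
    test_labels: np.ndarray   # (n_test,)
    centroids: np.ndarray     # (n_classes, dim)


def toy_problem(
    seed: int,
    n_test: int,
    n_train_per_class: int,
    n_classes: int,
    dim: int,
    separation: float = 6.0,
    noise: float = 0.5,
) -> ToyProblem:
    """Well-conditioned Gaussian clusters with per-class centroids.

    Centroids are drawn isotropically and rescaled so the minimum pairwise
    centroid distance equals ``separation``; samples are centroid + N(0, noise²).
    Deterministic per seed.
    """
    if min(n_test, n_train_per_class, n_classes, dim) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_classes, dim))
    if n_classes > 1:
        d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
        dmin = d[~np.eye(n_classes, dtype=bool)].min()
        if dmin == 0:
            raise ValueError("degenerate centroid draw")  # pragma: no cover
        centroids *= separation / dmin

    dict_labels = np.repeat(np.arange(1, n_classes + 1), n_train_per_class)
    dictionary = centroids[dict_labels - 1] + noise * rng.standard_normal(
        (dict_labels.size, dim)
    )
    test_labels = np.arange(n_test) % n_classes + 1
    test = centroids[test_labels - 1] + noise * rng.standard_normal((n_test, dim))
    return ToyProblem(dictionary, dict_labels, test, test_labels, centroids)
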