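"""Synthetic 3-class brain-MRI-like images and the preprocessing pipeline.

The generator emulates axial-slice structure at cartoon level: a bright
annulus ("cortical ribbon") whose thickness differs by class, enclosing
a dark interior cavity ("ventricle") whose area scales by class, over a
dark background, with per-sample geometric jitter and additive Gaussian
texture noise.  Class 0 (AD-like) has the thinnest ribbon and largest
cavity, class 1 (CI-like) is intermediate, class 2 (CN-like) has the
thickest ribbon and smallest cavity — so a localized, spatially coherent
discriminative region (the cavity/ribbon geometry) exists for the
attention gate and the LIME explainer to find.

The preprocessing ops mirror a standard imaging pipeline: random
horizontal/vertical flip augmentation, oversampling to balance classes,
[0,1] pixel normalization, and stratified train/validation/test
splitting (default 85/15 with 15% of train as validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import TensorBatch

__all__ = [
    "SyntheticSpec",
    "DatasetSplits",
    "generate",
    "augment_flips",
    "balance_by_oversampling",
    "normalize_pixels",
    "split",
    "stratified_indices",
    "CLASS_NAMES",
]

CLASS_NAMES = ("AD", "CI", "CN")

# (ring thickness in units of outer radius, cavity radius fraction)
_DEFAULT_SIGNATURES = (
    {"ring_thickness": 0.10, "cavity_scale": 0.45},  # AD-like
    {"ring_thickness": 0.18, "cavity_scale": 0.30},  # CI-like
    {"ring_thickness": 0.28, "cavity_scale": 0.15},  # CN-like
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    ``noise_sd`` is the standard deviation of the additive Gaussian
    texture noise on the [0,1] intensity scale; ``jitter`` is the
    standard deviation, in pixels, of the per-sample center offset and
    radius perturbation.  With both at 0, images within a class are
    bit-identical.
    """

    n_per_class: int = 300
    image_shape: tuple[int, int, int] = (64, 64, 1)
    class_signatures: tuple = _DEFAULT_SIGNATURES
    noise_sd: float = 0.05
    jitter: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        h, w, c = self.image_shape
        if h < 16 or w < 16:
            raise ValueError(f"image spatial dims must be >= 16, got {self.image_shape}")
        if self.noise_sd < 0 or self.jitter < 0:
            raise ValueError("noise_sd and jitter must be >= 0")
        sigs = [tuple(sorted(s.items())) for s in self.class_signatures]
        if len(set(sigs)) != len(sigs):
            raise ValueError("class signatures must be pairwise distinct")


def _render(shape, signature, center, outer_r, rng, noise_sd) -> np.ndarray:
    h, w, c = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - center[0], xx - center[1])
    inner_r = outer_r * (1.0 - signature["ring_thickness"])
    cavity_r = outer_r * signature["cavity_scale"]
    img = np.full((h, w), 0.05)
    img[r <= outer_r] = 0.45            # parenchyma
    img[(r <= outer_r) & (r > inner_r)] = 0.9   # bright cortical ribbon
    img[r <= cavity_r] = 0.12           # dark ventricular cavity
    img = np.repeat(img[:, :, None], c, axis=2)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate(spec: SyntheticSpec) -> TensorBatch:
    """Seeded, reproducible balanced 3-class image batch."""
    rng = np.random.default_rng(spec.seed)
    h, w, c = spec.image_shape
    base_r = 0.38 * min(h, w)
    images, labels = [], []
    for cls, sig in enumerate(spec.class_signatures):
        for _ in range(spec.n_per_class):
            if spec.jitter > 0:
                center = (h / 2 + rng.normal(0, spec.jitter),
                          w / 2 + rng.normal(0, spec.jitter))
                outer_r = base_r + rng.normal(0, spec.jitter)
            else:
                center = (h / 2, w / 2)
                outer_r = base_r
            images.append(_render(spec.image_shape, sig, center, outer_r,
                                  rng, spec.noise_sd))
            labels.append(cls)
    return TensorBatch(np.stack(images), np.asarray(labels, dtype=np.int64))


def augment_flips(x: TensorBatch, seed: int = 0) -> TensorBatch:
    """Flip every sample horizontally, vertically, or both (uniform choice).

    Labels are preserved; flipping is an involution per axis, so pixel
    histograms are unchanged.
    """
    rng = np.random.default_rng(seed)
    modes = rng.integers(0, 3, size=x.n)  # 0: horizontal, 1: vertical, 2: both
    out = x.values.copy()
    out[modes != 1] = out[modes != 1][:, :, ::-1]   # horizontal (and both)
    out[modes != 0] = out[modes != 0][:, ::-1, :]   # vertical (and both)
    labels = None if x.labels is None else x.labels.copy()
    return TensorBatch(out, labels)


def balance_by_oversampling(
    x: TensorBatch, target_per_class: int, seed: int = 0,
    num_classes: int | None = None,
) -> TensorBatch:
    """Equalize class counts at ``target_per_class``.

    Under-represented classes are topped up with flip-augmented copies
    of randomly chosen members; over-represented classes are subsampled
    without replacement.  ``num_classes`` defaults to ``max(label) + 1``;
    a class with no members is an error.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    if x.labels is None:
        raise ValueError("labels required for balancing")
    if num_classes is None:
        num_classes = int(x.labels.max()) + 1
    rng = np.random.default_rng(seed)
    chunks_v, chunks_l = [], []
    for cls in range(num_classes):
        idx = np.flatnonzero(x.labels == cls)
        if len(idx) == 0:
            raise ValueError(f"class {cls} is empty")
        if len(idx) >= target_per_class:
            keep = rng.choice(idx, size=target_per_class, replace=False)
            chunks_v.append(x.values[keep])
            chunks_l.append(x.labels[keep])
        else:
            chunks_v.append(x.values[idx])
            chunks_l.append(x.labels[idx])
            extra = rng.choice(idx, size=target_per_class - len(idx), replace=True)
            aug = augment_flips(x.subset(extra), seed=int(rng.integers(2**31)))
            chunks_v.append(aug.values)
            chunks_l.append(aug.labels)
    return TensorBatch(np.concatenate(chunks_v), np.concatenate(chunks_l))


def normalize_pixels(x: TensorBatch) -> TensorBatch:
    """Scale pixel values into [0, 1].

    8-bit inputs are detected by max > 1.5 and divided by 255; inputs
    already in [0, 1] pass through.  Negative values are rejected.
    """
    v = x.values
    if v.min() < 0:
        raise ValueError("negative pixel values cannot be normalized")
    if v.max() > 1.5:
        v = v / 255.0
        if v.max() > 1.0:
            raise ValueError("pixel values exceed 255 on the 8-bit scale")
    return TensorBatch(v, x.labels)


@dataclass
class DatasetSplits:
    """Disjoint stratified train/validation/test batches."""

    train: TensorBatch
    validation: TensorBatch
    test: TensorBatch
    test_frac: float = 0.15
    val_frac_of_train: float = 0.15


def stratified_indices(labels, frac, rng) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (rest, held-out) with per-class round(frac*n)."""
    labels = np.asarray(labels)
    rest, held = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        k = int(np.floor(frac * len(idx) + 0.5))  # round half up, per class
        if k < 1 or k >= len(idx):
            raise ValueError(
                f"class {cls} has {len(idx)} samples — too few to hold out "
                f"a fraction of {frac}")
        held.append(idx[:k])
        rest.append(idx[k:])
    return np.concatenate(rest), np.concatenate(held)


def split(
    x: TensorBatch,
    test_frac: float = 0.15,
    val_frac_of_train: float = 0.15,
    seed: int = 0,
) -> DatasetSplits:
    """Stratified train/validation/test split.

    Per class, ``round(test_frac * n)`` samples go to the test set, and
    ``round(val_frac_of_train * n_remaining)`` of the remainder to
    validation (round = half up, computed per class before pooling).
    Every sample lands in exactly one split.
    """
    if x.labels is None:
        raise ValueError("labels required for stratified splitting")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = stratified_indices(x.labels, test_frac, rng)
    rest_labels = x.labels[train_idx]
    rest_pos, val_pos = stratified_indices(rest_labels, val_frac_of_train, rng)
    return DatasetSplits(
        train=x.subset(train_idx[rest_pos]),
        validation=x.subset(train_idx[val_pos]),
        test=x.subset(test_idx),
        test_frac=test_frac,
        val_frac_of_train=val_frac_of_train,
    )
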