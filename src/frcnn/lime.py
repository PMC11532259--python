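"""Perturbation-based local explanations of an image classifier.

The procedure follows the standard LIME recipe: partition the instance
into segments, generate a perturbed dataset by switching random subsets
of segments off (replacing them with a baseline color), collect the
model's class probabilities on every perturbed image, and fit a locally
weighted linear surrogate (ridge regression on the binary on/off masks,
samples weighted by an exponential kernel on the cosine distance to the
unperturbed instance).  The surrogate's coefficients rank segments by
their contribution to the explained class; the top-k positive segments
form the highlight mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import Ridge

__all__ = [
    "SegmentMap",
    "PerturbationSet",
    "ExplanationResult",
    "LimeImageExplainer",
    "segment",
    "perturb",
    "fit_surrogate",
    "explain",
]


@dataclass
class SegmentMap:
    """Integer segment id per pixel; ids contiguous 0..n_segments-1."""

    labels: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.n_segments)):
            raise ValueError("segment ids must be contiguous 0..n_segments-1")


@dataclass
class PerturbationSet:
    """Binary segment masks, model probabilities, and locality weights."""

    masks: np.ndarray        # (n_samples, n_segments), {0,1}
    probabilities: np.ndarray | None = None   # explained-class prob per row
    weights: np.ndarray | None = None


@dataclass
class ExplanationResult:
    """Per-segment surrogate coefficients and the top-k highlight mask."""

    coefficients: np.ndarray
    top_segments: np.ndarray
    highlight_mask: np.ndarray
    fidelity: float
    explained_class: int
    segments: SegmentMap = field(repr=False, default=None)


def segment(image: np.ndarray, grid: int = 8) -> SegmentMap:
    """Deterministic partition into a grid of ``grid x grid`` blocks.

    Blocks are ``floor(H/grid) x floor(W/grid)``; the last row/column of
    blocks absorbs any remainder pixels, so every pixel gets exactly one
    id and ids are contiguous.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < grid or w < grid:
        raise ValueError(f"image ({h}x{w}) smaller than segmentation grid {grid}")
    bh, bw = h // grid, w // grid
    rows = np.minimum(np.arange(h) // bh, grid - 1)
    cols = np.minimum(np.arange(w) // bw, grid - 1)
    labels = rows[:, None] * grid + cols[None, :]
    return SegmentMap(labels, grid * grid)


def perturb(
    image: np.ndarray,
    segments: SegmentMap,
    n_samples: int = 1000,
    seed: int = 0,
    baseline=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Bernoulli(0.5) segment masks and the perturbed images.

    Returns ``(masks, images)``; the first mask row is all-ones and
    reconstructs the original instance exactly.  Segments switched off
    are replaced by ``baseline`` (default: the image mean color).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    image = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    masks = rng.integers(0, 2, size=(n_samples, segments.n_segments))
    masks[0] = 1
    if baseline is None:
        baseline = image.mean(axis=(0, 1))  # mean color per channel
    baseline = np.broadcast_to(np.asarray(baseline, dtype=np.float64), image.shape)
    keep = masks[:, segments.labels]           # (n_samples, H, W)
    if image.ndim == 3:
        keep = keep[..., None]
    images = np.where(keep.astype(bool), image, baseline)
    return masks, images


def fit_surrogate(
    pset: PerturbationSet, kernel_width: float = 0.25,
    ridge_alpha: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Locally weighted ridge fit of class probability on segment masks.

    Sample weight is ``exp(-d^2 / kernel_width^2)`` with ``d`` the cosine
    distance between the mask row and the all-ones row; weights are
    normalized to sum to 1 so the fit is invariant to duplicating
    samples.  Returns the coefficient vector and the weighted R^2 as
    local fidelity; a model constant over the perturbation set has no
    explainable variance and reports fidelity 0 by convention.
    """
    masks = np.asarray(pset.masks, dtype=np.float64)
    y = np.asarray(pset.probabilities, dtype=np.float64)
    if len(np.unique(masks, axis=0)) < 2:
        raise np.linalg.LinAlgError("degenerate perturbation design: all rows equal")
    ones = np.ones((1, masks.shape[1]))
    d = cdist(masks, ones, metric="cosine").ravel()
    d = np.nan_to_num(d, nan=1.0)  # the all-zeros mask is maximally distant
    weights = np.exp(-(d**2) / kernel_width**2)
    weights = weights / weights.sum()
    pset.weights = weights
    if np.ptp(y) == 0.0:
        return np.zeros(masks.shape[1]), 0.0
    model = Ridge(alpha=ridge_alpha)
    model.fit(masks, y, sample_weight=weights)
    fidelity = float(max(model.score(masks, y, sample_weight=weights), 0.0))
    return model.coef_, fidelity


def _predict_proba(model, images: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(images))
    return np.asarray(model(images))


def explain(
    image: np.ndarray,
    model,
    k: int = 5,
    n_samples: int = 1000,
    seed: int = 0,
    grid: int = 8,
    kernel_width: float = 0.25,
    baseline=None,
    explained_class: int | None = None,
) -> ExplanationResult:
    """End-to-end explanation of one instance.

    ``model`` is either a callable mapping an image batch (n, H, W, C)
    to class probabilities or an estimator exposing ``predict_proba``.
    The explained class defaults to the model's prediction on the
    unperturbed instance.  Deterministic given the seed.
    """
    image = np.asarray(image)
    segs = segment(image, grid=grid)
    masks, pert_images = perturb(image, segs, n_samples=n_samples, seed=seed,
                                 baseline=baseline)
    probs = _predict_proba(model, pert_images)
    if explained_class is None:
        explained_class = int(np.argmax(probs[0]))  # all-ones row = original
    pset = PerturbationSet(masks, probs[:, explained_class])
    coefs, fidelity = fit_surrogate(pset, kernel_width=kernel_width)
    positive = np.flatnonzero(coefs > 0)
    order = positive[np.argsort(-coefs[positive], kind="stable")]
    top = order[:k]
    mask = np.isin(segs.labels, top)
    return ExplanationResult(
        coefficients=coefs,
        top_segments=top,
        highlight_mask=mask,
        fidelity=fidelity,
        explained_class=explained_class,
        segments=segs,
    )


class LimeImageExplainer:
    """Configured explainer: ``LimeImageExplainer(k=5).explain(image, model)``."""

    def __init__(self, k: int = 5, n_samples: int = 1000, grid: int = 8,
                 kernel_width: float = 0.25, baseline=None, seed: int = 0):
        self.k = k
        self.n_samples = n_samples
        self.grid = grid
        self.kernel_width = kernel_width
        self.baseline = baseline
        self.seed = seed

    def explain(self, image, model, explained_class=None) -> ExplanationResult:
        return explain(image, model, k=self.k, n_samples=self.n_samples,
                       seed=self.seed, grid=self.grid,
                       kernel_width=self.kernel_width, baseline=self.baseline,
                       explained_class=explained_class)
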