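"""Template selection for conventional stain normalization.

A template is the single reference patch whose stain statistics every source
image is mapped onto. Rather than picking one subjectively, the dataset's
average image is formed and five strategies score each candidate against it:

- T1: cosine similarity between the average image and the candidate;
- T2: cosine similarity between constant images filled with their dominant
  colors;
- T3: minimum mean squared error against the average image;
- T4: maximum global structural similarity (SSIM) against the average image;
- T5: MSE (equivalently SSIM) between the constant dominant-color images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.transform import resize

from .image_core import as_rgb_image

__all__ = [
    "AverageImage",
    "DominantColor",
    "TemplateReport",
    "average_image",
    "dominant_color",
    "cosine_similarity",
    "mse",
    "ssim_global",
    "select_template",
]

STRATEGIES = ("T1", "T2", "T3", "T4", "T5")

# Eq-style stability constants of the global SSIM, on the 8-bit dynamic range.
_SSIM_C1 = (0.01 * 255.0) ** 2
_SSIM_C2 = (0.03 * 255.0) ** 2


@dataclass
class AverageImage:
    """Element-wise mean of an image stack (float-valued, in [0, 255])."""

    pixels: np.ndarray
    n_source: int


@dataclass
class DominantColor:
    """Most frequent exact 24-bit RGB triple of an image."""

    rgb: tuple[int, int, int]
    count: int


@dataclass
class TemplateReport:
    strategy: str
    winner: str
    score: float
    scores: Mapping[str, float] = field(default_factory=dict)


def average_image(images: Iterable[np.ndarray]) -> AverageImage:
    """Mean image of a stack, accumulated in float64 so arbitrarily many
    8-bit patches can be averaged without overflow.

    All images must share one H×W×3 shape.
    """
    total = None
    shape = None
    n = 0
    for img in images:
        arr = as_rgb_image(img).astype(np.float64)
        if total is None:
            shape = arr.shape
            total = np.zeros(shape, dtype=np.float64)
        elif arr.shape != shape:
            raise ValueError(
                f"image {n} has shape {arr.shape}, expected {shape}"
            )
        total += arr
        n += 1
    if n == 0:
        raise ValueError("average_image requires at least one image")
    return AverageImage(pixels=total / n, n_source=n)


def dominant_color(img: np.ndarray | AverageImage) -> DominantColor:
    """Argmax over exact RGB triples of the occurrence count.

    Real-valued inputs (e.g. an average image) are rounded half away from
    zero to 8-bit first; count ties break to the lexicographically smallest
    triple.
    """
    if isinstance(img, AverageImage):
        arr = img.pixels
    else:
        arr = img
    arr = as_rgb_image(arr)
    # pack to 24-bit codes: lexicographic order on (r, g, b) == numeric order
    codes = (
        arr[..., 0].astype(np.int64) << 16
    ) | (arr[..., 1].astype(np.int64) << 8) | arr[..., 2].astype(np.int64)
    values, counts = np.unique(codes, return_counts=True)
    best = values[counts == counts.max()].min()
    r, g, b = (best >> 16) & 255, (best >> 8) & 255, best & 255
    return DominantColor(rgb=(int(r), int(g), int(b)), count=int(counts.max()))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """``Σ aᵢbᵢ / (‖a‖ ‖b‖)`` on flattened pixel vectors (scale-invariant)."""
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.size != bv.size:
        raise ValueError(f"length mismatch: {av.size} vs {bv.size}")
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine similarity of a zero vector defined as 0", stacklevel=2)
        return 0.0
    return float(av @ bv / (na * nb))


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error over all pixel-channel entries."""
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.shape != bb.shape:
        raise ValueError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    return float(np.mean((aa - bb) ** 2))


def ssim_global(a: np.ndarray, b: np.ndarray) -> float:
    """Single global-statistics SSIM (no sliding window).

    Means, variances and the covariance are taken over each whole channel
    plane, the SSIM formula is evaluated once per channel with
    C1 = (0.01·255)², C2 = (0.03·255)², and the three channel values are
    averaged.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.shape != bb.shape:
        raise ValueError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    if aa.ndim == 2:
        aa = aa[..., None]
        bb = bb[..., None]
    vals = []
    for c in range(aa.shape[-1]):
        x, y = aa[..., c].ravel(), bb[..., c].ravel()
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        vals.append(
            ((2 * mx * my + _SSIM_C1) * (2 * cov + _SSIM_C2))
            / ((mx**2 + my**2 + _SSIM_C1) * (vx + vy + _SSIM_C2))
        )
    return float(np.mean(vals))


def _constant_image(shape: tuple[int, ...], rgb: Sequence[int]) -> np.ndarray:
    out = np.empty(shape, dtype=np.uint8)
    out[...] = np.asarray(rgb, dtype=np.uint8)
    return out


def _match_shape(img: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    arr = as_rgb_image(img)
    if arr.shape == shape:
        return arr
    resized = resize(arr.astype(float), shape, order=1, preserve_range=True, anti_aliasing=False)
    return as_rgb_image(resized)


def select_template(
    candidates: Sequence[tuple[str, np.ndarray]],
    avg: AverageImage,
    strategy: str,
) -> TemplateReport:
    """Score every candidate against the dataset average under one of the
    five strategies and report the winner with all per-candidate scores.

    Candidates whose shape differs from the average image are bilinearly
    resized to it before scoring. Ties resolve to the first candidate in the
    given order, so the result is deterministic for a fixed ordering.
    """
    strategy = strategy.upper()
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if len(candidates) == 0:
        raise ValueError("no candidates given")

    avg_pixels = avg.pixels
    shape = avg_pixels.shape
    avg_dom = dominant_color(avg) if strategy in ("T2", "T5") else None

    scores: dict[str, float] = {}
    for ident, img in candidates:
        arr = _match_shape(img, shape)
        if strategy == "T1":
            scores[ident] = cosine_similarity(avg_pixels, arr)
        elif strategy == "T2":
            cand_dom = dominant_color(arr)
            scores[ident] = cosine_similarity(
                _constant_image(shape, avg_dom.rgb), _constant_image(shape, cand_dom.rgb)
            )
        elif strategy == "T3":
            scores[ident] = mse(avg_pixels, arr)
        elif strategy == "T4":
            scores[ident] = ssim_global(avg_pixels, arr)
        else:  # T5
            cand_dom = dominant_color(arr)
            scores[ident] = mse(
                _constant_image(shape, avg_dom.rgb), _constant_image(shape, cand_dom.rgb)
            )

    minimize = strategy in ("T3", "T5")
    ids = list(scores)
    vals = np.array([scores[i] for i in ids])
    idx = int(np.argmin(vals)) if minimize else int(np.argmax(vals))
    return TemplateReport(strategy=strategy, winner=ids[idx], score=float(vals[idx]), scores=scores)
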