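"""Image I/O, value-range handling and the color-space conversions
(RGB ↔ lαβ, RGB ↔ optical density) that every stain normalizer builds on.

All public contracts are stated on the 8-bit 0–255 integer scale; floats are
used internally. Optical density follows the Beer–Lambert law,
``OD = -log(I / I_max)``, in which stains combine linearly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "EPSILON",
    "LabImage",
    "ODImage",
    "read_image",
    "write_image",
    "as_rgb_image",
    "rgb_to_lab",
    "lab_to_rgb",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_background_intensity",
]

#: Guard for zero intensities before taking logarithms (one 8-bit level on the
#: unit scale).
EPSILON = 1.0 / 255.0

# Ruderman et al. RGB -> LMS cone-response matrix, the variant used by the
# original Reinhard color transfer.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)

# Fixed orthogonal log-LMS -> lαβ rotation (decorrelates the channels).
_LMS2LAB = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)]) @ np.array(
    [[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]]
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)


@dataclass
class LabImage:
    """Ruderman lαβ representation: ``l`` achromatic, ``alpha`` blue–yellow,
    ``beta`` green–red. Planes share the source image's H×W shape."""

    l: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.l, self.alpha, self.beta], axis=-1)


@dataclass
class ODImage:
    """Optical-density image.

    Parameters
    ----------
    od : (H, W, 3) float array, ≥ 0 up to numerical epsilon.
    log_base : 10.0 or ``numpy.e`` — which logarithm produced the values.
    i_max : per-channel background intensity in (0, 255], scalar or length-3.
    """

    od: np.ndarray
    log_base: float = 10.0
    i_max: np.ndarray = field(default_factory=lambda: np.array(255.0))

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        self.i_max = np.asarray(self.i_max, dtype=float)
        if self.log_base not in (10.0, np.e):
            raise ValueError("log_base must be 10 or e")


def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce ``arr`` to an H×W×3 uint8 RGB image."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[-1] not in (3, 4):
        raise ValueError(f"expected H×W×3 image, got shape {a.shape}")
    if a.shape[-1] == 4:
        a = a[..., :3]
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError("image must have H, W >= 1")
    if np.issubdtype(a.dtype, np.floating):
        a = _quantize(a)
    if a.min() < 0 or a.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return a.astype(np.uint8)


def _quantize(x: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero to uint8."""
    x = np.clip(x, 0.0, 255.0)
    return np.floor(x + 0.5).astype(np.uint8)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an H×W×3 uint8 array.

    Grayscale inputs are broadcast to three channels; an alpha channel is
    dropped.
    """
    try:
        with Image.open(path) as im:
            im.load()
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises several unrelated types
        raise IOError(f"could not read image file {os.fspath(path)!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {os.fspath(path)!r}")
    return arr


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB image to ``path`` (format from the extension; PNG and TIFF
    are lossless)."""
    arr = as_rgb_image(img)
    try:
        Image.fromarray(arr, mode="RGB").save(path)
    except (FileNotFoundError, OSError) as exc:
        raise IOError(f"could not write image file {os.fspath(path)!r}: {exc}") from exc


def rgb_to_lab(img: np.ndarray) -> LabImage:
    """Convert RGB to Ruderman lαβ via RGB → LMS → log10 LMS → lαβ.

    Zero channels are floored at ε = 1/255 before the logarithm, so pure black
    maps to finite coordinates.
    """
    arr = as_rgb_image(img).astype(float) / 255.0
    lms = arr @ _RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, EPSILON))
    lab = log_lms @ _LMS2LAB.T
    return LabImage(l=lab[..., 0], alpha=lab[..., 1], beta=lab[..., 2])


def lab_to_rgb(lab: LabImage) -> np.ndarray:
    """Invert :func:`rgb_to_lab`; output clipped to [0, 255] uint8."""
    stack = lab.stack()
    log_lms = stack @ _LAB2LMS.T
    lms = np.power(10.0, log_lms)
    rgb = lms @ _LMS2RGB.T
    return _quantize(rgb * 255.0)


def rgb_to_od(
    img: np.ndarray,
    i_max: float | np.ndarray = 255.0,
    log_base: float = 10.0,
) -> ODImage:
    """Beer–Lambert transform ``od = -log(max(I, ε) / i_max)``.

    Pixels at the background intensity map to exactly zero density (white =
    no stain); zero intensities are floored at ε = 1/255 of one intensity
    level so the result stays finite.
    """
    i_max_arr = np.asarray(i_max, dtype=float)
    if np.any(i_max_arr <= 0):
        raise ValueError("i_max must be positive")
    if log_base not in (10.0, np.e):
        raise ValueError("log_base must be 10 or e")
    arr = as_rgb_image(img).astype(float)
    ratio = np.maximum(arr, EPSILON) / i_max_arr
    od = -np.log(ratio) / np.log(log_base)
    # I == i_max must give exactly 0, not -0.0 noise
    od[arr == i_max_arr * np.ones(3)] = 0.0
    return ODImage(od=od, log_base=log_base, i_max=i_max_arr)


def od_to_rgb(od: ODImage) -> np.ndarray:
    """Inverse Beer–Lambert transform: ``I = round(clip(base^(-od) · i_max))``."""
    intensity = np.power(od.log_base, -od.od) * od.i_max
    return _quantize(intensity)


def estimate_background_intensity(
    img: np.ndarray, mode: str = "fixed", percentile: float = 90.0
) -> np.ndarray:
    """Background (unstained) intensity ``I_max`` per channel.

    ``fixed`` returns 255 for every channel; ``percentile`` returns the p-th
    per-channel percentile of the pixel intensities (default p = 90), a robust
    stand-in for the brightest tissue-free region.
    """
    arr = as_rgb_image(img)
    if arr.size == 0:
        raise ValueError("empty image")
    if mode == "fixed":
        return np.array([255.0, 255.0, 255.0])
    if mode == "percentile":
        flat = arr.reshape(-1, 3).astype(float)
        # linear interpolation would yield non-attained intensities; use the
        # nearest attained level like a rank statistic
        return np.percentile(flat, percentile, axis=0, method="closest_observation")
    raise ValueError(f"unknown mode {mode!r}")
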