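"""Synthetic H&E patches with known ground truth.

The forward model is the Beer–Lambert law: given a 3×2 stain color
appearance matrix M with unit columns (hematoxylin, eosin) and per-pixel
non-negative concentrations C, the optical density is ``OD = M·C`` (plus
optional truncated Gaussian noise in OD space, where the linear model
lives), and the emitted 8-bit intensity is ``I = base^(−OD) · I_max``.

Because M and C are known exactly, stain-vector recovery, factorization
accuracy and round-trip consistency of the normalizers can be tested without
downloading any real histology dataset. The generator mimics the gross
structure of an H&E patch — dense nuclei-like hematoxylin blobs over a
diffuse eosin field — not the texture statistics of real tissue.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_core import ODImage, od_to_rgb
from .stain_normalizers import RUIFROK_HE_BASIS, DensityMaps, StainBasis

__all__ = [
    "SyntheticPatchSpec",
    "GradedDatasetSpec",
    "generate_he_patch",
    "generate_fixture_set",
    "generate_graded_dataset",
]

#: Default ground-truth basis: Ruifrok H&E columns, unit-normalized.
DEFAULT_BASIS = RUIFROK_HE_BASIS[:, :2].copy()


@dataclass
class SyntheticPatchSpec:
    """Everything needed to reproduce one synthetic patch bit-for-bit.

    ``density_scale`` sets the peak hematoxylin and eosin concentrations (OD
    units at full saturation); ``od_noise_sd`` the Gaussian OD noise level.
    96×96 matches the patch-camera lymph-node patch size used as the template
    pool in conventional stain normalization.
    """

    height: int = 96
    width: int = 96
    stain_basis: np.ndarray = field(default_factory=lambda: DEFAULT_BASIS.copy())
    concentration_model: str = "gaussian_blobs"
    density_scale: tuple[float, float] = (1.0, 0.6)
    i_max: float = 255.0
    od_noise_sd: float = 0.0
    log_base: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stain_basis = np.asarray(self.stain_basis, dtype=float)
        if self.stain_basis.shape != (3, 2):
            raise ValueError("stain_basis must be 3×2")
        if not np.allclose(np.linalg.norm(self.stain_basis, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain_basis columns must be unit vectors")
        if self.concentration_model not in ("gaussian_blobs", "uniform_field", "single_stain"):
            raise ValueError(f"unknown concentration model {self.concentration_model!r}")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be >= 0")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["stain_basis"] = self.stain_basis.tolist()
        d["density_scale"] = list(self.density_scale)
        return d


@dataclass
class GradedDatasetSpec:
    """Class structure of a synthetic graded dataset.

    Default counts mirror a four-grade invasive-ductal-carcinoma corpus
    (588/107/102/91). Each grade's signature raises the mean hematoxylin
    density, emulating increasing nuclear density with grade, so a trivial
    intensity-threshold classifier can beat chance.
    """

    class_counts: dict = field(
        default_factory=lambda: {"G0": 588, "G1": 107, "G2": 102, "G3": 91}
    )
    hematoxylin_scale: dict = field(
        default_factory=lambda: {"G0": 0.45, "G1": 0.75, "G2": 1.05, "G3": 1.35}
    )
    eosin_scale: float = 0.6
    height: int = 96
    width: int = 96
    seed: int = 0


def _nuclei_field(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Nuclei-like concentration field: sum of anisotropic Gaussian bumps."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    field_ = np.zeros((h, w))
    n_nuclei = max(3, (h * w) // 350)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(2.0, 5.0), rng.uniform(2.0, 5.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        field_ += rng.uniform(0.6, 1.0) * np.exp(-0.5 * ((u / ry) ** 2 + (v / rx) ** 2))
    return np.clip(field_, 0.0, 1.0)


def _diffuse_field(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Smooth low-frequency field in [0.15, 1], emulating diffuse cytoplasm."""
    noise = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 12.0)
    lo, hi = noise.min(), noise.max()
    span = hi - lo if hi > lo else 1.0
    return 0.15 + 0.85 * (noise - lo) / span


def generate_he_patch(
    spec: SyntheticPatchSpec,
) -> tuple[np.ndarray, StainBasis, DensityMaps]:
    """Emit one synthetic patch plus its ground-truth basis and (noise-free)
    concentration maps."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    s1, s2 = spec.density_scale

    if spec.concentration_model == "gaussian_blobs":
        nuclei = _nuclei_field(rng, h, w)
        c1 = s1 * nuclei
        # nuclei displace cytoplasm: eosin vanishes where hematoxylin
        # saturates, so the two stains do not co-saturate in one pixel
        c2 = s2 * _diffuse_field(rng, h, w) * (1.0 - nuclei)
    elif spec.concentration_model == "uniform_field":
        c1 = rng.uniform(0.0, s1, size=(h, w))
        c2 = rng.uniform(0.0, s2, size=(h, w))
    else:  # single_stain
        c1 = s1 * _nuclei_field(rng, h, w)
        c2 = np.zeros((h, w))

    conc = np.stack([c1.ravel(), c2.ravel()])  # 2×n
    od = (spec.stain_basis @ conc).T.reshape(h, w, 3)
    if spec.od_noise_sd > 0:
        od = od + rng.normal(0.0, spec.od_noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)

    rgb = od_to_rgb(ODImage(od=od, log_base=spec.log_base, i_max=np.asarray(spec.i_max)))
    space = "od10" if spec.log_base == 10.0 else "oden"
    return (
        rgb,
        StainBasis(columns=spec.stain_basis.copy(), space=space),
        DensityMaps(maps=conc, shape=(h, w)),
    )


def generate_fixture_set(out_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Write the canonical test battery and a JSON manifest of ground truths.

    Fixtures: blank-white, constant-color, single-stain, two-stain low/high
    density, and a noisy two-stain patch. Deterministic: one seed, one byte
    stream.
    """
    from .image_core import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs = {
        "blank_white": SyntheticPatchSpec(seed=seed, density_scale=(0.0, 0.0)),
        "constant_color": SyntheticPatchSpec(
            seed=seed + 1, concentration_model="uniform_field", density_scale=(0.0, 0.0)
        ),
        "single_stain": SyntheticPatchSpec(
            seed=seed + 2, concentration_model="single_stain", density_scale=(0.8, 0.0)
        ),
        "two_stain_low": SyntheticPatchSpec(seed=seed + 3, density_scale=(0.5, 0.3)),
        "two_stain_high": SyntheticPatchSpec(seed=seed + 4, density_scale=(1.2, 0.8)),
        "noisy_two_stain": SyntheticPatchSpec(
            seed=seed + 5, density_scale=(1.0, 0.6), od_noise_sd=0.02
        ),
    }
    # constant_color: a flat mid-pink patch rather than white
    manifest: dict = {"seed": seed, "fixtures": {}}
    for name, spec in specs.items():
        if name == "constant_color":
            rgb = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
            rgb[...] = (220, 160, 200)
            basis = StainBasis(columns=spec.stain_basis, space="od10")
        else:
            rgb, basis, _ = generate_he_patch(spec)
        path = out / f"{name}.png"
        write_image(rgb, path)
        manifest["fixtures"][name] = {
            "path": path.name,
            "spec": spec.to_jsonable(),
            "stain_basis": basis.columns.tolist(),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def generate_graded_dataset(
    spec: GradedDatasetSpec, out_dir: str | os.PathLike
) -> pd.DataFrame:
    """Emit per-grade synthetic patches and a ``labels.csv`` table.

    Patch appearance varies by grade through the hematoxylin density scale,
    so the emitted dataset exercises stratified splitting, class weighting
    and balanced accuracy end to end.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    rng = np.random.default_rng(spec.seed)
    for grade in sorted(spec.class_counts):
        count = spec.class_counts[grade]
        if count < 1:
            raise ValueError(f"class {grade} must have count >= 1")
        h_scale = spec.hematoxylin_scale.get(grade, 1.0)
        for k in range(count):
            patch_seed = int(rng.integers(0, 2**31 - 1))
            pspec = SyntheticPatchSpec(
                height=spec.height,
                width=spec.width,
                density_scale=(h_scale, spec.eosin_scale),
                seed=patch_seed,
            )
            rgb, _, _ = generate_he_patch(pspec)
            ident = f"{grade}_{k:04d}"
            from .image_core import write_image

            write_image(rgb, out / f"{ident}.png")
            rows.append({"id": ident, "grade": grade, "seed": patch_seed})
    labels = pd.DataFrame(rows)
    labels.to_csv(out / "labels.csv", index=False)
    return labels
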