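"""The four conventional stain-normalization algorithms.

- Reinhard: per-channel mean/std transfer in the Ruderman lαβ color space.
- Macenko: SVD of tissue optical densities; the two stain vectors are read
  off at robust percentiles of the angle distribution in the leading plane.
- SPCN (structure-preserving color normalization): sparse non-negative
  matrix factorization ``V ≈ W·H`` of the OD map into a stain color
  appearance matrix W (unit columns) and sparse density maps H; the source
  densities are recombined with the template's colors.
- ACD (adaptive color deconvolution): gradient descent over a 6-angle
  parameterization of the stain color appearance matrix M(φ) plus stain
  weights (w_h, w_e), minimizing a stain-separation objective; the fitted
  deconvolution is recombined with a template basis.

Conventions: Macenko and SPCN work in base-10 optical density, ACD in
natural-log optical density. Hematoxylin is always the first stain column
(the column with the larger blue-channel OD component — hematoxylin absorbs
blue light least, leaving the blue-purple hue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_core import (
    ODImage,
    as_rgb_image,
    lab_to_rgb,
    od_to_rgb,
    rgb_to_lab,
    rgb_to_od,
)

__all__ = [
    "InsufficientTissueError",
    "ChannelStats",
    "StainBasis",
    "DensityMaps",
    "SNMFResult",
    "ACDParams",
    "RUIFROK_HE_BASIS",
    "reinhard_normalize",
    "macenko_estimate_stains",
    "macenko_normalize",
    "spcn_snmf",
    "spcn_normalize",
    "acd_fit",
    "acd_normalize",
]


class InsufficientTissueError(ValueError):
    """Raised when too few stained pixels remain after OD thresholding."""


def _unit_columns(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=0, keepdims=True)


# Standard Ruifrok & Johnston H&E(+residual) OD vectors, unit-normalized.
RUIFROK_HE_BASIS = _unit_columns(
    np.array(
        [
            [0.650, 0.072, 0.268],
            [0.704, 0.990, 0.570],
            [0.286, 0.105, 0.776],
        ]
    )
)


@dataclass
class ChannelStats:
    """Per-channel mean and standard deviation triples (lαβ order)."""

    mean: np.ndarray
    std: np.ndarray


@dataclass
class StainBasis:
    """Stain color appearance matrix: 3×r, unit Euclidean columns, one per
    stain (hematoxylin first), entries ≥ 0 in OD space."""

    columns: np.ndarray
    space: str = "od10"  # {"od10", "oden"}

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        norms = np.linalg.norm(self.columns, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain basis columns must be unit vectors")


@dataclass
class DensityMaps:
    """r×n non-negative stain concentrations plus the H×W shape to restore."""

    maps: np.ndarray
    shape: tuple[int, int]

    def plane(self, j: int) -> np.ndarray:
        return self.maps[j].reshape(self.shape)


@dataclass
class SNMFResult:
    basis: StainBasis
    densities: DensityMaps
    objective_trace: np.ndarray
    converged: bool


@dataclass
class ACDParams:
    """Fitted adaptive color deconvolution parameters.

    ``phi`` holds six angles (α, β per stain column) parameterizing the unit
    columns of M(φ); ``w`` the positive stain weights (w_h, w_e, 1).
    """

    phi: np.ndarray
    w: np.ndarray
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def sca_matrix(self) -> np.ndarray:
        return _m_of_phi(self.phi)

    def deconvolution_matrix(self) -> np.ndarray:
        return np.linalg.inv(_m_of_phi(self.phi))


# --------------------------------------------------------------------------
# Reinhard
# --------------------------------------------------------------------------

def _lab_stats(lab) -> ChannelStats:
    planes = [lab.l, lab.alpha, lab.beta]
    return ChannelStats(
        mean=np.array([p.mean() for p in planes]),
        std=np.array([p.std() for p in planes]),
    )


def reinhard_normalize(src: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Match the source's per-channel lαβ mean and spread to the template's.

    Each channel is remapped as ``out = μ_t + (src − μ_s)·(σ_t/σ_s)``; a
    zero-spread source channel is set flat at the template mean.
    """
    src_lab = rgb_to_lab(src)
    tmpl_stats = _lab_stats(rgb_to_lab(template))
    src_stats = _lab_stats(src_lab)

    out_planes = []
    for i, plane in enumerate([src_lab.l, src_lab.alpha, src_lab.beta]):
        if src_stats.std[i] <= 1e-8:  # degenerate constant channel
            warnings.warn(
                f"source lαβ channel {i} has zero spread; set to template mean",
                stacklevel=2,
            )
            out_planes.append(np.full_like(plane, tmpl_stats.mean[i]))
        else:
            out_planes.append(
                tmpl_stats.mean[i]
                + (plane - src_stats.mean[i]) * (tmpl_stats.std[i] / src_stats.std[i])
            )
    lab = type(src_lab)(l=out_planes[0], alpha=out_planes[1], beta=out_planes[2])
    return lab_to_rgb(lab)


# --------------------------------------------------------------------------
# Macenko
# --------------------------------------------------------------------------

def _tissue_mask(od: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of stained pixels: those not transparent in every channel."""
    return od.reshape(-1, 3).max(axis=1) >= threshold


def _order_hematoxylin_first(columns: np.ndarray) -> np.ndarray:
    # hematoxylin has the larger blue-channel OD component
    if columns[2, 0] < columns[2, 1]:
        columns = columns[:, ::-1]
    return columns


def macenko_estimate_stains(
    src: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    i_max: float | np.ndarray = 255.0,
) -> StainBasis:
    """Estimate the two H&E stain vectors from the fringe of the OD cloud.

    Tissue ODs are projected onto the plane of the two leading SVD
    directions; the stain vectors are the unit OD directions at the extreme
    (``angle_percentile``-th and ``100−angle_percentile``-th) percentiles of
    the in-plane angle distribution.
    """
    od_img = rgb_to_od(src, i_max=i_max, log_base=10.0)
    od = od_img.od.reshape(-1, 3)
    tissue = od[_tissue_mask(od_img.od, od_threshold)]
    if tissue.shape[0] < 10:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels above OD {od_threshold}"
        )

    # plane of the two most significant right-singular directions
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    plane = vt[:2].copy()  # 2×3
    # orient the first direction along the OD cloud so in-plane angles stay
    # clear of the ±π wraparound (flipping the second only mirrors the angles)
    if tissue.mean(axis=0) @ plane[0] < 0:
        plane[0] *= -1

    proj = tissue @ plane.T  # n×2
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, angle_percentile)
    hi = np.percentile(angles, 100.0 - angle_percentile)

    v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]
    cols = np.stack([v1, v2], axis=1)
    # flip signs so each stain direction is a non-negative OD direction
    cols *= np.where(cols.sum(axis=0) < 0, -1.0, 1.0)
    cols = np.clip(cols, 0.0, None)
    cols = _unit_columns(cols)
    cols = _order_hematoxylin_first(cols)
    return StainBasis(columns=cols, space="od10")


def macenko_normalize(
    src: np.ndarray,
    template: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    concentration_percentile: float = 99.0,
    i_max: float | np.ndarray = 255.0,
) -> np.ndarray:
    """Remap the source's stain concentrations onto the template's stain
    vectors, rescaling each stain so its robust maximum concentration
    matches the template's."""
    basis_s = macenko_estimate_stains(src, od_threshold, angle_percentile, i_max)
    basis_t = macenko_estimate_stains(template, od_threshold, angle_percentile, i_max)

    od_s = rgb_to_od(src, i_max=i_max, log_base=10.0)
    od_t = rgb_to_od(template, i_max=i_max, log_base=10.0)
    conc_s = np.linalg.pinv(basis_s.columns) @ od_s.od.reshape(-1, 3).T  # 2×n
    conc_t = np.linalg.pinv(basis_t.columns) @ od_t.od.reshape(-1, 3).T

    max_s = np.percentile(conc_s, concentration_percentile, axis=1)
    max_t = np.percentile(conc_t, concentration_percentile, axis=1)
    scale = np.divide(max_t, max_s, out=np.ones_like(max_t), where=max_s > 1e-8)
    conc_scaled = conc_s * scale[:, None]

    od_out = (basis_t.columns @ conc_scaled).T.reshape(od_s.od.shape)
    return od_to_rgb(ODImage(od=np.clip(od_out, 0.0, None), log_base=10.0, i_max=od_s.i_max))


# --------------------------------------------------------------------------
# SPCN — sparse NMF stain separation
# --------------------------------------------------------------------------

def _snmf_objective(v: np.ndarray, w: np.ndarray, h: np.ndarray, lam: float) -> float:
    return 0.5 * np.linalg.norm(v - w @ h, "fro") ** 2 + lam * np.abs(h).sum()


def _rescale_rows_optimally(
    v: np.ndarray, w: np.ndarray, h: np.ndarray, lam: float
) -> np.ndarray:
    """Scale each row of H by the t ≥ 0 minimizing ½‖V−W·diag(t)·H‖²_F + λΣt_j‖H(j,:)‖₁.

    The objective is a convex quadratic in t with Gram matrix
    (WᵀW)⊙(HHᵀ); solved in closed form with an active-set pass for the
    non-negativity constraint.
    """
    gram = (w.T @ w) * (h @ h.T)
    lin = np.einsum("ij,jk,ik->i", w.T, v, h) - lam * np.abs(h).sum(axis=1)
    try:
        t = np.linalg.solve(gram, lin)
    except np.linalg.LinAlgError:
        return h
    if np.any(t < 0):
        t = np.clip(t, 0.0, None)
        free = t > 0
        if free.any():
            sub = np.linalg.pinv(gram[np.ix_(free, free)]) @ lin[free]
            t[free] = np.clip(sub, 0.0, None)
    return t[:, None] * h


def _nnls_columns(w: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Non-negative least-squares fit of H given W, column by column."""
    from scipy.optimize import nnls

    gram = w.T @ w
    # fast path: if unconstrained solution is already non-negative, use it
    h = np.linalg.lstsq(w, v, rcond=None)[0]
    neg = np.any(h < 0, axis=0)
    if np.any(neg):
        cols = np.where(neg)[0]
        for j in cols:
            h[:, j] = nnls(w, v[:, j])[0]
    return np.clip(h, 0.0, None)


def spcn_snmf(
    od: ODImage,
    r: int = 2,
    lambda_sparsity: float = 0.1,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SNMFResult:
    """Sparse NMF ``V ≈ W·H`` of an OD map.

    Minimizes ``½‖V−WH‖²_F + λ·Σ_j ‖H(j,:)‖₁`` with W, H ≥ 0 by multiplicative
    alternating updates. W is initialized from randomly sampled OD pixel
    vectors and re-normalized to unit columns after every outer iteration
    (with the compensating scale folded into H), so the objective is
    non-increasing across iterations and the factorization is reproducible
    from the seed.
    """
    if not np.all(np.isfinite(od.od)):
        raise ValueError("OD map contains non-finite values")
    if r < 1:
        raise ValueError("stain count r must be >= 1")
    if lambda_sparsity < 0:
        raise ValueError("lambda_sparsity must be >= 0")

    h_px, w_px = od.od.shape[:2]
    v = od.od.reshape(-1, 3).T.astype(float)  # 3×n
    n = v.shape[1]

    if np.linalg.norm(v) == 0.0:
        w = np.eye(3)[:, :r]
        h = np.zeros((r, n))
        return SNMFResult(
            basis=StainBasis(columns=w, space="od10" if od.log_base == 10.0 else "oden"),
            densities=DensityMaps(maps=h, shape=(h_px, w_px)),
            objective_trace=np.zeros(1),
            converged=True,
        )

    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(v, axis=0)
    stained = np.where(norms > 0.05)[0]
    if stained.size < r:
        raise InsufficientTissueError("too few stained pixels to seed the factorization")
    # init W from randomly sampled OD pixel vectors; among a seeded sample,
    # greedily take mutually dissimilar directions so the columns do not
    # start collapsed onto one stain
    pool = _unit_columns(
        v[:, rng.choice(stained, size=min(64, stained.size), replace=False)]
    )
    picks = [0]
    while len(picks) < r:
        cos_to_picked = np.max(pool[:, picks].T @ pool, axis=0)
        picks.append(int(np.argmin(cos_to_picked)))
    w = pool[:, picks].copy()
    # NNLS init for H, floored above zero: multiplicative updates cannot
    # move an entry off an exact zero
    h = _nnls_columns(w, v)
    h = np.maximum(h, 1e-3 * max(h.max(), 1e-12))

    delta = 1e-12
    trace = [_snmf_objective(v, w, h, lambda_sparsity)]
    converged = False
    for _ in range(max_iter):
        # multiplicative H step: monotone for ½‖V−WH‖² + λΣ|H| at fixed W
        h = h * (w.T @ v) / (w.T @ w @ h + lambda_sparsity + delta)
        obj_h = _snmf_objective(v, w, h, lambda_sparsity)
        # W step, unit-column renormalization, then an *optimal* non-negative
        # rescaling of each density row (closed-form quadratic including the
        # L1 cost) — naive norm compensation shifts mass into the L1 term
        # and can only lose ground. Guarded: accept only if not worse.
        w_new = w * (v @ h.T) / (w @ h @ h.T + delta)
        scale = np.linalg.norm(w_new, axis=0)
        scale[scale == 0] = 1.0
        w_new = w_new / scale
        h_new = _rescale_rows_optimally(v, w_new, h, lambda_sparsity)
        obj_w = _snmf_objective(v, w_new, h_new, lambda_sparsity)
        if obj_w <= obj_h:
            w, h, obj = w_new, h_new, obj_w
        else:
            obj = obj_h
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(trace[-2], 1e-30):
            converged = True
            break

    order = np.argsort(-w[2, :]) if r == 2 else np.arange(r)
    w, h = w[:, order], h[order]
    return SNMFResult(
        basis=StainBasis(columns=w, space="od10" if od.log_base == 10.0 else "oden"),
        densities=DensityMaps(maps=h, shape=(h_px, w_px)),
        objective_trace=np.asarray(trace),
        converged=converged,
    )


def _polish_basis(v: np.ndarray, w: np.ndarray, h: np.ndarray, iters: int = 30) -> np.ndarray:
    """Debias a sparsity-learned basis: unpenalized alternating least
    squares (NNLS densities, projected least-squares basis) from the sparse
    solution's basin, returning the unit-column W of the plain fit."""
    for _ in range(iters):
        h = _nnls_columns(w, v)
        gram = h @ h.T
        try:
            w = np.clip(v @ h.T @ np.linalg.inv(gram), 0.0, None)
        except np.linalg.LinAlgError:
            break
        norms = np.linalg.norm(w, axis=0)
        norms[norms == 0] = 1.0
        w = w / norms
    return w


def _match_stain_columns(basis_src: np.ndarray, basis_tmpl: np.ndarray) -> np.ndarray:
    """Permutation of template columns best aligned (by cosine) with source."""
    r = basis_src.shape[1]
    if r != 2:
        return np.arange(r)
    cos = basis_src.T @ basis_tmpl  # unit columns: dot = cosine
    return np.array([0, 1]) if cos[0, 0] + cos[1, 1] >= cos[0, 1] + cos[1, 0] else np.array([1, 0])


def spcn_normalize(
    src: np.ndarray,
    template: np.ndarray,
    lambda_sparsity: float = 0.1,
    seed: int = 0,
    concentration_percentile: float = 99.0,
    i_max: float | np.ndarray = 255.0,
) -> np.ndarray:
    """Structure-preserving color normalization.

    Factorizes source and template OD maps as W·H, rescales each source
    density row so its robust maximum matches the template's, and recombines
    the source densities with the *template's* color appearance matrix —
    structure (H) is preserved, color (W) is exchanged.
    """
    od_s = rgb_to_od(src, i_max=i_max, log_base=10.0)
    od_t = rgb_to_od(template, i_max=i_max, log_base=10.0)
    fac_s = spcn_snmf(od_s, r=2, lambda_sparsity=lambda_sparsity, seed=seed)
    fac_t = spcn_snmf(od_t, r=2, lambda_sparsity=lambda_sparsity, seed=seed)

    # the L1 penalty selects the factorization basin; the bases and density
    # maps used for recombination are debiased by a short unpenalized
    # refinement plus an NNLS density refit, so the reconstruction carries
    # no sparsity shrinkage
    v_s = od_s.od.reshape(-1, 3).T
    v_t = od_t.od.reshape(-1, 3).T
    w_s = _polish_basis(v_s, fac_s.basis.columns, fac_s.densities.maps)
    w_t = _polish_basis(v_t, fac_t.basis.columns, fac_t.densities.maps)
    perm = _match_stain_columns(w_s, w_t)
    w_t = w_t[:, perm]
    h_s = _nnls_columns(w_s, v_s)
    h_t = _nnls_columns(w_t, v_t)

    max_s = np.percentile(h_s, concentration_percentile, axis=1)
    max_t = np.percentile(h_t, concentration_percentile, axis=1)
    scale = np.divide(max_t, max_s, out=np.ones_like(max_t), where=max_s > 1e-8)
    od_out = (w_t @ (h_s * scale[:, None])).T.reshape(od_s.od.shape)
    return od_to_rgb(ODImage(od=np.clip(od_out, 0.0, None), log_base=10.0, i_max=od_s.i_max))


# --------------------------------------------------------------------------
# ACD — adaptive color deconvolution
# --------------------------------------------------------------------------

def _m_of_phi(phi: np.ndarray) -> np.ndarray:
    """Unit-column SCA matrix from six spherical angles (α_j, β_j per stain)."""
    phi = np.asarray(phi, dtype=float)
    cols = []
    for j in range(3):
        a, b = phi[2 * j], phi[2 * j + 1]
        cols.append([np.sin(b) * np.cos(a), np.sin(b) * np.sin(a), np.cos(b)])
    return np.array(cols).T


def _phi_of_m(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_m_of_phi` for unit-column matrices."""
    phi = np.empty(6)
    for j in range(3):
        x, y, z = m[:, j]
        phi[2 * j] = np.arctan2(y, x)
        phi[2 * j + 1] = np.arccos(np.clip(z, -1.0, 1.0))
    return phi


def _acd_loss(params: np.ndarray, od: np.ndarray, c0: float) -> float:
    """Composite stain-separation objective.

    Terms, each with its rationale:
    (a) mean pixelwise product of the positive-part densities h₊·e₊ — the
        two stains rarely co-saturate in the same pixel;
    (b) mean squared residual density d² — a two-stain slide should need no
        third component;
    (c) mean squared negative-part densities h₋², e₋² — physical stain
        densities are non-negative; the stiff weight makes this a soft
        constraint that bounds (a) below (the signed product is unbounded
        under rotations of M);
    (d) intensity-balance penalty (mean h − mean e)², absorbed by the stain
        weights;
    (e) a scale anchor (mean h + mean e − c₀)², c₀ fixed at initialization,
        removing the degenerate minimum at vanishing stain weights.
    Weights 1, 1, 50, 0.5, 0.5.
    """
    phi, log_w = params[:6], params[6:]
    m = _m_of_phi(phi)
    try:
        d = np.linalg.inv(m)
    except np.linalg.LinAlgError:
        return np.inf
    w = np.exp(log_w)
    s = np.diag([w[0], w[1], 1.0]) @ d @ od  # 3×n
    h_, e_, r_ = s
    h_pos, e_pos = np.maximum(h_, 0.0), np.maximum(e_, 0.0)
    h_neg, e_neg = np.minimum(h_, 0.0), np.minimum(e_, 0.0)
    mh, me = h_.mean(), e_.mean()
    return float(
        np.mean(h_pos * e_pos)
        + np.mean(r_**2)
        + 50.0 * np.mean(h_neg**2 + e_neg**2)
        + 0.5 * (mh - me) ** 2
        + 0.5 * (mh + me - c0) ** 2
    )


def acd_fit(
    src: np.ndarray,
    lr: float = 0.01,
    iters: int = 300,
    sample_size: int = 10000,
    seed: int = 0,
    od_threshold: float = 0.15,
    i_max: float | np.ndarray = 255.0,
) -> ACDParams:
    """Fit the adaptive color deconvolution parameters of one image.

    Plain gradient descent (central finite differences) over the six SCA
    angles and the log stain weights, on a seeded random sample of at most
    ``sample_size`` tissue pixels in natural-log OD space. Initialization is
    the standard Ruifrok H&E basis with unit weights.
    """
    od_img = rgb_to_od(src, i_max=i_max, log_base=np.e)
    od_flat = od_img.od.reshape(-1, 3)
    tissue = od_flat[_tissue_mask(od_img.od, od_threshold)]
    if tissue.shape[0] < 10:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels above OD {od_threshold}"
        )
    rng = np.random.default_rng(seed)
    if tissue.shape[0] > sample_size:
        tissue = tissue[rng.choice(tissue.shape[0], size=sample_size, replace=False)]
    od = tissue.T  # 3×n

    params = np.concatenate([_phi_of_m(RUIFROK_HE_BASIS), np.zeros(2)])
    d0 = np.linalg.inv(_m_of_phi(params[:6]))
    s0 = d0 @ od
    c0 = float(s0[0].mean() + s0[1].mean())

    eps = 1e-4
    trace = [_acd_loss(params, od, c0)]
    for _ in range(iters):
        grad = np.empty_like(params)
        for k in range(params.size):
            up, dn = params.copy(), params.copy()
            up[k] += eps
            dn[k] -= eps
            grad[k] = (_acd_loss(up, od, c0) - _acd_loss(dn, od, c0)) / (2 * eps)
        params = params - lr * grad
        loss = _acd_loss(params, od, c0)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "ACD optimization diverged (non-finite loss); try a smaller lr"
            )
        trace.append(loss)

    phi, log_w = params[:6], params[6:]
    return ACDParams(
        phi=phi,
        w=np.array([np.exp(log_w[0]), np.exp(log_w[1]), 1.0]),
        loss_trace=np.asarray(trace),
    )


def acd_normalize(
    src: np.ndarray,
    template_sca: StainBasis | np.ndarray | None = None,
    params: ACDParams | None = None,
    i_max: float | np.ndarray = 255.0,
    seed: int = 0,
) -> np.ndarray:
    """Recombine the source's weighted stain components with a template SCA
    matrix: per pixel ``ō = M̄·Ŵ·D(φ̂)·o`` then ``I = exp(−ō)·I_max``.

    ``params`` defaults to fitting on the source; ``template_sca`` defaults
    to the standard Ruifrok H&E reference basis.
    """
    if params is None:
        params = acd_fit(src, seed=seed, i_max=i_max)
    if template_sca is None:
        m_bar = RUIFROK_HE_BASIS
    elif isinstance(template_sca, StainBasis):
        if template_sca.space not in ("oden", "od10"):
            raise ValueError("template basis must live in OD space")
        m_bar = template_sca.columns
        if m_bar.shape[1] == 2:
            m_bar = np.column_stack([m_bar, RUIFROK_HE_BASIS[:, 2]])
    else:
        m_bar = np.asarray(template_sca, dtype=float)

    od_img = rgb_to_od(src, i_max=i_max, log_base=np.e)
    if od_img.log_base != np.e:
        raise ValueError("ACD requires natural-log optical density")
    od = od_img.od.reshape(-1, 3).T
    transfer = m_bar @ np.diag(params.w) @ params.deconvolution_matrix()
    od_out = (transfer @ od).T.reshape(od_img.od.shape)
    return od_to_rgb(ODImage(od=np.clip(od_out, 0.0, None), log_base=np.e, i_max=od_img.i_max))
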