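"""Reinhard, Macenko, SPCN and ACD normalizers: recovery of known stain
parameters on synthetic Beer–Lambert patches, self-normalization identity,
white-pixel fixed points, and solver properties."""

import numpy as np
import pytest

import stainkit as sk
from stainkit.image_core import ODImage, rgb_to_lab
from stainkit.stain_normalizers import (
    RUIFROK_HE_BASIS,
    _unit_columns,
    spcn_snmf,
)


def angle_deg(a, b):
    return np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


def frac_within(a, b, tol):
    return np.mean(np.all(np.abs(a.astype(int) - b.astype(int)) <= tol, axis=-1))


def perturbed_basis(seed, scale=0.09):
    rng = np.random.default_rng(seed)
    m = RUIFROK_HE_BASIS[:, :2].copy()
    p = m + rng.normal(0, scale, size=m.shape).clip(-0.12, 0.12)
    return _unit_columns(np.clip(p, 0, None))


# --------------------------------------------------------------- Reinhard
class TestReinhard:
    def test_identity_transfer(self, he_patch):
        rgb, _, _ = he_patch
        out = sk.reinhard_normalize(rgb, rgb)
        assert np.max(np.abs(out.astype(int) - rgb.astype(int))) <= 1

    def test_constant_source_takes_template_mean(self, rng):
        src = np.full((8, 8, 3), 120, dtype=np.uint8)
        # moderate-range template so its mean lαβ color is inside the gamut
        tmpl = rng.integers(60, 200, size=(8, 8, 3), dtype=np.uint8)
        with pytest.warns(UserWarning):
            out = sk.reinhard_normalize(src, tmpl)
        assert np.ptp(out.reshape(-1, 3), axis=0).max() <= 1  # constant output
        tl = rgb_to_lab(tmpl)
        tmpl_mean_lab = np.array([tl.l.mean(), tl.alpha.mean(), tl.beta.mean()])
        out_lab = rgb_to_lab(out)
        out_mean = np.array([out_lab.l.mean(), out_lab.alpha.mean(), out_lab.beta.mean()])
        assert np.allclose(out_mean, tmpl_mean_lab, atol=0.01)

    def test_two_tone_transfer_matches_independent_oracle(self):
        """Straight-line re-derivation of the whole transfer for a two-tone
        source and a doubled-spread template."""
        src = np.zeros((2, 2, 3), dtype=np.uint8)
        src[0, :, :] = (100, 80, 120)
        src[1, :, :] = (140, 120, 160)
        tmpl = np.zeros((2, 2, 3), dtype=np.uint8)
        tmpl[0, :, :] = (80, 60, 100)
        tmpl[1, :, :] = (160, 140, 180)

        m_rgb2lms = np.array(
            [[0.3811, 0.5783, 0.0402], [0.1967, 0.7244, 0.0782], [0.0241, 0.1288, 0.8444]]
        )
        m_lms2lab = np.diag([3**-0.5, 6**-0.5, 2**-0.5]) @ np.array(
            [[1, 1, 1], [1, 1, -2], [1, -1, 0.0]]
        )

        def to_lab(img):
            lms = (img.astype(float) / 255.0) @ m_rgb2lms.T
            return np.log10(np.maximum(lms, 1 / 255)) @ m_lms2lab.T

        ls, lt = to_lab(src), to_lab(tmpl)
        mu_s, sd_s = ls.reshape(-1, 3).mean(0), ls.reshape(-1, 3).std(0)
        mu_t, sd_t = lt.reshape(-1, 3).mean(0), lt.reshape(-1, 3).std(0)
        lab_out = mu_t + (ls - mu_s) * (sd_t / sd_s)
        lms_out = np.power(10.0, lab_out @ np.linalg.inv(m_lms2lab).T)
        rgb_out = lms_out @ np.linalg.inv(m_rgb2lms).T * 255.0
        expected = np.floor(np.clip(rgb_out, 0, 255) + 0.5).astype(np.uint8)

        got = sk.reinhard_normalize(src, tmpl)
        assert np.array_equal(got, expected)
        # and the output statistics match the template's in lαβ
        out_lab = to_lab(got).reshape(-1, 3)
        assert np.allclose(out_lab.mean(0), mu_t, atol=5e-3)
        assert np.allclose(out_lab.std(0), sd_t, atol=5e-3)


# ---------------------------------------------------------------- Macenko
class TestMacenko:
    def test_blank_white_raises(self):
        white = np.full((8, 8, 3), 255, dtype=np.uint8)
        with pytest.raises(sk.InsufficientTissueError):
            sk.macenko_estimate_stains(white)

    def test_single_stain_extremes_collapse_to_true_vector(self):
        spec = sk.SyntheticPatchSpec(
            seed=2, concentration_model="single_stain", density_scale=(1.0, 0.0)
        )
        rgb, basis, _ = sk.generate_he_patch(spec)
        est = sk.macenko_estimate_stains(rgb)
        for j in range(2):
            assert angle_deg(est.columns[:, j], basis.columns[:, 0]) <= 1.0

    def test_two_stain_recovery_within_two_degrees(self):
        spec = sk.SyntheticPatchSpec(
            seed=1,
            concentration_model="uniform_field",
            density_scale=(1.2, 0.9),
        )
        rgb, basis, _ = sk.generate_he_patch(spec)
        est = sk.macenko_estimate_stains(rgb)
        for j in range(2):
            assert angle_deg(est.columns[:, j], basis.columns[:, j]) <= 2.0

    def test_self_normalization_near_identity(self, bordered_patch):
        out = sk.macenko_normalize(bordered_patch, bordered_patch)
        assert frac_within(bordered_patch, out, 2) >= 0.99

    def test_white_pixels_fixed(self, bordered_patch):
        out = sk.macenko_normalize(bordered_patch, bordered_patch)
        assert np.all(out[:4, :, :] >= 253)

    def test_concentration_percentiles_match_template(self):
        basis = RUIFROK_HE_BASIS[:, :2]
        lo = sk.SyntheticPatchSpec(seed=4, density_scale=(0.6, 0.4))
        hi = sk.SyntheticPatchSpec(seed=4, density_scale=(1.2, 0.8))
        src, _, _ = sk.generate_he_patch(lo)
        tmpl, _, _ = sk.generate_he_patch(hi)
        out = sk.macenko_normalize(src, tmpl)
        est_t = sk.macenko_estimate_stains(tmpl)
        conc = lambda img: np.linalg.pinv(est_t.columns) @ sk.rgb_to_od(img).od.reshape(-1, 3).T
        p_out = np.percentile(conc(out), 99, axis=1)
        p_tmpl = np.percentile(conc(tmpl), 99, axis=1)
        assert np.allclose(p_out, p_tmpl, rtol=0.01)


# ------------------------------------------------------------------- SPCN
class TestSNMF:
    def make_exact_v(self, seed=7, n=200):
        rng = np.random.default_rng(seed)
        w_true = RUIFROK_HE_BASIS[:, :2]
        h_true = rng.uniform(0.5, 2.0, size=(2, n)) * (rng.random((2, n)) < 0.4)
        return w_true, h_true, w_true @ h_true

    def test_exact_factorization_recovered(self):
        _, _, v = self.make_exact_v()
        od = ODImage(od=v.T.reshape(10, 20, 3), log_base=10.0)
        res = spcn_snmf(od, lambda_sparsity=0.01, seed=0, max_iter=5000, tol=1e-12)
        rel = np.linalg.norm(v - res.basis.columns @ res.densities.maps) / np.linalg.norm(v)
        assert rel <= 0.01

    def test_plain_nmf_limit_full_rank(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.1, 1.0, size=(3, 150))
        od = ODImage(od=v.T.reshape(10, 15, 3), log_base=10.0)
        res = spcn_snmf(od, r=3, lambda_sparsity=0.0, seed=1, max_iter=5000, tol=1e-13)
        rel = np.linalg.norm(v - res.basis.columns @ res.densities.maps) / np.linalg.norm(v)
        assert rel <= 1e-3

    def test_zero_input_gives_zero_densities(self):
        od = ODImage(od=np.zeros((4, 4, 3)), log_base=10.0)
        res = spcn_snmf(od, seed=0)
        assert np.all(res.densities.maps == 0)
        assert res.objective_trace[-1] == 0.0

    def test_objective_monotone_nonincreasing(self):
        _, _, v = self.make_exact_v(seed=11)
        od = ODImage(od=v.T.reshape(10, 20, 3), log_base=10.0)
        res = spcn_snmf(od, lambda_sparsity=0.1, seed=3)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_unit_columns_and_nonnegativity(self):
        _, _, v = self.make_exact_v(seed=2)
        od = ODImage(od=v.T.reshape(10, 20, 3), log_base=10.0)
        res = spcn_snmf(od, seed=0)
        assert np.allclose(np.linalg.norm(res.basis.columns, axis=0), 1.0)
        assert np.all(res.basis.columns >= 0)
        assert np.all(res.densities.maps >= 0)

    def test_deterministic_given_seed(self):
        _, _, v = self.make_exact_v(seed=5)
        od = ODImage(od=v.T.reshape(10, 20, 3), log_base=10.0)
        r1 = spcn_snmf(od, seed=42)
        r2 = spcn_snmf(od, seed=42)
        assert np.array_equal(r1.basis.columns, r2.basis.columns)
        assert np.array_equal(r1.densities.maps, r2.densities.maps)

    def test_nonfinite_od_rejected(self):
        od = ODImage(od=np.full((2, 2, 3), np.nan), log_base=10.0)
        with pytest.raises(ValueError):
            spcn_snmf(od)


class TestSPCNNormalize:
    def test_self_normalization_near_identity(self, bordered_patch):
        out = sk.spcn_normalize(bordered_patch, bordered_patch, seed=0)
        assert frac_within(bordered_patch, out, 2) >= 0.99

    def test_white_pixels_fixed(self, bordered_patch):
        out = sk.spcn_normalize(bordered_patch, bordered_patch, seed=0)
        assert np.all(out[:4, :, :] >= 253)

    def test_color_swap_with_shared_concentrations(self):
        basis_a = RUIFROK_HE_BASIS[:, :2]
        basis_b = perturbed_basis(21, scale=0.08)
        shared = dict(seed=4, density_scale=(1.0, 0.6))
        src, _, dens = sk.generate_he_patch(sk.SyntheticPatchSpec(stain_basis=basis_a, **shared))
        tmpl, _, _ = sk.generate_he_patch(sk.SyntheticPatchSpec(stain_basis=basis_b, **shared))
        out = sk.spcn_normalize(src, tmpl, seed=0)
        od_out = sk.rgb_to_od(out).od.reshape(-1, 3).T
        target = basis_b @ dens.maps
        rel = np.linalg.norm(od_out - target) / np.linalg.norm(target)
        assert rel <= 0.02

    def test_white_image_insufficient_tissue(self):
        white = np.full((8, 8, 3), 255, dtype=np.uint8)
        try:
            out = sk.spcn_normalize(white, white, seed=0)
        except sk.InsufficientTissueError:
            return
        assert np.all(out >= 253)


# -------------------------------------------------------------------- ACD
class TestACD:
    def test_sca_recovery_within_five_degrees(self):
        pert = perturbed_basis(11)
        spec = sk.SyntheticPatchSpec(
            seed=111, stain_basis=pert, density_scale=(1.2, 0.9), log_base=np.e
        )
        rgb, _, _ = sk.generate_he_patch(spec)
        params = sk.acd_fit(rgb, seed=0)
        m_hat = params.sca_matrix()
        for j in range(2):
            assert angle_deg(m_hat[:, j], pert[:, j]) <= 5.0

    def test_loss_decreases(self, he_patch):
        rgb, _, _ = he_patch
        params = sk.acd_fit(rgb, seed=0, iters=60)
        assert params.loss_trace[-1] <= params.loss_trace[0]

    def test_deterministic_given_seed(self, he_patch):
        rgb, _, _ = he_patch
        p1 = sk.acd_fit(rgb, seed=7, iters=40)
        p2 = sk.acd_fit(rgb, seed=7, iters=40)
        assert np.array_equal(p1.phi, p2.phi)
        assert np.array_equal(p1.w, p2.w)

    def test_blank_raises_insufficient_tissue(self):
        white = np.full((8, 8, 3), 255, dtype=np.uint8)
        with pytest.raises(sk.InsufficientTissueError):
            sk.acd_fit(white)

    def test_self_recombination_identity(self, bordered_patch):
        params = sk.acd_fit(bordered_patch, seed=0)
        ident = sk.ACDParams(phi=params.phi, w=np.array([1.0, 1.0, 1.0]))
        basis = sk.StainBasis(columns=params.sca_matrix(), space="oden")
        out = sk.acd_normalize(bordered_patch, basis, ident)
        assert frac_within(bordered_patch, out, 2) >= 0.99
        assert np.all(out[:4, :, :] >= 253)  # white fixed points

    def test_cross_basis_transfer(self):
        basis_a = perturbed_basis(31, scale=0.06)
        spec = sk.SyntheticPatchSpec(
            seed=77, stain_basis=basis_a, density_scale=(1.0, 0.7), log_base=np.e
        )
        rgb, _, dens = sk.generate_he_patch(spec)
        params = sk.acd_fit(rgb, seed=0, iters=600)
        basis_b = np.column_stack([RUIFROK_HE_BASIS[:, :2], RUIFROK_HE_BASIS[:, 2]])
        ident = sk.ACDParams(phi=params.phi, w=np.array([1.0, 1.0, 1.0]))
        out = sk.acd_normalize(rgb, basis_b, ident)
        od_out = sk.rgb_to_od(out, log_base=np.e).od.reshape(-1, 3).T
        target = basis_b[:, :2] @ dens.maps
        rel = np.linalg.norm(od_out - target) / np.linalg.norm(target)
        assert rel <= 0.05


def test_all_normalizers_preserve_shape_and_range(he_patch):
    rgb, _, _ = he_patch
    tmpl, _, _ = sk.generate_he_patch(sk.SyntheticPatchSpec(seed=8, density_scale=(0.9, 0.5)))
    for out in (
        sk.reinhard_normalize(rgb, tmpl),
        sk.macenko_normalize(rgb, tmpl),
        sk.spcn_normalize(rgb, tmpl, seed=0),
    ):
        assert out.shape == rgb.shape
        assert out.dtype == np.uint8
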