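"""EMSC dewaxing: basis construction, least-squares fits, image correction."""

import numpy as np
import pytest

from irsh.core_io import SpectralImage, Spectrum, WavenumberAxis, crop_spectral_range
from irsh.emsc import (
    EMSCBasis,
    MaskRule,
    build_paraffin_basis,
    choose_target,
    correct_spectrum,
    dewax_image,
    fit_emsc,
)
from irsh.errors import CollinearityError, DegeneratePixelError, RankError
from irsh.phantom import (
    CLASS_NAMES,
    PhantomConfig,
    build_endmember,
    default_endmembers,
    generate_paraffin_image,
    generate_phantom,
    paraffin_endmember,
)


@pytest.fixture
def axis():
    return WavenumberAxis(np.arange(1800.0, 799.0, -2.0))


@pytest.fixture
def basis(axis):
    target = build_endmember(default_endmembers()["dermis"], axis)
    p = build_endmember(paraffin_endmember(), axis)
    return EMSCBasis(target=target, interference=[Spectrum(axis, p.absorbance, name="paraffin")], poly_order=1)


class TestParaffinBasis:
    def test_zero_components_is_mean_only(self, axis, rng):
        cube = rng.normal(1.0, 0.1, (4, 5, axis.n))
        img = SpectralImage(axis, cube)
        target = build_endmember(default_endmembers()["dermis"], axis)
        b = build_paraffin_basis(img, 0, 2, target)
        assert len(b.interference) == 1
        np.testing.assert_allclose(
            b.interference[0].absorbance, cube.reshape(-1, axis.n).mean(axis=0)
        )

    def test_identical_pixels_zero_variance_rank_error(self, axis):
        p = build_endmember(paraffin_endmember(), axis).absorbance
        img = SpectralImage(axis, np.broadcast_to(p, (3, 3, axis.n)).copy())
        target = Spectrum(axis, np.ones(axis.n), name="t")
        with pytest.raises(RankError):
            build_paraffin_basis(img, 1, 2, target)

    def test_too_many_components_rank_error(self, axis, rng):
        img = SpectralImage(axis, rng.normal(size=(2, 2, axis.n)))
        with pytest.raises(RankError):
            build_paraffin_basis(img, 4, 0, Spectrum(axis, np.ones(axis.n)))

    def test_loadings_match_eigendecomposition_oracle(self, axis, rng):
        # oracle: eigenvectors of the pixel covariance matrix, by explicit
        # eigendecomposition, compared up to sign
        cube = rng.normal(0.0, 1.0, (10, 5, axis.n))
        img = SpectralImage(axis, cube)
        target = build_endmember(default_endmembers()["dermis"], axis)
        b = build_paraffin_basis(img, 3, 0, target)
        X = cube.reshape(-1, axis.n)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        for i in range(3):
            got = b.interference[1 + i].absorbance
            expect = evecs[:, order[i]]
            if np.dot(got, expect) < 0:
                expect = -expect
            np.testing.assert_allclose(got, expect, atol=1e-8)
            # sign convention: largest-magnitude element positive
            assert got[np.argmax(np.abs(got))] > 0


class TestFit:
    def test_identity(self, basis):
        fit = fit_emsc(basis.target, basis)
        assert fit.c == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.b, 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.d, 0.0, atol=1e-10)
        assert fit.residual_rms < 1e-12

    def test_pure_scaling(self, basis):
        s = Spectrum(basis.axis, 2.0 * basis.target.absorbance)
        fit = fit_emsc(s, basis)
        assert fit.c == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(fit.b, 0.0, atol=1e-10)

    def test_known_coefficients_vs_normal_equations_oracle(self, basis):
        nu = basis.axis.values
        x = 2.0 * (nu - nu.min()) / (nu.max() - nu.min()) - 1.0
        s = Spectrum(
            basis.axis,
            basis.target.absorbance
            + 0.5 * basis.interference[0].absorbance
            + 0.1
            + 0.05 * x,
        )
        fit = fit_emsc(s, basis)
        np.testing.assert_allclose(
            [fit.c, fit.b[0], fit.d[0], fit.d[1]], [1.0, 0.5, 0.1, 0.05], atol=1e-8
        )
        # oracle: explicit normal equations (X'X)^-1 X'y
        X = basis.design_matrix()
        beta = np.linalg.inv(X.T @ X) @ (X.T @ s.absorbance)
        np.testing.assert_allclose(
            [fit.c, *fit.b, *fit.d], beta, atol=1e-8
        )

    def test_random_spectra_match_oracle(self, basis, rng):
        X = basis.design_matrix()
        for _ in range(5):
            y = rng.normal(size=basis.axis.n)
            fit = fit_emsc(Spectrum(basis.axis, y), basis)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose([fit.c, *fit.b, *fit.d], beta, atol=1e-8)

    def test_equivariance_under_scaling(self, basis, rng):
        y = (
            0.8 * basis.target.absorbance
            + 0.3 * basis.interference[0].absorbance
            + rng.normal(0.0, 0.01, basis.axis.n)
        )
        fit1 = fit_emsc(Spectrum(basis.axis, y), basis)
        fit3 = fit_emsc(Spectrum(basis.axis, 3.0 * y), basis)
        assert fit3.c == pytest.approx(3 * fit1.c, rel=1e-9)
        np.testing.assert_allclose(fit3.b, 3 * np.asarray(fit1.b), atol=1e-9)
        c1 = correct_spectrum(Spectrum(basis.axis, y), fit1, basis)
        c3 = correct_spectrum(Spectrum(basis.axis, 3.0 * y), fit3, basis)
        np.testing.assert_allclose(c1.absorbance, c3.absorbance, atol=1e-9)

    def test_collinear_design_names_culprit(self, axis):
        target = build_endmember(default_endmembers()["dermis"], axis)
        dup = Spectrum(axis, target.absorbance.copy(), name="duplicate_of_target")
        with pytest.raises(CollinearityError, match="duplicate_of_target|target"):
            EMSCBasis(target=target, interference=[dup], poly_order=0)


class TestCorrectSpectrum:
    def test_target_is_fixed_point(self, basis):
        fit = fit_emsc(basis.target, basis)
        out = correct_spectrum(basis.target, fit, basis)
        np.testing.assert_allclose(out.absorbance, basis.target.absorbance, atol=1e-10)

    def test_scaled_plus_interference_recovers_target(self, basis):
        s = Spectrum(
            basis.axis, 3.0 * basis.target.absorbance + basis.interference[0].absorbance
        )
        out = correct_spectrum(s, fit_emsc(s, basis), basis)
        np.testing.assert_allclose(out.absorbance, basis.target.absorbance, atol=1e-10)

    def test_degenerate_scale_raises(self, basis):
        s = Spectrum(basis.axis, 0.01 * basis.target.absorbance)
        fit = fit_emsc(s, basis)
        with pytest.raises(DegeneratePixelError):
            correct_spectrum(s, fit, basis, MaskRule(c_min=0.2))


class TestChooseTarget:
    def test_mean_of_two_pixels(self, axis, rng):
        u, v = rng.normal(size=axis.n), rng.normal(size=axis.n)
        img = SpectralImage(axis, np.stack([u, v])[None, :, :])
        np.testing.assert_allclose(choose_target(img).absorbance, (u + v) / 2)

    def test_matches_elementwise_mean_oracle(self, axis, rng):
        cube = rng.normal(size=(2, 5, axis.n))
        got = choose_target(SpectralImage(axis, cube)).absorbance
        expect = cube.reshape(-1, axis.n).sum(axis=0) / 10.0
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_respects_mask(self, axis):
        cube = np.zeros((1, 2, axis.n))
        cube[0, 1] = 7.0
        mask = np.array([[False, True]])
        img = SpectralImage(axis, cube, mask=mask)
        np.testing.assert_allclose(choose_target(img).absorbance, 7.0)


class TestDewaxImage:
    @pytest.fixture
    def noiseless(self):
        cfg = PhantomConfig(
            rows=16, cols=16, n_hair_bulbs=0, noise_sd=0.0, seed=11,
            layer_fractions_wt={"epidermis": 0.2, "dermis": 0.3, "hypodermis": 0.2,
                                "muscle": 0.15, "subcutaneous_fat": 0.15},
        )
        return generate_phantom(cfg)

    def test_noiseless_dermis_pixels_recover_endmember(self, noiseless):
        raw = crop_spectral_range(noiseless.image, 800, 1800)
        target = build_endmember(default_endmembers()["dermis"], raw.axis)
        p = build_endmember(paraffin_endmember(), raw.axis)
        basis = EMSCBasis(target=target, interference=[p], poly_order=2)
        corrected, maps = dewax_image(raw, basis)
        dermis = noiseless.truth.labels == CLASS_NAMES.index("dermis")
        dev = np.abs(corrected.cube[dermis] - target.absorbance).max()
        assert dev < 1e-8
        np.testing.assert_allclose(
            maps.c[dermis], noiseless.true_thickness[dermis], atol=1e-8
        )
        np.testing.assert_allclose(
            maps.b[dermis, 0], noiseless.true_paraffin[dermis], atol=1e-8
        )

    def test_pure_paraffin_pixels_masked(self, noiseless):
        raw = crop_spectral_range(noiseless.image, 800, 1800)
        p = build_endmember(paraffin_endmember(), raw.axis)
        blank = SpectralImage(raw.axis, np.broadcast_to(0.8 * p.absorbance, (2, 2, raw.axis.n)).copy())
        target = build_endmember(default_endmembers()["dermis"], raw.axis)
        basis = EMSCBasis(target=target, interference=[p], poly_order=2)
        with pytest.warns(UserWarning, match="all-background"):
            corrected, maps = dewax_image(blank, basis, MaskRule(c_min=0.2))
        assert not corrected.mask.any()
        assert np.abs(maps.c).max() < 0.2

    def test_idempotence(self, noiseless):
        raw = crop_spectral_range(noiseless.image, 800, 1800)
        target = choose_target(raw)
        p = build_endmember(paraffin_endmember(), raw.axis)
        basis = EMSCBasis(target=target, interference=[p], poly_order=2)
        once, _ = dewax_image(raw, basis)
        twice, maps = dewax_image(once, basis)
        assert np.abs(maps.c[once.mask] - 1.0).max() < 1e-6
        assert np.abs(maps.b[once.mask]).max() < 1e-6
        np.testing.assert_allclose(
            twice.cube[once.mask], once.cube[once.mask], atol=1e-6
        )

    def test_noise_rmse_bound(self):
        # corrected pixels stay within ~2 sigma RMSE of the clean endmember
        sigma = 0.005
        cfg = PhantomConfig(rows=32, cols=32, n_hair_bulbs=0, noise_sd=sigma, seed=21)
        ph = generate_phantom(cfg)
        raw = crop_spectral_range(ph.image, 800, 1800)
        p = build_endmember(paraffin_endmember(), raw.axis)
        ems = default_endmembers()
        rmses = []
        for ci, name in enumerate(CLASS_NAMES[:5]):
            target = build_endmember(ems[name], raw.axis)
            basis = EMSCBasis(target=target, interference=[p], poly_order=2)
            corrected, _ = dewax_image(raw, basis)
            sel = ph.truth.labels == ci
            diff = corrected.cube[sel] - target.absorbance
            rmses.extend(np.sqrt(np.mean(diff**2, axis=1)))
        assert np.median(rmses) < 2 * sigma

    def test_cohort_basis_from_paraffin_image(self):
        # a basis built from a noisy paraffin calibration image dewaxes a
        # default-noise phantom to near paraffin-free spectra
        cfg = PhantomConfig(rows=16, cols=16, n_hair_bulbs=0, seed=31)
        ph = generate_phantom(cfg)
        par = generate_paraffin_image(cfg)
        raw = crop_spectral_range(ph.image, 800, 1800)
        parc = crop_spectral_range(par, 800, 1800)
        basis = build_paraffin_basis(parc, 4, 2, choose_target(raw))
        corrected, maps = dewax_image(raw, basis)
        assert corrected.mask.all()
        # reconstruct each pixel's fitted interference and project it onto
        # the paraffin endmember: within a class the recovered amplitude is
        # a + t*beta (true load plus thickness-scaled endmember leakage), so
        # a partial regression on (a, t) must find a unit coefficient on a
        dermis = ph.truth.labels == CLASS_NAMES.index("dermis")
        interference = np.stack([s.absorbance for s in basis.interference])
        p = build_endmember(paraffin_endmember(), raw.axis).absorbance
        a_hat = (maps.b[dermis] @ interference) @ p / (p @ p)
        a = ph.true_paraffin[dermis]
        t = ph.true_thickness[dermis]
        design = np.column_stack([a, t, np.ones_like(a)])
        coef, *_ = np.linalg.lstsq(design, a_hat, rcond=None)
        resid = a_hat - design @ coef
        assert coef[0] == pytest.approx(1.0, abs=0.02)
        assert 1 - resid.var() / a_hat.var() > 0.99
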