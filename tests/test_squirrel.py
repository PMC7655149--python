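import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from srmtools import squirrel as sq
from srmtools import synthetic_data as syn
from srmtools.exceptions import DegenerateInputError, ValidationError
from srmtools.image_io import ImageStack


@pytest.fixture(scope="module")
def filament_sr():
    scene = syn.generate_filament_scene(4, (128, 128), 300, seed=11)
    return syn.render_scene(scene).frames[0]


def direct_ring_frc(a, b):
    """Brute-force per-ring summation oracle for the FRC."""
    n = a.shape[0]
    f1 = np.fft.fft2(a)
    f2 = np.fft.fft2(b)
    fy = np.fft.fftfreq(n)[:, None] * n
    fx = np.fft.fftfreq(n)[None, :] * n
    r = np.round(np.sqrt(fy**2 + fx**2)).astype(int)
    out = []
    for ring in range(1, n // 2 + 1):
        mask = r == ring
        num = (f1[mask] * np.conj(f2[mask])).real.sum()
        den = np.sqrt((np.abs(f1[mask]) ** 2).sum() * (np.abs(f2[mask]) ** 2).sum())
        out.append(num / den)
    return np.array(out)


class TestMatchScales:
    def test_same_shape_identity(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(sq.match_scales(img, img), img)

    def test_constant_upsample_stays_constant(self):
        wf = np.full((8, 8), 4.2)
        out = sq.match_scales(np.zeros((16, 16)), wf)
        np.testing.assert_allclose(out, 4.2, rtol=1e-12)

    def test_upsample_then_block_average_roundtrip(self):
        scene = syn.generate_bead_scene(10, (32, 32), seed=13, psf_sigma_px=2.5)
        wf = syn.render_scene(scene).frames[0]
        up = sq.match_scales(np.zeros((64, 64)), wf)
        down = up.reshape(32, 2, 32, 2).mean(axis=(1, 3))
        rms = np.sqrt(np.mean((down - wf) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(wf**2))

    def test_non_integer_scale_rejected(self):
        with pytest.raises(ValidationError):
            sq.match_scales(np.zeros((24, 24)), np.zeros((16, 16)))


class TestFitRSF:
    def test_parameter_recovery(self, filament_sr):
        wf = gaussian_filter(3.0 * filament_sr + 10.0, 2.0, mode="nearest")
        fit = sq.fit_rsf(filament_sr, wf)
        assert fit.sigma_px == pytest.approx(2.0, abs=0.05)
        assert fit.alpha == pytest.approx(3.0, rel=0.01)
        assert fit.beta == pytest.approx(10.0, rel=0.01)

    def test_unblurred_pair_pins_sigma_at_lower_bound(self, filament_sr):
        fit = sq.fit_rsf(filament_sr, filament_sr.copy())
        assert fit.at_bound
        assert fit.sigma_px == pytest.approx(sq.SIGMA_BOUNDS[0], abs=0.01)

    def test_intensity_scale_linearity(self, filament_sr):
        wf = gaussian_filter(2.0 * filament_sr + 5.0, 1.5, mode="nearest")
        f1 = sq.fit_rsf(filament_sr, wf)
        f2 = sq.fit_rsf(filament_sr, 2.0 * wf)
        assert f2.alpha == pytest.approx(2.0 * f1.alpha, rel=1e-3)
        assert f2.beta == pytest.approx(2.0 * f1.beta, rel=1e-3)
        assert f2.sigma_px == pytest.approx(f1.sigma_px, abs=0.05)

    def test_constant_sr_rejected(self):
        with pytest.raises(DegenerateInputError):
            sq.fit_rsf(np.ones((32, 32)), np.ones((32, 32)))


class TestErrorMap:
    def test_perfect_pair_rsp_one_rse_zero(self, filament_sr):
        wf = gaussian_filter(3.0 * filament_sr + 10.0, 2.0, mode="nearest")
        res = sq.error_map(filament_sr, wf)
        assert res.rsp == pytest.approx(1.0, abs=1e-6)
        assert res.rse <= 1e-6 * (wf.max() - wf.min())

    def test_rsp_invariant_rse_linear_under_wf_scaling(self, filament_sr):
        wf = gaussian_filter(filament_sr + 5.0, 2.0, mode="nearest") \
            + np.random.default_rng(2).normal(0, 0.5, filament_sr.shape)
        r1 = sq.error_map(filament_sr, wf)
        r2 = sq.error_map(filament_sr, 3.0 * wf)
        assert r2.rsp == pytest.approx(r1.rsp, abs=1e-6)
        assert r2.rse == pytest.approx(3.0 * r1.rse, rel=1e-3)

    def test_lesion_localised_in_error_map(self):
        # deleting a structure from the SR image must light up the error map
        # inside the deleted region (the "incomplete structure" artefact)
        scene = syn.generate_filament_scene(3, (128, 128), 300, seed=19)
        sr = syn.render_scene(scene).frames[0]
        wf = gaussian_filter(sr + 2.0, 2.5, mode="nearest")
        lesioned = sr.copy()
        region = (slice(40, 80), slice(40, 80))
        lesioned[region] = 0.0
        assert sr[region].max() > 0  # the lesion actually removed signal
        res = sq.error_map(lesioned, wf)
        r, c = np.unravel_index(res.error_map.argmax(), res.error_map.shape)
        assert 40 <= r < 80 and 40 <= c < 80

    def test_scale_match_integration(self, filament_sr):
        # WF acquired on a 2x coarser grid than SR
        wf_coarse = gaussian_filter(filament_sr, 2.0, mode="nearest") \
            .reshape(64, 2, 64, 2).mean(axis=(1, 3))
        res = sq.error_map(filament_sr, wf_coarse)
        assert res.error_map.shape == filament_sr.shape
        assert res.rsp > 0.99


class TestFRCCurve:
    def test_identical_images_no_crossing(self, rng):
        img = rng.random((64, 64))
        res = sq.frc_curve(img, img, 100.0)
        np.testing.assert_allclose(res.correlations, 1.0, atol=1e-9)
        assert res.resolution_nm is None

    def test_independent_noise_mean_near_zero(self):
        r = np.random.default_rng(5)
        res = sq.frc_curve(r.normal(size=(256, 256)), r.normal(size=(256, 256)),
                           100.0)
        assert abs(res.correlations.mean()) < 0.1

    def test_matches_direct_ring_sums(self):
        r = np.random.default_rng(7)
        scene = syn.generate_bead_scene(30, (64, 64), seed=7)
        base = syn.render_scene(scene).frames[0]
        a = r.poisson(base + 5).astype(float)
        b = r.poisson(base + 5).astype(float)
        res = sq.frc_curve(a, b, 100.0)
        np.testing.assert_allclose(res.correlations, direct_ring_frc(a, b),
                                   atol=1e-9)

    def test_resolution_near_psf_cutoff(self):
        # two independently noised renders of one bead scene: the FRC
        # resolution should sit near the PSF FWHM (2.355 * sigma)
        r = np.random.default_rng(9)
        scene = syn.generate_bead_scene(150, (256, 256), seed=9)
        base = syn.render_scene(scene).frames[0]
        a = r.poisson(base + 10).astype(float)
        b = r.poisson(base + 10).astype(float)
        res = sq.frc_curve(a, b, 100.0)
        fwhm_nm = 2.355 * 1.5 * 100.0
        assert res.resolution_nm == pytest.approx(fwhm_nm, rel=0.3)

    def test_symmetry(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        np.testing.assert_allclose(sq.frc_curve(a, b).correlations,
                                   sq.frc_curve(b, a).correlations, atol=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            sq.frc_curve(np.ones((16, 16)), np.ones((16, 16)))

    def test_rectangular_images_padded(self, rng):
        a = rng.random((32, 48))
        res = sq.frc_curve(a, a + rng.normal(0, 0.1, a.shape))
        assert res.correlations.ndim == 1


class TestFRCMap:
    @staticmethod
    def _noisy_pair(scene, seed):
        base = syn.render_scene(scene).frames[0]
        r = np.random.default_rng(seed)
        return (r.poisson(base + 10).astype(float),
                r.poisson(base + 10).astype(float))

    def test_uniform_pair_homogeneous_blocks(self):
        scene = syn.generate_bead_scene(400, (256, 256), seed=23, margin_px=4)
        a, b = self._noisy_pair(scene, 23)
        rmap = sq.frc_map(a, b, blocks_per_axis=4, pixel_size_nm=100.0)
        vals = rmap.block_grid[~rmap.interpolated_mask]
        assert vals.std() < 0.25 * vals.mean()

    def test_empty_half_flagged_interpolated(self):
        # the right half of the field carries no photons at all, so its
        # blocks are degenerate by construction and must be filled in
        rows = cols = 128
        scene = syn.generate_bead_scene(200, (rows, cols), seed=29, margin_px=4)
        keep = scene.positions[:, 0] < cols / 2 - 10
        from dataclasses import replace
        left = replace(scene, positions=scene.positions[keep],
                       intensities=scene.intensities[keep])
        base = syn.render_scene(left).frames[0]
        r = np.random.default_rng(29)
        a = r.poisson(base).astype(float)  # zero offset: empty half stays 0
        b = r.poisson(base).astype(float)
        rmap = sq.frc_map(a, b, blocks_per_axis=4, pixel_size_nm=100.0)
        assert rmap.interpolated_mask[:, 2:].all()
        assert not rmap.interpolated_mask[:, 0].all()
        assert np.isfinite(rmap.block_grid).all()

    def test_density_resolution_monotonicity(self):
        # doubling the emitter density halves the shot noise per structure,
        # pushing the FRC crossing to higher frequency (finer resolution)
        rows = cols = 256
        r = np.random.default_rng(31)
        dense = syn.generate_bead_scene(600, (rows, cols), seed=31, margin_px=4)
        sparse_keep = r.random(600) < 0.25
        from dataclasses import replace
        mixed = replace(
            dense,
            positions=np.where(
                (dense.positions[:, 0] < cols / 2)[:, None] | sparse_keep[:, None],
                dense.positions, np.full_like(dense.positions, np.nan)),
        )
        pos = mixed.positions[~np.isnan(mixed.positions[:, 0])]
        mixed = replace(dense, positions=pos,
                        intensities=np.full(len(pos), dense.intensities[0]))
        a, b = self._noisy_pair(mixed, 31)
        rmap = sq.frc_map(a, b, blocks_per_axis=4, pixel_size_nm=100.0)
        left = np.nanmedian(rmap.block_grid[:, :2])
        right = np.nanmedian(rmap.block_grid[:, 2:])
        assert left <= right

    def test_all_blocks_invalid_raises(self):
        blank = np.zeros((64, 64))
        with pytest.raises(ValidationError):
            sq.frc_map(blank, blank, blocks_per_axis=4)


class TestSplitHalves:
    def test_odd_even_partition(self, rng):
        frames = rng.random((6, 8, 8))
        odd, even = sq.split_halves(ImageStack(frames))
        np.testing.assert_allclose(odd, frames[0::2].mean(axis=0))
        np.testing.assert_allclose(even, frames[1::2].mean(axis=0))
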