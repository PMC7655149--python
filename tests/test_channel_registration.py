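from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srmtools import channel_registration as reg
from srmtools import synthetic_data as syn
from srmtools._interpolation import translate
from srmtools.drift_correction import Shift
from srmtools.exceptions import CalibrationError, ValidationError
from srmtools.image_io import DisplacementField


def shepard_by_hand(points, values, query, power):
    """Literal Shepard formula, one query point at a time."""
    out = []
    for q in np.atleast_2d(query):
        d = np.hypot(points[:, 0] - q[0], points[:, 1] - q[1])
        if (d == 0).any():
            out.append(values[d.argmin()])
            continue
        w = 1.0 / d**power
        out.append((w * values).sum() / w.sum())
    return np.array(out)


class TestBlockShifts:
    def test_identical_channels_near_zero(self, bead_frame):
        samples = reg.estimate_block_shifts(bead_frame, bead_frame, 4)
        for s in samples:
            if s.valid:
                assert abs(s.shift.dx_px) < 0.02 and abs(s.shift.dy_px) < 0.02

    def test_global_shift_recovered_per_block(self, bead_frame):
        target = translate(bead_frame, 1.5, 0.0)
        samples = reg.estimate_block_shifts(bead_frame, target, 4,
                                            max_shift_px=4)
        valid = [s for s in samples if s.valid]
        assert len(valid) >= 8
        for s in valid:
            assert s.shift.dx_px == pytest.approx(1.5, abs=0.05)
            assert s.shift.dy_px == pytest.approx(0.0, abs=0.05)

    def test_empty_block_flagged_invalid(self, rng):
        # structure confined well inside one block so the prefilter halo
        # cannot leak into the others
        ref = np.zeros((64, 64))
        ref[:20, :20] = rng.random((20, 20))
        tgt = ref.copy()
        samples = reg.estimate_block_shifts(ref, tgt, 2)
        flags = [s.valid for s in samples]
        assert flags[0] and not all(flags)

    def test_all_blocks_invalid_raises(self):
        with pytest.raises(CalibrationError):
            reg.estimate_block_shifts(np.random.default_rng(0).random((32, 32)),
                                      np.zeros((32, 32)), 2)


class TestDisplacementFieldFit:
    def test_single_sample_constant_field(self):
        s = reg.BlockShiftSample((10.0, 12.0), Shift(2.0, -1.0, 0.9), True)
        fld = reg.fit_displacement_field([s], (24, 24))
        np.testing.assert_allclose(fld.shift_x, 2.0)
        np.testing.assert_allclose(fld.shift_y, -1.0)

    def test_exact_hit_at_sample_centre(self):
        samples = [
            reg.BlockShiftSample((4.0, 4.0), Shift(1.0, 0.5, 0.9), True),
            reg.BlockShiftSample((20.0, 16.0), Shift(-2.0, 1.5, 0.9), True),
        ]
        fld = reg.fit_displacement_field(samples, (24, 24))
        assert fld.shift_x[4, 4] == pytest.approx(1.0, abs=1e-6)
        assert fld.shift_y[16, 20] == pytest.approx(1.5, abs=1e-6)

    def test_matches_hand_computed_shepard(self):
        pts = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0], [30.0, 30.0]])
        vx = np.array([1.0, -1.0, 2.0, 0.5])
        samples = [reg.BlockShiftSample(tuple(p), Shift(v, 0.0, 1.0), True)
                   for p, v in zip(pts, vx)]
        fld = reg.fit_displacement_field(samples, (31, 31), idw_power=2.0)
        query = np.array([[15.0, 15.0], [3.0, 27.0], [10.0, 5.0]])
        expect = shepard_by_hand(pts, vx, query, 2.0)
        for (qx, qy), e in zip(query, expect):
            assert fld.shift_x[int(qy), int(qx)] == pytest.approx(e, abs=1e-9)

    def test_no_valid_samples_raises(self):
        s = reg.BlockShiftSample((1.0, 1.0), Shift(0, 0, 0.0), False)
        with pytest.raises(ValidationError):
            reg.fit_displacement_field([s], (8, 8))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_field_bounded_by_sample_extrema(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 8))
        samples = [reg.BlockShiftSample((float(x), float(y)),
                                        Shift(float(dx), float(dy), 1.0), True)
                   for x, y, dx, dy in zip(r.uniform(0, 15, k), r.uniform(0, 15, k),
                                           r.normal(0, 2, k), r.normal(0, 2, k))]
        fld = reg.fit_displacement_field(samples, (16, 16))
        dxs = [s.shift.dx_px for s in samples]
        dys = [s.shift.dy_px for s in samples]
        assert fld.shift_x.min() >= min(dxs) - 1e-6
        assert fld.shift_x.max() <= max(dxs) + 1e-6
        assert fld.shift_y.min() >= min(dys) - 1e-6
        assert fld.shift_y.max() <= max(dys) + 1e-6


class TestCalibrateRegistration:
    def test_identical_channels_near_zero_field(self, bead_frame):
        calib = reg.calibrate_registration(np.stack([bead_frame, bead_frame]))
        fld = calib.fields[1]
        assert np.abs(fld.shift_x).max() < 0.05
        assert np.abs(fld.shift_y).max() < 0.05

    def test_three_channels_two_fields(self, bead_frame):
        calib = reg.calibrate_registration(
            np.stack([bead_frame, bead_frame, bead_frame]), reference_channel=1)
        assert sorted(calib.fields) == [0, 2]

    def test_sinusoidal_warp_recovery(self):
        scene = syn.generate_bead_scene(150, (128, 128), seed=9)
        field = syn.sinusoidal_field((128, 128), amplitude_px=2.0)
        ref = syn.render_scene(scene).frames[0]
        tgt, _ = syn.simulate_warped_channel(scene, field)
        calib = reg.calibrate_registration(np.stack([ref, tgt]))
        est = calib.fields[1]
        x, y = scene.positions.T
        rr, cc = y.round().astype(int), x.round().astype(int)
        ex = est.shift_x[rr, cc] - field.shift_x[rr, cc]
        ey = est.shift_y[rr, cc] - field.shift_y[rr, cc]
        # global Shepard weighting regresses the field toward the sample
        # mean between block centres; ~0.17 px RMS is the interpolator's
        # intrinsic accuracy for a 2 px sinusoidal warp
        assert np.sqrt(np.mean(ex**2 + ey**2)) < 0.25


class TestApplyRegistration:
    def test_zero_field_identity(self, bead_frame):
        fld = DisplacementField(np.zeros((64, 64)), np.zeros((64, 64)))
        np.testing.assert_allclose(reg.apply_registration(bead_frame, fld),
                                   bead_frame, atol=1e-9)

    def test_constant_field_is_rigid_translation(self, bead_frame):
        # a channel displaced by (+dx,+dy) is corrected by sampling at
        # +shift, i.e. the content moves by the negated shift
        fld = DisplacementField(np.full((64, 64), 1.5), np.full((64, 64), -2.0))
        out = reg.apply_registration(bead_frame, fld)
        expect = translate(bead_frame, -1.5, 2.0)
        interior = (slice(4, -4), slice(4, -4))
        np.testing.assert_allclose(out[interior], expect[interior], atol=1e-6)

    def test_apply_then_negate_recovers_interior(self, bead_frame):
        fld = syn.sinusoidal_field((64, 64), amplitude_px=1.0)
        neg = DisplacementField(-fld.shift_x, -fld.shift_y)
        out = reg.apply_registration(
            reg.apply_registration(bead_frame, fld), neg)
        interior = (slice(5, -5), slice(5, -5))
        dev = np.abs(out[interior] - bead_frame[interior]).max()
        assert dev < 0.01 * bead_frame.max()

    def test_shape_mismatch_without_scale_raises(self, bead_frame):
        fld = DisplacementField(np.zeros((32, 32)), np.zeros((32, 32)))
        with pytest.raises(ValidationError):
            reg.apply_registration(bead_frame, fld)

    def test_rescaled_field_on_magnified_image(self, bead_frame):
        # constant field rescales exactly: values scale with magnification
        fld = DisplacementField(np.full((32, 32), 0.5), np.zeros((32, 32)))
        big = reg.rescale_field(fld, 2)
        assert big.shape == (64, 64)
        np.testing.assert_allclose(big.shift_x, 1.0, atol=1e-6)
        out = reg.apply_registration(bead_frame, fld, magnification=2)
        expect = translate(bead_frame, -1.0, 0.0)
        interior = (slice(4, -4), slice(4, -4))
        np.testing.assert_allclose(out[interior], expect[interior], atol=1e-6)


class TestTRE:
    def test_perfect_field_zero_tre(self):
        scene = syn.generate_bead_scene(10, (64, 64), seed=3)
        field = syn.sinusoidal_field((64, 64), amplitude_px=1.5)
        _, tgt = syn.simulate_warped_channel(scene, field)
        tre = reg.compute_tre(scene.positions, tgt, field, 100.0)
        assert tre == pytest.approx(0.0, abs=1e-9)

    def test_uniform_error_gives_expected_tre(self):
        scene = syn.generate_bead_scene(10, (64, 64), seed=3)
        field = syn.sinusoidal_field((64, 64), amplitude_px=1.5)
        _, tgt = syn.simulate_warped_channel(scene, field)
        biased = DisplacementField(field.shift_x + 0.1, field.shift_y)
        tre = reg.compute_tre(scene.positions, tgt, biased, 100.0)
        # inverting the biased map evaluates the field 0.1 px away from the
        # true fixed point, so the residual is 10 nm up to field-gradient
        # terms (|grad f| * 0.1 px, a few tenths of a nm here)
        assert tre == pytest.approx(10.0, abs=0.5)

    def test_too_few_beads_rejected(self):
        field = DisplacementField(np.zeros((8, 8)), np.zeros((8, 8)))
        pos = np.array([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValidationError):
            reg.compute_tre(pos, pos, field)

    def test_tre_improves_with_bead_density(self):
        # more calibration beads -> better field -> lower hold-out TRE,
        # on average over seeds
        field = syn.sinusoidal_field((128, 128), amplitude_px=2.0)
        means = []
        for n in (20, 120):
            tres = []
            for seed in range(4):
                scene = syn.generate_bead_scene(n, (128, 128), seed=50 + seed)
                ref = syn.render_scene(scene).frames[0]
                tgt, _ = syn.simulate_warped_channel(scene, field)
                samples = reg.estimate_block_shifts(ref, tgt, 5)
                est = reg.fit_displacement_field(samples, (128, 128))
                hold = syn.generate_bead_scene(30, (128, 128), seed=90 + seed)
                _, hold_tgt = syn.simulate_warped_channel(hold, field)
                tres.append(reg.compute_tre(hold.positions, hold_tgt, est))
            means.append(np.mean(tres))
        assert means[1] <= means[0]
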