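"""Cross-correlation, subpixel interpolation and vector validation."""

import numpy as np
import pytest

import plumekin as pk
from plumekin.errors import InputError
from plumekin.piv import (
    InterrogationGrid,
    compute_vector_field,
    correlate,
    subpixel_peak,
    successive_abandonment,
    velocity_error_bound,
)

from ._oracles import blob_frame, zncc_bruteforce


def _frame(data, t=0.0, pixel_size=4.4 / 21.0):
    return pk.Frame(np.asarray(data, dtype=np.uint8), t, pixel_size)


class TestCorrelate:
    def test_self_correlation_peaks_at_one(self):
        rng = np.random.default_rng(0)
        tpl = rng.integers(0, 256, size=(21, 21)).astype(float)
        search = np.pad(tpl, 5, mode="constant")
        surf = correlate(tpl, search)
        r, c = np.unravel_index(np.argmax(surf), surf.shape)
        assert (r, c) == (5, 5)
        assert surf[r, c] == pytest.approx(1.0, abs=1e-10)

    def test_integer_shift_recovered_at_argmax(self):
        # search region holds the template shifted by (dx, dy) = (3, -2)
        rng = np.random.default_rng(1)
        big = rng.integers(0, 256, size=(60, 60)).astype(float)
        tpl = big[20:41, 20:41]
        search = big[2:59, 3:60]
        surf = correlate(tpl, search)
        r, c = np.unravel_index(np.argmax(surf), surf.shape)
        # template top-left (20, 20) sits at row 20-2=18, col 20-3=17 here
        assert (r, c) == (18, 17)
        assert surf[r, c] == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_correlates_weakly(self):
        rng = np.random.default_rng(2)
        tpl = rng.integers(0, 256, size=(21, 21)).astype(float)
        search = rng.integers(0, 256, size=(51, 51)).astype(float)
        assert correlate(tpl, search).max() < 0.5

    def test_constant_template_is_flagged_not_raised(self):
        assert correlate(np.full((21, 21), 7.0), np.zeros((51, 51))) is None

    def test_fft_matches_bruteforce_oracle(self):
        # every 21x21 window of a rendered 64x64 pair, to 1e-8
        rng = np.random.default_rng(3)
        pts = rng.uniform(10, 54, size=(12, 2))
        a = blob_frame((64, 64), pts).astype(float)
        b = blob_frame((64, 64), pts + [1.7, -0.6]).astype(float)
        for y0 in (0, 21, 42):
            for x0 in (0, 21, 42):
                tpl = a[y0 : y0 + 21, x0 : x0 + 21]
                if tpl.std() == 0:
                    continue
                surf = correlate(tpl, b)
                np.testing.assert_allclose(
                    surf, zncc_bruteforce(tpl, b), atol=1e-8
                )


class TestSubpixelPeak:
    def test_symmetric_surface_has_zero_correction(self):
        surf = np.zeros((5, 5))
        surf[2, 2], surf[1, 2], surf[3, 2], surf[2, 1], surf[2, 3] = 1.0, 0.5, 0.5, 0.5, 0.5
        r, c, reduced = subpixel_peak(surf, (2, 2))
        assert (r, c) == (2.0, 2.0)
        assert not reduced

    def test_three_point_gaussian_closed_form(self):
        # triple (0.5, 1.0, 0.5/e): delta = (ln l - ln r) / (2 ln l - 4 ln c + 2 ln r)
        l, ctr, rgt = 0.5, 1.0, 0.5 * np.exp(-1.0)
        expected = (np.log(l) - np.log(rgt)) / (
            2 * np.log(l) - 4 * np.log(ctr) + 2 * np.log(rgt)
        )
        surf = np.zeros((3, 3))
        surf[1, 0], surf[1, 1], surf[1, 2] = l, ctr, rgt
        surf[0, 1] = surf[2, 1] = ctr * 0.5  # symmetric along rows
        _, c, _ = subpixel_peak(surf, (1, 1))
        assert c - 1.0 == pytest.approx(expected, abs=1e-9)

    def test_border_peak_returns_integer_with_flag(self):
        surf = np.zeros((5, 5))
        surf[0, 2] = 1.0
        r, c, reduced = subpixel_peak(surf, (0, 2))
        assert (r, c) == (0.0, 2.0)
        assert reduced

    def test_imposed_03px_shift_recovered_within_tenth_px(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, size=(100, 2))
        a = _frame(blob_frame((100, 100), pts, sigma=1.5, amplitude=80), t=0.0)
        b = _frame(
            blob_frame((100, 100), pts + [0.3, 0.0], sigma=1.5, amplitude=80),
            t=1 / 300,
        )
        field = compute_vector_field(a, b, InterrogationGrid(search_radius=5))
        dx = field.displacements[field.valid, 0]
        assert len(dx) > 0
        assert np.mean(dx) == pytest.approx(0.3, abs=0.1)

    def test_subpixel_rms_error_under_tenth_px_over_sweep(self):
        # adequately seeded windows (several particles per 21x21 window),
        # the operating regime the 1/10 px accuracy figure refers to
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, size=(100, 2))
        a = _frame(blob_frame((100, 100), pts, sigma=1.5, amplitude=80), t=0.0)
        errs = []
        for shift in np.arange(0.1, 0.95, 0.1):
            b = _frame(
                blob_frame((100, 100), pts + [shift, 0.0], sigma=1.5, amplitude=80),
                t=1 / 300,
            )
            field = compute_vector_field(a, b, InterrogationGrid(search_radius=5))
            dx = field.displacements[field.valid, 0]
            errs.extend(dx - shift)
        rms = float(np.sqrt(np.mean(np.square(errs))))
        assert rms <= 0.1


class TestSuccessiveAbandonment:
    NEIGHBORS = np.array([[2.0, 0.1], [1.9, 0.0], [2.1, -0.1], [2.0, 0.0]])

    def test_consensus_candidate_accepted_without_abandonment(self):
        chosen, count = successive_abandonment([(2.0, 0.0)], self.NEIGHBORS)
        assert (chosen, count) == (0, 0)

    def test_outlier_top_peak_abandoned_for_consistent_second(self):
        cands = [(9.0, -7.0), (2.0, 0.0)]  # top peak far from neighborhood
        chosen, count = successive_abandonment(cands, self.NEIGHBORS)
        assert (chosen, count) == (1, 1)

    def test_all_candidates_deviant_gives_invalid(self):
        cands = [(9.0, -7.0), (-8.0, 6.0), (12.0, 12.0)]
        chosen, count = successive_abandonment(cands, self.NEIGHBORS)
        assert chosen is None
        assert count == 3

    def test_sparse_neighborhood_accepts_top_peak(self):
        chosen, count = successive_abandonment(
            [(9.0, -7.0)], np.array([[2.0, 0.0]])
        )
        assert (chosen, count) == (0, 0)


class TestComputeVectorField:
    def test_identical_frames_yield_zero_vectors(self):
        rng = np.random.default_rng(6)
        img = blob_frame(
            (100, 100), rng.uniform(0, 100, size=(100, 2)), sigma=1.5, amplitude=80
        )
        a, b = _frame(img, 0.0), _frame(img, 1 / 300)
        field = compute_vector_field(a, b)
        assert field.n_valid > 0
        # zero motion recovered within the 1/10 px subpixel error bound
        np.testing.assert_allclose(
            field.displacements[field.valid], 0.0, atol=0.1
        )

    def test_uniform_two_px_shift_recovered(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, size=(100, 2))
        a = _frame(blob_frame((100, 100), pts, sigma=1.5, amplitude=80), 0.0)
        b = _frame(
            blob_frame((100, 100), pts + [2.0, 0.0], sigma=1.5, amplitude=80), 1 / 300
        )
        field = compute_vector_field(a, b)
        dx = field.displacements[field.valid, 0]
        assert np.mean(dx) == pytest.approx(2.0, abs=0.05)

    def test_displacements_equivariant_under_extra_integer_shift(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, size=(100, 2))
        a = _frame(blob_frame((100, 100), pts, sigma=1.5, amplitude=80), 0.0)
        b1 = _frame(
            blob_frame((100, 100), pts + [1.0, 2.0], sigma=1.5, amplitude=80), 1 / 300
        )
        b2 = _frame(
            blob_frame((100, 100), pts + [4.0, 0.0], sigma=1.5, amplitude=80), 1 / 300
        )  # an extra (+3, -2) relative to b1
        f1 = compute_vector_field(a, b1)
        f2 = compute_vector_field(a, b2)
        both = f1.valid & f2.valid
        delta = f2.displacements[both] - f1.displacements[both]
        np.testing.assert_allclose(delta, [[3.0, -2.0]] * both.sum(), atol=0.15)

    def test_velocity_scaling_by_calibration(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, size=(100, 2))
        a = _frame(blob_frame((100, 100), pts, sigma=1.5, amplitude=80), 0.0)
        b = _frame(
            blob_frame((100, 100), pts + [2.0, 0.0], sigma=1.5, amplitude=80), 1 / 300
        )
        field = compute_vector_field(a, b)
        v = field.velocities[field.valid]
        d = field.displacements[field.valid]
        np.testing.assert_allclose(
            v, d * (4.4 / 21.0) * 300.0, rtol=1e-12
        )

    def test_mismatched_shapes_rejected(self):
        a = _frame(np.zeros((50, 50)), 0.0)
        b = _frame(np.zeros((60, 50)), 1 / 300)
        with pytest.raises(InputError):
            compute_vector_field(a, b)

    def test_textureless_windows_are_invalid(self):
        a = _frame(np.zeros((64, 64)), 0.0)
        b = _frame(np.zeros((64, 64)), 1 / 300)
        field = compute_vector_field(a, b)
        assert field.n_valid == 0


def test_vector_field_dataframe_roundtrip():
    import pandas as pd

    from plumekin.piv import fields_from_dataframe

    rng = np.random.default_rng(10)
    img_a = blob_frame((100, 100), rng.uniform(0, 100, size=(100, 2)), 1.5, 80)
    img_b = blob_frame(
        (100, 100), rng.uniform(0, 100, size=(100, 2)) + [1.0, 0.5], 1.5, 80
    )
    f = compute_vector_field(_frame(img_a, 0.0), _frame(img_b, 1 / 300))
    df = f.to_dataframe()
    df.insert(0, "frame_index", 0)
    (g,) = fields_from_dataframe(df, f.pixel_size, f.dt)
    np.testing.assert_array_equal(g.displacements, f.displacements)
    np.testing.assert_array_equal(g.valid, f.valid)
    np.testing.assert_array_equal(g.velocities, f.velocities)
    assert g.t == f.t


class TestVelocityErrorBound:
    def test_reference_calibration_rounds_to_six_point_three(self):
        # 1/10 px at 21 px = 4.4 cm and 300 frames/s
        v = velocity_error_bound(0.1, 4.4 / 21.0, 1.0 / 300.0)
        assert round(v, 1) == 6.3
        # the same 21 px window spans ~4.4 cm: the quoted spatial resolution
        assert 21 * (4.4 / 21.0) == pytest.approx(4.4)

    def test_zero_pixel_error_gives_zero(self):
        assert velocity_error_bound(0.0, 1.0, 1.0) == 0.0

    def test_unit_case(self):
        assert velocity_error_bound(1.0, 1.0, 1.0) == 1.0

    @pytest.mark.parametrize("args", [(-0.1, 1, 1), (0.1, 0, 1), (0.1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(InputError):
            velocity_error_bound(*args)
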