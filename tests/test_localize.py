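"""Detection and phasor localization: kernel identities, anchor cases, and
accuracy against a least-squares Gaussian-fit oracle."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.special import erf

import smlmkit as sk
from smlmkit.localize import DetectionParams, dog_filter, find_candidates, phasor_localize


def integrated_gaussian_roi(x0, y0, sigma, size=7, photons=1.0):
    """Pixel-integrated Gaussian PSF on a size x size ROI; (x0, y0) are
    continuous coordinates in the ROI frame (pixel centers at k + 0.5)."""
    s = sigma * np.sqrt(2)
    edges = np.arange(size + 1, dtype=float)
    fx = 0.5 * (erf((edges[1:] - x0) / s) - erf((edges[:-1] - x0) / s))
    fy = 0.5 * (erf((edges[1:] - y0) / s) - erf((edges[:-1] - y0) / s))
    return photons * np.outer(fy, fx)


def gaussian_fit_oracle(roi):
    """Independent least-squares 2D-Gaussian fit returning the center
    relative to the ROI center (same convention as phasor_localize)."""
    size = roi.shape[0]
    h = size // 2

    def residual(theta):
        x0, y0, log_sigma, log_amp, bg = theta
        model = np.exp(log_amp) * integrated_gaussian_roi(x0, y0, np.exp(log_sigma), size) + bg
        return (model - roi).ravel()

    peak = np.unravel_index(np.argmax(roi), roi.shape)
    theta0 = [peak[1] + 0.5, peak[0] + 0.5, np.log(1.3), np.log(max(roi.sum(), 1.0)), float(roi.min())]
    sol = least_squares(residual, theta0)
    return sol.x[0] - (h + 0.5), sol.x[1] - (h + 0.5)


class TestDogFilter:
    def test_constant_frame_zero(self):
        out = dog_filter(np.full((21, 21), 5.0), 1.0, 2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_impulse_response_is_kernel_difference(self):
        frame = np.zeros((33, 33))
        frame[16, 16] = 1.0
        out = dog_filter(frame, 1.0, 2.0)
        from scipy.ndimage import gaussian_filter

        expected = gaussian_filter(frame, 1.0) - gaussian_filter(frame, 2.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert np.unravel_index(np.argmax(out), out.shape) == (16, 16)

    def test_linearity(self, rng):
        frame = rng.uniform(0, 10, size=(16, 16))
        np.testing.assert_allclose(
            dog_filter(3.5 * frame, 1.0, 2.0), 3.5 * dog_filter(frame, 1.0, 2.0), atol=1e-9
        )

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((4, 4, 4)), 1.0, 2.0)

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((8, 8)), 2.0, 1.0)


class TestFindCandidates:
    def test_blank_frames_empty(self):
        frame = np.zeros((32, 32))
        assert find_candidates(frame, frame, DetectionParams()) == []

    def test_single_gaussian_single_peak(self):
        frame = np.zeros((40, 40))
        frame += integrated_gaussian_roi(20.5, 10.5, 1.3, size=40, photons=5000)
        dog = dog_filter(frame, 1.0, 2.0)
        peaks = find_candidates(dog, frame, DetectionParams())
        assert peaks == [(10, 20)]

    def test_two_separated_gaussians_two_peaks(self):
        frame = np.zeros((40, 40))
        frame += integrated_gaussian_roi(10.5, 20.5, 1.3, size=40, photons=5000)
        frame += integrated_gaussian_roi(30.5, 20.5, 1.3, size=40, photons=5000)
        dog = dog_filter(frame, 1.0, 2.0)
        peaks = find_candidates(dog, frame, DetectionParams())
        assert set(peaks) == {(20, 10), (20, 30)}

    def test_close_pair_both_dropped(self):
        frame = np.zeros((40, 40))
        frame += integrated_gaussian_roi(18.5, 20.5, 1.3, size=40, photons=5000)
        frame += integrated_gaussian_roi(22.5, 20.5, 1.3, size=40, photons=5000)
        dog = dog_filter(frame, 1.0, 2.0)
        peaks = find_candidates(dog, frame, DetectionParams())  # separation 4 < 6
        assert peaks == []

    def test_plateau_resolved_to_smallest_row_col(self):
        frame = np.full((20, 20), 1.0)
        frame[9:11, 9:11] = 100.0  # 2x2 plateau
        dog = dog_filter(frame, 1.0, 2.0)
        peaks = find_candidates(dog, frame, DetectionParams(threshold_k=1))
        assert peaks == [(9, 9)]

    def test_border_peaks_discarded(self):
        frame = np.zeros((20, 20))
        frame[1, 1] = 1000.0
        dog = dog_filter(frame, 1.0, 2.0)
        assert find_candidates(dog, frame, DetectionParams()) == []


class TestPhasor:
    def test_centered_gaussian_returns_zero(self):
        roi = integrated_gaussian_roi(3.5, 3.5, 1.3, size=7)
        dx, dy, mag = phasor_localize(roi)
        assert abs(dx) < 1e-9 and abs(dy) < 1e-9
        assert mag > 0

    @pytest.mark.parametrize("u0,v0,want_dx,want_dy", [
        (5, 3, 2.0, 0.0), (0, 0, -3.0, -3.0), (3, 3, 0.0, 0.0), (6, 1, 3.0, -2.0),
    ])
    def test_delta_pixel_exact_offsets(self, u0, v0, want_dx, want_dy):
        roi = np.zeros((7, 7))
        roi[v0, u0] = 1.0
        dx, dy, _ = phasor_localize(roi)
        assert dx == pytest.approx(want_dx, abs=1e-12)
        assert dy == pytest.approx(want_dy, abs=1e-12)

    def test_delta_matches_direct_dft_phase(self, rng):
        # independent direct evaluation of the first DFT coefficient phase
        n = 7
        for _ in range(10):
            u0, v0 = rng.integers(0, n, size=2)
            roi = np.zeros((n, n))
            roi[v0, u0] = rng.uniform(0.5, 2.0)
            fx = sum(roi[v, u] * np.exp(-2j * np.pi * u / n) for v in range(n) for u in range(n))
            expect_dx = (-np.angle(fx)) % (2 * np.pi) / (2 * np.pi) * n - n // 2
            dx, dy, _ = phasor_localize(roi)
            assert dx == pytest.approx(expect_dx, abs=1e-9)

    def test_constant_roi_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            phasor_localize(np.full((7, 7), 3.0))

    def test_even_or_rectangular_roi_rejected(self):
        with pytest.raises(ValueError):
            phasor_localize(np.zeros((6, 6)))
        with pytest.raises(ValueError):
            phasor_localize(np.zeros((7, 5)))

    def test_subpixel_scan_accuracy_vs_gaussian_fit_oracle(self):
        # noiseless pixel-integrated PSF scanned over sub-pixel offsets:
        # phasor must stay within 0.05 px of the true (= oracle) position
        offsets = np.linspace(-0.5, 0.5, 11)
        for off in offsets:
            roi = integrated_gaussian_roi(3.5 + off, 3.5 - off / 2, 1.3, size=7, photons=1000)
            dx, dy, _ = phasor_localize(roi)
            ox, oy = gaussian_fit_oracle(roi)
            assert abs(dx - off) < 0.05
            assert abs(dy - (-off / 2)) < 0.05
            assert abs(ox - off) < 1e-3  # oracle itself is near-exact here
            assert abs(dx - ox) < 0.05


class TestLocalizeMovie:
    def test_blank_movie_empty_table(self):
        movie = sk.Movie(np.zeros((5, 32, 32)))
        table = sk.localize_movie(movie)
        assert len(table) == 0

    def test_five_emitters_recovered_accurately(self):
        positions = np.array([[8.3, 9.7], [24.2, 7.4], [10.6, 25.2], [26.8, 27.1], [16.5, 16.5]])
        em = sk.EmitterModel(positions, k_on=1.0, k_off=0.0, photons_per_frame=8000,
                             initial_on_fraction=1.0)
        noise = sk.NoiseModel(background_offset=10, read_noise_sigma=1.0)
        movie, _ = sk.simulate_movie(em, noise, None, 20, (36, 36), seed=21)
        table = sk.localize_movie(movie, None, DetectionParams(threshold_k=6))
        assert len(table) == 5 * 20
        errs = []
        for tx, ty in positions:
            sel = (np.abs(table.df["x"] - tx) < 1) & (np.abs(table.df["y"] - ty) < 1)
            assert sel.sum() == 20
            errs.append(np.hypot(table.df["x"][sel] - tx, table.df["y"][sel] - ty))
        rms = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rms < 0.1

    def test_translation_equivariance(self):
        em = sk.EmitterModel([[12.3, 14.6]], k_on=1.0, k_off=0.0, photons_per_frame=5000,
                             initial_on_fraction=1.0)
        noise = sk.NoiseModel(background_offset=5, poisson=False, read_noise_sigma=0.0)
        movie, _ = sk.simulate_movie(em, noise, None, 1, (40, 40), seed=0)
        shifted = sk.Movie(np.roll(movie.data, (3, 5), axis=(1, 2)))
        t1 = sk.localize_movie(movie)
        t2 = sk.localize_movie(shifted)
        assert len(t1) == len(t2) == 1
        assert t2.df["x"][0] - t1.df["x"][0] == pytest.approx(5.0, abs=1e-9)
        assert t2.df["y"][0] - t1.df["y"][0] == pytest.approx(3.0, abs=1e-9)

    def test_localization_never_outside_roi(self, blinking_movie):
        movie, _ = blinking_movie
        filt = sk.temporal_median_filter(movie, sk.MedianFilterParams(51), clamp=False)
        table = sk.localize_movie(movie, filt, DetectionParams())
        # x = col + 0.5 + dx with |dx| <= 3.5 inside a 7x7 ROI
        frac_x = table.df["x"] - np.round(table.df["x"] - 0.5) - 0.5
        assert len(table) > 0
        assert (np.abs(frac_x) <= 3.5 + 1e-9).all()

    def test_shape_mismatch_rejected(self):
        raw = sk.Movie(np.zeros((3, 16, 16)))
        filt = sk.Movie(np.zeros((3, 16, 8)))
        with pytest.raises(ValueError):
            sk.localize_movie(raw, filt)
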