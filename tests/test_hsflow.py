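"""Horn–Schunck optical flow: translation/rotation oracles, energy descent."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from heartflow.core import ImageSequence
from heartflow.hsflow import HornSchunck, HSParams, estimate_flow, flow_sequence

from conftest import small_phantom, speckle

INTERIOR = (slice(8, -8), slice(8, -8))


def shift_image(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Move image content by (+dx, +dy) via bilinear resampling."""
    h, w = img.shape
    y, x = np.mgrid[0:h, 0:w]
    return map_coordinates(img, [y - dy, x - dx], order=1, mode="nearest")


def ssd_shift_oracle(a: np.ndarray, b: np.ndarray, max_shift=2.0, step=0.125):
    """Brute-force global shift minimizing the sum of squared differences."""
    best = (np.inf, 0.0, 0.0)
    m = int(np.ceil(max_shift)) + 2
    core_a = a[m:-m, m:-m]
    for dx in np.arange(-max_shift, max_shift + step / 2, step):
        for dy in np.arange(-max_shift, max_shift + step / 2, step):
            moved = shift_image(b, -dx, -dy)[m:-m, m:-m]
            ssd = float(((moved - core_a) ** 2).sum())
            if ssd < best[0]:
                best = (ssd, dx, dy)
    return best[1], best[2]


class TestValidation:
    def test_shape_mismatch_rejected(self, speckle_img):
        with pytest.raises(ValueError):
            estimate_flow(speckle_img, speckle_img[:-2])

    def test_nonfinite_pixels_rejected(self, speckle_img):
        bad = speckle_img.copy()
        bad[3, 3] = np.nan
        with pytest.raises(ValueError):
            estimate_flow(speckle_img, bad)

    def test_tiny_frames_rejected(self):
        img = np.zeros((4, 4))
        with pytest.raises(ValueError):
            estimate_flow(img, img)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            HSParams(alpha=0.0)
        with pytest.raises(ValueError):
            HSParams(pyramid_scale=1.5)


class TestDegenerateInputs:
    def test_identical_frames_zero_flow(self, speckle_img):
        f = estimate_flow(speckle_img, speckle_img)
        assert np.all(f.u == 0.0)
        assert np.all(f.v == 0.0)

    def test_featureless_frames_zero_flow(self):
        const = np.full((32, 32), 0.5)
        f = estimate_flow(const, const + 0.0)
        np.testing.assert_array_equal(f.u, 0.0)
        np.testing.assert_array_equal(f.v, 0.0)

    def test_grad_strength_nonnegative_and_shaped(self, speckle_img):
        f = estimate_flow(speckle_img, speckle_img)
        assert f.grad_strength.shape == speckle_img.shape
        assert (f.grad_strength >= 0).all()


class TestTranslationOracle:
    @pytest.mark.parametrize("dx,dy", [(0.5, 0.0), (0.0, -0.5), (0.3, 0.4)])
    def test_subpixel_translation_recovered(self, speckle_img, dx, dy):
        moved = shift_image(speckle_img, dx, dy)
        f = estimate_flow(speckle_img, moved)
        assert f.u[INTERIOR].mean() == pytest.approx(dx, abs=0.1)
        assert f.v[INTERIOR].mean() == pytest.approx(dy, abs=0.1)

    def test_agrees_with_ssd_oracle(self, speckle_img):
        dx, dy = 0.75, -0.25
        moved = shift_image(speckle_img, dx, dy)
        ox, oy = ssd_shift_oracle(speckle_img, moved)
        f = estimate_flow(speckle_img, moved)
        assert f.u[INTERIOR].mean() == pytest.approx(ox, abs=0.1)
        assert f.v[INTERIOR].mean() == pytest.approx(oy, abs=0.1)

    def test_flow_magnitude_bounded_by_oracle_shift(self, speckle_img):
        moved = shift_image(speckle_img, 1.0, 0.5)
        ox, oy = ssd_shift_oracle(speckle_img, moved)
        f = estimate_flow(speckle_img, moved)
        bound = np.hypot(ox, oy) + 0.5
        assert f.magnitude()[INTERIOR].max() <= bound

    def test_pyramid_recovers_large_shift(self, speckle_img):
        moved = shift_image(speckle_img, 2.0, 0.0)
        f = estimate_flow(speckle_img, moved, HSParams(pyramid_levels=2))
        assert f.u[INTERIOR].mean() == pytest.approx(2.0, abs=0.15)


class TestRotationAndEnergy:
    def test_small_rotation_field_recovered(self):
        img = speckle((64, 64), seed=3)
        omega = 0.02  # ≤ 1.3 px motion at the corners
        h, w = img.shape
        cy, cx = (h - 1) / 2, (w - 1) / 2
        y, x = np.mgrid[0:h, 0:w]
        # inverse rotation sampling: image content rotates by +omega
        xs = cx + np.cos(omega) * (x - cx) + np.sin(omega) * (y - cy)
        ys = cy - np.sin(omega) * (x - cx) + np.cos(omega) * (y - cy)
        rotated = map_coordinates(img, [ys, xs], order=1, mode="nearest")
        f = estimate_flow(img, rotated)
        true_u = -omega * (y - cy)
        true_v = omega * (x - cx)
        err = np.hypot(f.u - true_u, f.v - true_v)[INTERIOR]
        assert np.median(err) < 0.15

    @pytest.mark.parametrize("seed", [0, 1])
    def test_energy_monotone_nonincreasing(self, seed):
        img = speckle((24, 24), grain_px=1.5, seed=seed)
        moved = shift_image(img, 0.4, -0.3)
        _, energies = estimate_flow(
            img, moved, HSParams(pyramid_levels=1, max_iter=50), track_energy=True
        )
        diffs = np.diff(energies)
        assert (diffs <= 1e-9 * max(energies)).all()


class TestSequences:
    def test_sequence_yields_t_minus_1_fields(self, burst_25_05):
        seq, _ = burst_25_05
        short = ImageSequence(seq.frames[:6], seq.pixel_size_um, seq.frame_rate_hz)
        flows = flow_sequence(short)
        assert len(flows) == 5

    def test_single_frame_rejected(self, burst_25_05):
        seq, _ = burst_25_05
        one = ImageSequence(seq.frames[:1], seq.pixel_size_um, seq.frame_rate_hz)
        with pytest.raises(ValueError):
            flow_sequence(one)

    def test_phantom_flow_matches_ground_truth(self, burst_25_05, burst_flows):
        """Interior flow error vs the analytic displacement field."""
        _, gt = burst_25_05
        meds = []
        for j in range(8):  # one full beat period
            u, v = gt.displacement(j)
            core = gt.chamber_mask(0, j, shrink=0.8)
            err = np.hypot(burst_flows[j].u - u, burst_flows[j].v - v)[core]
            meds.append(np.median(err))
        assert max(meds) < 0.15

    def test_reversed_sequence_negates_flow(self, burst_25_05):
        seq, _ = burst_25_05
        fwd = flow_sequence(
            ImageSequence(seq.frames[:5], seq.pixel_size_um, seq.frame_rate_hz)
        )
        rev = flow_sequence(
            ImageSequence(seq.frames[4::-1], seq.pixel_size_um, seq.frame_rate_hz)
        )
        for k in range(4):
            resid = np.hypot(
                fwd[k].u + rev[3 - k].u, fwd[k].v + rev[3 - k].v
            )[INTERIOR]
            assert np.median(resid) < 0.06


class TestBrightnessMatching:
    def test_mean_matching_suppresses_offset_induced_flow(self, speckle_img):
        """A global brightness step violates brightness constancy; the
        optional per-frame mean matching restores near-zero flow."""
        brighter = speckle_img + 0.05
        plain = estimate_flow(speckle_img, brighter)
        matched = estimate_flow(speckle_img, brighter,
                                HSParams(match_means=True))
        assert np.abs(matched.u).max() < 1e-9
        assert np.abs(matched.u).mean() <= np.abs(plain.u).mean()


class TestPersistence:
    def test_flow_save_load_round_trip(self, tmp_path, speckle_img):
        from heartflow.hsflow import load_flow, save_flow

        f = estimate_flow(speckle_img, shift_image(speckle_img, 0.5, 0.0))
        save_flow(tmp_path / "f.npz", f)
        g = load_flow(tmp_path / "f.npz")
        np.testing.assert_allclose(g.u, f.u, atol=1e-6)
        np.testing.assert_allclose(g.v, f.v, atol=1e-6)
        np.testing.assert_allclose(g.grad_strength, f.grad_strength, atol=1e-6)


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        hs = HornSchunck(alpha=0.2, pyramid_levels=3)
        params = hs.get_params()
        assert params["alpha"] == 0.2
        clone = HornSchunck().set_params(**params)
        assert clone.get_params() == params

    def test_transform_accepts_arrays(self, speckle_img):
        stack = np.stack([speckle_img, shift_image(speckle_img, 0.5, 0.0)])
        flows = HornSchunck().fit().transform(stack)
        assert len(flows) == 1
        assert flows[0].u[INTERIOR].mean() == pytest.approx(0.5, abs=0.1)
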