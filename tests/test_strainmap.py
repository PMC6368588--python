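"""Strain tensor, divergence maps, weighted smoothing, strain integration."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from heartflow.core import FlowField
from heartflow.strainmap import (
    SmoothingSpec,
    StrainMapper,
    ellipse_mask,
    integrate_strain,
    region_mean_series,
    smooth_weighted,
    strain_tensor,
    volumetric_strain_rate,
)

from conftest import small_phantom

IN = (slice(2, -2), slice(2, -2))


def make_flow(u, v):
    return FlowField(u=u, v=v, grad_strength=np.ones_like(np.asarray(u, dtype=float)))


def grid(n=32):
    y, x = np.mgrid[0:n, 0:n]
    return x.astype(float), y.astype(float)


class TestStrainTensor:
    def test_uniaxial_stretch_exact_on_linear_field(self):
        x, y = grid()
        s = strain_tensor(make_flow(0.05 * x, np.zeros_like(x)))
        np.testing.assert_allclose(s.e_xx[IN], 0.05, atol=1e-12)
        np.testing.assert_allclose(s.e_yy[IN], 0.0, atol=1e-12)
        np.testing.assert_allclose(s.e_xy[IN], 0.0, atol=1e-12)

    def test_rigid_rotation_strain_free(self):
        x, y = grid()
        omega = 0.03
        s = strain_tensor(make_flow(-omega * y, omega * x))
        for comp in (s.e_xx, s.e_yy, s.e_xy):
            np.testing.assert_allclose(comp[IN], 0.0, atol=1e-12)

    def test_div_is_trace_pointwise(self):
        rng = np.random.default_rng(0)
        u = gaussian_filter(rng.standard_normal((32, 32)), 2)
        v = gaussian_filter(rng.standard_normal((32, 32)), 2)
        s = strain_tensor(make_flow(u, v))
        np.testing.assert_allclose(s.div, s.e_xx + s.e_yy, atol=1e-15)
        np.testing.assert_allclose(volumetric_strain_rate(make_flow(u, v)), s.div)

    def test_matches_independent_finite_differences(self):
        """Oracle: explicit loop-based central differences on a smooth field."""
        rng = np.random.default_rng(1)
        u = gaussian_filter(rng.standard_normal((20, 20)), 1.5)
        v = gaussian_filter(rng.standard_normal((20, 20)), 1.5)
        s = strain_tensor(make_flow(u, v))
        for i in range(1, 19):
            for j in range(1, 19):
                e_xx = (u[i, j + 1] - u[i, j - 1]) / 2
                e_yy = (v[i + 1, j] - v[i - 1, j]) / 2
                e_xy = ((u[i + 1, j] - u[i - 1, j]) / 2 + (v[i, j + 1] - v[i, j - 1]) / 2) / 2
                assert s.e_xx[i, j] == pytest.approx(e_xx, abs=1e-13)
                assert s.e_yy[i, j] == pytest.approx(e_yy, abs=1e-13)
                assert s.e_xy[i, j] == pytest.approx(e_xy, abs=1e-13)


class TestDivergence:
    def test_uniform_dilation_gives_2alpha(self):
        x, y = grid()
        alpha = 0.04
        div = volumetric_strain_rate(make_flow(alpha * (x - 10), alpha * (y - 3)))
        np.testing.assert_allclose(div[IN], 2 * alpha, atol=1e-12)

    def test_translation_divergence_free(self):
        x, y = grid()
        div = volumetric_strain_rate(make_flow(np.full_like(x, 0.7), np.full_like(y, -0.2)))
        np.testing.assert_allclose(div, 0.0, atol=1e-12)

    def test_phantom_peak_rate_within_10pct(self, burst_25_05, burst_flows):
        """Interior mean divergence matches the analytic rate at peak."""
        _, gt = burst_25_05
        true_rates = gt.region_rate_series(0)
        j = int(np.argmax(np.abs(true_rates)))
        core = gt.chamber_mask(0, j, shrink=0.6)
        measured = volumetric_strain_rate(burst_flows[j])[core].mean()
        assert measured == pytest.approx(true_rates[j], rel=0.10)


class TestWeightedSmoothing:
    SPEC = SmoothingSpec(sigma_um=11.0, weight_mode="gradient")

    def test_constant_field_preserved(self):
        out = smooth_weighted(np.full((32, 32), 3.7), np.ones((32, 32)), self.SPEC, 2.5)
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_uniform_weights_reduce_to_gaussian(self):
        rng = np.random.default_rng(2)
        field = rng.standard_normal((40, 40))
        out = smooth_weighted(field, np.ones_like(field), self.SPEC, 2.5)
        plain = gaussian_filter(field, 11.0 / 2.5, mode="nearest")
        np.testing.assert_allclose(out, plain, atol=1e-10)

    def test_zero_weight_stripe_filled_from_neighbors(self):
        """Oracle: direct per-pixel weighted sums with an explicit kernel."""
        rng = np.random.default_rng(3)
        field = rng.standard_normal((24, 24))
        w = np.ones_like(field)
        w[:, 10:13] = 0.0
        spec = SmoothingSpec(sigma_um=2.0, weight_mode="gradient")
        out = smooth_weighted(field, w, spec, 1.0)
        # brute-force normalized convolution at a few stripe pixels
        sigma = 2.0
        half = 9
        for (i, j) in [(12, 11), (6, 10), (18, 12)]:
            num = den = 0.0
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    ii = min(max(i + di, 0), 23)
                    jj = min(max(j + dj, 0), 23)
                    g = np.exp(-(di**2 + dj**2) / (2 * sigma**2))
                    num += g * w[ii, jj] * field[ii, jj]
                    den += g * w[ii, jj]
            assert out[i, j] == pytest.approx(num / den, rel=5e-3)

    def test_weighted_mean_preserved_for_interior_support(self):
        rng = np.random.default_rng(4)
        field = np.zeros((48, 48))
        w = np.zeros((48, 48))
        field[16:32, 16:32] = rng.standard_normal((16, 16))
        w[16:32, 16:32] = rng.uniform(0.5, 2.0, (16, 16))
        out = smooth_weighted(field, w, self.SPEC, 2.5)
        wk = gaussian_filter(w, 11.0 / 2.5, mode="nearest")
        before = (w * field).sum() / w.sum()
        after = (wk * out).sum() / wk.sum()
        assert after == pytest.approx(before, abs=1e-6)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            smooth_weighted(np.ones((16, 16)), np.zeros((16, 16)), self.SPEC, 1.0)


class TestIntegration:
    def test_constant_rate_accumulates_linearly(self):
        trace = integrate_strain(np.full(50, 0.01), frame_rate_hz=20.0)
        assert trace.values[-1] == pytest.approx(0.5)
        assert trace.sampling_rate_hz == 20.0

    def test_whole_periods_integrate_to_zero(self):
        t = np.arange(200)
        rate = 0.05 * np.sin(2 * np.pi * t / 20)  # 10 whole periods
        trace = integrate_strain(rate, 20.0)
        assert abs(trace.values[-1]) < 1e-6 * 0.05 * 20

    def test_differencing_returns_rates(self):
        rng = np.random.default_rng(5)
        rates = rng.standard_normal(100)
        trace = integrate_strain(rates, 20.0)
        recovered = np.diff(np.concatenate([[0.0], trace.values]))
        np.testing.assert_allclose(recovered, rates, atol=1e-12)

    def test_empty_region_rejected(self, burst_flows):
        maps = [f.u for f in burst_flows[:3]]
        with pytest.raises(ValueError):
            region_mean_series(maps, np.zeros((64, 64), dtype=bool))

    def test_detrend_removes_linear_drift(self):
        t = np.arange(300)
        rate = 0.02 * np.sin(2 * np.pi * t / 8) + 0.001
        plain = integrate_strain(rate, 20.0)
        detr = integrate_strain(rate, 20.0, detrend=True)
        assert np.ptp(detr.values) < np.ptp(plain.values)


class TestPhantomAmplitudeLinearity:
    def test_integrated_amplitude_linear_in_a0(self):
        """Peak-to-peak integrated strain tracks ln(1+A0): R² > 0.99."""
        from heartflow.beatline import BeatEstimator
        from heartflow.hsflow import flow_sequence

        a0s = np.array([0.2, 0.5, 1.0])
        amps = []
        for a0 in a0s:
            ph = small_phantom(f0=2.5, a0=float(a0))
            seq, gt = ph.generate_burst(0.0)
            flows = flow_sequence(seq)
            mask = gt.chamber_mask(0, 0, shrink=0.6)
            trace = StrainMapper().trace(flows, mask, seq.pixel_size_um, seq.frame_rate_hz)
            amps.append(BeatEstimator(band_hz=(1.5, 5.0)).fit(trace).amplitude_pp_)
        amps = np.array(amps)
        coef = np.polyfit(a0s, amps, 1)
        resid = amps - np.polyval(coef, a0s)
        r2 = 1 - (resid**2).sum() / ((amps - amps.mean()) ** 2).sum()
        assert r2 > 0.99
        assert coef[0] > 0  # increasing


class TestMasksAndMapper:
    def test_ellipse_mask_area(self):
        mask = ellipse_mask((64, 64), (32.0, 30.0), (12.0, 8.0))
        assert mask.sum() == pytest.approx(np.pi * 12 * 8, rel=0.03)

    def test_mapper_params_round_trip(self):
        m = StrainMapper(sigma_um=8.0, weight_mode="uniform", detrend=True)
        clone = StrainMapper().set_params(**m.get_params())
        assert clone.get_params() == m.get_params()
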