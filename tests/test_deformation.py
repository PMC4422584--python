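"""Displacement estimation, strain operator and frequency recovery."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vibrostim.deformation import (
    DeformationTimecourse,
    FeaturelessFrameError,
    MatchingParams,
    compute_strain,
    estimate_displacement,
    estimate_frequency,
    max_timecourse,
)
from vibrostim.fields import VectorField
from vibrostim.synthetic import BeadSimConfig, generate_bead_stack


def brute_force_gradient(u: np.ndarray, spacing: float, axis: int) -> np.ndarray:
    """Independent loop oracle: central 3-point interior, one-sided 2-point
    boundary differences."""
    u = np.moveaxis(u, axis, 0)
    out = np.empty_like(u, dtype=float)
    n = u.shape[0]
    for i in range(n):
        if i == 0:
            out[i] = (u[1] - u[0]) / spacing
        elif i == n - 1:
            out[i] = (u[-1] - u[-2]) / spacing
        else:
            out[i] = (u[i + 1] - u[i - 1]) / (2.0 * spacing)
    return np.moveaxis(out, 0, axis)


class TestEstimateDisplacement:
    def test_identical_frames_zero_field(self, bead_stack_noisy):
        cfg = bead_stack_noisy.config
        f0 = bead_stack_noisy.frames[0]
        vf = estimate_displacement(f0, f0, cfg.pixel_size_um)
        assert vf.valid.all()
        assert vf.max_displacement_um() < 0.1 * cfg.pixel_size_um

    def test_uniform_integer_shift_recovered(self, bead_stack_noisy):
        cfg = bead_stack_noisy.config
        f0 = bead_stack_noisy.frames[0]
        mov = np.roll(f0, shift=(-2, 3), axis=(0, 1))  # displacement (+3, -2) px
        vf = estimate_displacement(f0, mov, cfg.pixel_size_um)
        m = vf.valid
        assert m.mean() > 0.9
        assert np.abs(vf.ux[m] / cfg.pixel_size_um - 3.0).max() < 0.2
        assert np.abs(vf.uy[m] / cfg.pixel_size_um + 2.0).max() < 0.2

    def test_radial_field_rmse(self, bead_stack_clean, estimated_field_clean):
        """Default radial simulation, peak-deformation frame: vector RMSE vs
        ground truth below 0.3 px over the jointly valid nodes."""
        cfg = bead_stack_clean.config
        truth = bead_stack_clean.truth[1]
        vf = estimated_field_clean
        both = vf.valid & truth.valid
        assert both.sum() > 200
        err_px = np.hypot(vf.ux - truth.ux, vf.uy - truth.uy) / cfg.pixel_size_um
        assert np.sqrt(np.mean(err_px[both] ** 2)) < 0.3

    def test_featureless_frames_rejected(self):
        flat = np.full((128, 128), 9.0)
        with pytest.raises(FeaturelessFrameError):
            estimate_displacement(flat, flat, 0.4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_displacement(np.zeros((64, 64)), np.zeros((65, 64)), 0.4)


class TestComputeStrain:
    def grid(self, ux, uy, spacing=1.0):
        return VectorField((0.0, 0.0), spacing, ux, uy)

    def test_uniform_translation_zero_strain(self):
        vf = self.grid(np.full((6, 7), 3.1), np.full((6, 7), -1.2))
        sf = compute_strain(vf)
        assert np.allclose(sf.E, 0.0)
        assert np.allclose(sf.Ex, 0.0) and np.allclose(sf.Ey, 0.0)

    def test_linear_field_exact_everywhere(self):
        y, x = np.mgrid[0:6, 0:8].astype(float) * 2.0
        vf = self.grid(0.03 * x, 0.04 * y, spacing=2.0)
        sf = compute_strain(vf)
        assert np.allclose(sf.Ex, 0.03)
        assert np.allclose(sf.Ey, 0.04)
        assert np.allclose(sf.E, 0.05)

    @given(
        a=st.floats(-0.05, 0.05),
        b=st.floats(-0.05, 0.05),
        c=st.floats(-5.0, 5.0),
        d=st.floats(-5.0, 5.0),
    )
    def test_affine_fields_exact(self, a, b, c, d):
        """Finite differences are exact (to float tolerance) for affine
        displacement fields at interior and boundary nodes alike."""
        y, x = np.mgrid[0:5, 0:6].astype(float) * 1.5
        vf = self.grid(a * x + c, b * y + d, spacing=1.5)
        sf = compute_strain(vf)
        assert np.allclose(sf.Ex, a, atol=1e-12)
        assert np.allclose(sf.Ey, b, atol=1e-12)

    def test_quadratic_matches_brute_force_oracle(self):
        a = 0.004
        y, x = np.mgrid[0:5, 0:5].astype(float)
        ux = a * x**2
        uy = 0.5 * a * y**2 + 0.01 * x
        vf = self.grid(ux, uy, spacing=1.0)
        sf = compute_strain(vf)
        assert np.allclose(sf.Ex, brute_force_gradient(ux, 1.0, axis=1))
        assert np.allclose(sf.Ey, brute_force_gradient(uy, 1.0, axis=0))
        # interior columns follow the exact derivative 2 a x
        assert np.allclose(sf.Ex[:, 1:-1], 2 * a * x[:, 1:-1])

    def test_axis_swap_symmetry(self, rng):
        ux = rng.normal(size=(7, 7))
        uy = rng.normal(size=(7, 7))
        sf = compute_strain(self.grid(ux, uy))
        swapped = compute_strain(self.grid(uy.T, ux.T))
        assert np.allclose(swapped.E, sf.E.T)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            compute_strain(self.grid(np.zeros((1, 5)), np.zeros((1, 5))))

    def test_invalid_nodes_propagate(self):
        valid = np.ones((5, 5), dtype=bool)
        valid[2, 2] = False
        vf = VectorField((0, 0), 1.0, np.zeros((5, 5)), np.zeros((5, 5)), valid)
        sf = compute_strain(vf)
        assert not sf.valid[2, 2]
        assert not sf.valid[1, 2] and not sf.valid[2, 1]


class TestMaxTimecourse:
    def test_zero_amplitude_series_zero(self):
        cfg = BeadSimConfig(
            image_size_px=(128, 128),
            n_beads=250,
            probe_xy_px=(40.0, 64.0),
            amplitude_um=0.0,
            noise_sigma=0.0,
            duration_ms=6.0,
        )
        res = generate_bead_stack(cfg)
        tc = max_timecourse(res.truth, res.times_ms, probe_xy_um=cfg.probe_xy_um)
        assert np.allclose(tc.max_displacement_um, 0.0)
        assert np.allclose(tc.max_strain, 0.0)

    def test_period_peaks_and_strain_decay(self, bead_stack_noisy):
        res = bead_stack_noisy
        cfg = res.config
        tc = max_timecourse(res.truth, res.times_ms, probe_xy_um=cfg.probe_xy_um)
        spacing = np.diff(res.times_ms[tc.peak_indices])
        assert np.all(np.abs(spacing - 1000.0 / cfg.frequency_hz) <= cfg.frame_interval_ms)
        # envelope decays across per-period peaks (1 ms sampling wobbles the
        # phase slightly, hence the small tolerance)
        strains = tc.max_strain[tc.peak_indices]
        assert np.all(np.diff(strains) <= 0.02 * strains[:-1].max())
        assert strains[-1] < strains[0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            max_timecourse([], [])


def damped_series(freq_hz, seed, duration_ms=40.0, dt_ms=1.0, noise_um=0.1):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms + 0.5 * dt_ms, dt_ms)
    s = 6.0 * np.exp(-t / 50.0) * np.maximum(np.sin(2e-3 * np.pi * freq_hz * t), 0.0)
    noisy = np.abs(s + rng.normal(0.0, noise_um, size=t.size))
    return DeformationTimecourse(t, noisy, np.zeros_like(t), noisy)


class TestEstimateFrequency:
    def test_damped_sinusoid_200hz(self):
        tc = damped_series(200.0, seed=0, noise_um=0.0)
        est = estimate_frequency(tc)
        assert abs(est.frequency_hz - 200.0) / 200.0 < 0.03

    def test_constant_series_rejected(self):
        t = np.arange(0.0, 40.0, 1.0)
        tc = DeformationTimecourse(t, np.ones_like(t), np.zeros_like(t), np.ones_like(t))
        with pytest.raises(ValueError):
            estimate_frequency(tc)

    def test_default_simulation_within_band(self, bead_stack_noisy):
        """207 Hz sampled at 1 kHz: inter-peak estimate lands in [201, 213]."""
        res = bead_stack_noisy
        tc = max_timecourse(res.truth, res.times_ms, probe_xy_um=res.config.probe_xy_um)
        est = estimate_frequency(tc)
        assert 201.0 <= est.frequency_hz <= 213.0

    def test_image_pipeline_frequency_recovery(self):
        """Full pipeline (rendered frames -> matching -> peaks) on a reduced
        geometry still recovers the vibration frequency within a few percent."""
        cfg = BeadSimConfig(
            image_size_px=(144, 144),
            n_beads=300,
            probe_xy_px=(44.0, 72.0),
            duration_ms=25.0,
        )
        res = generate_bead_stack(cfg)
        params = MatchingParams(search_radius_px=18, warp_iterations=2)
        fields = [
            estimate_displacement(res.frames[0], frame, cfg.pixel_size_um, params)
            for frame in res.frames
        ]
        tc = max_timecourse(fields, res.times_ms, probe_xy_um=cfg.probe_xy_um)
        est = estimate_frequency(tc)
        assert abs(est.frequency_hz - cfg.frequency_hz) / cfg.frequency_hz < 0.05
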