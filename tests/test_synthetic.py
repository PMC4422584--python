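"""Generator contracts: seed reproducibility, ground-truth consistency."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from vibrostim.deformation import compute_strain
from vibrostim.fields import VectorField
from vibrostim.synthetic import (
    AdhesionSimConfig,
    BeadSimConfig,
    FretSimConfig,
    generate_adhesion_dishes,
    generate_bead_stack,
    generate_fret_stack,
)

SMALL_BEADS = BeadSimConfig(
    image_size_px=(128, 128), n_beads=250, probe_xy_px=(40.0, 64.0), duration_ms=6.0
)


class TestBeadStack:
    def test_seed_reproducibility_bitwise(self):
        a = generate_bead_stack(SMALL_BEADS)
        b = generate_bead_stack(replace(SMALL_BEADS, seed=SMALL_BEADS.seed))
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.bead_positions_um, b.bead_positions_um)
        c = generate_bead_stack(replace(SMALL_BEADS, seed=99))
        assert not np.array_equal(a.frames, c.frames)

    def test_zero_amplitude_frames_identical(self):
        res = generate_bead_stack(replace(SMALL_BEADS, amplitude_um=0.0, noise_sigma=0.0))
        for frame in res.frames[1:]:
            assert np.array_equal(frame, res.frames[0])

    def test_peak_spacing_matches_vibration_period(self, bead_stack_noisy):
        """At 207 Hz the per-period maxima of the true displacement series
        are ~4.83 ms apart."""
        res = bead_stack_noisy
        series = np.array([vf.max_displacement_um() for vf in res.truth])
        from vibrostim.deformation import find_period_peaks

        peaks = find_period_peaks(series)
        spacing = np.diff(res.times_ms[peaks])
        assert abs(spacing.mean() - 1000.0 / 207.0) <= 0.5

    def test_default_max_strain_in_printed_band(self, bead_stack_noisy):
        """Analytic strain of the configured field peaks at 45-55% over the
        visible (non-occluded) grid across the frame schedule."""
        res = bead_stack_noisy
        cfg = res.config
        tr = res.truth[0]
        gx, gy = tr.meshgrid_um()
        peak = max(
            np.nanmax(np.abs(cfg.analytic_strain(gx, gy, t)[2][tr.valid]))
            for t in res.times_ms
        )
        assert 0.45 <= peak <= 0.55

    def test_overlapping_bead_density_rejected(self):
        dense = replace(SMALL_BEADS, n_beads=4000)
        with pytest.raises(ValueError, match="overlap"):
            generate_bead_stack(dense)

    def test_truth_never_adds_displacement_under_probe(self, bead_stack_noisy):
        for vf in bead_stack_noisy.truth:
            assert not vf.valid.all() or bead_stack_noisy.config.occlusion_radius_um == 0

    def test_analytic_strain_matches_finite_differences(self):
        """Closed-form strain agrees with the finite-difference operator on
        the true field to <1% of the field maximum at spacing <= lambda/10."""
        cfg = BeadSimConfig()
        spacing = 0.5  # well under lambda/10; the 1/r terms near the probe
        # set the accuracy-limiting scale
        xs = np.arange(10.0, 90.0, spacing)
        ys = np.arange(20.0, 85.0, spacing)
        gx, gy = np.meshgrid(xs, ys)
        ux, uy = cfg.displacement(gx, gy, 1.0)
        r = np.hypot(gx - cfg.probe_xy_um[0], gy - cfg.probe_xy_um[1])
        vf = VectorField((xs[0], ys[0]), spacing, ux, uy, valid=r >= cfg.occlusion_radius_um)
        sf = compute_strain(vf)
        _, _, analytic = cfg.analytic_strain(gx, gy, 1.0)
        m = sf.valid & np.isfinite(analytic)
        scale = np.nanmax(analytic[m])
        assert np.max(np.abs(sf.E[m] - analytic[m])) / scale < 0.01


class TestFretStack:
    def test_seed_reproducibility(self, small_fret_config):
        a = generate_fret_stack(small_fret_config)
        b = generate_fret_stack(replace(small_fret_config, seed=small_fret_config.seed))
        assert np.array_equal(a.donor, b.donor)
        assert np.array_equal(a.acceptor, b.acceptor)

    def test_zero_rise_gives_zero_true_reldiff(self, small_fret_config):
        res = generate_fret_stack(replace(small_fret_config, rel_rise=0.0))
        basal = res.true_ratio[: res.stim_index].mean()
        assert (res.true_ratio[res.stim_index :].max() - basal) / basal == pytest.approx(0.0)

    def test_configured_reldiff_forced_by_construction(self, small_fret_config):
        res = generate_fret_stack(replace(small_fret_config, basal_ratio=1.0, rel_rise=0.25))
        basal = res.true_ratio[: res.stim_index].mean()
        reldiff = (res.true_ratio[res.stim_index :].max() - basal) / basal
        assert reldiff == pytest.approx(0.25, abs=1e-12)

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            FretSimConfig(stim_xy_px=(5.0, 5.0))

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            FretSimConfig(frame_times_s=(0.0, 30.0, 30.0, 100.0))
        with pytest.raises(ValueError):
            FretSimConfig(basal_ratio=0.0)


class TestAdhesionDishes:
    def test_seed_reproducibility(self):
        cfg = AdhesionSimConfig(n_cells=2000)
        a = generate_adhesion_dishes(cfg)
        b = generate_adhesion_dishes(replace(cfg, seed=cfg.seed))
        assert a.cells.equals(b.cells)
        assert a.screenshots.equals(b.screenshots)

    def test_after_subset_of_before(self, adhesion_default):
        cells = adhesion_default.cells
        assert set(cells.present_after.unique()) <= {0, 1}
        after = adhesion_default.positions(0, "after")
        before = adhesion_default.positions(0, "before")
        assert after.shape[0] <= before.shape[0]

    def test_zero_probabilities_keep_everything(self):
        cfg = AdhesionSimConfig(baseline_prob=0.0, edge_prob=0.0, n_cells=3000)
        res = generate_adhesion_dishes(cfg)
        assert res.cells.present_after.all()

    def test_uniform_detachment_survival_fraction(self):
        """Uniform p=0.5 over 10,000 cells: surviving fraction 0.5 +- 3 SE
        (binomial oracle: SE = sqrt(0.25 / n))."""
        cfg = AdhesionSimConfig(baseline_prob=0.5, edge_prob=0.5, n_cells=10000, seed=7)
        res = generate_adhesion_dishes(cfg)
        se = np.sqrt(0.25 / cfg.n_cells)
        assert abs(res.cells.present_after.mean() - 0.5) <= 3 * se

    def test_fewer_cells_than_screenshots_rejected(self):
        with pytest.raises(ValueError, match="fewer cells"):
            AdhesionSimConfig(n_cells=10, screenshots_per_dish=20)

    def test_edge_weaker_than_baseline_rejected(self):
        with pytest.raises(ValueError, match="periphery"):
            AdhesionSimConfig(baseline_prob=0.3, edge_prob=0.1)
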