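"""Ground-truthed synthetic inputs for every analysis stage.

Three generators emulate the raw microscopy data of a localized
substrate-vibration experiment, each returning the rendered data together
with the exact ground truth the downstream estimators should recover:

* :func:`generate_bead_stack` — frames of 1 µm fluorescent beads embedded in
  a gel, displaced by a probe-localized, radially decaying, exponentially
  damped oscillation ``u(p, t) = A0 exp(-r/lambda) exp(-t/tau)
  s(2 pi f t) d(p)`` with radial direction field ``d`` and a one-sided
  (pull-and-release) half-sine cycle ``s`` by default. Beads under the
  probe tip are occluded (not rendered) and the corresponding ground-truth
  nodes are flagged invalid, as in real images where the probe shadows the
  gel.
* :func:`generate_fret_stack` — donor/acceptor channel pairs of an
  elliptical cell whose acceptor/donor expectation ratio carries a calcium
  transient localized around the stimulation site, normalized so that the
  ROI-averaged response equals the configured fractional rise exactly.
* :func:`generate_adhesion_dishes` — before/after cell positions on a
  circular gel, each cell independently detached with a probability that
  increases toward the gel edge (logistic profile in distance from the
  edge, since shear is stronger at the periphery), plus randomly placed
  edge-touching screenshot fields of view.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .deformation import MatchingParams, matching_grid
from .fields import VectorField
from .fret import RoiSpec

__all__ = [
    "BeadSimConfig",
    "FretSimConfig",
    "AdhesionSimConfig",
    "BeadStackResult",
    "FretStackResult",
    "AdhesionSimResult",
    "generate_bead_stack",
    "generate_fret_stack",
    "generate_adhesion_dishes",
]


# --------------------------------------------------------------------------
# bead stacks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BeadSimConfig:
    """Bead-image simulation under a probe-localized damped oscillation.

    Defaults reproduce the characterized stimulation conditions: a ~207 Hz
    oscillation with displacement amplitude 8.8 µm decaying over ~40 µm from
    the probe and damping out within ~180 ms, imaged at 1,000 frames/s.
    ``occlusion_radius_um`` is the probe-tip shadow: no beads are rendered
    and ground truth is invalid within it.
    """

    image_size_px: tuple[int, int] = (256, 256)  # (ny, nx)
    pixel_size_um: float = 0.4
    n_beads: int = 1200
    bead_radius_um: float = 0.5
    probe_xy_px: tuple[float, float] = (64.0, 128.0)  # (x, y)
    amplitude_um: float = 8.8
    decay_length_um: float = 40.0
    frequency_hz: float = 207.0
    tau_ms: float = 50.0
    frame_interval_ms: float = 1.0
    duration_ms: float = 40.0
    noise_sigma: float = 15.0
    seed: int = 0
    oscillation: str = "half-sine"
    occlusion_radius_um: float = 12.0
    background: float = 200.0
    bead_peak: float = 1800.0
    max_overlap_fraction: float = 0.35

    def __post_init__(self) -> None:
        ny, nx = self.image_size_px
        if ny < 16 or nx < 16:
            raise ValueError("image must be at least 16x16 px")
        for name in (
            "pixel_size_um",
            "bead_radius_um",
            "decay_length_um",
            "frequency_hz",
            "tau_ms",
            "frame_interval_ms",
            "duration_ms",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.amplitude_um < 0 or self.noise_sigma < 0:
            raise ValueError("amplitude_um and noise_sigma must be >= 0")
        px, py = self.probe_xy_px
        if not (0 <= px < nx and 0 <= py < ny):
            raise ValueError("probe contact point must lie inside the image")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.oscillation not in ("half-sine", "sine"):
            raise ValueError("oscillation must be 'half-sine' or 'sine'")

    @property
    def probe_xy_um(self) -> tuple[float, float]:
        return (
            self.probe_xy_px[0] * self.pixel_size_um,
            self.probe_xy_px[1] * self.pixel_size_um,
        )

    @property
    def frame_times_ms(self) -> np.ndarray:
        n = int(round(self.duration_ms / self.frame_interval_ms)) + 1
        return np.arange(n) * self.frame_interval_ms

    def temporal_factor(self, t_ms) -> np.ndarray:
        """Damped oscillation time factor.

        Default ``"half-sine"``: ``exp(-t/tau) max(sin(2 pi f t), 0)`` —
        the probe pulls the gel away from rest once per cycle and releases
        it, so the displacement magnitude peaks at the vibration period
        1/f, matching how per-period peak frames are identified. The
        ``"sine"`` mode keeps the signed oscillation (magnitude peaks at
        half the period).
        """
        t = np.asarray(t_ms, dtype=float)
        osc = np.sin(2.0 * np.pi * self.frequency_hz * t / 1000.0)
        if self.oscillation == "half-sine":
            osc = np.maximum(osc, 0.0)
        return np.exp(-t / self.tau_ms) * osc

    def displacement(self, x_um, y_um, t_ms: float):
        """True displacement (ux, uy) in µm at positions and time.

        Radial direction field away from the probe contact point; zero at
        the probe point itself, where the direction is undefined.
        """
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        cx, cy = self.probe_xy_um
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        s = float(self.temporal_factor(t_ms))
        env = self.amplitude_um * np.exp(-r / self.decay_length_um) * s
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r > 0, env * dx / r, 0.0)
            uy = np.where(r > 0, env * dy / r, 0.0)
        return ux, uy

    def analytic_strain(self, x_um, y_um, t_ms: float):
        """Closed-form (Ex, Ey, E) of the configured field.

        For ``u = g(r) * (dx, dy) / r`` with ``g(r) = A0 exp(-r/lambda) s(t)``
        the normal gradients are ``Ex = g * (-dx^2/(lambda r^2) + dy^2/r^3)``
        and ``Ey = g * (-dy^2/(lambda r^2) + dx^2/r^3)``; the field is
        singular at the probe point (excluded by the occlusion radius,
        reported as NaN).
        """
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        cx, cy = self.probe_xy_um
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        lam = self.decay_length_um
        s = float(self.temporal_factor(t_ms))
        g = self.amplitude_um * np.exp(-r / lam) * s
        with np.errstate(invalid="ignore", divide="ignore"):
            ex = g * (-(dx**2) / (lam * r**2) + dy**2 / r**3)
            ey = g * (-(dy**2) / (lam * r**2) + dx**2 / r**3)
        ex = np.where(r > 0, ex, np.nan)
        ey = np.where(r > 0, ey, np.nan)
        return ex, ey, np.hypot(ex, ey)


@dataclass
class BeadStackResult:
    """Rendered bead frames plus exact per-frame ground truth."""

    frames: np.ndarray  # (T, ny, nx) uint16
    times_ms: np.ndarray
    truth: list[VectorField]  # on the matching grid, invalid under the probe
    bead_positions_um: np.ndarray  # (n, 2) rest positions
    config: BeadSimConfig


def _render_beads(shape, pos_px: np.ndarray, sigma_px: float, peak: float) -> np.ndarray:
    """Sum of 2-D Gaussian spots; each rendered on a +-4 sigma window."""
    ny, nx = shape
    img = np.zeros((ny, nx))
    w = max(2, int(np.ceil(4.0 * sigma_px)))
    for bx, by in pos_px:
        i0, i1 = int(np.floor(bx)) - w, int(np.floor(bx)) + w + 1
        j0, j1 = int(np.floor(by)) - w, int(np.floor(by)) + w + 1
        i0c, i1c = max(i0, 0), min(i1, nx)
        j0c, j1c = max(j0, 0), min(j1, ny)
        if i0c >= i1c or j0c >= j1c:
            continue
        xs = np.arange(i0c, i1c)
        ys = np.arange(j0c, j1c)
        gx = np.exp(-((xs - bx) ** 2) / (2.0 * sigma_px**2))
        gy = np.exp(-((ys - by) ** 2) / (2.0 * sigma_px**2))
        img[j0c:j1c, i0c:i1c] += peak * gy[:, None] * gx[None, :]
    return img


def generate_bead_stack(
    config: BeadSimConfig, params: MatchingParams | None = None
) -> BeadStackResult:
    """Render a bead-image stack under the configured displacement field.

    Each bead at rest position ``p`` appears at ``p + u(p, t)`` in frame
    ``t``; frame 0 (t = 0) is the resting reference. Ground truth is
    returned per frame as a :class:`VectorField` sampled on exactly the grid
    :func:`vibrostim.deformation.estimate_displacement` reports on (nodes
    inside the probe occlusion are invalid).

    Raises ``ValueError`` when the bead density is so high that more than
    ``config.max_overlap_fraction`` of beads touch a neighbour (displacement
    estimation would be ill-posed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.image_size_px
    width_um = nx * cfg.pixel_size_um
    height_um = ny * cfg.pixel_size_um
    cx, cy = cfg.probe_xy_um

    # rejection-sample bead rest positions outside the probe shadow
    pos = np.empty((0, 2))
    while pos.shape[0] < cfg.n_beads:
        cand = rng.uniform(
            low=(0.0, 0.0), high=(width_um, height_um), size=(2 * cfg.n_beads, 2)
        )
        r = np.hypot(cand[:, 0] - cx, cand[:, 1] - cy)
        pos = np.vstack([pos, cand[r >= cfg.occlusion_radius_um]])
    pos = pos[: cfg.n_beads]

    if cfg.n_beads >= 2:
        nn_dist, _ = cKDTree(pos).query(pos, k=2)
        overlap_frac = float(np.mean(nn_dist[:, 1] < 2.0 * cfg.bead_radius_um))
        if overlap_frac > cfg.max_overlap_fraction:
            raise ValueError(
                f"bead overlap fraction {overlap_frac:.2f} exceeds "
                f"{cfg.max_overlap_fraction}: density too high for matching"
            )

    params = params or MatchingParams()
    xs_px, ys_px = matching_grid((ny, nx), params)
    gx_um = xs_px * cfg.pixel_size_um
    gy_um = ys_px * cfg.pixel_size_um
    gxx, gyy = np.meshgrid(gx_um, gy_um)
    node_r = np.hypot(gxx - cx, gyy - cy)
    node_valid = node_r >= cfg.occlusion_radius_um
    origin = (float(gx_um[0]), float(gy_um[0]))
    spacing = float(params.grid_step_px * cfg.pixel_size_um)

    sigma_px = (cfg.bead_radius_um / cfg.pixel_size_um) / 2.0
    times = cfg.frame_times_ms
    frames = np.empty((times.size, ny, nx), dtype=np.uint16)
    truth: list[VectorField] = []
    for k, t in enumerate(times):
        bux, buy = cfg.displacement(pos[:, 0], pos[:, 1], t)
        moved_px = np.column_stack(
            [(pos[:, 0] + bux) / cfg.pixel_size_um, (pos[:, 1] + buy) / cfg.pixel_size_um]
        )
        img = cfg.background + _render_beads((ny, nx), moved_px, sigma_px, cfg.bead_peak)
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        frames[k] = np.clip(img, 0, 65535).astype(np.uint16)

        tux, tuy = cfg.displacement(gxx, gyy, t)
        truth.append(VectorField(origin, spacing, tux, tuy, node_valid.copy()))

    return BeadStackResult(frames, times, truth, pos, cfg)


# --------------------------------------------------------------------------
# FRET stacks
# --------------------------------------------------------------------------


def _default_fret_times() -> tuple[float, ...]:
    # 30 s cadence before the stimulus at t = 95 s, 5 s cadence after
    return tuple(float(t) for t in (0, 30, 60, 90)) + tuple(
        float(t) for t in range(100, 165, 5)
    )


@dataclass(frozen=True)
class FretSimConfig:
    """Two-channel FRET simulation with a localized calcium transient.

    The acceptor/donor expectation ratio inside the elliptical cell is
    ``R0 * (1 + rel_rise * w(p)/w_roi * h(t))`` where ``w`` decays
    exponentially with distance from the stimulation site, ``w_roi`` is its
    mean over the analysis ROI and ``h`` is a rise/decay transient
    normalized to peak 1 over the frame schedule — so the true ROI-averaged
    RelDiff equals ``rel_rise`` exactly by construction. Pixel noise is
    Poisson on the signal plus a per-channel offset; background pixels carry
    only offset + noise.
    """

    image_size_px: tuple[int, int] = (192, 192)  # (ny, nx)
    pixel_size_um: float = 0.33
    cell_center_px: tuple[float, float] = (96.0, 96.0)  # (x, y)
    cell_axes_px: tuple[float, float] = (70.0, 55.0)  # (semi-x, semi-y)
    stim_xy_px: tuple[float, float] = (96.0, 96.0)
    roi_diameter_px: float = 50.0
    basal_ratio: float = 1.3
    rel_rise: float = 0.25  # configured RelDiff (delta R / R0)
    spatial_decay_um: float = 30.0
    tau_rise_s: float = 3.0
    tau_decay_s: float = 25.0
    frame_times_s: tuple[float, ...] = field(default_factory=_default_fret_times)
    stim_time_s: float = 95.0
    donor_level: float = 600.0
    gains: tuple[float, float] = (1.0, 1.0)  # (donor, acceptor)
    offsets: tuple[float, float] = (100.0, 120.0)
    background_level: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.basal_ratio > 0:
            raise ValueError("basal_ratio must be > 0")
        times = np.asarray(self.frame_times_s, dtype=float)
        if times.size < 2 or not np.all(np.diff(times) > 0):
            raise ValueError("frame schedule must be strictly increasing")
        if not (times[0] < self.stim_time_s < times[-1]):
            raise ValueError("stimulation time must fall inside the frame schedule")
        if self.stim_index == 0:
            raise ValueError("need at least one pre-stimulus frame")
        for name in ("pixel_size_um", "spatial_decay_um", "tau_rise_s", "tau_decay_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.rel_rise < 0:
            raise ValueError("rel_rise must be >= 0")
        ny, nx = self.image_size_px
        sx, sy = self.stim_xy_px
        r = self.roi_diameter_px / 2.0
        if sx - r < 0 or sy - r < 0 or sx + r > nx - 1 or sy + r > ny - 1:
            raise ValueError("analysis ROI extends outside the image")

    @property
    def stim_index(self) -> int:
        """Index of the first post-stimulus frame."""
        times = np.asarray(self.frame_times_s, dtype=float)
        return int(np.searchsorted(times, self.stim_time_s))

    @property
    def roi(self) -> RoiSpec:
        """Standard analysis ROI at the stimulation site, with a corner background patch."""
        return RoiSpec(
            center_px=self.stim_xy_px,
            diameter_px=self.roi_diameter_px,
            background_rect=(4, 4, 24, 24),
        )

    def transient(self, times_s) -> np.ndarray:
        """Normalized transient h(t): 0 before the stimulus, peak 1 over the schedule."""
        t = np.asarray(times_s, dtype=float)
        dt = t - self.stim_time_s
        raw = np.where(
            dt > 0,
            (1.0 - np.exp(-np.maximum(dt, 0) / self.tau_rise_s))
            * np.exp(-np.maximum(dt, 0) / self.tau_decay_s),
            0.0,
        )
        sched = np.asarray(self.frame_times_s, dtype=float) - self.stim_time_s
        sched_raw = np.where(
            sched > 0,
            (1.0 - np.exp(-np.maximum(sched, 0) / self.tau_rise_s))
            * np.exp(-np.maximum(sched, 0) / self.tau_decay_s),
            0.0,
        )
        peak = sched_raw.max()
        return raw / peak if peak > 0 else raw


@dataclass
class FretStackResult:
    """Donor/acceptor stacks plus the exact ROI ratio time course."""

    donor: np.ndarray  # (T, ny, nx) uint16
    acceptor: np.ndarray
    times_s: np.ndarray
    stim_index: int
    true_ratio: np.ndarray  # expectation of the measured ROI ratio per frame
    config: FretSimConfig


def generate_fret_stack(config: FretSimConfig) -> FretStackResult:
    """Render a two-channel FRET stack with a known calcium transient."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.image_size_px
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)

    ax, ay = cfg.cell_axes_px
    ccx, ccy = cfg.cell_center_px
    cell = ((xx - ccx) / ax) ** 2 + ((yy - ccy) / ay) ** 2 <= 1.0

    roi_mask = cfg.roi.mask((ny, nx))
    roi_in_cell = roi_mask & cell
    if not roi_in_cell.any():
        raise ValueError("analysis ROI does not overlap the cell")

    sx, sy = cfg.stim_xy_px
    dist_um = np.hypot(xx - sx, yy - sy) * cfg.pixel_size_um
    w = np.exp(-dist_um / cfg.spatial_decay_um)
    w_roi = w[roi_mask].mean()

    times = np.asarray(cfg.frame_times_s, dtype=float)
    h = cfg.transient(times)
    g_d, g_a = cfg.gains
    off_d, off_a = cfg.offsets

    donor = np.empty((times.size, ny, nx), dtype=np.uint16)
    acceptor = np.empty_like(donor)
    true_ratio = np.empty(times.size)
    for k in range(times.size):
        ratio_map = cfg.basal_ratio * (1.0 + cfg.rel_rise * (w / w_roi) * h[k])
        # diffuse background light adds everywhere, including under the cell,
        # so background subtraction from a cell-free region is exact in
        # expectation
        d_signal = cfg.background_level + np.where(cell, cfg.donor_level, 0.0)
        a_signal = cfg.background_level + np.where(
            cell, cfg.donor_level * ratio_map, 0.0
        )
        d_frame = rng.poisson(g_d * d_signal).astype(float) + off_d
        a_frame = rng.poisson(g_a * a_signal).astype(float) + off_a
        donor[k] = np.clip(d_frame, 0, 65535).astype(np.uint16)
        acceptor[k] = np.clip(a_frame, 0, 65535).astype(np.uint16)
        # expectation of the background-subtracted ROI means' ratio
        d_mean = g_d * (cfg.donor_level * cell[roi_mask].mean())
        a_mean = g_a * (cfg.donor_level * (ratio_map * cell)[roi_mask].mean())
        true_ratio[k] = a_mean / d_mean

    return FretStackResult(donor, acceptor, times, cfg.stim_index, true_ratio, cfg)


# --------------------------------------------------------------------------
# adhesion dishes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AdhesionSimConfig:
    """Before/after cell positions with edge-weighted random detachment.

    Detachment probability is logistic in the distance ``d`` from the gel
    edge: ``p(d) = baseline + (edge - baseline) * sigmoid((midpoint - d) /
    width)`` — close to ``edge_prob`` at the rim, decaying to
    ``baseline_prob`` toward the center, emulating the stronger shear at
    the periphery of an orbitally shaken dish. Screenshots are square
    fields of view whose outer edge touches the gel rim at random angles.
    """

    gel_radius_um: float = 7000.0
    n_cells: int = 20000
    baseline_prob: float = 0.02
    edge_prob: float = 0.17
    profile_midpoint_um: float = 300.0
    profile_width_um: float = 80.0
    fov_um: float = 800.0
    screenshots_per_dish: int = 20
    n_dishes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gel_radius_um > 0:
            raise ValueError("gel_radius_um must be > 0")
        for name in ("baseline_prob", "edge_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.edge_prob < self.baseline_prob:
            raise ValueError(
                "edge_prob must be >= baseline_prob (shear is stronger at the periphery)"
            )
        if not (0 < self.fov_um <= 2 * self.gel_radius_um):
            raise ValueError("fov_um must be in (0, gel diameter]")
        if self.screenshots_per_dish < 1 or self.n_dishes < 1:
            raise ValueError("need at least one screenshot and one dish")
        if self.n_cells < self.screenshots_per_dish:
            raise ValueError("fewer cells than screenshots require")
        if not (self.profile_width_um > 0 and self.profile_midpoint_um >= 0):
            raise ValueError("invalid detachment profile parameters")

    def detachment_probability(self, dist_from_edge_um) -> np.ndarray:
        """Detachment probability at a distance from the gel edge (µm)."""
        d = np.asarray(dist_from_edge_um, dtype=float)
        return self.baseline_prob + (self.edge_prob - self.baseline_prob) * expit(
            (self.profile_midpoint_um - d) / self.profile_width_um
        )


@dataclass
class AdhesionSimResult:
    """Cell table plus screenshot placements for the adhesion assay.

    ``cells`` columns: dish_id, cell_id, x_um, y_um, present_after (0/1),
    detach_prob (the exact per-cell probability, for oracle checks).
    ``screenshots`` columns: dish_id, shot_id, phase (before/after),
    center_x_um, center_y_um.
    """

    cells: pd.DataFrame
    screenshots: pd.DataFrame
    config: AdhesionSimConfig

    def positions(self, dish_id: int, phase: str = "before") -> np.ndarray:
        """(n, 2) cell positions of a dish; after-shaking keeps survivors only."""
        sub = self.cells[self.cells.dish_id == dish_id]
        if phase == "after":
            sub = sub[sub.present_after == 1]
        elif phase != "before":
            raise ValueError("phase must be 'before' or 'after'")
        return sub[["x_um", "y_um"]].to_numpy()

    def fov_centers(self, dish_id: int, phase: str) -> np.ndarray:
        """(k, 2) screenshot centers of a dish for one phase."""
        sub = self.screenshots[
            (self.screenshots.dish_id == dish_id) & (self.screenshots.phase == phase)
        ]
        return sub[["center_x_um", "center_y_um"]].to_numpy()


def generate_adhesion_dishes(config: AdhesionSimConfig) -> AdhesionSimResult:
    """Simulate before/after cell positions and screenshot placements.

    The after set is the before set with each cell independently removed
    with its radial detachment probability — cells are never added. Each
    phase gets ``screenshots_per_dish`` independent square fields of view
    centered ``fov_um / 2`` inside the rim at uniform random angles.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cell_rows = []
    shot_rows = []
    for dish in range(cfg.n_dishes):
        r = cfg.gel_radius_um * np.sqrt(rng.uniform(size=cfg.n_cells))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_cells)
        x, y = r * np.cos(theta), r * np.sin(theta)
        p_detach = cfg.detachment_probability(cfg.gel_radius_um - r)
        stays = rng.uniform(size=cfg.n_cells) >= p_detach
        cell_rows.append(
            pd.DataFrame(
                {
                    "dish_id": dish,
                    "cell_id": np.arange(cfg.n_cells),
                    "x_um": x,
                    "y_um": y,
                    "present_after": stays.astype(int),
                    "detach_prob": p_detach,
                }
            )
        )
        ring = cfg.gel_radius_um - cfg.fov_um / 2.0
        for phase in ("before", "after"):
            angles = rng.uniform(0.0, 2.0 * np.pi, size=cfg.screenshots_per_dish)
            shot_rows.append(
                pd.DataFrame(
                    {
                        "dish_id": dish,
                        "shot_id": np.arange(cfg.screenshots_per_dish),
                        "phase": phase,
                        "center_x_um": ring * np.cos(angles),
                        "center_y_um": ring * np.sin(angles),
                    }
                )
            )
    cells = pd.concat(cell_rows, ignore_index=True)
    screenshots = pd.concat(shot_rows, ignore_index=True)
    return AdhesionSimResult(cells, screenshots, cfg)


def with_seed(config, seed: int):
    """A copy of any simulation config with a different seed."""
    return replace(config, seed=seed)
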