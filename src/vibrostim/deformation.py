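"""Substrate deformation analysis from bead-image pairs.

The workflow mirrors how bead-embedded polyacrylamide gels are analysed after
a localized vibration stimulus:

1. :func:`estimate_displacement` — block matching by normalized
   cross-correlation between a resting reference frame and a displaced
   frame, with a coarse predictor pass, iterative window-deformation
   refinement and fractional-NCC subpixel localization, giving a gridded
   displacement field with per-node validity flags.
2. :func:`compute_strain` — normal strains ``Ex = dux/dx``, ``Ey = duy/dy``
   by finite differences (central 3-point stencils for interior nodes,
   one-sided 2-point differences at the boundaries) and total strain
   ``E = sqrt(Ex**2 + Ey**2)``.
3. :func:`max_timecourse` — per-frame maxima of displacement and strain plus
   the per-vibration-period peak frames, located from the beads nearest the
   probe (the probe's vertical motion itself is not directly observable).
4. :func:`estimate_frequency` — vibration frequency from the mean interval
   between per-period peaks, with a periodogram cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.feature import match_template

from .fields import StrainField, VectorField

__all__ = [
    "MatchingParams",
    "DeformationTimecourse",
    "FrequencyEstimate",
    "FeaturelessFrameError",
    "matching_grid",
    "estimate_displacement",
    "compute_strain",
    "max_timecourse",
    "find_period_peaks",
    "estimate_frequency",
]


class FeaturelessFrameError(ValueError):
    """Raised when a frame has too little texture for bead matching."""


@dataclass(frozen=True)
class MatchingParams:
    """Parameters of the block-matching displacement estimator.

    block_size_px
        Side of the square interrogation block taken from the reference
        frame (must be >= 8 px).
    search_radius_px
        Maximum displacement searched in each direction; must exceed the
        expected peak displacement in pixels.
    grid_step_px
        Spacing between grid nodes. The default of 8 px balances spatial
        resolution against bead content per block.
    min_correlation
        Nodes whose best normalized correlation falls below this are
        flagged invalid (deformed or empty blocks).
    subpixel
        Enable 3-point subpixel refinement of the correlation peak
        (Gaussian interpolation with parabolic fallback).
    min_texture_std
        Minimum intensity standard deviation of the reference frame below
        which it is considered featureless (no beads).
    coarse_factor
        Block-size multiplier of the coarse predictor pass (1 disables the
        predictor and searches the full radius directly).
    refine_radius_px
        Residual search radius of each warp-refinement iteration.
    warp_iterations
        Number of window-deformation iterations: the displaced frame is
        warped back by the current field estimate and the residual is
        re-matched, which removes the bias translation-only matching
        suffers where the field varies across a block.
    outlier_px
        Universal outlier threshold (px): nodes deviating from the median
        of their 3x3 valid neighbours by more than this are substituted
        during warping and flagged invalid in the returned field. Must
        exceed the genuine inter-node displacement difference (about
        max-strain times the grid step), or real gradients get clamped.
    max_block_shear_px
        Measurement limit of correlation matching: a node whose local
        displacement gradient times the half block exceeds this many
        pixels (about the blurred bead-image radius) is flagged invalid —
        the pattern deforms too much within one block for a translation
        fit.
    presmooth_sigma_px
        Gaussian blur applied to both frames before matching. Sub-pixel
        bead spots decorrelate under the slightest within-block shear; a
        mild blur keeps the correlation peak intact without biasing its
        position (0 disables).
    """

    block_size_px: int = 16
    search_radius_px: int = 24
    grid_step_px: int = 8
    min_correlation: float = 0.6
    subpixel: bool = True
    min_texture_std: float = 1e-6
    coarse_factor: int = 3
    refine_radius_px: int = 8
    warp_iterations: int = 3
    outlier_px: float = 5.0
    max_block_shear_px: float = 1.5
    presmooth_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if self.block_size_px < 8:
            raise ValueError("block_size_px must be >= 8")
        if self.search_radius_px < 1:
            raise ValueError("search_radius_px must be >= 1")
        if self.grid_step_px < 1:
            raise ValueError("grid_step_px must be >= 1")
        if self.coarse_factor < 1:
            raise ValueError("coarse_factor must be >= 1")
        if self.refine_radius_px < 1:
            raise ValueError("refine_radius_px must be >= 1")


def matching_grid(
    shape: tuple[int, int], params: MatchingParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates (x_px, y_px) of the matching grid nodes.

    Shared between the estimator and the synthetic generator so that
    ground-truth fields are sampled on exactly the grid the estimator
    reports on.
    """
    params = params or MatchingParams()
    half = params.block_size_px // 2
    margin = half + params.search_radius_px
    ny, nx = shape
    xs = np.arange(margin, nx - margin + 1, params.grid_step_px)
    ys = np.arange(margin, ny - margin + 1, params.grid_step_px)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("image too small for the requested matching parameters")
    return xs, ys


def _subpixel_offset(cm: float, c0: float, cp: float) -> float:
    """Peak offset from 3 correlation samples.

    Gaussian (log-parabola) interpolation when all samples are positive —
    exact for the Gaussian-shaped peaks that Gaussian bead spots produce —
    with a plain parabola as fallback. The integer argmax already brackets
    the true peak within half a pixel, so the offset is clamped to +-0.5;
    when a neighbour sample has fallen well off the peak the local fit is
    extrapolating outside its validity and the offset is left at 0.
    """
    if min(cm, cp) < 0.2 * c0:
        return 0.0
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm - 2.0 * l0 + lp
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def _ncc_at(template, window, oy: float, ox: float) -> float:
    """Zero-normalized cross-correlation of the template with the window
    patch whose top-left corner sits at fractional offset (oy, ox)."""
    bs_y, bs_x = template.shape
    yy, xx = np.mgrid[0:bs_y, 0:bs_x].astype(float)
    patch = ndimage.map_coordinates(
        window, [yy + oy, xx + ox], order=3, mode="nearest"
    )
    a = template - template.mean()
    b = patch - patch.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else 0.0


def _frac_refine(template, window, oy: float, ox: float) -> tuple[float, float]:
    """Sub-pixel peak localization by direct fractional NCC evaluation.

    Three-point interpolation of the integer correlation surface is
    unreliable on sparse bead patterns (rugged, asymmetric tails); the
    continuous NCC maximum, in contrast, sits exactly at the true
    alignment. Two per-axis parabolic steps on actually-evaluated
    fractional samples reach ~0.01 px.
    """
    for h in (0.5, 0.25, 0.1):
        c0 = _ncc_at(template, window, oy, ox)
        cm = _ncc_at(template, window, oy, ox - h)
        cp = _ncc_at(template, window, oy, ox + h)
        den = cm - 2.0 * c0 + cp
        if den < 0:
            ox += h * float(np.clip(0.5 * (cm - cp) / den, -1.0, 1.0))
        c0 = _ncc_at(template, window, oy, ox)
        cm = _ncc_at(template, window, oy - h, ox)
        cp = _ncc_at(template, window, oy + h, ox)
        den = cm - 2.0 * c0 + cp
        if den < 0:
            oy += h * float(np.clip(0.5 * (cm - cp) / den, -1.0, 1.0))
    return oy, ox


def _match_block(ref, mov, cx, cy, half, rad, shift_x, shift_y, params, frac=False):
    """NCC match of one block; returns (dx, dy, peak_corr, on_border) or None.

    The search window in ``mov`` is displaced by the integer predictor
    ``(shift_x, shift_y)`` so only ``rad`` px around the prediction are
    searched. With ``frac`` the sub-pixel offset comes from direct
    fractional NCC evaluation instead of 3-point interpolation.
    """
    ny, nx = ref.shape
    template = ref[cy - half : cy + half, cx - half : cx + half]
    if template.std() <= params.min_texture_std:
        return None
    y0 = cy - half - rad + shift_y
    y1 = cy + half + rad + shift_y
    x0 = cx - half - rad + shift_x
    x1 = cx + half + rad + shift_x
    if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
        return None
    window = mov[y0:y1, x0:x1]
    corr = match_template(window, template)
    py, px = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[py, px])
    on_border = px in (0, corr.shape[1] - 1) or py in (0, corr.shape[0] - 1)
    dx = float(px - rad + shift_x)
    dy = float(py - rad + shift_y)
    if params.subpixel and not on_border:
        if frac:
            oy, ox = _frac_refine(template, window, float(py), float(px))
            dx += ox - px
            dy += oy - py
        else:
            dx += _subpixel_offset(corr[py, px - 1], peak, corr[py, px + 1])
            dy += _subpixel_offset(corr[py - 1, px], peak, corr[py + 1, px])
    return dx, dy, peak, on_border


def _neighborhood_median(ux, uy, valid):
    """Per-node medians over the valid 3x3 neighbours (self excluded).

    Returns (med_x, med_y, has_neighbors); nodes without any valid
    neighbour get 0 medians.
    """
    ny, nx = ux.shape
    med_x = np.zeros((ny, nx))
    med_y = np.zeros((ny, nx))
    has = np.zeros((ny, nx), dtype=bool)
    for j in range(ny):
        for i in range(nx):
            j0, j1 = max(j - 1, 0), min(j + 2, ny)
            i0, i1 = max(i - 1, 0), min(i + 2, nx)
            m = valid[j0:j1, i0:i1].copy()
            m[j - j0, i - i0] = False
            if m.any():
                med_x[j, i] = np.median(ux[j0:j1, i0:i1][m])
                med_y[j, i] = np.median(uy[j0:j1, i0:i1][m])
                has[j, i] = True
    return med_x, med_y, has


def _median_fill(ux, uy, valid, outlier_px: float | None = None):
    """Regularize a sparse vector field for warping.

    Invalid nodes are filled with the median of their valid 3x3
    neighbours (0 when isolated). With ``outlier_px`` set, a valid node
    deviating from its neighbourhood median by more than that many pixels
    is also replaced (universal outlier substitution); compliant nodes
    keep their values so genuine steep gradients survive.
    Without it, every node takes the neighbourhood median (plain median
    filter).
    """
    med_x, med_y, has = _neighborhood_median(ux, uy, valid)
    out_x = np.where(has, med_x, 0.0)
    out_y = np.where(has, med_y, 0.0)
    if outlier_px is not None:
        dev = np.hypot(ux - med_x, uy - med_y)
        keep = valid & has & (dev <= outlier_px)
        keep |= valid & ~has  # nothing to compare against
        out_x = np.where(keep, ux, out_x)
        out_y = np.where(keep, uy, out_y)
    return out_x, out_y


def _flag_outliers(ux, uy, valid, outlier_px: float):
    """Validity mask with nodes deviating from the local median removed."""
    med_x, med_y, has = _neighborhood_median(ux, uy, valid)
    dev = np.hypot(ux - med_x, uy - med_y)
    return valid & (~has | (dev <= outlier_px))


def estimate_displacement(
    reference: np.ndarray,
    displaced: np.ndarray,
    pixel_size_um: float,
    params: MatchingParams | None = None,
) -> VectorField:
    """Estimate the displacement field between two bead frames.

    ``reference`` is the frame with the probe merely positioned but not
    moving; ``displaced`` is a frame during the vibration. Two-pass block
    matching by normalized cross-correlation: a coarse pass with blocks
    ``coarse_factor`` times larger builds a median-filtered predictor field
    over the full ``search_radius_px``, then each fine block searches only
    ``refine_radius_px`` around the interpolated prediction — individual
    beads look alike, so an unguided fine search would lock onto the wrong
    bead at large displacements.

    Returns a :class:`VectorField` in micrometres on the
    :func:`matching_grid`. Nodes are flagged invalid when the reference
    block is textureless, the correlation peak is below
    ``params.min_correlation``, or the refinement pegs at its search border
    (unconverged).
    """
    params = params or MatchingParams()
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(displaced, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("frames must have the same shape")
    if ref.ndim != 2:
        raise ValueError("frames must be 2-D")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    if ref.std() <= params.min_texture_std:
        raise FeaturelessFrameError(
            "reference frame has no texture: no beads detected"
        )
    if params.presmooth_sigma_px > 0:
        ref = ndimage.gaussian_filter(ref, params.presmooth_sigma_px)
        mov = ndimage.gaussian_filter(mov, params.presmooth_sigma_px)

    xs, ys = matching_grid(ref.shape, params)
    half = params.block_size_px // 2
    rad = params.search_radius_px

    # --- coarse predictor pass ---------------------------------------
    pred_x = np.zeros((ys.size, xs.size))
    pred_y = np.zeros((ys.size, xs.size))
    if params.coarse_factor > 1:
        half_c = (params.coarse_factor * params.block_size_px) // 2
        # a rough lock suffices for the predictor; the fine pass re-decides
        coarse_min_corr = min(params.min_correlation, 0.3)
        cux = np.zeros((ys.size, xs.size))
        cuy = np.zeros((ys.size, xs.size))
        cvalid = np.zeros((ys.size, xs.size), dtype=bool)
        ny, nx = ref.shape
        for j, cy in enumerate(ys):
            for i, cx in enumerate(xs):
                # clamp the coarse block inside the searchable area
                h = min(half_c, cy - rad, ny - rad - cy, cx - rad, nx - rad - cx)
                if h < params.block_size_px // 2:
                    continue
                res = _match_block(ref, mov, cx, cy, h, rad, 0, 0, params)
                if res is None:
                    continue
                dx, dy, peak, border = res
                if peak >= coarse_min_corr and not border:
                    cux[j, i], cuy[j, i] = dx, dy
                    cvalid[j, i] = True
        pred_x, pred_y = _median_fill(cux, cuy, cvalid)

    # --- iterative warp refinement ------------------------------------
    # Warp the displaced frame back by the current field estimate and
    # re-match the residual; with the local gradient absorbed into the
    # warp, block matching sees a nearly rigid pattern. Corrections are
    # lightly smoothed before application — blocks average the error over
    # their area, so unsmoothed updates leave node-scale error modes.
    from scipy.interpolate import RegularGridInterpolator

    ny, nx = ref.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    warp_x, warp_y = pred_x.copy(), pred_y.copy()
    ux = np.zeros((ys.size, xs.size))
    uy = np.zeros((ys.size, xs.size))
    valid = np.zeros((ys.size, xs.size), dtype=bool)
    for _ in range(max(params.warp_iterations, 1)):
        fx = RegularGridInterpolator(
            (ys, xs), warp_x, method="linear", bounds_error=False, fill_value=None
        )
        fy = RegularGridInterpolator(
            (ys, xs), warp_y, method="linear", bounds_error=False, fill_value=None
        )
        pts = np.column_stack([yy.ravel(), xx.ravel()])
        px_map = fx(pts).reshape(ny, nx)
        py_map = fy(pts).reshape(ny, nx)
        warped = ndimage.map_coordinates(
            mov, [yy + py_map, xx + px_map], order=3, mode="nearest"
        )
        last = _ == max(params.warp_iterations, 1) - 1
        ddx = np.zeros((ys.size, xs.size))
        ddy = np.zeros((ys.size, xs.size))
        valid[:] = False
        for j, cy in enumerate(ys):
            for i, cx in enumerate(xs):
                res = _match_block(
                    ref, warped, cx, cy, half, params.refine_radius_px,
                    0, 0, params, frac=last
                )
                if res is None:
                    continue
                rx, ry, peak, border = res
                if peak < params.min_correlation or border:
                    continue
                ddx[j, i], ddy[j, i] = rx, ry
                valid[j, i] = True
        wgt = valid.astype(float)
        norm = np.maximum(ndimage.gaussian_filter(wgt, 0.8), 1e-9)
        if last:
            # fractional refinement is unbiased: report raw values
            ux = warp_x + np.where(valid, ddx, ndimage.gaussian_filter(ddx * wgt, 0.8) / norm)
            uy = warp_y + np.where(valid, ddy, ndimage.gaussian_filter(ddy * wgt, 0.8) / norm)
        else:
            ux = warp_x + ndimage.gaussian_filter(ddx * wgt, 0.8) / norm
            uy = warp_y + ndimage.gaussian_filter(ddy * wgt, 0.8) / norm
        # gap-filled, outlier-substituted field for the next warp;
        # compliant nodes keep their values so steep near-probe
        # gradients survive into the warp. The warp is lightly smoothed:
        # node-scale wiggle in the warp cannot be cancelled by the block
        # residual (blocks average it away), so it must not enter at all.
        warp_x, warp_y = _median_fill(ux, uy, valid, outlier_px=params.outlier_px)
        warp_x = ndimage.gaussian_filter(warp_x, 0.8)
        warp_y = ndimage.gaussian_filter(warp_y, 0.8)

    valid = _flag_outliers(ux, uy, valid, params.outlier_px)
    # measurement-limit flag: local gradient too steep for a translation fit
    step = float(params.grid_step_px)
    jac = np.maximum.reduce([
        np.abs(np.gradient(warp_x, step, axis=1, edge_order=1)),
        np.abs(np.gradient(warp_x, step, axis=0, edge_order=1)),
        np.abs(np.gradient(warp_y, step, axis=1, edge_order=1)),
        np.abs(np.gradient(warp_y, step, axis=0, edge_order=1)),
    ])
    valid &= jac * half <= params.max_block_shear_px
    origin = (float(xs[0] * pixel_size_um), float(ys[0] * pixel_size_um))
    spacing = float(params.grid_step_px * pixel_size_um)
    return VectorField(
        origin, spacing, ux * pixel_size_um, uy * pixel_size_um, valid
    )


def compute_strain(vfield: VectorField) -> StrainField:
    """Normal strain components and total strain from a displacement field.

    Derivatives are computed by finite differences: central differences
    ``(u[i+1] - u[i-1]) / (2*spacing)`` at interior nodes and one-sided
    2-point differences ``(u[1] - u[0]) / spacing`` at the boundaries
    (``np.gradient`` with ``edge_order=1`` implements exactly this scheme).

    A strain node is flagged invalid when its own displacement node or any
    4-neighbour entering its stencil is invalid (slightly conservative at
    the grid boundary, where only the inward neighbour is used).
    """
    ny, nx = vfield.shape
    if ny < 2 or nx < 2:
        raise ValueError("strain needs at least 2 nodes per axis")
    d = vfield.spacing_um
    ex = np.gradient(vfield.ux, d, axis=1, edge_order=1)
    ey = np.gradient(vfield.uy, d, axis=0, edge_order=1)
    bad = ~vfield.valid
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    bad = ndimage.binary_dilation(bad, structure=cross)
    return StrainField(vfield.origin_um, d, ex, ey, valid=~bad)


def find_period_peaks(
    series: np.ndarray,
    min_separation: int = 2,
    min_height_frac: float = 0.15,
) -> np.ndarray:
    """Indices of per-vibration-period peaks of a displacement series.

    Local maxima at least ``min_separation`` samples apart and at least
    ``min_height_frac`` of the global maximum high; late, fully decayed
    oscillations therefore do not contribute spurious peaks.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return np.array([], dtype=int)
    height = min_height_frac * series.max()
    if not height > 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(series, height=height, distance=min_separation)
    return peaks


@dataclass
class DeformationTimecourse:
    """Maximum displacement/strain over time plus per-period peak frames.

    ``near_probe_um`` is the maximum displacement among nodes close to the
    probe contact point; the per-period peak frames are its local maxima
    (the frame with the largest displacement for the beads closest to the
    probe stands in for the unobservable probe motion).
    """

    times_ms: np.ndarray
    max_displacement_um: np.ndarray
    max_strain: np.ndarray
    near_probe_um: np.ndarray = None  # type: ignore[assignment]
    peak_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.max_displacement_um = np.asarray(self.max_displacement_um, dtype=float)
        self.max_strain = np.asarray(self.max_strain, dtype=float)
        if self.near_probe_um is None:
            self.near_probe_um = self.max_displacement_um
        else:
            self.near_probe_um = np.asarray(self.near_probe_um, dtype=float)
        n = self.times_ms.size
        if not (
            self.max_displacement_um.size
            == self.max_strain.size
            == self.near_probe_um.size
            == n
        ):
            raise ValueError("all series must have the same length")
        if n >= 2 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("times must be strictly increasing")
        if self.peak_indices is None:
            self.peak_indices = find_period_peaks(self.near_probe_um)
        else:
            self.peak_indices = np.asarray(self.peak_indices, dtype=int)


def max_timecourse(
    vfields,
    times_ms,
    probe_xy_um: tuple[float, float] | None = None,
    near_radius_um: float = 30.0,
) -> DeformationTimecourse:
    """Per-frame maxima of displacement and strain over a field sequence.

    All fields must share one grid. ``probe_xy_um`` selects the nodes within
    ``near_radius_um`` of the probe whose maximum displacement defines the
    per-period peak series; when omitted the global maximum series is used.
    """
    vfields = list(vfields)
    if not vfields:
        raise ValueError("empty field sequence")
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.size != len(vfields):
        raise ValueError("times and fields length mismatch")
    first = vfields[0]
    for vf in vfields[1:]:
        if vf.shape != first.shape or vf.spacing_um != first.spacing_um:
            raise ValueError("fields must share a common grid")

    near_mask = None
    if probe_xy_um is not None:
        gx, gy = first.meshgrid_um()
        dist = np.hypot(gx - probe_xy_um[0], gy - probe_xy_um[1])
        near_mask = dist <= near_radius_um

    max_disp = np.zeros(len(vfields))
    max_str = np.zeros(len(vfields))
    near = np.zeros(len(vfields))
    for k, vf in enumerate(vfields):
        max_disp[k] = vf.max_displacement_um()
        max_str[k] = compute_strain(vf).max_strain()
        if near_mask is not None:
            sel = near_mask & vf.valid
            mags = vf.magnitude[sel]
            near[k] = float(mags.max()) if mags.size else 0.0
        else:
            near[k] = max_disp[k]
    return DeformationTimecourse(times_ms, max_disp, max_str, near)


@dataclass(frozen=True)
class FrequencyEstimate:
    """Vibration-frequency estimate in Hz.

    ``frequency_hz`` comes from the mean interval between per-period peaks
    (primary); ``spectral_hz`` is the periodogram-peak cross-check of the
    mean-removed maximum-displacement series, coarse at short records.
    """

    frequency_hz: float
    spectral_hz: float
    n_peaks: int

    def __float__(self) -> float:
        return self.frequency_hz


def estimate_frequency(tc: DeformationTimecourse) -> FrequencyEstimate:
    """Vibration frequency from inter-peak timing, with spectral cross-check.

    Raises ``ValueError`` when fewer than 3 per-period peaks are resolved
    (e.g. a constant series carries no oscillation).
    """
    peaks = np.asarray(tc.peak_indices, dtype=int)
    if peaks.size < 3:
        raise ValueError(
            f"only {peaks.size} per-period peaks detected; oscillation unresolvable"
        )
    intervals_ms = np.diff(tc.times_ms[peaks])
    f_peaks = 1000.0 / float(np.mean(intervals_ms))

    dt_ms = float(np.median(np.diff(tc.times_ms)))
    series = tc.max_displacement_um - tc.max_displacement_um.mean()
    freqs, power = signal.periodogram(series, fs=1000.0 / dt_ms)
    if freqs.size > 1:
        k = 1 + int(np.argmax(power[1:]))  # exclude the DC bin
        f_spec = float(freqs[k])
    else:
        f_spec = float("nan")
    return FrequencyEstimate(f_peaks, f_spec, int(peaks.size))
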