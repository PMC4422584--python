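"""Peripheral-annulus adhesion scoring from before/after cell positions.

The orbital-shaker detachment assay exploits the stronger shear stress at
the periphery of a circular gel: cells are counted only inside the annulus
from the gel edge to a fixed band width (default 200 µm) toward the center,
in ~20 randomly placed screenshots per dish before and after shaking. Each
post-shaking screenshot yields an attachment ratio

    AttRatio = C_after / mean(C_before),

the screenshot's peripheral count divided by the dish's mean peripheral
count per screenshot before shaking. (The source protocol labels the same
formula DetRatio; they are one quantity, named attachment ratio here.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats

__all__ = [
    "PeripheryRule",
    "AdhesionCounts",
    "select_periphery",
    "screenshot_counts",
    "attachment_ratios",
    "compare_conditions",
]


@dataclass(frozen=True)
class PeripheryRule:
    """Counting band of a circular gel: edge to ``band_um`` toward the center.

    Membership is inclusive: a cell exactly ``band_um`` from the edge is
    counted ("up to 200 µm" read as a closed interval).
    """

    gel_radius_um: float
    band_um: float = 200.0
    center_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.gel_radius_um > 0:
            raise ValueError("gel_radius_um must be > 0")
        if not 0 < self.band_um < self.gel_radius_um:
            raise ValueError("band_um must be in (0, gel_radius_um)")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of positions inside the peripheral band."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        r = np.hypot(xy[:, 0] - self.center_um[0], xy[:, 1] - self.center_um[1])
        return (self.gel_radius_um - r) <= self.band_um


def select_periphery(xy: np.ndarray, rule: PeripheryRule) -> np.ndarray:
    """Subset of positions within the peripheral counting band.

    ``xy`` has shape (n, 2) in micrometres, gel-center origin. Idempotent:
    re-applying the rule to its own output changes nothing.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if xy.size == 0:
        return xy
    return xy[rule.contains(xy)]


def screenshot_counts(
    xy: np.ndarray,
    fov_centers_um: np.ndarray,
    fov_um: float,
    rule: PeripheryRule,
) -> np.ndarray:
    """Peripheral cell count per screenshot field of view.

    Screenshots are axis-aligned squares of side ``fov_um`` centered at
    ``fov_centers_um`` (shape (k, 2)); a cell is counted when it lies in the
    field of view AND in the peripheral band.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    centers = np.atleast_2d(np.asarray(fov_centers_um, dtype=float))
    half = fov_um / 2.0
    in_band = rule.contains(xy) if xy.size else np.zeros(0, dtype=bool)
    counts = np.empty(len(centers), dtype=int)
    for k, (cx, cy) in enumerate(centers):
        in_fov = (
            (np.abs(xy[:, 0] - cx) <= half) & (np.abs(xy[:, 1] - cy) <= half)
            if xy.size
            else np.zeros(0, dtype=bool)
        )
        counts[k] = int(np.count_nonzero(in_fov & in_band))
    return counts


@dataclass
class AdhesionCounts:
    """Per-dish adhesion score: screenshot counts and attachment ratios."""

    before_counts: np.ndarray
    after_counts: np.ndarray
    dish_id: str | int | None = None

    def __post_init__(self) -> None:
        self.before_counts = np.asarray(self.before_counts, dtype=float)
        self.after_counts = np.asarray(self.after_counts, dtype=float)
        if self.before_counts.size < 1:
            raise ValueError("need at least one before-shaking screenshot")
        if np.any(self.before_counts < 0) or np.any(self.after_counts < 0):
            raise ValueError("counts must be >= 0")
        if self.mean_before <= 0:
            raise ValueError("mean before-shaking count must be > 0")

    @property
    def mean_before(self) -> float:
        """Dish mean peripheral count per screenshot before shaking."""
        return float(self.before_counts.mean())

    @property
    def ratios(self) -> np.ndarray:
        """One attachment ratio per after-shaking screenshot."""
        return self.after_counts / self.mean_before

    @property
    def mean_ratio(self) -> float:
        return float(self.ratios.mean())

    @property
    def sem_ratio(self) -> float:
        r = self.ratios
        return float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else float("nan")


def attachment_ratios(
    before_counts, after_counts, dish_id=None
) -> AdhesionCounts:
    """Attachment ratios ``C_after / mean(C_before)`` for one dish."""
    return AdhesionCounts(before_counts, after_counts, dish_id=dish_id)


def compare_conditions(ratios_a, ratios_b) -> float:
    """Two-tailed pooled-variance Student's t-test p-value on two ratio samples."""
    return stats.student_t_two_tailed(ratios_a, ratios_b)
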