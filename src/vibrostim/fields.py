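"""Gridded displacement and strain fields for substrate deformation maps.

Both containers share the same regular-grid convention: node ``(j, i)``
(row ``j``, column ``i``) sits at physical position
``(origin_um[0] + i * spacing_um, origin_um[1] + j * spacing_um)``,
i.e. axis 0 is y and axis 1 is x, matching image row/column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VectorField", "StrainField"]


def _as_2d(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={out.ndim}")
    return out


@dataclass
class VectorField:
    """2-D substrate displacement field (ux, uy) on a regular grid.

    Parameters
    ----------
    origin_um : (float, float)
        Physical position ``(x0, y0)`` of node ``(0, 0)`` in micrometres.
    spacing_um : float
        Grid spacing in micrometres (isotropic, > 0).
    ux, uy : ndarray, shape (ny, nx)
        Displacement components in micrometres.
    valid : ndarray of bool, optional
        Per-node validity flag. Invalid nodes are excluded from maxima and
        propagate into strain validity. Defaults to all-valid.
    """

    origin_um: tuple[float, float]
    spacing_um: float
    ux: np.ndarray
    uy: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ux = _as_2d(self.ux, "ux")
        self.uy = _as_2d(self.uy, "uy")
        if self.ux.shape != self.uy.shape:
            raise ValueError("ux and uy must have the same shape")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be > 0")
        if self.valid is None:
            self.valid = np.ones(self.ux.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.ux.shape:
                raise ValueError("valid must match ux/uy shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ux.shape

    @property
    def x_um(self) -> np.ndarray:
        """x coordinates of grid columns (µm)."""
        return self.origin_um[0] + self.spacing_um * np.arange(self.shape[1])

    @property
    def y_um(self) -> np.ndarray:
        """y coordinates of grid rows (µm)."""
        return self.origin_um[1] + self.spacing_um * np.arange(self.shape[0])

    @property
    def magnitude(self) -> np.ndarray:
        """Displacement magnitude |u| per node (µm)."""
        return np.hypot(self.ux, self.uy)

    def max_displacement_um(self) -> float:
        """Maximum |u| over valid nodes (µm); 0 if no node is valid."""
        mag = self.magnitude[self.valid]
        return float(mag.max()) if mag.size else 0.0

    def meshgrid_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of all nodes, each shaped like ux."""
        return np.meshgrid(self.x_um, self.y_um)


@dataclass
class StrainField:
    """Normal strain components and total strain magnitude on a grid.

    ``Ex = dux/dx``, ``Ey = duy/dy`` and ``E = sqrt(Ex**2 + Ey**2)``; shear
    components are deliberately not part of this container.
    """

    origin_um: tuple[float, float]
    spacing_um: float
    Ex: np.ndarray
    Ey: np.ndarray
    E: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Ex = _as_2d(self.Ex, "Ex")
        self.Ey = _as_2d(self.Ey, "Ey")
        if self.Ex.shape != self.Ey.shape:
            raise ValueError("Ex and Ey must have the same shape")
        if self.E is None:
            self.E = np.hypot(self.Ex, self.Ey)
        else:
            self.E = _as_2d(self.E, "E")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be > 0")
        if self.valid is None:
            self.valid = np.ones(self.Ex.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.Ex.shape

    def max_strain(self) -> float:
        """Maximum total strain E over valid nodes; 0 if none valid."""
        vals = self.E[self.valid]
        return float(vals.max()) if vals.size else 0.0
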