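"""File I/O: TIFF stacks, field/timecourse CSVs, ground-truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .deformation import DeformationTimecourse
from .fields import StrainField, VectorField
from .fret import RatioTimecourse

__all__ = [
    "save_stack",
    "load_stack",
    "field_to_dataframe",
    "write_field_csv",
    "read_field_csv",
    "write_deformation_timecourse_csv",
    "read_deformation_timecourse_csv",
    "write_ratio_timecourse",
    "write_cells_csv",
    "read_cells_csv",
    "write_json",
]


def save_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (T, ny, nx) stack as a 16-bit multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.uint16))


def load_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (T, ny, nx) array (single page -> T=1)."""
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def field_to_dataframe(vf: VectorField, sf: StrainField | None = None) -> pd.DataFrame:
    gx, gy = vf.meshgrid_um()
    data = {
        "x_um": gx.ravel(),
        "y_um": gy.ravel(),
        "ux_um": vf.ux.ravel(),
        "uy_um": vf.uy.ravel(),
        "valid": vf.valid.ravel().astype(int),
    }
    if sf is not None:
        data["Ex"] = sf.Ex.ravel()
        data["Ey"] = sf.Ey.ravel()
        data["E"] = sf.E.ravel()
        data["strain_valid"] = sf.valid.ravel().astype(int)
    return pd.DataFrame(data)


def write_field_csv(
    path: str | Path, vf: VectorField, sf: StrainField | None = None
) -> None:
    """Write a displacement field (and optional strain) as one node-per-row CSV."""
    field_to_dataframe(vf, sf).to_csv(path, index=False)


def read_field_csv(path: str | Path) -> tuple[VectorField, StrainField | None]:
    """Read a field CSV back into VectorField (+ StrainField if present)."""
    df = pd.read_csv(path)
    xs = np.unique(df.x_um.to_numpy())
    ys = np.unique(df.y_um.to_numpy())
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("field CSV must contain a 2-D grid")
    spacing = float(xs[1] - xs[0])
    shape = (len(ys), len(xs))
    df = df.sort_values(["y_um", "x_um"])

    def grid(col):
        return df[col].to_numpy().reshape(shape)

    vf = VectorField(
        (float(xs[0]), float(ys[0])),
        spacing,
        grid("ux_um"),
        grid("uy_um"),
        grid("valid").astype(bool),
    )
    sf = None
    if "E" in df.columns:
        sf = StrainField(
            vf.origin_um,
            spacing,
            grid("Ex"),
            grid("Ey"),
            grid("E"),
            grid("strain_valid").astype(bool) if "strain_valid" in df.columns else None,
        )
    return vf, sf


def write_deformation_timecourse_csv(path: str | Path, tc: DeformationTimecourse) -> None:
    is_peak = np.zeros(tc.times_ms.size, dtype=int)
    is_peak[tc.peak_indices] = 1
    pd.DataFrame(
        {
            "t_ms": tc.times_ms,
            "max_displacement_um": tc.max_displacement_um,
            "max_strain": tc.max_strain,
            "near_probe_um": tc.near_probe_um,
            "is_period_peak": is_peak,
        }
    ).to_csv(path, index=False)


def read_deformation_timecourse_csv(path: str | Path) -> DeformationTimecourse:
    df = pd.read_csv(path)
    peaks = np.flatnonzero(df.is_period_peak.to_numpy()) if "is_period_peak" in df else None
    return DeformationTimecourse(
        df.t_ms.to_numpy(),
        df.max_displacement_um.to_numpy(),
        df.max_strain.to_numpy(),
        df.near_probe_um.to_numpy() if "near_probe_um" in df else None,
        peaks,
    )


def write_ratio_timecourse(path_csv: str | Path, tc: RatioTimecourse) -> None:
    """Write a ratio time course as CSV plus a JSON summary next to it."""
    pd.DataFrame({"t_s": tc.times_s, "ratio": tc.ratios}).to_csv(path_csv, index=False)
    summary = {
        "basalRatio": tc.basal_ratio,
        "maxRatio": tc.max_ratio,
        "RelDiff": tc.rel_diff,
        "stim_index": int(tc.stim_index),
    }
    Path(path_csv).with_suffix(".json").write_text(json.dumps(summary, indent=2))


def write_cells_csv(path: str | Path, cells: pd.DataFrame) -> None:
    """Write the adhesion cell table (dish_id, cell_id, x_um, y_um, present_after)."""
    cols = ["dish_id", "cell_id", "x_um", "y_um", "present_after"]
    cells[cols].to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
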