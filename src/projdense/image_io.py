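"""Reading and writing of image stacks and cell tables.

Image stacks are grayscale multi-page TIFFs, one page per optical section,
with the physical voxel spacing carried in the TIFF resolution tags (x, y)
and the ImageJ ``spacing`` field (z), or in a YAML sidecar next to the file.
Cell tables are comma-separated text with one row per counted neuron.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Recognised mPFC subregion labels (dorsal to ventral order as used in the
#: distribution tables), plus a catch-all for cells outside the mapped areas.
SUBREGIONS = ("Cg2", "Cg1", "PrL", "IL", "MO", "DP", "DTT", "other")

#: Cortical layer labels. L2/3 is treated as a single lamina; L5 is split into
#: its superficial (5a) and deep (5b) tiers because the two projection
#: populations segregate across that boundary.
LAYERS = ("L1", "L2/3", "L5a", "L5b", "L6")

#: Molecular marker columns of a cell table. Values are 1 (positive),
#: 0 (negative) or NA (section not stained / cell not assessed).
MARKERS = ("calb1", "ctip2", "foxp2")

CELL_TABLE_COLUMNS = (
    "animal",
    "bregma_mm",
    "subregion",
    "layer",
    "tracer_nac",
    "tracer_vta",
) + MARKERS


@dataclass(frozen=True)
class ImageStack:
    """A 3D fluorescence stack with anisotropic physical voxel spacing.

    ``voxels`` is indexed ``(z, y, x)``; ``spacing_um`` is ``(dz, dy, dx)``
    in micrometres. The physical position of a voxel centre is
    ``index * spacing`` (0-based indices).
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"stack must be a non-empty 3D array, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("stack intensities must be finite")
        if len(self.spacing_um) != 3 or any(
            not (s > 0 and math.isfinite(s)) for s in self.spacing_um
        ):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing_um}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_um", tuple(float(s) for s in self.spacing_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_mm3(self) -> float:
        """Physical extent of the full stack in mm^3."""
        nz, ny, nx = self.voxels.shape
        dz, dy, dx = self.spacing_um
        return (nz * dz) * (ny * dy) * (nx * dx) * 1e-9


@dataclass(frozen=True)
class ROISpec:
    """Analyzed-volume specification: ROI area x slice count x z-step.

    Mirrors how analyzed tissue volume is computed from a confocal stack:
    ``volume = roi_area_mm2 * n_slices * step_um``.
    """

    roi_area_mm2: float
    n_slices: int
    step_um: float

    def __post_init__(self) -> None:
        if not self.roi_area_mm2 > 0:
            raise ValueError("roi_area_mm2 must be > 0")
        if not self.n_slices > 0:
            raise ValueError("n_slices must be > 0")
        if not self.step_um > 0:
            raise ValueError("step_um must be > 0")


def _sidecar_path(path: str | os.PathLike) -> str:
    return str(path) + ".spacing.yaml"


def write_stack(stack: ImageStack, path: str | os.PathLike, sidecar: bool = True) -> None:
    """Write a stack as a multi-page TIFF with spacing metadata.

    The x/y spacing is stored in the TIFF resolution tags (pixels per
    micron), the z spacing in the ImageJ ``spacing`` field. When ``sidecar``
    is true a ``<path>.spacing.yaml`` file carrying the exact floating-point
    spacing is written alongside (resolution tags are rationals and may lose
    a few ulps).
    """
    dz, dy, dx = stack.spacing_um
    data = stack.voxels
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    if sidecar:
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(
                {"spacing_um": {"dz": dz, "dy": dy, "dx": dx}}, fh, sort_keys=False
            )


def _spacing_from_tags(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    meta = tf.imagej_metadata or {}
    dz = meta.get("spacing")
    if xres is None or yres is None or dz is None:
        return None
    xn, xd = xres.value
    yn, yd = yres.value
    if xn == 0 or yn == 0:
        return None
    return (float(dz), yd / yn, xd / xn)


def read_stack(
    path: str | os.PathLike,
    spacing_override: Sequence[float] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Spacing resolution order: ``spacing_override`` argument, then a
    ``<path>.spacing.yaml`` sidecar, then TIFF tags. A stack whose spacing
    cannot be established raises — isotropy is never silently assumed.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        tag_spacing = _spacing_from_tags(tf)
    if data.ndim == 2:  # single-page file
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected a grayscale z-stack, got array of shape {data.shape}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif os.path.exists(_sidecar_path(path)):
        with open(_sidecar_path(path)) as fh:
            doc = yaml.safe_load(fh)
        s = doc["spacing_um"]
        spacing = (float(s["dz"]), float(s["dy"]), float(s["dx"]))
    elif tag_spacing is not None:
        spacing = tag_spacing
    else:
        raise ValueError(
            f"{path}: no voxel spacing in TIFF metadata or sidecar and no override given"
        )
    return ImageStack(voxels=data, spacing_um=spacing)


def _check_categories(
    series: pd.Series, allowed: Iterable[str], column: str
) -> None:
    allowed = set(allowed)
    bad = ~series.isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"row {row}: unknown {column} {series.iloc[row]!r}; allowed: {sorted(allowed)}"
        )


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a cell table; returns a normalized copy.

    Marker columns become nullable Int8 (1/0/NA); tracer flags int8.
    Unknown subregion or layer labels raise with the offending row index.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    out = df.loc[:, list(CELL_TABLE_COLUMNS)].copy().reset_index(drop=True)
    if len(out):
        _check_categories(out["subregion"], SUBREGIONS, "subregion")
        _check_categories(out["layer"], LAYERS, "layer")
        if not np.all(np.isfinite(out["bregma_mm"].astype(float))):
            raise ValueError("bregma_mm must be finite")
    out["bregma_mm"] = out["bregma_mm"].astype(float)
    for col in ("tracer_nac", "tracer_vta"):
        out[col] = out[col].astype("int8")
        if not out[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be 0 or 1")
    if len(out) and not (out["tracer_nac"] | out["tracer_vta"]).all():
        row = int(np.flatnonzero(~(out["tracer_nac"] | out["tracer_vta"]).to_numpy())[0])
        raise ValueError(f"row {row}: cell carries no tracer flag")
    for col in MARKERS:
        out[col] = pd.array(
            pd.to_numeric(out[col].replace({"NA": pd.NA, "": pd.NA}), errors="raise"),
            dtype="Int8",
        )
        vals = out[col].dropna()
        if not vals.isin([0, 1]).all():
            raise ValueError(f"{col} must be 1, 0 or NA")
    return out


def read_cell_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a comma-separated cell table (one row per counted neuron)."""
    df = pd.read_csv(path, keep_default_na=True, na_values=["NA"])
    return validate_cell_table(df)


def write_cell_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    for col in MARKERS:
        if col in out:
            out[col] = out[col].astype(object).where(out[col].notna(), "NA")
    out.to_csv(path, index=False)


def read_roi_spec(source: str | os.PathLike | Mapping) -> ROISpec:
    """Build an :class:`ROISpec` from a YAML/JSON file or a mapping."""
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return ROISpec(
        roi_area_mm2=float(doc["roi_area_mm2"]),
        n_slices=int(doc["n_slices"]),
        step_um=float(doc["step_um"]),
    )
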