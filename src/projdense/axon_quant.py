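"""Axon length and relative axon density (RAD) from 3D stacks.

The measurement chain is: segment the stack into an axon mask, thin the
mask to a one-voxel centerline skeleton, build a graph over 26-adjacent
skeleton voxels, and sum anisotropic Euclidean edge lengths. Density is
total length over analyzed volume (mm/mm^3); the per-animal RAD ratio
RAD_VTA / RAD_NAc equals 1 when the two target regions are equally
innervated.

Segmentation is deliberately explicit and configurable (Gaussian
pre-smoothing, Otsu or fixed threshold, small-object removal) and the
parameters used are recorded on the returned mask, since any densitometric
result is only interpretable together with its segmentation settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects, skeletonize

from .image_io import ImageStack, ROISpec

#: The 13 neighbor offsets spanning the positive half of the 26-neighborhood;
#: enumerating shifted voxel pairs over these yields each undirected
#: adjacency exactly once.
HALF_NEIGHBORHOOD = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


@dataclass(frozen=True)
class BinaryMask:
    """Foreground mask of a stack, with the segmentation provenance."""

    mask: np.ndarray
    spacing_um: tuple[float, float, float]
    threshold: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 3:
            raise ValueError("mask must be a 3D boolean array")


@dataclass(frozen=True)
class SkeletonGraph:
    """Centerline graph: nodes are skeleton voxels, edges 26-adjacencies.

    Node keys are voxel index triples ``(z, y, x)``; each node carries its
    physical position (``pos_um = index * spacing``) and each edge the
    anisotropic Euclidean distance between its endpoints in um.
    """

    graph: nx.Graph
    spacing_um: tuple[float, float, float]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class StackMeasurement:
    """Per-stack axon length, analyzed volume and density."""

    axon_length_mm: float
    volume_mm3: float

    def __post_init__(self) -> None:
        if self.axon_length_mm < 0 or self.volume_mm3 <= 0:
            raise ValueError("length must be >= 0 and volume > 0")

    @property
    def density_mm_per_mm3(self) -> float:
        return self.axon_length_mm / self.volume_mm3


@dataclass(frozen=True)
class RegionSummary:
    """Region totals over stacks and the resulting relative axon density."""

    region: str
    total_length_mm: float
    total_volume_mm3: float

    @property
    def rad(self) -> float:
        return self.total_length_mm / self.total_volume_mm3


@dataclass(frozen=True)
class RadRatio:
    """Per-animal RAD_VTA / RAD_NAc; 1 means equal innervation."""

    value: float


def binarize_stack(
    stack: ImageStack,
    method: str | float = "otsu",
    min_object_vox: int = 27,
    smooth_sigma_vox: Sequence[float] = (0.0, 1.0, 1.0),
) -> BinaryMask:
    """Threshold a stack into an axon mask.

    ``method`` is ``"otsu"`` or a fixed numeric threshold (foreground is
    strictly above it). Smoothing sigma is given in voxels per axis
    (z, y, x); the default smooths in-plane only. Connected components
    (26-connectivity) smaller than ``min_object_vox`` voxels are removed.
    A constant stack yields an empty mask.
    """
    img = stack.voxels.astype(np.float64)
    if any(s > 0 for s in smooth_sigma_vox):
        img = gaussian_filter(img, sigma=tuple(smooth_sigma_vox))
    lo, hi = float(img.min()), float(img.max())
    if method == "otsu":
        if hi == lo:
            mask = np.zeros(stack.shape, dtype=bool)
            thr = hi
        else:
            thr = float(threshold_otsu(img))
            mask = img > thr
    else:
        thr = float(method)
        if thr < lo or thr > hi:
            warnings.warn(
                f"fixed threshold {thr} outside intensity range [{lo}, {hi}]",
                stacklevel=2,
            )
        mask = img > thr
    if min_object_vox > 1 and mask.any():
        # max_size removes components of <= that many voxels (26-connectivity)
        mask = remove_small_objects(mask, max_size=min_object_vox - 1, connectivity=3)
    return BinaryMask(
        mask=mask,
        spacing_um=stack.spacing_um,
        threshold=thr,
        params={
            "method": method,
            "min_object_vox": min_object_vox,
            "smooth_sigma_vox": tuple(smooth_sigma_vox),
        },
    )


def skeletonize_stack(mask: BinaryMask) -> SkeletonGraph:
    """Thin a mask to a one-voxel centerline and build its adjacency graph.

    Thinning runs on the native (anisotropic) grid; the anisotropy enters
    only through the physical edge lengths, never through resampling.
    """
    skel = skeletonize(mask.mask) if mask.mask.any() else mask.mask
    return skeleton_graph_from_voxels(skel, mask.spacing_um)


def skeleton_graph_from_voxels(
    skel: np.ndarray, spacing_um: Sequence[float]
) -> SkeletonGraph:
    """Graph over 26-adjacent foreground voxels of a (thinned) mask."""
    spacing = np.asarray(spacing_um, dtype=float)
    g = nx.Graph()
    coords = np.argwhere(skel)
    for z, y, x in coords:
        g.add_node(
            (int(z), int(y), int(x)),
            pos_um=(z * spacing[0], y * spacing[1], x * spacing[2]),
        )
    voxset = set(map(tuple, coords.tolist()))
    for z, y, x in voxset:
        for dz, dy, dx in HALF_NEIGHBORHOOD:
            nb = (z + dz, y + dy, x + dx)
            if nb in voxset:
                length = float(
                    np.sqrt((dz * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dx * spacing[2]) ** 2)
                )
                g.add_edge((z, y, x), nb, length_um=length)
    return SkeletonGraph(graph=g, spacing_um=tuple(float(s) for s in spacing))


def skeleton_length(skel: SkeletonGraph, spacing_um: Sequence[float] | None = None) -> float:
    """Total centerline length in mm: sum of unique-edge anisotropic
    Euclidean distances ``sqrt((dz*Δz)^2 + (dy*Δy)^2 + (dx*Δx)^2)``."""
    spacing = np.asarray(
        skel.spacing_um if spacing_um is None else spacing_um, dtype=float
    )
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be positive, got {tuple(spacing)}")
    total_um = 0.0
    for (a, b) in skel.graph.edges():
        delta = (np.asarray(a) - np.asarray(b)) * spacing
        total_um += float(np.sqrt((delta ** 2).sum()))
    return total_um / 1000.0


def stack_volume(roi: ROISpec) -> float:
    """Analyzed volume in mm^3: ROI area x number of slices x z-step."""
    return roi.roi_area_mm2 * roi.n_slices * (roi.step_um / 1000.0)


def measure_stack(
    stack: ImageStack,
    roi: ROISpec | None = None,
    method: str | float = "otsu",
    min_object_vox: int = 27,
    smooth_sigma_vox: Sequence[float] = (0.0, 1.0, 1.0),
) -> StackMeasurement:
    """Full per-stack pipeline: segment, skeletonize, measure.

    When an :class:`ROISpec` is given its volume formula overrides the
    stack's own physical extent.
    """
    mask = binarize_stack(
        stack, method=method, min_object_vox=min_object_vox, smooth_sigma_vox=smooth_sigma_vox
    )
    skel = skeletonize_stack(mask)
    length_mm = skeleton_length(skel)
    volume = stack_volume(roi) if roi is not None else stack.volume_mm3()
    return StackMeasurement(axon_length_mm=length_mm, volume_mm3=volume)


def region_rad(
    measurements: Sequence[StackMeasurement], region: str = ""
) -> RegionSummary:
    """Sum lengths and volumes over a region's stacks; RAD = total/total."""
    if not measurements:
        raise ValueError("need at least one stack measurement")
    total_length = float(sum(m.axon_length_mm for m in measurements))
    total_volume = float(sum(m.volume_mm3 for m in measurements))
    if total_volume <= 0:
        raise ValueError("total volume must be positive")
    return RegionSummary(
        region=region, total_length_mm=total_length, total_volume_mm3=total_volume
    )


def rad_ratio(rad_vta: RegionSummary | float, rad_nac: RegionSummary | float) -> RadRatio:
    """Per-animal RAD_VTA / RAD_NAc from region summaries or raw densities."""
    vta = rad_vta.rad if isinstance(rad_vta, RegionSummary) else float(rad_vta)
    nac = rad_nac.rad if isinstance(rad_nac, RegionSummary) else float(rad_nac)
    if nac <= 0:
        raise ValueError("RAD ratio undefined: NAc density must be positive")
    return RadRatio(value=vta / nac)
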