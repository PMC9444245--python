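"""Synthetic confocal stacks and cell tables with known ground truth.

The axon phantom emulates sparse tubular arbors imaged at high magnification
in anisotropic z-stacks: piecewise-linear random-walk centerlines with a
bounded per-step turn angle are rasterized as tubes of fixed physical
radius, blurred by an anisotropic Gaussian point-spread function, and
corrupted with Poisson (or Gaussian) noise. The exact centerline polylines —
and hence the exact total length — are recorded, giving every downstream
measurement a parameter-recovery target.

The cell-table generator draws per-animal neuron counts around prescribed
expectations (Poisson), with Bernoulli marker co-labeling and double-tracer
flags, emulating the structure of retrograde-tracing count tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import (
    CELL_TABLE_COLUMNS,
    LAYERS,
    MARKERS,
    SUBREGIONS,
    ImageStack,
    validate_cell_table,
)

# Default voxel spacing (dz, dy, dx) in um. The z-step mirrors the 0.27 um
# optical sectioning of a 63x stack; the in-plane pixel size is a typical
# value for that magnification (the acquisitions being emulated did not
# record it) and is freely configurable.
DEFAULT_SPACING_UM = (0.27, 0.2, 0.2)

#: Default stack shape (nz, ny, nx): 17.3 x 80 x 80 um, i.e. ~1.1e-4 mm^3.
DEFAULT_SHAPE_VOX = (64, 400, 400)


@dataclass(frozen=True)
class AxonPhantomSpec:
    """Parameters of a synthetic axon stack.

    ``length_dist_um`` is a uniform range for the target centerline length
    per axon; ``tortuosity_deg`` bounds the turn angle between consecutive
    steps; ``psf_sigma_um`` is the Gaussian blur sigma per axis (z, y, x);
    ``noise_model`` is ``("poisson",)`` or ``("gaussian", sigma)``.
    """

    n_axons: int = 10
    length_dist_um: tuple[float, float] = (20.0, 60.0)
    tortuosity_deg: float = 20.0
    tube_radius_um: float = 0.4
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.13, 0.13)
    background_level: float = 20.0
    peak_intensity: float = 120.0
    noise_model: tuple = ("poisson",)
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    shape_vox: tuple[int, int, int] = DEFAULT_SHAPE_VOX
    step_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axons < 0:
            raise ValueError("n_axons must be >= 0")
        lo, hi = self.length_dist_um
        if not (0 < lo <= hi):
            raise ValueError("length_dist_um must satisfy 0 < min <= max")
        if not (0 <= self.tortuosity_deg <= 180):
            raise ValueError("tortuosity_deg must be in [0, 180]")
        for name in ("tube_radius_um", "background_level", "peak_intensity", "step_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if any(s <= 0 for s in self.spacing_um) or any(s < 0 for s in self.psf_sigma_um):
            raise ValueError("spacing must be positive, psf sigma non-negative")
        if any(n < 1 for n in self.shape_vox):
            raise ValueError("shape_vox components must be >= 1")
        if self.noise_model[0] not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        # The rasterized tube must be at least one voxel thick in every axis.
        if any(2 * self.tube_radius_um < s for s in self.spacing_um):
            raise ValueError(
                "tube diameter smaller than one voxel along some axis: "
                f"2*{self.tube_radius_um} um vs spacing {self.spacing_um}"
            )

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape_vox, self.spacing_um))


@dataclass(frozen=True)
class GroundTruth:
    """Exact centerlines (z, y, x in um) and their total Euclidean length."""

    centerlines: tuple
    total_length_um: float

    @staticmethod
    def from_centerlines(centerlines: Sequence[np.ndarray]) -> "GroundTruth":
        total = sum(polyline_length_um(c) for c in centerlines)
        return GroundTruth(
            centerlines=tuple(np.asarray(c, dtype=float) for c in centerlines),
            total_length_um=float(total),
        )


def polyline_length_um(points: np.ndarray) -> float:
    """Sum of Euclidean segment lengths of a polyline in physical um."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (N, 3) array")
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _turn(direction: np.ndarray, max_angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by a uniform angle in [0, max] about a random
    axis perpendicular to it."""
    if max_angle_rad <= 0:
        return direction
    angle = rng.uniform(0.0, max_angle_rad)
    # random perpendicular axis
    helper = _random_unit_vector(rng)
    perp = np.cross(direction, helper)
    n = np.linalg.norm(perp)
    while n < 1e-9:
        helper = _random_unit_vector(rng)
        perp = np.cross(direction, helper)
        n = np.linalg.norm(perp)
    perp /= n
    new = direction * math.cos(angle) + np.cross(perp, direction) * math.sin(angle)
    return new / np.linalg.norm(new)


def _clip_segment(p: np.ndarray, q: np.ndarray, hi: np.ndarray) -> np.ndarray | None:
    """Clip endpoint ``q`` of segment p->q to the box [0, hi]; ``p`` must be
    inside. Returns the clipped endpoint, or None if q is inside already."""
    if np.all(q >= 0) and np.all(q <= hi):
        return None
    d = q - p
    t = 1.0
    for k in range(3):
        if d[k] > 0 and q[k] > hi[k]:
            t = min(t, (hi[k] - p[k]) / d[k])
        elif d[k] < 0 and q[k] < 0:
            t = min(t, -p[k] / d[k])
    return p + max(t, 0.0) * d


def _walk_centerline(
    spec: AxonPhantomSpec, rng: np.random.Generator, extent: np.ndarray, margin: float
) -> np.ndarray:
    target = rng.uniform(*spec.length_dist_um)
    lo = np.full(3, margin)
    hi = extent - margin
    start = rng.uniform(lo, hi)
    direction = _random_unit_vector(rng)
    max_turn = math.radians(spec.tortuosity_deg)
    pts = [start]
    travelled = 0.0
    while travelled < target:
        step = min(spec.step_um, target - travelled)
        nxt = pts[-1] + direction * step
        clipped = _clip_segment(pts[-1], nxt, extent)
        if clipped is not None:
            # Axon leaves the stack: keep the in-stack part and stop.
            if np.linalg.norm(clipped - pts[-1]) > 1e-9:
                pts.append(clipped)
            break
        pts.append(nxt)
        travelled += step
        direction = _turn(direction, max_turn, rng)
    return np.asarray(pts)


def _rasterize_tube(
    mask: np.ndarray, polyline: np.ndarray, spacing: np.ndarray, radius: float
) -> None:
    """Mark voxels whose centre lies within ``radius`` (um) of the polyline.

    Distances are measured in physical coordinates, so the tube respects
    voxel anisotropy. Operates segment by segment on local bounding boxes.
    """
    shape = np.asarray(mask.shape)
    for i in range(len(polyline) - 1):
        p, q = polyline[i], polyline[i + 1]
        lo_um = np.minimum(p, q) - radius
        hi_um = np.maximum(p, q) + radius
        lo = np.maximum(np.floor(lo_um / spacing).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]) * spacing[0],
            np.arange(lo[1], hi[1]) * spacing[1],
            np.arange(lo[2], hi[2]) * spacing[2],
            indexing="ij",
        )
        pts = np.stack([zz, yy, xx], axis=-1)
        d = q - p
        dd = float(d @ d)
        if dd < 1e-18:
            dist = np.linalg.norm(pts - p, axis=-1)
        else:
            t = np.clip(((pts - p) @ d) / dd, 0.0, 1.0)
            proj = p + t[..., None] * d
            dist = np.linalg.norm(pts - proj, axis=-1)
        sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub |= dist <= radius


def generate_axon_stack(spec: AxonPhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Generate a noisy tubular-phantom stack and its exact ground truth.

    Fully deterministic for a fixed ``spec.seed``; each axon consumes an
    independent child RNG stream, so the first ``k`` axons are identical
    across specs that differ only in ``n_axons``.
    """
    extent = np.asarray(spec.extent_um)
    margin = spec.tube_radius_um
    if np.any(extent <= 2 * margin):
        raise ValueError(
            f"phantom cannot fit: extent {tuple(extent)} um too small for "
            f"tube radius {spec.tube_radius_um} um plus margin"
        )
    spacing = np.asarray(spec.spacing_um)
    ss = np.random.SeedSequence(spec.seed)
    axon_streams = ss.spawn(spec.n_axons + 1)
    noise_rng = np.random.default_rng(axon_streams[-1])

    centerlines = []
    mask = np.zeros(spec.shape_vox, dtype=bool)
    for i in range(spec.n_axons):
        rng = np.random.default_rng(axon_streams[i])
        line = _walk_centerline(spec, rng, extent, margin)
        if len(line) >= 2:
            centerlines.append(line)
            _rasterize_tube(mask, line, spacing, spec.tube_radius_um)
    truth = GroundTruth.from_centerlines(centerlines)

    sigma_vox = np.asarray(spec.psf_sigma_um) / spacing
    signal = mask.astype(np.float64)
    if np.any(sigma_vox > 0):
        signal = gaussian_filter(signal, sigma=sigma_vox)
    image = spec.background_level + (spec.peak_intensity - spec.background_level) * signal
    kind = spec.noise_model[0]
    if kind == "poisson":
        image = noise_rng.poisson(image).astype(np.float64)
    elif kind == "gaussian":
        image = image + noise_rng.normal(0.0, float(spec.noise_model[1]), size=image.shape)
        image = np.clip(image, 0.0, None)
    stack = ImageStack(voxels=image.astype(np.float32), spacing_um=spec.spacing_um)
    return stack, truth


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTableSpec:
    """Generative parameters for a synthetic retrograde-tracing cell table.

    ``expected_counts`` maps population ('nac' / 'vta') to per-animal
    expected cell counts per (subregion, layer). ``marker_probs`` maps
    (population, marker, layer) to the Bernoulli probability that a cell of
    that stratum is marker-positive; strata absent from the map are emitted
    as untested (NA). ``double_projection_prob`` is the probability that a
    projecting cell carries both tracers.
    """

    n_animals: int = 3
    expected_counts: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {
            "nac": {("PrL", "L2/3"): 60, ("PrL", "L5a"): 110, ("MO", "L5a"): 90},
            "vta": {("PrL", "L5b"): 120, ("MO", "L6"): 80},
        }
    )
    marker_probs: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    double_projection_prob: float = 0.015
    bregma_range_mm: tuple[float, float] = (1.10, 3.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0 <= self.double_projection_prob <= 1:
            raise ValueError("double_projection_prob must be in [0, 1]")
        for pop, table in self.expected_counts.items():
            if pop not in ("nac", "vta"):
                raise ValueError(f"unknown population {pop!r}")
            for (sub, layer), n in table.items():
                if sub not in SUBREGIONS:
                    raise ValueError(f"unknown subregion {sub!r}")
                if layer not in LAYERS:
                    raise ValueError(f"unknown layer {layer!r}")
                if n < 0:
                    raise ValueError("expected counts must be >= 0")
        for (pop, marker, layer), p in self.marker_probs.items():
            if marker not in MARKERS:
                raise ValueError(f"unknown marker {marker!r}")
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r}")
            if not 0 <= p <= 1:
                raise ValueError("marker probabilities must be in [0, 1]")


def generate_cell_table(spec: CellTableSpec) -> pd.DataFrame:
    """Draw a cell table from the generative model; deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows = []
    lo, hi = spec.bregma_range_mm
    for a in range(1, spec.n_animals + 1):
        animal = f"A{a}"
        for pop, table in spec.expected_counts.items():
            for (sub, layer), expected in table.items():
                n = rng.poisson(expected)
                for _ in range(n):
                    double = rng.random() < spec.double_projection_prob
                    row = {
                        "animal": animal,
                        "bregma_mm": float(rng.uniform(lo, hi)),
                        "subregion": sub,
                        "layer": layer,
                        "tracer_nac": int(pop == "nac" or double),
                        "tracer_vta": int(pop == "vta" or double),
                    }
                    for marker in MARKERS:
                        p = spec.marker_probs.get((pop, marker, layer))
                        row[marker] = pd.NA if p is None else int(rng.random() < p)
                    rows.append(row)
    df = pd.DataFrame(rows, columns=list(CELL_TABLE_COLUMNS))
    return validate_cell_table(df) if len(df) else df
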