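"""Synthetic tissues with known ground truth.

Two generators emulate the pipeline's two input regimes:

* :func:`generate_voronoi_tissue` rasterizes the Voronoi tessellation of
  random generator points into a labeled image.  Because the Voronoi diagram
  is the dual of the Delaunay triangulation, the true cell-adjacency graph of
  the image is known exactly: it is the Delaunay edge set of the generators.
  Optional fluorescence channels are filled from a per-type Gaussian
  intensity model, so thresholding-based phenotyping can be tested against
  known types.
* :func:`generate_spheroid_cloud` samples a spheroid-like 3D point cloud
  (uniform in a ball, thinned to a minimum separation mimicking nuclear
  exclusion) with categorical cell types, emulating table input from a
  nuclei-only 3D segmentation.

All randomness flows through :class:`numpy.random.Generator` (PCG64) seeded
from the spec, so outputs are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .cell_features import CellTable
from .errors import GenerationError, ValidationError
from .image_io import LabeledImage

__all__ = [
    "SyntheticTissueSpec",
    "VoronoiTissue",
    "generate_voronoi_tissue",
    "generate_spheroid_cloud",
]


def _default_type_fractions() -> dict[str, float]:
    return {"PCNA+": 0.25, "PCNA-": 0.75}


def _default_intensity_model() -> dict[str, dict[str, tuple[float, float]]]:
    # Two populations straddling a 6500-style intensity threshold, 5 SD away
    # from it on either side (means 9000 / 4000, SD 500).
    return {"PCNA+": {"pcna": (9000.0, 500.0)}, "PCNA-": {"pcna": (4000.0, 500.0)}}


@dataclass
class SyntheticTissueSpec:
    """Parameters of a synthetic Voronoi tissue.

    ``min_separation`` and ``membrane_gap`` are in physical units / pixels
    respectively; ``intensity_model`` maps type -> channel -> (mean, SD) of
    the per-cell intensity, with ``pixel_noise`` the per-pixel Gaussian SD
    added on top (all intensities clipped at 0).
    """

    n_cells: int = 30
    shape: tuple[int, ...] = (512, 512)
    spacing: tuple[float, ...] = (1.0, 1.0)
    seed: int = 0
    min_separation: float = 20.0
    type_fractions: dict[str, float] = field(default_factory=_default_type_fractions)
    intensity_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_intensity_model
    )
    pixel_noise: float = 50.0
    membrane_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.min_separation < 0:
            raise ValidationError("min_separation must be >= 0")
        if len(self.shape) != len(self.spacing):
            raise ValidationError("shape and spacing must have equal rank")
        if self.type_fractions:
            total = sum(self.type_fractions.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValidationError(f"type_fractions sum to {total}, expected 1")


class VoronoiTissue(NamedTuple):
    """A rasterized Voronoi tissue with its ground truth."""

    image: LabeledImage
    generators: np.ndarray  # (n, ndim) physical coords in array-axis order
    adjacency: set[tuple[int, int]]  # ground-truth Delaunay edges, labels i<j
    cell_types: list[str]  # per cell, in label order (label = index + 1)


def _sample_separated(
    rng: np.random.Generator, n: int, extent: np.ndarray, min_sep: float
) -> np.ndarray:
    """Rejection-sample ``n`` points in a box at pairwise distance >= min_sep."""
    pts: list[np.ndarray] = []
    attempts = 0
    cap = max(10_000, 1_000 * n)
    while len(pts) < n:
        if attempts >= cap:
            raise GenerationError(
                f"placed only {len(pts)}/{n} points at separation {min_sep}; "
                "lower min_separation or n_cells"
            )
        cand = rng.uniform(0.0, 1.0, size=extent.shape[0]) * extent
        attempts += 1
        if min_sep > 0 and pts:
            d2 = np.sum((np.asarray(pts) - cand) ** 2, axis=1)
            if d2.min() < min_sep**2:
                continue
        pts.append(cand)
    return np.asarray(pts)


def _nearest_two(grid: np.ndarray, gens: np.ndarray, chunk: int = 1 << 20):
    """Index of the nearest generator (lowest index on ties) and the two
    smallest distances, per grid point."""
    n = gens.shape[0]
    nearest = np.empty(grid.shape[0], dtype=np.int32)
    d1 = np.empty(grid.shape[0])
    d2 = np.empty(grid.shape[0])
    for start in range(0, grid.shape[0], chunk):
        block = grid[start : start + chunk]
        # full distance matrix per block: argmin picks the lowest index on ties
        diff = block[:, None, :] - gens[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        nearest[start : start + chunk] = np.argmin(dist2, axis=1)
        if n >= 2:
            part = np.partition(dist2, 1, axis=1)[:, :2]
            d1[start : start + chunk] = np.sqrt(part[:, 0])
            d2[start : start + chunk] = np.sqrt(part[:, 1])
        else:
            d1[start : start + chunk] = np.sqrt(dist2[:, 0])
            d2[start : start + chunk] = np.inf
    return nearest, d1, d2


def generate_voronoi_tissue(spec: SyntheticTissueSpec) -> VoronoiTissue:
    """Rasterize the Voronoi tessellation of random generator points.

    Every pixel gets the label of its nearest generator (label = generator
    index + 1; ties go to the lowest index).  With ``membrane_gap > 0``,
    pixels whose two nearest-generator distances differ by less than the gap
    — i.e. pixels within ~gap/2 of a Voronoi boundary — are set to
    background, emulating an unstained membrane ridge.  The ground-truth
    adjacency is the Delaunay edge set of the generators.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = (np.asarray(shape) - 1) * spacing

    gens = _sample_separated(rng, spec.n_cells, extent, spec.min_separation)

    axes = [np.arange(s) * sp for s, sp in zip(shape, spacing)]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)
    nearest, d1, d2 = _nearest_two(grid, gens)
    labels = (nearest + 1).astype(np.int32)
    if spec.membrane_gap > 0:
        gap_phys = spec.membrane_gap * float(np.min(spacing))
        labels[d2 - d1 < gap_phys] = 0
    labels = labels.reshape(shape)

    # ground-truth adjacency: Delaunay edges of the generators
    adjacency: set[tuple[int, int]] = set()
    if spec.n_cells >= len(shape) + 1:
        tri = Delaunay(gens)
        for simplex in tri.simplices:
            for a in range(len(simplex)):
                for b in range(a + 1, len(simplex)):
                    i, j = int(simplex[a]) + 1, int(simplex[b]) + 1
                    adjacency.add((i, j) if i < j else (j, i))

    # cell types and fluorescence
    types = sorted(spec.type_fractions)
    if types:
        probs = [spec.type_fractions[t] for t in types]
        cell_types = [str(t) for t in rng.choice(types, size=spec.n_cells, p=probs)]
    else:
        cell_types = [""] * spec.n_cells

    channels: dict[str, np.ndarray] = {}
    channel_names = sorted({ch for model in spec.intensity_model.values() for ch in model})
    for ch_name in channel_names:
        cell_means = np.zeros(spec.n_cells)
        for k, ctype in enumerate(cell_types):
            mean, sd = spec.intensity_model.get(ctype, {}).get(ch_name, (0.0, 0.0))
            cell_means[k] = max(0.0, rng.normal(mean, sd))
        ch = np.where(labels > 0, cell_means[np.maximum(labels, 1) - 1], 0.0)
        if spec.pixel_noise > 0:
            ch = ch + rng.normal(0.0, spec.pixel_noise, size=shape)
        ch = np.clip(ch, 0.0, None)
        ch[labels == 0] = 0.0
        channels[ch_name] = ch

    image = LabeledImage(labels=labels, spacing=tuple(spacing), channels=channels)
    return VoronoiTissue(image=image, generators=gens, adjacency=adjacency, cell_types=cell_types)


def generate_spheroid_cloud(
    n_cells: int = 300,
    radius: float = 75.0,
    seed: int = 0,
    type_fractions: dict[str, float] | None = None,
    min_separation: float = 12.0,
) -> CellTable:
    """Sample a spheroid-like 3D point cloud with categorical cell types.

    Centroids are uniform in a ball of the given radius (micrometres by
    convention), thinned so no two are closer than ``min_separation`` —
    about a nuclear diameter, mimicking the packing of a cell aggregate.
    Types are i.i.d. draws from ``type_fractions``.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if type_fractions is None:
        type_fractions = {"CD146+": 0.5, "CD146-": 0.5}
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    attempts, cap = 0, max(10_000, 1_000 * n_cells)
    while len(pts) < n_cells:
        if attempts >= cap:
            raise GenerationError(
                f"placed only {len(pts)}/{n_cells} points in radius {radius} "
                f"at separation {min_separation}"
            )
        attempts += 1
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        r = radius * rng.uniform() ** (1.0 / 3.0)
        cand = direction / norm * r
        if min_separation > 0 and pts:
            d2 = np.sum((np.asarray(pts) - cand) ** 2, axis=1)
            if d2.min() < min_separation**2:
                continue
        pts.append(cand)
    coords = np.asarray(pts)
    types = sorted(type_fractions)
    probs = [type_fractions[t] for t in types]
    cell_types = [str(t) for t in rng.choice(types, size=n_cells, p=probs)]
    df = pd.DataFrame(
        {
            "label": np.arange(1, n_cells + 1),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "cell_type": cell_types,
        }
    )
    return CellTable(df, ndim=3, spacing=None)
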