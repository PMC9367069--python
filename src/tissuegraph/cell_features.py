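"""Per-cell attribute measurement on labeled images.

For every positive label the module measures the node attributes of the
tissue graph: geometric centre ``x, y(, z)``, mask size (area in 2D, volume
in 3D), eccentricity and principal-axis orientation from the second central
moments, and the mean fluorescence per channel.  All measurements are made in
physical units: pixel indices are scaled by the per-axis spacing before any
moment is computed, so orientations are physical angles even for anisotropic
voxels (the usual case in 3D stacks, where z-spacing differs from xy).

Orientation and eccentricity come from the second central moment (covariance)
matrix ``C`` of the member pixel coordinates.  With eigenvalues
``lam_1 >= ... >= lam_d``,

    eccentricity = sqrt(1 - lam_d / lam_1)

which reduces to the standard ellipse eccentricity in 2D and extends it to
3D with a single formula.  ``theta`` is the angle of the major axis
(``lam_1`` eigenvector): in 2D the angle with the x-axis folded into
``(-pi/2, pi/2]``; in 3D the polar angle of the axis, with ``psi`` its
azimuth, the axis sign fixed so its z (then y, then x) component is >= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .image_io import LabeledImage

__all__ = [
    "CellTable",
    "extract_cells",
    "mask_moments",
    "measure_fluorescence",
    "classify_by_threshold",
]


@dataclass
class CellTable:
    """One row per cell; the node-attribute store of the tissue graph.

    ``df`` always has a unique integer ``label`` column and physical
    coordinate columns ``x, y`` (``z`` in 3D); measured tables add ``area``,
    ``eccentricity``, ``theta`` (``psi`` in 3D) and ``mean_<channel>``
    columns, plus an optional categorical ``cell_type``.
    """

    df: pd.DataFrame
    ndim: int
    spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValidationError(f"ndim must be 2 or 3, got {self.ndim}")
        if "label" in self.df.columns and self.df["label"].duplicated().any():
            raise ValidationError("cell labels must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def positions(self) -> np.ndarray:
        """Centroids as an ``(n, ndim)`` array in ``x, y(, z)`` order."""
        cols = ["x", "y", "z"][: self.ndim]
        return self.df[cols].to_numpy(dtype=float)

    def copy(self) -> "CellTable":
        return CellTable(self.df.copy(), self.ndim, self.spacing)


def _label_pixel_groups(labels: np.ndarray):
    """Split nonzero pixel coordinates by label.

    Returns ``(uniq, counts, index_arrays)`` where ``index_arrays`` is the
    per-axis coordinate tuple of all foreground pixels sorted by label, and
    ``counts`` gives the slice length per label in ``uniq`` order.
    """
    idx = np.nonzero(labels)
    vals = labels[idx]
    uniq, inv = np.unique(vals, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    counts = np.bincount(inv, minlength=len(uniq))
    sorted_idx = tuple(ax[order] for ax in idx)
    return uniq, counts, sorted_idx


def _principal_axes(coords_xy: np.ndarray) -> tuple[float, float, float | None]:
    """Eccentricity and orientation from pixel coordinates in x,y(,z) order.

    Single-pixel (or otherwise fully degenerate) masks return zeros by
    convention.
    """
    d = coords_xy.shape[1]
    if coords_xy.shape[0] < 2:
        return 0.0, 0.0, 0.0 if d == 3 else None
    centred = coords_xy - coords_xy.mean(axis=0)
    cov = centred.T @ centred / coords_xy.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_max, lam_min = float(evals[-1]), float(evals[0])
    if lam_max <= 0.0:
        return 0.0, 0.0, 0.0 if d == 3 else None
    ecc = math.sqrt(max(0.0, 1.0 - lam_min / lam_max))
    v = evecs[:, -1]
    if d == 2:
        theta = math.atan2(v[1], v[0])
        # fold into (-pi/2, pi/2]: an axis has no sign
        if theta > math.pi / 2:
            theta -= math.pi
        elif theta <= -math.pi / 2:
            theta += math.pi
        return ecc, theta, None
    # 3D: fix the axis sign so the z (then y, then x) component is >= 0
    for comp in (2, 1, 0):
        if v[comp] != 0.0:
            if v[comp] < 0.0:
                v = -v
            break
    theta = math.acos(min(1.0, max(-1.0, float(v[2]))))
    psi = math.atan2(v[1], v[0])
    return ecc, theta, psi


def extract_cells(
    image: LabeledImage,
    measure_geometry: bool = True,
    measure_fluorescence: bool = True,
) -> CellTable:
    """Measure one record per cell mask in ``image``.

    Centroid = mean of member pixel coordinates scaled by spacing; area =
    pixel count times the pixel area (2D) or voxel volume (3D).  Shape
    (eccentricity, orientation) and per-channel mean fluorescence are
    included when the corresponding flag is set.  An empty image yields an
    empty table.
    """
    d = image.ndim
    uniq, counts, idx = _label_pixel_groups(image.labels)
    spacing = np.asarray(image.spacing)

    data: dict[str, np.ndarray] = {"label": uniq.astype(np.int64)}
    # centroids, physical: mean index per axis * spacing, reported as x,y(,z)
    boundaries = np.concatenate([[0], np.cumsum(counts)])
    cent_axis = np.empty((d, len(uniq)))
    for a in range(d):
        sums = np.add.reduceat(idx[a].astype(np.float64), boundaries[:-1]) if len(uniq) else np.empty(0)
        cent_axis[a] = sums / np.maximum(counts, 1) * spacing[a]
    axis_names = ("y", "x") if d == 2 else ("z", "y", "x")
    for a, name in enumerate(axis_names):
        data[name] = cent_axis[a]
    data["area"] = counts * image.pixel_volume

    if measure_geometry:
        ecc = np.empty(len(uniq))
        theta = np.empty(len(uniq))
        psi = np.empty(len(uniq)) if d == 3 else None
        phys = np.column_stack([idx[a] * spacing[a] for a in reversed(range(d))])
        for k in range(len(uniq)):
            sl = slice(boundaries[k], boundaries[k + 1])
            e, t, p = _principal_axes(phys[sl])
            ecc[k], theta[k] = e, t
            if psi is not None:
                psi[k] = p
        data["eccentricity"] = ecc
        data["theta"] = theta
        if psi is not None:
            data["psi"] = psi

    if measure_fluorescence:
        for name, ch in image.channels.items():
            vals = np.asarray(ch, dtype=np.float64)[idx]
            sums = np.add.reduceat(vals, boundaries[:-1]) if len(uniq) else np.empty(0)
            data[f"mean_{name}"] = sums / np.maximum(counts, 1)

    df = pd.DataFrame(data)
    order = [c for c in ("label", "x", "y", "z", "area", "eccentricity", "theta", "psi") if c in df]
    order += [c for c in df.columns if c not in order]
    return CellTable(df[order], ndim=d, spacing=image.spacing)


def mask_moments(image: LabeledImage, label: int) -> tuple[float, float, float | None]:
    """Eccentricity and orientation of one mask.

    Returns ``(eccentricity, theta, psi)`` with ``psi`` None in 2D.  Raises
    ``KeyError`` if the label is absent.
    """
    idx = np.nonzero(image.labels == label)
    if idx[0].size == 0:
        raise KeyError(f"label {label} not present in image")
    spacing = image.spacing
    d = image.ndim
    phys = np.column_stack([idx[a] * spacing[a] for a in reversed(range(d))])
    return _principal_axes(phys)


def measure_fluorescence(image: LabeledImage) -> dict[tuple[int, str], float]:
    """Mean intensity of every channel over every cell mask.

    Returns a map ``(label, channel) -> mean``.  With nucleus-only masks this
    is, by construction, the mean over the nucleus pixels only.
    """
    if not image.channels:
        raise ConfigError("image has no fluorescence channels")
    uniq, counts, idx = _label_pixel_groups(image.labels)
    boundaries = np.concatenate([[0], np.cumsum(counts)])
    out: dict[tuple[int, str], float] = {}
    for name, ch in image.channels.items():
        vals = np.asarray(ch, dtype=np.float64)[idx]
        sums = np.add.reduceat(vals, boundaries[:-1]) if len(uniq) else np.empty(0)
        means = sums / np.maximum(counts, 1)
        for k, lab in enumerate(uniq):
            out[(int(lab), name)] = float(means[k])
    return out


def classify_by_threshold(
    table: CellTable,
    channel: str,
    threshold: float,
    positive_label: str = "positive",
    negative_label: str = "negative",
) -> CellTable:
    """Binarize cells on mean intensity: strictly above ``threshold`` is positive.

    Sets ``cell_type`` and leaves every other field untouched.  A mean that
    equals the threshold exactly is negative (strict inequality keeps the
    rule deterministic).
    """
    col = f"mean_{channel}"
    if col not in table.df.columns:
        raise ValidationError(f"no fluorescence column {col!r} in table")
    missing = table.df.loc[table.df[col].isna(), "label"].tolist()
    if missing:
        raise ValidationError(f"cells missing {channel!r} fluorescence: {missing}")
    out = table.copy()
    out.df["cell_type"] = np.where(
        out.df[col] > threshold, positive_label, negative_label
    )
    return out
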