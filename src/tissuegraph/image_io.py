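"""Reading and writing the pipeline's on-disk formats.

Labeled images come in as TIFF stacks (2D ``(y, x)`` or 3D ``(z, y, x)``,
optionally with a leading channel axis), cell tables as CSV, graphs go out as
GraphML or node-link JSON, and run parameters are read from a flat TOML file.

Conventions
-----------
Arrays are indexed in image order — ``(y, x)`` in 2D, ``(z, y, x)`` in 3D —
and ``spacing`` is given per axis in that same order.  All exported
coordinates are physical ``x, y(, z)`` values: a pixel's position is its
integer index scaled by the spacing (no half-pixel offset; constant offsets
cancel in every distance).
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, FormatError, SerializationError, ValidationError

__all__ = [
    "LabeledImage",
    "RunConfig",
    "read_labeled_image",
    "write_labeled_image",
    "read_cell_table",
    "write_cell_table",
    "write_graph",
    "read_graph",
    "load_run_config",
]

CONSTRUCTION_RULES = ("geometric", "delaunay", "contact")


@dataclass
class LabeledImage:
    """A segmented tissue: integer cell masks plus optional fluorescence.

    Parameters
    ----------
    labels
        Integer array of rank 2 or 3.  Each cell is a unique positive label;
        0 is background.
    spacing
        Physical size of one pixel along each array axis, in image axis order
        (``(y, x)`` or ``(z, y, x)``), e.g. micrometres.
    channels
        Named scalar fluorescence arrays congruent with ``labels``.
    """

    labels: np.ndarray
    spacing: tuple[float, ...]
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim not in (2, 3):
            raise ValidationError(f"labels must be rank 2 or 3, got rank {self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.floating) and np.all(
                self.labels == np.floor(self.labels)
            ):
                self.labels = self.labels.astype(np.int64)
            else:
                raise FormatError("label channel must contain integer values")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.labels.ndim:
            raise ConfigError(
                f"spacing has {len(self.spacing)} entries for a rank-{self.labels.ndim} image"
            )
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("all spacing entries must be strictly positive")
        for name, ch in self.channels.items():
            arr = np.asarray(ch)
            if arr.shape != self.labels.shape:
                raise ValidationError(
                    f"channel {name!r} has shape {arr.shape}, labels {self.labels.shape}"
                )
            self.channels[name] = arr

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    @property
    def cell_labels(self) -> np.ndarray:
        """Sorted unique positive labels (the cell inventory)."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.size)

    @property
    def pixel_volume(self) -> float:
        """Physical area (2D) or volume (3D) of one pixel/voxel."""
        return math.prod(self.spacing)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    construction_rule: str = "delaunay"
    dmax: float | None = None
    spacing: tuple[float, ...] | None = None
    thresholds: dict[str, float] = field(default_factory=dict)
    touch_distance: int = 1
    label_channel: int | str = 0
    layer_method: str | None = None

    def __post_init__(self) -> None:
        if self.construction_rule not in CONSTRUCTION_RULES:
            raise ConfigError(
                f"construction_rule must be one of {CONSTRUCTION_RULES}, "
                f"got {self.construction_rule!r}"
            )
        if self.dmax is not None and self.dmax <= 0:
            raise ConfigError("dmax must be strictly positive")
        if self.touch_distance < 1:
            raise ConfigError("touch_distance must be >= 1")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a flat TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {
        "construction_rule",
        "dmax",
        "spacing",
        "thresholds",
        "touch_distance",
        "label_channel",
        "layer_method",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "spacing" in raw:
        raw["spacing"] = tuple(raw["spacing"])
    return RunConfig(**raw)


def read_labeled_image(
    path: str | Path,
    label_channel: int | str = 0,
    spacing: tuple[float, ...] | None = None,
    channel_names: list[str] | None = None,
) -> LabeledImage:
    """Read a labeled TIFF, attaching any extra channels as fluorescence.

    The channel axis is found from the TIFF axes metadata when present
    (files written by :func:`write_labeled_image` carry it); otherwise a
    leading axis beyond the image rank implied by ``spacing`` is treated as
    the channel axis, and with no ``spacing`` either the whole array is taken
    as a single-channel image with unit spacing.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. "YX", "CYX", "CZYX"; "Q" marks unknown axes
        if channel_names is None and tif.shaped_metadata:
            names = tif.shaped_metadata[0].get("channel_names")
            if names:
                channel_names = list(names)
    if "C" in axes and all(a in "CZYX" for a in axes):
        c_axis = axes.index("C")
        planes = np.moveaxis(arr, c_axis, 0)
        rank = arr.ndim - 1
        if spacing is None:
            spacing = (1.0,) * rank
        else:
            spacing = tuple(float(s) for s in spacing)
            if len(spacing) != rank:
                raise ConfigError(
                    f"spacing of length {len(spacing)} for a rank-{rank} image"
                )
    else:
        if spacing is None:
            if arr.ndim not in (2, 3):
                raise FormatError(
                    f"cannot infer image rank of a {arr.ndim}-axis TIFF without spacing"
                )
            rank = arr.ndim
            spacing = (1.0,) * rank
        else:
            spacing = tuple(float(s) for s in spacing)
            rank = len(spacing)
        if arr.ndim == rank:
            planes = arr[np.newaxis]
        elif arr.ndim == rank + 1:
            planes = arr
        else:
            raise ConfigError(
                f"spacing of length {rank} does not match a {arr.ndim}-axis TIFF"
            )

    n_ch = planes.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    if len(channel_names) != n_ch:
        raise ConfigError(f"{len(channel_names)} channel names for {n_ch} channels")
    if isinstance(label_channel, str):
        if label_channel not in channel_names:
            raise ConfigError(f"label channel {label_channel!r} not in {channel_names}")
        label_idx = channel_names.index(label_channel)
    else:
        label_idx = int(label_channel)
        if not 0 <= label_idx < n_ch:
            raise ConfigError(f"label channel index {label_idx} out of range (0..{n_ch - 1})")

    labels = planes[label_idx]
    if not np.issubdtype(labels.dtype, np.integer) and not (
        np.issubdtype(labels.dtype, np.floating) and np.all(labels == np.floor(labels))
    ):
        raise FormatError("designated label channel does not contain integer values")
    channels = {
        channel_names[i]: planes[i].astype(np.float64)
        for i in range(n_ch)
        if i != label_idx
    }
    return LabeledImage(labels=labels, spacing=spacing, channels=channels)


def write_labeled_image(image: LabeledImage, path: str | Path) -> None:
    """Write a LabeledImage as a TIFF (labels first, then channels).

    Multi-channel images carry axes metadata (``CYX`` / ``CZYX``) so that
    :func:`read_labeled_image` can locate the channel axis without hints.
    """
    if image.channels:
        # float64 keeps channel round-trips exact (labels are exact anyway)
        stack = np.stack(
            [image.labels.astype(np.float64)]
            + [np.asarray(c, dtype=np.float64) for c in image.channels.values()]
        )
        axes = "CYX" if image.ndim == 2 else "CZYX"
        names = ["labels"] + list(image.channels)
        tifffile.imwrite(str(path), stack, metadata={"axes": axes, "channel_names": names})
    else:
        tifffile.imwrite(str(path), image.labels.astype(np.int32))


# -- cell tables -------------------------------------------------------------

#: canonical cell-table column order; ``mean_<channel>`` columns follow.
CANONICAL_COLUMNS = ["label", "x", "y", "z", "area", "eccentricity", "theta", "psi"]


def read_cell_table(path: str | Path, column_map: dict[str, str] | None = None):
    """Read a CSV cell table into a :class:`~tissuegraph.cell_features.CellTable`.

    ``column_map`` renames source columns to canonical names (``x``, ``y``,
    ``z``, ``label``, ...).  Dimensionality is 2 unless a ``z`` column is
    present; extra columns are preserved as node attributes.
    """
    from .cell_features import CellTable

    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "x" not in df.columns or "y" not in df.columns:
        raise FormatError(f"cell table {path} must have x and y columns (after mapping)")
    ndim = 3 if "z" in df.columns else 2
    if "label" not in df.columns:
        df.insert(0, "label", np.arange(1, len(df) + 1))
    if df["label"].duplicated().any():
        dup = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValidationError(f"duplicate cell labels in table: {dup}")
    df["label"] = df["label"].astype(np.int64)
    return CellTable(df.reset_index(drop=True), ndim=ndim, spacing=None)


def write_cell_table(table, path: str | Path) -> None:
    """Write a CellTable as CSV with canonical column order."""
    df = table.df
    ordered = [c for c in CANONICAL_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, index=False)


# -- graphs ------------------------------------------------------------------


def _check_serializable(graph: nx.Graph) -> None:
    for node, attrs in graph.nodes(data=True):
        for key, val in attrs.items():
            if not isinstance(val, (int, float, str, bool, np.integer, np.floating)):
                raise SerializationError(
                    f"node {node} attribute {key!r} of type {type(val).__name__} "
                    "cannot be serialized; flatten it to scalar keys"
                )


def _native_graph(graph: nx.Graph) -> nx.Graph:
    """Copy with numpy scalars cast to Python natives (GraphML-safe)."""
    out = nx.Graph(**{k: _native(v) for k, v in graph.graph.items()})
    for node, attrs in graph.nodes(data=True):
        out.add_node(_native(node), **{k: _native(v) for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        out.add_edge(_native(u), _native(v), **{k: _native(a) for k, a in attrs.items()})
    return out


def _native(v: Any) -> Any:
    if isinstance(v, np.generic):
        return v.item()
    return v


def write_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Serialize a tissue graph as GraphML (default) or node-link JSON."""
    _check_serializable(graph)
    g = _native_graph(graph)
    if format == "graphml":
        nx.write_graphml(g, str(path))
    elif format == "node-link-json":
        with open(path, "w") as fh:
            json.dump(nx.node_link_data(g, edges="links"), fh, indent=1)
    else:
        raise ConfigError(f"unknown graph format {format!r}")


def read_graph(path: str | Path, format: str | None = None) -> nx.Graph:
    """Read a graph written by :func:`write_graph`; node ids restored to int."""
    path = Path(path)
    if format is None:
        format = "node-link-json" if path.suffix == ".json" else "graphml"
    if format == "graphml":
        g = nx.read_graphml(str(path), node_type=int)
        # read_graphml returns per-format graph metadata keys untouched
        return nx.Graph(g)
    if format == "node-link-json":
        with open(path) as fh:
            data = json.load(fh)
        return nx.node_link_graph(data, edges="links")
    raise ConfigError(f"unknown graph format {format!r}")
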