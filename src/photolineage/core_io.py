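"""Shared data types, image/table IO, projections and ROI handling.

Conventions used throughout the package:

* image axis order is ``(t, c, z, y, x)`` with singleton axes allowed;
* pixel indices are 0-based; a centroid in physical units is the unweighted
  mean of member pixel indices multiplied by the per-axis pixel size;
* nucleus tables use the fixed CSV schema ``frame, label, centroid_z_um,
  centroid_y_um, centroid_x_um, voxels, mean_<role>, integrated_<role>,
  bgsub_mean_<role>``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNEL_ROLES = ("membrane", "nuclear_unconverted", "nuclear_converted")

NUCLEUS_BASE_COLUMNS = [
    "frame",
    "label",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "voxels",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ChannelStack:
    """Multi-channel, optionally time-resolved image volume.

    Parameters
    ----------
    pixels:
        Non-negative intensity array indexed ``(t, c, z, y, x)``.
    channel_roles:
        One role per channel, drawn from :data:`CHANNEL_ROLES`, unique.
    pixel_size_um:
        Physical spacing ``(z, y, x)`` in micrometres, strictly positive.
    time_step_min:
        Frame interval in minutes; ``None`` for single frames.
    """

    pixels: np.ndarray
    channel_roles: tuple[str, ...]
    pixel_size_um: tuple[float, float, float]
    time_step_min: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 5:
            raise ValueError(f"pixels must be 5D (t,c,z,y,x), got {self.pixels.ndim}D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be non-negative")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.pixels.shape[1]:
            raise ValueError(
                f"{len(self.channel_roles)} roles for {self.pixels.shape[1]} channels"
            )
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError("channel roles must be unique")
        for role in self.channel_roles:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        self.pixel_size_um = tuple(float(v) for v in self.pixel_size_um)
        if len(self.pixel_size_um) != 3 or any(v <= 0 for v in self.pixel_size_um):
            raise ValueError("pixel_size_um must be 3 strictly positive values (z,y,x)")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.pixels.shape[2:]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(t, z, y, x)`` sub-array for one channel role."""
        try:
            c = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"stack has no channel with role {role!r}") from None
        return self.pixels[:, c]


@dataclass
class LabelMask:
    """Integer label image aligned to one spatial frame; 0 is background."""

    labels: np.ndarray
    frame: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim not in (2, 3):
            raise ValueError("labels must be (y,x) or (z,y,x)")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("positive labels must form the contiguous set 1..N")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def spatial3d(self) -> np.ndarray:
        """Labels as (z, y, x) with a singleton z if the mask is 2D."""
        return self.labels if self.labels.ndim == 3 else self.labels[None]


@dataclass
class RoiPolygon:
    """Simple polygon ROI with (y, x) vertices in pixel coordinates."""

    vertices: np.ndarray
    sense: str = "keep_inside"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (y, x) points")
        if np.unique(self.vertices, axis=0).shape[0] < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        if self.sense not in ("keep_inside", "keep_outside"):
            raise ValueError("sense must be keep_inside or keep_outside")
        if not _polygon_is_simple(self.vertices):
            raise ValueError("polygon must be simple (non-self-intersecting)")


def _polygon_is_simple(verts: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon([(x, y) for y, x in verts]).is_valid


@dataclass
class PipelineConfig:
    """Validated bundle of all stage parameters for one pipeline run."""

    scenario: str = "regeneration_7dpa"
    seed: int = 0
    out_dir: str = "photolineage_out"
    # segmentation
    k_bg: float = 3.0
    min_size_px: int = 20
    membrane_guided: bool = False
    # mixture
    k_min: int = 1
    k_max: int = 6
    restarts: int = 20
    halving_constrained: bool = False
    force_k: int | None = None
    # tracking
    gate_um: float | None = None
    direction: str = "forward"
    # spatial
    n_perm: int = 999
    bright_rule: str = "component:0"
    # generator
    no_noise: bool = False

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.gate_um is not None and self.gate_um <= 0:
            raise ValueError("gate_um must be > 0")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be forward or backward")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# image IO
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    roles: Sequence[str],
    pixel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    time_step_min: float | None = None,
) -> ChannelStack:
    """Read a TIFF/OME-TIFF into a :class:`ChannelStack`.

    The axis order is normalized to ``(t, c, z, y, x)`` using the file's
    axes metadata where available; unknown axes are assigned to the channel
    axis when their length matches ``len(roles)``, otherwise to time.
    """
    roles = list(roles)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
    except Exception as exc:  # pragma: no cover - exercised via error test
        raise PipelineError(f"cannot read image file {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim != len(axes):
        axes = "Q" * (arr.ndim - len(axes)) + axes

    assigned: dict[str, int] = {}
    for pos, letter in enumerate(axes):
        if letter in "TZYX" and letter not in assigned:
            assigned[letter] = pos
        elif letter in "CS" and "C" not in assigned:
            assigned["C"] = pos
        else:  # unknown axis: channel if the size matches the role count
            if "C" not in assigned and arr.shape[pos] == len(roles):
                assigned["C"] = pos
            elif "T" not in assigned:
                assigned["T"] = pos
            elif "Z" not in assigned:
                assigned["Z"] = pos
            else:
                raise PipelineError(f"cannot interpret axes {axes!r} of {path}")

    order = [assigned[a] for a in "TCZYX" if a in assigned]
    arr = np.transpose(arr, order)
    for i, a in enumerate("TCZYX"):
        if a not in assigned:
            arr = np.expand_dims(arr, i)

    if arr.shape[1] != len(roles):
        raise PipelineError(
            f"{path}: {len(roles)} roles given but image has {arr.shape[1]} channels"
        )
    if arr.min() < 0:
        raise PipelineError(f"{path}: negative intensities after decoding")
    return ChannelStack(arr.astype(np.float64), tuple(roles), pixel_size_um, time_step_min)


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    tifffile.imwrite(
        str(path),
        stack.pixels.astype(np.float32),
        ome=True,
        metadata={"axes": "TCZYX"},
    )


def write_labels(mask: LabelMask, path: str | Path) -> None:
    tifffile.imwrite(str(path), mask.labels.astype(np.uint32))


def read_labels(path: str | Path, frame: int = 0) -> LabelMask:
    return LabelMask(tifffile.imread(str(path)).astype(np.int64), frame=frame)


# ---------------------------------------------------------------------------
# table / JSON IO
# ---------------------------------------------------------------------------


def write_nucleus_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_nucleus_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_bytes(dumps_canonical(obj))


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def dumps_canonical(obj: dict) -> bytes:
    """Deterministic JSON encoding (sorted keys, native floats)."""
    return (json.dumps(_jsonable(obj), sort_keys=True, indent=2) + "\n").encode()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def write_outputs(obj, path: str | Path) -> None:
    """Write any pipeline artifact to ``path`` based on its type."""
    from . import tracking
    from .division_mixture import MixtureModel
    from .spatial_stats import SpatialResult

    if isinstance(obj, pd.DataFrame):
        write_nucleus_table(obj, path)
    elif isinstance(obj, ChannelStack):
        write_stack(obj, path)
    elif isinstance(obj, LabelMask):
        write_labels(obj, path)
    elif isinstance(obj, tracking.LineageForest):
        write_json(obj.to_dict(), path)
    elif isinstance(obj, MixtureModel):
        write_json(obj.to_dict(), path)
    elif isinstance(obj, SpatialResult):
        write_json(obj.to_dict(), path)
    elif isinstance(obj, dict):
        write_json(obj, path)
    else:
        raise TypeError(f"don't know how to write {type(obj).__name__}")


# ---------------------------------------------------------------------------
# projections and ROI
# ---------------------------------------------------------------------------


def project_mip(stack: ChannelStack) -> ChannelStack:
    """Maximum intensity projection along z; metadata carried over."""
    projected = stack.pixels.max(axis=2, keepdims=True)
    return ChannelStack(projected, stack.channel_roles, stack.pixel_size_um, stack.time_step_min)


def points_in_polygon(points_yx: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test; on-edge counts inside.

    Vectorized over points: casts a ray in +x and counts edge crossings.
    """
    pts = np.atleast_2d(np.asarray(points_yx, dtype=np.float64))
    py, px = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    verts = np.asarray(vertices, dtype=np.float64)
    n = len(verts)
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        # point exactly on the segment
        dy, dx = y2 - y1, x2 - x1
        seg_len2 = dy * dy + dx * dx
        if seg_len2 > 0:
            t = ((py - y1) * dy + (px - x1) * dx) / seg_len2
            t = np.clip(t, 0.0, 1.0)
            d2 = (py - (y1 + t * dy)) ** 2 + (px - (x1 + t * dx)) ** 2
            on_edge |= d2 < 1e-18
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * dx / np.where(dy == 0, np.inf, dy)
        inside ^= crosses & (px < x_at)
    return inside | on_edge


def apply_roi(frame: np.ndarray, roi: RoiPolygon) -> np.ndarray:
    """Zero out pixels on the discarded side of a polygon ROI.

    Works on any array whose trailing two axes are (y, x); pixel membership
    is decided by the even-odd rule at the pixel center, boundary pixels
    belonging to the inside.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[-2:]
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    inside = points_in_polygon(pts, roi.vertices).reshape(h, w)
    keep = inside if roi.sense == "keep_inside" else ~inside
    return np.where(keep, frame, 0)
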