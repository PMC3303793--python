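"""Per-nucleus intensity measurement and colocalization calls.

The nucleus table is the hand-off contract between segmentation and every
downstream stage; its columns are fixed (see :mod:`photolineage.core_io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import ChannelStack, LabelMask
from .segmentation import BackgroundEstimate


@dataclass
class ColocalizationCall:
    label: int
    ratio: float  # unconverted / (unconverted + converted), nan if both 0
    call: str  # non_divided | divided_or_renewed | indeterminate


def measure_nuclei(
    mask: LabelMask,
    stack: ChannelStack,
    backgrounds: dict[str, BackgroundEstimate] | None = None,
    frame: int | None = None,
) -> pd.DataFrame:
    """One record per label: centroid (um), size, per-channel intensities.

    Means are arithmetic over member pixels; centroids are unweighted means
    of 0-based pixel indices scaled by the pixel size. Background-subtracted
    means are clamped at 0.
    """
    t = mask.frame if frame is None else frame
    labels3d = mask.spatial3d()
    if labels3d.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack spatial shape")
    n = mask.n_labels
    index = np.arange(1, n + 1)
    rows: dict[str, np.ndarray] = {}
    rows["frame"] = np.full(n, t, dtype=int)
    rows["label"] = index
    if n:
        voxels = ndimage.sum_labels(np.ones(labels3d.shape), labels3d, index=index)
        cents = np.asarray(
            ndimage.center_of_mass(np.ones(labels3d.shape), labels3d, index=index)
        )
    else:
        voxels = np.zeros(0)
        cents = np.zeros((0, 3))
    pz, py, px = stack.pixel_size_um
    rows["centroid_z_um"] = cents[:, 0] * pz if n else np.zeros(0)
    rows["centroid_y_um"] = cents[:, 1] * py if n else np.zeros(0)
    rows["centroid_x_um"] = cents[:, 2] * px if n else np.zeros(0)
    rows["voxels"] = voxels.astype(int)
    for role in stack.channel_roles:
        img = stack.channel(role)[t]
        if n:
            means = ndimage.mean(img, labels3d, index=index)
        else:
            means = np.zeros(0)
        means = np.asarray(means, dtype=float)
        rows[f"mean_{role}"] = means
        rows[f"integrated_{role}"] = means * voxels
        bg = (backgrounds or {}).get(role)
        level = bg.level if bg is not None else 0.0
        rows[f"bgsub_mean_{role}"] = np.clip(means - level, 0.0, None)
    return pd.DataFrame(rows)


def classify_colocalization(
    record: pd.Series,
    r_low: float = 0.2,
    bright_floor: float = 0.0,
) -> ColocalizationCall:
    """Call divided vs non-divided from the unconverted/converted balance.

    r = u / (u + c) on background-subtracted means. Bright converted nuclei
    lacking unconverted signal (r < r_low) are called non-divided; nuclei
    with substantial unconverted signal are divided (or label-renewed);
    everything else is indeterminate.
    """
    if not 0.0 < r_low < 1.0:
        raise ValueError("r_low must be in (0, 1)")
    c = float(record["bgsub_mean_nuclear_converted"])
    u = float(record["bgsub_mean_nuclear_unconverted"])
    denom = u + c
    r = u / denom if denom > 0 else float("nan")
    if c >= bright_floor and denom > 0 and r < r_low:
        call = "non_divided"
    elif denom > 0 and r >= r_low:
        call = "divided_or_renewed"
    else:
        call = "indeterminate"
    return ColocalizationCall(label=int(record["label"]), ratio=r, call=call)
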