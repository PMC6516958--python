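"""3D chromosome-territory volume and overlap quantification.

Per channel: an iterative-intermeans (isodata-variant) threshold is
computed on the whole-stack histogram, connected components of the
binary mask are extracted (26-connectivity by default), components of
30 voxels or fewer are discarded as background, and the survivors are
merged into a single territory object.  Volumes and all pairwise
intersection volumes between channels are then measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}


@dataclass
class QuantParams:
    min_object_voxels: int = 30  # kept iff size > this (strict)
    connectivity: int = 26
    threshold_method: str = "intermeans"

    def __post_init__(self) -> None:
        if self.min_object_voxels < 0:
            raise ValueError("min_object_voxels must be >= 0")
        if self.connectivity not in CONNECTIVITY_TO_SKIMAGE:
            raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_TO_SKIMAGE)}")


def intermeans_threshold(values: np.ndarray) -> float:
    """Iterative intermeans threshold on the full intensity histogram.

    Starting from the global mean, the threshold is repeatedly replaced
    by the midpoint of the means of the two classes it induces
    (background <= T < foreground) until it stabilizes.  Raises on a
    constant image, whose histogram is degenerate.
    """
    flat = np.asarray(values).ravel()
    if flat.size == 0:
        raise ValueError("empty stack")
    lo, hi = flat.min(), flat.max()
    if lo == hi:
        raise ValueError(
            f"constant image (all voxels = {lo}): histogram is degenerate, "
            "no threshold exists"
        )
    bins = np.arange(int(lo), int(hi) + 2)
    hist, edges = np.histogram(flat, bins=bins)
    centers = edges[:-1].astype(np.float64)
    weighted = hist * centers
    t = float(flat.mean())
    for _ in range(1000):
        below = centers <= t
        n_below, n_above = hist[below].sum(), hist[~below].sum()
        mean_below = weighted[below].sum() / n_below if n_below else centers[0]
        mean_above = weighted[~below].sum() / n_above if n_above else centers[-1]
        new_t = (mean_below + mean_above) / 2.0
        if abs(new_t - t) < 0.5:  # stable at histogram-bin resolution
            t = new_t
            break
        t = new_t
    return t


def threshold_stack(stack: np.ndarray, method: str = "intermeans") -> np.ndarray:
    """Binary mask of voxels strictly above the stack-wide threshold."""
    if method != "intermeans":
        raise ValueError(f"unknown threshold method {method!r}")
    t = intermeans_threshold(stack)
    return np.asarray(stack) > t


def extract_objects(mask: np.ndarray, params: QuantParams | None = None
                    ) -> tuple[np.ndarray, dict[int, int]]:
    """Label connected components and drop those of <= min_object_voxels.

    Returns the relabeled array (discarded components zeroed) and a
    mapping of surviving label -> voxel count.
    """
    params = params or QuantParams()
    mask = np.asarray(mask).astype(bool)
    labels = cc_label(mask, connectivity=CONNECTIVITY_TO_SKIMAGE[params.connectivity])
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes > params.min_object_voxels)
    keep = keep[keep != 0]
    out = np.where(np.isin(labels, keep), labels, 0)
    return out, {int(lbl): int(sizes[lbl]) for lbl in keep}


@dataclass
class TerritoryStats:
    channels: list[str]
    volumes: dict[str, int]  # merged-object voxel counts
    overlap: pd.DataFrame  # symmetric pairwise intersection voxel counts
    overlap_fraction: pd.DataFrame  # intersection / volume of the row channel
    volumes_um3: dict[str, float] | None = None

    def to_csv(self, path) -> None:
        rows = []
        for ch in self.channels:
            row = {"channel": ch, "volume_voxels": self.volumes[ch]}
            if self.volumes_um3 is not None:
                row["volume_um3"] = self.volumes_um3[ch]
            for other in self.channels:
                row[f"overlap_{other}"] = self.overlap.loc[ch, other]
                row[f"overlap_frac_{other}"] = self.overlap_fraction.loc[ch, other]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def territory_mask(stack: np.ndarray, params: QuantParams | None = None) -> np.ndarray:
    """Threshold one channel and merge surviving objects into one mask."""
    params = params or QuantParams()
    mask = threshold_stack(stack, params.threshold_method)
    labeled, _ = extract_objects(mask, params)
    return labeled > 0


def measure_territories(stacks: Mapping[str, np.ndarray],
                        params: QuantParams | None = None,
                        voxel_size: tuple[float, float, float] | None = None
                        ) -> TerritoryStats:
    """Full per-nucleus quantification across channels.

    ``stacks`` maps channel name to its 3D (z, y, x) intensity array;
    all channels must share dimensions.  ``voxel_size`` (um per axis)
    additionally reports volumes in cubic micrometers.
    """
    params = params or QuantParams()
    channels = list(stacks)
    if not channels:
        raise ValueError("need at least one channel")
    shapes = {ch: np.asarray(stacks[ch]).shape for ch in channels}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"channel dimensions differ: {shapes}")

    masks = {ch: territory_mask(stacks[ch], params) for ch in channels}
    volumes = {ch: int(masks[ch].sum()) for ch in channels}
    overlap = pd.DataFrame(0, index=channels, columns=channels, dtype=np.int64)
    for i, a in enumerate(channels):
        for b in channels[i:]:
            inter = int(np.count_nonzero(masks[a] & masks[b]))
            overlap.loc[a, b] = inter
            overlap.loc[b, a] = inter
    with np.errstate(divide="ignore", invalid="ignore"):
        vol_col = np.array([volumes[ch] for ch in channels], dtype=float)
        frac = overlap.to_numpy(dtype=float) / vol_col[:, None]
    overlap_fraction = pd.DataFrame(np.nan_to_num(frac), index=channels, columns=channels)

    volumes_um3 = None
    if voxel_size is not None:
        voxel_um3 = float(np.prod(voxel_size))
        volumes_um3 = {ch: volumes[ch] * voxel_um3 for ch in channels}
    return TerritoryStats(channels, volumes, overlap, overlap_fraction, volumes_um3)


def read_stack_tiff(path, n_channels: int | None = None) -> dict[str, np.ndarray]:
    """Read a multi-channel TIFF written as (C, Z, Y, X) into channel arrays."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[None, ...]
    if arr.ndim != 4:
        raise ValueError(f"expected a (C, Z, Y, X) stack, got shape {arr.shape}")
    if n_channels is not None and arr.shape[0] != n_channels:
        raise ValueError(f"expected {n_channels} channels, got {arr.shape[0]}")
    return {f"ch{i}": arr[i] for i in range(arr.shape[0])}


def write_stack_tiff(stacks: Mapping[str, np.ndarray] | np.ndarray, path) -> None:
    import tifffile

    if isinstance(stacks, Mapping):
        arr = np.stack([np.asarray(stacks[ch]) for ch in stacks])
    else:
        arr = np.asarray(stacks)
    tifffile.imwrite(str(path), arr)
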