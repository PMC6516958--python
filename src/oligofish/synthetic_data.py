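"""Synthetic genomes and synthetic 3D nucleus stacks with ground truth.

Every other module is testable offline: genomes are random sequences
with controllable GC and implanted exact repeats (which the uniqueness
screen must reject), and nucleus images are ellipsoidal territories
rendered per channel with optional Gaussian blur and Poisson noise,
with volumes/overlaps recorded before degradation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass
class SimGenomeParams:
    n_chrom: int = 1
    chrom_length: int = 100_000
    gc: float = 0.50
    repeat_blocks: tuple[tuple[int, int], ...] = ()  # (length, copies)
    seed: int = 0
    chrom_prefix: str = "chr"

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.chrom_length < 1:
            raise ValueError("n_chrom and chrom_length must be positive")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        for length, copies in self.repeat_blocks:
            if length > self.chrom_length:
                raise ValueError(
                    f"repeat block of {length} bp exceeds chromosome length "
                    f"{self.chrom_length}"
                )
            if copies < 2:
                raise ValueError("repeat blocks need at least 2 copies")


@dataclass
class GroundTruth:
    """Known truth for a simulated object (genome or nucleus image)."""

    repeat_locations: list[dict] = field(default_factory=list)
    territory_volumes: dict[str, int] = field(default_factory=dict)
    territory_overlaps: dict[str, int] = field(default_factory=dict)  # "a|b" -> voxels
    masks: dict[str, np.ndarray] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"repeat_locations": self.repeat_locations,
                       "territory_volumes": self.territory_volumes,
                       "territory_overlaps": self.territory_overlaps},
                      fh, indent=2)


def simulate_genome(params: SimGenomeParams) -> tuple[dict[str, str], GroundTruth]:
    """Generate random chromosomes, then implant exact repeat copies.

    Deterministic for a fixed seed.  Repeat copies are placed at
    non-overlapping positions on chromosomes chosen round-robin; their
    coordinates are recorded in the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    p_gc = params.gc / 2.0
    p = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]  # A, C, G, T
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences: dict[str, str] = {}
    for i in range(params.n_chrom):
        draw = rng.choice(bases, size=params.chrom_length, p=p)
        sequences[f"{params.chrom_prefix}{i + 1}"] = draw.tobytes().decode("ascii")

    truth = GroundTruth()
    chrom_names = list(sequences)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for block_i, (length, copies) in enumerate(params.repeat_blocks):
        block = rng.choice(bases, size=length).tobytes().decode("ascii")
        for copy_i in range(copies):
            chrom = chrom_names[(block_i + copy_i) % len(chrom_names)]
            placed = False
            for _ in range(1000):
                start = int(rng.integers(0, params.chrom_length - length + 1))
                span = (start, start + length)
                if all(span[1] <= a or span[0] >= b for a, b in occupied[chrom]):
                    occupied[chrom].append(span)
                    seq = sequences[chrom]
                    sequences[chrom] = seq[: span[0]] + block + seq[span[1]:]
                    truth.repeat_locations.append(
                        {"block": block_i, "chrom": chrom,
                         "start": span[0], "end": span[1]}
                    )
                    placed = True
                    break
            if not placed:
                raise RuntimeError("could not place repeat block without overlap")
    return sequences, truth


@dataclass
class SimNucleusParams:
    shape: tuple[int, int, int] = (32, 64, 64)  # (z, y, x)
    n_territories: int = 3
    semi_axes_range: tuple[float, float] = (6.0, 10.0)
    placement: str = "disjoint"  # or "overlap"
    target_overlap: float = 0.0  # fraction of the smaller territory, overlap mode
    blur_sigma: float = 0.0
    background: int = 10
    signal: int = 200
    poisson: bool = False
    seed: int = 0
    max_attempts: int = 500
    radius_scale: float = 1.0  # inflate/deflate all territories (aging-style)

    def __post_init__(self) -> None:
        if self.placement not in ("disjoint", "overlap"):
            raise ValueError("placement must be 'disjoint' or 'overlap'")
        if self.n_territories < 1:
            raise ValueError("n_territories must be >= 1")
        if 2 * self.semi_axes_range[0] * self.radius_scale >= min(self.shape):
            raise ValueError("territories cannot fit inside the grid")


def ellipsoid_mask(shape: tuple[int, int, int], center: Sequence[float],
                   semi_axes: Sequence[float]) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid on a voxel grid."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
            + ((xx - cx) / ax) ** 2) <= 1.0


def simulate_nucleus_image(params: SimNucleusParams
                           ) -> tuple[np.ndarray, GroundTruth]:
    """Render one territory per channel; returns a (C, z, y, x) uint16 stack.

    Ground-truth volumes and pairwise overlaps are recorded from the
    clean masks before blur and noise.  Placement is rejection-sampled;
    an impossible request errors out after a bounded attempt budget.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    masks: list[np.ndarray] = []
    lo, hi = params.semi_axes_range
    for t in range(params.n_territories):
        placed = False
        for _ in range(params.max_attempts):
            semi = rng.uniform(lo, hi, size=3) * params.radius_scale
            margin = semi + 1.0
            if any(margin[i] >= shape[i] - margin[i] for i in range(3)):
                continue  # this draw cannot fit; burn an attempt
            center = [rng.uniform(margin[i], shape[i] - margin[i]) for i in range(3)]
            mask = ellipsoid_mask(shape, center, semi)
            if params.placement == "disjoint":
                ok = all(not (mask & m).any() for m in masks)
            else:
                if not masks:
                    ok = True
                else:
                    inter = int((mask & masks[-1]).sum())
                    smaller = min(int(mask.sum()), int(masks[-1].sum()))
                    frac = inter / smaller if smaller else 0.0
                    ok = (abs(frac - params.target_overlap) <= 0.08
                          and all(not (mask & m).any() for m in masks[:-1]))
            if ok:
                masks.append(mask)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place territory {t} after {params.max_attempts} attempts"
            )

    truth = GroundTruth(masks={f"ch{i}": m for i, m in enumerate(masks)})
    for i, m in enumerate(masks):
        truth.territory_volumes[f"ch{i}"] = int(m.sum())
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            truth.territory_overlaps[f"ch{i}|ch{j}"] = int((masks[i] & masks[j]).sum())

    channels = []
    for m in masks:
        img = np.full(shape, float(params.background))
        img[m] = float(params.signal)
        if params.blur_sigma > 0:
            img = gaussian_filter(img, params.blur_sigma)
        if params.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        channels.append(np.clip(np.rint(img), 0, 65535).astype(np.uint16))
    return np.stack(channels), truth
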