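"""Bridge/detection oligo design and combinatorial color coding.

A bridge oligo base-pairs with one barcode of a primary oligo and
presents two tandem docking sites for dye-conjugated detection oligos.
Assigning each target a distinct nonempty subset of imaging channels
(up to ``max_code_size`` dyes) lets N targets share K channels; with
dual-labeled detection oligos, two detections per bridge and bridges on
both the 5' and 3' barcode, one primary can recruit eight fluorophores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import pandas as pd

from ._sequtil import revcomp
from .barcode_engine import Barcode, BarcodeConstraints, generate_barcodes

BRIDGE_BARCODE_LEN = 23
DOCK_LEN = 20
DOCKS_PER_BRIDGE = 2


@dataclass(frozen=True)
class BridgeOligo:
    id: str
    target_barcode_id: str
    dock_id: str
    sequence: str  # rc(target barcode) + tandem docking sites

    def __post_init__(self) -> None:
        # rc(barcode) + 2 docks; 63 nt for the 23-nt inner barcodes, 60 nt
        # for the 20-nt chromosome primer sites.
        minimum = DOCKS_PER_BRIDGE * DOCK_LEN + 1
        if len(self.sequence) < minimum:
            raise ValueError(f"bridge {self.id} length {len(self.sequence)} < {minimum}")


@dataclass(frozen=True)
class DetectionOligo:
    id: str
    dock_id: str
    sequence: str  # rc of the docking site
    dye_5prime: str | None
    dye_3prime: str | None


@dataclass
class MultiplexConfig:
    bridges_per_primary: int = 2
    detections_per_bridge: int = 2
    dyes_per_detection: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.bridges_per_primary <= 2):
            raise ValueError("bridges_per_primary must be 1 or 2 (5'/3' barcodes)")
        if self.detections_per_bridge < 1 or self.dyes_per_detection < 1:
            raise ValueError("all multiplex counts must be >= 1")
        if self.dyes_per_detection > 2:
            raise ValueError("detection oligos carry at most two dyes (5' and 3')")


def fluorophore_multiplicity(config: MultiplexConfig) -> int:
    """Fluorophores recruited per primary oligo."""
    return (config.bridges_per_primary * config.detections_per_bridge
            * config.dyes_per_detection)


def color_capacity(k_channels: int, max_code_size: int) -> int:
    """Number of distinguishable targets on k channels with codes of size <= s."""
    if k_channels < 1:
        raise ValueError("k_channels must be >= 1")
    if not (1 <= max_code_size <= k_channels):
        raise ValueError("require 1 <= max_code_size <= k_channels")
    return sum(comb(k_channels, s) for s in range(1, max_code_size + 1))


@dataclass
class ColorScheme:
    channels: list[str]
    code_per_target: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        codes = list(self.code_per_target.values())
        if any(not c for c in codes):
            raise ValueError("every color code must be nonempty")
        if len(set(codes)) != len(codes):
            raise ValueError("color codes must be pairwise distinct")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"channels": self.channels,
                       "code_per_target": {t: list(c) for t, c in
                                           self.code_per_target.items()}},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ColorScheme":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["channels"],
                   {t: tuple(c) for t, c in raw["code_per_target"].items()})


def assign_colors(targets: Sequence[str], channels: Sequence[str],
                  max_code_size: int = 2) -> ColorScheme:
    """Deterministic code assignment: singletons in channel order, then
    pairs (triples, ...) in lexicographic channel-index order."""
    capacity = color_capacity(len(channels), max_code_size)
    if len(targets) > capacity:
        needed = len(channels)
        while color_capacity(needed, min(max_code_size, needed)) < len(targets):
            needed += 1
        raise ValueError(
            f"{len(targets)} targets exceed capacity {capacity} of "
            f"{len(channels)} channels (codes <= {max_code_size}); "
            f"need at least {needed} channels"
        )
    codes = []
    for size in range(1, max_code_size + 1):
        codes.extend(combinations(channels, size))
    return ColorScheme(list(channels),
                       {t: codes[i] for i, t in enumerate(targets)})


@dataclass(frozen=True)
class TargetAddress:
    """Addressable primary-oligo barcodes for one FISH target.

    Whole-chromosome targets expose both the 5' and 3' barcode; inner
    (3 Mb / 500 kb) targets expose the single segment barcode.
    """

    target: str
    barcodes: tuple[Barcode, ...]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError(f"target {self.target} has no addressable barcode")


@dataclass
class OrderSheet:
    bridges: list[BridgeOligo]
    detections: list[DetectionOligo]
    rows: pd.DataFrame  # species, role, target, sequence, dye

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def compile_hybridization(addresses: Sequence[TargetAddress], scheme: ColorScheme,
                          config: MultiplexConfig | None = None,
                          seed: int = 0) -> OrderSheet:
    """Compile the bridge + detection oligo order sheet for a color scheme.

    Each (target, dye) pair gets its own bridge with a private docking
    site, so no dock is shared between two dyes.  For pair codes the two
    dyes are routed through distinct barcodes (5' vs 3') of the same
    primary; a target whose address has fewer barcodes than its code
    size is an error.
    """
    config = config or MultiplexConfig()
    by_target = {a.target: a for a in addresses}
    missing = set(scheme.code_per_target) - set(by_target)
    if missing:
        raise ValueError(f"no addressable barcodes for targets: {sorted(missing)}")

    n_bridges = sum(len(code) for code in scheme.code_per_target.values())
    dock_constraints = BarcodeConstraints(min_hamming=6)
    docks = generate_barcodes(n_bridges, "dock", dock_constraints, genome=None,
                              seed=seed, length=DOCK_LEN, id_prefix="dock")

    bridges: list[BridgeOligo] = []
    detections: list[DetectionOligo] = []
    rows = []
    dock_iter = iter(docks)
    for target, code in scheme.code_per_target.items():
        address = by_target[target]
        if len(code) > len(address.barcodes):
            raise ValueError(
                f"target {target} code uses {len(code)} dyes but only "
                f"{len(address.barcodes)} addressable barcode(s) exist at its level"
            )
        if len(code) > config.bridges_per_primary:
            raise ValueError(
                f"target {target} code size {len(code)} exceeds "
                f"bridges_per_primary={config.bridges_per_primary}"
            )
        for dye, barcode in zip(code, address.barcodes):
            dock = next(dock_iter)
            bridge_seq = revcomp(barcode.sequence) + dock.sequence * DOCKS_PER_BRIDGE
            bridge = BridgeOligo(
                id=f"bridge_{target}_{dye}",
                target_barcode_id=barcode.id,
                dock_id=dock.id,
                sequence=bridge_seq,
            )
            bridges.append(bridge)
            rows.append({"species": bridge.id, "role": "bridge", "target": target,
                         "sequence": bridge.sequence, "dye": "."})
            det = DetectionOligo(
                id=f"det_{target}_{dye}",
                dock_id=dock.id,
                sequence=revcomp(dock.sequence),
                dye_5prime=dye,
                dye_3prime=dye if config.dyes_per_detection == 2 else None,
            )
            detections.append(det)
            rows.append({"species": det.id, "role": "detection", "target": target,
                         "sequence": det.sequence, "dye": dye})
    return OrderSheet(bridges, detections, pd.DataFrame(rows))
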