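"""Genome loading, k-mer occurrence indexing and nested segmentation.

A genome is held as uppercase sequences plus a genome-wide canonical
k-mer occurrence table (both strands).  Chromosomes are partitioned into
two nested tiers of fixed-size segments — 3 Mb and 500 kb — used to
address sub-pools of the probe library.  All coordinates are 0-based,
half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from ._sequtil import (
    IUPAC_DNA,
    canonical_kmer_codes,
    canonical_pack_kmer,
    encode,
)

MB3 = 3_000_000
KB500 = 500_000

#: bp per segment at each addressable level; ``chromosome`` spans the
#: whole chromosome and has no fixed size.
LEVEL_SIZES: dict[str, int] = {"mb3": MB3, "kb500": KB500}

LEVELS = ("chromosome", "mb3", "kb500")


@dataclass(frozen=True)
class Segment:
    """A fixed-size genomic bin at one addressing level."""

    chrom: str
    level: str
    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown segment level {self.level!r}")
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} <= start {self.start}")

    @property
    def name(self) -> str:
        return f"{self.chrom}_{self.level}_{self.index}"

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


def segment_chromosome(chrom_length: int, level: str, chrom: str = "chr") -> list[Segment]:
    """Tile ``[0, chrom_length)`` with segments of the requested level.

    The final segment is truncated at the chromosome end; every other
    segment has the exact level size.
    """
    if chrom_length <= 0:
        raise ValueError(f"chromosome length must be positive, got {chrom_length}")
    if level not in LEVEL_SIZES:
        raise ValueError(f"level must be one of {sorted(LEVEL_SIZES)}, got {level!r}")
    size = LEVEL_SIZES[level]
    return [
        Segment(chrom, level, i, start, min(start + size, chrom_length))
        for i, start in enumerate(range(0, chrom_length, size))
    ]


def segment_index(position: int, level: str) -> int:
    """0-based segment ordinal (within its chromosome) holding ``position``."""
    return position // LEVEL_SIZES[level]


def segments_to_bed(segments: Iterable[Segment], path) -> None:
    """Write segments as BED6 (name = ``<chrom>_<level>_<index>``)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.name}\t0\t+\n")


class GenomeIndex:
    """Chromosome sequences plus a canonical k-mer occurrence index.

    The index maps each canonical k-mer (lexicographic min of the k-mer
    and its reverse complement, packed 2 bits/base) to its genome-wide
    occurrence count over both strands.  Windows containing N are not
    indexed.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 18):
        if k < 8:
            raise ValueError(f"k must be >= 8, got {k}")
        if not sequences:
            raise ValueError("genome contains no sequences")
        self.k = k
        self.chrom_names: list[str] = list(sequences)
        self.sequences: dict[str, str] = {}
        self._codes: dict[str, np.ndarray] = {}
        self._canon: dict[str, np.ndarray] = {}
        self._canon_valid: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            self.sequences[name] = seq
            self._codes[name] = encode(seq)
            canon, valid = canonical_kmer_codes(self._codes[name], k)
            self._canon[name] = canon
            self._canon_valid[name] = valid
        self.chrom_lengths: dict[str, int] = {n: len(s) for n, s in self.sequences.items()}
        all_canon = np.concatenate(
            [self._canon[n][self._canon_valid[n]] for n in self.chrom_names]
        ) if any(self._canon_valid[n].any() for n in self.chrom_names) else np.empty(0, np.uint64)
        self._uniq, self._uniq_counts = np.unique(all_canon, return_counts=True)

    # -- construction ------------------------------------------------

    @classmethod
    def from_fasta(cls, fasta_path, k: int = 18) -> "GenomeIndex":
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records found in {fasta_path}")
        names = [r.id for r in records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names in FASTA: {dupes}")
        return cls({r.id: str(r.seq) for r in records}, k=k)

    # -- queries -----------------------------------------------------

    def kmer_count(self, kmer: str) -> int:
        """Genome-wide occurrence count (both strands) of a k-mer; 0 if absent."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != index k {self.k}")
        code = np.uint64(canonical_pack_kmer(kmer))
        i = np.searchsorted(self._uniq, code)
        if i < len(self._uniq) and self._uniq[i] == code:
            return int(self._uniq_counts[i])
        return 0

    def kmer_hits_per_position(self, chrom: str) -> np.ndarray:
        """Occurrence count of the k-mer starting at each position of ``chrom``.

        Positions whose window contains N get count 0 (no valid k-mer).
        """
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        canon, valid = self._canon[chrom], self._canon_valid[chrom]
        counts = np.zeros(len(canon), dtype=np.int64)
        if valid.any():
            idx = np.searchsorted(self._uniq, canon[valid])
            counts[valid] = self._uniq_counts[idx]
        return counts

    def encoded(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._codes[chrom]

    def kmer_presence_set(self, k: int) -> set[int]:
        """Set of canonical packed k-mers present anywhere in the genome.

        Used for screening non-genomic sequences (barcodes) against the
        target genome at a k different from the index k.
        """
        present: set[int] = set()
        for name in self.chrom_names:
            canon, valid = canonical_kmer_codes(self._codes[name], k)
            present.update(np.unique(canon[valid]).tolist())
        return present

    def segments(self, level: str, chrom: str | None = None) -> list[Segment]:
        chroms = [chrom] if chrom is not None else self.chrom_names
        out: list[Segment] = []
        for c in chroms:
            if c not in self.chrom_lengths:
                raise KeyError(f"unknown chromosome {c!r}")
            if level == "chromosome":
                out.append(Segment(c, "chromosome", 0, 0, self.chrom_lengths[c]))
            else:
                out.extend(segment_chromosome(self.chrom_lengths[c], level, chrom=c))
        return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
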