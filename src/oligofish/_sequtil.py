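"""Low-level nucleotide encoding helpers shared across modules.

Bases are encoded as uint8: A=0, C=1, G=2, T=3; anything else (N and
IUPAC ambiguity codes) becomes 4 and is excluded from k-mer windows.
With this encoding two bases are Watson-Crick complements iff their
codes sum to 3.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into the 0-4 uint8 alphabet."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    return float(np.count_nonzero((codes == 1) | (codes == 2)) / len(codes))


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer of an encoded sequence into a uint64.

    Returns ``(packed, valid)`` of length ``len(codes) - k + 1``;
    ``valid[i]`` is False when the window contains a non-ACGT base
    (its packed value is then meaningless).
    """
    if k < 1 or k > 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    is_bad = (codes >= 4).astype(np.int32)
    bad_cum = np.concatenate(([0], np.cumsum(is_bad)))
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    b = np.where(codes >= 4, 0, codes).astype(np.uint64)
    packed = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        packed = (packed << np.uint64(2)) | b[j : j + n]
    return packed, valid


def canonical_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-symmetric) packed k-mers: min(code, revcomp code)."""
    fwd, valid = kmer_codes(codes, k)
    rc_seq = (np.uint8(3) - codes)[::-1]
    rc_seq = np.where(codes[::-1] >= 4, np.uint8(4), rc_seq)
    rev, _ = kmer_codes(rc_seq, k)
    rev_aligned = rev[::-1]  # rev[i] is the rc of the window ending at the other strand's i
    canon = np.minimum(fwd, rev_aligned)
    return canon, valid


def pack_kmer(seq: str) -> int:
    codes = encode(seq)
    if np.any(codes >= 4):
        raise ValueError(f"k-mer contains non-ACGT characters: {seq!r}")
    packed, _ = kmer_codes(codes, len(codes))
    return int(packed[0])


def canonical_pack_kmer(seq: str) -> int:
    return min(pack_kmer(seq), pack_kmer(revcomp(seq)))
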