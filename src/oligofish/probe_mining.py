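"""Genome mining for 42-nt probe homology sequences.

Candidate windows must (1) map uniquely to the genome (every constituent
k-mer occurs at most ``max_kmer_hits`` times, both strands counted),
(2) fall inside configurable melting-temperature and GC windows,
(3) lack repetitive stretches (homopolymers and dinucleotide repeats)
and (4) lack predicted hairpin secondary structure.  Every start
position is evaluated; survivors are greedily thinned left-to-right to a
non-overlapping candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._sequtil import encode
from .genome_model import GenomeIndex

R_GAS = 1.987  # cal/(K*mol)

# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/(K*mol)),
# indexed by packed dinucleotide (4*first + second) of the top strand.
_NN_BY_DINUC: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)

_DH_TABLE = np.zeros(16)
_DS_TABLE = np.zeros(16)
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
for _d, (_h, _s) in _NN_BY_DINUC.items():
    _i = 4 * _BASE_IDX[_d[0]] + _BASE_IDX[_d[1]]
    _DH_TABLE[_i] = _h
    _DS_TABLE[_i] = _s


@dataclass
class ProbeParams:
    """Filter thresholds and hybridization conditions for probe mining.

    ``formamide_pct`` describes the hybridization buffer and is used for
    effective-Tm reporting only; the ``tm_min``/``tm_max`` screen applies
    to the formamide-free nearest-neighbor Tm at ``na_conc``.
    """

    homology_length: int = 42
    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 60.0
    tm_max: float = 80.0
    na_conc: float = 0.39  # molar monovalent cation (2x SSC)
    formamide_pct: float = 50.0
    formamide_coeff: float = 0.65  # degC depression per % formamide
    k_unique: int = 18
    max_kmer_hits: int = 1
    max_homopolymer: int = 5
    max_dinuc_repeat: int = 4
    max_hairpin_stem: int = 7
    min_hairpin_loop: int = 3
    dnac1_nM: float = 25.0
    dnac2_nM: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min < self.gc_max <= 1.0):
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if not self.tm_min < self.tm_max:
            raise ValueError("require tm_min < tm_max")
        if self.homology_length < self.k_unique:
            raise ValueError("homology_length must be >= k_unique")


@dataclass(frozen=True)
class CandidateProbe:
    chrom: str
    start: int
    sequence: str
    tm: float
    gc: float
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class FilterVerdict:
    passes_unique: bool
    passes_gc: bool
    passes_tm: bool
    passes_repeat: bool
    passes_structure: bool

    @property
    def overall(self) -> bool:
        return (self.passes_unique and self.passes_gc and self.passes_tm
                and self.passes_repeat and self.passes_structure)


def melting_temperature(
    sequence: str,
    na_conc: float = 0.39,
    dnac1_nM: float = 25.0,
    dnac2_nM: float = 25.0,
    formamide_pct: float = 0.0,
    formamide_coeff: float = 0.65,
) -> float:
    """Nearest-neighbor duplex Tm (degC) with entropic salt correction.

    Uses the unified NN table, dS += 0.368*(N-1)*ln[Na+], and
    Tm = dH/(dS + R ln CT) with CT = dnac1 - dnac2/2 (non-self-
    complementary convention).  Formamide depresses the result by
    ``formamide_coeff`` degC per percent.
    """
    if len(sequence) < 8:
        raise ValueError(f"sequence too short for NN Tm: {len(sequence)} nt")
    sequence = sequence.upper()
    if set(sequence) - set("ACGT"):
        raise ValueError(f"ambiguous bases not supported in Tm: {sequence!r}")
    dh, ds = 0.0, 0.0
    for terminal in (sequence[0], sequence[-1]):
        init = _INIT_AT if terminal in "AT" else _INIT_GC
        dh += init[0]
        ds += init[1]
    for i in range(len(sequence) - 1):
        h, s = _NN_BY_DINUC[sequence[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(sequence) - 1) * math.log(na_conc)
    ct = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    tm = dh * 1000.0 / (ds + R_GAS * math.log(ct)) - 273.15
    return tm - formamide_coeff * formamide_pct


def longest_hairpin_stem(sequence: str, min_loop: int = 3) -> int:
    """Length of the longest self-complementary stem with loop >= min_loop.

    A stem of length L pairs positions (i..i+L-1) with (j-L+1..j)
    antiparallel; the unpaired loop between them must span at least
    ``min_loop`` nt.
    """
    codes = encode(sequence)
    n = len(codes)
    best = 0
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            length = 0
            while (i + length < j - length
                   and codes[i + length] + codes[j - length] == 3
                   and (j - length) - (i + length) - 1 >= min_loop):
                length += 1
            if length > best:
                best = length
    return best


def _has_stem_over(codes: np.ndarray, max_stem: int, min_loop: int = 3) -> bool:
    """True iff a self-complementary stem of length > max_stem exists."""
    stem = max_stem + 1
    n = len(codes)
    if 2 * stem + min_loop > n:
        return False
    small = codes.astype(np.int16)
    comp = small[:, None] + small[None, :] == 3
    acc = comp.copy()
    for d in range(1, stem):
        acc[: n - d, d:] &= comp[d:, : n - d]
    # acc[i, j]: pairs (i,j)..(i+stem-1, j-stem+1) all complementary
    i_idx, j_idx = np.nonzero(acc)
    return bool(np.any(j_idx - i_idx >= 2 * stem + min_loop - 1))


def max_homopolymer_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def max_dinucleotide_repeat(sequence: str) -> int:
    """Longest tandem repeat of a 2-nt unit, in units (ATATAT -> 3)."""
    n = len(sequence)
    best = 1 if n >= 2 else 0
    for phase in range(2):
        run = 2  # nt covered by the current period-2 stretch
        for i in range(phase, n - 2):
            if sequence[i] == sequence[i + 2]:
                run += 1
            else:
                best = max(best, run // 2)
                run = 2
        best = max(best, run // 2)
    return best


def evaluate_probe(sequence: str, kmer_index: GenomeIndex, params: ProbeParams) -> FilterVerdict:
    """Apply all four filter classes to a single homology-length window."""
    if len(sequence) != params.homology_length:
        raise ValueError(
            f"sequence length {len(sequence)} != homology_length {params.homology_length}"
        )
    sequence = sequence.upper()
    k = params.k_unique
    has_n = bool(set(sequence) - set("ACGT"))
    if has_n:
        passes_unique = False
    else:
        passes_unique = all(
            1 <= kmer_index.kmer_count(sequence[i : i + k]) <= params.max_kmer_hits
            for i in range(len(sequence) - k + 1)
        )
    gc = (sequence.count("G") + sequence.count("C")) / len(sequence)
    passes_gc = params.gc_min <= gc <= params.gc_max
    if has_n:
        passes_tm = False
    else:
        tm = melting_temperature(sequence, na_conc=params.na_conc,
                                 dnac1_nM=params.dnac1_nM, dnac2_nM=params.dnac2_nM)
        passes_tm = params.tm_min <= tm <= params.tm_max
    passes_repeat = (max_homopolymer_run(sequence) <= params.max_homopolymer
                     and max_dinucleotide_repeat(sequence) <= params.max_dinuc_repeat)
    passes_structure = (
        longest_hairpin_stem(sequence, params.min_hairpin_loop) <= params.max_hairpin_stem
    )
    return FilterVerdict(passes_unique, passes_gc, passes_tm, passes_repeat, passes_structure)


def _window_sums(values: np.ndarray, w: int) -> np.ndarray:
    cum = np.concatenate(([0], np.cumsum(values, dtype=np.int64)))
    return cum[w:] - cum[:-w]


def _vector_tm(codes: np.ndarray, w: int, params: ProbeParams) -> np.ndarray:
    """Formamide-free NN Tm for every w-window (N windows yield nan)."""
    n = len(codes) - w + 1
    safe = np.where(codes >= 4, 0, codes).astype(np.intp)
    dinuc = 4 * safe[:-1] + safe[1:]
    dh_c = np.concatenate(([0.0], np.cumsum(_DH_TABLE[dinuc])))
    ds_c = np.concatenate(([0.0], np.cumsum(_DS_TABLE[dinuc])))
    dh = dh_c[w - 1 :] - dh_c[: n]
    ds = ds_c[w - 1 :] - ds_c[: n]
    first_at = (safe[:n] == 0) | (safe[:n] == 3)
    last_at = (safe[w - 1 :] == 0) | (safe[w - 1 :] == 3)
    dh += np.where(first_at, _INIT_AT[0], _INIT_GC[0])
    ds += np.where(first_at, _INIT_AT[1], _INIT_GC[1])
    dh += np.where(last_at, _INIT_AT[0], _INIT_GC[0])
    ds += np.where(last_at, _INIT_AT[1], _INIT_GC[1])
    ds += 0.368 * (w - 1) * math.log(params.na_conc)
    ct = (params.dnac1_nM - params.dnac2_nM / 2.0) * 1e-9
    tm = dh * 1000.0 / (ds + R_GAS * math.log(ct)) - 273.15
    bad = _window_sums(codes >= 4, w) > 0
    tm[bad] = np.nan
    return tm


def _repeat_fail_windows(codes: np.ndarray, w: int, params: ProbeParams) -> np.ndarray:
    """Boolean per window: contains a disallowed homopolymer or dinuc repeat."""
    n = len(codes) - w + 1
    fail = np.zeros(n, dtype=bool)

    hp = params.max_homopolymer + 1  # run length that violates
    if hp <= w:
        same = codes[1:] == codes[:-1]
        runs = _window_sums(same, hp - 1) == hp - 1  # run of hp starting here
        fail |= _window_sums(runs, w - hp + 1) > 0

    dn = 2 * (params.max_dinuc_repeat + 1)  # nt length that violates
    if dn <= w:
        per2 = codes[2:] == codes[:-2]
        runs2 = _window_sums(per2, dn - 2) == dn - 2
        fail |= _window_sums(runs2, w - dn + 1) > 0
    return fail


def scan_candidates(genome: GenomeIndex, chrom: str, params: ProbeParams | None = None
                    ) -> list[CandidateProbe]:
    """Mine one chromosome for non-overlapping passing candidate probes.

    Every start position is scored against the cheap vectorized filters
    (uniqueness, GC, Tm, repeats); the hairpin screen is applied during
    the left-to-right greedy thinning pass, so accepted candidates never
    overlap and satisfy every filter.
    """
    if params is None:
        params = ProbeParams()
    if params.k_unique != genome.k:
        raise ValueError(
            f"params.k_unique={params.k_unique} but genome index built with k={genome.k}"
        )
    if chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome.sequences[chrom]
    w = params.homology_length
    if len(seq) < w:
        return []
    codes = genome.encoded(chrom)
    n = len(seq) - w + 1

    hits = genome.kmer_hits_per_position(chrom)
    n_kmers_per_win = w - params.k_unique + 1
    win_valid = _window_sums(hits >= 1, n_kmers_per_win)[:n] == n_kmers_per_win
    if n_kmers_per_win == 1:
        win_max_hits = hits[:n]
    else:
        win_max_hits = np.lib.stride_tricks.sliding_window_view(
            hits, n_kmers_per_win
        ).max(axis=1)[:n]
    passes_unique = win_valid & (win_max_hits <= params.max_kmer_hits)

    gc_count = _window_sums((codes == 1) | (codes == 2), w)[:n]
    gc = gc_count / w
    passes_gc = (gc >= params.gc_min) & (gc <= params.gc_max)

    tm = _vector_tm(codes, w, params)
    with np.errstate(invalid="ignore"):
        passes_tm = (tm >= params.tm_min) & (tm <= params.tm_max)

    passes_repeat = ~_repeat_fail_windows(codes, w, params)

    cheap = passes_unique & passes_gc & passes_tm & passes_repeat

    out: list[CandidateProbe] = []
    positions = np.flatnonzero(cheap)
    cursor = 0
    i = 0
    while i < len(positions):
        pos = int(positions[i])
        if pos < cursor:
            i += 1
            continue
        if _has_stem_over(codes[pos : pos + w], params.max_hairpin_stem,
                          params.min_hairpin_loop):
            i += 1
            continue
        out.append(CandidateProbe(chrom, pos, seq[pos : pos + w],
                                  float(tm[pos]), float(gc[pos])))
        cursor = pos + w
        i += 1
    return out


def candidates_to_bed(candidates, path) -> None:
    """Write candidates as BED6 with the Tm in the score column."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t"
                     f"{c.chrom}:{c.start}-{c.end}\t{c.tm:.2f}\t{c.strand}\n")
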