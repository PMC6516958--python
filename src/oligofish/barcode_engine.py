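"""Orthogonal barcode generation, 150-nt oligo assembly and in-silico PCR.

Each library oligo carries its 42-nt genomic homology flanked by five
barcode slots: chromosome forward primer site, 3 Mb barcode, 500 kb
barcode, a 500 kb-specific spare barcode (reserved, unused for
detection), and the chromosome reverse primer site.  The chromosome
barcodes double as the outermost PCR primer pair, so any chromosome
sub-pool can be amplified; inner segments are addressed by bridges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._sequtil import canonical_kmer_codes, encode, gc_fraction, revcomp
from .genome_model import KB500, MB3, GenomeIndex, Segment, segment_index
from .probe_mining import CandidateProbe, longest_hairpin_stem

#: slot order and default lengths; homology is the genomic 42-mer.
DEFAULT_SLOTS: tuple[tuple[str, int], ...] = (
    ("chrom_fwd", 20),
    ("mb3", 23),
    ("kb500", 23),
    ("homology", 42),
    ("seg_specific", 22),
    ("chrom_rev", 20),
)

BARCODE_ROLES = ("chrom_fwd", "chrom_rev", "mb3", "kb500", "seg_specific")


@dataclass(frozen=True)
class LibraryLayout:
    slots: tuple[tuple[str, int], ...] = DEFAULT_SLOTS
    total_length: int = 150

    def __post_init__(self) -> None:
        if sum(n for _, n in self.slots) != self.total_length:
            raise ValueError(
                f"slot lengths sum to {sum(n for _, n in self.slots)}, "
                f"expected total_length {self.total_length}"
            )

    def slot_length(self, name: str) -> int:
        for slot, n in self.slots:
            if slot == name:
                return n
        raise KeyError(f"unknown slot {name!r}")

    def slot_bounds(self) -> dict[str, tuple[int, int]]:
        bounds, offset = {}, 0
        for slot, n in self.slots:
            bounds[slot] = (offset, offset + n)
            offset += n
        return bounds


@dataclass(frozen=True)
class Barcode:
    id: str
    role: str
    sequence: str
    target_segment: Segment | None = None

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"barcode {self.id} contains non-ACGT characters")


@dataclass
class BarcodeConstraints:
    min_hamming: int = 8
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_genome_kmer: int = 14  # no (max+1)-mer of a barcode may occur in the genome
    max_hairpin_stem: int = 6
    max_cross_3prime: int = 4
    max_homopolymer: int = 5
    attempts_per_barcode: int = 20_000


class BarcodeSet:
    """Barcodes indexed by id and by (role, segment name)."""

    def __init__(self, barcodes: Iterable[Barcode] = ()):
        self._by_id: dict[str, Barcode] = {}
        for bc in barcodes:
            self.add(bc)

    def add(self, barcode: Barcode) -> None:
        if barcode.id in self._by_id:
            raise ValueError(f"duplicate barcode id {barcode.id}")
        self._by_id[barcode.id] = barcode

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __getitem__(self, barcode_id: str) -> Barcode:
        return self._by_id[barcode_id]

    def lookup(self, role: str, chrom: str, index: int = 0) -> Barcode:
        for bc in self._by_id.values():
            seg = bc.target_segment
            if bc.role == role and seg is not None and seg.chrom == chrom and seg.index == index:
                return bc
        raise KeyError(f"no {role} barcode for segment ({chrom}, {index})")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\trole\tsegment\tsequence\n")
            for bc in self._by_id.values():
                seg = bc.target_segment.name if bc.target_segment else "."
                fh.write(f"{bc.id}\t{bc.role}\t{seg}\t{bc.sequence}\n")

    @classmethod
    def from_tsv(cls, path) -> "BarcodeSet":
        out = cls()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                bc_id, role, seg_name, seq = line.rstrip("\n").split("\t")
                seg = None
                if seg_name != ".":
                    chrom, level, idx = seg_name.rsplit("_", 2)
                    size = MB3 if level == "mb3" else KB500
                    start = int(idx) * size if level in ("mb3", "kb500") else 0
                    # end is unknown from the name alone; store a 1-bp stub upper bound
                    seg = Segment(chrom, level, int(idx), start,
                                  start + size if level in ("mb3", "kb500") else start + 1)
                out.add(Barcode(bc_id, role, seq, seg))
        return out


def cross_3prime_complementarity(a: str, b: str) -> int:
    """Longest t with a[-t:] the reverse complement of b[-t:] (3' ends anneal)."""
    best = 0
    limit = min(len(a), len(b))
    for t in range(1, limit + 1):
        if a[-t:] == revcomp(b[-t:]):
            best = t
    return best


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_barcodes(
    n: int,
    role: str,
    constraints: BarcodeConstraints | None = None,
    genome: GenomeIndex | None = None,
    seed: int = 0,
    length: int | None = None,
    layout: LibraryLayout | None = None,
    existing: Sequence[Barcode] = (),
    id_prefix: str | None = None,
) -> list[Barcode]:
    """Rejection-sample ``n`` orthogonal barcodes for one slot role.

    Constraints: GC window, homopolymer cap, hairpin cap, pairwise
    Hamming distance (same-length comparisons, including ``existing``),
    3'-end cross-complementarity, and — when a genome is supplied —
    absence of every (max_genome_kmer+1)-mer from the target genome on
    either strand.  Deterministic for a fixed seed; raises after a
    bounded attempt budget naming the most-violated constraint.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    constraints = constraints or BarcodeConstraints()
    if length is None:
        layout = layout or LibraryLayout()
        slot = "chrom_fwd" if role in ("chrom_fwd", "chrom_rev") else role
        length = layout.slot_length(slot)
    if 4 ** length < n:
        raise ValueError(
            f"infeasible: {n} barcodes requested but only {4 ** length} "
            f"distinct {length}-mers exist"
        )
    kg = constraints.max_genome_kmer + 1
    genome_kmers: set[int] | None = None
    if genome is not None and length >= kg:
        genome_kmers = genome.kmer_presence_set(kg)

    rng = np.random.default_rng(seed)
    accepted: list[Barcode] = []
    pool = [bc.sequence for bc in existing]
    rejections = {"gc": 0, "homopolymer": 0, "hairpin": 0, "genome": 0,
                  "hamming": 0, "cross_3prime": 0}
    prefix = id_prefix or role
    attempts_budget = constraints.attempts_per_barcode * n
    attempts = 0
    while len(accepted) < n:
        if attempts >= attempts_budget:
            worst = max(rejections, key=rejections.get)
            raise ValueError(
                f"could not generate {n} {role!r} barcodes of length {length} "
                f"within {attempts_budget} attempts; most-violated bound: "
                f"{worst} ({rejections[worst]} rejections)"
            )
        attempts += 1
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        gc = gc_fraction(seq)
        if not (constraints.gc_min <= gc <= constraints.gc_max):
            rejections["gc"] += 1
            continue
        if _max_run(seq) > constraints.max_homopolymer:
            rejections["homopolymer"] += 1
            continue
        if longest_hairpin_stem(seq) > constraints.max_hairpin_stem:
            rejections["hairpin"] += 1
            continue
        if genome_kmers is not None and _hits_genome(seq, kg, genome_kmers):
            rejections["genome"] += 1
            continue
        if any(len(other) == length and _hamming(seq, other) < constraints.min_hamming
               for other in pool):
            rejections["hamming"] += 1
            continue
        if any(cross_3prime_complementarity(seq, other) > constraints.max_cross_3prime
               for other in pool):
            rejections["cross_3prime"] += 1
            continue
        bc = Barcode(f"{prefix}_{len(accepted):03d}", role, seq)
        accepted.append(bc)
        pool.append(seq)
    return accepted


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _hits_genome(seq: str, k: int, genome_kmers: set[int]) -> bool:
    canon, valid = canonical_kmer_codes(encode(seq), k)
    return any(int(c) in genome_kmers for c in canon[valid])


@dataclass(frozen=True)
class LibraryOligo:
    full_sequence: str
    candidate: CandidateProbe
    barcode_ids: Mapping[str, str]
    assignments: tuple[str, int, int]  # (chrom, mb3 index, kb500 index)

    @property
    def chrom(self) -> str:
        return self.assignments[0]

    @property
    def mb3_index(self) -> int:
        return self.assignments[1]

    @property
    def kb500_index(self) -> int:
        return self.assignments[2]


def assemble_oligo(candidate: CandidateProbe, barcodes: Mapping[str, Barcode],
                   layout: LibraryLayout | None = None) -> LibraryOligo:
    """Assemble the barcoded oligo for one candidate.

    ``barcodes`` maps each barcode role to the Barcode for the
    candidate's segment.  The chrom_rev slot stores the reverse
    complement of the reverse primer so the primer pair amplifies the
    oligo.  Raises when a barcode targets the wrong segment.
    """
    layout = layout or LibraryLayout()
    missing = set(BARCODE_ROLES) - set(barcodes)
    if missing:
        raise ValueError(f"missing barcode roles: {sorted(missing)}")
    mb3_idx = segment_index(candidate.start, "mb3")
    kb500_idx = segment_index(candidate.start, "kb500")
    expected_index = {"chrom_fwd": 0, "chrom_rev": 0, "mb3": mb3_idx,
                      "kb500": kb500_idx, "seg_specific": kb500_idx}
    for role, bc in barcodes.items():
        seg = bc.target_segment
        if seg is None:
            continue
        if seg.chrom != candidate.chrom or seg.index != expected_index[role]:
            raise ValueError(
                f"{role} barcode {bc.id} targets segment ({seg.chrom}, {seg.index}) "
                f"but candidate {candidate.chrom}:{candidate.start} needs index "
                f"{expected_index[role]}"
            )
    parts = []
    for slot, slot_len in layout.slots:
        if slot == "homology":
            piece = candidate.sequence
        elif slot == "chrom_rev":
            piece = revcomp(barcodes[slot].sequence)
        else:
            piece = barcodes[slot].sequence
        if len(piece) != slot_len:
            raise ValueError(
                f"slot {slot!r} expects {slot_len} nt, got {len(piece)}"
            )
        parts.append(piece)
    full = "".join(parts)
    assert len(full) == layout.total_length
    return LibraryOligo(
        full_sequence=full,
        candidate=candidate,
        barcode_ids={role: bc.id for role, bc in barcodes.items()},
        assignments=(candidate.chrom, mb3_idx, kb500_idx),
    )


def generate_library_barcodes(genome: GenomeIndex,
                              constraints: BarcodeConstraints | None = None,
                              seed: int = 0,
                              layout: LibraryLayout | None = None) -> BarcodeSet:
    """Generate every barcode a genome-wide library needs.

    One fwd+rev chromosome pair per chromosome, one mb3 barcode per 3 Mb
    segment, and one kb500 plus one reserved seg_specific barcode per
    500 kb segment; all roles are mutually orthogonal.
    """
    constraints = constraints or BarcodeConstraints()
    layout = layout or LibraryLayout()
    out = BarcodeSet()
    existing: list[Barcode] = []

    def _emit(role: str, segments: list[Segment], length: int, sub_seed: int) -> None:
        raw = generate_barcodes(len(segments), role, constraints, genome,
                                seed=sub_seed, length=length, existing=existing,
                                id_prefix=role)
        for bc, seg in zip(raw, segments):
            bound = Barcode(f"{role}_{seg.name}", role, bc.sequence, seg)
            out.add(bound)
            existing.append(bound)

    chrom_segs = genome.segments("chromosome")
    _emit("chrom_fwd", chrom_segs, layout.slot_length("chrom_fwd"), seed)
    _emit("chrom_rev", chrom_segs, layout.slot_length("chrom_rev"), seed + 1)
    _emit("mb3", genome.segments("mb3"), layout.slot_length("mb3"), seed + 2)
    kb500_segs = genome.segments("kb500")
    _emit("kb500", kb500_segs, layout.slot_length("kb500"), seed + 3)
    _emit("seg_specific", kb500_segs, layout.slot_length("seg_specific"), seed + 4)
    return out


def build_library(selected: Sequence[CandidateProbe], barcodes: BarcodeSet,
                  layout: LibraryLayout | None = None) -> list[LibraryOligo]:
    """Assemble the full oligo library for a selected candidate set."""
    layout = layout or LibraryLayout()
    library = []
    for cand in selected:
        mb3_idx = segment_index(cand.start, "mb3")
        kb500_idx = segment_index(cand.start, "kb500")
        per_role = {
            "chrom_fwd": barcodes.lookup("chrom_fwd", cand.chrom),
            "chrom_rev": barcodes.lookup("chrom_rev", cand.chrom),
            "mb3": barcodes.lookup("mb3", cand.chrom, mb3_idx),
            "kb500": barcodes.lookup("kb500", cand.chrom, kb500_idx),
            "seg_specific": barcodes.lookup("seg_specific", cand.chrom, kb500_idx),
        }
        library.append(assemble_oligo(cand, per_role, layout))
    return library


def simulate_pcr(library: Sequence[LibraryOligo], fwd_primer: str, rev_primer: str
                 ) -> list[LibraryOligo]:
    """Exact-match PCR: keep oligos whose 5' end equals the forward primer
    and whose 3' end equals the reverse complement of the reverse primer."""
    fwd = fwd_primer.upper()
    tail = revcomp(rev_primer.upper())
    return [o for o in library
            if o.full_sequence.startswith(fwd) and o.full_sequence.endswith(tail)]


def select_subpool(library: Sequence[LibraryOligo], level: str,
                   segment: tuple[str, int] | Segment | str) -> list[LibraryOligo]:
    """Metadata-based sub-pool selection at any addressing level."""
    if level not in ("chromosome", "mb3", "kb500"):
        raise ValueError(f"unknown level {level!r}")
    if isinstance(segment, Segment):
        chrom, index = segment.chrom, segment.index
    elif isinstance(segment, str):
        chrom, index = segment, 0
    else:
        chrom, index = segment
    known_chroms = {o.chrom for o in library}
    if chrom not in known_chroms:
        raise KeyError(f"unknown chromosome {chrom!r} (library covers {sorted(known_chroms)})")
    if level == "chromosome":
        return [o for o in library if o.chrom == chrom]
    attr = "mb3_index" if level == "mb3" else "kb500_index"
    max_index = max(getattr(o, attr) for o in library if o.chrom == chrom)
    if not (0 <= index <= max_index):
        raise KeyError(f"unknown {level} segment index {index} for {chrom} "
                       f"(library covers 0..{max_index})")
    return [o for o in library if o.chrom == chrom and getattr(o, attr) == index]


# -- library I/O -----------------------------------------------------

def write_library_fasta(library: Sequence[LibraryOligo], path) -> None:
    with open(path, "w") as fh:
        for o in library:
            c = o.candidate
            fh.write(f">{c.chrom}:{c.start}-{c.end}|mb3={o.mb3_index}|kb500={o.kb500_index}\n")
            fh.write(o.full_sequence + "\n")


def read_library_fasta(path, layout: LibraryLayout | None = None) -> list[LibraryOligo]:
    """Re-parse a library FASTA; candidates are rebuilt from the homology slot."""
    from .probe_mining import melting_temperature

    layout = layout or LibraryLayout()
    bounds = layout.slot_bounds()
    library = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                header = line[1:]
            elif header is not None:
                locus, mb3_part, kb500_part = header.split("|")
                chrom, span = locus.rsplit(":", 1)
                start = int(span.split("-")[0])
                h0, h1 = bounds["homology"]
                homology = line[h0:h1]
                cand = CandidateProbe(chrom, start, homology,
                                      tm=melting_temperature(homology),
                                      gc=gc_fraction(homology))
                library.append(LibraryOligo(
                    full_sequence=line,
                    candidate=cand,
                    barcode_ids={},
                    assignments=(chrom, int(mb3_part.split("=")[1]),
                                 int(kb500_part.split("=")[1])),
                ))
                header = None
    return library


def write_library_manifest(library: Sequence[LibraryOligo], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmb3_index\tkb500_index\t"
                 + "\t".join(role for role in BARCODE_ROLES) + "\tfull_sequence\n")
        for o in library:
            c = o.candidate
            ids = "\t".join(o.barcode_ids.get(r, ".") for r in BARCODE_ROLES)
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{o.mb3_index}\t"
                     f"{o.kb500_index}\t{ids}\t{o.full_sequence}\n")
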