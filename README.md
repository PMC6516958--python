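# oligofish

A design and quantification toolkit for multiplexed, barcoded oligo DNA FISH
libraries. It covers the full computational path of an Oligopaint-style
experiment:

1. **Genome model** — FASTA loading, a canonical k-mer occurrence index
   (both strands, default k=18), and nested 3 Mb / 500 kb chromosome
   segmentation with BED export (`genome_model`).
2. **Probe mining** — scan every position for 42-nt homology windows passing
   four filter classes: genome-wide k-mer uniqueness, nearest-neighbor Tm and
   GC windows, repetitive-stretch exclusion (homopolymers, dinucleotide
   repeats), and hairpin secondary-structure exclusion; survivors are greedily
   thinned to a non-overlapping candidate set (`probe_mining`).
3. **Library layout** — every-Nth decimation (default N=5, restarting inside
   each 500 kb segment), spacing/gap statistics, and a per-chromosome summary
   table whose totals row sums counts and takes unweighted means of the
   per-kb and distance columns (`library_layout`).
4. **Barcode engine** — orthogonal barcode generation (Hamming distance, GC,
   hairpin, 3'-cross-complementarity, and genome 15-mer exclusion
   constraints), assembly of 150-nt primary oligos with the nested slot
   layout `chrom_fwd(20) | mb3(23) | kb500(23) | homology(42) |
   seg_specific(22) | chrom_rev(20)`, exact-match in-silico PCR of sub-pools
   via the outermost chromosome barcodes, and metadata-based sub-pool
   selection at chromosome / 3 Mb / 500 kb levels (`barcode_engine`).
5. **Hybridization scheme** — bridge oligos (reverse-complement of a primary
   barcode plus two tandem detection docking sites), dual-labeled detection
   oligos, fluorophore multiplicity (2 bridges × 2 detections × 2 dyes = 8),
   and combinatorial color codes so six targets fit on three channels
   (`hybridization_scheme`).
6. **Territory quantification** — iterative-intermeans (isodata-variant)
   thresholding on the whole-stack histogram, 26-connectivity connected
   components with a strict >30-voxel size filter, merged per-channel
   territory volumes, and pairwise overlap volumes/fractions from 3D
   multi-channel TIFF stacks (`territory_quant`).
7. **Synthetic data** — seeded random genomes with implanted exact repeats
   and seeded synthetic nucleus stacks (ellipsoidal territories, optional
   Gaussian blur and Poisson noise) with ground-truth volumes and overlaps
   (`synthetic_data`).
8. **Scoring / CLI** — all-or-nothing staining tallies with rounded
   percentages, and a `click` CLI wrapping every step (`scoring`, `cli`).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes independent brute-force oracles (dictionary k-mer scan,
quadratic hairpin enumeration, all-pairs Hamming scan, BFS flood fill,
a literal intermeans update loop, and Biopython's `Tm_NN` for the melting
temperature), property tests (hypothesis), and `tests/test_acceptance.py`,
which checks the headline design-table arithmetic, multiplex combinatorics,
proportion reporting, and end-to-end synthetic pipeline criteria.

## CLI

```sh
oligofish simulate-genome --n-chrom 2 --length 1000000 --seed 1 --out g.fa
oligofish mine      --genome g.fa --out candidates.bed
oligofish design    --genome g.fa --step 5 --out selected.bed --summary summary.tsv
oligofish barcodes  --genome g.fa --seed 1 --out barcodes.tsv
oligofish assemble  --genome g.fa --selected selected.bed --barcodes barcodes.tsv \
                    --out library.fa --manifest library.tsv
oligofish subpool   --library library.fa --level kb500 --chrom chr1 --index 2 --out pool.fa
oligofish scheme    --targets c1,c2,c3,c4,c5,c6 --out scheme.json
oligofish simulate-image --shape 32,64,64 --n-territories 3 --seed 1 --out nucleus.tif
oligofish quantify  --nucleus nucleus.tif --out volumes.csv
oligofish score     --successes 51 --total 61
```

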