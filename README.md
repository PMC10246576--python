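# genomictk

Genomic interval algebra on persistent red-black trees, with readers and
writers for the standard bioinformatic file formats — BED, GFF3, GTF, WIG,
VCF, SAM, BAM/BGZF, FASTA and FASTQ — implemented entirely with the Python
standard library.

## What problem this addresses

Much of day-to-day genomics is moving annotated features — genes, repeats,
variants, aligned reads — between file formats and asking set questions
about the intervals they occupy: which reads overlap this repeat, what
fraction of a target is covered, what is left of the genome once the
annotation is removed. `genomictk` gives both an API and a CLI for this,
for people writing analysis scripts and pipelines who want a dependency-free,
inspectable implementation whose behavior is pinned down by property-based
tests rather than by folklore.

Every interval lives on a named assembled sequence (chromosome, scaffold
or contig) of a `GenomeAssembly`, in 0-based half-open coordinates
`[start, end)` with `0 ≤ start < end ≤ L` for a sequence of length *L*.
Formats that use 1-based inclusive coordinates (GFF3, GTF, WIG, VCF, SAM)
are converted at the I/O boundary and nowhere else.

## The core structure

An `IntervalSet` stores one **persistent red-black tree** per sequence,
ordered by `(start, end)` and augmented with the maximum interval end of
each subtree (`max_end`). Insertion is the functional four-case rebalance:
no node is ever mutated, every operation returns a new set and old versions
stay valid — the height bound `h ≤ 2·log₂(n+1)` and the augmentation are
audited by the test suite after randomized insertion campaigns.

On top of the tree sit the five set operations: `search_overlapping`
(with `max_end` pruning), `merge`, `intersect`, `subtract` and
`complement`, all defined on covered-base sets and all verified
base-for-base against an independent per-base occupancy-array oracle on
thousands of random instances. Two analyses are built from them: breadth
of coverage of target intervals by aligned reads, and the
transition/transversion ratio Ti/Tv = #(A↔G, C↔T) / #(other substitutions)
stratified by caller-supplied genome regions.

All format round-trips satisfy the inverse property: serializing a parsed
record reproduces the input byte-for-byte (the two documented exceptions:
FASTA line wrapping is not preserved, and the SAM integer-tag width codes
`c,C,s,S,I` canonicalize to `i` through BAM).

## Worked example

```python
from genomictk import GenomeAssembly, GenomicInterval, IntervalSet

asm = GenomeAssembly.from_pairs([("chr1", 1000)])
peaks = IntervalSet.from_intervals(asm, [
    GenomicInterval("chr1", 1, 5),
    GenomicInterval("chr1", 4, 8),
    GenomicInterval("chr1", 10, 12),
])
for iv in peaks.merge():
    print(iv.seq_name, iv.start, iv.end)
print("covered:", peaks.covered_bases())
for iv in peaks.complement():
    print("gap:", iv.seq_name, iv.start, iv.end)
```

prints

```
chr1 1 8
chr1 10 12
covered: 9
gap: chr1 0 1
gap: chr1 8 10
gap: chr1 12 1000
```

`[1,5)` and `[4,8)` overlap and coalesce into `[1,8)`; `[10,12)` stands
alone, so 7 + 2 = 9 bases are covered, and the complement is everything
else on the 1000-bp sequence. The same operations are available from the
shell and compose under pipes:

```sh
$ printf 'chr1\t1\t5\nchr1\t4\t8\nchr1\t10\t12\n' > a.bed
$ printf 'chr1\t1000\n' > g.genome
$ genomictk merge a.bed --genome g.genome
chr1	1	8
chr1	10	12
```

Other subcommands: `intersect`, `subtract`, `complement`, `search`,
`convert` (including `sam`↔`bam`), `coverage`, `titv` and `view`.

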