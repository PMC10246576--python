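# Methods

This note records the models, conventions and deliberate design choices
behind `genomictk`, and what the validation campaigns do and do not show.

## Coordinate model

The canonical in-memory convention is 0-based half-open on every sequence;
an interval is `(seq_name, start, end, strand)` with `0 ≤ start < end` and,
once validated against a `GenomeAssembly`, `end ≤ length(seq_name)`.
Keeping a single convention internally confines every off-by-one to the
I/O boundary: BED passes through unchanged, GFF3/GTF/WIG/VCF/SAM convert
their 1-based inclusive coordinates with `start − 1` on read and `+1` on
write.

Empty intervals are unrepresentable by construction. Empty *results* are
empty collections, which keeps the set-operation postconditions simple
(no "is this interval real" checks downstream). Strand is carried as
metadata and never partitions the algebra — merge and intersect combine
`+` and `−` features; callers who need strand-aware algebra filter first.
Circular chromosomes and liftover between assemblies are out of scope.

## The persistent red-black interval tree

Each sequence of an `IntervalSet` owns an immutable red-black tree keyed
by `(start, end)`, augmented with `max_end`, the maximum interval end in
each subtree. Insertion uses the functional four-case rebalance (Okasaki's
scheme): the insertion path is copied, everything off-path is shared, so
an insert allocates O(log n) nodes and every previous version of the set
remains valid. `max_end` is recomputed in the node constructor, never
patched, which makes a stale augmentation impossible rather than merely
untested.

Decisions that were genuinely open:

* **Duplicates are retained** (multiset semantics). Files legitimately
  contain duplicate records; dropping them on insert would silently break
  read→write round-trips. `merge` collapses duplicates with everything
  else. Equal keys descend to the right, so in-order traversal is stable.
* **Merge coalesces abutting intervals** (`end == next.start`). This makes
  merge exactly "the maximal runs of the covered-base set", which in turn
  makes intersect/subtract/complement mutually consistent at the base
  level and lets the per-base oracle serve as ground truth for all four.
* **No deletion.** Derived sets are rebuilt; immutable trees make rebuild
  cheap to reason about and deletion is the one red-black operation whose
  functional variants are genuinely intricate. Nothing in the toolkit
  needs it.

Overlap search prunes any subtree whose `max_end ≤ query.start` and any
right subtree whose node starts at or past `query.end`; output order is
`(start, end)`.

The binary operations walk the merged, sorted runs of both operands with a
two-pointer sweep (intersection) or a gap-sweep (subtraction, complement),
so their cost is linear in the number of runs, independent of sequence
length. `complement` iterates over the *assembly*, not the stored trees,
so sequences with no intervals contribute their full span.

## Format codecs

All readers stream; all writers are the inverse of their readers. The
round-trip property is the design constraint that shaped the record types:
tokens whose lexical form is not recoverable from a typed value are stored
verbatim (BED optional columns, GFF3/GTF score and phase, VCF QUAL/FILTER/
INFO values, WIG value tokens), with typed access layered on top.

Format-specific choices:

* **BED** is treated as a column-prefix family (BED3–BED12): three typed
  columns, the rest validated where the standard constrains them (score
  0–1000, strand alphabet, block-count consistency) but stored as-is.
  Track/browser/comment lines pass through the file reader verbatim.
* **GFF3** attribute values decode exactly the seven reserved escapes
  (`%09 %0A %25 %3B %3D %26 %2C`) and re-encode exactly those seven
  characters; other `%XX` sequences pass through untouched. Restricting
  the codec to the reserved set is what makes parse/serialize a bijection.
  Multi-valued attributes are kept as tuples of comma-separated parts.
  A CDS without a phase warns rather than fails.
* **GTF** is strict about the `key "value";` grammar including the
  trailing semicolon; strictness is what makes the inverse property
  testable. Relaxation would be a reader flag, not a default.
* **WIG** values remember their declaration context (fixedStep step or
  variableStep, plus span). The writer emits a canonical form —
  declarations always carry an explicit `span=`, variableStep lines are
  single-space separated — so any value list serializes deterministically
  and canonical files round-trip byte-exactly.
* **VCF** targets the 4.x line grammar. Meta lines are preserved verbatim
  (with structured views for INFO/FORMAT/FILTER/contig); INFO values are
  typed lazily per the header and the raw token wins when writing.
  Multi-allelic records contribute one classification per alternate
  allele in the Ti/Tv analysis. `END` in INFO overrides the interval end;
  symbolic REF alleles have no interval and raise.
* **SAM/BAM.** Integer tag widths (`c,C,s,S,i,I`) canonicalize to `i`
  because SAM text has a single integer code; float tags pass through
  float32 and are re-rendered with `%g`; `=` in RNEXT canonicalizes to
  the explicit reference name through BAM. Round-trip equality through
  BAM is therefore defined on values, and SAM→BAM→SAM is byte-exact for
  files that already use the canonical renderings (the synthetic corpus
  does; its float tags are multiples of ¼, exact in float32). The BAM
  `bin` field is recomputed with the standard region-to-bin function on
  write and ignored on read, since no index support exists.
* **BGZF** writes 65280-byte chunks (the conventional maximum leaving
  header room) at the codec's default deflate level — equality is defined
  on the decompressed payload, so the level is semantically irrelevant.
  CRC32 and ISIZE of every block are validated on read by default
  (`check_crc=False` to skip); a missing EOF block warns by default and
  can be promoted to an error.
* **FASTQ** is strict four-line; multi-line FASTQ is ambiguous (a quality
  line may begin with `@`) and effectively extinct. The repeated
  identifier after `+` is dropped — the one deliberately lossy read.
  FASTA wrapping is likewise not preserved; re-wrapping at the source
  width restores byte equality. Sequence alphabets are not validated:
  these modules are transport, not biology.

## Analyses

Coverage is computed with interval algebra only: mapped reads (excluding
secondary 0x100 and supplementary 0x800 alignments by default, with flags
to include them) are projected through their CIGAR reference span
(`M,D,N,=,X`), merged, and intersected against each merged target
interval. Breadth is covered/length per target plus totals. A variant
belongs to a Ti/Tv stratum iff its interval overlaps the stratum's region
set under half-open semantics; a stratum with zero transversions reports
an undefined ratio (rendered `NA`), never infinity. Group labels are
caller-supplied strata — the toolkit does not guess how populations map
onto VCF content.

## Synthetic fixtures and what the tests show

All test inputs come from the seeded generator module. Defaults: three
sequences of 1–10 kb, 5–50 records per file, interval lengths 1–500 bp,
read lengths 20–120 bp, uniform ACGT sequence content — small enough for
the per-base oracle to be exhaustive, varied enough to hit every optional
column, tag type, CIGAR op and declaration form. Seeding is explicit and
string-based (process-independent); identical config + seed regenerates
the corpus byte-identically.

The generators emulate the formats' *structural* space, not biology: no
mutation model, no quality-error profile, no linkage between reads and a
reference sequence. Passing tests therefore certify the algebra and the
codecs — coordinate conventions, escaping, binary packing, invariants —
and say nothing about, e.g., variant-caller idiosyncrasies or malformed
files in the wild beyond the explicit negative-case corpus (which checks
that corrupted lines produce diagnostics, not crashes).

Validation campaign sizes: 1000 random instances (≤ 100 intervals,
sequences ≤ 10 kb) for oracle equivalence; 10⁴ insertions for the
structural audit; 100 operation sequences for persistence; 500 records
per format for round-trips; 100 BAM files and 100 BGZF payloads up to
1 MiB for the binary checks. Independent cross-checks in the test suite:
the generic `gzip` codec must decompress our BGZF output, and `samtools`
(when on `PATH`) must render our BAM byte-identically to our own SAM text
and vice versa.

## Known limitations

No BAI/CSI/tabix indexing, BCF or CRAM; no GFF3 feature hierarchy
resolution or embedded `##FASTA`; no bigWig/bigBed; no variant
normalization; no mate-pair validation, sorting or duplicate marking.
The pure-Python engine favors auditability over raw speed; the algebra is
O(n log n) in interval counts, but constant factors are those of Python
objects.
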