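# Methods

## Problem and model

Genome scaffolding orders and orients assembled contigs using linking
information from read pairs. `scafflink` builds the scaffolding graph —
contig nodes; edges weighted by supporting pairs, carrying relative
orientation and a gap estimate — without base-level alignment. The key
observation is that a read pair only needs to be *located*, not aligned:
k-mers that occur exactly once in the contig set (canonically, counting
both strands) identify a genomic position unambiguously, so a handful of
unique-k-mer hits suffices to place a read with high confidence.

The same machinery turns long, error-rich reads (nanopore, PacBio) into
linking information: two short windows cut from one long read at a
chosen distance D behave like a mate pair with insert D, and many D
values produce many synthetic libraries from the same reads, up to the
read length.

## Unique-k-mer index

Construction: (1) count canonical k-mers over all contigs; the canonical
form is the lexicographic minimum of a k-mer and its reverse complement,
so both strands share one key; (2) hash each k-mer to 64 bits — for
k ≤ 32 the k-mer is packed 2 bits/base and passed through the splitmix64
finalizer, for larger k the first 8 bytes of a blake2b digest of the
canonical string are used; (3) keep exactly the frequency-1 keys;
(4) store, per key, a 16-bit fingerprint (low bits of an xorshift64*
remix of the key hash) and a payload of 32-bit contig id, 32-bit
coordinate and 1-bit strand (the orientation of the canonical form on
the contig). K-mers containing non-ACGT symbols are never counted,
indexed or queried. Palindromic k-mers are counted once per position
with the strand bit set to forward.

The key table is an exact sorted array queried by binary search rather
than a minimal perfect hash; the observable contract is the same and is
preserved deliberately: a stored key always returns its true record (no
false negatives), and an absent key is routed to a pseudo-random
occupied slot whose fingerprint it must match, so absent queries
succeed falsely with probability 2^-16 ≈ 1.5e-5 — the behaviour of an
MPHF backed by a 16-bit probabilistic dictionary. The empirical rate is
checked against a 3-sigma binomial band at 10^7 absent queries.

Construction scans contigs in chunks (default 5 Mb, overlapping by k−1)
and is invariant to the chunk size; `--threads` is accepted for
interface compatibility and never changes results. Coordinates are
0-based internally and only converted to 1-based at SAM emission.
Inputs whose coordinates or contig counts would overflow 32 bits are
rejected with a clear error.

## Pair placement

Per read: look up its k-mers left to right (both strands via the
canonical hash), keep the first `capacity` fingerprint-verified hits
(10 for short reads, 20 for synthetic long-read pairs), group hits by
(contig, strand), sort by inferred read start (hit coordinate minus
read offset, strand-adjusted) and score the read as the maximum number
of hits inside any window as wide as the read. A maximum attained at
two distinct locations makes the read ambiguous and its effective score
0; ties between overlapping windows at one location are not ambiguity.

Per pair: the forward read gates the pair (score strictly greater than
3, default), then both reads report when each scores strictly above the
report threshold (5 short, 15 long) at an unambiguous location.
Otherwise the better-scored read (tie → forward) is fixed — provided it
itself clears the report threshold — and the mate is rescued: its hits
are restricted to placements on the anchor's contig within
mean ± 3 sd of the library insert and in the library orientation, and
the filtered hits must window-score at least 4 (inclusive, unlike the
strict report thresholds). The 3-sd window covers >99% of a Gaussian
insert distribution. Restricting rescue to the anchor's contig is a
design choice: the expected-distance constraint is only measurable
within one contig, so cross-contig graph edges come from score-reported
pairs only.

The reported position derives from a single representative hit — the
smallest read offset inside the winning window — clamped into contig
bounds. Orientation labels are positional: with opposite strands, FR
when the forward-strand read starts at or left of the reverse-strand
read, RF otherwise; FF/RR with equal strands. The observed insert is
the outer distance (leftmost read start to rightmost read end).

## Synthetic mate-pairs from long reads

From each long read, for every insert size D and offset s stepped by
100 bp, the pair is read[s, s+200) and the reverse complement of
read[s+D−200, s+D); D is the outer distance, so on error-free reads the
observed insert of a placed pair is exactly D, and the pair count per
read is floor((L−D)/step)+1. Pairs are physically forward-reverse, and
pair names encode provenance (`read:offset:D`). Deletion-dominant
(nanopore-like) errors shrink read coordinates relative to genomic
span, so observed inserts exceed D on average — a direction the test
suite checks explicitly; substitution-dominant (PacBio-like) errors
reduce recall but leave the insert distribution centred on D.

## Library parameters and QC

Up to 100,000 short pairs (or synthetic pairs from 1,000 long reads)
are placed with report threshold 8 (15 for synthetic) and rescue
disabled; pairs within one contig yield observed inserts. The sorted
inserts lose exactly floor(0.1 n) values from each tail; the mean is
the trimmed mean. The sd is computed on the trimmed sample and rescaled
by 1/0.661549 — the sd of a standard normal truncated to its central
80% — so it consistently estimates the full library sd under a Gaussian
insert model; without this correction the trimmed sd understates the
spread by a third, which would both misreport the library and shrink
the rescue window. Orientation is a majority vote over FR/RF/FF/RR
(fixed tie-break order, hence input-order invariant); synthetic
libraries are FR by construction and skip the vote. Fewer than 50
usable pairs is an error advising a larger sample.

QC flags a library as low quality when more than 30% of observed
inserts fall outside the trimmed mean ± 3 sd or when the sd exceeds 30%
of the mean — thresholds aimed at catching contaminated or degenerate
libraries before scaffolding.

## Scaffolding graph and join evaluation

Cross-contig pairs vote for an edge between the two contig ends the
reads point at (forward-strand read → right end, reverse → left end).
The per-pair gap estimate is the library mean insert minus the two
read-to-contig-end distances; the edge stores the mean over supporting
pairs and its weight, and edges under a minimum weight (default 3) are
dropped.

Scaffold joins are classified against a true layout with bit-wise
flags: 0 correct; 1 wrong orientation; 2 different references; 4 wrong
distance; 5 = 4+1; 8 wrong order; 12 = 8+4. The gap tolerance for flag
4 defaults to 1,000 bp and is configurable. P (potential joins) is the
number of truly adjacent contig pairs in the layout; Recall = TP/P,
Precision = TP/(TP+FP), F-score their harmonic mean (0 when TP = 0).

## Synthetic data generator

Genomes are i.i.d. uniform bases with exact repeat blocks copied
verbatim to non-overlapping random positions; fragmentation tiles the
genome into contiguous contigs with a written layout. Illumina-like
pairs draw inserts from N(mean, sd) truncated at twice the read length,
FR-oriented, with optional per-base substitutions and a contamination
fraction of short (~N(300, 50)) RF pairs mimicking circularization
failures. Long reads draw lengths from N(mean_len, len_sd); the
error budget (default 15%, the typical raw long-read error rate) splits
60/25/15 across deletion/substitution/insertion for the nanopore-like
profile and 60/25/15 across substitution/insertion/deletion for the
PacBio-like profile — these proportions capture the dominant error type
of each technology, not a calibrated instrument model. All randomness
flows through numpy's PCG64 generator under an explicit seed; outputs
are bit-identical across runs and platforms.

What the generator does not emulate: quality-score structure (qualities
are constant placeholders; the method never reads them), coverage and
GC biases, chimeric long reads, structural heterozygosity. Passing
tests therefore demonstrate algorithmic correctness under the stated
error models, not performance on any particular instrument's data.

## Problem sizes and numerical choices

The test and acceptance workloads use a 1 Mb genome in 10 contigs with
a planted 5 kb repeat, 10,000 mate pairs per library at N(3000, 300),
10^7 absent-k-mer queries, and long-read sets of 12–15 reads near 10 kb
— sizes chosen so every ground-truth property is measurable with tight
statistics on a desktop. Thresholds follow the defaults above
throughout; score comparisons are strict where noted, rescue inclusive.
Degenerate inputs (reads shorter than k, all-N reads, contigs shorter
than k, zero unique k-mers, zero within-contig pairs) raise errors or
return empty results as documented per function.

## Known limitations

- No base-level alignment: CIGARs are full-length `M` placeholders and
  MAPQ encodes only reported (60) vs rescued (30) placement.
- Reads straddling a contig boundary can split their hits between two
  contigs and occasionally go unplaced or ambiguous; such reads have no
  single true contig location.
- Rescue never crosses contigs (see above).
- The index is an exact dictionary: memory per key exceeds the ~87 bits
  of a compressed MPHF layout; at desk scale this is irrelevant, and the
  lookup contract (including the 2^-16 false-positive rate) is
  preserved.
- Scaffold path selection is out of scope: the package builds and
  evaluates the graph; producing scaffolds from it is the job of a
  dedicated scaffolder.
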