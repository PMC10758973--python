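# Methods

## Search model

An off-target site is an alignment of the search query (guide+PAM, length
m) against a genome substring, scored with unit cost per substitution,
insertion and deletion. A gap in the aligned query is a **DNA bulge** (an
unpaired genome base); a gap in the aligned target is an **RNA bulge** (an
unpaired guide base). A site is reported when some alignment ending at its
end position satisfies all of:

| budget | meaning | default in CLI |
|---|---|---|
| `maxE` | total edits, `mc + bc` | required flag |
| `maxB` | bulges | `maxE` |
| `maxM` | mismatches when `bc == 0` | `maxE` |
| `maxMB` | mismatches when `bc >= 1` | `maxE` |

All budgets are non-negative integers, each at most `maxE`. The reported
alignment is one of minimum total edits among those satisfying the
budgets; ties are broken toward fewer bulges, then by fixed branch
priority (diagonal > RNA bulge > DNA bulge), making output byte-identical
across runs, thread counts and window lengths.

### Stage 1: semi-global scan

The DP matrix uses a free first row (`M[0,j] = 0`: the alignment may start
anywhere in the genome) but a charged first column (`M[i,0] = i`): the
query must be consumed in full, and a bulge before the first guide base is
not a meaningful alignment feature. Row m at column j then equals
`min_s Lev(query, window[s:j])`, and the candidate set is
`{ j : M[m,j] <= maxE }`. Cell values are bounded by the row index, so the
matrix is stored as uint8 (valid for m ≤ 255); each row is computed
vectorized by unrolling the horizontal recurrence into a cumulative
minimum. One fill serves every budget combination, which is why runtime is
nearly independent of the thresholds.

### Stage 2: constrained trace-back

From `(i=m, j=end, mc=0, bc=0)` the recursion explores diagonal, RNA-bulge
and DNA-bulge moves, accepting at `i == 0` and failing at `j == 0` with
`i > 0`. Budgets are re-checked at every call with the bulge-dependent
mismatch limit, so a branch acquiring its first bulge is immediately
re-validated against `maxMB`. Two correctness-neutral accelerations:

* **Matrix pruning.** `M[i][j]` is the cheapest completion of the
  remaining prefix, so a branch dies when it exceeds
  `effMaxE - mc - bc`, with `effMaxE = maxE` if `bc == 0` else
  `min(maxE, maxB + maxMB)`. A dedicated test disables this pruning and
  verifies identical output.
* **Memoization on `(i, j, mc, bc)`.** The optimal completion of a state
  is independent of how it was reached; the memo is shared across all end
  positions of a window, bounding the otherwise exponential recursion.

With the per-call check, a bulge-free branch whose mismatch count exceeds
`maxM` is cut even though, under `maxMB > maxM`, a later bulge could have
legitimized it. We keep the per-call rule (it matches the recursion's
stated form); it is exact whenever `maxMB <= maxM`, which is the
biologically sensible regime (bulge-carrying sites tolerate *fewer*
mismatches) and the only one exercised by the default grids. The
enumeration oracle implements the identical rule, so the equivalence tests
are exact on every grid.

### PAM handling

The PAM pattern (IUPAC, e.g. NGG) is appended 3' of the guide; the
reverse-strand query is the reverse complement of guide+PAM with the PAM
mask moved to the front. With `allow_pam_edits=False` (default), while the
next query character to consume is a PAM position only a zero-cost
diagonal move is permitted: degenerate codes still match for free, but PAM
mismatches, RNA bulges at PAM positions, and DNA bulges adjacent to the
unconsumed PAM are all forbidden. With `allow_pam_edits=True` PAM columns
are ordinary columns. `observed_pam` reports the genome bases opposite the
PAM, oriented 5'→3' in the guide's sense on both strands.

### Alphabet policy

Genome text is normalized per character (case-folded, U→T, anything else
→ N) and a genomic N matches **no** query code — assembly gaps cost
mismatches and cannot seed spurious sites. Query-side degenerate codes
match their IUPAC sets (query N matches any concrete base, not genomic N).
Soft-masked lowercase is treated as ordinary sequence. This N policy is a
design choice; the matching table is enumerable and pinned by tests.

## Windowing and parallelism

Chromosomes are cut into windows of `window_length` (default 1 Mb; ~24 MB
of matrix per 23-nt query) overlapping by `overlap` (default `m + maxE`,
one more than the minimal `m + maxE - 1` needed so no alignment can span a
boundary without lying wholly inside one window). Each end position is
*owned* by exactly one window — the first window of a chromosome owns all
its ends, later windows only ends beyond `offset + overlap` — so the
output is provably identical for any valid window length and any thread
count; cross-window deduplication on (guide, chrom, strand, end, aligned
strings) remains as a safety net. Parallelism is a thread pool over
windows (the numpy fill releases the GIL); the contract is only that
results equal the serial run. Only queries are reverse-complemented; the
genome is read once, streamed per record.

## Site accounting

* **Unique sites**: distinct (chromosome, strand, end) triplets — two
  alignments differing only in composition are one site.
* **Non-consecutive unique sites**: runs of consecutive end positions on
  one (chromosome, strand) collapse to one site (bulge-shifted duplicates
  of a single physical site); the representative is the smallest end.
* **Best-in-window** (`--best-in-window W`): streaming per (guide,
  chromosome, strand) over end-sorted sites, holding the last kept site
  and resolving any clash within W toward fewer edits, first site on a
  tie. This pairwise-stream rule (rather than a global tiling optimum) is
  deliberate; it is idempotent and with `W=1` merges only identical ends.
  Grouping includes the guide because edit counts are only comparable
  within one guide.
* **In-a-window association**: a reference site is associated with
  another site list if a key shares chromosome (and strand, by default —
  the stricter choice; `same_strand=False` relaxes it) with end inside
  the site span padded by the maximum bulge size.

## Synthetic data and oracles

`generate_genome` draws i.i.d. bases at a target GC content (default
0.41, the human-genome average). `plant_site` overwrites a genome slice
with a mutated guide+PAM copy built from an explicit edit script:
substitutions to a different base, RNA bulges as deleted guide bases, DNA
bulges as inserted bases chosen to differ from both neighbours; edits are
restricted to interior guide positions and spaced ≥ 2 bp so the
minimum-edit reading of each planted site is unambiguous; the PAM is
written as a concrete match of the pattern. Reverse-strand sites insert
the reverse complement, keeping ground-truth keys in forward coordinates.
The generator emulates isolated off-target loci in random background; it
does **not** model repeats, segmental duplications or chromatin — passing
tests certify algorithmic correctness of the search, not cleavage
likelihood at real loci.

Two independent oracles define expected results. The end-position oracle
runs one textbook start-anchored Levenshtein DP per start position
(substring length capped at `m + maxE`, which cannot alter any distance
≤ `maxE`); it shares no code or orientation with the scan and is itself
cross-checked against edlib. The alignment oracle exhaustively enumerates
every monotone path ending at a column — no memoization, no matrix
pruning — applying the same per-step budget and PAM semantics, and
returns the feasible minimum.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic material sized
for completeness of coverage rather than scale: 500 scan-oracle instances
(m ∈ [4,23], n ∈ [30,300], maxE ∈ 0..4), 200 trace-oracle instances
(m ≤ 12, n ≤ 40, three threshold grids × both PAM policies), and 100 × 50-kb
genomes × 10 planted sites for recall; the whole suite completes in well
under a minute. Whole-genome runs use the same code path with the default
1-Mb windows. Degenerate cases: an empty window yields no candidates; an
all-gap "alignment" cannot be produced because the trace-back must consume
the query against at least `m - maxB` genome bases; empty FASTA records
are skipped with a warning.

## Known limitations

* Worst-case trace-back cost grows exponentially with `maxB`; memoization
  and matrix pruning make it negligible for the practical `maxB ≤ 2`.
* Per-record streaming holds one chromosome string in memory at a time.
* No genetic-variant awareness, no affine gap costs, no cleavage-activity
  scoring (CFD/MIT) — the output is a complete candidate list, not a
  ranked risk estimate.
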