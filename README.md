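# offscan

Exhaustive CRISPR/Cas9 off-target search with mismatches **and** bulges,
under separate, user-chosen budgets for each edit type.

## The problem

A Cas9 ribonucleoprotein is directed by a ~20-nt single-guide RNA (sgRNA)
to loci complementary to the guide and flanked by a PAM (NGG for SpCas9).
It can also cleave *off-target sites*: loci within a small edit distance of
guide+PAM — a few substitutions (mismatches), plus insertions and deletions
that appear in the guide–target duplex as *DNA bulges* (an unpaired genome
base, a gap in the aligned guide) or *RNA bulges* (an unpaired guide base,
a gap in the aligned genome). Safe guide design requires enumerating
**every** such locus genome-wide, with realistic, operation-specific limits
— e.g. "up to 4 edits total, at most 1 bulge, and at most 1 mismatch once a
bulge is present".

`offscan` solves this with a two-step procedure, for users who need a
complete, deterministic site list rather than a heuristic or indexed
approximation:

**Step 1 — semi-global scan.** For a query *a* of length *m* (guide+PAM)
and a genome window *b* of length *n*, fill the (m+1)×(n+1) matrix

    M[i,j] = min( M[i-1,j-1] + s(i,j), M[i,j-1] + 1, M[i-1,j] + 1 )
    s(i,j) = 0 if a_i matches b_j (IUPAC-aware) else 1
    M[0,j] = 0   (an alignment may start anywhere in the genome)
    M[i,0] = i   (no free gaps at the start of the guide)

with unit cost for every edit. Row *m* then holds, at column *j*, the
minimum edit distance of the whole query against any genome substring
ending at *j*; every column with `M[m,j] <= maxE` is a candidate end
position. One O(mn) fill serves **all** threshold combinations.

**Step 2 — constrained trace-back.** From each candidate end position a
recursive reconstruction finds an alignment satisfying

* `bc <= maxB` (bulges),
* `mc <= maxM` if `bc == 0`, else `mc <= maxMB` (mismatches),
* `mc + bc <= maxE` (total edits),

with minimum total edits, or rejects the site. Branches are cut against
the matrix (`M[i,j] > effMaxE - mc - bc`, where `effMaxE = maxE` while
bulge-free and `min(maxE, maxB + maxMB)` otherwise) and states are
memoized, so the step costs a negligible fraction of the scan.

Both strands are searched over the forward genome text by
reverse-complementing the *query*, so all coordinates are directly
comparable; PAM edits can be prohibited (default) or allowed and counted.
Correctness is defined by brute-force oracles (naive per-start Levenshtein
DP; exhaustive alignment-path enumeration) that share no code with the
search, and by synthetic genomes with planted, edit-scripted sites.

## Worked example

Plant one site containing 1 mismatch, 1 RNA bulge and 1 DNA bulge into a
4-kb synthetic genome, then search for it:

```python
from offscan.synthetic import generate_genome, plant_site, write_fixture

guide = "AUUGAGAUAGUGUGGGGAAG"          # RNA alphabet is fine
genome = generate_genome(4000, seed=11)
genome, site = plant_site(genome, guide, "NGG", 1, 1, 1,
                          position=1500, strand="+", seed=5,
                          edit_positions=[3, 9, 15])
write_fixture("demo.fa", "demo.json", genome, [site])
```

```sh
offscan --genome demo.fa --guide AUUGAGAUAGUGUGGGGAAG --pam NGG \
        --max-e 3 --max-m 3 --max-b 2 --max-mb 1 --out demo_sites.tsv
```

which logs and writes:

```
INFO offscan: search: 1 guide(s), PAM NGG, maxE=3 maxM=3 maxB=2 maxMB=1 pam_edits=False strands=both threads=1 window=1000000
INFO offscan: wrote 1 sites to demo_sites.tsv
```

```
chrom      strand start end  aligned_query            aligned_target           mismatches rna_bulges dna_bulges bulges edits observed_pam guide_name
chr_synth  +      1500  1523 ATTGAGATA-GTGTGGGGAAGNGG ATT-AGATACGTGTGGTGAAGCGG 1          1          1          2     3     CGG          guide
```

Reading the row: the site sits on the forward strand at 0-based half-open
coordinates [1500, 1523). The gap in `aligned_target` is the RNA bulge
(guide base G unpaired), the gap in `aligned_query` is the DNA bulge
(genome base C unpaired), and `G→T` at guide position 15 is the mismatch
— 3 edits total, within `maxE=3`, `maxB=2`, `maxMB=1`. The observed PAM is
CGG, a concrete match of NGG. Re-running with `--max-b 1 --max-mb 0`
reports nothing: the same locus is correctly rejected once the budgets no
longer admit two bulges.

The same search is available in-library via
`offscan.search_genome(records, queries, thresholds, config)`, and
`--best-in-window 1000` collapses each 1-kb window to its minimum-edit
site (ties keep the first).

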