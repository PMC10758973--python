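"""Post-search site accounting.

Counting conventions used when comparing off-target search outputs:

* a *unique site* is a distinct (chromosome, strand, end position) triplet;
* *non-consecutive* unique sites merge runs of consecutive end positions,
  which typically represent one physical site shifted by permitted bulges;
* *best-in-window* keeps, per (guide, chromosome, strand), only sites at
  least W apart, resolving each clash toward the minimum edit distance
  (first site on a tie) — the mode used when experimental reads localize a
  cut only to a window;
* *in-a-window association* asks, for each reference site, whether a key
  from another site list falls inside the site span padded by the maximum
  bulge size.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from typing import Iterable, Sequence

from .core import SiteAlignment, SiteKey


def unique_sites(sites: Iterable[SiteAlignment]) -> set[SiteKey]:
    """The distinct (chrom, strand, end) triplets among the alignments."""
    return {s.key for s in sites}


def collapse_consecutive(keys: Iterable[SiteKey]) -> tuple[int, list[SiteKey]]:
    """Merge, per (chrom, strand), maximal runs of end positions whose
    successive differences are exactly 1.  Returns (run count,
    representative keys), the representative being the smallest end of
    each run.  Runs never merge across chromosomes or strands."""
    by_group: dict[tuple[str, str], list[int]] = defaultdict(list)
    for k in keys:
        by_group[(k.chrom, k.strand)].append(k.end)
    reps: list[SiteKey] = []
    for (chrom, strand), ends in sorted(by_group.items()):
        prev = None
        for e in sorted(set(ends)):
            if prev is None or e != prev + 1:
                reps.append(SiteKey(chrom, strand, e))
            prev = e
    return len(reps), reps


def best_in_window(sites: Sequence[SiteAlignment], W: int) -> list[SiteAlignment]:
    """Streaming per (guide, chrom, strand) over end-sorted sites: while the
    incoming site's end is within W of the held site's end, keep the one
    with fewer edits (the earlier one on a tie); output sites are pairwise
    >= W apart in end position per group."""
    if W < 1:
        raise ValueError("W must be >= 1")
    groups: dict[tuple[str, str, str], list[SiteAlignment]] = defaultdict(list)
    for s in sorted(sites, key=lambda s: (s.guide_name, s.chrom, s.strand, s.end)):
        groups[(s.guide_name, s.chrom, s.strand)].append(s)
    kept: list[SiteAlignment] = []
    for group in groups.values():
        held = None
        for s in group:
            if held is None:
                held = s
            elif s.end - held.end < W:
                if s.edits < held.edits:
                    held = s
            else:
                kept.append(held)
                held = s
        if held is not None:
            kept.append(held)
    kept.sort(key=lambda s: (s.chrom, s.end, s.strand, s.start, s.guide_name))
    return kept


def associate_in_window(
    reference: Sequence[SiteAlignment],
    other: Iterable[SiteKey],
    max_bulge: int,
    same_strand: bool = True,
) -> tuple[int, list[SiteAlignment]]:
    """For each reference site, test whether some key in ``other`` shares
    the chromosome (and, by default, the strand) and has its end within
    [start - max_bulge, end + max_bulge].  Returns (number associated,
    list of unassociated reference sites)."""
    by_group: dict[tuple[str, str] | str, list[int]] = defaultdict(list)
    for k in other:
        g = (k.chrom, k.strand) if same_strand else k.chrom
        by_group[g].append(k.end)
    for ends in by_group.values():
        ends.sort()
    associated = 0
    missed: list[SiteAlignment] = []
    for r in reference:
        g = (r.chrom, r.strand) if same_strand else r.chrom
        ends = by_group.get(g, [])
        lo, hi = r.start - max_bulge, r.end + max_bulge
        idx = bisect.bisect_left(ends, lo)
        if idx < len(ends) and ends[idx] <= hi:
            associated += 1
        else:
            missed.append(r)
    return associated, missed
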