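"""Step 1: fill the modified alignment matrix and scan for end positions.

This is a semi-global edit-distance DP, not classic Smith-Waterman scoring:

* unit cost for every edit operation (substitution, insertion, deletion);
* the first row is zero (``M[0,j] = 0``) so an alignment may start at any
  genome position for free;
* the first column is ``M[i,0] = i`` — the query cannot start mid-way, so
  there are no free gaps at the beginning of the guide;
* row m (the boundary where the whole query has been consumed) then holds,
  at column j, the minimum edit distance of the query against any genome
  substring ending at j.  Every column with ``M[m,j] <= maxE`` is a
  candidate off-target end position handed to the trace-back step.

The fill is O(m*n) and independent of the thresholds, so one matrix serves
every (maxM, maxB, maxMB) combination.  The whole matrix is kept (uint8 —
values never exceed m, since ``M[i,j] <= i``) because the trace-back reads
arbitrary cells for pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomeWindow, GuideQuery, encode_genome, match_table


@dataclass
class DPMatrix:
    """The filled (m+1) x (n+1) matrix for one (query, window) pair."""

    values: np.ndarray  # uint8, shape (m+1, n+1)
    m: int
    n: int


@dataclass(frozen=True)
class EndPositionHit:
    """A candidate end column j with its unconstrained edit distance."""

    column: int
    edit_distance: int


def fill_matrix(query: GuideQuery, window: GenomeWindow) -> DPMatrix:
    """Fill the matrix row by row, vectorized over genome columns.

    The horizontal dependency ``M[i,j] = min(t_j, M[i,j-1]+1)`` (with t_j
    the best of the diagonal and vertical moves) unrolls to the prefix
    minimum ``M[i,j] = j + min(i, min_{k<=j}(t_k - k))``, which lets each
    row be computed with cumulative-minimum array ops.
    """
    m = query.m
    if m < 1:
        raise ValueError("query must be non-empty")
    n = window.n
    codes = encode_genome(window.seq)
    matches = match_table(query.search_seq)  # (m, 5) bool

    values = np.empty((m + 1, n + 1), dtype=np.uint8)
    values[0, :] = 0
    values[:, 0] = np.arange(m + 1, dtype=np.uint8)
    if n == 0:
        return DPMatrix(values=values, m=m, n=0)

    cols = np.arange(1, n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)  # row 0
    for i in range(1, m + 1):
        s = np.where(matches[i - 1][codes], 0, 1).astype(np.int32)
        t = np.minimum(prev[:-1] + s, prev[1:] + 1)
        cur = cols + np.minimum(
            np.minimum.accumulate(t - cols), np.int32(i)
        )
        values[i, 1:] = cur.astype(np.uint8)
        prev[1:] = cur
        prev[0] = i
    return DPMatrix(values=values, m=m, n=n)


def scan_end_positions(dp: DPMatrix, maxE: int) -> list[EndPositionHit]:
    """All columns j in [1, n] whose full-query distance is within maxE,
    in ascending column order.  Column 0 (empty text) is never reported."""
    last_row = dp.values[dp.m, 1:]
    hits = np.flatnonzero(last_row <= maxE)
    return [EndPositionHit(int(j) + 1, int(last_row[j])) for j in hits]
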