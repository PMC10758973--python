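"""Step 2: constrained recursive trace-back from each candidate end position.

Given an end column found by the scan, reconstruct an alignment of the
whole query ending there that satisfies the *separate* budgets —

* ``bc <= maxB`` bulges,
* ``mc <= maxM`` mismatches while the alignment has no bulges, or
  ``mc <= maxMB`` once it has any,
* ``mc + bc <= maxE`` total edits —

and among all such alignments return one with minimum total edits, or
reject the site.  The recursion explores three moves from state (i, j):
the diagonal (consume query[i-1] against genome[j-1], mismatch penalty 0
or 1), an RNA bulge (consume query[i-1] against a gap), and a DNA bulge
(consume genome[j-1] against a gap).  Two devices keep it fast:

* pruning against the scan matrix: if ``M[i][j]`` (the cheapest way to
  finish aligning the query prefix) already exceeds the remaining budget
  ``effMaxE - mc - bc``, the branch is dead.  ``effMaxE`` is ``maxE``
  while the alignment is bulge-free and ``min(maxE, maxB + maxMB)`` once
  a bulge is present;
* memoization on (i, j, mc, bc): the best completion from a state does
  not depend on how the state was reached, so states are solved once per
  (window, query, thresholds), shared across all end positions.

Selection among surviving children is deterministic: minimum total edits,
then fewer bulges, then branch priority diagonal > RNA bulge > DNA bulge.

PAM policy: with ``allow_pam_edits=False`` the only move permitted while
the next query character to consume is a PAM position is a zero-cost
diagonal (degenerate PAM codes such as N still match for free); RNA
bulges at PAM positions and DNA bulges adjacent to the unconsumed PAM are
forbidden.  With ``allow_pam_edits=True`` PAM columns are ordinary
columns and their edits count toward the budgets.
"""

from __future__ import annotations

from .core import (
    GAP,
    GenomeWindow,
    GuideQuery,
    SiteAlignment,
    Thresholds,
    iupac_match,
)
from .scan import DPMatrix

DIAGONAL = "diagonal"
RNA_BULGE = "rna_bulge"  # gap in the genome string (unpaired guide base)
DNA_BULGE = "dna_bulge"  # gap in the query string (unpaired genome base)

_BRANCH_ORDER = {DIAGONAL: 0, RNA_BULGE: 1, DNA_BULGE: 2}


def effective_max_edits(bc: int, th: Thresholds) -> int:
    """The edit budget actually reachable given the bulge state: maxE for a
    bulge-free alignment, min(maxE, maxB + maxMB) once bulges exist."""
    return th.maxE if bc == 0 else min(th.maxE, th.maxB + th.maxMB)


def apply_pam_policy(i: int, query: GuideQuery, th: Thresholds) -> frozenset[str]:
    """Moves permitted at state (i, ·) — i.e. when query position i-1 is the
    next to be consumed.  Outside the PAM, or when PAM edits are allowed,
    every move is permitted; inside a protected PAM only the zero-cost
    diagonal survives (the caller enforces the zero cost)."""
    if th.allow_pam_edits or i == 0 or not query.pam_mask[i - 1]:
        return frozenset((DIAGONAL, RNA_BULGE, DNA_BULGE))
    return frozenset((DIAGONAL,))


def trace_back(
    dp: DPMatrix,
    query: GuideQuery,
    window: GenomeWindow,
    end_column: int,
    th: Thresholds,
    prune: bool = True,
    _memo: dict | None = None,
) -> SiteAlignment | None:
    """Reconstruct a minimum-edit alignment ending at ``end_column``
    satisfying all four budgets and the PAM policy, or return None.

    ``prune=False`` disables the scan-matrix pruning (identical results,
    used only to test pruning safety).  ``_memo`` may be shared across
    calls for the same (dp, query, window, th) to reuse solved states.
    """
    if dp.m != query.m or dp.n != window.n:
        raise ValueError("DP matrix does not match query/window dimensions")
    if not 1 <= end_column <= dp.n:
        raise ValueError("end_column out of range")

    a = query.search_seq
    b = window.seq
    M = dp.values
    memo: dict = {} if _memo is None else _memo

    def post(i: int, j: int, mc: int, bc: int):
        # budgets (re-checked against the bulge-dependent mismatch limit
        # at every call, so a branch acquiring its first bulge is
        # immediately re-validated against maxMB)
        if bc > th.maxB or mc > th.mismatch_limit(bc) or mc + bc > th.maxE:
            return None
        if i == 0:
            return (mc, bc, "", "")  # free prefix: alignment starts at column j
        if j == 0:
            return None
        if prune and int(M[i][j]) > effective_max_edits(bc, th) - mc - bc:
            return None

        state = (i, j, mc, bc)
        if state in memo:
            return memo[state]

        allowed = apply_pam_policy(i, query, th)
        qc, tc = a[i - 1], b[j - 1]
        mp = 0 if iupac_match(qc, tc) else 1
        candidates = []
        if DIAGONAL in allowed and not (mp == 1 and len(allowed) == 1):
            r = post(i - 1, j - 1, mc + mp, bc)
            if r is not None:
                candidates.append((r[0], r[1], r[2] + qc, r[3] + tc, DIAGONAL))
        if RNA_BULGE in allowed:
            r = post(i - 1, j, mc, bc + 1)
            if r is not None:
                candidates.append((r[0], r[1], r[2] + qc, r[3] + GAP, RNA_BULGE))
        if DNA_BULGE in allowed:
            r = post(i, j - 1, mc, bc + 1)
            if r is not None:
                candidates.append((r[0], r[1], r[2] + GAP, r[3] + tc, DNA_BULGE))

        if not candidates:
            best = None
        else:
            fm, fb, pa, pb, _ = min(
                candidates,
                key=lambda c: (c[0] + c[1], c[1], _BRANCH_ORDER[c[4]]),
            )
            best = (fm, fb, pa, pb)
        memo[state] = best
        return best

    result = post(query.m, end_column, 0, 0)
    if result is None:
        return None
    fm, fb, pa, pb = result
    rna = pb.count(GAP)
    dna = pa.count(GAP)
    target_len = len(pb) - rna
    start = end_column - target_len
    return SiteAlignment(
        chrom=window.chrom,
        strand=query.strand,
        start=start,
        end=end_column,
        aligned_query=pa,
        aligned_target=pb,
        mismatches=fm,
        rna_bulges=rna,
        dna_bulges=dna,
        observed_pam=_observed_pam(pa, pb, query),
        guide_name=query.name,
    )


def _observed_pam(pa: str, pb: str, query: GuideQuery) -> str:
    """Genome bases aligned opposite PAM query positions, reported 5'->3'
    in the guide's sense (reverse-complemented for reverse-strand sites).
    RNA-bulged PAM positions contribute nothing; only possible when PAM
    edits are allowed."""
    from .core import reverse_complement

    out = []
    qi = 0
    for ac, bc_ in zip(pa, pb):
        if ac != GAP:
            if query.pam_mask[qi] and bc_ != GAP:
                out.append(bc_)
            qi += 1
    pam = "".join(out)
    return reverse_complement(pam) if query.strand == "-" else pam
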