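"""Constrained trace-back: threshold semantics, optimality, PAM policy."""

import random

import pytest

from offscan.core import GAP, Thresholds, compile_queries
from offscan.scan import fill_matrix, scan_end_positions
from offscan.synthetic import oracle_constrained_alignment
from offscan.trace import effective_max_edits, trace_back

from conftest import bare_query, random_dna, window

ALL4 = Thresholds(4, 4, 4, 4)


@pytest.mark.parametrize(
    "bc, th, expected",
    [
        (0, Thresholds(4, 4, 1, 1), 4),
        (1, Thresholds(4, 4, 1, 1), 2),
        (2, Thresholds(3, 3, 2, 3), 3),
        (1, Thresholds(5, 5, 2, 1), 3),
        (3, Thresholds(2, 2, 0, 0), 0),
    ],
)
def test_effective_max_edits(bc, th, expected):
    assert effective_max_edits(bc, th) == expected


def test_effective_max_edits_grid():
    """min(maxE, maxB+maxMB) once bulges exist, maxE while bulge-free."""
    for maxE in range(5):
        for maxB in range(maxE + 1):
            for maxMB in range(maxE + 1):
                th = Thresholds(maxE, maxE, maxB, maxMB)
                assert effective_max_edits(0, th) == maxE
                for bc in (1, 2, 3):
                    assert effective_max_edits(bc, th) == min(maxE, maxB + maxMB)


def traced(query, text, end_column, th, **kw):
    w = window(text)
    dp = fill_matrix(query, w)
    return trace_back(dp, query, w, end_column, th, **kw)


class TestTraceBack:
    def test_exact_site(self):
        q = bare_query("ACGTT")
        site = traced(q, "GGACGTTAA", 7, ALL4)
        assert site is not None
        assert (site.mismatches, site.bulges) == (0, 0)
        assert site.aligned_query == site.aligned_target == "ACGTT"
        assert (site.start, site.end) == (2, 7)

    def test_bulge_needed_but_forbidden(self):
        # target is the query with one extra base: needs one DNA bulge
        q = bare_query("ACGTACGT")
        text = "ACGTTACGT"
        th = Thresholds(maxE=2, maxM=2, maxB=0, maxMB=2)
        assert traced(q, text, 9, th) is None
        th2 = Thresholds(maxE=2, maxM=2, maxB=1, maxMB=2)
        site = traced(q, text, 9, th2)
        assert site is not None and site.bulges == 1 and site.mismatches == 0

    def test_composite_mismatch_and_both_bulges(self):
        """A site built with one substitution, one deleted guide base and
        one inserted genome base aligns with mc=1, bc=2, edits=3."""
        q = bare_query("ATTGAGATAGTGTGGGGAAG")
        # RNA bulge: guide[3]='G' deleted; DNA bulge: 'C' inserted before
        # guide[9]; mismatch: guide[15] G->C.  Verified via oracle below.
        target = "ATTAGATACGTGTGGCGAAG"
        text = "CC" + target + "CC"
        th = Thresholds(3, 3, 2, 1)
        site = traced(q, text, 2 + len(target), th)
        assert site is not None
        assert (site.mismatches, site.bulges, site.edits) == (1, 2, 3)
        orc = oracle_constrained_alignment(q, text, 2 + len(target), th)
        assert orc == (3, 1, 2)

    def test_replay_counts_and_string_invariants(self, rng):
        """Soundness: aligned strings replay to the reported counts, gaps
        never face gaps, and the query string is recoverable."""
        from offscan.core import recount_alignment

        for _ in range(30):
            q = bare_query(random_dna(rng, rng.randint(5, 12)))
            text = random_dna(rng, 40)
            w = window(text)
            dp = fill_matrix(q, w)
            for h in scan_end_positions(dp, 3):
                site = trace_back(dp, q, w, h.column, Thresholds(3, 3, 3, 3))
                if site is None:
                    continue
                mm, rna, dna = recount_alignment(
                    site.aligned_query, site.aligned_target, q
                )
                assert (mm, rna, dna) == (
                    site.mismatches, site.rna_bulges, site.dna_bulges)
                assert site.aligned_query.replace(GAP, "") == q.search_seq
                assert len(site.aligned_target.replace(GAP, "")) == site.end - site.start

    def test_oracle_equivalence_random(self, rng):
        """Accept/reject and minimum edits match exhaustive enumeration."""
        grids = [Thresholds(4, 4, 4, 4), Thresholds(3, 2, 1, 1),
                 Thresholds(2, 2, 0, 0)]
        checked = 0
        for _ in range(40):
            m = rng.randint(4, 10)
            q = bare_query(random_dna(rng, m))
            text = random_dna(rng, rng.randint(15, 40))
            w = window(text)
            dp = fill_matrix(q, w)
            for th in grids:
                for h in scan_end_positions(dp, th.maxE):
                    site = trace_back(dp, q, w, h.column, th)
                    orc = oracle_constrained_alignment(q, text, h.column, th)
                    checked += 1
                    if site is None:
                        assert orc is None
                    else:
                        assert orc is not None and site.edits == orc[0]
        assert checked > 100

    def test_pruning_is_only_an_optimization(self, rng):
        for _ in range(15):
            q = bare_query(random_dna(rng, 8))
            text = random_dna(rng, 30)
            w = window(text)
            dp = fill_matrix(q, w)
            th = Thresholds(3, 2, 1, 1)
            for h in scan_end_positions(dp, th.maxE):
                a = trace_back(dp, q, w, h.column, th, prune=True)
                b = trace_back(dp, q, w, h.column, th, prune=False)
                assert a == b

    def test_deterministic(self, rng):
        q = bare_query(random_dna(rng, 10))
        text = random_dna(rng, 60)
        w = window(text)
        dp = fill_matrix(q, w)
        for h in scan_end_positions(dp, 4):
            assert trace_back(dp, q, w, h.column, ALL4) == trace_back(
                dp, q, w, h.column, ALL4
            )

    def test_never_accepts_beyond_scan_distance(self, rng):
        """Agreement with step 1: no acceptance at a column whose scan
        distance exceeds maxE."""
        q = bare_query(random_dna(rng, 8))
        text = random_dna(rng, 60)
        w = window(text)
        dp = fill_matrix(q, w)
        th = Thresholds(2, 2, 2, 2)
        for col in range(1, len(text) + 1):
            site = trace_back(dp, q, w, col, th)
            if int(dp.values[q.m][col]) > th.maxE:
                assert site is None


class TestPamPolicy:
    def make(self, target_tail):
        (q,) = compile_queries("ACGTACGTAC", "NGG", ["+"])
        text = "TT" + "ACGTACGTAC" + target_tail + "TT"
        return q, text, 2 + 10 + 3

    def test_matching_pam_protected(self):
        q, text, end = self.make("AGG")
        th = Thresholds(2, 2, 2, 2, allow_pam_edits=False)
        site = traced(q, text, end, th)
        assert site is not None
        assert site.observed_pam == "AGG"
        assert site.mismatches == 0

    def test_pam_mismatch_blocked_without_edits(self):
        q, text, end = self.make("ATG")
        th = Thresholds(2, 2, 2, 2, allow_pam_edits=False)
        assert traced(q, text, end, th) is None

    def test_pam_mismatch_counted_when_allowed(self):
        q, text, end = self.make("ATG")
        th = Thresholds(2, 2, 2, 2, allow_pam_edits=True)
        site = traced(q, text, end, th)
        assert site is not None
        assert site.mismatches == 1
        orc = oracle_constrained_alignment(q, text, end, th)
        assert orc is not None and orc[0] == site.edits

    def test_reverse_strand_pam_protection(self):
        """The reverse query carries its PAM at the start; a CCN prefix on
        the forward text satisfies it."""
        (q,) = compile_queries("ACGTACGTAC", "NGG", ["-"])
        core = "CCT" + "GTACGTACGT"  # revcomp(guide)=GTACGTACGT, revcomp PAM=CCN
        text = "AA" + core + "AA"
        th = Thresholds(1, 1, 1, 1, allow_pam_edits=False)
        site = traced(q, text, 2 + len(core), th)
        assert site is not None
        assert site.strand == "-"
        assert site.observed_pam == "AGG"
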