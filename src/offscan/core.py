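"""Domain types and nucleotide-alphabet logic shared by all search stages.

The search problem: given a guide (sgRNA, typically 20 nt) and a PAM
pattern in IUPAC code (NGG for SpCas9), find every genomic locus whose
guide+PAM alignment stays within an edit-distance budget, with separate
limits on mismatches and bulges.  This module holds the value types
(queries, thresholds, windows, reported sites) and the alphabet rules:

* Genome bases outside A/C/G/T are normalized to N, and a genomic N
  matches *no* query character (it costs a mismatch), so assembly gaps
  never produce spurious sites.
* Query characters may be degenerate IUPAC codes (used for the PAM);
  a query N matches any concrete base but not a genomic N.
* The reverse strand is searched by reverse-complementing the *query*
  (never the genome), so coordinates from both strands live directly on
  the forward strand and are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

FORWARD = "+"
REVERSE = "-"
GAP = "-"

#: concrete genome alphabet after normalization, in encoding order
GENOME_ALPHABET = "ACGTN"
GENOME_CODE = {c: i for i, c in enumerate(GENOME_ALPHABET)}

#: IUPAC degeneracy sets.  Note: these are the sets of *concrete* bases a
#: query code accepts; a genomic N is a member of none of them.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

class _NormalizeTable(dict):
    """Per-character translation: anything unmapped becomes N.  Character
    by character (not str.upper) so the output length always equals the
    input length, even for case-unstable Unicode."""

    def __missing__(self, _ordinal: int) -> str:
        return "N"


_NORMALIZE = _NormalizeTable(
    {ord(c): b for b in "ACGT" for c in (b, b.lower())}
)
_NORMALIZE.update({ord("u"): "T", ord("U"): "T"})


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U to T, and map every other non-ACGT character to N.

    Total function: never raises, always returns a string of the same
    length.  Used for genome text; guide/PAM inputs are validated
    separately because degenerate codes are legal there.
    """
    return raw.translate(_NORMALIZE)


def iupac_match(query_char: str, target_char: str) -> bool:
    """True iff the concrete genome base ``target_char`` satisfies the
    IUPAC code ``query_char``.  A genomic N matches nothing.

    Raises ``ValueError`` for an invalid query code (bad guide/PAM input).
    """
    try:
        accepted = IUPAC_SETS[query_char]
    except KeyError:
        raise ValueError(f"invalid IUPAC code in query: {query_char!r}") from None
    return target_char in accepted


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, B<->V, N<->N, ...)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code: {exc.args[0]!r}") from None


def match_table(search_seq: str) -> np.ndarray:
    """Boolean lookup of shape (m, 5): row i says which encoded genome
    characters (A,C,G,T,N) match query position i.  Column N is always
    False — genomic ambiguity costs a mismatch."""
    table = np.zeros((len(search_seq), len(GENOME_ALPHABET)), dtype=bool)
    for i, q in enumerate(search_seq):
        for b in IUPAC_SETS[q]:  # raises KeyError upstream via validation
            table[i, GENOME_CODE[b]] = True
    return table


def encode_genome(seq: str) -> np.ndarray:
    """Encode a normalized genome string as uint8 codes into GENOME_ALPHABET."""
    buf = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, GENOME_CODE["N"], dtype=np.uint8)
    for c, i in GENOME_CODE.items():
        lut[ord(c)] = i
    return lut[buf]


@dataclass(frozen=True)
class GuideQuery:
    """A compiled search sequence for one strand.

    ``search_seq`` is the string actually aligned against forward-strand
    genome text: guide+PAM for the forward strand, its reverse complement
    for the reverse strand.  ``pam_mask[i]`` is True where position i of
    the search sequence belongs to the PAM.
    """

    guide: str
    pam_pattern: str
    strand: str
    search_seq: str
    pam_mask: tuple[bool, ...]
    name: str = "guide"

    def __post_init__(self) -> None:
        if len(self.search_seq) != len(self.guide) + len(self.pam_pattern):
            raise ValueError("search_seq length must equal guide + PAM length")
        if len(self.pam_mask) != len(self.search_seq):
            raise ValueError("pam_mask length must equal search_seq length")
        if sum(self.pam_mask) != len(self.pam_pattern):
            raise ValueError("pam_mask must mark exactly the PAM positions")

    @property
    def m(self) -> int:
        return len(self.search_seq)


def compile_queries(
    guide: str,
    pam_pattern: str = "NGG",
    strands: Iterable[str] = (FORWARD, REVERSE),
    name: str = "guide",
) -> list[GuideQuery]:
    """Build one :class:`GuideQuery` per requested strand.

    The guide may be given in RNA alphabet (U is normalized to T); the PAM
    is appended 3' of the guide (Cas9 convention).  The reverse-strand
    query is the reverse complement of guide+PAM, with the PAM mask moved
    to the first positions accordingly.
    """
    if not guide:
        raise ValueError("guide must be non-empty")
    guide = guide.upper().replace("U", "T")
    pam_pattern = pam_pattern.upper().replace("U", "T")
    for c in guide + pam_pattern:
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code in query: {c!r}")
    g, p = len(guide), len(pam_pattern)
    queries = []
    for strand in strands:
        if strand == FORWARD:
            seq = guide + pam_pattern
            mask = (False,) * g + (True,) * p
        elif strand == REVERSE:
            seq = reverse_complement(guide + pam_pattern)
            mask = (True,) * p + (False,) * g
        else:
            raise ValueError(f"unknown strand: {strand!r}")
        queries.append(
            GuideQuery(
                guide=guide,
                pam_pattern=pam_pattern,
                strand=strand,
                search_seq=seq,
                pam_mask=mask,
                name=name,
            )
        )
    return queries


@dataclass(frozen=True)
class Thresholds:
    """The four search budgets plus the PAM-edit policy.

    maxE   — total edits (mismatches + bulges) allowed; drives the scan.
    maxM   — mismatches allowed when the alignment has no bulges.
    maxB   — bulges allowed.
    maxMB  — mismatches allowed when the alignment has at least one bulge.
    allow_pam_edits — whether mismatches/bulges may fall in the PAM.
    """

    maxE: int
    maxM: int
    maxB: int
    maxMB: int
    allow_pam_edits: bool = False

    def __post_init__(self) -> None:
        for fname in ("maxE", "maxM", "maxB", "maxMB"):
            v = getattr(self, fname)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{fname} must be a non-negative integer")
        for fname in ("maxM", "maxB", "maxMB"):
            if getattr(self, fname) > self.maxE:
                raise ValueError(f"{fname} must not exceed maxE")

    def mismatch_limit(self, bulge_count: int) -> int:
        """The mismatch bound in force given the current bulge count."""
        return self.maxM if bulge_count == 0 else self.maxMB


@dataclass(frozen=True)
class GenomeWindow:
    """One overlapping slice of a chromosome, already normalized."""

    chrom: str
    offset: int  # 0-based forward-strand start
    seq: str
    is_terminal: bool = False

    @property
    def n(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SiteKey:
    """Site identity: the (chromosome, strand, end position) triplet."""

    chrom: str
    strand: str
    end: int


@dataclass(frozen=True)
class SiteAlignment:
    """One reported off-target site with its minimum-edit alignment.

    Coordinates are 0-based half-open on the forward strand for both
    strands.  ``aligned_query`` is the search-orientation query with '-'
    gaps (a gap here is a DNA bulge: an unpaired genome base);
    ``aligned_target`` is the genome slice with '-' gaps (a gap here is an
    RNA bulge: an unpaired guide base).
    """

    chrom: str
    strand: str
    start: int
    end: int
    aligned_query: str
    aligned_target: str
    mismatches: int
    rna_bulges: int
    dna_bulges: int
    observed_pam: str
    guide_name: str = "guide"

    @property
    def bulges(self) -> int:
        return self.rna_bulges + self.dna_bulges

    @property
    def edits(self) -> int:
        return self.mismatches + self.bulges

    @property
    def key(self) -> SiteKey:
        return SiteKey(self.chrom, self.strand, self.end)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("aligned strings must have equal length")
        if any(
            a == GAP and b == GAP
            for a, b in zip(self.aligned_query, self.aligned_target)
        ):
            raise ValueError("a column cannot be a gap in both strings")
        target_len = sum(c != GAP for c in self.aligned_target)
        if self.end - self.start != target_len:
            raise ValueError("coordinates inconsistent with aligned target")


def recount_alignment(
    aligned_query: str, aligned_target: str, query: GuideQuery
) -> tuple[int, int, int]:
    """Recount (mismatches, rna_bulges, dna_bulges) column by column from
    the aligned strings — the replay used by soundness checks."""
    mm = rna = dna = 0
    for a, b in zip(aligned_query, aligned_target):
        if a == GAP:
            dna += 1
        elif b == GAP:
            rna += 1
        elif not iupac_match(a, b):
            mm += 1
    return mm, rna, dna
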