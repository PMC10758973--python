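"""Synthetic genomes with planted ground truth, and brute-force oracles.

Two independent reference implementations define correctness for the two
search stages:

* :func:`oracle_end_positions` — the end-position set of the scan stage,
  computed by a textbook start-anchored Levenshtein DP per start position
  (no free-prefix boundary, no code shared with the vectorized scan).
  Substring lengths are capped at m + maxE, which cannot change any
  distance <= maxE because longer substrings cost more than maxE by the
  length difference alone.
* :func:`oracle_constrained_alignment` — exhaustive enumeration of every
  monotone alignment path ending at a given column (no memoization, no
  matrix pruning), applying exactly the per-step threshold and PAM
  semantics of the trace-back stage.

The generator plants mutated guide+PAM copies into random background
sequence with a recorded edit script.  Planted edits are spaced at least
2 bp apart (and inserted bases differ from their neighbours) so the
minimum-edit interpretation of each planted site is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import (
    IUPAC_SETS,
    GuideQuery,
    Thresholds,
    iupac_match,
    normalize_sequence,
    reverse_complement,
)

BASES = "ACGT"


def generate_genome(length: int, gc_fraction: float = 0.41, seed: int = 0) -> str:
    """Reproducible i.i.d. background sequence at the given GC content.

    The default GC fraction of 0.41 mirrors the human genome average.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return "".join(rng.choice(list(BASES), size=length, p=[at, gc, gc, at]))


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted off-target copy.

    ``edit_script`` records, per edited guide position, the operation:
    ("mm", pos, new_base), ("rna", pos) for a deleted guide base, or
    ("dna", pos, inserted_base) for an extra genome base placed before
    guide position pos.  Coordinates are forward-strand, 0-based
    half-open, so (chrom, strand, end) is the site's identity triplet.
    """

    chrom: str
    strand: str
    start: int
    end: int
    mismatches_planted: int
    rna_bulges_planted: int
    dna_bulges_planted: int
    mutated_target: str
    edit_script: tuple = ()

    @property
    def edits_planted(self) -> int:
        return (
            self.mismatches_planted
            + self.rna_bulges_planted
            + self.dna_bulges_planted
        )


def _build_target(
    guide: str,
    pam_concrete: str,
    ops: dict[int, tuple],
    rng: np.random.Generator,
) -> str:
    """Apply the edit operations (keyed by guide position) left to right."""
    out: list[str] = []
    for pos, base in enumerate(guide):
        op = ops.get(pos)
        if op is None:
            out.append(base)
        elif op[0] == "mm":
            out.append(op[2])
        elif op[0] == "rna":
            pass  # guide base unpaired: absent from the genome copy
        elif op[0] == "dna":
            out.append(op[2])
            out.append(base)
    return "".join(out) + pam_concrete


def plant_site(
    genome: str,
    guide: str,
    pam_pattern: str,
    n_mm: int,
    n_rna_bulge: int,
    n_dna_bulge: int,
    position: int,
    strand: str = "+",
    seed: int = 0,
    chrom: str = "chr_synth",
    edit_positions: list[int] | None = None,
) -> tuple[str, PlantedSite]:
    """Overwrite ``genome[position:...]`` with a mutated guide+PAM copy.

    Substitutions and bulges fall only in the guide region (positions
    1..len(guide)-2, pairwise >= 2 apart); the PAM is written as a concrete
    match of the pattern.  For strand '-', the reverse complement of the
    mutated copy is written, so the planted (chrom, strand, end) triplet is
    expressed in forward coordinates like every search result.
    """
    rng = np.random.default_rng(seed)
    guide = normalize_sequence(guide)
    g = len(guide)
    n_edits = n_mm + n_rna_bulge + n_dna_bulge
    if edit_positions is None:
        candidates = list(range(1, g - 1))
        rng.shuffle(candidates)
        chosen: list[int] = []
        for c in candidates:
            if all(abs(c - x) >= 2 for x in chosen):
                chosen.append(c)
            if len(chosen) == n_edits:
                break
        if len(chosen) < n_edits:
            raise ValueError("guide too short for the requested edits")
        edit_positions = sorted(chosen)
    elif len(edit_positions) != n_edits:
        raise ValueError("edit_positions must match the requested edit count")

    labels = ["mm"] * n_mm + ["rna"] * n_rna_bulge + ["dna"] * n_dna_bulge
    rng.shuffle(labels)
    ops: dict[int, tuple] = {}
    prev_base = None
    for pos, label in zip(sorted(edit_positions), labels):
        if label == "mm":
            choices = [b for b in BASES if b != guide[pos]]
            ops[pos] = ("mm", pos, str(rng.choice(choices)))
        elif label == "rna":
            ops[pos] = ("rna", pos)
        else:
            # inserted base must differ from both neighbours so the bulge
            # cannot slide and merge with a flanking match
            avoid = {guide[pos], guide[pos - 1]}
            choices = [b for b in BASES if b not in avoid]
            ops[pos] = ("dna", pos, str(rng.choice(choices)))

    pam_concrete = "".join(
        str(rng.choice(sorted(IUPAC_SETS[c]))) for c in pam_pattern.upper()
    )
    target = _build_target(guide, pam_concrete, ops, rng)
    inserted = reverse_complement(target) if strand == "-" else target
    end = position + len(inserted)
    if position < 0 or end > len(genome):
        raise ValueError("planted site does not fit in the genome")
    genome2 = genome[:position] + inserted + genome[end:]
    site = PlantedSite(
        chrom=chrom,
        strand=strand,
        start=position,
        end=end,
        mismatches_planted=n_mm,
        rna_bulges_planted=n_rna_bulge,
        dna_bulges_planted=n_dna_bulge,
        mutated_target=target,
        edit_script=tuple(ops[p] for p in sorted(ops)),
    )
    return genome2, site


def planted_genome(
    length: int,
    guide: str,
    pam_pattern: str,
    compositions: list[tuple[int, int, int, str]],
    seed: int = 0,
    chrom: str = "chr_synth",
    gc_fraction: float = 0.41,
) -> tuple[str, list[PlantedSite]]:
    """Generate a background genome and plant one site per composition
    (n_mm, n_rna, n_dna, strand) at evenly spread, non-overlapping
    positions.  Returns the final sequence and the ground-truth list."""
    rng = np.random.default_rng(seed)
    genome = generate_genome(length, gc_fraction, seed=int(rng.integers(2**31)))
    k = len(compositions)
    site_room = len(guide) + len(pam_pattern) + 8
    if k * (site_room + 20) > length:
        raise ValueError("genome too short for the requested sites")
    slot = length // k
    sites: list[PlantedSite] = []
    for idx, (n_mm, n_rna, n_dna, strand) in enumerate(compositions):
        pos = idx * slot + int(rng.integers(0, slot - site_room))
        genome, site = plant_site(
            genome, guide, pam_pattern, n_mm, n_rna, n_dna,
            position=pos, strand=strand, chrom=chrom,
            seed=int(rng.integers(2**31)),
        )
        sites.append(site)
    return genome, sites


def write_fixture(
    path_fasta: str | Path,
    path_manifest: str | Path,
    genome: str,
    sites: list[PlantedSite],
    chrom: str = "chr_synth",
) -> None:
    """Write a fixture FASTA plus a JSON manifest of every planted script."""
    with open(path_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")
    with open(path_manifest, "w") as fh:
        json.dump([asdict(s) for s in sites], fh, indent=1)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_end_positions(
    query: str, text: str, maxE: int
) -> set[tuple[int, int]]:
    """All (end column, distance) pairs with distance <= maxE, where the
    distance at column j is min over starts s <= j of Levenshtein(query,
    text[s:j]) — one textbook start-anchored DP per start position."""
    m, n = len(query), len(text)
    accept = [IUPAC_SETS[q] for q in query]
    best: dict[int, int] = {}
    cap = m + maxE
    for s in range(n + 1):
        v = list(range(m + 1))  # Lev(query[:i], "")
        if v[m] <= maxE:
            j = s
            if j >= 1 and v[m] < best.get(j, maxE + 1):
                best[j] = v[m]
        for l in range(1, min(n - s, cap) + 1):
            c = text[s + l - 1]
            new = [l] + [0] * m
            for i in range(1, m + 1):
                cost = 0 if c in accept[i - 1] else 1
                new[i] = min(v[i - 1] + cost, new[i - 1] + 1, v[i] + 1)
            v = new
            if v[m] <= maxE:
                j = s + l
                if v[m] < best.get(j, maxE + 1):
                    best[j] = v[m]
    return {(j, d) for j, d in best.items()}


def oracle_constrained_alignment(
    query: GuideQuery, text: str, end_column: int, th: Thresholds
) -> tuple[int, int, int] | None:
    """Exhaustively enumerate every monotone alignment path that ends at
    ``end_column`` and consumes the whole query; apply the per-step
    threshold semantics and PAM policy of the trace-back stage; return
    (min edits, mc, bc) of the best feasible path (ties resolved toward
    fewer bulges) or None.  No memoization, no matrix pruning."""
    a = query.search_seq
    pam_mask = query.pam_mask
    m = query.m
    results: list[tuple[int, int, int]] = []

    def walk(i: int, j: int, mc: int, bc: int) -> None:
        if bc > th.maxB or mc > th.mismatch_limit(bc) or mc + bc > th.maxE:
            return
        if i == 0:
            results.append((mc + bc, mc, bc))
            return
        if j == 0:
            return
        protected = not th.allow_pam_edits and pam_mask[i - 1]
        match = iupac_match(a[i - 1], text[j - 1])
        if not protected:
            walk(i - 1, j - 1, mc + (0 if match else 1), bc)
            walk(i - 1, j, mc, bc + 1)
            walk(i, j - 1, mc, bc + 1)
        elif match:
            walk(i - 1, j - 1, mc, bc)

    walk(m, end_column, 0, 0)
    if not results:
        return None
    edits, mc, bc = min(results, key=lambda r: (r[0], r[2]))
    return edits, mc, bc
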