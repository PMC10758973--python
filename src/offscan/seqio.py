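"""File formats: FASTA input, TSV site tables, BED6 export.

TSV is the primary output because it carries the aligned strings and the
per-operation counts losslessly; BED6 is provided for genome browsers.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .core import SiteAlignment, normalize_sequence

SITE_COLUMNS = [
    "chrom", "strand", "start", "end", "aligned_query", "aligned_target",
    "mismatches", "rna_bulges", "dna_bulges", "bulges", "edits",
    "observed_pam", "guide_name",
]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (name, normalized sequence) records from a plain or
    gzip-compressed FASTA file.  The record name is the first whitespace
    token of the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        first = handle.read(1)
        if first not in (">", ""):
            raise ValueError(f"malformed FASTA (no '>' at start): {path}")
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            yield header.split()[0] if header.split() else header, normalize_sequence(seq)


def sites_to_frame(sites: Iterable[SiteAlignment]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.chrom, "strand": s.strand, "start": s.start, "end": s.end,
            "aligned_query": s.aligned_query, "aligned_target": s.aligned_target,
            "mismatches": s.mismatches, "rna_bulges": s.rna_bulges,
            "dna_bulges": s.dna_bulges, "bulges": s.bulges, "edits": s.edits,
            "observed_pam": s.observed_pam, "guide_name": s.guide_name,
        }
        for s in sites
    ]
    frame = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return frame.sort_values(
        ["chrom", "end", "strand", "start", "guide_name"], kind="stable"
    ).reset_index(drop=True)


def write_sites(sites: Iterable[SiteAlignment], path: str | Path) -> None:
    """Write the site table as TSV, ordered by (chrom, end, strand)."""
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[SiteAlignment]:
    """Parse a TSV written by :func:`write_sites` back into alignments
    (exact inverse for the fields a SiteAlignment owns)."""
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"observed_pam": str, "aligned_query": str, "aligned_target": str},
        keep_default_na=False,
    )
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            SiteAlignment(
                chrom=str(row.chrom), strand=row.strand,
                start=int(row.start), end=int(row.end),
                aligned_query=row.aligned_query, aligned_target=row.aligned_target,
                mismatches=int(row.mismatches), rna_bulges=int(row.rna_bulges),
                dna_bulges=int(row.dna_bulges), observed_pam=str(row.observed_pam),
                guide_name=str(row.guide_name),
            )
        )
    return out


def write_bed(sites: Iterable[SiteAlignment], path: str | Path) -> None:
    """BED6 export: chrom, start, end, name=guide, score=edits, strand."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.start, s.end, s.strand)):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.guide_name}\t{s.edits}\t{s.strand}\n"
            )
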