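"""Whole-genome orchestration: windowing, per-window search, dedup.

The genome is read once and cut per chromosome into overlapping windows;
the reverse strand is handled by reverse-complemented queries, never by
complementing the genome.  The overlap is at least m + maxE - 1 so that
no alignment can straddle a window boundary without lying wholly inside
one window.  To make the output exactly independent of the window length
and of the thread count, each end position is *owned* by exactly one
window: the first window of a chromosome reports every end it finds,
every later window only ends beyond its overlap region.  Deduplication
across windows is kept as a safety net on top of that rule.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

from .core import FORWARD, REVERSE, GenomeWindow, GuideQuery, SiteAlignment, Thresholds
from .scan import fill_matrix, scan_end_positions
from .trace import trace_back

DEFAULT_WINDOW_LENGTH = 1_000_000


@dataclass(frozen=True)
class SearchConfig:
    """Engineering knobs; none of them may change the result set (except
    ``best_in_window``, which is an explicit output filter)."""

    window_length: int = DEFAULT_WINDOW_LENGTH
    overlap: int | None = None  # default: m + maxE (one above the minimum)
    threads: int = 1
    strands: frozenset[str] = frozenset((FORWARD, REVERSE))
    best_in_window: int | None = None

    def resolved_overlap(self, queries: Sequence[GuideQuery], th: Thresholds) -> int:
        if self.overlap is not None:
            return self.overlap
        return max(q.m for q in queries) + th.maxE

    def validate(self, queries: Sequence[GuideQuery], th: Thresholds) -> None:
        ov = self.resolved_overlap(queries, th)
        need = max(q.m for q in queries) + th.maxE - 1
        if ov < need:
            raise ValueError(f"overlap {ov} < m + maxE - 1 = {need}")
        if self.window_length <= ov:
            raise ValueError("window_length must exceed the overlap")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


def partition_genome(
    records: Iterable[tuple[str, str]],
    window_length: int,
    overlap: int,
) -> Iterator[GenomeWindow]:
    """Cut each (name, normalized sequence) record into windows starting at
    0, L-ov, 2(L-ov), ...; the last window is truncated.  Every interval
    of length <= overlap + 1 lies wholly inside at least one window."""
    if window_length <= overlap:
        raise ValueError("window_length must exceed the overlap")
    step = window_length - overlap
    for name, seq in records:
        length = len(seq)
        if length == 0:
            logging.getLogger(__name__).warning("skipping empty record %s", name)
            continue
        offset = 0
        while True:
            end = min(offset + window_length, length)
            terminal = end == length
            yield GenomeWindow(chrom=name, offset=offset, seq=seq[offset:end],
                               is_terminal=terminal)
            if terminal:
                break
            offset += step


def search_window(
    window: GenomeWindow,
    queries: Sequence[GuideQuery],
    th: Thresholds,
) -> list[SiteAlignment]:
    """Scan one window with every query: matrix fill, end-position scan at
    maxE, trace-back per hit; survivors lifted to global coordinates."""
    out: list[SiteAlignment] = []
    for query in queries:
        dp = fill_matrix(query, window)
        memo: dict = {}
        for hit in scan_end_positions(dp, th.maxE):
            site = trace_back(dp, query, window, hit.column, th, _memo=memo)
            if site is not None:
                out.append(
                    replace(site, start=site.start + window.offset,
                            end=site.end + window.offset)
                )
    return out


def _sort_key(s: SiteAlignment):
    return (s.chrom, s.end, s.strand, s.start, s.guide_name)


def search_genome(
    records: Iterable[tuple[str, str]],
    queries: Sequence[GuideQuery],
    th: Thresholds,
    cfg: SearchConfig | None = None,
) -> list[SiteAlignment]:
    """Search every window on every requested strand and return the
    deduplicated site list ordered by (chrom, end, strand).

    The result is invariant to ``cfg.threads`` and to ``cfg.window_length``
    (given a valid overlap).
    """
    cfg = cfg or SearchConfig()
    queries = [q for q in queries if q.strand in cfg.strands]
    if not queries:
        raise ValueError("no queries for the requested strands")
    cfg.validate(queries, th)
    overlap = cfg.resolved_overlap(queries, th)

    windows = list(partition_genome(records, cfg.window_length, overlap))

    def owned_sites(window: GenomeWindow) -> list[SiteAlignment]:
        floor = window.offset + overlap  # ends <= floor belong to a prior window
        return [
            s
            for s in search_window(window, queries, th)
            if window.offset == 0 or s.end > floor
        ]

    if cfg.threads == 1 or len(windows) <= 1:
        per_window = [owned_sites(w) for w in windows]
    else:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            per_window = list(pool.map(owned_sites, windows))

    seen: set = set()
    sites: list[SiteAlignment] = []
    for group in per_window:
        for s in group:
            dk = (s.guide_name, s.chrom, s.strand, s.end, s.aligned_query,
                  s.aligned_target)
            if dk not in seen:
                seen.add(dk)
                sites.append(s)
    sites.sort(key=_sort_key)

    if cfg.best_in_window is not None:
        from .accounting import best_in_window

        sites = best_in_window(sites, cfg.best_in_window)
    return sites
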