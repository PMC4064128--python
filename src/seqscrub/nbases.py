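"""Handling of un-called 'N' bases: filter by percentage or count, or split
the read around N-runs.

N bases usually carry very low quality scores, and De Bruijn graph
assemblers either discard reads containing them or silently replace them
with an arbitrary nucleotide.  Splitting excises every N-run of length >= l
and salvages the flanking segments as daughter reads instead of discarding
the whole read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

from .core import Read, TrimOutcome


@dataclass(frozen=True)
class NSpec:
    """Parameters for the three N-base methods: percentage cutoff ``p``
    (nperc), count cutoff ``n`` (ncutoff), minimum N-run length ``l``
    (nsplit).  Only the field the chosen method uses need be set."""

    p: Optional[float] = None
    n: Optional[int] = None
    l: Optional[int] = None

    def __post_init__(self) -> None:
        if self.p is not None and not 0 < self.p <= 100:
            raise ValueError("percentage cutoff p must be in (0, 100]")
        if self.n is not None and self.n < 1:
            raise ValueError("count cutoff n must be >= 1")
        if self.l is not None and self.l < 1:
            raise ValueError("minimum N-run length l must be >= 1")


def filter_n_percent(read: Read, p: float) -> TrimOutcome:
    """Remove the read when its N percentage is >= p (inclusive boundary)."""
    if len(read) == 0:
        raise ValueError("filter_n_percent requires a non-empty read")
    if 100.0 * read.seq.count("N") / len(read) >= p:
        return TrimOutcome.removed(read)
    return TrimOutcome.kept(read)


def filter_n_count(read: Read, n: int) -> TrimOutcome:
    """Remove the read when it contains >= n N bases; n=1 is the classic
    drop-any-read-with-an-N filter."""
    if len(read) == 0:
        raise ValueError("filter_n_count requires a non-empty read")
    if read.seq.count("N") >= n:
        return TrimOutcome.removed(read)
    return TrimOutcome.kept(read)


def split_on_n(read: Read, l: int) -> TrimOutcome:
    """Excise every maximal N-run of length >= l and emit the intervening
    segments as daughter reads (ids suffixed /s1, /s2, ... 5'->3').

    Shorter N-runs are left in place.  Empty segments are dropped; with no
    qualifying run the read is kept untouched, and with no surviving
    daughter it is removed.
    """
    if len(read) == 0:
        raise ValueError("split_on_n requires a non-empty read")
    runs = [m.span() for m in re.finditer(f"N{{{l},}}", read.seq)]
    if not runs:
        return TrimOutcome.kept(read)
    daughters: list[Read] = []
    prev = 0
    segments: list[tuple[int, int]] = []
    for start, end in runs:
        if start > prev:
            segments.append((prev, start))
        prev = end
    if prev < len(read):
        segments.append((prev, len(read)))
    for k, (s, e) in enumerate(segments, start=1):
        daughters.append(
            replace(read, id=f"{read.id}/s{k}", seq=read.seq[s:e], qual=read.qual[s:e])
        )
    kept_bases = sum(len(d) for d in daughters)
    return TrimOutcome.split(daughters, len(read) - kept_bases)
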