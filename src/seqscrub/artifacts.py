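"""Sequencing-artifact (adapter/primer/linker) detection and removal, and
homopolymer-run removal.

Detection is approximate matching under unit-cost Levenshtein edit distance:
the artifact must align *in full* inside the read (semi-global alignment,
free read ends), with the alignment start constrained to the first
``search_depth`` bases.  The edit budget comes either from a match
percentage ``mp`` (budget = floor(len(artifact) * (1 - mp/100)), flooring
toward stringency) or from explicit per-edit-type caps on insertions,
substitutions and deletions; when any per-type cap is given the caps replace
the percentage budget and unset caps default to 0.

The best match is the lowest edit distance, tie-broken by smallest start,
then longest artifact, then library order — a fixed rule so results are
deterministic and independent of search internals.

The uncapped matcher computes, in one O(len(artifact) x len(read)) pass per
library entry, the best distance achievable from *every* start position:
running the standard free-start semi-global recurrence over the reversed
strings turns "free end at the right" into "free start at the left", so row
m of that DP holds min_e dist(artifact, read[s:e]) for all s at once.  Rows
are vectorised with numpy; the horizontal (+1 per step) dependency is folded
into a running minimum of (cell - column index).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core import Read, TrimOutcome

# Common Illumina adapter / primer / transposase sequences (public
# catalogue); user libraries replace or extend this list.
BUILTIN_ADAPTERS: tuple[tuple[str, str], ...] = (
    ("Illumina_Single_End_Adapter_1", "GATCGGAAGAGCTCGTATGCCGTCTTCTGCTTG"),
    ("Illumina_Single_End_PCR_Primer_1", "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"),
    ("Illumina_Paired_End_Adapter_1", "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"),
    ("Illumina_Paired_End_Adapter_2", "GATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"),
    ("Illumina_Paired_End_PCR_Primer_2", "CAAGCAGAAGACGGCATACGAGATCGGTCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT"),
    ("TruSeq_Adapter_Index_Prefix", "GATCGGAAGAGCACACGTCTGAACTCCAGTCAC"),
    ("Nextera_Transposase_Adapter_R1", "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"),
    ("Nextera_Transposase_Adapter_R2", "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"),
)

_VALID_ARTIFACT = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class ArtifactLibrary:
    """Ordered adapter/primer library; order matters for tie-breaking."""

    entries: tuple[tuple[str, str], ...]
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("artifact library must not be empty")
        for name, seq in self.entries:
            if not _VALID_ARTIFACT.match(seq):
                raise ValueError(f"artifact {name!r}: sequence must be non-empty over ACGT")

    @staticmethod
    def builtin() -> "ArtifactLibrary":
        return ArtifactLibrary(BUILTIN_ADAPTERS, source="built-in")

    @staticmethod
    def from_sequences(seqs: Iterable[str], names: Optional[Iterable[str]] = None) -> "ArtifactLibrary":
        seqs = [s.upper() for s in seqs]
        if names is None:
            names = [f"artifact_{i + 1}" for i in range(len(seqs))]
        return ArtifactLibrary(tuple(zip(names, seqs)))

    @staticmethod
    def from_file(path: str | PathLike) -> "ArtifactLibrary":
        """Load a FASTA file or a plain one-sequence-per-line list."""
        with open(path) as fh:
            text = fh.read()
        if text.lstrip().startswith(">"):
            from Bio import SeqIO
            from io import StringIO

            records = list(SeqIO.parse(StringIO(text), "fasta"))
            return ArtifactLibrary(tuple((r.id, str(r.seq).upper()) for r in records))
        lines = [l.strip().upper() for l in text.splitlines() if l.strip()]
        return ArtifactLibrary.from_sequences(lines)


@dataclass(frozen=True)
class MatchSpec:
    """Approximate-match policy for artifact detection.

    ``mp`` is the match percentage in (0, 100]; ``search_depth`` bounds the
    alignment *start* (0-based, exclusive upper bound); ``action`` is what
    to do with a matched read: ``kr`` removes it, ``ka`` keeps the bases 5'
    of the match.
    """

    mp: float = 100.0
    max_ins: Optional[int] = None
    max_sub: Optional[int] = None
    max_del: Optional[int] = None
    search_depth: int = 50
    action: Literal["kr", "ka"] = "ka"

    def __post_init__(self) -> None:
        if not 0 < self.mp <= 100:
            raise ValueError(f"mp must be in (0, 100], got {self.mp}")
        if self.search_depth < 1:
            raise ValueError("search_depth must be >= 1")
        if self.action not in ("kr", "ka"):
            raise ValueError(f"action must be 'kr' or 'ka', got {self.action!r}")

    @property
    def capped(self) -> bool:
        return any(c is not None for c in (self.max_ins, self.max_sub, self.max_del))

    def caps(self) -> tuple[int, int, int]:
        """(max_ins, max_sub, max_del), unset caps defaulting to 0."""
        return (self.max_ins or 0, self.max_sub or 0, self.max_del or 0)

    def budget(self, artifact_len: int) -> int:
        if self.capped:
            return sum(self.caps())
        return int(artifact_len * (1.0 - self.mp / 100.0))


@dataclass(frozen=True)
class MatchResult:
    """Best artifact hit: 0-based half-open interval on the read."""

    artifact_name: str
    start: int
    end: int
    distance: int


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)


def _start_distances(art: np.ndarray, read: np.ndarray) -> np.ndarray:
    """G[s] = min over e >= s of levenshtein(artifact, read[s:e]), for all s.

    Computed as the free-start semi-global DP over the reversed strings;
    see the module docstring for the derivation.
    """
    a = art[::-1]
    r = read[::-1]
    L = len(r)
    j = np.arange(L + 1, dtype=np.int32)
    row = np.zeros(L + 1, dtype=np.int32)
    for i in range(1, len(a) + 1):
        cost = (a[i - 1] != r).astype(np.int32)
        e = np.empty(L + 1, dtype=np.int32)
        e[0] = i
        np.minimum(row[:-1] + cost, row[1:] + 1, out=e[1:])
        # fold in horizontal moves: row[j] = min_{j'<=j} e[j'] + (j - j')
        row = np.minimum.accumulate(e - j) + j
    return row[::-1]  # index s = L - j


def _prefix_distances(art: np.ndarray, segment: np.ndarray) -> np.ndarray:
    """D[e] = levenshtein(artifact, segment[:e]) for e = 0..len(segment)."""
    m, n = len(art), len(segment)
    idx = np.arange(n + 1, dtype=np.int32)
    row = idx.copy()
    for i in range(1, m + 1):
        cost = (art[i - 1] != segment).astype(np.int32)
        e = np.empty(n + 1, dtype=np.int32)
        e[0] = i
        np.minimum(row[:-1] + cost, row[1:] + 1, out=e[1:])
        row = np.minimum.accumulate(e - idx) + idx
    return row


def _capped_feasible(art: str, seg: str, caps: tuple[int, int, int]) -> Optional[int]:
    """Min total edits aligning ``art`` to all of ``seg`` under per-type caps.

    Cell state is the Pareto-minimal set of (ins, sub, del) counts;
    insertions are read bases absent from the artifact, deletions artifact
    bases absent from the read.  Returns None when no alignment satisfies
    the caps.  Intended for short artifacts/segments (caps are small).
    """
    ci, cs, cd = caps
    m, n = len(art), len(seg)

    def prune(cands: set[tuple[int, int, int]]) -> frozenset:
        out = set()
        for c in cands:
            if any(d != c and d[0] <= c[0] and d[1] <= c[1] and d[2] <= c[2] for d in cands):
                continue
            out.add(c)
        return frozenset(out)

    prev: list[frozenset] = [frozenset()] * (n + 1)
    prev[0] = frozenset({(0, 0, 0)})
    for j in range(1, n + 1):
        if j <= ci:
            prev[j] = frozenset({(j, 0, 0)})
    for i in range(1, m + 1):
        cur: list[frozenset] = [frozenset()] * (n + 1)
        if i <= cd:
            cur[0] = frozenset({(0, 0, i)})
        for j in range(1, n + 1):
            cands: set[tuple[int, int, int]] = set()
            match = art[i - 1] == seg[j - 1]
            for ni, ns, nd in prev[j - 1]:
                if match:
                    cands.add((ni, ns, nd))
                elif ns < cs:
                    cands.add((ni, ns + 1, nd))
            for ni, ns, nd in prev[j]:  # delete artifact base
                if nd < cd:
                    cands.add((ni, ns, nd + 1))
            for ni, ns, nd in cur[j - 1]:  # insert read base
                if ni < ci:
                    cands.add((ni + 1, ns, nd))
            cur[j] = prune(cands)
        prev = cur
    if not prev[n]:
        return None
    return min(sum(t) for t in prev[n])


def _find_capped(read: Read, lib: ArtifactLibrary, spec: MatchSpec) -> Optional[MatchResult]:
    ci, cs, cd = spec.caps()
    L = len(read)
    best: Optional[tuple[int, int, int, int, str]] = None  # dist, start, -alen, order, name; end separate
    best_end = -1
    for order, (name, art) in enumerate(lib.entries):
        m = len(art)
        for s in range(min(spec.search_depth, L)):
            for e in range(s + max(1, m - cd), min(L, s + m + ci) + 1):
                d = _capped_feasible(art, read.seq[s:e], (ci, cs, cd))
                if d is None:
                    continue
                # e ascends, so the first occurrence of a winning key
                # already carries the smallest end for that (dist, start)
                key = (d, s, -m, order, name)
                if best is None or key < best:
                    best, best_end = key, e
    if best is None:
        return None
    return MatchResult(artifact_name=best[4], start=best[1], end=best_end, distance=best[0])


def find_artifact(read: Read, lib: ArtifactLibrary, spec: MatchSpec) -> Optional[MatchResult]:
    """Best artifact match starting within ``spec.search_depth`` bases, or None.

    Matching is case-insensitive; 'N' in the read mismatches every artifact
    base.  The artifact must be contained in full (overhang past the read's
    3' end is not matched).
    """
    if len(read) == 0:
        raise ValueError("find_artifact requires a non-empty read")
    if spec.capped:
        return _find_capped(read, lib, spec)
    rcodes = _codes(read.seq)
    L = len(read)
    depth = min(spec.search_depth, L)
    best: Optional[tuple[int, int, int, int]] = None  # dist, start, -alen, order
    best_art: Optional[str] = None
    best_name = ""
    for order, (name, art) in enumerate(lib.entries):
        k = spec.budget(len(art))
        g = _start_distances(_codes(art), rcodes)[:depth]
        smin = int(g.argmin())
        if g[smin] > k:
            continue
        # smallest start among starts achieving the entry's best distance
        s = int(np.flatnonzero(g == g[smin])[0])
        key = (int(g[smin]), s, -len(art), order)
        if best is None or key < best:
            best, best_art, best_name = key, art, name
    if best is None:
        return None
    dist, start, neg_alen, _ = best
    m = -neg_alen
    # recover the smallest end attaining the winning distance
    seg = rcodes[start : min(L, start + m + dist)]
    d = _prefix_distances(_codes(best_art), seg)
    end_off = int(np.flatnonzero(d == dist)[0])
    return MatchResult(artifact_name=best_name, start=start, end=start + end_off, distance=dist)


def apply_5adpt(read: Read, lib: ArtifactLibrary, spec: MatchSpec) -> TrimOutcome:
    """Remove a detected 5' artifact: ``kr`` drops the read, ``ka`` keeps the
    bases 5' of the match (removal if the match starts at base 0)."""
    hit = find_artifact(read, lib, spec)
    if hit is None:
        return TrimOutcome.kept(read)
    if spec.action == "kr" or hit.start == 0:
        return TrimOutcome.removed(read)
    survivor = read.prefix(hit.start)
    return TrimOutcome.trimmed(survivor, len(read) - hit.start)


@dataclass(frozen=True)
class HomopolymerSpec:
    """Minimum run length ``h`` and the set of bases eligible to form runs."""

    h: int
    b: frozenset[str] = frozenset("ACGT")

    def __post_init__(self) -> None:
        if self.h < 2:
            raise ValueError("homopolymer minimum length h must be >= 2")
        if not self.b or not set(self.b) <= set("ACGT"):
            raise ValueError("homopolymer base set must be a non-empty subset of ACGT")


def remove_homopolymer(read: Read, spec: HomopolymerSpec) -> TrimOutcome:
    """Excise the 5'-most homopolymer run of length >= h (bases in ``b``)
    together with everything 3' of it."""
    if len(read) == 0:
        raise ValueError("remove_homopolymer requires a non-empty read")
    pattern = "|".join(f"{base}{{{spec.h},}}" for base in sorted(spec.b))
    m = re.search(pattern, read.seq)
    if m is None:
        return TrimOutcome.kept(read)
    if m.start() == 0:
        return TrimOutcome.removed(read)
    return TrimOutcome.trimmed(read.prefix(m.start()), len(read) - m.start())
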