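"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (substring
enumeration + edlib global edit distance, direct per-suffix summation,
regex splitting) so they share no code path with the implementation they
check.
"""

from __future__ import annotations

import math
import re
from typing import Optional

import edlib
import numpy as np
import pytest
from hypothesis import settings

from seqscrub import Read

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


def mk(seq: str, qual=None, rid: str = "r", **kw) -> Read:
    """Terse read factory; default quality Q30 everywhere."""
    if qual is None:
        qual = [30] * len(seq)
    elif isinstance(qual, int):
        qual = [qual] * len(seq)
    return Read(id=rid, seq=seq, qual=list(qual), **kw)


def levenshtein(a: str, b: str) -> int:
    """Global edit distance via edlib (independent of the package's DP)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def oracle_find_artifact(
    seq: str,
    entries,
    mp: float,
    search_depth: int,
) -> Optional[tuple[str, int, int, int]]:
    """Exhaustive all-substring matcher oracle.

    Enumerates every substring whose start lies in [0, search_depth),
    scores it against every library entry with full global edit distance,
    and applies the documented budget and tie-break rules (distance, then
    start, then longest artifact, then library order; smallest end among
    equals).  Returns (name, start, end, distance) or None.
    """
    L = len(seq)
    best_key = None
    best = None
    for order, (name, art) in enumerate(entries):
        m = len(art)
        budget = math.floor(m * (1.0 - mp / 100.0))
        for s in range(min(search_depth, L)):
            for e in range(s + 1, L + 1):
                if not (m - budget <= e - s <= m + budget):
                    continue  # distance necessarily exceeds the budget
                d = levenshtein(art, seq[s:e])
                if d > budget:
                    continue
                key = (d, s, -m, order, e)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (name, s, e, d)
    return best


def oracle_mott(qual: list[int], ml: float) -> Optional[tuple[int, int]]:
    """Mott window by direct per-index summation: for each base i compute
    S(i) = sum_{j>=i} (ml - 10**(-q_j/10)) independently; returns the
    0-based inclusive (start, end) of the retained window or None."""
    L = len(qual)
    s_vals = [sum(ml - 10.0 ** (-qual[j] / 10.0) for j in range(i, L)) for i in range(L)]
    positives = [i for i in range(L) if s_vals[i] > 0]
    if not positives:
        return None
    end = max(positives)
    best = max(s_vals)
    start = s_vals.index(best)
    return start, end


def oracle_lqr_removes(qual: list[int], lqs: int, p: float) -> bool:
    low = sum(1 for q in qual if q < lqs)
    return 100.0 * low / len(qual) > p


def oracle_split(seq: str, l: int) -> list[str]:
    """Daughter sequences by regex splitting on N-runs of length >= l."""
    return [seg for seg in re.split(f"N{{{l},}}", seq) if seg]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_read(rng: np.random.Generator, length: int, alphabet: str = "ACGT",
                qmin: int = 0, qmax: int = 40, rid: str = "r") -> Read:
    seq = "".join(rng.choice(list(alphabet), size=length))
    qual = rng.integers(qmin, qmax + 1, size=length).tolist()
    return Read(id=rid, seq=seq, qual=[int(q) for q in qual])
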