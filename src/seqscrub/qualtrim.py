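"""Quality-score-based filtering and trimming.

Four families:

* LQR — drop a read whose fraction of low-quality bases (Phred strictly
  under ``lqs``) strictly exceeds ``p`` percent.
* Mott window extraction — per base error probability P = 10**(-Q/10);
  walking from the 3' end, accumulate the running sum of (ml - P) (no reset
  at negative values).  The retained window runs from the base attaining
  the maximum running sum (5' cut) to the 3'-most base where the sum is
  positive (3' cut); a read whose sum never goes positive is removed.
* TERA — walking from the 3' end, compute the running average Phred of the
  last k bases; the first base at which the average strictly exceeds
  ``avg`` is kept together with everything 5' of it.
* Fixed-count end trimming (3' then 5').

All trimming methods obey a global minimum retained length ``min_rl``
(set it at or above the assembler K-mer size): trimming stops once the
survivor would drop below min(min_rl, original length).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import PHRED_MAX, Read, TrimOutcome


@dataclass(frozen=True)
class LqrParams:
    lqs: int
    p: float

    def __post_init__(self) -> None:
        if not 0 <= self.lqs <= PHRED_MAX:
            raise ValueError(f"lqs must be in [0, {PHRED_MAX}]")
        if not 0 < self.p <= 100:
            raise ValueError("p must be in (0, 100]")


@dataclass(frozen=True)
class MottParams:
    """``ml`` is the error-probability limit: bases with P_error below it
    push the running sum up, bases above pull it down."""

    ml: float

    def __post_init__(self) -> None:
        if not 0 < self.ml < 1:
            raise ValueError("ml must be in (0, 1)")


@dataclass(frozen=True)
class TeraParams:
    avg: float

    def __post_init__(self) -> None:
        if not 0 < self.avg < PHRED_MAX:
            raise ValueError(f"avg must be in (0, {PHRED_MAX})")


@dataclass(frozen=True)
class EndTrimParams:
    """``x`` bases off the 3' end, then ``y`` off the 5' end."""

    x: int = 0
    y: int = 0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("end-trim counts must be >= 0")


@dataclass(frozen=True)
class MinLengthPolicy:
    """Global minimum retained read length; 0 disables the floor."""

    min_rl: int = 0

    def __post_init__(self) -> None:
        if self.min_rl < 0:
            raise ValueError("min_rl must be >= 0")

    def floor(self, read_len: int) -> int:
        return min(self.min_rl, read_len)


NO_MIN_LENGTH = MinLengthPolicy(0)


def error_prob(q: int) -> float:
    """Phred score -> base-call error probability, P = 10**(-Q/10)."""
    return 10.0 ** (-q / 10.0)


def filter_lqr(read: Read, params: LqrParams) -> TrimOutcome:
    """Remove the read when strictly more than p% of bases score strictly
    under lqs; comparisons are strict on both sides."""
    if len(read) == 0:
        raise ValueError("filter_lqr requires a non-empty read")
    low = sum(1 for q in read.qual if q < params.lqs)
    if 100.0 * low / len(read) > params.p:
        return TrimOutcome.removed(read)
    return TrimOutcome.kept(read)


def mott_running_sums(qual: list[int], ml: float) -> list[float]:
    """S[i] (0-based, aligned with bases 5'->3') where S is the cumulative
    sum of (ml - P_error) taken from the 3' end toward the 5' end."""
    s = [0.0] * len(qual)
    acc = 0.0
    for i in range(len(qual) - 1, -1, -1):
        acc += ml - error_prob(qual[i])
        s[i] = acc
    return s


def extract_mott_window(read: Read, params: MottParams, policy: MinLengthPolicy = NO_MIN_LENGTH) -> TrimOutcome:
    """Extract the maximal-sum quality window (trims both ends).

    The 3' cut is the 3'-most base with a positive running sum; the 5' cut
    is the base attaining the maximum running sum (ties resolved 5'-most,
    maximising survivor length).  A read with no positive sum is removed.
    If the window is shorter than the length floor, bases are restored
    first on the 3' side of the window, then on the 5' side — the 5' cut is
    the one driven by the maximal sum, so it is preserved preferentially.
    """
    L = len(read)
    if L == 0:
        raise ValueError("extract_mott_window requires a non-empty read")
    s = mott_running_sums(read.qual, params.ml)
    end = None  # 0-based index of last retained base
    for i in range(L - 1, -1, -1):
        if s[i] > 0:
            end = i
            break
    if end is None:
        return TrimOutcome.removed(read)
    best = max(s)
    start = s.index(best)  # smallest index attaining the max
    # length-floor restoration: 3' side first, then 5'
    floor = policy.floor(L)
    deficit = floor - (end - start + 1)
    if deficit > 0:
        give3 = min(deficit, L - 1 - end)
        end += give3
        deficit -= give3
        start -= min(deficit, start)
    if start == 0 and end == L - 1:
        return TrimOutcome.kept(read)
    return TrimOutcome.trimmed(read.window(start, end + 1), L - (end - start + 1))


def trim_tera(read: Read, params: TeraParams, policy: MinLengthPolicy = NO_MIN_LENGTH) -> TrimOutcome:
    """3'-end trim by running average quality.

    Walking k = 1, 2, ... suffix bases from the 3' end, the first base at
    which the running average strictly exceeds ``avg`` is kept along with
    everything 5' of it.  Trimming never takes the read below the length
    floor; if the average never exceeds ``avg``, the 5'-most floor bases
    are retained (removal when the floor is 0).
    """
    L = len(read)
    if L == 0:
        raise ValueError("trim_tera requires a non-empty read")
    floor = policy.floor(L)
    max_trim = L - floor
    acc = 0.0
    for k in range(1, L + 1):
        acc += read.qual[L - k]
        if acc / k > params.avg:
            trim = min(k - 1, max_trim)
            if trim == 0:
                return TrimOutcome.kept(read)
            return TrimOutcome.trimmed(read.prefix(L - trim), trim)
    # running average never exceeded the cutoff
    if floor == 0:
        return TrimOutcome.removed(read)
    if floor == L:
        return TrimOutcome.kept(read)
    return TrimOutcome.trimmed(read.prefix(floor), L - floor)


def trim_ends(read: Read, params: EndTrimParams, policy: MinLengthPolicy = NO_MIN_LENGTH) -> TrimOutcome:
    """Fixed-count trimming: up to ``x`` bases off the 3' end, then up to
    ``y`` off the 5' end, stopping at the length floor."""
    L = len(read)
    if L == 0:
        raise ValueError("trim_ends requires a non-empty read")
    budget = L - policy.floor(L)
    t3 = min(params.x, budget)
    t5 = min(params.y, budget - t3)
    if t3 + t5 == 0:
        return TrimOutcome.kept(read)
    if t3 + t5 == L:
        return TrimOutcome.removed(read)
    return TrimOutcome.trimmed(read.window(t5, L - t3), t3 + t5)
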