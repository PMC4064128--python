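"""QSEQ-specific filters and quality-offset conversion.

Legacy Illumina data (pre-Casava 1.8) carries two things plain FASTQ loses:
a per-read chastity (signal purity) pass/fail flag and the 'B' quality
character (Phred 2 at the +64 offset), Illumina's "unknown quality" marker
that tags unreliable read tails.  ``filter_chastity`` drops failed reads;
``trim_b_scores`` removes or trims reads by their Phred-2 content;
``switch_score`` re-tags a read's declared ASCII offset (scores themselves
are stored as integers, so conversion is exact and invertible) — run it
first to apply B-score trimming to FASTQ data that was converted from QSEQ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .core import (
    ILLUMINA_LEGACY,
    PHRED_MAX,
    EncodingError,
    MethodApplicabilityError,
    QualityEncoding,
    Read,
    TrimOutcome,
)

# Phred value of the 'B' character under the legacy +64 offset (ord('B')=66).
B_SCORE = 2


@dataclass(frozen=True)
class BScoreSpec:
    """B-score filter policy.

    ``count`` mode removes a read whose *total* number of Phred-2 bases is
    >= n; ``run`` mode acts on the 5'-most run of >= n consecutive Phred-2
    bases (``kr`` removes the read, ``ka`` keeps the bases 5' of the run).
    """

    n: int
    mode: Literal["count", "run"] = "run"
    action: Literal["kr", "ka"] = "ka"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("B-score threshold n must be >= 1")
        if self.mode not in ("count", "run"):
            raise ValueError(f"mode must be 'count' or 'run', got {self.mode!r}")
        if self.action not in ("kr", "ka"):
            raise ValueError(f"action must be 'kr' or 'ka', got {self.action!r}")


def filter_chastity(read: Read) -> TrimOutcome:
    """Remove a QSEQ read that failed the chastity filter; never alters bases."""
    if read.chastity == "unknown":
        raise MethodApplicabilityError(
            f"read {read.id!r}: qseq0 requires QSEQ input (FASTQ carries no chastity flag)"
        )
    if read.chastity == "failed":
        return TrimOutcome.removed(read)
    return TrimOutcome.kept(read)


def trim_b_scores(read: Read, spec: BScoreSpec, enc: QualityEncoding) -> TrimOutcome:
    """Remove/trim by 'B'-scored (Phred 2 at offset 64) base content."""
    if enc.offset != 64:
        raise MethodApplicabilityError(
            "qseqB requires the legacy +64 encoding; apply switch_score first"
        )
    if spec.mode == "count":
        if sum(1 for q in read.qual if q == B_SCORE) >= spec.n:
            return TrimOutcome.removed(read)
        return TrimOutcome.kept(read)
    # run mode: 5'-most run of >= n consecutive Phred-2 bases
    run_start = run_len = 0
    i = 0
    L = len(read)
    while i < L:
        if read.qual[i] == B_SCORE:
            j = i
            while j < L and read.qual[j] == B_SCORE:
                j += 1
            if j - i >= spec.n:
                run_start, run_len = i, j - i
                break
            i = j
        else:
            i += 1
    else:
        return TrimOutcome.kept(read)
    if run_len == 0:
        return TrimOutcome.kept(read)
    if spec.action == "kr" or run_start == 0:
        return TrimOutcome.removed(read)
    return TrimOutcome.trimmed(read.prefix(run_start), L - run_start)


def switch_score(read: Read, from_enc: QualityEncoding, to_enc: QualityEncoding) -> Read:
    """Re-tag the read's declared ASCII offset (Phred values are unchanged).

    Exactly invertible; raises :class:`EncodingError` if any score is not
    representable as a printable character at the target offset.
    """
    if from_enc == to_enc:
        raise ValueError("switch_score requires two different encodings")
    if read.encoding != from_enc:
        raise MethodApplicabilityError(
            f"read {read.id!r} is tagged {read.encoding.name}, not {from_enc.name}"
        )
    ceiling = min(PHRED_MAX, 126 - to_enc.offset)
    for q in read.qual:
        if q > ceiling:
            raise EncodingError(
                f"read {read.id!r}: Phred {q} not printable at offset {to_enc.offset}"
            )
    return replace(read, encoding=to_enc)
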