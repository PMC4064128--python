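"""Core domain objects shared by every pre-processing method.

A sequencing read is held as an id, its base string and a list of integer
Phred scores; methods never see the on-disk quality characters, so they are
independent of the input file format (FASTQ at either ASCII offset, or
Illumina QSEQ).  Every method returns a :class:`TrimOutcome` describing what
happened to the read, which the pipeline and the summary report consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

# Phred scores above this are rejected at parse time: 62 is the largest
# score representable as a printable character at the legacy +64 offset.
PHRED_MAX = 62

Chastity = Literal["passed", "failed", "unknown"]
Status = Literal["kept", "trimmed", "removed", "split"]


class SeqScrubError(Exception):
    """Base class for all package errors."""


class FormatError(SeqScrubError):
    """Malformed FASTQ/QSEQ input (names the record and line where known)."""


class EncodingError(SeqScrubError):
    """Quality character or score outside the declared ASCII offset's range."""


class MethodApplicabilityError(SeqScrubError):
    """A method was applied to input it cannot act on (e.g. qseq0 on FASTQ)."""


class PairSyncError(SeqScrubError):
    """Paired input files disagree in length; names the first unmatched ordinal."""


class ConfigError(SeqScrubError):
    """Invalid pipeline configuration, detected before any data is read."""


@dataclass(frozen=True)
class QualityEncoding:
    """ASCII-to-Phred mapping: ``offset`` is the ASCII code of Phred 0."""

    name: str
    offset: int

    def __post_init__(self) -> None:
        if self.offset not in (33, 64):
            raise ValueError(f"quality offset must be 33 or 64, got {self.offset}")


#: Standard Sanger/Casava>=1.8 FASTQ encoding ('!' is Phred 0).
SANGER = QualityEncoding("sanger", 33)
#: Legacy Illumina/QSEQ encoding ('@' is Phred 0; 'B' is Phred 2).
ILLUMINA_LEGACY = QualityEncoding("illumina_legacy", 64)


def encoding_from_offset(offset: int) -> QualityEncoding:
    if offset == 33:
        return SANGER
    if offset == 64:
        return ILLUMINA_LEGACY
    raise ValueError(f"unknown quality offset {offset}")


@dataclass
class Read:
    """One sequencing read.

    ``qual`` holds integer Phred scores (same length as ``seq``).
    ``chastity`` is only meaningful for QSEQ-sourced reads; FASTQ cannot
    carry it, so FASTQ reads are always ``unknown``.  ``encoding`` records
    the declared ASCII offset the read was parsed under (re-tagged by
    switch_score) so writers emit the right characters.
    """

    id: str
    seq: str
    qual: list[int]
    chastity: Chastity = "unknown"
    encoding: QualityEncoding = SANGER

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        for q in self.qual:
            if not 0 <= q <= PHRED_MAX:
                raise ValueError(f"read {self.id!r}: Phred score {q} outside [0, {PHRED_MAX}]")

    def __len__(self) -> int:
        return len(self.seq)

    def prefix(self, n: int) -> "Read":
        """The 5'-most ``n`` bases as a new read."""
        return replace(self, seq=self.seq[:n], qual=self.qual[:n])

    def window(self, start: int, end: int) -> "Read":
        """Bases ``[start, end)`` (0-based half-open) as a new read."""
        return replace(self, seq=self.seq[start:end], qual=self.qual[start:end])


@dataclass(frozen=True)
class TrimOutcome:
    """Result of applying one method to one read.

    ``reads`` is empty for ``removed``, a single read for ``kept``/
    ``trimmed`` and any number of daughter reads for ``split``.
    ``bases_removed`` counts bases deleted relative to the input read.
    """

    status: Status
    reads: tuple[Read, ...]
    bases_removed: int = 0

    @staticmethod
    def kept(read: Read) -> "TrimOutcome":
        return TrimOutcome("kept", (read,), 0)

    @staticmethod
    def removed(read: Read) -> "TrimOutcome":
        return TrimOutcome("removed", (), len(read))

    @staticmethod
    def trimmed(survivor: Read, bases_removed: int) -> "TrimOutcome":
        return TrimOutcome("trimmed", (survivor,), bases_removed)

    @staticmethod
    def split(daughters: Sequence[Read], bases_removed: int) -> "TrimOutcome":
        status: Status = "split" if daughters else "removed"
        return TrimOutcome(status, tuple(daughters), bases_removed)
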