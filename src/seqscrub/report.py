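"""Summary-statistics accounting and rendering.

One :class:`MethodCounters` row per pipeline step plus a TOTAL row.  Two
quality metrics accompany the read/base accounting: mean Phred (computed
over bases, not over per-read means) and the count of low-quality bases,
Phred <= 10 by default.  Conservation identities hold after every update:

    bases_in == bases_out + bases_removed
    reads_in == reads_kept + reads_trimmed + reads_removed + reads_split
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import pandas as pd

from .core import Read, TrimOutcome

#: Phred threshold under which a base counts as "low quality" in reports.
DEFAULT_LOWQ_THRESHOLD = 10

_COUNTER_FIELDS = (
    "reads_in", "reads_kept", "reads_trimmed", "reads_removed", "reads_split",
    "daughters_emitted", "widows_emitted",
    "bases_in", "bases_out", "bases_removed",
    "qsum_before", "qsum_after", "lowq_bases_before", "lowq_bases_after",
)


@dataclass
class MethodCounters:
    reads_in: int = 0
    reads_kept: int = 0
    reads_trimmed: int = 0
    reads_removed: int = 0
    reads_split: int = 0
    daughters_emitted: int = 0
    widows_emitted: int = 0
    bases_in: int = 0
    bases_out: int = 0
    bases_removed: int = 0
    qsum_before: int = 0
    qsum_after: int = 0
    lowq_bases_before: int = 0
    lowq_bases_after: int = 0

    @property
    def mean_q_before(self) -> float | None:
        return self.qsum_before / self.bases_in if self.bases_in else None

    @property
    def mean_q_after(self) -> float | None:
        return self.qsum_after / self.bases_out if self.bases_out else None

    def add(self, other: "MethodCounters") -> None:
        for f in _COUNTER_FIELDS:
            setattr(self, f, getattr(self, f) + getattr(other, f))


class SummaryReport:
    """Ordered per-step counters plus a TOTAL aggregate."""

    def __init__(self, labels: Iterable[str] = (), lowq_threshold: int = DEFAULT_LOWQ_THRESHOLD):
        self.lowq_threshold = lowq_threshold
        self.methods: dict[str, MethodCounters] = {label: MethodCounters() for label in labels}
        self.total = MethodCounters()

    def _observe(self, c: MethodCounters, read_in: Read, outcome: TrimOutcome) -> None:
        t = self.lowq_threshold
        c.reads_in += 1
        c.bases_in += len(read_in)
        c.qsum_before += sum(read_in.qual)
        c.lowq_bases_before += sum(1 for q in read_in.qual if q <= t)
        out_bases = 0
        for r in outcome.reads:
            out_bases += len(r)
            c.qsum_after += sum(r.qual)
            c.lowq_bases_after += sum(1 for q in r.qual if q <= t)
        c.bases_out += out_bases
        c.bases_removed += len(read_in) - out_bases
        if outcome.status == "kept":
            c.reads_kept += 1
        elif outcome.status == "trimmed":
            c.reads_trimmed += 1
        elif outcome.status == "removed":
            c.reads_removed += 1
        else:
            c.reads_split += 1
            c.daughters_emitted += len(outcome.reads)

    def update(self, label: str, read_in: Read, outcome: TrimOutcome) -> None:
        """Advance one step's counters with one read's outcome."""
        self._observe(self.methods.setdefault(label, MethodCounters()), read_in, outcome)

    def update_total(self, read_in: Read, outcome: TrimOutcome) -> None:
        """Advance the TOTAL row with one read's whole-chain outcome."""
        self._observe(self.total, read_in, outcome)

    def count_widow(self) -> None:
        self.total.widows_emitted += 1

    def merge(self, other: "SummaryReport") -> None:
        """Fold another (chunk) report into this one, label-wise."""
        for label, counters in other.methods.items():
            self.methods.setdefault(label, MethodCounters()).add(counters)
        self.total.add(other.total)

    # -- rendering ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, c in list(self.methods.items()) + [("TOTAL", self.total)]:
            row = {"method": label}
            row.update({f: getattr(c, f) for f in _COUNTER_FIELDS})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path) -> "SummaryReport":
        df = pd.read_csv(path, sep="\t")
        report = SummaryReport()
        for _, row in df.iterrows():
            c = MethodCounters(**{f: int(row[f]) for f in _COUNTER_FIELDS})
            if row["method"] == "TOTAL":
                report.total = c
            else:
                report.methods[str(row["method"])] = c
        return report

    def render(self) -> str:
        """Human-readable report text."""

        def fmt_mean(v: float | None) -> str:
            return "NA" if v is None else f"{v:.2f}"

        def pct(part: int, whole: int) -> str:
            return "NA" if whole == 0 else f"{100.0 * part / whole:.2f}%"

        lines = ["seqscrub summary report", "=" * 60]
        for label, c in list(self.methods.items()) + [("TOTAL", self.total)]:
            lines += [
                "",
                f"[{label}]",
                f"  reads: in={c.reads_in} kept={c.reads_kept} trimmed={c.reads_trimmed} "
                f"removed={c.reads_removed} split={c.reads_split}",
                f"  daughters emitted: {c.daughters_emitted}   widows emitted: {c.widows_emitted}",
                f"  bases: in={c.bases_in} out={c.bases_out} removed={c.bases_removed}",
                f"  mean Phred quality score: before={fmt_mean(c.mean_q_before)} "
                f"after={fmt_mean(c.mean_q_after)}",
                f"  low Phred quality score (<={self.lowq_threshold}) bases: "
                f"before={c.lowq_bases_before} ({pct(c.lowq_bases_before, c.bases_in)}) "
                f"after={c.lowq_bases_after} ({pct(c.lowq_bases_after, c.bases_out)})",
            ]
        return "\n".join(lines) + "\n"
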