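"""Method-chain orchestration over SR/PE/MP streams.

Each mate is trimmed independently through the configured chain; pairing is
resolved afterwards.  Pairs where both mates survive are written to the
paired outputs at the same ordinal position; a surviving mate whose partner
was removed ("widow") is diverted to the singleton file so the two paired
files stay line-synchronised; daughter reads from N-splitting always go to
the singleton file (pairing is undefined for fragments).

Parallel mode partitions the input into fixed-size chunks of whole records
(whole pairs for PE/MP), processes chunks in worker threads and writes the
results back in chunk order, so output files are byte-identical for any
worker count or chunk size.
"""

from __future__ import annotations

import gzip
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence, Union

from . import artifacts, nbases, qseq, qualtrim, seqio
from .core import (
    ILLUMINA_LEGACY,
    SANGER,
    ConfigError,
    PairSyncError,
    QualityEncoding,
    Read,
    TrimOutcome,
)
from .report import DEFAULT_LOWQ_THRESHOLD, SummaryReport

Layout = Literal["SR", "PE", "MP"]


@dataclass(frozen=True)
class AdapterParams:
    """5adpt step parameters: the artifact library plus the match policy."""

    library: artifacts.ArtifactLibrary
    match: artifacts.MatchSpec


@dataclass(frozen=True)
class MethodStep:
    """One chain step: canonical method name + its parameter record."""

    method: str
    params: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", self.method.lower())


_PARAM_TYPES: dict[str, type | None] = {
    "5adpt": AdapterParams,
    "rmhp": artifacts.HomopolymerSpec,
    "qseq0": type(None),
    "qseqb": qseq.BScoreSpec,
    "nperc": nbases.NSpec,
    "ncutoff": nbases.NSpec,
    "nsplit": nbases.NSpec,
    "lqr": qualtrim.LqrParams,
    "mott": qualtrim.MottParams,
    "tera": qualtrim.TeraParams,
    "3end": qualtrim.EndTrimParams,
    "5end": qualtrim.EndTrimParams,
    "switch_score": QualityEncoding,
}

_NSPEC_FIELD = {"nperc": "p", "ncutoff": "n", "nsplit": "l"}


@dataclass(frozen=True)
class PipelineConfig:
    """Ordered method chain plus stream-level settings."""

    steps: tuple[MethodStep, ...]
    layout: Layout = "SR"
    input_format: Literal["fastq", "qseq"] = "fastq"
    encoding: QualityEncoding = SANGER
    min_rl: qualtrim.MinLengthPolicy = qualtrim.NO_MIN_LENGTH
    workers: int = 1
    chunk_size: int = 100_000
    gzip_output: bool = False
    lowq_threshold: int = DEFAULT_LOWQ_THRESHOLD

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ConfigError("workers must be >= 1")
        if self.chunk_size < 1:
            raise ConfigError("chunk_size must be >= 1")

    @property
    def step_labels(self) -> tuple[str, ...]:
        return tuple(f"{i + 1}:{s.method}" for i, s in enumerate(self.steps))

    def validate(self) -> QualityEncoding:
        """Check the chain before any data is read; returns the encoding
        output records will be written under (switch_score re-tags it)."""
        enc = ILLUMINA_LEGACY if self.input_format == "qseq" else self.encoding
        for step in self.steps:
            expected = _PARAM_TYPES.get(step.method)
            if step.method not in _PARAM_TYPES:
                raise ConfigError(f"unknown method {step.method!r}")
            if not isinstance(step.params, expected if expected is not None else type(None)):
                raise ConfigError(
                    f"method {step.method!r} expects params of type "
                    f"{expected.__name__ if expected else 'None'}, "
                    f"got {type(step.params).__name__}"
                )
            if step.method in _NSPEC_FIELD:
                if getattr(step.params, _NSPEC_FIELD[step.method]) is None:
                    raise ConfigError(
                        f"method {step.method!r} requires NSpec field "
                        f"{_NSPEC_FIELD[step.method]!r}"
                    )
            if step.method == "qseq0" and self.input_format != "qseq":
                raise ConfigError("qseq0 requires QSEQ input")
            if step.method == "qseqb" and enc.offset != 64:
                raise ConfigError(
                    "qseqB requires the legacy +64 encoding at its chain "
                    "position; insert switch_score first"
                )
            if step.method == "switch_score":
                if step.params == enc:
                    raise ConfigError("switch_score target equals the current encoding")
                enc = step.params
        return enc


def apply_step(read: Read, step: MethodStep, policy: qualtrim.MinLengthPolicy) -> TrimOutcome:
    """Dispatch one method to one read."""
    m, p = step.method, step.params
    if m == "5adpt":
        return artifacts.apply_5adpt(read, p.library, p.match)
    if m == "rmhp":
        return artifacts.remove_homopolymer(read, p)
    if m == "qseq0":
        return qseq.filter_chastity(read)
    if m == "qseqb":
        return qseq.trim_b_scores(read, p, read.encoding)
    if m == "nperc":
        return nbases.filter_n_percent(read, p.p)
    if m == "ncutoff":
        return nbases.filter_n_count(read, p.n)
    if m == "nsplit":
        return nbases.split_on_n(read, p.l)
    if m == "lqr":
        return qualtrim.filter_lqr(read, p)
    if m == "mott":
        return qualtrim.extract_mott_window(read, p, policy)
    if m == "tera":
        return qualtrim.trim_tera(read, p, policy)
    if m in ("3end", "5end"):
        return qualtrim.trim_ends(read, p, policy)
    if m == "switch_score":
        return TrimOutcome.kept(qseq.switch_score(read, read.encoding, p))
    raise ConfigError(f"unknown method {m!r}")


@dataclass(frozen=True)
class ChainOutcome:
    """Aggregate of one read's trip through the whole chain."""

    status: str  # kept | trimmed | removed | split
    reads: tuple[Read, ...]
    bases_removed: int

    def as_trim_outcome(self) -> TrimOutcome:
        return TrimOutcome(self.status, self.reads, self.bases_removed)  # type: ignore[arg-type]


def apply_chain(
    read: Read,
    steps: Sequence[MethodStep],
    policy: qualtrim.MinLengthPolicy = qualtrim.NO_MIN_LENGTH,
    report: Optional[SummaryReport] = None,
    labels: Optional[Sequence[str]] = None,
) -> ChainOutcome:
    """Run one read through the chain; short-circuits once nothing survives.

    Split daughters continue through the remaining steps individually.
    """
    if labels is None:
        labels = [f"{i + 1}:{s.method}" for i, s in enumerate(steps)]
    current: list[Read] = [read]
    was_split = False
    bases_removed = 0
    for step, label in zip(steps, labels):
        survivors: list[Read] = []
        for r in current:
            outcome = apply_step(r, step, policy)
            if report is not None:
                report.update(label, r, outcome)
            bases_removed += outcome.bases_removed
            if outcome.status == "split":
                was_split = True
            survivors.extend(outcome.reads)
        current = survivors
        if not current:
            break
    if not current:
        status = "removed"
    elif was_split:
        status = "split"
    elif bases_removed > 0:
        status = "trimmed"
    else:
        status = "kept"
    result = ChainOutcome(status, tuple(current), bases_removed)
    if report is not None:
        report.update_total(read, result.as_trim_outcome())
    return result


@dataclass(frozen=True)
class ReadPair:
    fwd: Read
    rev: Read
    index: int  # 1-based ordinal in the input stream


@dataclass
class StreamSet:
    """Routing targets: synchronised paired sinks + the singleton sink."""

    out_fwd: list[Read] = field(default_factory=list)
    out_rev: list[Read] = field(default_factory=list)
    out_single: list[Read] = field(default_factory=list)


def process_pair(
    pair: ReadPair,
    steps: Sequence[MethodStep],
    streams: StreamSet,
    policy: qualtrim.MinLengthPolicy = qualtrim.NO_MIN_LENGTH,
    report: Optional[SummaryReport] = None,
    labels: Optional[Sequence[str]] = None,
) -> None:
    """Trim both mates independently, then resolve pairing.

    Both survive intact -> paired outputs; exactly one survives intact ->
    singleton (widow); split daughters always go to the singleton stream
    and their mate counts as unpaired.
    """
    fwd_out = apply_chain(pair.fwd, steps, policy, report, labels)
    rev_out = apply_chain(pair.rev, steps, policy, report, labels)
    fwd_paired = fwd_out.status in ("kept", "trimmed")
    rev_paired = rev_out.status in ("kept", "trimmed")
    if fwd_paired and rev_paired:
        streams.out_fwd.append(fwd_out.reads[0])
        streams.out_rev.append(rev_out.reads[0])
        return
    for out, paired in ((fwd_out, fwd_paired), (rev_out, rev_paired)):
        if paired:
            streams.out_single.extend(out.reads)
            if report is not None:
                report.count_widow()
        elif out.status == "split":
            streams.out_single.extend(out.reads)


def _paired_records(fwd_iter: Iterator[Read], rev_iter: Iterator[Read]) -> Iterator[ReadPair]:
    sentinel = object()
    for i, (f, r) in enumerate(zip_longest(fwd_iter, rev_iter, fillvalue=sentinel), start=1):
        if f is sentinel or r is sentinel:
            short = "first" if f is sentinel else "second"
            raise PairSyncError(
                f"paired input files have unequal lengths: the {short} file "
                f"ends before record {i}"
            )
        yield ReadPair(fwd=f, rev=r, index=i)


def _chunks(items: Iterator, size: int) -> Iterator[list]:
    chunk: list = []
    for item in items:
        chunk.append(item)
        if len(chunk) == size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def _process_chunk_sr(
    chunk: list[Read], config: PipelineConfig, labels
) -> tuple[StreamSet, SummaryReport]:
    streams = StreamSet()
    report = SummaryReport(labels, config.lowq_threshold)
    for read in chunk:
        out = apply_chain(read, config.steps, config.min_rl, report, labels)
        streams.out_single.extend(out.reads)
    return streams, report


def _process_chunk_pe(
    chunk: list[ReadPair], config: PipelineConfig, labels
) -> tuple[StreamSet, SummaryReport]:
    streams = StreamSet()
    report = SummaryReport(labels, config.lowq_threshold)
    for pair in chunk:
        process_pair(pair, config.steps, streams, config.min_rl, report, labels)
    return streams, report


def run(
    config: PipelineConfig,
    inputs: Sequence[Union[str, Path]],
    output_prefix: Union[str, Path],
) -> SummaryReport:
    """Process the input file(s) through the chain and write the outputs.

    SR expects one input file; PE/MP expect two order-synchronised files.
    Outputs are ``PREFIX_1/2.fastq`` (PE/MP), ``PREFIX_single.fastq`` and
    ``PREFIX_report.txt``/``.tsv``; ``.gz`` is appended when gzip output is
    enabled.  Output content is invariant to ``workers``/``chunk_size``.
    """
    out_enc = config.validate()
    paired = config.layout in ("PE", "MP")
    if paired and len(inputs) != 2:
        raise ConfigError(f"layout {config.layout} requires two input files")
    if not paired and len(inputs) != 1:
        raise ConfigError("layout SR requires one input file")

    parse = seqio.parse_qseq if config.input_format == "qseq" else (
        lambda src: seqio.parse_fastq(src, config.encoding)
    )
    if paired:
        records: Iterator = _paired_records(parse(inputs[0]), parse(inputs[1]))
        worker = _process_chunk_pe
    else:
        records = parse(inputs[0])
        worker = _process_chunk_sr

    prefix = str(output_prefix)
    ext = ".fastq.gz" if config.gzip_output else ".fastq"
    opener = (lambda p: gzip.open(p, "wt")) if config.gzip_output else (lambda p: open(p, "w"))
    labels = config.step_labels
    total_report = SummaryReport(labels, config.lowq_threshold)

    sinks = {}
    try:
        sinks["single"] = opener(prefix + "_single" + ext)
        if paired:
            sinks["fwd"] = opener(prefix + "_1" + ext)
            sinks["rev"] = opener(prefix + "_2" + ext)

        def write_result(result: tuple[StreamSet, SummaryReport]) -> None:
            streams, chunk_report = result
            if paired:
                seqio.write_fastq(streams.out_fwd, out_enc, sinks["fwd"])
                seqio.write_fastq(streams.out_rev, out_enc, sinks["rev"])
            seqio.write_fastq(streams.out_single, out_enc, sinks["single"])
            total_report.merge(chunk_report)

        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            pending: deque = deque()
            for chunk in _chunks(records, config.chunk_size):
                pending.append(pool.submit(worker, chunk, config, labels))
                while len(pending) > config.workers * 4:
                    write_result(pending.popleft().result())
            while pending:
                write_result(pending.popleft().result())
    finally:
        for fh in sinks.values():
            fh.close()

    Path(prefix + "_report.txt").write_text(total_report.render())
    total_report.to_tsv(prefix + "_report.tsv")
    return total_report
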