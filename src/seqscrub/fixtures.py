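"""Deterministic synthetic short-read generator with ground-truth manifests.

Emulates the error modes the pre-processing methods target: a linear 5'->3'
Phred decay with Gaussian noise (the Illumina 3'-end degradation pattern),
injected adapter fragments at known positions with a known number of
substitution edits, injected N-runs, Phred-2 ("B"-scored) read tails, and
failed-chastity flags for QSEQ output.  Every injection is recorded in a
per-read manifest so tests can compare method behaviour against ground
truth exactly.  It is a testing generator, not an error-model simulator:
there is no quality-dependent substitution model and no fragment-size
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

from .core import ILLUMINA_LEGACY, SANGER, Read
from .artifacts import ArtifactLibrary

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation recipe; all rates are per-read probabilities in [0, 1].

    ``quality_profile`` is (start_mean, end_mean, noise_sd) in Phred units,
    interpolated linearly from the 5' to the 3' end.  ``adapter_max_edits``
    bounds the number of substitution edits applied to an injected adapter
    (the realised count per read is recorded in the manifest).
    """

    n_reads: int = 1000
    read_len: int = 100
    layout: Literal["SR", "PE"] = "SR"
    quality_profile: tuple[float, float, float] = (38.0, 28.0, 3.0)
    adapter_rate: float = 0.0
    adapter_max_edits: int = 1
    n_run_rate: float = 0.0
    n_run_len: int = 2
    b_tail_rate: float = 0.0
    b_tail_len: int = 4
    chastity_fail_rate: float = 0.0
    out_format: Literal["fastq", "qseq"] = "fastq"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.adapter_rate, self.n_run_rate, self.b_tail_rate, self.chastity_fail_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        start, end, sd = self.quality_profile
        if not (0 <= start <= 62 and 0 <= end <= 62 and sd >= 0):
            raise ValueError("quality profile means must be in [0, 62], sd >= 0")


def _qseq_line(read: Read, mate: int, ordinal: int, flag: str) -> str:
    # id fields 1-8: machine, run, lane, tile, x, y, index, mate
    fields = ["SIM", "1", "1", "1", str(ordinal), str(ordinal), "0", str(mate)]
    seq = read.seq.replace("N", ".")
    qual = "".join(chr(64 + q) for q in read.qual)
    return "\t".join(fields + [seq, qual, flag])


class _MateGenerator:
    """Builds one mate's read + manifest row; one shared RNG for determinism."""

    def __init__(self, spec: SyntheticSpec, rng: np.random.Generator, library: ArtifactLibrary):
        self.spec = spec
        self.rng = rng
        self.library = library.entries
        start, end, _ = spec.quality_profile
        self.q_base = np.linspace(start, end, spec.read_len)

    def make(self, read_id: str) -> tuple[Read, dict]:
        spec, rng = self.spec, self.rng
        L = spec.read_len
        seq = _BASES[rng.integers(0, 4, L)]
        noise = rng.normal(0.0, spec.quality_profile[2], L)
        qual = np.clip(np.rint(self.q_base + noise), 0, 62).astype(int)

        row: dict = {
            "read_id": read_id,
            "length": L,
            "adapter_name": "",
            "adapter_pos": -1,
            "adapter_edits": -1,
            "n_run_pos": -1,
            "n_run_len": 0,
            "b_tail_len": 0,
            "chastity": "unknown",
        }

        adapter_interval: Optional[tuple[int, int]] = None
        if rng.random() < spec.adapter_rate:
            name, art = self.library[rng.integers(0, len(self.library))]
            alen = len(art)
            if alen <= L:
                pos = int(rng.integers(0, L - alen + 1))
                frag = np.frombuffer(art.encode(), dtype=np.uint8).copy()
                n_edits = int(rng.integers(0, spec.adapter_max_edits + 1))
                if n_edits:
                    sites = rng.choice(alen, size=n_edits, replace=False)
                    for s in sites:
                        choices = _BASES[_BASES != frag[s]]
                        frag[s] = choices[rng.integers(0, len(choices))]
                seq[pos : pos + alen] = frag
                adapter_interval = (pos, pos + alen)
                row.update(adapter_name=name, adapter_pos=pos, adapter_edits=n_edits)

        if rng.random() < spec.n_run_rate and spec.n_run_len <= L:
            starts = np.arange(0, L - spec.n_run_len + 1)
            if adapter_interval is not None:
                a, b = adapter_interval
                starts = starts[(starts + spec.n_run_len <= a) | (starts >= b)]
            if len(starts):
                pos = int(starts[rng.integers(0, len(starts))])
                seq[pos : pos + spec.n_run_len] = ord("N")
                row.update(n_run_pos=pos, n_run_len=spec.n_run_len)

        if rng.random() < spec.b_tail_rate:
            tail = min(spec.b_tail_len, L)
            qual[L - tail :] = 2
            row["b_tail_len"] = tail

        chastity = "unknown"
        if spec.out_format == "qseq":
            chastity = "failed" if rng.random() < spec.chastity_fail_rate else "passed"
        row["chastity"] = chastity
        row["mean_q"] = float(qual.mean())

        enc = ILLUMINA_LEGACY if spec.out_format == "qseq" else SANGER
        read = Read(
            id=read_id,
            seq=seq.tobytes().decode("ascii"),
            qual=[int(q) for q in qual],
            chastity=chastity,
            encoding=enc,
        )
        return read, row


def generate(
    spec: SyntheticSpec,
    output_prefix: Union[str, Path],
    library: Optional[ArtifactLibrary] = None,
) -> pd.DataFrame:
    """Write the synthetic files plus a TSV manifest; returns the manifest.

    SR writes ``PREFIX.fastq``/``.qseq``; PE writes ``PREFIX_1``/``_2``
    files (manifest column ``mate`` distinguishes them).  The same seed
    always produces byte-identical files and manifest.
    """
    if library is None:
        library = ArtifactLibrary.builtin()
    rng = np.random.default_rng(spec.seed)
    gen = _MateGenerator(spec, rng, library)
    prefix = str(output_prefix)
    ext = ".qseq" if spec.out_format == "qseq" else ".fastq"

    rows: list[dict] = []
    mates = (1, 2) if spec.layout == "PE" else (1,)
    paths = (
        [prefix + f"_{m}" + ext for m in mates] if spec.layout == "PE" else [prefix + ext]
    )
    handles = [open(p, "w") for p in paths]
    try:
        for ordinal in range(1, spec.n_reads + 1):
            for mate, fh in zip(mates, handles):
                if spec.out_format == "qseq":
                    rid = f"SIM:1:1:1:{ordinal}:{ordinal}:0:{mate}"
                else:
                    rid = f"sim_{ordinal:06d}" + (f"/{mate}" if spec.layout == "PE" else "")
                read, row = gen.make(rid)
                row["mate"] = mate
                rows.append(row)
                if spec.out_format == "qseq":
                    flag = "0" if read.chastity == "failed" else "1"
                    fh.write(_qseq_line(read, mate, ordinal, flag) + "\n")
                else:
                    chars = "".join(chr(SANGER.offset + q) for q in read.qual)
                    fh.write(f"@{read.id}\n{read.seq}\n+\n{chars}\n")
    finally:
        for fh in handles:
            fh.close()

    manifest = pd.DataFrame(rows)
    manifest.to_csv(prefix + "_manifest.tsv", sep="\t", index=False)
    return manifest
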