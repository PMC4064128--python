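# seqscrub

Pre-processing for Illumina-style short sequencing reads, aimed at the step
between the sequencer and downstream analysis — in particular De Bruijn
graph (DBG) assembly, which degrades badly on uncalled bases, adapter
contamination and low-quality 3' tails. `seqscrub` is both a library and a
command-line tool: it reads single-read or paired-end/mate-pair FASTQ
(Phred+33 or Phred+64) or legacy Illumina QSEQ files (gzip transparent),
runs them through an ordered chain of trimming/filtering methods, preserves
pair-file synchronisation by diverting "widowed" mates to a singleton file,
and emits a summary-statistics report. Chunked multi-threaded execution is
deterministic: output files are byte-identical for any worker count.

## Methods

| Chain name | What it does |
|---|---|
| `5adpt` | Detect 5' adapter/primer artifacts by exact or approximate matching (bounded Levenshtein; percentage budget or per-edit-type caps); remove the read (`kr`) or keep the bases 5' of the match (`ka`). |
| `rmhp` | Remove the 5'-most homopolymer run of length ≥ h and everything 3' of it. |
| `qseq0` | Remove QSEQ reads failing the chastity filter. |
| `qseqb` | Remove/trim reads by "B"-scored (Phred 2 at offset +64) base content — total count or consecutive run. |
| `nperc`, `ncutoff` | Remove reads whose N percentage / count is ≥ the cutoff. |
| `nsplit` | Excise N-runs of length ≥ l and salvage the flanking segments as daughter reads. |
| `lqr` | Remove reads with > p% of bases under Phred `lqs`. |
| `mott` | Quality-window extraction: running sum of (ml − 10^(−Q/10)) from the 3' end; keep from the maximal-sum base to the 3'-most positive-sum base. |
| `tera` | 3' trim by running average: keep the first base (from the 3' end) whose suffix mean Phred exceeds `avg`, and everything 5' of it. |
| `3end`, `5end` | Fixed-count end trimming. |
| `switch_score` | Re-tag Phred+33 ↔ Phred+64 (exact, invertible). |

A global `min_rl` (set ≥ the assembler K-mer size) stops Mott/TERA/3end/5end
from ever trimming a read below that length. See `docs/methods.md` for the
precise semantics, tie-breaks and design decisions.

## Worked example

Generate a small synthetic paired-end dataset with known injected features
(the bundled generator records every injection in a manifest), then run the
recommended `lqr,5adpt,tera` chain:

```sh
python -c "
from seqscrub import SyntheticSpec, generate
generate(SyntheticSpec(n_reads=2000, layout='PE', adapter_rate=0.05,
                       n_run_rate=0.05, b_tail_rate=0.1,
                       quality_profile=(38.0, 22.0, 6.0), seed=7), 'raw')"

seqscrub -pe1 raw_1.fastq -pe2 raw_2.fastq -layout pe \
         -methods lqr,5adpt,tera -lqs 10 -lq_p 50 -mp 90 -tera_avg 20 \
         -min_rl 36 -t 4 -o trimmed
```

which prints

```
seqscrub: 4000 reads in; kept=2043 trimmed=1956 removed=1 split=0; report: trimmed_report.txt
```

and writes `trimmed_1.fastq`/`trimmed_2.fastq` (still line-synchronised),
`trimmed_single.fastq` (the one widowed mate) and the report, whose TOTAL
block reads:

```
[TOTAL]
  reads: in=4000 kept=2043 trimmed=1956 removed=1 split=0
  daughters emitted: 0   widows emitted: 1
  bases: in=400000 out=372876 removed=27124
  mean Phred quality score: before=29.93 after=30.36
  low Phred quality score (<=10) bases: before=3254 (0.81%) after=1217 (0.33%)
```

Reading it: LQR removed one whole low-quality read (its surviving mate is
the widow in `trimmed_single.fastq`), `5adpt` excised 14,120 bases of
injected adapter sequence, and TERA shaved low-quality 3' tails — the mean
Phred of retained bases rises from 29.93 to 30.36 and the fraction of
Phred ≤ 10 bases falls from 0.81% to 0.33%, while no survivor is shorter
than 36 bp.

The same pipeline is available as a library (`seqscrub.run`,
`seqscrub.apply_chain`, and the per-method functions), with the
`SummaryReport` object returned directly.

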