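# Methods

`seqscrub` pre-processes Illumina-style short reads before downstream
analysis — most pointedly before De Bruijn graph (DBG) assembly, which is
sensitive to uncalled bases, adapter contamination and low-quality 3' tails.
This note records the algorithms as implemented, the parameter semantics,
the numerical and design choices made where more than one reading was
defensible, and what the synthetic test data does and does not demonstrate.

## Data model

A read is (id, bases over {A,C,G,T,N}, integer Phred scores 0–62, chastity
flag, declared ASCII offset). Phred scores are decoded once at parse time
(`qual[i] = ascii(char) − offset`, offset 33 "sanger" or 64
"illumina_legacy") and every method operates on integers, so methods are
format-independent. The ceiling of 62 is the largest score printable at the
legacy +64 offset; higher characters are rejected at parse time rather than
silently accepted. QSEQ input (11 tab-separated fields) contributes two
extras FASTQ cannot carry: the chastity pass/fail flag (field 11) and the
native +64 offset; '.' (uncalled) is normalised to 'N' at parse time so the
N-handling methods apply uniformly. FASTQ is parsed strictly as 4-line
records; wrapped FASTQ is rejected. Gzip input is detected by magic bytes
only; gzip is the only supported container.

## Artifact detection (5adpt)

An artifact (adapter/primer/linker) matches a read when it aligns *in
full* inside the read under unit-cost Levenshtein distance — semi-global
alignment with free read ends. Partial artifact overhang past the read's 3'
end is deliberately not matched: full containment keeps the definition (and
its brute-force oracle) exact; read-through-aware 3'-overlap trimming is a
different algorithm and out of scope.

* Budget from match percentage: `floor(len(artifact) × (1 − mp/100))` —
  flooring errs toward stringency.
* Per-edit-type caps (`max_ins`, `max_sub`, `max_del`) replace the
  percentage budget when any is given; an unset cap defaults to 0, because
  the caps are specified per edit type and leaving one unlimited would make
  nearly anything match. The capped matcher tracks Pareto-minimal
  (ins, sub, del) triples per DP cell; it is exact but slower, intended for
  the short search depths it is meant for.
* `search_depth` bounds the alignment *start* (the 5'-anchored use case),
  not its end.
* Best match = lowest distance, then smallest start, then longest artifact,
  then library order; among those, smallest end. The paper trail for such
  tie-breaks is thin everywhere in this field; the rule is chosen once so
  results are reproducible and independent of search internals.
* 'N' in the read mismatches every artifact base (conservative);
  comparison is case-insensitive.

The uncapped matcher runs the free-start semi-global recurrence over the
*reversed* strings, which yields `min_e dist(artifact, read[s:e])` for every
start `s` in a single O(m·L) pass; rows are numpy-vectorised by folding the
horizontal +1 dependency into a running minimum of (cell − column). The
match end is recovered afterwards by one small prefix-distance pass. Tests
check this machinery against two independent routes: exhaustive substring
enumeration scored with edlib, and a vectorised textbook DP over all 4^8
8-bp reads — reduced to the 15 alphabet-orbit representatives of the 4-bp
artifacts, which covers all 4^8 × 4^4 pairs exactly because edit distance is
invariant under relabelling both strings with one alphabet permutation.

Homopolymer removal (rmHP) excises the 5'-most run of length ≥ h of any
single base in the configured set, together with everything 3' of it; later
runs need no handling because they are inside the removed tail.

## QSEQ methods

* qseq0 removes chastity-failed reads; applying it to FASTQ input is a
  configuration error, not a no-op.
* "B-scored base" is operationalised as Phred 2 under the +64 offset
  (ASCII 'B' = 66). qseqB has two explicit modes, because the two
  historical descriptions of the method disagree: `count` removes a read
  with ≥ n Phred-2 bases in total (the ≥ reading is the stricter of the two
  printed variants and is the one implemented); `run` finds the 5'-most run
  of ≥ n consecutive Phred-2 bases and either removes the read (kr) or
  keeps the bases 5' of the run (ka).
* switch_score re-tags the declared offset only — scores are stored as
  integers, so the conversion is exact and a double application is the
  identity. It exists so qseqB can be applied to FASTQ files that were
  converted from QSEQ (e.g. SRA downloads).

The "sanger" offset is 33, the universal FASTQ standard, even though some
legacy documentation places Sanger Phred 0 at ASCII 32; 32 is a space and
no extant FASTQ uses it.

## N handling

nperc and ncutoff remove a read when the percentage (resp. count) of N
bases is ≥ the cutoff — both boundaries inclusive. nsplit excises *every*
maximal N-run of length ≥ l and emits the intervening segments as daughter
reads (`/s1`, `/s2`, … 5'→3'), dropping empty segments; runs shorter than l
are left in place. Generalising from the single-run ("two daughters") case
to all runs follows the method's stated purpose — salvaging information
instead of discarding the read. All three operations are idempotent.

## Quality trimming

* **LQR** removes a read when strictly more than `p`% of bases score
  strictly under `lqs`. "Over"/"under" are implemented as strict
  comparisons throughout this module.
* **Mott window extraction**: with `P_err = 10^(−Q/10)`, compute the
  running sum of `(ml − P_err)` from the 3' end cumulatively, with *no*
  reset at negative values — the recurrence is implemented literally as
  printed in the lineage this method comes from, not as the classical
  reset-to-zero variant found elsewhere in the literature. The retained
  window runs from the base attaining the maximum sum (ties: 5'-most,
  maximising length) to the 3'-most base with a positive sum; no positive
  sum ⇒ read removed. Consequence worth knowing: without the reset, a bad
  3' tail must be amortised by ≈ `P_err(bad)/ml` good bases before the 3'
  cut moves right, so this variant trims 3' tails more aggressively than
  the reset variant. When the window is shorter than the length floor,
  bases are restored first on the 3' side, then the 5' side — the 5' cut is
  the one determined by the maximal sum, so it is preserved preferentially.
* **TERA**: walking suffix lengths k = 1, 2, … from the 3' end, the first
  base where the running average Phred strictly exceeds `avg` is kept along
  with everything 5' of it. When the average never exceeds `avg` the read
  is cut to the length floor rather than removed (removed when the floor
  is 0) — consistent with the floor's "stop trimming" semantics.
* **3end/5end** remove fixed counts, 3' first, then 5'.
* **min_rl** (set ≥ the assembler K-mer length) is a hard floor for all
  four trimming methods: no survivor is shorter than
  `min(min_rl, original length)`. It never resurrects removed reads.

## Pair engine

Each mate runs the whole chain independently; pairing is resolved
afterwards. Both mates survive intact → written to the paired outputs at
the same ordinal; exactly one survives → diverted to the singleton file
("widow"), keeping the paired files line-synchronised; nsplit daughters
always go to the singleton file and their mate counts as unpaired, because
ordinal pairing is undefined for fragments. The chain short-circuits per
read on removal; daughters continue through the remaining steps.

Parallelism is chunk-based: the input is split into fixed-size chunks of
whole records (whole pairs for PE/MP), chunks are processed in a thread
pool, and outputs are concatenated in chunk order. Because every method is
per-read, chunk boundaries cannot affect results, and output files are
byte-identical for every (workers, chunk_size) combination — asserted in
the tests across workers ∈ {1,2,4,8} × chunk_size ∈ {10, 10³, 10⁵}.

Configuration is validated before any data is read: parameter types per
method, qseq0 only on QSEQ input, and qseqB only at a chain position where
the prevailing encoding (tracked through switch_score steps) is +64.

## Summary report

One counter row per chain step plus TOTAL: read counts by outcome
(kept/trimmed/removed/split), daughters, widows, base counts, mean Phred
and low-quality base counts before/after. "Low quality" is Phred ≤ 10
(configurable). Mean Phred is computed over bases, not as a mean of
per-read means — the base-weighted definition is the one that composes
across merges. The identities `bases_in = bases_out + bases_removed` and
`reads_in = kept + trimmed + removed + split` hold after every update and
are property-tested under arbitrary outcome streams.

## Synthetic data

The generator emulates exactly the error modes the methods target: linear
5'→3' Phred decay (default 38 → 22, Gaussian noise sd 6, clipped to
[0, 62]) matching the Illumina pattern of 3'-concentrated errors; adapter
fragments from the bundled Illumina library injected at recorded positions
with a recorded number of substitution edits; N-runs of fixed length at
recorded positions (kept disjoint from injected adapters so each ground
truth stays exact); Phred-2 tails; chastity failures for QSEQ output. One
`numpy` Generator seeded once drives everything, so equal seeds give
byte-identical files and manifests.

It is deliberately not a sequencing simulator: no quality-dependent
substitution model, no fragment-size model, no indel errors in the read
body, no tile/cycle structure. Passing tests therefore demonstrate
correctness of the *methods* against known injected features, not
performance on any particular instrument's error profile.

## Problem sizes used in the test suite

Fixture-scale checks run on a 10,000-pair PE fixture (100 bp reads).  The
matcher is verified on 10,000 randomised instances (reads ≤ 30 bp,
artifacts ≤ 10 bp) plus the exhaustive 8-bp × 4-bp sweep described above;
Mott exhaustively on all quality vectors of length ≤ 12 over Phred
{2, 20, 40}; LQR exhaustively to length 6 over {0, 20, 40}; nsplit
exhaustively on all sequences of length ≤ 8 over {A,C,G,T,N} at
l ∈ {1,2,3} plus a 20,000-sequence seeded sample at lengths 9–10 — the
package's chosen exhaustive frontier; beyond it the combinatorial space
grows 5× per base while the code paths exercised stay the same.

## Known limitations

* No 3'-partial-overlap adapter trimming and no paired-overlap analysis.
* Mott idempotence is not an algebraic property of the no-reset
  recurrence; it is not asserted in general.
* The capped matcher is exponential in the caps in the worst case (Pareto
  sets stay tiny for realistic caps ≤ 3).
* gzip only; no bzip2/xz; no interleaved FASTQ.
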