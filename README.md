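# seqscrub

Integrated quality control and preprocessing for high-throughput
sequencing reads: a **QC → preprocess → QC** workflow in one executable.

Raw FASTQ from short-read instruments carries low-quality tails, 3'
adapter read-through, ambiguous bases, duplicates, and occasionally whole
failed sequencing batches (Illumina tiles, BGI fields of view). seqscrub
computes full statistics on the raw data, applies trimming and filtering
in a predefined order, recomputes the same statistics on the cleaned
data, and judges the *cleaned* data against preset warn/fail thresholds —
so an unsuitable preprocessing setup is visible immediately rather than
in downstream analysis. It is aimed at anyone preparing resequencing,
digital gene expression (DGE), small-RNA, or metagenomic libraries for
analysis.

## The model

**Statistics.** For a dataset of reads with bases $b_{ij}$ and Phred
scores $q_{ij}$ (read $i$, cycle $j$), seqscrub accumulates per cycle a
base-composition count vector over $\{A,C,G,T,N\}$ and a quality
histogram $h_j(q)$, plus dataset totals: read and base counts,
$\mathrm{Q20} = \Pr[q \ge 20]$, $\mathrm{Q30} = \Pr[q \ge 30]$, GC
content, and a per-reason filter tally. These accumulators form a
commutative monoid under elementwise addition, which is what makes
deterministic block-parallel execution possible: data are cut into
fixed-size blocks, each block is processed independently, and block
results are merged in block order — the output is byte-identical for any
worker count.

**Verdict.** Per-cycle quantiles are taken from $h_j$ by the
inverted-CDF (type-1) rule. On the cleaned data:

* median quality at any cycle $< 25$ → **warn**, $< 20$ → **fail**;
* $|A\% - T\%|$ or $|G\% - C\%|$ at any cycle $> 10$ percentage points →
  **warn**, $> 20$ → **fail**.

Comparisons are strict: a median of exactly 20 or a difference of
exactly 10 does not trigger.

**Preprocessing.** Per read (or pair): fixed end trimming → ungapped,
mismatch-tolerant 3' adapter localization and cutting (no indels; a hit
needs overlap ≥ 6 columns and mismatches ≤ ⌊0.1·columns⌋ by default) →
quality end trimming → the filter battery (excluded batch, adapter,
length, ambiguous-base fraction, mean quality, low-quality-base
fraction; first failing check attributed) → optional exact
sequence-identity deduplication keeping the first copy. Four modules
tailor this chain: **general** (full chain), **dge** (extract the 17-bp
tag following the CATG anchor, zero tolerance for N), **srna** (adapter
cut, poly-A contaminant removal, 18–30 nt length window), **meta**
(adapter/quality trimming with length and ambiguity filters only).

## Worked example

Generate a synthetic dataset with 10% planted adapter read-through and
2% duplicates, then clean it:

```
seqscrub fixtures generate --out demo_fx --n-reads 2000 --read-len 100 \
    --adapter AGATCGGAAGAGC --adapter-rate 0.1 --dup-rate 0.02 --seed 42
seqscrub general -1 demo_fx/reads.fq -o demo_out \
    --adapter AGATCGGAAGAGC --dedup
```

which reports on standard error

```
[seqscrub] general: 2000 reads in, 1962 out, verdict pass
```

and writes `demo_out/summary.json` containing (abridged):

```json
{
  "raw":   {"n_reads": 2000, "n_bases": 200000, "q20": 1.0,
            "q30": 0.96726,  "gc": 0.502065},
  "clean": {"n_reads": 1962, "n_bases": 185271, "q20": 1.0,
            "q30": 0.967226, "gc": 0.501384},
  "filter_tally": {"duplicate": 38},
  "verdict": {"status": "pass"}
}
```

38 duplicate reads were removed (the generator planted 2% duplicate
draws), adapter-bearing reads were trimmed back to their insert (hence
the drop from 200 000 to 185 271 bases with the read count only down by
the duplicates), and no per-cycle median or composition threshold was
crossed, so the verdict is `pass`. Alongside `summary.json` the output
directory holds clean FASTQ, per-cycle TSV tables (quality histogram,
boxplot quantiles, Q20/Q30, composition; `_raw`/`_clean` and `_1`/`_2`
variants), and a `manifest.json` recording the resolved configuration.
Exit codes: 0 completed (pass or warn), 1 usage error, 2 I/O or parse
error, 3 completed with a fail verdict.

The same machinery is available as a library:

```python
from seqscrub import AdapterSpec, default_config, run_pipeline
cfg = default_config("general", adapter=AdapterSpec("AGATCGGAAGAGC"))
result = run_pipeline(cfg, "demo_fx/reads.fq", out_dir="demo_out")
print(result.verdict.status, dict(result.clean.filter_tally))
```

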