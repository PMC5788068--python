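"""The four data-type-specific workflows: General, DGE, sRNA, Meta.

Each pipeline composes the same machinery — streaming FASTQ input, an
optional global deduplication pre-pass, block-parallel per-read
processing, mergeable statistics, threshold evaluation, report emission —
and differs only in the per-read stage and its default thresholds:

* **general** — DNA re-sequencing: fixed end trim, 3' adapter cut,
  quality end trim, the full filter battery, optional dedup and batch
  exclusion.
* **dge** — tag-based expression profiling: extract the 17-bp target
  segment next to the CATG anchor (the NlaIII restriction site), drop
  anchor-less reads and tags containing any ambiguous base.
* **srna** — small-RNA libraries: 3' adapter cut (inserts are shorter
  than the read), poly-A contaminant removal, an 18–30 nt length window,
  then quality filters.
* **meta** — metagenomics: adapter cut and quality end trim plus length
  and ambiguous-base filters only; dedup and quality-fraction filters are
  off by default but can be overridden.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

from .fastq_io import (
    PHRED33,
    FastqWriter,
    QualityEncoding,
    ReadPair,
    SequenceRead,
    _open_source,
    encoding_by_name,
    iterate_pairs,
    parse_batch_coordinate,
)
from .preprocess import (
    AdapterSpec,
    FilterSpec,
    TrimSpec,
    align_adapter,
    apply_filters,
    dedup_key,
    transform_sequence,
    trim_adapter,
    trim_fixed_ends,
    trim_low_quality_ends,
)
from .qc import (
    DatasetStats,
    QCVerdict,
    evaluate_thresholds,
    merge_stats,
    summarize,
    write_qc_report,
)
from .parallel import (
    BlockResult,
    merge_block_stats,
    process_blocks,
    split_into_blocks,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "default_config",
    "find_dge_tag",
    "is_polya",
    "run_pipeline",
    "run_general",
    "run_dge",
    "run_srna",
    "run_meta",
    "detect_file_encoding",
]

MODULES = ("general", "dge", "srna", "meta")


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    module: str = "general"
    trim: TrimSpec = field(default_factory=TrimSpec)
    adapter: Optional[AdapterSpec] = None
    adapter2: Optional[AdapterSpec] = None  # mate-2 adapter; falls back to adapter
    filters: FilterSpec = field(default_factory=FilterSpec)
    transform: Optional[str] = None  # "dna_to_rna" | "rna_to_dna"
    polya_fraction: float = 0.7
    dge_anchor: str = "CATG"
    dge_tag_len: int = 17
    keep_anchor: bool = False
    block_size: int = 100_000
    workers: int = 1
    in_encoding: Optional[str] = None  # None = auto-detect
    out_encoding: Optional[str] = None  # None = same as input
    gzip_out: bool = False
    merge_fastq: bool = True
    plots: bool = False

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}")
        if self.dge_tag_len < 1:
            raise ValueError("dge_tag_len must be >= 1")


def default_config(module: str = "general", **overrides) -> PipelineConfig:
    """Module defaults: sRNA gets the 18–30 nt length window; Meta disables
    dedup and the mean-quality / low-quality-fraction filters."""
    cfg = PipelineConfig(module=module)
    if module == "srna":
        cfg.filters = replace(cfg.filters, max_length=30)
    elif module == "meta":
        cfg.filters = replace(
            cfg.filters, min_mean_quality=0.0, max_low_qual_fraction=1.0, dedup=False
        )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown configuration key {key!r}")
        setattr(cfg, key, value)
    return cfg


def find_dge_tag(
    read: SequenceRead,
    anchor: str = "CATG",
    tag_len: int = 17,
    keep_anchor: bool = False,
) -> Optional[SequenceRead]:
    """Extract the target segment following the first anchor occurrence.

    Returns the ``tag_len`` bases immediately after the anchor (with their
    qualities); ``keep_anchor`` prepends the anchor itself. ``None`` when
    the anchor is absent or fewer than ``tag_len`` bases follow it.
    """
    pos = read.bases.upper().find(anchor.upper())
    if pos < 0:
        return None
    start = pos + len(anchor)
    stop = start + tag_len
    if stop > len(read):
        return None
    if keep_anchor:
        start = pos
    return replace(read, bases=read.bases[start:stop], quals=read.quals[start:stop])


def is_polya(read: SequenceRead, polya_fraction: float = 0.7) -> bool:
    """Poly-A contaminant test: fraction of A (case-insensitive) at or
    above the threshold; zero-length reads are never poly-A."""
    n = len(read)
    if n == 0:
        return False
    a = read.bases.count("A") + read.bases.count("a")
    return a / n >= polya_fraction


def _adapter_for_mate(config: PipelineConfig, mate: int) -> Optional[AdapterSpec]:
    if mate == 1 and config.adapter2 is not None:
        return config.adapter2
    return config.adapter


def _excluded_batch(config: PipelineConfig, pair: ReadPair):
    """Return the pair's batch coordinate if it belongs to an excluded
    batch, else None."""
    excluded = config.filters.excluded_batches
    if not excluded:
        return None
    for kind in {b.kind for b in excluded}:
        coord = parse_batch_coordinate(pair.mate1.read_id, pair.mate1.comment, kind)
        if coord is not None and coord in excluded:
            return coord
    return None


def _cut_adapter(read: SequenceRead, spec: Optional[AdapterSpec], trim_hit: bool):
    if spec is None or len(read) < spec.min_overlap:
        return read, False
    hit = align_adapter(read, spec)
    if hit is None:
        return read, False
    return (trim_adapter(read, hit) if trim_hit else read), True


def _general_stage(config: PipelineConfig, pair: ReadPair):
    """General/Meta per-pair stage: trim -> adapter -> quality end trim ->
    transform -> filter battery. Meta differs only through its defaults."""
    filters = config.filters
    batch = _excluded_batch(config, pair)
    mates = []
    found_flags = []
    for m, read in enumerate(pair.mates()):
        read = trim_fixed_ends(read, config.trim)
        read, found = _cut_adapter(
            read, _adapter_for_mate(config, m), trim_hit=not filters.drop_adapter_reads
        )
        read = trim_low_quality_ends(read, config.trim.qual_threshold)
        if config.transform:
            read = transform_sequence(read, config.transform)
        mates.append(read)
        found_flags.append(found)
    out = ReadPair(*mates) if len(mates) == 2 else ReadPair(mates[0])
    verdict = apply_filters(out, filters, tuple(found_flags), batch)
    if verdict.keep:
        return out, None
    return None, verdict.reason


def _dge_stage(config: PipelineConfig, pair: ReadPair):
    """DGE per-read stage: anchor the tag, zero-tolerance ambiguity."""
    read = pair.mate1
    tag = find_dge_tag(read, config.dge_anchor, config.dge_tag_len, config.keep_anchor)
    if tag is None:
        return None, "no_anchor"
    if "N" in tag.bases.upper():
        return None, "ambiguous_bases"
    return ReadPair(tag), None


def _srna_stage(config: PipelineConfig, pair: ReadPair):
    """sRNA per-read stage: adapter cut, poly-A drop, length window,
    quality filters."""
    read, found = _cut_adapter(pair.mate1, config.adapter, trim_hit=True)
    if is_polya(read, config.polya_fraction):
        return None, "polya"
    verdict = apply_filters(ReadPair(read), config.filters, (found,), None)
    if verdict.keep:
        return ReadPair(read), None
    return None, verdict.reason


_STAGES = {
    "general": _general_stage,
    "dge": _dge_stage,
    "srna": _srna_stage,
    "meta": _general_stage,
}


def detect_file_encoding(path, max_records: int = 1000) -> QualityEncoding:
    """Auto-detect Phred+33/Phred+64 from the first records of a file."""
    from .fastq_io import detect_quality_encoding

    def qual_lines():
        stream = _open_source(path)
        while True:
            header = stream.readline()
            if not header:
                return
            stream.readline()
            stream.readline()
            qual = stream.readline()
            yield qual.rstrip(b"\r\n")

    try:
        encoding, _ambiguous = detect_quality_encoding(qual_lines(), max_records)
    except ValueError:
        # empty or unreadable quality data: fall back to the default and let
        # the parser report any malformation with its record ordinal
        return PHRED33
    return encoding


@dataclass
class PipelineResult:
    raw: DatasetStats
    clean: DatasetStats
    verdict: QCVerdict
    summary: dict
    output_files: list[Path]
    n_written: int


def _output_paths(
    out_dir: Path, paired: bool, gzip_out: bool, block_index: Optional[int] = None
) -> list[Path]:
    ext = ".fq.gz" if gzip_out else ".fq"
    infix = "" if block_index is None else f".{block_index:03d}"
    if paired:
        return [out_dir / f"clean_1{infix}{ext}", out_dir / f"clean_2{infix}{ext}"]
    return [out_dir / f"clean{infix}{ext}"]


def _write_results_fastq(
    results: list[BlockResult],
    out_dir: Path,
    paired: bool,
    encoding: QualityEncoding,
    gzip_out: bool,
    merge_fastq: bool,
) -> tuple[list[Path], int]:
    """Write clean FASTQ in ascending block order; merged files are built
    under temporary names and moved into place atomically."""
    written: list[Path] = []
    n = 0
    if merge_fastq:
        paths = _output_paths(out_dir, paired, gzip_out)
        tmp_paths = [p.with_name(p.name + ".tmp") for p in paths]
        writers = [FastqWriter(p, encoding, gzip_out) for p in tmp_paths]
        try:
            for res in results:
                for pair in res.kept:
                    for w, read in zip(writers, pair.mates()):
                        w.write(read)
                    n += 1
        finally:
            for w in writers:
                w.close()
        for tmp, final in zip(tmp_paths, paths):
            os.replace(tmp, final)
        written.extend(paths)
    else:
        for res in results:
            paths = _output_paths(out_dir, paired, gzip_out, res.index)
            writers = [FastqWriter(p, encoding, gzip_out) for p in paths]
            try:
                for pair in res.kept:
                    for w, read in zip(writers, pair.mates()):
                        w.write(read)
                    n += 1
            finally:
                for w in writers:
                    w.close()
            written.extend(paths)
    return written, n


def run_pipeline(
    config: PipelineConfig,
    in1,
    in2=None,
    out_dir: Union[str, Path] = "seqscrub_out",
) -> PipelineResult:
    """Execute the full QC -> preprocess -> QC chain for one dataset.

    Raw statistics are taken on the input reads, the module's per-read
    stage runs block-parallel, clean statistics are taken on the output,
    thresholds are evaluated on the clean summary, and the report file set
    plus clean FASTQ are written to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.module in ("dge", "srna") and in2 is not None:
        raise ValueError(f"the {config.module} module is single-end only")

    if config.in_encoding:
        encoding = encoding_by_name(config.in_encoding)
    else:
        encoding = detect_file_encoding(in1)
    out_encoding = (
        encoding_by_name(config.out_encoding) if config.out_encoding else encoding
    )

    pairs = iterate_pairs(in1, in2, encoding)
    paired = in2 is not None

    # Deduplication is order-dependent, so it runs as a single streaming
    # pre-pass before blocking; dropped duplicates still enter raw stats.
    pre = DatasetStats()

    def dedup_pass(stream):
        seen: set[bytes] = set()
        for pair in stream:
            key = dedup_key(pair if paired else pair.mate1)
            if key in seen:
                for m, r in enumerate(pair.mates()):
                    pre.add_read(r, m)
                pre.tally("duplicate", len(pair.mates()))
                continue
            seen.add(key)
            yield pair

    if config.filters.dedup:
        pairs = dedup_pass(pairs)

    stage = _STAGES[config.module]

    def stage_fn(pair: ReadPair):
        return stage(config, pair)

    blocks = split_into_blocks(pairs, config.block_size)
    results = process_blocks(blocks, stage_fn, config.workers)

    raw, clean = merge_block_stats(results)
    raw = merge_stats(raw, DatasetStats(
        n_reads=pre.n_reads, n_bases=pre.n_bases, base_totals=pre.base_totals,
        q20_bases=pre.q20_bases, q30_bases=pre.q30_bases, position=pre.position,
    ))
    clean.filter_tally.update(pre.filter_tally)

    files, n_written = _write_results_fastq(
        results, out_dir, paired, out_encoding, config.gzip_out, config.merge_fastq
    )

    verdict = evaluate_thresholds(summarize(clean))
    summary_doc = write_qc_report(raw, clean, verdict, out_dir, plots=config.plots)
    return PipelineResult(raw, clean, verdict, summary_doc, files, n_written)


def run_general(config: PipelineConfig, in1, in2=None, out_dir="seqscrub_out"):
    assert config.module == "general"
    return run_pipeline(config, in1, in2, out_dir)


def run_dge(config: PipelineConfig, in1, out_dir="seqscrub_out"):
    assert config.module == "dge"
    return run_pipeline(config, in1, None, out_dir)


def run_srna(config: PipelineConfig, in1, out_dir="seqscrub_out"):
    assert config.module == "srna"
    return run_pipeline(config, in1, None, out_dir)


def run_meta(config: PipelineConfig, in1, in2=None, out_dir="seqscrub_out"):
    assert config.module == "meta"
    return run_pipeline(config, in1, in2, out_dir)
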