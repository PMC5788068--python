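"""Deterministic block-parallel execution.

Input pairs are cut into fixed-size blocks; each block is processed
independently (one task per block, dispatched to a thread pool) and yields
a :class:`BlockResult` carrying the kept reads plus mergeable statistics
deltas. Results are merged in ascending block index, so the output is a
pure function of (input, configuration) — identical for any worker count
and any completion order. Order-dependent stages (deduplication) run as a
streaming pre-pass before blocking and are never part of a block stage.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional

from .fastq_io import ReadPair
from .qc import DatasetStats, merge_stats

__all__ = [
    "Block",
    "BlockResult",
    "BlockProcessingError",
    "split_into_blocks",
    "process_blocks",
    "merge_block_stats",
]


@dataclass
class Block:
    """A fixed-size chunk of read pairs with its ordinal position."""

    index: int
    items: list[ReadPair]


@dataclass
class BlockResult:
    """Outcome of one block: kept pairs (input order preserved) plus the
    raw/clean statistics deltas, including the per-reason filter tally."""

    index: int
    kept: list[ReadPair]
    raw: DatasetStats
    clean: DatasetStats


class BlockProcessingError(RuntimeError):
    def __init__(self, index: int, cause: BaseException):
        super().__init__(f"processing failed in block {index}: {cause}")
        self.index = index
        self.__cause__ = cause


def split_into_blocks(
    pairs: Iterable[ReadPair], block_size: int
) -> Iterator[Block]:
    """Chunk a pair stream into consecutive blocks of ``block_size``; the
    concatenation of block items reproduces the input order exactly."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    buf: list[ReadPair] = []
    index = 0
    for pair in pairs:
        buf.append(pair)
        if len(buf) == block_size:
            yield Block(index, buf)
            buf = []
            index += 1
    if buf:
        yield Block(index, buf)


StageFn = Callable[[ReadPair], tuple[Optional[ReadPair], Optional[str]]]


def process_block(block: Block, stage_fn: StageFn) -> BlockResult:
    """Run the per-pair stage over one block, accumulating statistics.

    ``stage_fn`` maps a pair to ``(kept_pair, None)`` or ``(None, reason)``.
    Filter tallies are recorded in read units (2 per dropped pair) so that
    raw reads = clean reads + tally holds exactly.
    """
    raw = DatasetStats()
    clean = DatasetStats()
    kept: list[ReadPair] = []
    for pair in block.items:
        n_mates = len(pair.mates())
        for m, r in enumerate(pair.mates()):
            raw.add_read(r, m)
        out, reason = stage_fn(pair)
        if out is None:
            clean.tally(reason or "unspecified", n_mates)
        else:
            kept.append(out)
            for m, r in enumerate(out.mates()):
                clean.add_read(r, m)
    return BlockResult(block.index, kept, raw, clean)


def process_blocks(
    blocks: Iterable[Block],
    stage_fn: StageFn,
    workers: int = 1,
) -> list[BlockResult]:
    """Process every block and return results sorted by block index.

    The result is independent of ``workers`` and of completion order; a
    stage failure on block k raises :class:`BlockProcessingError` naming k.
    """
    results: list[BlockResult] = []
    if workers <= 1:
        for block in blocks:
            try:
                results.append(process_block(block, stage_fn))
            except Exception as exc:  # noqa: BLE001 - contract: name the block
                raise BlockProcessingError(block.index, exc) from exc
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futures = [
                (block.index, pool.submit(process_block, block, stage_fn))
                for block in blocks
            ]
            for index, fut in futures:
                try:
                    results.append(fut.result())
                except Exception as exc:  # noqa: BLE001
                    raise BlockProcessingError(index, exc) from exc
    results.sort(key=lambda r: r.index)
    indices = [r.index for r in results]
    if indices != list(range(len(results))):
        raise RuntimeError(f"incomplete block result set: {indices}")
    return results


def merge_block_stats(
    results: Iterable[BlockResult],
) -> tuple[DatasetStats, DatasetStats]:
    """Fold the per-block raw/clean deltas into whole-run statistics."""
    raw = DatasetStats()
    clean = DatasetStats()
    for res in results:
        raw = merge_stats(raw, res.raw)
        clean = merge_stats(clean, res.clean)
    return raw, clean
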