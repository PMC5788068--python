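"""Per-read preprocessing: adapter cutting, trimming, filtering, dedup.

Adapter localization is an ungapped, mismatch-tolerant scan: the adapter is
slid along the read at every offset, overhang off the 3' end is allowed,
and a candidate is accepted when the aligned columns reach ``min_overlap``
and the mismatch count stays within ``floor(rate * aligned_len)``.
Insertions and deletions are never considered. Everything from the adapter
start through the 3' end is removed.

Filters run in a fixed order so that a dropped read (or pair) is tallied
under exactly one reason, which makes the read-count conservation law
raw = clean + sum(tally) exact. All comparisons are strict: a value exactly
at a threshold never triggers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Union

from .fastq_io import BatchCoordinate, ReadPair, SequenceRead

__all__ = [
    "AdapterSpec",
    "AdapterHit",
    "TrimSpec",
    "FilterSpec",
    "FilterVerdict",
    "FILTER_ORDER",
    "align_adapter",
    "trim_adapter",
    "trim_fixed_ends",
    "trim_low_quality_ends",
    "mean_quality",
    "ambiguous_fraction",
    "low_quality_fraction",
    "apply_filters",
    "dedup_key",
    "deduplicate_stream",
    "transform_sequence",
]


@dataclass(frozen=True)
class AdapterSpec:
    """A 3' adapter and the tolerance of its ungapped alignment."""

    sequence: str
    max_mismatch_rate: float = 0.1
    min_overlap: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.max_mismatch_rate < 0.5):
            raise ValueError("max_mismatch_rate must be in [0, 0.5)")
        if not (1 <= self.min_overlap <= len(self.sequence)):
            raise ValueError("min_overlap must be in [1, adapter length]")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class AdapterHit:
    read_offset: int  # 0-based start of the adapter in the read
    aligned_len: int
    mismatches: int


@dataclass(frozen=True)
class TrimSpec:
    """Unconditional end trimming plus quality-based end trimming."""

    head_fixed: int = 0
    tail_fixed: int = 0
    qual_threshold: int = 0  # 0 disables quality end-trimming

    def __post_init__(self) -> None:
        if min(self.head_fixed, self.tail_fixed, self.qual_threshold) < 0:
            raise ValueError("trim parameters must be non-negative")


@dataclass(frozen=True)
class FilterSpec:
    """The read-filter battery and its thresholds."""

    min_length: int = 18
    max_length: Optional[int] = None  # length-window upper bound (sRNA)
    max_n_fraction: float = 0.05
    min_mean_quality: float = 0.0  # 0 disables
    low_qual_value: int = 5  # a base is "low quality" when Phred < this
    max_low_qual_fraction: float = 0.5
    drop_adapter_reads: bool = False
    excluded_batches: frozenset = frozenset()
    dedup: bool = False

    def __post_init__(self) -> None:
        for frac in (self.max_n_fraction, self.max_low_qual_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        object.__setattr__(self, "excluded_batches", frozenset(self.excluded_batches))


# reason keys, in evaluation order; `polya` and `no_anchor` are the
# module-specific additions recorded through the same tally mechanism
FILTER_ORDER = (
    "excluded_batch",
    "adapter",
    "short_length",
    "ambiguous_bases",
    "low_mean_quality",
    "low_quality_bases",
)


@dataclass(frozen=True)
class FilterVerdict:
    keep: bool
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.keep != (self.reason is None):
            raise ValueError("keep is true iff reason is none")


def align_adapter(read: SequenceRead, spec: AdapterSpec) -> Optional[AdapterHit]:
    """Locate the adapter in the read by exhaustive ungapped scanning.

    Every start offset in ``[0, len(read) - min_overlap]`` is scored; the
    alignment may overhang the 3' end. 'N' in the read counts as a
    mismatch. Among valid candidates the one with the smallest mismatch
    rate wins, ties broken by the smallest offset. Returns ``None`` when
    no candidate is valid.
    """
    bases = read.bases.upper()
    n, adapter = len(bases), spec.sequence
    m = len(adapter)
    rate, min_ov = spec.max_mismatch_rate, spec.min_overlap
    best: Optional[AdapterHit] = None
    best_rate = 2.0
    for offset in range(0, n - min_ov + 1):
        aligned_len = min(m, n - offset)
        budget = int(rate * aligned_len)
        mism = 0
        for i in range(aligned_len):
            b = bases[offset + i]
            if b != adapter[i] or b == "N":
                mism += 1
                if mism > budget:
                    break
        else:
            cand_rate = mism / aligned_len
            if cand_rate < best_rate:
                best_rate = cand_rate
                best = AdapterHit(offset, aligned_len, mism)
                if mism == 0:
                    break  # rate 0 cannot be beaten; leftmost wins ties
    return best


def trim_adapter(read: SequenceRead, hit: AdapterHit) -> SequenceRead:
    """Cut from the adapter start through the 3' end."""
    k = hit.read_offset
    return replace(read, bases=read.bases[:k], quals=read.quals[:k])


def trim_fixed_ends(read: SequenceRead, spec: TrimSpec) -> SequenceRead:
    """Remove a fixed number of bases from the 5' and 3' ends."""
    if spec.head_fixed == 0 and spec.tail_fixed == 0:
        return read
    n = len(read)
    start = min(spec.head_fixed, n)
    stop = max(start, n - spec.tail_fixed)
    return replace(read, bases=read.bases[start:stop], quals=read.quals[start:stop])


def trim_low_quality_ends(read: SequenceRead, qual_threshold: int) -> SequenceRead:
    """Strip terminal bases whose quality is below the threshold, from both
    ends inward; interior bases are never touched."""
    if qual_threshold <= 0:
        return read
    q = read.quals
    start, stop = 0, len(q)
    while start < stop and q[start] < qual_threshold:
        start += 1
    while stop > start and q[stop - 1] < qual_threshold:
        stop -= 1
    if start == 0 and stop == len(q):
        return read
    return replace(read, bases=read.bases[start:stop], quals=read.quals[start:stop])


def mean_quality(read: SequenceRead) -> float:
    """Arithmetic mean Phred score; requires a nonempty read."""
    return sum(read.quals) / len(read.quals)


def ambiguous_fraction(read: SequenceRead) -> float:
    bases = read.bases
    return (bases.count("N") + bases.count("n")) / len(bases)


def low_quality_fraction(read: SequenceRead, low_qual_value: int) -> float:
    """Fraction of bases with Phred strictly below ``low_qual_value``."""
    return sum(1 for q in read.quals if q < low_qual_value) / len(read.quals)


def apply_filters(
    item: Union[SequenceRead, ReadPair],
    spec: FilterSpec,
    adapter_found: tuple[bool, ...] = (False,),
    batch: Optional[BatchCoordinate] = None,
) -> FilterVerdict:
    """Run the filter battery in fixed order; the first failure wins.

    For a pair, a check fails when EITHER mate fails it, and one verdict
    covers the pair (no orphan output). Zero-length reads fall through to
    the length filter.
    """
    mates = item.mates() if isinstance(item, ReadPair) else (item,)

    if batch is not None and batch in spec.excluded_batches:
        return FilterVerdict(False, "excluded_batch")
    if spec.drop_adapter_reads and any(adapter_found):
        return FilterVerdict(False, "adapter")
    for r in mates:
        if len(r) < spec.min_length:
            return FilterVerdict(False, "short_length")
        if spec.max_length is not None and len(r) > spec.max_length:
            return FilterVerdict(False, "short_length")  # length-window drop
    for r in mates:
        if ambiguous_fraction(r) > spec.max_n_fraction:
            return FilterVerdict(False, "ambiguous_bases")
    if spec.min_mean_quality > 0:
        for r in mates:
            if mean_quality(r) < spec.min_mean_quality:
                return FilterVerdict(False, "low_mean_quality")
    for r in mates:
        if low_quality_fraction(r, spec.low_qual_value) > spec.max_low_qual_fraction:
            return FilterVerdict(False, "low_quality_bases")
    return FilterVerdict(True, None)


def dedup_key(item: Union[SequenceRead, ReadPair]) -> bytes:
    """128-bit digest of the uppercase nucleotide content; qualities and
    read names are ignored, so identical sequences collide by design."""
    if isinstance(item, ReadPair):
        payload = item.mate1.bases.upper()
        if item.mate2 is not None:
            payload += "\x00" + item.mate2.bases.upper()
    else:
        payload = item.bases.upper()
    return hashlib.md5(payload.encode("ascii")).digest()


def deduplicate_stream(
    items: Iterable[Union[SequenceRead, ReadPair]],
    enabled: bool = True,
    on_duplicate=None,
) -> Iterator[Union[SequenceRead, ReadPair]]:
    """Keep the first occurrence of each nucleotide sequence, in order.

    ``on_duplicate``, when given, is called once per dropped item (used by
    the pipelines to tally the ``duplicate`` reason). Disabled, this is the
    identity.
    """
    if not enabled:
        yield from items
        return
    seen: set[bytes] = set()
    for item in items:
        key = dedup_key(item)
        if key in seen:
            if on_duplicate is not None:
                on_duplicate(item)
            continue
        seen.add(key)
        yield item


_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")


def transform_sequence(read: SequenceRead, mode: str) -> SequenceRead:
    """DNA<->RNA interconversion: T<->U, all else (and qualities) untouched."""
    if mode == "dna_to_rna":
        table = _DNA_TO_RNA
    elif mode == "rna_to_dna":
        table = _RNA_TO_DNA
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    new = read.bases.translate(table)
    if new == read.bases:
        return read
    return replace(read, bases=new)
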