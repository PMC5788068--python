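"""Streaming FASTQ input/output with Phred+33/Phred+64 handling.

Reads are represented with numeric Phred scores; the serialization offset
(33 or 64) is carried alongside so that encoding conversion is a pure
re-serialization and never changes a quality value. Only the 4-line FASTQ
dialect is supported, which covers modern instrument output. Gzip input is
detected from the RFC 1952 magic bytes; output is gzip-compressed when
requested or when the destination filename ends in ``.gz``.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

__all__ = [
    "QualityEncoding",
    "PHRED33",
    "PHRED64",
    "SequenceRead",
    "ReadPair",
    "BatchCoordinate",
    "FastqParseError",
    "PairSyncError",
    "parse_fastq_stream",
    "open_fastq",
    "write_fastq",
    "FastqWriter",
    "detect_quality_encoding",
    "convert_quality_encoding",
    "parse_batch_coordinate",
    "iterate_pairs",
    "strip_mate_suffix",
]

# highest Phred score representable as printable ASCII under Phred+33
MAX_PHRED = 93

GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class QualityEncoding:
    """A FASTQ quality serialization: Phred score + offset -> ASCII."""

    name: str
    offset: int

    def __post_init__(self) -> None:
        if self.offset not in (33, 64):
            raise ValueError(f"quality offset must be 33 or 64, got {self.offset}")


PHRED33 = QualityEncoding("phred33", 33)
PHRED64 = QualityEncoding("phred64", 64)

_ENCODINGS = {"phred33": PHRED33, "phred64": PHRED64}


def encoding_by_name(name: str) -> QualityEncoding:
    try:
        return _ENCODINGS[name]
    except KeyError:
        raise ValueError(f"unknown quality encoding {name!r}") from None


@dataclass(frozen=True)
class SequenceRead:
    """One FASTQ record.

    ``quals`` holds numeric Phred scores as a ``bytes`` object (one score
    per base, values 0..93); it is independent of the serialization offset
    recorded in ``source_encoding``.
    """

    read_id: str
    bases: str
    quals: bytes
    comment: str = ""
    source_encoding: QualityEncoding = PHRED33

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def stripped_id(self) -> str:
        return strip_mate_suffix(self.read_id)


@dataclass(frozen=True)
class ReadPair:
    """A mate pair; ``mate2`` is ``None`` for single-end data."""

    mate1: SequenceRead
    mate2: Optional[SequenceRead] = None

    def __post_init__(self) -> None:
        if self.mate2 is not None:
            a, b = self.mate1.stripped_id, self.mate2.stripped_id
            if a != b:
                raise PairSyncError(f"mate IDs disagree: {a!r} vs {b!r}")

    @property
    def is_paired(self) -> bool:
        return self.mate2 is not None

    def mates(self) -> tuple[SequenceRead, ...]:
        return (self.mate1,) if self.mate2 is None else (self.mate1, self.mate2)


_FOV_RE = re.compile(r"C\d+R\d+")


@dataclass(frozen=True)
class BatchCoordinate:
    """A sequencing batch: an Illumina tile or a BGI field of view (fov)."""

    kind: str  # "tile" | "fov"
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("tile", "fov"):
            raise ValueError(f"batch kind must be 'tile' or 'fov', got {self.kind!r}")


class FastqParseError(ValueError):
    """Malformed FASTQ; carries the 1-based ordinal of the offending record."""

    def __init__(self, message: str, record_ordinal: int):
        super().__init__(f"record {record_ordinal}: {message}")
        self.record_ordinal = record_ordinal


class PairSyncError(ValueError):
    """Paired-end mate files are out of step."""


def strip_mate_suffix(read_id: str) -> str:
    """Drop a trailing ``/1`` or ``/2`` mate tag from a read name."""
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


def _open_source(source: Union[str, Path, IO[bytes]]) -> IO[bytes]:
    if isinstance(source, (str, Path)):
        handle: IO[bytes] = open(source, "rb")
    else:
        handle = source
    buffered = handle if isinstance(handle, io.BufferedReader) else io.BufferedReader(handle)  # type: ignore[arg-type]
    if buffered.peek(2)[:2] == GZIP_MAGIC:
        return gzip.open(buffered, "rb")  # type: ignore[return-value]
    return buffered


def parse_fastq_stream(
    source: Union[str, Path, IO[bytes]],
    encoding: QualityEncoding = PHRED33,
) -> Iterator[SequenceRead]:
    """Lazily yield reads from 4-line FASTQ, plain or gzipped.

    Quality characters are decoded by subtracting ``encoding.offset``.
    Raises :class:`FastqParseError` naming the 1-based record ordinal on a
    truncated record, a missing ``@``/``+`` sentinel, or a base/quality
    length mismatch.
    """
    stream = _open_source(source)
    offset = encoding.offset
    ordinal = 0
    while True:
        header = stream.readline()
        if not header:
            return
        ordinal += 1
        seq = stream.readline()
        plus = stream.readline()
        qual = stream.readline()
        if not qual and not (seq and plus):
            raise FastqParseError("truncated record", ordinal)
        header = header.rstrip(b"\r\n")
        seq = seq.rstrip(b"\r\n")
        plus = plus.rstrip(b"\r\n")
        qual = qual.rstrip(b"\r\n")
        if not header.startswith(b"@"):
            raise FastqParseError("expected '@' at start of header", ordinal)
        if not plus.startswith(b"+"):
            raise FastqParseError("expected '+' separator line", ordinal)
        name_part = header[1:].decode("ascii")
        read_id, _, comment = name_part.partition(" ")
        if len(seq) != len(qual):
            raise FastqParseError(
                f"{len(seq)} bases but {len(qual)} quality characters", ordinal
            )
        quals = bytes(c - offset for c in qual)
        if any(q > MAX_PHRED for q in quals):
            raise FastqParseError("quality value above Phred 93", ordinal)
        if offset > 33 and any(c < offset for c in qual):
            raise FastqParseError(
                "quality character below the declared encoding offset", ordinal
            )
        yield SequenceRead(
            read_id=read_id,
            bases=seq.decode("ascii"),
            quals=quals,
            comment=comment,
            source_encoding=encoding,
        )


# alias used by the pipelines; reads a path and returns the lazy iterator
open_fastq = parse_fastq_stream


def serialize_read(read: SequenceRead, encoding: QualityEncoding) -> bytes:
    offset = encoding.offset
    if any(q + offset > 126 for q in read.quals):
        raise ValueError(
            f"read {read.read_id!r}: quality not representable under {encoding.name}"
        )
    header = "@" + read.read_id + (" " + read.comment if read.comment else "")
    qual_str = bytes(q + offset for q in read.quals)
    return b"\n".join(
        (header.encode("ascii"), read.bases.encode("ascii"), b"+", qual_str, b"")
    )


class FastqWriter:
    """Incremental FASTQ writer; counts records; optional gzip output."""

    def __init__(
        self,
        sink: Union[str, Path, IO[bytes]],
        encoding: QualityEncoding = PHRED33,
        gzip_out: Optional[bool] = None,
    ):
        name = str(sink) if isinstance(sink, (str, Path)) else getattr(sink, "name", "")
        if gzip_out is None:
            gzip_out = str(name).endswith(".gz")
        if isinstance(sink, (str, Path)):
            raw: IO[bytes] = open(sink, "wb")
            self._owns = True
        else:
            raw = sink
            self._owns = False
        self._raw = raw
        self._stream: IO[bytes] = gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) if gzip_out else raw  # type: ignore[assignment]
        self._gzip = gzip_out
        self.encoding = encoding
        self.count = 0

    def write(self, read: SequenceRead) -> None:
        self._stream.write(serialize_read(read, self.encoding))
        self.count += 1

    def close(self) -> None:
        if self._gzip:
            self._stream.close()
        if self._owns:
            self._raw.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_fastq(
    reads: Iterable[SequenceRead],
    sink: Union[str, Path, IO[bytes]],
    encoding: QualityEncoding = PHRED33,
    gzip_out: Optional[bool] = None,
) -> int:
    """Write reads as canonical 4-line FASTQ; returns the record count."""
    with FastqWriter(sink, encoding, gzip_out) as writer:
        for read in reads:
            writer.write(read)
        return writer.count


def detect_quality_encoding(
    quality_strings: Iterable[bytes],
    max_records: int = 10000,
) -> tuple[QualityEncoding, bool]:
    """Infer the quality encoding from raw quality lines.

    Any character with ASCII < 59 proves Phred+33 (it would decode to a
    negative score under +64). If every character is >= 64 and at least one
    exceeds 74 the sample is taken as Phred+64. Otherwise the two encodings
    cannot be distinguished and Phred+33 is returned with the ambiguity
    flag set. Returns ``(encoding, ambiguous)``.
    """
    lo, hi = 255, 0
    seen = False
    for i, qs in enumerate(quality_strings):
        if i >= max_records:
            break
        if qs:
            seen = True
            lo = min(lo, min(qs))
            hi = max(hi, max(qs))
    if not seen:
        raise ValueError("no quality data available for encoding detection")
    if lo < 59:
        return PHRED33, False
    if lo >= 64 and hi > 74:
        return PHRED64, False
    return PHRED33, True


def convert_quality_encoding(
    read: SequenceRead, target: QualityEncoding
) -> SequenceRead:
    """Re-tag a read with a new serialization offset; scores are untouched."""
    if read.source_encoding == target:
        return read
    return replace(read, source_encoding=target)


def parse_batch_coordinate(
    read_id: str, comment: str = "", kind: str = "tile"
) -> Optional[BatchCoordinate]:
    """Extract the sequencing-batch label from a read name.

    Tiles follow the CASAVA >= 1.8 convention: the 5th colon-delimited
    field of the name. BGI fovs are the first ``C<digits>R<digits>``
    substring. Returns ``None`` when the pattern is absent.
    """
    if kind == "tile":
        fields = read_id.split(":")
        if len(fields) >= 5:
            return BatchCoordinate("tile", fields[4])
        return None
    if kind == "fov":
        m = _FOV_RE.search(read_id)
        if m:
            return BatchCoordinate("fov", m.group(0))
        return None
    raise ValueError(f"batch kind must be 'tile' or 'fov', got {kind!r}")


def iterate_pairs(
    in1: Union[str, Path, IO[bytes]],
    in2: Optional[Union[str, Path, IO[bytes]]] = None,
    encoding: QualityEncoding = PHRED33,
) -> Iterator[ReadPair]:
    """Stream read pairs, zipping two mate files for paired-end data.

    Mate names must agree after stripping a trailing ``/1``/``/2`` and the
    header comment; a desynchronization raises :class:`PairSyncError` at
    the first offending record, as do mate files of unequal length.
    """
    stream1 = parse_fastq_stream(in1, encoding)
    if in2 is None:
        for read in stream1:
            yield ReadPair(read)
        return
    stream2 = parse_fastq_stream(in2, encoding)
    ordinal = 0
    while True:
        r1 = next(stream1, None)
        r2 = next(stream2, None)
        ordinal += 1
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise PairSyncError(
                f"mate files have unequal record counts (at record {ordinal})"
            )
        if r1.stripped_id != r2.stripped_id:
            raise PairSyncError(
                f"record {ordinal}: mate IDs disagree: "
                f"{r1.stripped_id!r} vs {r2.stripped_id!r}"
            )
        yield ReadPair(r1, r2)
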