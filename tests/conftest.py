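import math
from pathlib import Path

import pytest

from seqscrub.fastq_io import PHRED33, SequenceRead, write_fastq
from seqscrub.preprocess import AdapterSpec


def make_read(bases, quals=None, read_id="r", comment="", encoding=PHRED33):
    if quals is None:
        quals = [30] * len(bases)
    return SequenceRead(read_id, bases, bytes(quals), comment, encoding)


def type1_quantile(sorted_values, q):
    """Brute-force inverted-CDF quantile: the ceil(q*n)-th order statistic."""
    n = len(sorted_values)
    k = max(1, math.ceil(q * n))
    return sorted_values[k - 1]


def naive_adapter_scan(bases, adapter, max_mismatch_rate, min_overlap):
    """Independent exhaustive ungapped adapter scorer (oracle).

    Tries every offset, counts mismatches over the full aligned span
    (overhang allowed, N counts as a mismatch), collects valid candidates
    and picks smallest mismatch rate, ties by smallest offset. Returns
    (offset, aligned_len, mismatches) or None.
    """
    bases = bases.upper()
    adapter = adapter.upper()
    n, m = len(bases), len(adapter)
    candidates = []
    for offset in range(0, n - min_overlap + 1):
        aligned_len = min(m, n - offset)
        if aligned_len < min_overlap:
            continue
        mism = 0
        for i in range(aligned_len):
            b = bases[offset + i]
            if b != adapter[i] or b == "N":
                mism += 1
        if mism <= math.floor(max_mismatch_rate * aligned_len):
            candidates.append((mism / aligned_len, offset, aligned_len, mism))
    if not candidates:
        return None
    rate, offset, aligned_len, mism = min(candidates)
    return (offset, aligned_len, mism)


@pytest.fixture()
def adapter_spec():
    return AdapterSpec("AGATCGGAAGAGC", max_mismatch_rate=0.1, min_overlap=6)


@pytest.fixture()
def fastq_file(tmp_path):
    def _write(reads, name="reads.fq", encoding=PHRED33, gzip_out=None):
        path = tmp_path / name
        write_fastq(reads, path, encoding, gzip_out)
        return path

    return _write
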