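"""Seeded synthetic-FASTQ generation with byte-exact ground truth.

Every dataset is fully determined by its seed. The generator plants the
structures the pipelines are meant to recover — 3' adapter contamination
at recorded offsets, exact duplicates of earlier reads, CATG-anchored DGE
tags, short sRNA inserts that read through into the adapter, poly-A
contaminants, per-position quality medians, and per-position composition
bias — and emits a sidecar ground-truth table (one row per read) so tests
can compare recovered against planted values read-by-read.

Quality scores come from a symmetric discretized normal around the target
median, so the per-position median recovers the target exactly in
expectation. This emulates instrument-like quality profiles and planted
artifacts only; it does not model platform-specific error spectra,
indels, or genome-derived sequence composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fastq_io import PHRED33, ReadPair, SequenceRead, write_fastq
from .preprocess import AdapterSpec

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_reads",
    "generate",
    "median_boundary_reads",
    "composition_scan_reads",
    "worked_example_corpus",
]

BASES = "ACGT"
MAX_SIM_QUAL = 41  # instrument-style ceiling
MIN_SIM_QUAL = 2


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; ``seed`` fixes every byte."""

    n_reads: int = 1000
    read_len: int = 100
    paired: bool = False
    qual_median: Union[int, Sequence[int]] = 35
    qual_spread: float = 3.0
    adapter: Optional[AdapterSpec] = None
    adapter_rate: float = 0.0
    adapter_offset_range: tuple[int, int] = (20, 80)  # inclusive bounds
    dup_rate: float = 0.0
    n_rate: float = 0.0
    composition_bias: Optional[dict[int, float]] = None  # 0-based pos -> A-T pct pts
    module_structure: Optional[str] = None  # None | "dge" | "srna"
    dge_anchor: str = "CATG"
    dge_tag_len: int = 17
    srna_insert_range: tuple[int, int] = (18, 30)
    srna_contaminant_rate: float = 0.0
    polya_fraction: float = 0.7
    tiles: tuple[str, ...] = ("1101", "1102")
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.adapter_rate, self.dup_rate, self.n_rate,
                     self.srna_contaminant_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.adapter is not None and self.adapter_rate > 0:
            lo, hi = self.adapter_offset_range
            if not (0 <= lo <= hi < self.read_len):
                raise ValueError(
                    "adapter_offset_range must fit inside the read"
                )
        if self.module_structure == "srna":
            lo, hi = self.srna_insert_range
            if self.adapter is None:
                raise ValueError("srna structure requires an adapter to fill with")
            if hi >= self.read_len:
                raise ValueError("srna inserts must be shorter than the read")


@dataclass
class GroundTruthRow:
    index: int
    read_id: str
    adapter_offset: int = -1  # -1 = no planted adapter
    duplicate_of: int = -1  # ordinal of the copied read, -1 = unique
    tag: str = ""  # planted DGE tag
    insert_len: int = -1  # planted sRNA insert length
    polya: bool = False  # planted poly-A contaminant


@dataclass
class GroundTruth:
    rows: list[GroundTruthRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows]).set_index("index")

    def write(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _qual_targets(spec: FixtureSpec) -> np.ndarray:
    if np.isscalar(spec.qual_median):
        return np.full(spec.read_len, int(spec.qual_median))
    targets = np.asarray(spec.qual_median, dtype=int)
    if len(targets) != spec.read_len:
        raise ValueError("per-position qual_median must have read_len entries")
    return targets


def _sample_quals(rng: np.random.Generator, targets: np.ndarray, spread: float) -> bytes:
    jitter = np.rint(rng.normal(0.0, spread, size=len(targets))).astype(int)
    q = np.clip(targets + jitter, MIN_SIM_QUAL, MAX_SIM_QUAL)
    return bytes(int(v) for v in q)


def _sample_bases(rng: np.random.Generator, spec: FixtureSpec) -> list[str]:
    probs = np.full((spec.read_len, 4), 0.25)
    if spec.composition_bias:
        for pos, delta in spec.composition_bias.items():
            shift = delta / 200.0  # pct points -> fraction, split between A and T
            probs[pos] = (0.25 + shift, 0.25, 0.25, 0.25 - shift)
    u = rng.random(spec.read_len)
    cum = probs.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return [BASES[i] for i in idx]


def _scrub_anchor(bases: list[str], anchor: str, planted_at: int, rng) -> None:
    """Mutate any anchor occurrence before the planted one so the planted
    occurrence is the first."""
    text = "".join(bases)
    pos = text.find(anchor)
    while 0 <= pos < planted_at:
        repl = BASES[(BASES.index(bases[pos]) + 1) % 4]
        bases[pos] = repl
        text = "".join(bases)
        pos = text.find(anchor)


def generate_reads(spec: FixtureSpec) -> tuple[list[ReadPair], GroundTruth]:
    """Build the dataset in memory; same spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    targets = _qual_targets(spec)
    truth = GroundTruth()
    pairs: list[ReadPair] = []
    mate_bank: list[tuple[str, ...]] = []  # bases per mate, for duplicates

    for i in range(spec.n_reads):
        tile = spec.tiles[i % len(spec.tiles)]
        read_id = f"SIM:1:FC1:1:{tile}:{i}:{i}"
        row = GroundTruthRow(index=i, read_id=read_id)

        dup = spec.dup_rate > 0 and i > 0 and rng.random() < spec.dup_rate
        if dup:
            src = int(rng.integers(0, i))
            row.duplicate_of = src
            row.adapter_offset = truth.rows[src].adapter_offset
            row.tag = truth.rows[src].tag
            row.insert_len = truth.rows[src].insert_len
            row.polya = truth.rows[src].polya
            mates = tuple(
                SequenceRead(read_id, b, _sample_quals(rng, targets[: len(b)],
                                                       spec.qual_spread))
                for b in mate_bank[src]
            )
            mate_bank.append(mate_bank[src])
            pairs.append(ReadPair(*mates))
            truth.rows.append(row)
            continue

        mate_bases: list[str] = []
        for _mate in range(2 if spec.paired else 1):
            bases = _sample_bases(rng, spec)
            if spec.n_rate > 0:
                mask = rng.random(spec.read_len) < spec.n_rate
                for j in np.nonzero(mask)[0]:
                    bases[j] = "N"

            if spec.module_structure == "dge":
                anchor, tag_len = spec.dge_anchor, spec.dge_tag_len
                prefix_len = int(rng.integers(0, spec.read_len - len(anchor) - tag_len + 1))
                tag = "".join(BASES[k] for k in rng.integers(0, 4, tag_len))
                seq = bases[:prefix_len] + list(anchor) + list(tag)
                seq += bases[len(seq): spec.read_len]
                _scrub_anchor(seq, anchor, prefix_len, rng)
                bases = seq
                if _mate == 0:
                    row.tag = tag
            elif spec.module_structure == "srna":
                if rng.random() < spec.srna_contaminant_rate:
                    n_a = int(np.ceil(spec.polya_fraction * spec.read_len))
                    a_pos = rng.choice(spec.read_len, size=n_a, replace=False)
                    for j in a_pos:
                        bases[j] = "A"
                    row.polya = True
                else:
                    lo, hi = spec.srna_insert_range
                    insert_len = int(rng.integers(lo, hi + 1))
                    adapter_seq = spec.adapter.sequence
                    tail = (adapter_seq * (spec.read_len // len(adapter_seq) + 2))
                    seq = bases[:insert_len] + list(tail[: spec.read_len - insert_len])
                    bases = seq
                    row.insert_len = insert_len
                    row.adapter_offset = insert_len
            elif (
                spec.adapter is not None
                and spec.adapter_rate > 0
                and rng.random() < spec.adapter_rate
            ):
                lo, hi = spec.adapter_offset_range
                offset = int(rng.integers(lo, hi + 1))
                adapter_seq = spec.adapter.sequence
                fill = adapter_seq[: spec.read_len - offset]
                bases = bases[:offset] + list(fill) + bases[offset + len(fill):]
                if _mate == 0:
                    row.adapter_offset = offset

            mate_bases.append("".join(bases))

        mates = tuple(
            SequenceRead(read_id, b, _sample_quals(rng, targets[: len(b)],
                                                   spec.qual_spread))
            for b in mate_bases
        )
        mate_bank.append(tuple(mate_bases))
        pairs.append(ReadPair(*mates))
        truth.rows.append(row)

    return pairs, truth


def generate(spec: FixtureSpec, out_dir: Union[str, Path]) -> dict:
    """Write the dataset as FASTQ plus a ground-truth TSV sidecar.

    Returns a manifest dict naming the emitted files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs, truth = generate_reads(spec)
    files = {}
    if spec.paired:
        f1, f2 = out_dir / "reads_1.fq", out_dir / "reads_2.fq"
        write_fastq((p.mate1 for p in pairs), f1, PHRED33)
        write_fastq((p.mate2 for p in pairs), f2, PHRED33)
        files["reads_1"], files["reads_2"] = str(f1), str(f2)
    else:
        f1 = out_dir / "reads.fq"
        write_fastq((p.mate1 for p in pairs), f1, PHRED33)
        files["reads"] = str(f1)
    truth_path = out_dir / "ground_truth.tsv"
    truth.write(truth_path)
    files["ground_truth"] = str(truth_path)
    manifest = {"files": files, "n_reads": spec.n_reads, "seed": spec.seed}
    with open(out_dir / "fixture_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def median_boundary_reads(
    n_reads: int = 1000,
    read_len: int = 20,
    position: int = 10,
    median_q: int = 30,
    baseline_q: int = 35,
) -> list[SequenceRead]:
    """Deterministic dataset whose designated position has an exact median.

    Half the reads carry ``median_q`` at the position and half ``median_q
    + 5``; under the inverted-CDF rule the per-position median is exactly
    ``median_q``. All other positions sit at ``baseline_q`` and the base
    composition is balanced, so only the designated position can trigger a
    quality finding.
    """
    if n_reads % 4:
        raise ValueError("n_reads must be divisible by 4 for exact balance")
    reads = []
    for i in range(n_reads):
        bases = "".join(BASES[(i + j) % 4] for j in range(read_len))
        quals = bytearray([baseline_q] * read_len)
        quals[position] = median_q if i < n_reads // 2 else min(median_q + 5, 93)
        reads.append(SequenceRead(f"MB:{i}", bases, bytes(quals)))
    return reads


def composition_scan_reads(
    n_reads: int = 1000,
    read_len: int = 20,
    position: int = 10,
    delta_pct: int = 0,
    qual: int = 35,
) -> list[SequenceRead]:
    """Deterministic dataset with an exact A-vs-T imbalance at one position.

    At the designated position A% = 50 + delta/2 and T% = 50 - delta/2
    (no G or C there); every other position carries 25% of each base, so
    only the designated position can trigger a composition finding.
    ``n_reads`` must make the counts exact (1000 works for integer
    deltas).
    """
    n_a = round(n_reads * (50 + delta_pct / 2) / 100)
    n_t = n_reads - n_a
    if n_a != n_reads * (50 + delta_pct / 2) / 100 or n_reads % 4:
        raise ValueError("n_reads incompatible with an exact imbalance")
    reads = []
    quals = bytes([qual] * read_len)
    for i in range(n_reads):
        bases = list(BASES[(i + j) % 4] for j in range(read_len))
        bases[position] = "A" if i < n_a else "T"
        reads.append(SequenceRead(f"CS:{i}", "".join(bases), quals))
    return reads


def worked_example_corpus(out_dir: Union[str, Path], seed: int = 7) -> dict:
    """Small per-module corpora (<=100 reads each) with planted structure,
    suitable as regression inputs; returns {module: fixture manifest}."""
    out_dir = Path(out_dir)
    adapter = AdapterSpec("AGATCGGAAGAGC")
    specs = {
        "general": FixtureSpec(
            n_reads=100, read_len=80, paired=True, adapter=adapter,
            adapter_rate=0.2, adapter_offset_range=(25, 70), dup_rate=0.1,
            n_rate=0.002, seed=seed,
        ),
        "dge": FixtureSpec(
            n_reads=100, read_len=49, module_structure="dge", seed=seed + 1,
        ),
        "srna": FixtureSpec(
            n_reads=100, read_len=49, module_structure="srna", adapter=adapter,
            srna_contaminant_rate=0.1, seed=seed + 2,
        ),
        "meta": FixtureSpec(
            n_reads=100, read_len=80, adapter=adapter, adapter_rate=0.15,
            adapter_offset_range=(25, 70), n_rate=0.01, seed=seed + 3,
        ),
    }
    return {
        module: generate(spec, out_dir / module) for module, spec in specs.items()
    }
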