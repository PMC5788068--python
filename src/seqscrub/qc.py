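"""Two-pass quality control: mergeable statistics, thresholds, reports.

Statistics are accumulated once per read into :class:`DatasetStats`, a
monoid under :func:`merge_stats` — block-level partial statistics can be
summed in any grouping and always equal the statistics of the whole run.
Per-position quantities (quality histogram, base composition) live in
:class:`PositionStats`; whole-dataset counters (reads, bases, Q20/Q30,
filter tallies) live alongside.

The warn/fail verdict is computed on the statistics of the *preprocessed*
data: a position whose median quality drops below 25 warns and below 20
fails; an A-versus-T or G-versus-C imbalance above 10 percentage points
warns and above 20 fails. Exactly-at-threshold values do not trigger.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fastq_io import MAX_PHRED, SequenceRead

__all__ = [
    "PositionStats",
    "DatasetStats",
    "Finding",
    "QCVerdict",
    "PositionSummary",
    "DatasetSummary",
    "accumulate_read",
    "merge_stats",
    "summarize",
    "summarize_positions",
    "evaluate_thresholds",
    "write_qc_report",
    "MEDIAN_FAIL",
    "MEDIAN_WARN",
    "COMPOSITION_FAIL",
    "COMPOSITION_WARN",
]

# verdict cut points (Phred units / percentage points); strict inequalities
MEDIAN_FAIL = 20
MEDIAN_WARN = 25
COMPOSITION_FAIL = 20.0
COMPOSITION_WARN = 10.0

BASE_ORDER = "ACGTN"
_N_QUAL = MAX_PHRED + 1

# 256-entry lookup: base byte -> row index in base_counts; U counts as T
# (RNA-transformed reads), anything unrecognized counts as N.
_BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER[:4]):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i
_BASE_INDEX[ord("U")] = 3
_BASE_INDEX[ord("u")] = 3


class PositionStats:
    """Per-cycle base counts and quality histograms; the mergeable QC unit.

    ``base_counts`` has shape (5, L) over rows A, C, G, T, N and
    ``qual_hist`` shape (94, L) over Phred values 0..93, where L grows to
    the longest read seen. Positions are 0-based internally; all reported
    coordinates are 1-based cycle numbers.
    """

    __slots__ = ("base_counts", "qual_hist")

    def __init__(self) -> None:
        self.base_counts = np.zeros((5, 0), dtype=np.int64)
        self.qual_hist = np.zeros((_N_QUAL, 0), dtype=np.int64)

    @property
    def max_len(self) -> int:
        return self.base_counts.shape[1]

    def _grow(self, length: int) -> None:
        if length > self.max_len:
            pad = length - self.max_len
            self.base_counts = np.pad(self.base_counts, ((0, 0), (0, pad)))
            self.qual_hist = np.pad(self.qual_hist, ((0, 0), (0, pad)))

    def add_read(self, read: SequenceRead) -> None:
        n = len(read)
        if n == 0:
            return
        self._grow(n)
        cols = np.arange(n)
        base_idx = _BASE_INDEX[np.frombuffer(read.bases.encode("ascii"), np.uint8)]
        self.base_counts[base_idx, cols] += 1
        qual_idx = np.frombuffer(read.quals, np.uint8)
        self.qual_hist[qual_idx, cols] += 1

    def merge(self, other: "PositionStats") -> "PositionStats":
        out = PositionStats()
        length = max(self.max_len, other.max_len)
        out._grow(length)
        out.base_counts[:, : self.max_len] += self.base_counts
        out.base_counts[:, : other.max_len] += other.base_counts
        out.qual_hist[:, : self.max_len] += self.qual_hist
        out.qual_hist[:, : other.max_len] += other.qual_hist
        return out

    def depth(self) -> np.ndarray:
        """Reads covering each position."""
        return self.base_counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionStats):
            return NotImplemented
        return (
            self.max_len == other.max_len
            and np.array_equal(self.base_counts, other.base_counts)
            and np.array_equal(self.qual_hist, other.qual_hist)
        )


@dataclass
class DatasetStats:
    """Whole-dataset summary counters plus per-mate position statistics."""

    n_reads: int = 0
    n_bases: int = 0
    base_totals: Counter = field(default_factory=Counter)
    q20_bases: int = 0
    q30_bases: int = 0
    filter_tally: Counter = field(default_factory=Counter)
    position: dict[int, PositionStats] = field(default_factory=dict)

    def mate_stats(self, mate: int) -> PositionStats:
        if mate not in self.position:
            self.position[mate] = PositionStats()
        return self.position[mate]

    def add_read(self, read: SequenceRead, mate: int = 0) -> None:
        self.n_reads += 1
        n = len(read)
        self.n_bases += n
        ps = self.mate_stats(mate)
        ps.add_read(read)
        if n:
            q = np.frombuffer(read.quals, np.uint8)
            self.q20_bases += int((q >= 20).sum())
            self.q30_bases += int((q >= 30).sum())
            idx = _BASE_INDEX[np.frombuffer(read.bases.encode("ascii"), np.uint8)]
            counts = np.bincount(idx, minlength=5)
            for i, b in enumerate(BASE_ORDER):
                if counts[i]:
                    self.base_totals[b] += int(counts[i])

    def tally(self, reason: str, count: int = 1) -> None:
        self.filter_tally[reason] += count

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetStats):
            return NotImplemented
        return (
            self.n_reads == other.n_reads
            and self.n_bases == other.n_bases
            and self.base_totals == other.base_totals
            and self.q20_bases == other.q20_bases
            and self.q30_bases == other.q30_bases
            and self.filter_tally == other.filter_tally
            and {k: v for k, v in self.position.items() if v.max_len}
            == {k: v for k, v in other.position.items() if v.max_len}
        )


def accumulate_read(stats: DatasetStats, read: SequenceRead, mate: int = 0) -> DatasetStats:
    """Fold one read into the counters; returns the successor state."""
    stats.add_read(read, mate)
    return stats


def merge_stats(a: DatasetStats, b: DatasetStats) -> DatasetStats:
    """Elementwise sum of every counter; associative, with the empty
    :class:`DatasetStats` as identity."""
    out = DatasetStats(
        n_reads=a.n_reads + b.n_reads,
        n_bases=a.n_bases + b.n_bases,
        base_totals=a.base_totals + b.base_totals,
        q20_bases=a.q20_bases + b.q20_bases,
        q30_bases=a.q30_bases + b.q30_bases,
        filter_tally=a.filter_tally + b.filter_tally,
    )
    for mate in sorted(set(a.position) | set(b.position)):
        pa = a.position.get(mate, PositionStats())
        pb = b.position.get(mate, PositionStats())
        out.position[mate] = pa.merge(pb)
    return out


def _hist_quantile(cum: np.ndarray, depth: np.ndarray, q: float) -> np.ndarray:
    """Type-1 (inverted-CDF) quantile per column of a cumulative histogram:
    the smallest value whose cumulative count reaches ceil(q * depth)."""
    target = np.ceil(q * depth).astype(np.int64)
    target = np.maximum(target, 1)
    # searchsorted per column on the cumulative counts
    out = np.empty(cum.shape[1], dtype=np.int64)
    for j in range(cum.shape[1]):
        out[j] = int(np.searchsorted(cum[:, j], target[j], side="left"))
    return out


@dataclass
class PositionSummary:
    """Per-position tables derived from one mate's :class:`PositionStats`."""

    depth: np.ndarray  # reads per position
    base_counts: np.ndarray  # (5, L) integer counts over A/C/G/T/N
    boxplot: pd.DataFrame  # min, q1, median, q3, max (0 at zero depth)
    composition: pd.DataFrame  # fraction of A/C/G/T/N per position
    q20_rate: np.ndarray
    q30_rate: np.ndarray
    zero_depth: np.ndarray  # mask of positions with no coverage


def summarize_positions(ps: PositionStats) -> PositionSummary:
    depth = ps.depth()
    nonzero = depth > 0
    length = ps.max_len
    cum = np.cumsum(ps.qual_hist, axis=0)

    box = np.zeros((length, 5), dtype=np.int64)
    if length and nonzero.any():
        safe_depth = np.where(nonzero, depth, 1)
        cols = {
            "min": _hist_quantile(cum, safe_depth, 1e-12),
            "q1": _hist_quantile(cum, safe_depth, 0.25),
            "median": _hist_quantile(cum, safe_depth, 0.5),
            "q3": _hist_quantile(cum, safe_depth, 0.75),
            "max": _hist_quantile(cum, safe_depth, 1.0),
        }
        for i, name in enumerate(("min", "q1", "median", "q3", "max")):
            box[:, i] = np.where(nonzero, cols[name], 0)
    boxplot = pd.DataFrame(
        box, columns=["min", "q1", "median", "q3", "max"],
        index=pd.RangeIndex(1, length + 1, name="position"),
    )

    safe = np.where(nonzero, depth, 1)
    comp = pd.DataFrame(
        (ps.base_counts / safe).T,
        columns=list(BASE_ORDER),
        index=boxplot.index,
    )
    comp[~nonzero] = 0.0

    q20 = ps.qual_hist[20:, :].sum(axis=0) / safe
    q30 = ps.qual_hist[30:, :].sum(axis=0) / safe
    q20 = np.where(nonzero, q20, 0.0)
    q30 = np.where(nonzero, q30, 0.0)
    return PositionSummary(
        depth=depth,
        base_counts=ps.base_counts.copy(),
        boxplot=boxplot,
        composition=comp,
        q20_rate=q20,
        q30_rate=q30,
        zero_depth=~nonzero,
    )


@dataclass
class DatasetSummary:
    """Dataset-wide rates plus per-mate per-position summaries."""

    n_reads: int
    n_bases: int
    base_totals: dict[str, int]
    q20: float  # fraction of bases with Phred >= 20
    q30: float
    gc: float
    filter_tally: dict[str, int]
    per_mate: dict[int, PositionSummary]


def summarize(stats: DatasetStats) -> DatasetSummary:
    nb = stats.n_bases
    gc = (stats.base_totals["G"] + stats.base_totals["C"]) / nb if nb else 0.0
    return DatasetSummary(
        n_reads=stats.n_reads,
        n_bases=nb,
        base_totals={b: stats.base_totals[b] for b in BASE_ORDER},
        q20=stats.q20_bases / nb if nb else 0.0,
        q30=stats.q30_bases / nb if nb else 0.0,
        gc=gc,
        filter_tally=dict(stats.filter_tally),
        per_mate={m: summarize_positions(ps) for m, ps in stats.position.items()},
    )


@dataclass(frozen=True)
class Finding:
    check: str  # "per_base_quality" | "base_composition"
    level: str  # "warn" | "fail"
    mate: int
    position: int  # 1-based cycle
    observed: float
    threshold: float


@dataclass
class QCVerdict:
    status: str  # "pass" | "warn" | "fail"
    findings: list[Finding] = field(default_factory=list)


def evaluate_thresholds(clean_summary: DatasetSummary) -> QCVerdict:
    """Apply the preset warn/fail rules to a clean-data summary.

    Per-base quality: a position with median < 20 fails, < 25 warns.
    Base composition: |A% - T%| or |G% - C%| above 20 percentage points
    fails, above 10 warns (percentages of position depth including N).
    """
    findings: list[Finding] = []
    for mate, summ in sorted(clean_summary.per_mate.items()):
        medians = summ.boxplot["median"].to_numpy()
        counts = summ.base_counts
        for pos0 in range(len(medians)):
            if summ.zero_depth[pos0]:
                continue
            pos = pos0 + 1
            med = int(medians[pos0])
            if med < MEDIAN_FAIL:
                findings.append(
                    Finding("per_base_quality", "fail", mate, pos, med, MEDIAN_FAIL)
                )
            elif med < MEDIAN_WARN:
                findings.append(
                    Finding("per_base_quality", "warn", mate, pos, med, MEDIAN_WARN)
                )
            # percentage-point differences from integer counts, so a value
            # exactly at a threshold is compared exactly
            depth = int(summ.depth[pos0])
            a, c, g, t = (int(counts[i, pos0]) for i in range(4))
            diff = max(abs(a - t), abs(g - c)) * 100.0 / depth
            if diff > COMPOSITION_FAIL:
                findings.append(
                    Finding("base_composition", "fail", mate, pos, diff, COMPOSITION_FAIL)
                )
            elif diff > COMPOSITION_WARN:
                findings.append(
                    Finding("base_composition", "warn", mate, pos, diff, COMPOSITION_WARN)
                )
    if any(f.level == "fail" for f in findings):
        status = "fail"
    elif findings:
        status = "warn"
    else:
        status = "pass"
    return QCVerdict(status=status, findings=findings)


def _mate_suffix(mate: int, paired: bool) -> str:
    return f"_{mate + 1}" if paired else ""


def _write_position_tables(
    summ: PositionSummary, ps: PositionStats, out_dir: Path, label: str, suffix: str
) -> None:
    index = pd.RangeIndex(1, ps.max_len + 1, name="position")
    hist = pd.DataFrame(
        ps.qual_hist.T, index=index,
        columns=[f"q{v}" for v in range(_N_QUAL)],
    )
    # drop all-zero quality columns to keep the table readable
    hist = hist.loc[:, (hist != 0).any(axis=0)]
    hist.to_csv(out_dir / f"base_quality_{label}{suffix}.txt", sep="\t")
    summ.boxplot.to_csv(out_dir / f"qual_boxplot_{label}{suffix}.txt", sep="\t")
    summ.composition.to_csv(
        out_dir / f"base_composition_{label}{suffix}.txt", sep="\t",
        float_format="%.6f",
    )
    q = pd.DataFrame(
        {"q20_rate": summ.q20_rate, "q30_rate": summ.q30_rate}, index=index
    )
    q.to_csv(out_dir / f"q20q30_by_pos_{label}{suffix}.txt", sep="\t",
             float_format="%.6f")


def _plot_panels(summ: PositionSummary, out_dir: Path, label: str, suffix: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = np.arange(1, len(summ.depth) + 1)
    fig, axes = plt.subplots(3, 1, figsize=(8, 10))
    bp = summ.boxplot
    axes[0].fill_between(pos, bp["q1"], bp["q3"], alpha=0.4, label="IQR")
    axes[0].plot(pos, bp["median"], label="median")
    axes[0].axhline(MEDIAN_WARN, ls="--", lw=0.8)
    axes[0].axhline(MEDIAN_FAIL, ls="--", lw=0.8)
    axes[0].set_ylabel("Phred quality")
    axes[0].legend()
    axes[1].plot(pos, summ.q20_rate * 100, label="Q20")
    axes[1].plot(pos, summ.q30_rate * 100, label="Q30")
    axes[1].set_ylabel("% bases")
    axes[1].legend()
    for base in BASE_ORDER:
        axes[2].plot(pos, summ.composition[base] * 100, label=base)
    axes[2].set_ylabel("% composition")
    axes[2].set_xlabel("position (cycle)")
    axes[2].legend(ncol=5)
    fig.tight_layout()
    fig.savefig(out_dir / f"qc_panels_{label}{suffix}.png", dpi=100)
    plt.close(fig)


def write_qc_report(
    raw: DatasetStats,
    clean: DatasetStats,
    verdict: QCVerdict,
    out_dir: Path,
    plots: bool = False,
) -> dict:
    """Emit the report file set; returns the summary document as a dict.

    ``summary.json`` holds raw-vs-clean counts, Q20/Q30/GC, the filter
    tally, and the verdict with findings. Per-position TSV tables are
    written for both raw and clean data, one row per 1-based cycle, with
    ``_1``/``_2`` mate suffixes for paired data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw_summary = summarize(raw)
    clean_summary = summarize(clean)
    doc = {
        "raw": _summary_section(raw_summary),
        "clean": _summary_section(clean_summary),
        "filter_tally": dict(clean.filter_tally),
        "verdict": {
            "status": verdict.status,
            "findings": [
                {
                    "check": f.check,
                    "level": f.level,
                    "mate": f.mate + 1,
                    "position": f.position,
                    "observed": f.observed,
                    "threshold": f.threshold,
                }
                for f in verdict.findings
            ],
        },
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    for label, stats, summary in (
        ("raw", raw, raw_summary),
        ("clean", clean, clean_summary),
    ):
        paired = len(stats.position) > 1
        for mate, ps in sorted(stats.position.items()):
            suffix = _mate_suffix(mate, paired)
            _write_position_tables(summary.per_mate[mate], ps, out_dir, label, suffix)
            if plots:
                _plot_panels(summary.per_mate[mate], out_dir, label, suffix)
    return doc


def _summary_section(s: DatasetSummary) -> dict:
    return {
        "n_reads": s.n_reads,
        "n_bases": s.n_bases,
        "base_totals": s.base_totals,
        "q20": round(s.q20, 6),
        "q30": round(s.q30, 6),
        "gc": round(s.gc, 6),
    }
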