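"""Exact-match sgRNA quantification from FASTQ and sequence-level QC.

Reads are assigned to guides by extracting the spacer-length window from
each read and requiring an exact, case-insensitive match to a library
spacer — no mismatches are tolerated, so a single substitution leaves a
read unmapped. The window is found either at a fixed 5' offset or by
scanning the first few offsets (vector/adapter lengths vary between
library preps).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Union

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .data import ScreenFormatError, ScreenValidationError, SgRNALibrary

__all__ = ["TrimSpec", "MappingStats", "SequenceQC", "quantify_sample", "sequence_qc"]

_MAX_PHRED = 94  # Phred+33 printable range

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class TrimSpec:
    """How to locate the spacer within a read.

    mode="fixed": take the window at exactly ``offset``.
    mode="scan": try offsets 0..max_offset and take the first exact hit.
    """

    mode: str = "scan"
    offset: int = 0
    max_offset: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "scan"):
            raise ScreenValidationError(f"unknown trim mode {self.mode!r}")
        if self.offset < 0 or self.max_offset < 0:
            raise ScreenValidationError("offsets must be non-negative")


@dataclass
class MappingStats:
    sample_id: str
    total_reads: int
    mapped_reads: int

    @property
    def percent_mapped(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.mapped_reads / self.total_reads

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_reads": self.total_reads,
            "mapped_reads": self.mapped_reads,
            "percent_mapped": self.percent_mapped,
        }


@dataclass
class SequenceQC:
    """Read-level sequence metrics for one sample.

    gc_histogram: reads per integer GC%% bin (101 bins, 0-100).
    base_quality_by_position: (n_positions, 3) Phred quartiles (Q1, median, Q3)
    per sequencing cycle. mean_read_quality_histogram: reads per integer
    mean-quality bin.
    """

    sample_id: str
    total_reads: int
    gc_histogram: np.ndarray
    base_quality_by_position: np.ndarray
    mean_read_quality_histogram: np.ndarray

    @property
    def median_base_quality(self) -> float:
        """Median Phred quality over all bases in all reads."""
        # reconstruct from the per-position count table kept at build time
        return float(self._overall_median)

    _overall_median: float = 0.0

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_reads": self.total_reads,
            "gc_histogram": self.gc_histogram.tolist(),
            "base_quality_by_position": self.base_quality_by_position.tolist(),
            "mean_read_quality_histogram": self.mean_read_quality_histogram.tolist(),
            "median_base_quality": self.median_base_quality,
        }


def _open_fastq(fastq: Union[str, Path, IO]) -> IO:
    if hasattr(fastq, "read"):
        return fastq  # already a handle
    path = Path(fastq)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(handle: IO) -> Iterator[tuple[str, str, str]]:
    it = FastqGeneralIterator(handle)
    idx = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ScreenFormatError(f"malformed FASTQ record at index {idx}: {exc}") from exc
        yield rec
        idx += 1


def quantify_sample(
    fastq: Union[str, Path, IO],
    library: SgRNALibrary,
    trim: TrimSpec = TrimSpec(),
    sample_id: str = "sample",
    reverse_complement: bool = False,
) -> tuple[np.ndarray, MappingStats]:
    """Count exact spacer matches per sgRNA in one FASTQ sample.

    Each read increments exactly one guide's count iff the extracted
    spacer-length window matches a library spacer exactly; everything else
    (mismatches, short reads) is unmapped. Returns the per-guide count
    vector in library order plus mapping statistics; counts always sum to
    mapped_reads.
    """
    if len(library) == 0:
        raise ScreenValidationError("cannot quantify against an empty library")
    L = library.spacer_length
    lookup: dict[str, int] = {}
    dupes = []
    for i, sp in enumerate(library.spacers):
        if sp in lookup:
            dupes.append(sp)
        lookup[sp] = i
    if reverse_complement:
        for i, sp in enumerate(library.spacers):
            rc = sp.translate(_COMPLEMENT)[::-1]
            if rc in lookup and lookup[rc] != i:
                dupes.append(rc)
            lookup.setdefault(rc, i)
    if dupes:
        raise ScreenValidationError(
            f"exact matching cannot disambiguate duplicate spacers: {sorted(set(dupes))[:5]}"
        )
    counts = np.zeros(len(library), dtype=np.int64)
    total = 0
    mapped = 0
    handle = _open_fastq(fastq)
    if trim.mode == "fixed":
        offsets = (trim.offset,)
    else:
        offsets = tuple(range(trim.max_offset + 1))
    for _title, seq, _qual in _iter_fastq(handle):
        total += 1
        seq = seq.upper()
        for off in offsets:
            window = seq[off : off + L]
            if len(window) < L:
                break
            hit = lookup.get(window)
            if hit is not None:
                counts[hit] += 1
                mapped += 1
                break
    return counts, MappingStats(sample_id=sample_id, total_reads=total, mapped_reads=mapped)


def sequence_qc(fastq: Union[str, Path, IO], sample_id: str = "sample") -> SequenceQC:
    """Compute GC-content and base-quality distributions for one FASTQ sample.

    Qualities are assumed Phred+33. Per-position quartiles are computed from
    the full per-cycle quality count table, so the median base quality over
    the whole sample is exact.
    """
    gc_hist = np.zeros(101, dtype=np.int64)
    mean_q_hist = np.zeros(_MAX_PHRED + 1, dtype=np.int64)
    # per-position x per-quality counts, grown as longer reads appear
    pos_q = np.zeros((0, _MAX_PHRED + 1), dtype=np.int64)
    total = 0
    handle = _open_fastq(fastq)
    for _title, seq, qual in _iter_fastq(handle):
        total += 1
        n = len(seq)
        if n == 0:
            gc_hist[0] += 1
            mean_q_hist[0] += 1
            continue
        gc = seq.count("G") + seq.count("g") + seq.count("C") + seq.count("c")
        gc_hist[int(round(100.0 * gc / n))] += 1
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
        if np.any(q < 0) or np.any(q > _MAX_PHRED):
            raise ScreenFormatError(f"quality characters outside Phred+33 range in read {total - 1}")
        mean_q_hist[int(round(q.mean()))] += 1
        if n > pos_q.shape[0]:
            grown = np.zeros((n, _MAX_PHRED + 1), dtype=np.int64)
            grown[: pos_q.shape[0]] = pos_q
            pos_q = grown
        pos_q[np.arange(n), q] += 1

    quartiles = _count_table_quartiles(pos_q)
    all_q = pos_q.sum(axis=0)
    overall_median = _weighted_quantile(all_q, 0.5) if all_q.sum() else 0.0
    qc = SequenceQC(
        sample_id=sample_id,
        total_reads=total,
        gc_histogram=gc_hist,
        base_quality_by_position=quartiles,
        mean_read_quality_histogram=mean_q_hist,
    )
    qc._overall_median = overall_median
    return qc


def _weighted_quantile(counts: np.ndarray, q: float) -> float:
    """Quantile of the integer values 0..len(counts)-1 weighted by counts.

    Matches np.percentile's default linear interpolation on the expanded
    sample without materializing it.
    """
    total = int(counts.sum())
    if total == 0:
        return float("nan")
    cum = np.cumsum(counts)
    target = q * (total - 1)
    lo_idx, hi_idx = int(np.floor(target)), int(np.ceil(target))
    # value at sorted position k is the first v with cum[v] > k
    lo_val = int(np.searchsorted(cum, lo_idx, side="right"))
    hi_val = int(np.searchsorted(cum, hi_idx, side="right"))
    frac = target - lo_idx
    return lo_val + frac * (hi_val - lo_val)


def _count_table_quartiles(pos_q: np.ndarray) -> np.ndarray:
    """(n_positions, 3) Q1/median/Q3 from a position x quality count table."""
    out = np.full((pos_q.shape[0], 3), np.nan)
    for p in range(pos_q.shape[0]):
        row = pos_q[p]
        if row.sum() == 0:
            continue
        out[p] = [_weighted_quantile(row, q) for q in (0.25, 0.5, 0.75)]
    return out
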