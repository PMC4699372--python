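"""Count-level and sample-level screen quality control.

Metrics per sample: number and fraction of zero-count guides, the Gini
index of the log-scaled count distribution (evenness of library
representation; high values mean a few guides dominate the pool), pairwise
Pearson correlations between samples on log-normalized counts, and a PCA
projection of samples. Each metric is evaluated against configurable
expectations (mapped-read floor, Gini ceilings by sample role, replicate
correlation floor); failures are warnings, never hard stops — a screen with
a flagged sample is still analyzable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .data import CountMatrix, ScreenValidationError
from .normalize import SizeFactors
from .quant import MappingStats, SequenceQC

__all__ = [
    "SampleQC",
    "QCThresholds",
    "QCReport",
    "gini_index",
    "sample_qc",
    "sample_correlations",
    "pca_projection",
    "correlation_clustering_order",
    "evaluate_thresholds",
    "gene_set_enrichment",
]

logger = logging.getLogger(__name__)


def gini_index(values: np.ndarray) -> float:
    """Population Gini index of a non-negative vector.

    G = sum_ij |v_i - v_j| / (2 n^2 mean), computed via the O(n log n)
    sorted-vector identity; ranges from 0 (perfectly even) to (n-1)/n
    (single owner). Undefined (error) for an all-zero vector.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ScreenValidationError("gini_index needs a 1-D non-empty vector")
    if np.any(v < 0):
        raise ScreenValidationError("gini_index requires non-negative values")
    total = v.sum()
    if total == 0:
        raise ScreenValidationError("gini index undefined for an all-zero vector")
    n = v.size
    v = np.sort(v)
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * v).sum() / (n * total) - (n + 1) / n)


@dataclass
class SampleQC:
    sample_id: str
    zero_sgrnas: int
    zero_fraction: float
    gini: Optional[float]  # None when undefined (all-zero sample)
    total_count: int

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "zero_sgrnas": self.zero_sgrnas,
            "zero_fraction": self.zero_fraction,
            "gini": self.gini,
            "total_count": self.total_count,
        }


def sample_qc(counts: CountMatrix) -> list[SampleQC]:
    """Per-sample zero-guide counts and Gini of log2(count + 1)."""
    out = []
    for j, sid in enumerate(counts.sample_ids):
        col = counts.counts[:, j]
        zeros = int((col == 0).sum())
        try:
            g = gini_index(np.log2(col + 1.0))
        except ScreenValidationError:
            g = None
            logger.warning("sample %s is all-zero; Gini undefined", sid)
        out.append(
            SampleQC(
                sample_id=sid,
                zero_sgrnas=zeros,
                zero_fraction=zeros / counts.n_sgrnas,
                gini=g,
                total_count=int(col.sum()),
            )
        )
    return out


def _log_normalized(counts: CountMatrix, sf: SizeFactors) -> np.ndarray:
    s = sf.for_samples(counts.sample_ids).s
    return np.log2(counts.counts / s[None, :] + 1.0)


def sample_correlations(counts: CountMatrix, sf: SizeFactors) -> np.ndarray:
    """Pairwise Pearson r on log2(normalized count + 1); NaN where undefined."""
    if counts.n_samples < 2:
        raise ScreenValidationError("need at least 2 samples for correlations")
    logc = _log_normalized(counts, sf)
    j = counts.n_samples
    corr = np.eye(j)
    for a in range(j):
        for b in range(a + 1, j):
            if np.std(logc[:, a]) == 0 or np.std(logc[:, b]) == 0:
                corr[a, b] = corr[b, a] = np.nan
            else:
                corr[a, b] = corr[b, a] = stats.pearsonr(logc[:, a], logc[:, b])[0]
    return corr


def pca_projection(counts: CountMatrix, sf: SizeFactors) -> np.ndarray:
    """Samples x 3 coordinates on the top principal components of log-normalized counts.

    Component signs are canonicalized (largest-magnitude loading positive);
    missing components (fewer samples than 3) are zero-filled.
    """
    if counts.n_samples < 2:
        raise ScreenValidationError("need at least 2 samples for PCA")
    logc = _log_normalized(counts, sf).T  # samples x guides
    centered = logc - logc.mean(axis=0, keepdims=True)
    out = np.zeros((counts.n_samples, 3))
    if not np.any(np.abs(centered) > 1e-12):
        return out
    k = min(3, counts.n_samples - 1, centered.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(centered)
    for c in range(k):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1.0
    out[:, :k] = coords
    return out


def correlation_clustering_order(corr: np.ndarray) -> list[int]:
    """Sample order from average-linkage clustering on 1 - r distances."""
    d = 1.0 - np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    if d.shape[0] < 2:
        return list(range(d.shape[0]))
    link = average(squareform(np.maximum(d, 0.0), checks=False))
    return [int(i) for i in leaves_list(link)]


@dataclass
class QCThresholds:
    """Expectations each metric is checked against (warn, never fail).

    Defaults: at least 65% of reads mapped; at least 300 mapped reads per
    guide in total; median base quality at least 25; at most 1% of guides
    with zero counts; Gini at most 0.1 for plasmid/initial samples and 0.2
    for selected samples; replicate correlation at least 0.8.
    """

    min_percent_mapped: float = 65.0
    min_reads_per_sgrna: float = 300.0
    min_median_base_quality: float = 25.0
    max_zero_fraction: float = 0.01
    max_gini_initial: float = 0.1
    max_gini_selected: float = 0.2
    min_replicate_correlation: float = 0.8


_ROLES = ("plasmid", "initial", "selected")


@dataclass
class QCReport:
    sample_ids: tuple[str, ...]
    sample_qc: list[SampleQC]
    mapping_stats: Optional[list[MappingStats]] = None
    sequence_qc: Optional[list[SequenceQC]] = None
    correlation_matrix: Optional[np.ndarray] = None
    pca_coordinates: Optional[np.ndarray] = None
    clustering_order: Optional[list[int]] = None
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "samples": {
                sq.sample_id: {
                    **sq.to_dict(),
                    **(
                        self.mapping_stats[i].to_dict()
                        if self.mapping_stats is not None
                        else {}
                    ),
                }
                for i, sq in enumerate(self.sample_qc)
            },
            "sequence_qc": (
                [q.to_dict() for q in self.sequence_qc] if self.sequence_qc is not None else None
            ),
            "correlation_matrix": (
                self.correlation_matrix.tolist() if self.correlation_matrix is not None else None
            ),
            "pca_coordinates": (
                self.pca_coordinates.tolist() if self.pca_coordinates is not None else None
            ),
            "clustering_order": self.clustering_order,
            "flags": self.flags,
        }


def evaluate_thresholds(
    report: QCReport,
    sample_roles: Mapping[str, str],
    replicate_groups: Optional[Sequence[Sequence[str]]] = None,
    thresholds: QCThresholds = QCThresholds(),
    n_sgrnas: Optional[int] = None,
) -> dict:
    """Flag each metric pass/warn against its expectation.

    sample_roles maps sample id to "plasmid", "initial" or "selected" (the
    Gini ceiling depends on it); replicate_groups lists samples whose
    pairwise correlations should exceed the replicate floor.
    """
    flags: dict[str, dict] = {}
    for sid in report.sample_ids:
        role = sample_roles.get(sid)
        if role is None or role not in _ROLES:
            raise ScreenValidationError(
                f"unknown role {role!r} for sample {sid!r}; expected one of {_ROLES}"
            )
    by_id = {sq.sample_id: sq for sq in report.sample_qc}
    maps = {m.sample_id: m for m in report.mapping_stats} if report.mapping_stats else {}
    seqs = {q.sample_id: q for q in report.sequence_qc} if report.sequence_qc else {}
    for sid in report.sample_ids:
        sq = by_id[sid]
        f: dict[str, dict] = {}
        if sid in maps:
            m = maps[sid]
            f["percent_mapped"] = _flag(
                m.percent_mapped >= thresholds.min_percent_mapped,
                m.percent_mapped, f">= {thresholds.min_percent_mapped}",
            )
            if n_sgrnas:
                need = thresholds.min_reads_per_sgrna * n_sgrnas
                f["mapped_reads"] = _flag(m.mapped_reads >= need, m.mapped_reads, f">= {need:g}")
        if sid in seqs and seqs[sid].median_base_quality is not None:
            q = seqs[sid].median_base_quality
            f["median_base_quality"] = _flag(
                q >= thresholds.min_median_base_quality,
                q, f">= {thresholds.min_median_base_quality}",
            )
        f["zero_fraction"] = _flag(
            sq.zero_fraction <= thresholds.max_zero_fraction,
            sq.zero_fraction, f"<= {thresholds.max_zero_fraction}",
        )
        gini_max = (
            thresholds.max_gini_initial
            if sample_roles[sid] in ("plasmid", "initial")
            else thresholds.max_gini_selected
        )
        if sq.gini is None:
            f["gini"] = {"status": "warn", "value": None, "expected": f"<= {gini_max}"}
        else:
            f["gini"] = _flag(sq.gini <= gini_max, sq.gini, f"<= {gini_max}")
        flags[sid] = f
    if replicate_groups and report.correlation_matrix is not None:
        idx = {s: i for i, s in enumerate(report.sample_ids)}
        rep_flags = {}
        for group in replicate_groups:
            for a in group:
                for b in group:
                    if a >= b:
                        continue
                    r = report.correlation_matrix[idx[a], idx[b]]
                    rep_flags[f"{a}~{b}"] = _flag(
                        bool(np.isfinite(r) and r >= thresholds.min_replicate_correlation),
                        None if not np.isfinite(r) else float(r),
                        f">= {thresholds.min_replicate_correlation}",
                    )
        flags["replicate_correlation"] = rep_flags
    report.flags = flags
    return flags


def _flag(ok: bool, value, expected: str) -> dict:
    return {"status": "pass" if ok else "warn", "value": value, "expected": expected}


def gene_set_enrichment(gene_scores: Mapping[str, float], gene_set: Sequence[str]) -> float:
    """One-sided Mann-Whitney p that genes in the set rank lower (more depleted).

    A rank-based stand-in for the negative-selection sanity check on a
    known-essential set (e.g. ribosomal genes): with a working screen those
    genes should concentrate at the depleted end of the beta ranking.
    """
    in_set = [v for g, v in gene_scores.items() if g in set(gene_set)]
    out_set = [v for g, v in gene_scores.items() if g not in set(gene_set)]
    if not in_set or not out_set:
        raise ScreenValidationError("gene set enrichment needs scores inside and outside the set")
    return float(stats.mannwhitneyu(in_set, out_set, alternative="less")[1])
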