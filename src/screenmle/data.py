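"""Core domain types and delimited-text I/O for pooled CRISPR screens.

The screen is represented by three tables that travel together: the sgRNA
library (guide -> gene map with spacer sequences and optional efficiency
priors), the sgRNA x sample count matrix, and the sample x condition binary
design matrix. Readers validate the invariants that the model downstream
relies on (unique guide ids, uniform spacer length, non-negative integer
counts, binary design entries); writers emit TSV.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SgRNALibrary",
    "CountMatrix",
    "DesignMatrix",
    "FitConfig",
    "GeneFit",
    "ScreenFormatError",
    "ScreenValidationError",
    "read_library",
    "read_counts",
    "write_counts",
    "read_design",
    "write_gene_results",
    "read_gene_results",
]

_VALID_SPACER = re.compile(r"^[ACGT]+$")


class ScreenFormatError(ValueError):
    """Malformed input file (missing columns, ragged rows, bad FASTQ record)."""


class ScreenValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


@dataclass(frozen=True)
class SgRNALibrary:
    """sgRNA -> gene map with spacer sequences and optional efficiency priors.

    ``efficiency_score`` is either a raw SSC-style score in (-2, 2) or a
    prior probability in [0, 1]; ``score_scale`` says which ("ssc" or
    "probability"). Scores are converted to priors by
    :func:`screenmle.mle.initial_efficiency`.
    """

    sgrna_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    spacers: tuple[str, ...]
    efficiency_scores: Optional[tuple[float, ...]] = None
    score_scale: str = "ssc"

    def __post_init__(self) -> None:
        n = len(self.sgrna_ids)
        if len(self.gene_ids) != n or len(self.spacers) != n:
            raise ScreenValidationError("library columns have unequal lengths")
        if self.efficiency_scores is not None and len(self.efficiency_scores) != n:
            raise ScreenValidationError("efficiency column length mismatch")
        if len(set(self.sgrna_ids)) != n:
            dupes = sorted({s for s in self.sgrna_ids if self.sgrna_ids.count(s) > 1})
            raise ScreenValidationError(f"duplicate sgRNA ids: {dupes[:5]}")
        if self.score_scale not in ("ssc", "probability"):
            raise ScreenValidationError(f"unknown score_scale {self.score_scale!r}")
        lengths = {len(s) for s in self.spacers}
        if len(lengths) > 1:
            raise ScreenValidationError(
                f"spacers must all have equal length, found lengths {sorted(lengths)}"
            )
        for row, s in enumerate(self.spacers):
            if not _VALID_SPACER.match(s):
                raise ScreenValidationError(
                    f"spacer for {self.sgrna_ids[row]!r} (row {row}) contains "
                    f"non-ACGT characters: {s!r}"
                )

    def __len__(self) -> int:
        return len(self.sgrna_ids)

    @property
    def spacer_length(self) -> int:
        if not self.spacers:
            raise ScreenValidationError("empty library has no spacer length")
        return len(self.spacers[0])

    @property
    def genes(self) -> tuple[str, ...]:
        """Unique gene ids in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.gene_ids:
            seen.setdefault(g)
        return tuple(seen)

    def gene_to_rows(self) -> dict[str, np.ndarray]:
        """Map each gene id to the row indices of its sgRNAs."""
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.gene_ids):
            out.setdefault(g, []).append(i)
        return {g: np.asarray(rows, dtype=int) for g, rows in out.items()}


@dataclass(frozen=True)
class CountMatrix:
    """sgRNA x sample non-negative integer read counts."""

    sgrna_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # (n_sgrna, n_samples) int64

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sgrna_ids), len(self.sample_ids)):
            raise ScreenValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.sgrna_ids)} sgRNAs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ScreenValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ScreenValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def n_sgrnas(self) -> int:
        return len(self.sgrna_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.sgrna_ids, tuple(sample_ids), self.counts[:, idx])


@dataclass(frozen=True)
class DesignMatrix:
    """Binary sample x condition indicator matrix d_jr.

    Row j marks which condition effects act on sample j; a sample with an
    all-zero row (typically plasmid/day-0) is modeled by guide baselines
    alone.
    """

    sample_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    entries: np.ndarray  # (J, R) of {0, 1}

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2 or entries.shape != (len(self.sample_ids), len(self.condition_ids)):
            raise ScreenValidationError(
                f"design shape {entries.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.condition_ids)} conditions"
            )
        if not np.isin(entries, (0, 1)).all():
            raise ScreenValidationError("design entries must be 0 or 1")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ScreenValidationError("duplicate sample ids in design")
        object.__setattr__(self, "entries", entries.astype(np.int64, copy=False))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)


@dataclass
class FitConfig:
    """Tunable parameters of the NB-GLM / EM fit.

    ridge_lambda is the precision of the zero-centered normal prior on all
    coefficients and must stay positive: the prior is what keeps beta finite
    when inefficient guides leave a condition effect unidentified.
    """

    ridge_lambda: float = 0.1
    max_em_iters: int = 100
    max_irls_iters: int = 50
    convergence_tol: float = 1e-4  # EM, on max|change in beta|
    irls_tol: float = 1e-6
    dispersion_prefit_alpha: float = 0.01
    alpha_floor: float = 1e-6
    n_permutations: int | str = "auto"  # "auto" -> 2 * number of genes
    rng_seed: int = 0
    size_factor_mode: str = "all"  # "all" | "control"
    control_sgrna_ids: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.ridge_lambda > 0:
            raise ScreenValidationError("ridge_lambda must be > 0 (the prior is always active)")
        if self.size_factor_mode not in ("all", "control"):
            raise ScreenValidationError(f"unknown size_factor_mode {self.size_factor_mode!r}")
        if not (isinstance(self.n_permutations, int) or self.n_permutations == "auto"):
            raise ScreenValidationError("n_permutations must be an integer or 'auto'")


@dataclass
class GeneFit:
    """Per-gene fit result: condition betas, efficiency posteriors, significance."""

    gene_id: str
    condition_ids: tuple[str, ...]
    sgrna_ids: tuple[str, ...]
    beta_conditions: np.ndarray  # (R,)
    beta_baselines: np.ndarray  # (N,)
    efficiency_posterior: np.ndarray  # (N,) in [0, 1]
    converged: bool
    n_iterations: int
    se: Optional[np.ndarray] = None  # (R,)
    wald_z: Optional[np.ndarray] = None
    wald_p: Optional[np.ndarray] = None
    wald_fdr: Optional[np.ndarray] = None
    perm_p: Optional[np.ndarray] = None
    perm_fdr: Optional[np.ndarray] = None
    loglik: float = math.nan
    estimable: bool = True


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


_LIBRARY_COLS = {
    "sgrna": "sgrna",
    "sgrna_id": "sgrna",
    "guide": "sgrna",
    "gene": "gene",
    "gene_id": "gene",
    "sequence": "sequence",
    "spacer": "sequence",
    "seq": "sequence",
    "efficiency": "efficiency",
    "efficiency_score": "efficiency",
    "ssc": "efficiency",
}


def read_library(
    path: str | Path,
    delimiter: Optional[str] = None,
    score_scale: str = "ssc",
) -> SgRNALibrary:
    """Read an sgRNA library table (columns: sgRNA, gene, sequence[, efficiency]).

    Delimiter is auto-detected from the header when not given. Column names
    are matched case-insensitively against common synonyms.
    """
    path = Path(path)
    with _open_text(path) as fh:
        header = fh.readline()
    if not header:
        raise ScreenFormatError(f"{path}: empty file")
    sep = delimiter or _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str)
    colmap: dict[str, str] = {}
    for col in df.columns:
        canon = _LIBRARY_COLS.get(col.strip().lower())
        if canon and canon not in colmap:
            colmap[canon] = col
    missing = {"sgrna", "gene", "sequence"} - set(colmap)
    if missing:
        raise ScreenFormatError(
            f"{path}: missing required library column(s): {sorted(missing)} "
            f"(found columns {list(df.columns)})"
        )
    scores = None
    if "efficiency" in colmap:
        scores = tuple(pd.to_numeric(df[colmap["efficiency"]]).astype(float))
    return SgRNALibrary(
        sgrna_ids=tuple(df[colmap["sgrna"]].astype(str)),
        gene_ids=tuple(df[colmap["gene"]].astype(str)),
        spacers=tuple(df[colmap["sequence"]].astype(str).str.upper()),
        efficiency_scores=scores,
        score_scale=score_scale,
    )


def read_counts(path: str | Path, library: Optional[SgRNALibrary] = None) -> CountMatrix:
    """Read an sgRNA x sample count table (TSV or CSV, auto-detected).

    The first column is the sgRNA id; an optional second column named
    ``gene`` is checked against ``library`` when given (disagreement is an
    error, never a silent override). Remaining columns are samples in header
    order.
    """
    path = Path(path)
    with _open_text(path) as fh:
        header = fh.readline()
    if not header:
        raise ScreenFormatError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ScreenFormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ScreenFormatError(f"{path}: need an id column plus at least one sample column")
    sgrna_col = df.columns[0]
    sample_cols = list(df.columns[1:])
    gene_col = None
    if sample_cols and sample_cols[0].strip().lower() in ("gene", "gene_id"):
        gene_col = sample_cols.pop(0)
    if not sample_cols:
        raise ScreenFormatError(f"{path}: no sample columns found")
    sgrna_ids = tuple(df[sgrna_col].astype(str))
    if library is not None:
        lib_gene = dict(zip(library.sgrna_ids, library.gene_ids))
        unknown = [s for s in sgrna_ids if s not in lib_gene]
        if unknown:
            raise ScreenValidationError(
                f"{path}: {len(unknown)} sgRNAs not in library, e.g. {unknown[:3]}"
            )
        if gene_col is not None:
            for s, g in zip(sgrna_ids, df[gene_col].astype(str)):
                if lib_gene[s] != g:
                    raise ScreenValidationError(
                        f"{path}: gene column disagrees with library for {s!r}: "
                        f"{g!r} vs {lib_gene[s]!r}"
                    )
    values = df[sample_cols]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().any(axis=1).idxmax()
        raise ScreenValidationError(f"{path}: non-numeric count at row {bad}")
    arr = numeric.to_numpy()
    if not np.all(arr == np.floor(arr)):
        raise ScreenValidationError(f"{path}: counts must be integers")
    if arr.min() < 0:
        raise ScreenValidationError(f"{path}: counts must be non-negative")
    return CountMatrix(sgrna_ids, tuple(str(c) for c in sample_cols), arr.astype(np.int64))


def write_counts(
    counts: CountMatrix, path: str | Path, library: Optional[SgRNALibrary] = None
) -> None:
    """Write a count matrix as TSV, with a gene column when a library is given."""
    df = pd.DataFrame(counts.counts, columns=list(counts.sample_ids))
    df.insert(0, "sgRNA", list(counts.sgrna_ids))
    if library is not None:
        gene = dict(zip(library.sgrna_ids, library.gene_ids))
        df.insert(1, "gene", [gene[s] for s in counts.sgrna_ids])
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> DesignMatrix:
    """Read a sample x condition binary design matrix (first column = sample id)."""
    path = Path(path)
    with _open_text(path) as fh:
        header = fh.readline()
    if not header:
        raise ScreenFormatError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 1:
        raise ScreenFormatError(f"{path}: empty design")
    sample_ids = tuple(df.iloc[:, 0].astype(str))
    condition_ids = tuple(str(c) for c in df.columns[1:])
    entries = df.iloc[:, 1:].to_numpy()
    return DesignMatrix(sample_ids, condition_ids, entries)


def write_design(design: DesignMatrix, path: str | Path) -> None:
    df = pd.DataFrame(design.entries, columns=list(design.condition_ids))
    df.insert(0, "sample", list(design.sample_ids))
    df.to_csv(path, sep="\t", index=False)


def align_design_to_counts(design: DesignMatrix, counts: CountMatrix) -> CountMatrix:
    """Select and order count columns to match the design's sample ids (by name)."""
    missing = [s for s in design.sample_ids if s not in counts.sample_ids]
    if missing:
        raise ScreenValidationError(
            f"design samples missing from count matrix: {missing}"
        )
    return counts.select_samples(design.sample_ids)


def gene_results_frame(fits: Iterable[GeneFit]) -> pd.DataFrame:
    """Assemble per-gene results into a flat table, one row per gene.

    Per condition: beta, se, wald_z, wald_p, wald_fdr, perm_p, perm_fdr
    columns named ``<condition>|<stat>``; plus convergence metadata.
    """
    fits = list(fits)
    if fits:
        cond = fits[0].condition_ids
        for f in fits:
            if f.condition_ids != cond:
                raise ScreenValidationError(
                    f"inconsistent condition sets: {f.gene_id} has {f.condition_ids}, "
                    f"expected {cond}"
                )
    else:
        cond = ()
    rows = []
    for f in fits:
        row: dict[str, object] = {"gene": f.gene_id}
        for r, c in enumerate(cond):
            row[f"{c}|beta"] = f.beta_conditions[r]
            for stat, arr in (
                ("se", f.se),
                ("wald_z", f.wald_z),
                ("wald_p", f.wald_p),
                ("wald_fdr", f.wald_fdr),
                ("perm_p", f.perm_p),
                ("perm_fdr", f.perm_fdr),
            ):
                row[f"{c}|{stat}"] = math.nan if arr is None else arr[r]
        row["converged"] = f.converged
        row["n_iterations"] = f.n_iterations
        row["estimable"] = f.estimable
        rows.append(row)
    columns = ["gene"]
    for c in cond:
        columns += [f"{c}|{s}" for s in ("beta", "se", "wald_z", "wald_p", "wald_fdr", "perm_p", "perm_fdr")]
    columns += ["converged", "n_iterations", "estimable"]
    return pd.DataFrame(rows, columns=columns)


def write_gene_results(fits: Iterable[GeneFit], path: str | Path) -> None:
    """Write per-gene results as TSV (round-trips through read_gene_results)."""
    gene_results_frame(fits).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
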