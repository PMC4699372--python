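"""Synthetic pooled CRISPR screens with known ground truth.

Counts are drawn from the same generative model the estimator assumes:
x_ij ~ NB(mu_ij, alpha) with mu_ij = s_j * exp(beta_i0 + sum_r d_jr beta_gr)
for efficient guides and mu_ij = s_j * exp(beta_i0) for inefficient ones.
Guide baselines beta_i0 are log-uniform over roughly two orders of
magnitude, mimicking the abundance unevenness of real libraries (so size-
factor and Gini behavior is non-degenerate). A FASTQ emitter places each
guide's spacer at a known offset with fixed flanks, giving an exact oracle
for the exact-match quantifier. What this generator does not emulate:
sequencing errors beyond an optional junk-read fraction, PCR duplicates,
copy-number effects, or guide-specific dispersion.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np

from .data import CountMatrix, DesignMatrix, ScreenValidationError, SgRNALibrary

__all__ = ["SimTruth", "ReadLayout", "default_design", "simulate_counts", "simulate_fastq"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth backing a simulated screen."""

    beta_conditions: np.ndarray  # genes x conditions
    beta_baselines: np.ndarray  # per sgRNA
    efficient: np.ndarray  # per sgRNA bool
    size_factors_true: np.ndarray  # per sample, positive
    alpha_true: float
    rng_seed: int

    def to_json(self, path: Union[str, Path], gene_ids: Sequence[str]) -> None:
        payload = {
            "beta_conditions": {g: list(map(float, row)) for g, row in zip(gene_ids, self.beta_conditions)},
            "beta_baselines": self.beta_baselines.tolist(),
            "efficient": self.efficient.astype(bool).tolist(),
            "size_factors_true": self.size_factors_true.tolist(),
            "alpha_true": self.alpha_true,
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def default_design(
    n_condition_samples: int = 2, n_replicates: int = 2, baseline_samples: int = 1
) -> DesignMatrix:
    """Baseline + multi-condition design: day-0 style samples with all-zero
    design rows, then one column per condition with the stated replicates."""
    sample_ids = [f"day0_{k}" for k in range(baseline_samples)]
    rows = [[0] * n_condition_samples for _ in range(baseline_samples)]
    condition_ids = [f"cond{r}" for r in range(n_condition_samples)]
    for r in range(n_condition_samples):
        for rep in range(n_replicates):
            sample_ids.append(f"cond{r}_rep{rep}")
            rows.append([1 if c == r else 0 for c in range(n_condition_samples)])
    return DesignMatrix(tuple(sample_ids), tuple(condition_ids), np.array(rows))


def _random_spacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Distinct random spacers (exact matching requires uniqueness)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        sp = "".join(rng.choice(_BASES, size=length))
        if sp not in seen:
            seen.add(sp)
            out.append(sp)
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(
    n_genes: int,
    sgrnas_per_gene: int,
    design: DesignMatrix,
    effect_spec: Union[Sequence[float], np.ndarray, float] = (-1.0, 0.0, 1.0),
    inefficient_fraction: float = 0.0,
    alpha_true: float = 0.1,
    depth_spec: Union[float, Sequence[float]] = 1.0,
    rng_seed: int = 0,
    baseline_log_range: tuple[float, float] = (math.log(30.0), math.log(3000.0)),
    spacer_length: int = 20,
) -> tuple[CountMatrix, SgRNALibrary, SimTruth]:
    """Draw a full synthetic screen.

    effect_spec: either a per-gene x per-condition matrix of true betas, a
    flat set of values assigned to genes in round-robin (each condition gets
    the gene's value), or a scalar sd for normal draws. Guides are flagged
    inefficient independently with probability inefficient_fraction; their
    counts ignore all condition effects. depth_spec gives per-sample depth
    multipliers (the true size factors).
    """
    if not 0.0 <= inefficient_fraction <= 1.0:
        raise ScreenValidationError("inefficient_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    j, r = design.entries.shape
    n_sgrna = n_genes * sgrnas_per_gene

    effect = np.asarray(effect_spec, dtype=float)
    if effect.ndim == 0:
        beta_cond = rng.normal(0.0, float(effect), size=(n_genes, r))
    elif effect.ndim == 1:
        beta_cond = np.empty((n_genes, r))
        for g in range(n_genes):
            beta_cond[g, :] = effect[g % effect.size]
    else:
        if effect.shape != (n_genes, r):
            raise ScreenValidationError(f"effect matrix must be {(n_genes, r)}, got {effect.shape}")
        beta_cond = effect.copy()

    beta0 = rng.uniform(*baseline_log_range, size=n_sgrna)
    efficient = rng.random(n_sgrna) >= inefficient_fraction
    s = np.broadcast_to(np.asarray(depth_spec, dtype=float), (j,)).copy()
    if np.any(s <= 0):
        raise ScreenValidationError("depths must be positive")

    gene_of = np.repeat(np.arange(n_genes), sgrnas_per_gene)
    cond_term = design.entries @ beta_cond.T  # (J, n_genes)
    h = beta0[:, None] + np.where(efficient[:, None], cond_term[:, gene_of].T, 0.0)
    mu = s[None, :] * np.exp(h)
    counts = _nb_draw(rng, mu, alpha_true).astype(np.int64)

    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    sgrna_ids = tuple(
        f"{gene_ids[g]}_sg{k}" for g in range(n_genes) for k in range(sgrnas_per_gene)
    )
    library = SgRNALibrary(
        sgrna_ids=sgrna_ids,
        gene_ids=tuple(gene_ids[g] for g in gene_of),
        spacers=tuple(_random_spacers(n_sgrna, spacer_length, rng)),
    )
    cm = CountMatrix(sgrna_ids, design.sample_ids, counts)
    truth = SimTruth(
        beta_conditions=beta_cond,
        beta_baselines=beta0,
        efficient=efficient,
        size_factors_true=s,
        alpha_true=alpha_true,
        rng_seed=rng_seed,
    )
    return cm, library, truth


@dataclass(frozen=True)
class ReadLayout:
    """Where the spacer sits within a simulated read."""

    prefix: str = "ACCG"  # fixed vector flank before the spacer
    read_length: int = 36
    quality_char: str = "I"  # Phred 40

    @property
    def offset(self) -> int:
        return len(self.prefix)


def simulate_fastq(
    counts_column: np.ndarray,
    library: SgRNALibrary,
    out: Union[str, Path, IO],
    layout: ReadLayout = ReadLayout(),
    junk_fraction: float = 0.0,
    rng_seed: int = 0,
) -> int:
    """Write a FASTQ with exactly count_i reads containing spacer i.

    Reads are prefix + spacer + random suffix padding to read_length, shuffled,
    plus an optional fraction of unmappable junk reads (random sequence checked
    against the library's spacers at every offset). Returns the number of
    reads written.
    """
    counts_column = np.asarray(counts_column)
    if len(counts_column) != len(library):
        raise ScreenValidationError("counts column and library length mismatch")
    L = library.spacer_length
    if layout.offset + L > layout.read_length:
        raise ScreenValidationError(
            f"spacer (offset {layout.offset} + length {L}) does not fit in "
            f"read length {layout.read_length}"
        )
    rng = np.random.default_rng(rng_seed)
    spacer_set = set(library.spacers)

    reads: list[str] = []
    pad = layout.read_length - layout.offset - L
    for sp, c in zip(library.spacers, counts_column):
        for _ in range(int(c)):
            suffix = "".join(rng.choice(_BASES, size=pad)) if pad else ""
            reads.append(layout.prefix + sp + suffix)
    n_mappable = len(reads)
    n_junk = int(round(junk_fraction * n_mappable / max(1.0 - junk_fraction, 1e-12)))
    for _ in range(n_junk):
        while True:
            seq = "".join(rng.choice(_BASES, size=layout.read_length))
            windows = {seq[o : o + L] for o in range(layout.read_length - L + 1)}
            if not (windows & spacer_set):
                break
        reads.append(seq)
    order = rng.permutation(len(reads))

    qual = layout.quality_char * layout.read_length
    own = not hasattr(out, "write")
    if own:
        path = Path(out)
        handle = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "wt")
    else:
        handle = out
    try:
        for k, idx in enumerate(order):
            handle.write(f"@read{k}\n{reads[idx]}\n+\n{qual}\n")
    finally:
        if own:
            handle.close()
    return len(reads)
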