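"""Wald and permutation significance for gene selection coefficients.

The Wald test compares beta / SE(beta) to the standard normal, with the
ridge-aware sandwich covariance

    Cov(beta) = (D'^T W D' + lambda I)^-1 (D'^T W D') (D'^T W D' + lambda I)^-1

evaluated at convergence. The permutation test builds an empirical null for
each gene size N by repeatedly drawing N guide rows at random from the whole
library, refitting the pseudo-gene, and recording its condition betas; the
two-sided p-value ranks the observed |beta| in that null with the add-one
rule, so p is never 0 and never below 1/(B + 1). Nulls are shared across all
genes of the same size within a run, keeping the cost linear in B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CountMatrix, DesignMatrix, FitConfig, GeneFit, ScreenValidationError, SgRNALibrary
from .normalize import SizeFactors

__all__ = ["NullDistribution", "wald_test", "permutation_test", "adjust_fdr", "attach_fdr"]

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Permutation null draws of condition betas for one gene size class."""

    gene_size: int
    condition_ids: tuple[str, ...]
    null_betas: np.ndarray  # (n_draws, R)

    @property
    def n_draws(self) -> int:
        return self.null_betas.shape[0]


def wald_test(state, n_sgrnas: int, ridge_lambda: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(se, z, two-sided p) for the condition coefficients of a converged fit."""
    dp = state.design_ext
    w = state.w
    xtwx = dp.T @ (dp * w[:, None])
    penalized = xtwx + ridge_lambda * np.eye(dp.shape[1])
    inv = np.linalg.inv(penalized)
    cov = inv @ xtwx @ inv
    se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    beta_cond = state.beta[n_sgrnas:]
    se = se_all[n_sgrnas:]
    z = np.zeros_like(beta_cond)
    p = np.ones_like(beta_cond)
    ok = se > 0
    z[ok] = beta_cond[ok] / se[ok]
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    degenerate = (~ok) & (beta_cond != 0)
    if degenerate.any():
        logger.warning("zero SE with nonzero beta; reporting p = 0")
        p[degenerate] = 0.0
        z[degenerate] = np.inf * np.sign(beta_cond[degenerate])
    return se, z, p


def build_null_distributions(
    counts: CountMatrix,
    library: SgRNALibrary,
    design: DesignMatrix,
    sf: SizeFactors,
    alpha: np.ndarray,
    cfg: FitConfig,
    gene_sizes: Sequence[int],
    prior_e: Optional[np.ndarray] = None,
) -> dict[int, NullDistribution]:
    """Draw B pseudo-genes per size class and record their fitted condition betas.

    Dispersions and efficiency priors are held at their observed-data values
    for each drawn guide row (they are not re-estimated inside the null
    refits).
    """
    from .mle import fit_gene, initial_efficiency

    n_genes = len(library.genes)
    b = 2 * n_genes if cfg.n_permutations == "auto" else int(cfg.n_permutations)
    rng = np.random.default_rng(cfg.rng_seed)
    if prior_e is None:
        prior_e = initial_efficiency(library)
    sfv = sf.for_samples(counts.sample_ids).s
    out: dict[int, NullDistribution] = {}
    for size in sorted(set(gene_sizes)):
        null = np.empty((b, design.n_conditions))
        for t in range(b):
            rows = rng.choice(counts.n_sgrnas, size=size, replace=False)
            fit, _ = fit_gene(
                counts.counts[rows, :], design, sfv, alpha[rows], prior_e[rows], cfg,
                gene_id=f"null_{size}_{t}",
            )
            null[t] = fit.beta_conditions
        out[size] = NullDistribution(size, design.condition_ids, null)
        logger.info("permutation null for gene size %d: %d draws", size, b)
    return out


def permutation_test(
    fits: Sequence[GeneFit],
    counts: CountMatrix,
    library: SgRNALibrary,
    design: DesignMatrix,
    sf: SizeFactors,
    alpha: np.ndarray,
    cfg: FitConfig,
    prior_e: Optional[np.ndarray] = None,
) -> None:
    """Fill perm_p on each fit: two-sided empirical p of |beta| with add-one rule."""
    sizes = [len(f.sgrna_ids) for f in fits]
    nulls = build_null_distributions(counts, library, design, sf, alpha, cfg, sizes, prior_e)
    for f, size in zip(fits, sizes):
        null = nulls[size]
        if null.n_draws == 0:
            f.perm_p = None  # reported as missing, not 1
            continue
        abs_null = np.abs(null.null_betas)
        abs_obs = np.abs(f.beta_conditions)
        exceed = (abs_null >= abs_obs[None, :]).sum(axis=0)
        f.perm_p = (1.0 + exceed) / (1.0 + null.n_draws)


def adjust_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (missing entries propagate as NaN)."""
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ScreenValidationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def attach_fdr(fits: Sequence[GeneFit]) -> None:
    """BH-adjust Wald and permutation p-values per condition across genes."""
    if not fits:
        return
    n_cond = len(fits[0].condition_ids)
    for r in range(n_cond):
        wald = np.array([f.wald_p[r] if f.wald_p is not None else np.nan for f in fits])
        qw = adjust_fdr(wald)
        perm = np.array([f.perm_p[r] if f.perm_p is not None else np.nan for f in fits])
        qp = adjust_fdr(perm)
        for i, f in enumerate(fits):
            if f.wald_fdr is None:
                f.wald_fdr = np.full(n_cond, np.nan)
            if f.perm_fdr is None:
                f.perm_fdr = np.full(n_cond, np.nan)
            f.wald_fdr[r] = qw[i]
            f.perm_fdr[r] = qp[i]
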