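"""Median-ratio size factors and the over-dispersion trend.

Sequencing depth is removed with median-ratio size factors: each count is
divided by its guide's geometric mean across samples (a pseudo-reference),
and the per-sample median of these ratios is the size factor s_j. Extra-
Poisson noise is captured by a negative-binomial dispersion alpha_i fitted
from the mean-variance trend sigma^2 = mu + k * mu^b across all guides,
following the VOOM-style residual regression: a first pass of the model is
run with a small fixed dispersion, residual variances (x - mu_hat)^2 are
regressed against fitted means in log space, and per-guide dispersions are
read off the trend as alpha = (sigma_f^2 - mu) / mu^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import (
    CountMatrix,
    DesignMatrix,
    FitConfig,
    ScreenValidationError,
    SgRNALibrary,
)

__all__ = ["SizeFactors", "DispersionModel", "size_factors", "normalized_counts", "fit_dispersion"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SizeFactors:
    sample_ids: tuple[str, ...]
    s: np.ndarray  # positive, one per sample

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if s.shape != (len(self.sample_ids),):
            raise ScreenValidationError("size factor length mismatch")
        if not np.all(s > 0):
            raise ScreenValidationError("size factors must be strictly positive")
        object.__setattr__(self, "s", s)

    def for_samples(self, sample_ids: tuple[str, ...]) -> "SizeFactors":
        idx = [self.sample_ids.index(x) for x in sample_ids]
        return SizeFactors(tuple(sample_ids), self.s[idx])


@dataclass
class DispersionModel:
    """Fitted mean-variance trend and per-guide NB dispersions."""

    k: float
    b: float
    alpha: np.ndarray  # per sgRNA, >= alpha_floor
    fitted_means: np.ndarray  # (n_sgrna, n_samples)
    residual_variances: np.ndarray  # (n_sgrna, n_samples)

    def trend_variance(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return mu + self.k * np.power(mu, self.b, where=mu > 0, out=np.zeros_like(mu))


def size_factors(
    counts: CountMatrix,
    mode: str = "all",
    control_ids: Optional[frozenset[str]] = None,
) -> SizeFactors:
    """Median-ratio size factors s_j = median_i x_ij / x_hat_i.

    The pseudo-reference x_hat_i is the geometric mean of guide i across
    samples; only guides nonzero in every sample enter it (a single zero
    would force x_hat = 0). mode="control" restricts the median to a
    predefined control-guide set.
    """
    x = counts.counts.astype(float)
    if mode not in ("all", "control"):
        raise ScreenValidationError(f"unknown size factor mode {mode!r}")
    positive = np.all(x > 0, axis=1)
    if mode == "control":
        if not control_ids:
            raise ScreenValidationError("control mode requires control_ids")
        missing = control_ids - set(counts.sgrna_ids)
        if missing:
            raise ScreenValidationError(f"control sgRNAs not in count matrix: {sorted(missing)[:5]}")
        in_ctrl = np.array([s in control_ids for s in counts.sgrna_ids])
        eligible = positive & in_ctrl
    else:
        eligible = positive
    if not eligible.any():
        raise ScreenValidationError(
            "no sgRNA has nonzero counts in every sample; median-ratio size factors are "
            "undefined (consider control mode or a total-count fallback)"
        )
    sub = x[eligible]
    log_gmean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_gmean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return SizeFactors(counts.sample_ids, s)


def normalized_counts(counts: CountMatrix, sf: SizeFactors) -> np.ndarray:
    """Depth-normalized counts x_ij / s_j (float matrix)."""
    sf = sf.for_samples(counts.sample_ids)
    return counts.counts / sf.s[None, :]


def fit_dispersion(
    counts: CountMatrix,
    sf: SizeFactors,
    design: DesignMatrix,
    library: SgRNALibrary,
    cfg: FitConfig,
) -> DispersionModel:
    """Fit the mean-variance trend and per-guide dispersions.

    Runs the full per-gene model once with dispersion pinned at
    cfg.dispersion_prefit_alpha to obtain fitted means mu_hat, computes
    squared residuals, regresses log(sigma^2 - mu) on log(mu) over points
    with positive excess variance to learn (k, b), and reads each guide's
    alpha off the fitted trend, floored at cfg.alpha_floor. With fewer than
    two usable points the fit falls back to the pre-fit constant.
    """
    from .mle import fit_all  # local import: mle depends on this module's types

    n_i, n_j = counts.n_sgrnas, counts.n_samples
    prefit_alpha = np.full(n_i, cfg.dispersion_prefit_alpha)
    fits = fit_all(counts, library, design, sf, prefit_alpha, cfg, compute_se=False)
    mu_hat = np.zeros((n_i, n_j))
    dof_scale = np.ones((n_i, 1))
    gene_rows = library.gene_to_rows()
    for fit in fits:
        rows = gene_rows[fit.gene_id]
        # reconstruct fitted means from the efficient-component linear predictor
        h = fit.beta_baselines[:, None] + (design.entries @ fit.beta_conditions)[None, :]
        mu_hat[rows, :] = sf.for_samples(counts.sample_ids).s[None, :] * np.exp(h)
        # residual-df correction: squared residuals around a p-parameter fit
        # underestimate the variance by about (n - p)/n
        n_obs = len(rows) * n_j
        p = len(rows) + design.n_conditions
        if n_obs > p:
            dof_scale[rows] = n_obs / (n_obs - p)
    resid_var = (counts.counts - mu_hat) ** 2 * dof_scale

    mu_flat = mu_hat.ravel()
    rv_flat = resid_var.ravel()
    usable = (mu_flat > 0) & (rv_flat > mu_flat)
    if usable.sum() < 2:
        logger.warning(
            "fewer than 2 points with excess variance; falling back to constant "
            "dispersion %.3g", cfg.dispersion_prefit_alpha,
        )
        alpha = np.full(n_i, max(cfg.dispersion_prefit_alpha, cfg.alpha_floor))
        return DispersionModel(0.0, 0.0, alpha, mu_hat, resid_var)

    logmu = np.log(mu_flat[usable])
    logexcess = np.log(rv_flat[usable] - mu_flat[usable])
    slope, intercept = np.polyfit(logmu, logexcess, 1)
    k, b = float(np.exp(intercept)), float(slope)
    # moment-based refinement of k on the raw scale: E[(x - mu)^2] - mu is
    # linear in k, so averaging excess / mu^b over all points (not only
    # those with positive excess) removes the log-space Jensen and
    # truncation biases that pull the exponentiated intercept down
    pos = mu_flat > 0
    k_raw = float(np.mean((rv_flat[pos] - mu_flat[pos]) / np.power(mu_flat[pos], b)))
    if np.isfinite(k_raw) and k_raw > 0:
        k = k_raw

    # per-guide alpha: mean over samples of (trend variance - mu) / mu^2 = k mu^(b-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_ij = np.where(mu_hat > 0, k * np.power(np.maximum(mu_hat, 1e-300), b - 2.0), np.nan)
    alpha = np.nanmean(alpha_ij, axis=1)
    alpha = np.where(np.isfinite(alpha), alpha, cfg.dispersion_prefit_alpha)
    alpha = np.maximum(alpha, cfg.alpha_floor)
    return DispersionModel(k, b, alpha, mu_hat, resid_var)
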