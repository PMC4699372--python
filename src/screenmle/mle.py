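"""Per-gene negative-binomial GLM with an EM mixture over guide efficiency.

Counts for guide i in sample j follow x_ij ~ NB(mu_ij, alpha_i) with
mu_ij = s_j * exp(beta_i0 + sum_r d_jr * beta_gr) when the guide cuts its
target (latent pi_i = 1), and mu_ij = s_j * exp(beta_i0) when it does not
(pi_i = 0). Gene selection under each condition is read off the shared
coefficients beta_gr (>0 positive selection, <0 negative selection); a
zero-centered normal prior (ridge penalty lambda) keeps beta finite when
inefficient guides leave an effect weakly identified.

Estimation alternates an E step (posterior efficiency e_i from the two
component likelihoods and the prior) with an M step that maximizes the full
expected complete-data penalized log-likelihood

    Q(beta) = sum_ij [ e_i log NB(x_ij; mu1_ij(beta), alpha_i)
                     + (1 - e_i) log NB(x_ij; mu0_ij(beta), alpha_i) ]
              - (lambda / 2) |beta|^2

by iteratively reweighted ridge regression on the two component designs
stacked, with step-halving so Q never decreases. Because the M step ascends
the exact Q — including the inefficient component's pull on the baselines —
the penalized observed-data (mixture) log-likelihood is non-decreasing
across EM iterations and the fixed point is a stationary point of the
penalized mixture objective. When every e_i = 1 (the default prior when no
efficiency scores are supplied) the update reduces to a single weighted NB
ridge regression with weights 1/(1/mu + alpha).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import (
    CountMatrix,
    DesignMatrix,
    FitConfig,
    GeneFit,
    ScreenValidationError,
    SgRNALibrary,
)
from .normalize import SizeFactors

__all__ = [
    "build_extended_design",
    "nb_loglik",
    "initial_efficiency",
    "e_step",
    "m_step_irls",
    "fit_gene",
    "fit_all",
    "GeneModelState",
]

logger = logging.getLogger(__name__)

_H_CLIP = 30.0  # linear-predictor clip; guards exp overflow on degenerate inputs


def build_extended_design(design: DesignMatrix, n_sgrnas: int) -> np.ndarray:
    """Extended design matrix D' linking (baselines, condition betas) to log q.

    Rows are ordered guide-fastest within sample: (q_11, q_21, ..., q_N1,
    q_12, ..., q_NJ). Columns are the N per-guide baseline indicators
    followed by the R condition columns; row (i, j) has a single 1 among the
    baseline columns (column i) and copies sample j's design row d_j.
    """
    if n_sgrnas < 1:
        raise ScreenValidationError("need at least one sgRNA")
    n, (j, r) = n_sgrnas, design.entries.shape
    out = np.zeros((n * j, n + r))
    baseline = np.tile(np.eye(n), (j, 1))
    out[:, :n] = baseline
    out[:, n:] = np.repeat(design.entries, n, axis=0)
    return out


def nb_loglik(
    x: Union[float, np.ndarray],
    mu: Union[float, np.ndarray],
    alpha: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """Log-pmf of NB with mean mu and variance mu + alpha * mu^2.

    alpha = 0 is the Poisson limit. Accepts scalars or broadcastable arrays;
    raises on any mu <= 0.
    """
    x = np.asarray(x, dtype=float)
    mu_arr = np.asarray(mu, dtype=float)
    alpha_arr = np.asarray(alpha, dtype=float)
    if np.any(mu_arr <= 0):
        raise ValueError("nb_loglik requires mu > 0")
    x, mu_b, a_b = np.broadcast_arrays(x, mu_arr, alpha_arr)
    out = np.empty(x.shape, dtype=float)
    pois = a_b <= 0
    if pois.any():
        xm, mm = x[pois], mu_b[pois]
        out[pois] = xm * np.log(mm) - mm - gammaln(xm + 1.0)
    nb = ~pois
    if nb.any():
        xm, mm, am = x[nb], mu_b[nb], a_b[nb]
        r = 1.0 / am
        out[nb] = (
            gammaln(xm + r)
            - gammaln(r)
            - gammaln(xm + 1.0)
            + r * np.log(r / (r + mm))
            + xm * np.log(mm / (r + mm))
        )
    return out if out.ndim else float(out)


def initial_efficiency(library: SgRNALibrary) -> np.ndarray:
    """Prior p(pi_i = 1) per guide from the library's efficiency scores.

    Raw SSC-style scores v in (-2, 2) map linearly to (v + 2) / 4; scores
    already on the probability scale pass through; with no scores the prior
    is 1 for every guide (all guides assumed efficient).
    """
    n = len(library)
    if library.efficiency_scores is None:
        return np.ones(n)
    scores = np.asarray(library.efficiency_scores, dtype=float)
    if library.score_scale == "probability":
        if np.any((scores < 0) | (scores > 1)):
            raise ScreenValidationError("probability-scale efficiency scores must lie in [0, 1]")
        return scores
    if np.any((scores <= -2) | (scores >= 2)):
        bad = library.sgrna_ids[int(np.argmax((scores <= -2) | (scores >= 2)))]
        raise ScreenValidationError(
            f"raw efficiency score outside (-2, 2) for {bad!r}; "
            "use score_scale='probability' for probabilities"
        )
    return (scores + 2.0) / 4.0


@dataclass
class GeneModelState:
    """Working state of one gene's fit; enough to compute Wald statistics."""

    beta: np.ndarray  # (N + R,)
    e: np.ndarray  # (N,) posterior efficiency
    prior_e: np.ndarray  # (N,)
    design_ext: np.ndarray  # D' (N*J, N+R)
    mu: np.ndarray  # efficient-component means (N*J,)
    w: np.ndarray  # diagonal IRLS weights e/(1/mu + alpha) (N*J,)
    loglik: float  # penalized observed-data log-likelihood
    loglik_history: list[float] = field(default_factory=list)
    iteration: int = 0
    converged: bool = False


def _component_logliks(
    x: np.ndarray,  # (N, J)
    beta: np.ndarray,  # (N + R,)
    design: DesignMatrix,
    sf: np.ndarray,  # (J,)
    alpha: np.ndarray,  # (N,)
) -> tuple[np.ndarray, np.ndarray]:
    """Per-guide log-likelihood sums under the efficient / inefficient models."""
    n, j = x.shape
    b0 = beta[:n]
    cond = design.entries @ beta[n:] if beta.size > n else np.zeros(j)
    h1 = np.clip(b0[:, None] + cond[None, :], -_H_CLIP, _H_CLIP)
    h0 = np.clip(b0[:, None] + np.zeros((1, j)), -_H_CLIP, _H_CLIP)
    mu1 = sf[None, :] * np.exp(h1)
    mu0 = sf[None, :] * np.exp(h0)
    a = alpha[:, None]
    l1 = nb_loglik(x, mu1, a).sum(axis=1)
    l0 = nb_loglik(x, mu0, a).sum(axis=1)
    return l1, l0


def e_step(
    x: np.ndarray,
    beta: np.ndarray,
    design: DesignMatrix,
    sf: np.ndarray,
    alpha: np.ndarray,
    prior_e: np.ndarray,
) -> np.ndarray:
    """Posterior efficiency e_i given the current beta.

    e_i is the posterior probability that guide i follows the condition-
    responsive model rather than the baseline-only model, combining the two
    per-guide likelihood products (in log space) with the prior. Degenerate
    priors 0 and 1 are pinned (no update).
    """
    l1, l0 = _component_logliks(x, beta, design, sf, alpha)
    e = np.array(prior_e, dtype=float)
    free = (prior_e > 0) & (prior_e < 1)
    if free.any():
        log_num = np.log(prior_e[free]) + l1[free]
        log_den = np.logaddexp(log_num, np.log1p(-prior_e[free]) + l0[free])
        e[free] = np.exp(log_num - log_den)
    return e


def _penalized_mixture_loglik(
    x: np.ndarray,
    beta: np.ndarray,
    design: DesignMatrix,
    sf: np.ndarray,
    alpha: np.ndarray,
    prior_e: np.ndarray,
    lam: float,
) -> float:
    """Observed-data penalized log-likelihood (the EM objective)."""
    l1, l0 = _component_logliks(x, beta, design, sf, alpha)
    with np.errstate(divide="ignore"):
        lp = np.log(prior_e)
        lq = np.log1p(-prior_e)
    terms = np.logaddexp(np.where(np.isneginf(lp), -np.inf, lp + l1),
                         np.where(np.isneginf(lq), -np.inf, lq + l0))
    return float(terms.sum() - 0.5 * lam * beta @ beta)


def _stacked_system(n: int, j: int, design_ext: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two component design blocks: full D' and D' with condition columns zeroed."""
    d0 = design_ext.copy()
    d0[:, n:] = 0.0
    return design_ext, d0


def m_step_irls(
    x: np.ndarray,  # (N, J)
    beta: np.ndarray,
    design: DesignMatrix,
    design_ext: np.ndarray,
    sf: np.ndarray,
    alpha: np.ndarray,
    e: np.ndarray,
    cfg: FitConfig,
) -> np.ndarray:
    """Maximize the expected complete-data penalized log-likelihood over beta.

    IRLS on the stacked component designs: observation (i, j) appears once
    under the efficient design with weight e_i and once under the baseline-
    only design with weight 1 - e_i; working weights are c / (1/mu + alpha)
    and working responses z = h + (x - mu)/mu. Each solve is followed by
    step-halving until the penalized objective does not decrease, so the M
    step is a genuine ascent step.
    """
    n, j = x.shape
    lam = cfg.ridge_lambda
    d1, d0 = _stacked_system(n, j, design_ext)
    a_stack = np.vstack([d1, d0])
    x_flat = x.T.ravel()  # guide-fastest within sample, matching D' row order
    x_stack = np.concatenate([x_flat, x_flat])
    s_stack = np.concatenate([np.repeat(sf, n)] * 2)
    alpha_stack = np.concatenate([np.tile(alpha, j)] * 2)
    c_stack = np.concatenate([np.tile(e, j), np.tile(1.0 - e, j)])

    def q_obj(b: np.ndarray) -> float:
        h = np.clip(a_stack @ b, -_H_CLIP, _H_CLIP)
        mu = s_stack * np.exp(h)
        ll = nb_loglik(x_stack, mu, alpha_stack)
        active = c_stack > 0
        return float((c_stack[active] * ll[active]).sum() - 0.5 * lam * b @ b)

    beta = beta.copy()
    q_cur = q_obj(beta)
    for _ in range(cfg.max_irls_iters):
        h = np.clip(a_stack @ beta, -_H_CLIP, _H_CLIP)
        mu = s_stack * np.exp(h)
        w = c_stack / (1.0 / mu + alpha_stack)
        z = h + (x_stack - mu) / mu
        aw = a_stack * w[:, None]
        lhs = a_stack.T @ aw + lam * np.eye(a_stack.shape[1])
        rhs = aw.T @ z
        try:
            beta_new = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - lam > 0 prevents this
            raise ScreenValidationError(f"singular IRLS system despite ridge: {exc}") from exc
        # step-halving: never let the penalized objective decrease
        step = beta_new - beta
        q_new = q_obj(beta_new)
        halvings = 0
        while q_new < q_cur - 1e-12 and halvings < 30:
            step *= 0.5
            beta_new = beta + step
            q_new = q_obj(beta_new)
            halvings += 1
        if q_new < q_cur - 1e-12:
            break  # no ascent direction left; keep current beta
        delta = np.max(np.abs(beta_new - beta))
        beta, q_cur = beta_new, q_new
        if delta < cfg.irls_tol:
            break
    return beta


def fit_gene(
    x: np.ndarray,  # (N, J) counts for one gene
    design: DesignMatrix,
    sf: np.ndarray,  # (J,)
    alpha: np.ndarray,  # (N,)
    prior_e: np.ndarray,  # (N,)
    cfg: FitConfig,
    gene_id: str = "gene",
    sgrna_ids: Optional[Sequence[str]] = None,
) -> tuple[GeneFit, GeneModelState]:
    """EM fit of one gene: alternate posterior-efficiency and beta updates.

    Baselines start at the log mean normalized count (+1 pseudo-count);
    condition effects start at 0 (the no-effect null). Iterates until
    max|change in beta| < cfg.convergence_tol or cfg.max_em_iters. A gene
    with all-zero counts is flagged not estimable (beta = 0, e = prior).
    """
    x = np.asarray(x, dtype=float)
    n, j = x.shape
    r = design.n_conditions
    sgrna_ids = tuple(sgrna_ids) if sgrna_ids is not None else tuple(f"{gene_id}_sg{i}" for i in range(n))
    design_ext = build_extended_design(design, n)
    prior_e = np.asarray(prior_e, dtype=float)
    alpha = np.asarray(alpha, dtype=float)

    if not x.any():
        state = GeneModelState(
            beta=np.zeros(n + r), e=prior_e.copy(), prior_e=prior_e,
            design_ext=design_ext, mu=sf.repeat(n) * 0 + 1.0,
            w=np.zeros(n * j), loglik=math.nan,
        )
        fit = GeneFit(
            gene_id=gene_id, condition_ids=design.condition_ids, sgrna_ids=sgrna_ids,
            beta_conditions=np.zeros(r), beta_baselines=np.zeros(n),
            efficiency_posterior=prior_e.copy(), converged=False, n_iterations=0,
            estimable=False,
        )
        return fit, state

    lam = cfg.ridge_lambda
    beta_init = np.zeros(n + r)
    norm_mean = (x / sf[None, :]).mean(axis=1)
    beta_init[:n] = np.log(norm_mean + 1.0)

    def run_em(first_e: Optional[np.ndarray]) -> tuple[np.ndarray, list[float], bool, int]:
        beta = beta_init.copy()
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, cfg.max_em_iters + 1):
            if it == 1 and first_e is not None:
                e = first_e
            else:
                e = e_step(x, beta, design, sf, alpha, prior_e)
            beta_new = m_step_irls(x, beta, design, design_ext, sf, alpha, e, cfg)
            history.append(_penalized_mixture_loglik(x, beta_new, design, sf, alpha, prior_e, lam))
            delta = np.max(np.abs(beta_new - beta))
            beta = beta_new
            if delta < cfg.convergence_tol:
                converged = True
                break
        return beta, history, converged, it

    # The mixture likelihood can be multimodal (an "efficient" and an
    # "inefficient" basin per guide); run EM from deterministic starts that
    # seed the first M step with different responsibility assignments and
    # keep the best penalized objective. For small genes every 0/1 corner
    # is enumerated; for larger genes the all-efficient, all-inefficient,
    # and single-flip corners cover the common configurations.
    mixture_active = bool(np.any((prior_e > 0) & (prior_e < 1)))
    starts: list[Optional[np.ndarray]] = [None]
    if mixture_active:
        if n <= 3:
            corners = [np.array(bits, dtype=float)
                       for bits in itertools.product((1.0, 0.0), repeat=n)]
        else:
            corners = [np.ones(n), np.zeros(n)]
            for i in range(n):
                flip = np.ones(n)
                flip[i] = 0.0
                corners.append(flip)
        starts += corners
    best = None
    for first_e in starts:
        beta_s, history_s, converged_s, it_s = run_em(first_e)
        if best is None or history_s[-1] > best[1][-1]:
            best = (beta_s, history_s, converged_s, it_s)
    beta, history, converged, it = best
    e = e_step(x, beta, design, sf, alpha, prior_e)

    h = np.clip(design_ext @ beta, -_H_CLIP, _H_CLIP)
    mu = np.repeat(sf, n) * np.exp(h)
    w = np.tile(e, j) / (1.0 / mu + np.tile(alpha, j))
    loglik = _penalized_mixture_loglik(x, beta, design, sf, alpha, prior_e, lam)
    state = GeneModelState(
        beta=beta, e=e, prior_e=prior_e, design_ext=design_ext, mu=mu, w=w,
        loglik=loglik, loglik_history=history, iteration=it, converged=converged,
    )
    fit = GeneFit(
        gene_id=gene_id, condition_ids=design.condition_ids, sgrna_ids=sgrna_ids,
        beta_conditions=beta[n:].copy(), beta_baselines=beta[:n].copy(),
        efficiency_posterior=e.copy(), converged=converged, n_iterations=it,
        loglik=loglik,
    )
    return fit, state


def fit_all(
    counts: CountMatrix,
    library: SgRNALibrary,
    design: DesignMatrix,
    sf: SizeFactors,
    alpha: np.ndarray,
    cfg: FitConfig,
    compute_se: bool = True,
    prior_e: Optional[np.ndarray] = None,
) -> list[GeneFit]:
    """Fit every gene independently; deterministic given the inputs.

    ``alpha`` is the per-guide dispersion vector in library row order;
    ``prior_e`` overrides the library-derived efficiency priors when given.
    Sample ids of design and counts must match by name (align upstream with
    :func:`screenmle.data.align_design_to_counts`).
    """
    from .significance import wald_test  # late import to avoid a cycle

    if tuple(design.sample_ids) != tuple(counts.sample_ids):
        raise ScreenValidationError(
            "design sample ids do not match count matrix sample ids: "
            f"{design.sample_ids} vs {counts.sample_ids}"
        )
    if tuple(library.sgrna_ids) != tuple(counts.sgrna_ids):
        raise ScreenValidationError("library and count matrix rows do not align")
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (counts.n_sgrnas,):
        raise ScreenValidationError("alpha must have one entry per sgRNA")
    if prior_e is None:
        prior_e = initial_efficiency(library)
    sfv = sf.for_samples(counts.sample_ids).s

    fits: list[GeneFit] = []
    gene_rows = library.gene_to_rows()
    for gi, gene in enumerate(library.genes):
        rows = gene_rows[gene]
        fit, state = fit_gene(
            counts.counts[rows, :], design, sfv, alpha[rows], prior_e[rows], cfg,
            gene_id=gene, sgrna_ids=[library.sgrna_ids[i] for i in rows],
        )
        if compute_se and fit.estimable:
            fit.se, fit.wald_z, fit.wald_p = wald_test(state, len(rows), cfg.ridge_lambda)
        fits.append(fit)
        if (gi + 1) % 500 == 0:
            logger.info("fitted %d/%d genes", gi + 1, len(library.genes))
    return fits
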