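"""Annotation enrichment of causal variants via an EM-fit logistic prior.

The prior causal probability of SNP j is tied to its binary annotations
through a logistic model::

    pi_j = logistic(alpha0 + sum_k alpha_k A_jk)

Causal indicators are independent Bernoulli(pi_j) truncated to at most one
causal variant per LD block, giving the block marginal likelihood

    L_b = prod_j (1 - pi_j) * (1 + sum_j odds_j BF_j),   odds_j = pi_j / (1 - pi_j)

where BF_j is the single-SNP approximate Bayes factor; the leading product
is the explicit no-causal configuration (for small pi_j its mass is
~ 1 - sum_j pi_j).  Coefficients are estimated genome-wide by EM: the E-step
computes per-block posterior causal probabilities including the no-causal
configuration, the M-step is a weighted logistic regression of the soft
causal labels on the annotations — the exact M-step for this model, so the
marginal log-likelihood is non-decreasing by construction.  alpha_k / ln 2
is the log2 fold enrichment of causal variants in annotation k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotationMatrix
from .finemap import SIGMA0_SQ_GRID, log_abf

logger = logging.getLogger("genepip")

ALPHA_CAP = 10.0


@dataclass
class EnrichmentModel:
    """Fitted logistic prior: intercept and per-annotation log-odds."""

    alpha0: float
    alpha: dict[str, float]
    se: dict[str, float]
    se_alpha0: float
    sigma0_sq: float
    converged: bool
    n_iter: int
    log_lik: float
    log_lik_path: list[float] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    capped: bool = False

    @property
    def names(self) -> list[str]:
        return list(self.alpha)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.alpha0] + [self.alpha[k] for k in self.alpha])


def _block_logsumexp(x: np.ndarray, reduce_at: np.ndarray) -> np.ndarray:
    """Per-block logsumexp over contiguous slices delimited by ``reduce_at``."""
    starts = reduce_at[:-1]
    m = np.maximum.reduceat(x, starts)
    lengths = np.diff(reduce_at)
    shifted = x - np.repeat(m, lengths)
    s = np.add.reduceat(np.exp(shifted), starts)
    return m + np.log(s)


def _marginal_loglik(eta: np.ndarray, lbf: np.ndarray, reduce_at: np.ndarray) -> float:
    """sum_j log(1-pi_j) + sum_b log(1 + sum_{j in b} odds_j BF_j)."""
    log1m = -np.logaddexp(0.0, eta)  # log(1 - pi)
    per_block = _block_logsumexp(eta + lbf, reduce_at)
    return float(log1m.sum() + np.logaddexp(0.0, per_block).sum())


def _estep(eta: np.ndarray, lbf: np.ndarray, reduce_at: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior causal probability per SNP and no-causal mass per block."""
    log_odds_bf = eta + lbf
    denom = np.logaddexp(0.0, _block_logsumexp(log_odds_bf, reduce_at))
    q = np.exp(log_odds_bf - np.repeat(denom, np.diff(reduce_at)))
    return q, np.exp(-denom)


def _weighted_logistic(X: np.ndarray, q: np.ndarray, theta0: np.ndarray, cap: float) -> np.ndarray:
    """Maximize sum_j q_j log pi_j + (1-q_j) log(1-pi_j) (concave), boxed at |alpha|<=cap."""

    def nll(theta):
        eta = X @ theta
        pi = expit(eta)
        val = q @ np.logaddexp(0.0, -eta) + (1.0 - q) @ np.logaddexp(0.0, eta)
        grad = X.T @ (pi - q)
        return val, grad

    bounds = [(-30.0, 30.0)] + [(-cap, cap)] * (X.shape[1] - 1)
    res = optimize.minimize(nll, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-14})
    return res.x if nll(res.x)[0] <= nll(theta0)[0] else theta0


def fit_enrichment_em(
    z: np.ndarray,
    block_ids: np.ndarray,
    annotations: AnnotationMatrix | pd.DataFrame,
    sigma0_grid: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    alpha_cap: float = ALPHA_CAP,
) -> EnrichmentModel:
    """Estimate annotation enrichment by EM over LD blocks.

    Parameters
    ----------
    z, block_ids
        Per-SNP z-scores and block labels, aligned; at least two blocks.
    annotations
        Binary annotation matrix aligned with ``z`` row order (an
        :class:`~genepip.annotate.AnnotationMatrix` or plain DataFrame).
        Columns constant across all SNPs are dropped with a warning.
    sigma0_grid
        Candidate prior effect variances; the best value is profiled jointly
        with the coefficients at each iteration (coordinate ascent, so the
        likelihood stays monotone).
    """
    A_df = annotations.data if isinstance(annotations, AnnotationMatrix) else annotations
    z = np.asarray(z, dtype=float)
    if len(A_df) != z.shape[0]:
        raise ValueError("annotation matrix and z-scores are not aligned")
    blocks = pd.Series(np.asarray(block_ids))
    if blocks.nunique() < 2:
        raise ValueError("enrichment EM needs >= 2 LD blocks")
    sigma0_grid = SIGMA0_SQ_GRID if sigma0_grid is None else np.asarray(sigma0_grid, float)

    dropped = [c for c in A_df.columns if A_df[c].nunique() <= 1]
    if dropped:
        logger.warning("dropping constant annotation column(s): %s", dropped)
    names = [c for c in A_df.columns if c not in dropped]
    A = A_df[names].to_numpy(dtype=float)
    n, k = A.shape

    # contiguous per-block layout (reorder once)
    order = np.argsort(blocks.to_numpy(), kind="stable")
    labels = blocks.to_numpy()[order]
    X = np.column_stack([np.ones(n), A[order]])
    z_s = z[order]
    reduce_at = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1], True])
    n_blocks = reduce_at.shape[0] - 1

    # Bayes factors per candidate sigma0 are data-only: precompute once
    lbf_grid = np.stack([log_abf(z_s, s) for s in sigma0_grid])

    theta = np.zeros(k + 1)
    theta[0] = np.log(n_blocks / max(n - n_blocks, 1))  # ~one causal per block
    ll_path: list[float] = []
    converged = False
    g_best = len(sigma0_grid) // 2

    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ theta
        lls = [_marginal_loglik(eta, lbf_grid[g], reduce_at) for g in range(len(sigma0_grid))]
        g_best = int(np.argmax(lls))
        ll_path.append(lls[g_best])

        q, _ = _estep(eta, lbf_grid[g_best], reduce_at)
        new_theta = _weighted_logistic(X, q, theta, alpha_cap)
        delta = float(np.max(np.abs(new_theta - theta)))
        theta = new_theta
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("enrichment EM did not converge in %d iterations", max_iter)

    eta = X @ theta
    final_ll = _marginal_loglik(eta, lbf_grid[g_best], reduce_at)
    ll_path.append(final_ll)
    sigma0_sq = float(sigma0_grid[g_best])

    se_vec = _wald_se(theta, X, lbf_grid[g_best], reduce_at)
    capped = bool(np.any(np.abs(theta[1:]) >= alpha_cap - 1e-9))
    if capped:
        logger.warning("enrichment coefficient(s) capped at |alpha| = %g", alpha_cap)
    return EnrichmentModel(
        alpha0=float(theta[0]),
        alpha={name: float(t) for name, t in zip(names, theta[1:])},
        se={name: float(s) for name, s in zip(names, se_vec[1:])},
        se_alpha0=float(se_vec[0]),
        sigma0_sq=sigma0_sq,
        converged=converged,
        n_iter=it,
        log_lik=float(final_ll),
        log_lik_path=ll_path,
        dropped=dropped,
        capped=capped,
    )


def _wald_se(theta: np.ndarray, X: np.ndarray, lbf: np.ndarray, reduce_at: np.ndarray) -> np.ndarray:
    """Wald SEs from the observed information of the marginal log-likelihood.

    The score has the closed form ``X' (q - pi)`` with q the E-step causal
    posteriors; the Hessian is taken by central finite differences of the
    score, which accounts for E-step (missing-information) uncertainty that
    plug-in logistic SEs would ignore.
    """

    def score(th):
        eta = X @ th
        q, _ = _estep(eta, lbf, reduce_at)
        return X.T @ (q - expit(eta))

    h = 1e-5
    p = theta.shape[0]
    H = np.zeros((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = h
        H[:, j] = (score(theta + step) - score(theta - step)) / (2 * h)
    info = -0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def priors_from_model(
    model: EnrichmentModel,
    annotations: AnnotationMatrix | pd.DataFrame,
    block_ids: np.ndarray | None = None,
) -> pd.Series | dict[str, np.ndarray]:
    """Per-SNP prior causal probabilities from a fitted enrichment model.

    ``pi_j = logistic(alpha0 + alpha . A_j)``.  With ``block_ids`` the priors
    are renormalized to sum to 1 within each block, the form required by the
    single-effect (L = 1) fine-mapping; without them the raw logistic
    probabilities are returned.
    """
    A_df = annotations.data if isinstance(annotations, AnnotationMatrix) else annotations
    missing = set(model.alpha) - set(A_df.columns)
    if missing:
        raise ValueError(f"annotation column(s) absent from matrix: {sorted(missing)}")
    eta = model.alpha0 + A_df[list(model.alpha)].to_numpy(float) @ np.array(list(model.alpha.values()))
    pi = pd.Series(expit(eta), index=A_df.index, name="prior")
    if block_ids is None:
        return pi
    out: dict[str, np.ndarray] = {}
    frame = pd.DataFrame({"pi": pi.to_numpy(), "block": np.asarray(block_ids)})
    for block, grp in frame.groupby("block", sort=False):
        v = grp["pi"].to_numpy()
        out[block] = v / v.sum()
    return out


def enrichment_report(
    models: dict[str, EnrichmentModel],
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Log2 fold enrichment, Wald CI and BH-adjusted p per annotation.

    ``models`` maps a label (e.g. the annotation fitted alone, or a trait)
    to its fit; every coefficient across all supplied models forms the
    multiple-testing family.
    """
    if not models:
        raise ValueError("no fitted models supplied")
    ln2 = np.log(2.0)
    rows = []
    for label, m in models.items():
        for name in m.alpha:
            a, s = m.alpha[name], m.se[name]
            if a == 0.0:
                zstat, p = 0.0, 1.0
            elif s > 0:
                zstat = a / s
                p = 2 * stats.norm.sf(abs(zstat))
            else:
                zstat, p = np.inf * np.sign(a), 0.0
            rows.append(
                {
                    "model": label,
                    "annotation": name,
                    "log2_fe": a / ln2,
                    "ci_low": (a - 1.96 * s) / ln2,
                    "ci_high": (a + 1.96 * s) / ln2,
                    "p": p,
                }
            )
    report = pd.DataFrame(rows)
    report["p_adj"] = multipletests(report["p"], method=fdr_method)[1]
    return report
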