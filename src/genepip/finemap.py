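"""Single-effect Bayesian fine-mapping from z-scores.

Each LD block is analyzed under a single-effect regression (SER): exactly one
variant in the block is causal, with effect prior N(0, sigma0^2) on the
z-score scale.  Under this model the posterior over the causal index depends
on the data only through the per-variant approximate Bayes factors, so the LD
matrix is not needed for the posterior itself — it enters only through
credible-set purity filtering.

GWAS mode conditions on the block containing a causal variant (loci are
pre-selected at genome-wide significance); the enrichment EM instead adds an
explicit no-causal configuration (see :func:`ser_posterior_with_null`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger("genepip")

#: log-spaced profiling grid for the prior effect variance sigma0^2
SIGMA0_SQ_GRID = np.logspace(-3.0, 3.0, 21)

GWAS_SIG_P = 5e-8
#: |z| threshold equivalent to the genome-wide significance level P < 5e-8
GWAS_SIG_Z = 5.451891797  # scipy.stats.norm.isf(5e-8 / 2)


def log_abf(z: float | np.ndarray, sigma0_sq: float) -> float | np.ndarray:
    """Log approximate Bayes factor for a single variant.

    Wakefield-style ABF comparing the N(0, sigma0^2) effect model against the
    null for a z-score whose standard error is normalized to 1::

        log BF = 1/2 log(1 / (1 + sigma0^2)) + (z^2 / 2) * sigma0^2 / (1 + sigma0^2)
    """
    if sigma0_sq < 0:
        raise ValueError(f"sigma0_sq must be >= 0, got {sigma0_sq}")
    z = np.asarray(z, dtype=float)
    shrink = sigma0_sq / (1.0 + sigma0_sq)
    out = -0.5 * np.log1p(sigma0_sq) + 0.5 * z**2 * shrink
    return float(out) if out.ndim == 0 else out


@dataclass
class CredibleSet:
    variant_indices: list[int]  # decreasing-PIP order
    coverage: float  # achieved PIP sum
    requested: float
    purity: float | None = None  # min pairwise |r|, None when R unavailable


@dataclass
class FineMapResult:
    """Per-block SER fine-mapping output."""

    pip: np.ndarray
    prior: np.ndarray
    log_bf: np.ndarray
    z: np.ndarray
    sigma0_sq: float
    log_lik: float
    variant_ids: list[str] | None = None
    credible_set: CredibleSet | None = None
    sigma0_on_boundary: bool = False


def _validate_priors(priors: np.ndarray, n: int) -> np.ndarray:
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (n,):
        raise ValueError(f"priors length {priors.shape} does not match {n} z-scores")
    if np.any(priors < 0):
        raise ValueError("priors must be non-negative")
    total = priors.sum()
    if total <= 0:
        raise ValueError("all-zero prior vector")
    return priors / total


def finemap_block(
    z: np.ndarray,
    priors: np.ndarray | None = None,
    sigma0_sq: float | str = "estimate",
    variant_ids: list[str] | None = None,
) -> FineMapResult:
    """Fine-map one LD block under the single-effect model.

    Parameters
    ----------
    z
        Vector of GWAS z-scores for the block's variants.
    priors
        Prior causal probabilities; uniform when omitted.  Renormalized to
        sum to 1 (single-effect semantics).
    sigma0_sq
        Prior effect variance on the z scale, or ``"estimate"`` to maximize
        the SER marginal likelihood ``sum_j pi_j BF_j`` over
        :data:`SIGMA0_SQ_GRID`.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    n = z.shape[0]
    priors = np.full(n, 1.0 / n) if priors is None else _validate_priors(priors, n)

    boundary = False
    if sigma0_sq == "estimate":
        sigma0_sq, boundary = _profile_sigma0(z, priors)
    elif not np.isreal(sigma0_sq) or sigma0_sq < 0:
        raise ValueError(f"sigma0_sq must be >= 0 or 'estimate', got {sigma0_sq!r}")

    lbf = log_abf(z, float(sigma0_sq))
    with np.errstate(divide="ignore"):
        logw = np.log(priors) + lbf
    log_lik = float(logsumexp(logw))
    pip = np.exp(logw - log_lik)
    pip /= pip.sum()
    return FineMapResult(
        pip=pip, prior=priors, log_bf=np.atleast_1d(lbf), z=z,
        sigma0_sq=float(sigma0_sq), log_lik=log_lik,
        variant_ids=variant_ids, sigma0_on_boundary=boundary,
    )


def _profile_sigma0(z: np.ndarray, priors: np.ndarray) -> tuple[float, bool]:
    with np.errstate(divide="ignore"):
        logpi = np.log(priors)
    lls = [logsumexp(logpi + log_abf(z, s)) for s in SIGMA0_SQ_GRID]
    k = int(np.argmax(lls))
    boundary = k in (0, len(SIGMA0_SQ_GRID) - 1)
    if boundary:
        logger.warning("sigma0^2 profile maximum on grid boundary (%.3g)", SIGMA0_SQ_GRID[k])
    return float(SIGMA0_SQ_GRID[k]), boundary


def finemap_blocks(
    Z: np.ndarray,
    priors: np.ndarray | None = None,
    sigma0_sq: float | str = "estimate",
) -> tuple[np.ndarray, float]:
    """Vectorized SER PIPs for many equal-sized blocks.

    ``Z`` and ``priors`` are (n_blocks, m) arrays; priors renormalized per
    row.  When estimating, a single sigma0^2 shared across blocks maximizes
    the summed marginal log-likelihood.  Returns (PIP matrix, sigma0_sq).
    """
    Z = np.asarray(Z, dtype=float)
    if priors is None:
        priors = np.full_like(Z, 1.0 / Z.shape[1])
    else:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        logpi = np.log(priors)
    if sigma0_sq == "estimate":
        lls = [logsumexp(logpi + log_abf(Z, s), axis=1).sum() for s in SIGMA0_SQ_GRID]
        sigma0_sq = float(SIGMA0_SQ_GRID[int(np.argmax(lls))])
    logw = logpi + log_abf(Z, float(sigma0_sq))
    logw -= logsumexp(logw, axis=1, keepdims=True)
    pips = np.exp(logw)
    pips /= pips.sum(axis=1, keepdims=True)
    return pips, float(sigma0_sq)


def ser_posterior_with_null(
    Z: np.ndarray, priors: np.ndarray, sigma0_sq: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-effect posterior with an explicit no-causal configuration.

    ``priors`` are per-variant prior causal probabilities pi_j (NOT
    renormalized): causal indicators are independent Bernoulli(pi_j)
    truncated to at most one causal per block, so the no-causal
    configuration carries mass ``prod_j (1 - pi_j)`` (approximately
    ``1 - sum_j pi_j`` for the small priors this is used with) and
    configuration j carries ``prod(1 - pi) * odds_j * BF_j`` with
    ``odds_j = pi_j / (1 - pi_j)``.  This is the block model the enrichment
    EM maximizes.

    Returns ``(Q, q0, loglik)``: per-variant posterior causal probabilities,
    per-block no-causal posterior, and per-block marginal log-likelihood.
    Rows of ``[q0 | Q]`` sum to 1.
    """
    Z = np.asarray(Z, dtype=float)
    priors = np.clip(np.asarray(priors, dtype=float), 0.0, 1.0 - 1e-12)
    log_odds = np.log(np.clip(priors, np.finfo(float).tiny, None)) - np.log1p(-priors)
    logw = log_odds + log_abf(Z, sigma0_sq)  # relative to the no-causal config
    log_all = np.concatenate([np.zeros((Z.shape[0], 1)), logw], axis=1)
    log_denom = logsumexp(log_all, axis=1)
    post = np.exp(log_all - log_denom[:, None])
    post /= post.sum(axis=1, keepdims=True)
    loglik = np.log1p(-priors).sum(axis=1) + log_denom
    return post[:, 1:], post[:, 0], loglik


def credible_set(
    result: FineMapResult,
    coverage: float = 0.95,
    R: np.ndarray | None = None,
    purity_min: float = 0.5,
    positions: np.ndarray | None = None,
) -> CredibleSet | None:
    """Smallest variant set whose PIP sum reaches ``coverage``.

    Variants enter in decreasing-PIP order (ties broken by ascending
    position, or input order when positions are not given).  When an LD
    matrix is supplied the set is discarded (``None``) if its minimum
    pairwise |r| falls below ``purity_min``; without R, purity filtering is
    skipped and the purity field is ``None``.
    """
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    pip = result.pip
    n = pip.shape[0]
    tie = positions if positions is not None else np.arange(n)
    order = np.lexsort((np.asarray(tie), -pip))
    csum = np.cumsum(pip[order])
    k = int(np.searchsorted(csum, coverage - 1e-12)) + 1
    k = min(k, n)
    members = [int(i) for i in order[:k]]
    achieved = float(csum[k - 1])
    purity = None
    if R is not None:
        sub = np.abs(np.asarray(R)[np.ix_(members, members)])
        purity = float(sub.min()) if len(members) > 1 else 1.0
        if purity < purity_min:
            logger.info("credible set discarded: purity %.3f < %.3f", purity, purity_min)
            return None
    cs = CredibleSet(variant_indices=members, coverage=achieved, requested=coverage, purity=purity)
    result.credible_set = cs
    return cs


def results_table(
    results: dict[str, FineMapResult],
    positions: dict[str, np.ndarray] | None = None,
) -> "pd.DataFrame":
    """Flatten per-block results into the per-SNP output table."""
    import pandas as pd

    rows = []
    for block_id, res in results.items():
        ids = res.variant_ids or [f"{block_id}:{j}" for j in range(len(res.pip))]
        cs = res.credible_set.variant_indices if res.credible_set else []
        pos = positions.get(block_id) if positions else None
        for j, vid in enumerate(ids):
            rows.append(
                {
                    "block_id": block_id,
                    "variant_id": vid,
                    "pos": int(pos[j]) if pos is not None else -1,
                    "z": res.z[j],
                    "prior": res.prior[j],
                    "log_bf": res.log_bf[j],
                    "pip": res.pip[j],
                    "cs_id": f"{block_id}_L1" if j in cs else ".",
                    "genome_wide_sig": bool(np.abs(res.z).max() >= GWAS_SIG_Z),
                }
            )
    return pd.DataFrame(rows)
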