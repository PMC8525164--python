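"""Phylogenetic signal statistics: Blomberg's K and Pagel's lambda.

Blomberg's K compares the observed ratio of trait variance among tips to the
variance after phylogenetic (GLS) correction against its expectation under
Brownian motion, so that K = 1 for a trait evolving by BM on the given tree,
K -> 0 for phylogenetically independent data, and K > 1 for stronger-than-BM
resemblance of relatives. Significance comes from randomising trait values
across tips.

Pagel's lambda multiplies the off-diagonal entries of the Brownian covariance
V by a factor in [0, 1] and maximises the multivariate-normal likelihood over
that factor; lambda = 1 recovers BM, lambda = 0 a star phylogeny. A one-sided
likelihood-ratio test against lambda = 0 (chi-squared, 1 df) gives the
p-value.

Binary 0/1 characters (polyphagy partitions) are accepted and analysed with
the same Gaussian machinery; a warning notes the approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .trees import PhyloTree, phylo_covariance

logger = logging.getLogger(__name__)

__all__ = [
    "SignalResult",
    "StarPhylogenyError",
    "blomberg_k",
    "blomberg_k_test",
    "lambda_transform",
    "pagel_lambda",
    "pagel_lambda_test",
]


class StarPhylogenyError(ValueError):
    """The likelihood is flat in lambda (star phylogeny): lambda undefined."""


@dataclass
class SignalResult:
    method: str  # "blomberg_K" or "pagel_lambda"
    statistic: float
    p_value: float
    n_tips: int
    character: str = ""
    n_randomizations: int | None = None
    lrt_df: int | None = None


def _prepare(tree: PhyloTree, trait: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Order the trait by tree tips, validate, and return (y, V).

    Zero-length terminal branches (possible after polytomy resolution) make V
    singular; the affected diagonal entries are jittered by 1e-8 x tree
    height, logged.
    """
    labels = tree.tip_labels
    missing = [l for l in labels if l not in trait]
    extra = [l for l in trait if l not in set(labels)]
    if missing or extra:
        raise ValueError(
            f"trait labels do not match tree tips (missing={missing}, extra={extra})"
        )
    y = np.array([float(trait[l]) for l in labels])
    if not np.all(np.isfinite(y)):
        raise ValueError("trait contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant across tips; signal statistics undefined")
    vals = set(np.unique(y))
    if vals <= {0.0, 1.0}:
        logger.warning(
            "binary 0/1 trait analysed with Gaussian machinery (approximation)"
        )
    V = phylo_covariance(tree).values.copy()
    n = len(y)
    height = V.diagonal().max()
    zero_term = V.diagonal() <= np.array(
        [V[i, np.arange(n) != i].max() if n > 1 else 0.0 for i in range(n)]
    )
    if zero_term.any():
        V[np.diag_indices(n)] += np.where(zero_term, 1e-8 * height, 0.0)
        logger.info(
            "jittered %d zero-length terminal branch(es) by 1e-8 x height",
            int(zero_term.sum()),
        )
    return y, V


def _k_statistic(y: np.ndarray, Vinv_solve, Vinv_one: np.ndarray, trV: float) -> float:
    n = len(y)
    one = np.ones(n)
    denom = one @ Vinv_one
    a_hat = (Vinv_one @ y) / denom
    r = y - a_hat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Vinv_solve(r)) / (n - 1)
    expected = (trV - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


def blomberg_k(tree: PhyloTree, trait: Mapping[str, float]) -> float:
    """Blomberg's K for a tip trait on a rooted tree with branch lengths."""
    y, V = _prepare(tree, trait)
    if len(y) < 3:
        raise ValueError("Blomberg's K needs at least 3 tips")
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "phylogenetic covariance is singular; jitter zero-length branches"
        ) from exc
    solve = lambda b: cho_solve(cf, b)
    return _k_statistic(y, solve, solve(np.ones(len(y))), float(np.trace(V)))


def blomberg_k_test(
    tree: PhyloTree,
    trait: Mapping[str, float],
    n_perm: int = 10_000,
    seed: int | None = None,
    character: str = "",
) -> SignalResult:
    """Randomisation test for K: trait values are permuted across tips.

    p = (1 + #{K_perm >= K_obs}) / (1 + n_perm), one-sided for high signal.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    y, V = _prepare(tree, trait)
    n = len(y)
    if n < 3:
        raise ValueError("Blomberg's K needs at least 3 tips")
    cf = cho_factor(V)
    solve = lambda b: cho_solve(cf, b)
    Vinv_one = solve(np.ones(n))
    trV = float(np.trace(V))
    k_obs = _k_statistic(y, solve, Vinv_one, trV)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        k_p = _k_statistic(rng.permutation(y), solve, Vinv_one, trV)
        if k_p >= k_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return SignalResult(
        method="blomberg_K",
        statistic=k_obs,
        p_value=p,
        n_tips=n,
        character=character,
        n_randomizations=n_perm,
    )


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal entries of V by lambda (diagonal unchanged)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    W = lam * np.asarray(V, dtype=float)
    np.fill_diagonal(W, np.diagonal(V))
    return W


def _profile_loglik(y: np.ndarray, W: np.ndarray) -> float:
    """Log-likelihood with GLS mean and variance scale profiled out."""
    n = len(y)
    cf = cho_factor(W)
    logdet = 2.0 * np.sum(np.log(np.diagonal(cf[0])))
    one = np.ones(n)
    Wi_one = cho_solve(cf, one)
    a_hat = (Wi_one @ y) / (one @ Wi_one)
    r = y - a_hat
    sigma2 = (r @ cho_solve(cf, r)) / n
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


@dataclass
class LambdaFit:
    lambda_hat: float
    loglik: float
    loglik0: float
    loglik1: float
    n_tips: int


def pagel_lambda(tree: PhyloTree, trait: Mapping[str, float]) -> LambdaFit:
    """ML estimate of Pagel's lambda on [0, 1] by bounded 1-D search.

    The mean and variance rate are profiled out analytically at each lambda.
    Raises :class:`StarPhylogenyError` when the tree is a star (the
    likelihood is constant in lambda).
    """
    y, V = _prepare(tree, trait)
    if len(y) < 3:
        raise ValueError("Pagel's lambda needs at least 3 tips")
    off = V - np.diag(np.diagonal(V))
    if np.abs(off).max() <= 1e-12 * np.diagonal(V).max():
        raise StarPhylogenyError(
            "star phylogeny: likelihood is flat in lambda; estimate undefined"
        )

    def nll(lam: float) -> float:
        return -_profile_loglik(y, lambda_transform(V, lam))

    res = minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    candidates = [(float(res.x), -res.fun), (0.0, -nll(0.0)), (1.0, -nll(1.0))]
    lam_hat, ll = max(candidates, key=lambda c: c[1])
    return LambdaFit(
        lambda_hat=lam_hat,
        loglik=ll,
        loglik0=-nll(0.0),
        loglik1=-nll(1.0),
        n_tips=len(y),
    )


def pagel_lambda_test(
    tree: PhyloTree, trait: Mapping[str, float], character: str = ""
) -> SignalResult:
    """One-sided LRT of lambda-hat against lambda = 0 (chi-squared, 1 df)."""
    fit = pagel_lambda(tree, trait)
    lr = max(0.0, 2.0 * (fit.loglik - fit.loglik0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(
        method="pagel_lambda",
        statistic=fit.lambda_hat,
        p_value=p,
        n_tips=fit.n_tips,
        character=character,
        lrt_df=1,
    )
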