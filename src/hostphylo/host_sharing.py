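"""Randomised source-host logistic regression of host sharing.

For each fly with at least ``min_hosts`` host genera, one of its hosts is
drawn uniformly as the *source*; every other genus in the pool of attacked
genera becomes a candidate *target* with response 1 if the fly attacks it
and 0 otherwise, and predictor x = log10(patristic distance in Myr + 1)
between source and target. All flies' rows are pooled into one logistic
regression logit P(share) = b0 + b1 * x per run; the procedure is repeated
with fresh source draws, and the run-level coefficients are summarised by
their mean and 2.5/97.5 percentile interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import TipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SharingDataset",
    "SharingFit",
    "SeparationError",
    "build_run_dataset",
    "fit_logistic",
    "resample_regression",
    "sharing_probability",
]


class SeparationError(RuntimeError):
    """Perfect separation or non-convergence of the logistic fit."""


@dataclass
class SharingDataset:
    """One run's pooled rows: predictor x, 0/1 response, and bookkeeping."""

    x: np.ndarray
    y: np.ndarray
    fly: np.ndarray  # fly label per row
    source: dict[str, str]  # fly -> source genus

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class SharingFit:
    beta0_mean: float
    beta1_mean: float
    beta0_ci: tuple[float, float]
    beta1_ci: tuple[float, float]
    n_runs: int
    n_flies: int
    n_flagged: int
    seed: int | None
    runs: pd.DataFrame = field(repr=False)  # columns beta0, beta1

    def to_dict(self) -> dict:
        return {
            "beta0_mean": self.beta0_mean,
            "beta1_mean": self.beta1_mean,
            "beta0_ci": list(self.beta0_ci),
            "beta1_ci": list(self.beta1_ci),
            "n_runs": self.n_runs,
            "n_flies": self.n_flies,
            "n_flagged_runs": self.n_flagged,
            "seed": self.seed,
            "ci_method": "percentile 2.5/97.5 of run-level coefficients",
        }


def build_run_dataset(
    matrix: pd.DataFrame,
    distances: TipMatrix,
    min_hosts: int = 3,
    rng: np.random.Generator | None = None,
) -> SharingDataset:
    """Assemble one run's rows with a fresh random source host per fly.

    ``matrix`` is the fly x genus binary interaction matrix; ``distances``
    the genus patristic distance matrix in Myr. Flies with fewer than
    ``min_hosts`` host genera contribute no rows.
    """
    rng = rng or np.random.default_rng()
    genera = list(matrix.columns)
    missing = [g for g in genera if g not in set(distances.labels)]
    if missing:
        raise ValueError(f"genera absent from the distance matrix: {missing}")
    D = distances.reorder(genera).values
    M = matrix.to_numpy()
    xs, ys, flies = [], [], []
    source: dict[str, str] = {}
    for i, fly in enumerate(matrix.index):
        hosts = np.flatnonzero(M[i])
        if len(hosts) < min_hosts:
            continue
        s = int(rng.choice(hosts))
        source[fly] = genera[s]
        targets = np.delete(np.arange(len(genera)), s)
        xs.append(np.log10(D[s, targets] + 1.0))
        ys.append(M[i, targets])
        flies.append(np.full(len(targets), fly, dtype=object))
    if not xs:
        raise ValueError(f"no fly has >= {min_hosts} host genera")
    return SharingDataset(
        x=np.concatenate(xs),
        y=np.concatenate(ys).astype(float),
        fly=np.concatenate(flies),
        source=source,
    )


def fit_logistic(
    dataset: SharingDataset, max_iter: int = 100, tol: float = 1e-8
) -> tuple[float, float]:
    """ML fit of logit P(y=1) = b0 + b1 x by Newton/IRLS.

    Deterministic for a fixed dataset; raises :class:`SeparationError` on
    one-class data, perfect separation, or non-convergence.
    """
    x, y = dataset.x, dataset.y
    if y.min() == y.max():
        raise SeparationError("only one response class present")
    if np.ptp(x) == 0:
        raise ValueError("all predictor values identical: design matrix rank 1")
    # a single covariate is perfectly separated iff the two response classes
    # occupy disjoint x intervals; the MLE then diverges
    if x[y == 1].max() < x[y == 0].min() or x[y == 1].min() > x[y == 0].max():
        raise SeparationError("perfect separation on the distance predictor")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            return float(beta[0]), float(beta[1])
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular Hessian (separation?)") from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e6:
            raise SeparationError("coefficients diverging (quasi-separation)")
    raise SeparationError(f"no convergence in {max_iter} iterations")


def resample_regression(
    matrix: pd.DataFrame,
    distances: TipMatrix,
    n_runs: int = 1000,
    min_hosts: int = 3,
    seed: int | None = None,
) -> SharingFit:
    """Repeat the source-host draw + pooled fit ``n_runs`` times.

    Pooled coefficients are arithmetic means over successful runs; the 95%
    interval is the 2.5/97.5 percentile of the run-level coefficients.
    Separated / non-converged runs are excluded from pooling (logged, and a
    hard warning if they exceed 10%).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    coefs = []
    n_flagged = 0
    n_flies = 0
    for _ in range(n_runs):
        ds = build_run_dataset(matrix, distances, min_hosts=min_hosts, rng=rng)
        n_flies = len(ds.source)
        try:
            coefs.append(fit_logistic(ds))
        except SeparationError:
            n_flagged += 1
    if not coefs:
        raise RuntimeError("every run was flagged; no coefficients to pool")
    if n_flagged > 0.10 * n_runs:
        logger.warning(
            "%d/%d runs flagged (separation or non-convergence)", n_flagged, n_runs
        )
    elif n_flagged:
        logger.info("%d/%d runs flagged and excluded", n_flagged, n_runs)
    runs = pd.DataFrame(coefs, columns=["beta0", "beta1"])
    lo0, hi0 = np.percentile(runs["beta0"], [2.5, 97.5])
    lo1, hi1 = np.percentile(runs["beta1"], [2.5, 97.5])
    return SharingFit(
        beta0_mean=float(runs["beta0"].mean()),
        beta1_mean=float(runs["beta1"].mean()),
        beta0_ci=(float(lo0), float(hi0)),
        beta1_ci=(float(lo1), float(hi1)),
        n_runs=len(runs),
        n_flies=n_flies,
        n_flagged=n_flagged,
        seed=seed,
        runs=runs,
    )


def sharing_probability(fit: SharingFit, distance) -> np.ndarray | float:
    """P(host sharing) at a patristic distance (Myr) from the pooled fit."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    eta = fit.beta0_mean + fit.beta1_mean * np.log10(d + 1.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p) if np.isscalar(distance) else p
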