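"""PCA block compression with Horn's parallel analysis.

The soil block (SOC, TN, TP, TK) and the 15-trait CWM block each get
compressed to principal-component scores. Because both blocks mix units,
the default is correlation-matrix PCA. Eigenvector sign is arbitrary, so
each axis is oriented to make its largest-magnitude loading positive —
this keeps downstream path coefficients reproducible across platforms.

Axis retention follows Horn's parallel analysis: an axis is kept when its
observed eigenvalue exceeds the mean (or 95th percentile) of eigenvalues
obtained from ``n_sim`` same-shaped standard-normal tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError


@dataclass
class PCAResult:
    eigenvalues: np.ndarray      # non-increasing
    explained_pct: np.ndarray    # sums to 100
    loadings: pd.DataFrame       # variables x axes, orthonormal columns
    scores: pd.DataFrame         # rows x axes
    scale: str                   # "correlation" or "covariance"
    retained: int | None = None  # set by parallel analysis


def _eigen_sorted(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pca(table: pd.DataFrame, scale: str = "correlation") -> PCAResult:
    """Principal components of a rows x variables table.

    ``scale="correlation"`` standardises the columns first (population
    sd); ``"covariance"`` only centres them. Scores are the (scaled)
    centred data projected on the loadings, so the variance of PC-k
    scores equals eigenvalue k.
    """
    X = table.to_numpy(dtype=float)
    n, v = X.shape
    if v < 2 or n < 3:
        raise DegenerateDataError("PCA needs >= 2 variables and >= 3 rows")
    if np.isnan(X).any():
        raise DegenerateDataError("PCA input contains missing values")
    Xc = X - X.mean(axis=0)
    if scale == "correlation":
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            const = list(table.columns[sd == 0])
            raise DegenerateDataError(
                f"constant column(s) under correlation scaling: {const}"
            )
        Xc = Xc / sd
        mat = np.corrcoef(X, rowvar=False)
    elif scale == "covariance":
        mat = np.cov(X, rowvar=False)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    vals, vecs = _eigen_sorted(mat)
    vals = np.clip(vals, 0.0, None)
    # orient each axis so its largest-|loading| entry is positive
    for k in range(v):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    axes = [f"PC{k + 1}" for k in range(v)]
    loadings = pd.DataFrame(vecs, index=table.columns, columns=axes)
    scores = pd.DataFrame(Xc @ vecs, index=table.index, columns=axes)
    return PCAResult(
        eigenvalues=vals,
        explained_pct=100.0 * vals / vals.sum(),
        loadings=loadings,
        scores=scores,
        scale=scale,
    )


def parallel_test(
    table: pd.DataFrame,
    n_sim: int = 1000,
    criterion: str = "mean",
    rng: np.random.Generator | None = None,
    scale: str = "correlation",
) -> int:
    """Number of axes to retain under Horn's parallel analysis.

    Simulates ``n_sim`` standard-normal tables of the observed shape,
    collects their eigenvalue spectra, and retains the leading axes whose
    observed eigenvalue exceeds the ``mean`` (or ``p95``) simulated
    eigenvalue at the same rank. Retention stops at the first failure so
    the retained axes are always the leading ones.
    """
    if n_sim < 100:
        raise ValueError("parallel analysis needs n_sim >= 100")
    if criterion not in ("mean", "p95"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rng = np.random.default_rng() if rng is None else rng
    n, v = table.shape
    observed = pca(table, scale=scale).eigenvalues
    sims = np.empty((n_sim, v))
    for s in range(n_sim):
        Z = rng.standard_normal((n, v))
        mat = np.corrcoef(Z, rowvar=False) if scale == "correlation" else np.cov(
            Z, rowvar=False
        )
        sims[s] = np.sort(np.linalg.eigvalsh(mat))[::-1]
    threshold = (
        sims.mean(axis=0) if criterion == "mean" else np.percentile(sims, 95, axis=0)
    )
    retained = 0
    for k in range(v):
        if observed[k] > threshold[k]:
            retained += 1
        else:
            break
    return retained


def compress_block(
    table: pd.DataFrame,
    n_sim: int = 1000,
    criterion: str = "mean",
    rng: np.random.Generator | None = None,
    scale: str = "correlation",
) -> PCAResult:
    """PCA plus parallel-analysis retention, in one call."""
    result = pca(table, scale=scale)
    result.retained = parallel_test(
        table, n_sim=n_sim, criterion=criterion, rng=rng, scale=scale
    )
    return result
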