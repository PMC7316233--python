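"""Separable spatiotemporal Gaussian Markov random field on the prediction grid.

Spatial precision follows the SPDE (alpha = 2) construction on the grid
graph: Q0 = (kappa^2 I + L)^2 with L the combinatorial Laplacian of the
rook-neighbour graph, rescaled so the implied marginal variance averages 1.
Time follows a stationary AR(1) with unit marginal variance.  The field
precision is Q = (Q_s kron Q_t) / sd^2 with node index = pixel * n_years + t,
pixels row-major.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

__all__ = [
    "spatial_precision",
    "ar1_precision",
    "space_time_precision",
    "sample_field",
]


def _grid_laplacian(n_rows: int, n_cols: int) -> sp.csr_matrix:
    """Combinatorial Laplacian of the rook-adjacency graph of an r x c grid."""
    n = n_rows * n_cols
    idx = np.arange(n).reshape(n_rows, n_cols)
    right = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    down = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    pairs = np.concatenate([right, down], axis=1)
    data = np.ones(pairs.shape[1])
    w = sp.coo_matrix((data, (pairs[0], pairs[1])), shape=(n, n))
    w = (w + w.T).tocsr()
    deg = np.asarray(w.sum(axis=1)).ravel()
    return sp.diags(deg) - w


@lru_cache(maxsize=64)
def _spatial_precision_cached(n_rows: int, n_cols: int, kappa: float):
    lap = _grid_laplacian(n_rows, n_cols)
    b = (kappa**2) * sp.eye(n_rows * n_cols) + lap
    q0 = (b @ b).tocsc()
    # Normalize to unit average marginal variance (dense inverse; grids are small).
    dense = q0.toarray()
    cf = cho_factor(dense)
    inv = cho_solve(cf, np.eye(dense.shape[0]))
    vbar = float(np.mean(np.diag(inv)))
    q_s = q0 * vbar
    logdet_b = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    # logdet(q0) = 2 logdet(B); q0 = B^2 is SPD since B is.
    logdet = dense.shape[0] * np.log(vbar) + logdet_b
    return q_s, logdet


def spatial_precision(n_rows: int, n_cols: int, range_cells: float) -> tuple[sp.csc_matrix, float]:
    """Sparse spatial precision with ~unit average marginal variance.

    ``range_cells`` is the correlation range in units of grid cells; the SPDE
    relation kappa = sqrt(8) / range (smoothness nu = 1) applies.

    Returns (Q_s, logdet Q_s).
    """
    if range_cells <= 0:
        raise ValueError("range must be > 0")
    kappa = np.sqrt(8.0) / float(range_cells)
    return _spatial_precision_cached(int(n_rows), int(n_cols), round(float(kappa), 10))


def ar1_precision(n_t: int, rho: float) -> tuple[sp.csc_matrix, float]:
    """Precision of a stationary AR(1) of length n_t with unit marginal variance.

    Returns (Q_t, logdet Q_t); logdet = -(n_t - 1) * log(1 - rho^2).
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("|rho| must be < 1")
    if n_t == 1:
        return sp.eye(1, format="csc"), 0.0
    s = 1.0 / (1.0 - rho**2)
    diag = np.full(n_t, (1.0 + rho**2) * s)
    diag[0] = diag[-1] = s
    off = np.full(n_t - 1, -rho * s)
    q = sp.diags([off, diag, off], [-1, 0, 1], format="csc")
    logdet = -(n_t - 1) * np.log(1.0 - rho**2)
    return q, float(logdet)


def space_time_precision(
    n_rows: int, n_cols: int, n_t: int, range_cells: float, sd: float, rho: float
) -> tuple[sp.csc_matrix, float]:
    """Precision of the separable field, node index = pixel * n_t + t.

    Returns (Q, logdet Q) with Q = (Q_s kron Q_t) / sd^2.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    q_s, ld_s = spatial_precision(n_rows, n_cols, range_cells)
    q_t, ld_t = ar1_precision(n_t, rho)
    n_s = n_rows * n_cols
    q = sp.kron(q_s, q_t, format="csc") / (sd**2)
    logdet = n_t * ld_s + n_s * ld_t - 2.0 * n_s * n_t * np.log(sd)
    return q, float(logdet)


def sample_field(
    n_rows: int,
    n_cols: int,
    n_t: int,
    range_cells: float,
    sd: float,
    rho: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw fields from the separable GMRF prior.

    Returns an array of shape (size, n_pixels, n_t).
    """
    q_s, _ = spatial_precision(n_rows, n_cols, range_cells)
    q_t, _ = ar1_precision(n_t, rho)
    l_s = cholesky(q_s.toarray(), lower=True)
    l_t = cholesky(q_t.toarray(), lower=True)
    n_s = n_rows * n_cols
    out = np.empty((size, n_s, n_t))
    for k in range(size):
        eps = rng.standard_normal((n_s, n_t))
        # Solve (L_s^T kron L_t^T) x = eps  ->  L_s^T X L_t = E.
        y = solve_triangular(l_s.T, eps, lower=False)
        x = solve_triangular(l_t.T, y.T, lower=False).T
        out[k] = sd * x
    return out
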