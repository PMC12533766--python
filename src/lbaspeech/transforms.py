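"""Bijective maps between unconstrained sampler space and LBA parameters.

Per-individual constraints: drifts and boosts are unconstrained (identity);
``A = exp(a)`` keeps the start-point range positive; ``b = A + exp(d)``
builds the threshold as A plus a positive offset so ``b > A`` holds by
construction; ``t0 = 0.150 + exp(e)`` enforces the 150 ms non-decision
floor.  All maps are monotone, so order statistics survive the transform.

The group-level correlation matrix is parameterized through canonical
partial correlations (CPCs): unconstrained reals ``y`` map through
``z = tanh(y)`` to a lower-Cholesky factor with unit-norm rows, exactly the
construction used for LKJ-distributed correlation matrices in modern
probabilistic programming systems.
"""

from __future__ import annotations

import numpy as np

from .lba import IDX_A, IDX_B, IDX_T0, N_PARAMS, T0_FLOOR


def constrain_vector(theta_unc: np.ndarray) -> np.ndarray:
    """Map one unconstrained 17-vector to the constrained scale."""
    return constrain_matrix(np.atleast_2d(theta_unc))[0]


def constrain_matrix(theta_unc: np.ndarray) -> np.ndarray:
    """Row-wise :func:`constrain_vector` for an (n, 17) array."""
    theta_unc = np.asarray(theta_unc, dtype=float)
    out = theta_unc.copy()
    # exponent clip only guards against transient overflow in far warmup
    # excursions; the clipped region is rejected by the sampler anyway
    out[..., IDX_A] = np.exp(np.minimum(theta_unc[..., IDX_A], 700.0))
    out[..., IDX_B] = out[..., IDX_A] + np.exp(np.minimum(theta_unc[..., IDX_B], 700.0))
    out[..., IDX_T0] = T0_FLOOR + np.exp(np.minimum(theta_unc[..., IDX_T0], 700.0))
    return out


def unconstrain_vector(theta_con: np.ndarray) -> np.ndarray:
    return unconstrain_matrix(np.atleast_2d(theta_con))[0]


def unconstrain_matrix(theta_con: np.ndarray) -> np.ndarray:
    theta_con = np.asarray(theta_con, dtype=float)
    out = theta_con.copy()
    out[..., IDX_A] = np.log(theta_con[..., IDX_A])
    out[..., IDX_B] = np.log(theta_con[..., IDX_B] - theta_con[..., IDX_A])
    out[..., IDX_T0] = np.log(theta_con[..., IDX_T0] - T0_FLOOR)
    return out


def n_corr_free(k: int = N_PARAMS) -> int:
    return k * (k - 1) // 2


_LOWER_IDX_CACHE: dict = {}


def _strict_lower_indices(k: int):
    if k not in _LOWER_IDX_CACHE:
        _LOWER_IDX_CACHE[k] = np.tril_indices(k, -1)
    return _LOWER_IDX_CACHE[k]


class CPCDecomposition:
    """Shared intermediates of the CPC correlation transform.

    Computing these once per log-posterior evaluation and passing the
    object to the prior/chain-rule helpers avoids rebuilding the Cholesky
    factor three times in the sampler's hot path.
    """

    __slots__ = ("k", "y", "z", "Z", "C", "prodc", "L")

    def __init__(self, y: np.ndarray, k: int = N_PARAMS):
        y = np.asarray(y, dtype=float)
        if y.shape != (n_corr_free(k),):
            raise ValueError(f"expected {n_corr_free(k)} free correlation values")
        rows, cols = _strict_lower_indices(k)
        self.k = k
        self.y = y
        self.z = np.tanh(y)
        Z = np.zeros((k, k))
        Z[rows, cols] = self.z
        self.Z = Z
        self.C = np.sqrt(1.0 - Z**2)
        prodc = np.empty((k, k))
        prodc[:, 0] = 1.0
        np.cumprod(self.C[:, :-1], axis=1, out=prodc[:, 1:])
        self.prodc = prodc
        L = Z * prodc
        idx = np.arange(k)
        L[idx, idx] = prodc[idx, idx]
        self.L = np.tril(L)


def corr_cholesky(y: np.ndarray, k: int = N_PARAMS) -> np.ndarray:
    """Lower-Cholesky factor of a correlation matrix from CPC vector ``y``.

    ``y`` has length k(k-1)/2 (row-major strict lower triangle).  Row ``r``
    of the result is ``L[r, j] = z[r, j] * prod_{m<j} sqrt(1 - z[r, m]^2)``
    for ``j < r`` and ``L[r, r]`` the remaining product, giving unit-norm
    rows and hence unit diagonal for ``L @ L.T``.
    """
    return CPCDecomposition(y, k).L


def corr_from_unconstrained(y: np.ndarray, k: int = N_PARAMS) -> np.ndarray:
    L = corr_cholesky(y, k)
    return L @ L.T


def unconstrained_from_corr(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_from_unconstrained` (for round trips)."""
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    L = np.linalg.cholesky(R)
    Z = np.zeros((k, k))
    for r in range(1, k):
        prod = 1.0
        for j in range(r):
            Z[r, j] = L[r, j] / prod
            prod *= np.sqrt(1.0 - Z[r, j] ** 2)
    rows, cols = _strict_lower_indices(k)
    return np.arctanh(np.clip(Z[rows, cols], -1 + 1e-15, 1 - 1e-15))


def corr_transform_log_jacobian_and_lkj(y: np.ndarray, k: int = N_PARAMS,
                                        eta: float = 1.0):
    """Log prior contribution of the correlation block, plus its gradient.

    Returns ``(logp, dlogp_dy, L)`` where ``logp`` is the LKJ(eta) log
    density of the implied Cholesky factor plus the log|Jacobian| of the
    CPC transform, so that adding it to a likelihood expressed in ``L``
    yields a correctly weighted posterior over ``y``.
    """
    cpc = CPCDecomposition(np.asarray(y, dtype=float), k)
    logp, dy = cpc_log_prior_and_grad(cpc, eta)
    return logp, dy, cpc.L


def cpc_log_prior_and_grad(cpc: CPCDecomposition, eta: float = 1.0):
    """LKJ(eta) + transform-Jacobian log density and its ``y`` gradient."""
    k = cpc.k
    rows, cols = _strict_lower_indices(k)
    # transform log|J| = sum over (r, j<r) [ sum_{m<j} log c_{rm} + log(1 - z_rj^2) ]
    # which regroups to sum_{r,j<r} [0.5 (r-1-j) + 1] log(1 - z_rj^2)
    log1mz2 = np.log1p(-cpc.z**2)
    coef_j = 0.5 * (rows - 1 - cols) + 1.0
    logj = float(np.sum(coef_j * log1mz2))
    # LKJ(eta) on L: sum_{r >= 1 (0-based)} (k - r - 1 + 2 eta - 2) log L_rr
    diag = np.diag(cpc.L)
    coefs = k - np.arange(k) - 1.0 + 2.0 * eta - 2.0
    lkj = float(np.sum(coefs[1:] * np.log(np.maximum(diag[1:], 1e-300))))
    # gradient wrt y: d/dy log(1-z^2) = -2 z, and the LKJ part flows through
    # log L_rr = sum_{m<r} log c_{r,m} with d log L_rr / dy_{r,j} = -z_{r,j}
    dy = (-2.0 * coef_j - coefs[rows]) * cpc.z
    return logj + lkj, dy


def corr_grad_y_from_grad_L(grad_L: np.ndarray, y: np.ndarray,
                            k: int = N_PARAMS) -> np.ndarray:
    """Chain rule: gradient wrt ``y`` from a gradient wrt the factor ``L``.

    Uses ``dL[r,j]/dy[r,m] = -L[r,j] z[r,m]`` for ``m < j <= r`` and
    ``dL[r,j]/dy[r,j] = prodc[r,j] (1 - z[r,j]^2)``.
    """
    return cpc_grad_y_from_grad_L(CPCDecomposition(np.asarray(y, float), k),
                                  grad_L)


def cpc_grad_y_from_grad_L(cpc: CPCDecomposition, grad_L: np.ndarray) -> np.ndarray:
    k = cpc.k
    rows, cols = _strict_lower_indices(k)
    gl_low = np.tril(grad_L)
    GL = gl_low * cpc.L  # elementwise, lower triangle only
    # suffix[r, j] = sum_{j' >= j} GL[r, j']; the chain-rule sum needs j' > j
    suffix = np.flip(np.cumsum(np.flip(GL, axis=1), axis=1), axis=1)
    suffix_excl = np.zeros((k, k))
    suffix_excl[:, :-1] = suffix[:, 1:]
    dy = gl_low * cpc.prodc * (1.0 - cpc.Z**2) - cpc.Z * suffix_excl
    return dy[rows, cols]
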