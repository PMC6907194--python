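"""GBLUP mixed-model equations and prediction error variance (PEV).

Model: ``y = 1 mu + W u + e`` with ``var(u) = G sigma_u^2`` over all
animals in the GRM (phenotyped or not) and ``var(e) = I sigma_e^2``.
The mixed-model equations (MME), scaled by ``sigma_e^2``, are

    [ 1'1     1'W          ] [mu]   [ 1'y ]
    [ W'1     W'W + a G^-1 ] [u ] = [ W'y ],    a = sigma_e^2 / sigma_u^2.

Any full-rank inverse can stand in for ``G^-1``: the dense inverse of
the blended GRM, the inverse of the blended eigen-truncated GRM, or the
assembled APY sparse inverse.  ``PEV_i`` is the animal-block diagonal of
the inverted coefficient matrix times ``sigma_e^2``.

:func:`pev_reduced_rank` computes the same PEV by rotating the equations
into the GRM eigenbasis, where the animal block becomes ``r``-dimensional;
at full rank it reproduces the dense route exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .grm import ApyInverse, GRMBundle

__all__ = [
    "GblupProblem",
    "GblupFit",
    "grm_inverse_standard",
    "grm_inverse_truncated",
    "solve",
    "pev_direct",
    "pev_reduced_rank",
]


@dataclass
class GblupProblem:
    """One GBLUP run: records, their mapping into the GRM, and variances.

    ``g_inverse`` is the (full-rank) inverse used in the animal block;
    build it with :func:`grm_inverse_standard`, :func:`grm_inverse_truncated`
    or :meth:`eigenblup.grm.ApyInverse.matrix`.
    """

    y: np.ndarray
    phen_idx: np.ndarray  # GRM row of the animal owning each record
    sigma_u2: float
    sigma_e2: float
    g_inverse: np.ndarray
    grm_option: str = "standard"
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.phen_idx = np.asarray(self.phen_idx, dtype=int)
        if self.y.shape != self.phen_idx.shape:
            raise ValueError("y and phen_idx must have the same length")
        if self.sigma_u2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")
        n = self.g_inverse.shape[0]
        if self.g_inverse.shape != (n, n):
            raise ValueError("g_inverse must be square")
        if self.phen_idx.min(initial=0) < 0 or self.phen_idx.max(initial=-1) >= n:
            raise ValueError("phen_idx outside the GRM")

    @property
    def alpha(self) -> float:
        return self.sigma_e2 / self.sigma_u2

    @property
    def n_animals(self) -> int:
        return self.g_inverse.shape[0]


@dataclass
class GblupFit:
    """Solved MME: fixed mean, GEBV for every GRM animal, optional PEV."""

    mu_hat: float
    gebv: np.ndarray
    grm_option: str
    lhs_inverse_diag: Optional[np.ndarray] = None


def grm_inverse_standard(bundle: GRMBundle) -> np.ndarray:
    """Dense inverse of the blended GRM (Cholesky + triangular inverse)."""
    Gb = np.asfortranarray(bundle.blended())
    c, info = scipy.linalg.lapack.dpotrf(Gb, lower=1, overwrite_a=True)
    if info != 0:
        raise ValueError(
            f"blended GRM is not positive definite (potrf info={info})"
        )
    invl, info = scipy.linalg.lapack.dpotri(c, lower=1, overwrite_c=True)
    if info != 0:  # pragma: no cover - potri cannot fail after potrf
        raise ValueError(f"inversion failed (potri info={info})")
    # potri fills the lower triangle; the strict upper one is stale
    inv = np.tril(invl) + np.tril(invl, k=-1).T
    return inv


def grm_inverse_truncated(bundle: GRMBundle, r: int) -> np.ndarray:
    """Inverse of the blended rank-truncated GRM ``G_eig + eps I``.

    In the eigenbasis the blended ``G_eig`` has eigenvalues ``d_i + eps``
    for ``i <= r`` and ``eps`` beyond, so the inverse is a single
    rescaled outer product — no dense factorization needed.
    """
    D, U = bundle.require_spectrum()
    if not 1 <= r <= len(D):
        raise ValueError(f"r={r} out of range [1, {len(D)}]")
    eps = bundle.blend_epsilon
    if eps <= 0:
        raise ValueError("truncated GRM requires a positive blend epsilon")
    w = np.full(len(D), 1.0 / eps)
    w[:r] = 1.0 / (D[:r] + eps)
    inv = (U * w) @ U.T
    return 0.5 * (inv + inv.T)


def _assemble_lhs(problem: GblupProblem) -> tuple[np.ndarray, np.ndarray, int]:
    """Coefficient matrix and right-hand side (scaled by sigma_e^2)."""
    n = problem.n_animals
    counts = np.zeros(n)
    wty = np.zeros(n)
    np.add.at(counts, problem.phen_idx, 1.0)
    np.add.at(wty, problem.phen_idx, problem.y)
    lhs_uu = problem.alpha * problem.g_inverse
    lhs_uu = lhs_uu + np.diag(counts)
    if problem.fit_intercept:
        n_rec = len(problem.y)
        lhs = np.empty((n + 1, n + 1))
        lhs[0, 0] = n_rec
        lhs[0, 1:] = counts
        lhs[1:, 0] = counts
        lhs[1:, 1:] = lhs_uu
        rhs = np.concatenate([[problem.y.sum()], wty])
        return lhs, rhs, 1
    return lhs_uu, wty, 0


def solve(problem: GblupProblem, return_lhs_inverse_diag: bool = False) -> GblupFit:
    """Solve the MME; unphenotyped animals are predicted through G."""
    lhs, rhs, k = _assemble_lhs(problem)
    try:
        cho = scipy.linalg.cho_factor(lhs)
    except scipy.linalg.LinAlgError:
        raise ValueError(
            f"singular MME coefficient matrix (grm_option={problem.grm_option!r})"
        ) from None
    sol = scipy.linalg.cho_solve(cho, rhs)
    diag = None
    if return_lhs_inverse_diag:
        inv = scipy.linalg.cho_solve(cho, np.eye(lhs.shape[0]))
        diag = inv.diagonal()[k:].copy()
    return GblupFit(
        mu_hat=float(sol[0]) if k else 0.0,
        gebv=sol[k:],
        grm_option=problem.grm_option,
        lhs_inverse_diag=diag,
    )


def pev_direct(problem: GblupProblem) -> np.ndarray:
    """PEV by dense inversion of the MME coefficient matrix.

    Returns ``sigma_e^2`` times the animal-block diagonal of the inverted
    left-hand side, i.e. prediction-error variance on the trait scale.
    Build the problem over training animals only when mimicking a
    validation protocol that excludes the validation animals entirely.
    """
    lhs, _, k = _assemble_lhs(problem)
    try:
        cho = scipy.linalg.cho_factor(lhs)
    except scipy.linalg.LinAlgError:
        raise ValueError(
            f"singular MME coefficient matrix (grm_option={problem.grm_option!r})"
        ) from None
    inv = scipy.linalg.cho_solve(cho, np.eye(lhs.shape[0]))
    return problem.sigma_e2 * inv.diagonal()[k:].copy()


def pev_reduced_rank(
    U: np.ndarray,
    D: np.ndarray,
    phen_idx: np.ndarray,
    y_or_n: int | np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    r: Optional[int] = None,
    blend_epsilon: float = 0.01,
    fit_intercept: bool = True,
) -> np.ndarray:
    """PEV through the GRM eigenbasis at cost ``O(n r^2 + r^3)``.

    Writes ``u = U_r gamma`` with ``var(gamma) = (D_r + eps I) sigma_u^2``
    and solves the ``r``-dimensional rotated MME; the PEV of ``u_i`` is
    the quadratic form of row ``i`` of ``U_r`` with the gamma-block of
    the inverted coefficient matrix.  With ``r = n`` this is algebraically
    identical to :func:`pev_direct` on the blended GRM.  ``y_or_n`` is
    only used for its length bookkeeping (PEV does not depend on the
    observed records), so the number of animals may be passed directly.
    """
    U = np.asarray(U)
    D = np.asarray(D, dtype=float)
    n = U.shape[0]
    if r is None:
        r = len(D)
    if not 1 <= r <= len(D):
        raise ValueError(f"r={r} out of range [1, {len(D)}]")
    if r < n:
        warnings.warn(
            f"rank-{r} eigenbasis cannot represent the blended GRM exactly "
            f"(n={n}); PEV is a reduced-rank approximation",
            stacklevel=2,
        )
    phen_idx = np.asarray(phen_idx, dtype=int)
    alpha = sigma_e2 / sigma_u2
    Ur = U[:, :r]
    d_b = D[:r] + blend_epsilon

    counts = np.zeros(n)
    np.add.at(counts, phen_idx, 1.0)
    UtWWU = (Ur * counts[:, None]).T @ Ur
    lhs_gg = UtWWU + np.diag(alpha / d_b)
    if fit_intercept:
        n_rec = len(phen_idx)
        cU = counts @ Ur
        lhs = np.empty((r + 1, r + 1))
        lhs[0, 0] = n_rec
        lhs[0, 1:] = cU
        lhs[1:, 0] = cU
        lhs[1:, 1:] = lhs_gg
        k = 1
    else:
        lhs, k = lhs_gg, 0
    inv = scipy.linalg.cho_solve(
        scipy.linalg.cho_factor(lhs), np.eye(lhs.shape[0])
    )
    C_gg = inv[k:, k:]
    pev = sigma_e2 * ((Ur @ C_gg) * Ur).sum(axis=1)
    return pev
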