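"""Genomic relationship matrices: VanRaden G, eigen-truncation, APY inverse.

The GRM is the marker-based covariance among genotyped individuals,

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),

where ``Z`` holds allele counts centered by twice the observed allele
frequency ``p_j`` of each marker.  Its eigendecomposition ``G = U D U'``
orders genomic variation by eigenvalue; truncating to the ``r`` largest
eigenvalues gives the reduced-rank ``G_eig = U D_r U'``.  Both ``G`` and
``G_eig`` are blended with ``0.01 I`` before inversion.  The APY inverse
is a sparse generalized inverse of ``G`` that only requires the dense
inverse of the core-animal block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

DEFAULT_BLEND_EPSILON = 0.01

__all__ = [
    "GenotypeMatrix",
    "GRMBundle",
    "ApyInverse",
    "build_grm",
    "eigendecompose",
    "variance_explained_profile",
    "truncate_grm",
    "blend",
    "select_core_random",
    "apy_inverse",
]


@dataclass
class GenotypeMatrix:
    """Animals x markers table of allele counts in {0, 1, 2}.

    Attributes
    ----------
    values
        Integer array of shape ``(n_animals, n_markers)``.
    animal_ids, marker_ids
        Identifier arrays aligned with the rows / columns of ``values``.
    """

    values: np.ndarray
    animal_ids: np.ndarray
    marker_ids: np.ndarray
    _freqs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.animal_ids = np.asarray(self.animal_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D animals x markers array")
        if self.values.shape[0] != len(self.animal_ids):
            raise ValueError("animal_ids length does not match genotype rows")
        if self.values.shape[1] != len(self.marker_ids):
            raise ValueError("marker_ids length does not match genotype columns")
        vmin, vmax = self.values.min(initial=0), self.values.max(initial=0)
        if vmin < 0 or vmax > 2:
            raise ValueError("allele counts must lie in {0, 1, 2}")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele at each marker."""
        if self._freqs is None:
            self._freqs = self.values.mean(axis=0) / 2.0
        return self._freqs

    def drop_monomorphic(self) -> "GenotypeMatrix":
        """Return a copy without markers that are fixed in this set."""
        p = self.allele_frequencies()
        keep = (p > 0.0) & (p < 1.0)
        return GenotypeMatrix(
            self.values[:, keep], self.animal_ids, self.marker_ids[keep]
        )


@dataclass
class GRMBundle:
    """A GRM together with (optionally) its spectral decomposition.

    ``G`` is the pre-blend VanRaden matrix; ``eigenvalues``/``eigenvectors``
    are filled by :func:`eigendecompose` with eigenvalues sorted in
    nonincreasing order and eigenvector columns aligned to them.
    """

    G: np.ndarray
    animal_ids: np.ndarray
    blend_epsilon: float = DEFAULT_BLEND_EPSILON
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_animals(self) -> int:
        return self.G.shape[0]

    def blended(self) -> np.ndarray:
        """``G + epsilon * I`` — the full-rank matrix used in the MME."""
        return blend(self.G, self.blend_epsilon)

    def require_spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        if self.eigenvalues is None or self.eigenvectors is None:
            raise ValueError("eigendecomposition not computed; call eigendecompose()")
        return self.eigenvalues, self.eigenvectors


def build_grm(genotypes: GenotypeMatrix) -> GRMBundle:
    """Construct the VanRaden GRM ``Z Z' / 2 sum p(1-p)``.

    Allele frequencies are the observed frequencies in the genotyped set.
    Monomorphic markers make the centering scale undefined and are
    rejected; filter them out first (:meth:`GenotypeMatrix.drop_monomorphic`).
    """
    if genotypes.n_animals < 2:
        raise ValueError("GRM needs at least two animals")
    if genotypes.n_markers < 1:
        raise ValueError("GRM needs at least one marker")
    p = genotypes.allele_frequencies()
    bad = np.flatnonzero((p <= 0.0) | (p >= 1.0))
    if bad.size:
        raise ValueError(
            f"{bad.size} monomorphic marker(s) (first: {genotypes.marker_ids[bad[0]]!r});"
            " centering is undefined at p=0 or p=1"
        )
    Z = np.asfortranarray(genotypes.values.astype(np.float64) - 2.0 * p)
    denom = 2.0 * np.sum(p * (1.0 - p))
    # rank-k update computes only one triangle (half the flops of dgemm)
    Gu = scipy.linalg.blas.dsyrk(1.0 / denom, Z, lower=0, trans=0)
    # dsyrk fills one triangle and leaves the other zero: mirror it
    G = Gu + Gu.T
    np.fill_diagonal(G, Gu.diagonal())
    return GRMBundle(
        G=G,
        animal_ids=genotypes.animal_ids,
        provenance={"builder": "vanraden", "n_markers": genotypes.n_markers},
    )


def eigendecompose(
    bundle: GRMBundle, clip_tol: float = 1e-8, vectors: bool = True
) -> GRMBundle:
    """Full symmetric eigendecomposition of the pre-blend GRM.

    Eigenvalues are sorted in nonincreasing order; small negative values
    (numerical noise on a Gramian matrix) are clipped at zero, anything
    below ``-clip_tol * max(|D|)`` aborts.  ``vectors=False`` computes
    eigenvalues only (several times faster; enough for variance-explained
    profiles).
    """
    if not np.all(np.isfinite(bundle.G)):
        raise ValueError("GRM contains non-finite entries")
    if vectors:
        D, U = scipy.linalg.eigh(bundle.G)
    else:
        D = scipy.linalg.eigh(bundle.G, eigvals_only=True)
        U = None
    order = np.argsort(D)[::-1]
    D = D[order]
    scale = max(abs(D[0]), 1.0)
    if D[-1] < -clip_tol * scale:
        raise ValueError(
            f"eigenvalue {D[-1]:.3e} is too negative for a relationship matrix"
        )
    bundle.eigenvalues = np.clip(D, 0.0, None)
    bundle.eigenvectors = U[:, order] if vectors else None
    return bundle


def variance_explained_profile(
    D: np.ndarray, thresholds: Sequence[float]
) -> tuple[Mapping[float, int], np.ndarray]:
    """Number of leading eigenvalues needed per explained-variance threshold.

    For each threshold ``t`` returns the smallest ``r`` such that
    ``tr(D_r)/tr(D) >= t``.  Also returns the full cumulative-fraction
    curve ``cum[k] = tr(D_{k+1})/tr(D)``.
    """
    D = np.asarray(D, dtype=float)
    total = D.sum()
    if total <= 0:
        raise ValueError("trace of D must be positive")
    for t in thresholds:
        if not 0.0 < t <= 1.0:
            raise ValueError(f"threshold {t} outside (0, 1]")
    cum = np.cumsum(D) / total
    # rounding can leave cum[-1] marginally below 1.0; the full spectrum
    # always explains everything
    counts = {
        t: int(min(np.searchsorted(cum, t) + 1, len(D))) for t in thresholds
    }
    return counts, cum


def truncate_grm(bundle: GRMBundle, r: int) -> np.ndarray:
    """Reduced-rank ``G_eig = U D_r U'`` keeping the r largest eigenvalues."""
    D, U = bundle.require_spectrum()
    if not 1 <= r <= len(D):
        raise ValueError(f"r={r} out of range [1, {len(D)}]")
    Ur = U[:, :r]
    G_eig = (Ur * D[:r]) @ Ur.T
    return 0.5 * (G_eig + G_eig.T)


def blend(matrix: np.ndarray, epsilon: float = DEFAULT_BLEND_EPSILON) -> np.ndarray:
    """Add ``epsilon * I`` so a rank-deficient relationship matrix inverts."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("blend expects a square matrix")
    out = matrix.copy()
    out[np.diag_indices_from(out)] += epsilon
    return out


def select_core_random(
    animal_ids: np.ndarray, n_core: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of core animals without replacement."""
    animal_ids = np.asarray(animal_ids)
    if not 1 <= n_core <= len(animal_ids):
        raise ValueError(f"n_core={n_core} out of range [1, {len(animal_ids)}]")
    idx = rng.choice(len(animal_ids), size=n_core, replace=False)
    return animal_ids[idx]


@dataclass
class ApyInverse:
    """The APY sparse generalized inverse of a (blended) GRM.

    Noncore animal effects are modelled by recursion on the core animals,
    with individual residual variance ``m_nn,i = g_ii - g_ic Gcc^-1 g_ci``.
    The assembled inverse is

        G_APY^-1 = [[Gcc^-1, 0], [0, 0]]
                   + [-Gcc^-1 Gcn; I] Mnn^-1 [-Gnc Gcc^-1, I]

    and is stored in blocks; :meth:`matrix` assembles it densely in the
    original animal order.
    """

    core_ids: np.ndarray
    noncore_ids: np.ndarray
    inv_Gcc: np.ndarray
    Gcn: np.ndarray
    m_nn: np.ndarray
    order: np.ndarray  # permutation mapping [core, noncore] -> original rows

    @property
    def n_core(self) -> int:
        return len(self.core_ids)

    def matrix(self) -> np.ndarray:
        n_c, n_n = self.inv_Gcc.shape[0], len(self.m_nn)
        n = n_c + n_n
        T = self.inv_Gcc @ self.Gcn  # Gcc^-1 Gcn
        out = np.zeros((n, n))
        out[:n_c, :n_c] = self.inv_Gcc + (T / self.m_nn) @ T.T
        out[:n_c, n_c:] = -T / self.m_nn
        out[n_c:, :n_c] = out[:n_c, n_c:].T
        out[n_c:, n_c:][np.diag_indices(n_n)] = 1.0 / self.m_nn
        # undo the core-first permutation
        inv_order = np.argsort(self.order)
        return out[np.ix_(inv_order, inv_order)]


def apy_inverse(
    bundle: GRMBundle, core_ids: np.ndarray, *, blended: bool = True
) -> ApyInverse:
    """APY inverse of ``bundle``'s GRM with the given core subset.

    The GRM is blended (``+ epsilon I``) before partitioning by default;
    without blending ``m_nn,i`` can hit zero for animals fully explained
    by the core.
    """
    G = bundle.blended() if blended else bundle.G
    ids = np.asarray(bundle.animal_ids)
    core_ids = np.asarray(core_ids)
    pos = {a: i for i, a in enumerate(ids.tolist())}
    try:
        core_idx = np.array([pos[a] for a in core_ids.tolist()], dtype=int)
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"core animal {e.args[0]!r} not in GRM") from None
    if len(np.unique(core_idx)) != len(core_idx):
        raise ValueError("duplicate core animals")
    mask = np.ones(len(ids), dtype=bool)
    mask[core_idx] = False
    noncore_idx = np.flatnonzero(mask)
    order = np.concatenate([core_idx, noncore_idx])

    Gcc = G[np.ix_(core_idx, core_idx)]
    Gcn = G[np.ix_(core_idx, noncore_idx)]
    cho = scipy.linalg.cho_factor(Gcc)
    inv_Gcc = scipy.linalg.cho_solve(cho, np.eye(len(core_idx)))
    inv_Gcc = 0.5 * (inv_Gcc + inv_Gcc.T)
    # m_nn,i = g_ii - g_ic Gcc^-1 g_ci
    m_nn = G[noncore_idx, noncore_idx] - np.einsum(
        "ij,ij->j", Gcn, scipy.linalg.cho_solve(cho, Gcn)
    )
    if noncore_idx.size and m_nn.min() <= 0.0:
        offender = bundle.animal_ids[noncore_idx[int(np.argmin(m_nn))]]
        raise ValueError(
            f"nonpositive APY residual variance for animal {offender!r};"
            " core too small or GRM not blended"
        )
    return ApyInverse(
        core_ids=ids[core_idx],
        noncore_ids=ids[noncore_idx],
        inv_Gcc=inv_Gcc,
        Gcn=Gcn,
        m_nn=m_nn,
        order=order,
    )
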