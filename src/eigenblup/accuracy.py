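"""Validation measures: realized accuracy, PEV-based accuracy, M_e formulas.

Two complementary views of prediction quality:

* realized accuracy — the correlation between GEBV and the simulated
  true breeding values in the unphenotyped validation generation;
* PEV-based accuracy — ``acc_i = sqrt(1 - PEV_i / (sigma_u^2 g_ii))``
  per training animal, convertible to an effective number of genomic
  records ``d_i^g`` through ``acc_i ~ sqrt(1 - a / (a + d_i^p + d_i^g))``
  with ``a = sigma_e^2 / sigma_u^2``; the training-set mean ``d^g``
  then approximates the accuracy of validation animals as
  ``sqrt(1 - a / (a + mean d^g))``.

Also provided: the count of eigenvalues exceeding the variance ratio
``a`` (a diagnostic for which eigen-components carry estimable signal)
and the classical formulas for the number of independent chromosome
segments M_e.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "realized_accuracy",
    "pev_accuracy",
    "effective_genomic_records",
    "population_accuracy",
    "alpha_threshold_count",
    "me_formulas",
    "MeFormulas",
]


def realized_accuracy(
    gebv: np.ndarray, tbv: np.ndarray, validation_idx: np.ndarray
) -> float:
    """Pearson correlation of GEBV with TBV over validation animals.

    Returns NaN when either vector has zero variance in the validation
    set (the correlation is undefined).
    """
    g = np.asarray(gebv, float)[validation_idx]
    t = np.asarray(tbv, float)[validation_idx]
    if np.std(g) == 0.0 or np.std(t) == 0.0:
        return float("nan")
    return float(np.corrcoef(g, t)[0, 1])


def pev_accuracy(
    pev: np.ndarray, sigma_u2: float, g_ii: np.ndarray, tol: float = 1e-8
) -> np.ndarray:
    """Per-animal accuracy ``sqrt(1 - PEV_i / (sigma_u^2 g_ii))``.

    PEV marginally above the prior variance (within ``tol`` relative) is
    clipped to accuracy 0; larger excess signals inconsistent inputs.
    """
    pev = np.asarray(pev, float)
    g_ii = np.asarray(g_ii, float)
    prior = sigma_u2 * g_ii
    ratio = pev / prior
    if np.any(ratio > 1.0 + tol):
        i = int(np.argmax(ratio))
        raise ValueError(
            f"PEV {pev.flat[i]:.6g} exceeds prior variance {prior.flat[i]:.6g}"
            " beyond tolerance; inconsistent inputs"
        )
    return np.sqrt(np.clip(1.0 - ratio, 0.0, None))


def effective_genomic_records(
    acc: np.ndarray, alpha: float, d_p: float = 1.0
) -> np.ndarray:
    """Invert ``acc = sqrt(1 - a/(a + d_p + d_g))`` for ``d_g``.

    ``d_p`` is the phenotypic information (1 for one record per animal).
    Negative solutions floor at 0; accuracy of exactly 1 implies
    infinite records and is reported as NaN.
    """
    acc = np.asarray(acc, float)
    if np.any((acc < 0.0) | (acc > 1.0)):
        raise ValueError("accuracies must lie in [0, 1]")
    rel = acc**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d_g = alpha * rel / (1.0 - rel) - d_p
    d_g = np.where(acc >= 1.0, np.nan, d_g)
    return np.clip(d_g, 0.0, None)


def population_accuracy(mean_d_g: float, alpha: float) -> float:
    """Approximate accuracy of unphenotyped animals from the same
    population: ``sqrt(1 - a / (a + mean d^g))``."""
    if mean_d_g < 0:
        raise ValueError("mean effective records must be nonnegative")
    return float(np.sqrt(1.0 - alpha / (alpha + mean_d_g)))


def alpha_threshold_count(D: np.ndarray, alpha: float) -> int:
    """Number of eigenvalues strictly greater than the variance ratio.

    Eigen-components with eigenvalue below ``a = sigma_e^2/sigma_u^2``
    contribute less signal than noise per record and are effectively
    ignored by the MME shrinkage, so this count marks where the accuracy
    plateau is expected.
    """
    D = np.asarray(D, float)
    return int(np.sum(D > alpha))


class MeFormulas(NamedTuple):
    """Independent chromosome segments by three classical formulas."""

    stam: float  # 4 Ne L
    hayes: float  # 2 Ne L
    goddard: float  # 2 Ne L / ln(4 Ne L)


def me_formulas(ne: float, genome_length_morgan: float) -> MeFormulas:
    """M_e from Ne and genome length L in Morgan (natural log)."""
    if ne <= 0 or genome_length_morgan <= 0:
        raise ValueError("Ne and L must be positive")
    four_nel = 4.0 * ne * genome_length_morgan
    return MeFormulas(
        stam=four_nel,
        hayes=2.0 * ne * genome_length_morgan,
        goddard=2.0 * ne * genome_length_morgan / np.log(four_nel),
    )
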