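"""GRM construction, spectrum, truncation, blending, and the APY inverse."""

import numpy as np
import pytest

from eigenblup import popsim
from eigenblup.gblup import grm_inverse_standard
from eigenblup.grm import (
    GenotypeMatrix,
    apy_inverse,
    blend,
    build_grm,
    eigendecompose,
    select_core_random,
    truncate_grm,
    variance_explained_profile,
)

from conftest import random_grm, tiny_scenario


def brute_force_vanraden(values: np.ndarray) -> np.ndarray:
    """Element-by-element double-loop VanRaden G (independent oracle)."""
    n, m = values.shape
    p = np.array([values[:, j].sum() / (2 * n) for j in range(m)])
    denom = 2 * sum(p[j] * (1 - p[j]) for j in range(m))
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum(
                (values[i, j] - 2 * p[j]) * (values[k, j] - 2 * p[j])
                for j in range(m)
            ) / denom
    return G


class TestBuildGrm:
    def test_duplicate_animals_share_all_entries(self):
        values = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0], [1, 0, 1, 2]])
        g = build_grm(GenotypeMatrix(values, np.arange(4), np.arange(4))).G
        assert g[0, 0] == pytest.approx(g[1, 1])
        assert g[0, 1] == pytest.approx(g[0, 0])

    def test_matches_double_loop_oracle(self, toy_genotypes):
        G = build_grm(toy_genotypes).G
        np.testing.assert_allclose(
            G, brute_force_vanraden(toy_genotypes.values), atol=1e-12
        )

    def test_rejects_monomorphic_marker(self):
        values = np.array([[0, 1], [0, 2], [0, 1]])
        geno = GenotypeMatrix(values, np.arange(3), np.array(["mono", "ok"]))
        with pytest.raises(ValueError, match="mono"):
            build_grm(geno)
        assert build_grm(geno.drop_monomorphic()).G.shape == (3, 3)

    def test_average_diagonal_near_one_in_simulated_population(self):
        sim = popsim.simulate(tiny_scenario(seed=5))
        bundle = build_grm(sim.genotypes)
        assert 0.9 <= bundle.G.trace() / bundle.n_animals <= 1.3

    def test_symmetry_exact(self, grm5):
        assert np.array_equal(grm5.G, grm5.G.T)


class TestEigendecomposition:
    def test_identity_matrix(self):
        from eigenblup.grm import GRMBundle

        b = GRMBundle(G=np.eye(3), animal_ids=np.arange(3))
        eigendecompose(b)
        np.testing.assert_allclose(b.eigenvalues, np.ones(3))
        np.testing.assert_allclose(b.eigenvectors @ b.eigenvectors.T, np.eye(3), atol=1e-12)

    def test_matches_characteristic_polynomial_roots(self, grm5):
        eigendecompose(grm5)
        # Faddeev-LeVerrier coefficients + a companion-matrix root finder:
        # an algorithm independent of the symmetric eigensolver
        A = grm5.G
        n = A.shape[0]
        coeffs = [1.0]
        M = np.zeros_like(A)
        for k in range(1, n + 1):
            M = A @ M + coeffs[-1] * np.eye(n)
            coeffs.append(-(A @ M).trace() / k)
        roots = np.sort(np.roots(coeffs))[::-1].real
        np.testing.assert_allclose(grm5.eigenvalues, roots, atol=1e-8)

    def test_rank_bounded_by_markers(self):
        bundle = random_grm(12, 5, seed=3)
        eigendecompose(bundle)
        assert np.sum(bundle.eigenvalues > 1e-8) <= 5

    def test_spectral_trace_consistency(self, grm5):
        eigendecompose(grm5)
        assert grm5.eigenvalues.sum() == pytest.approx(grm5.G.trace(), rel=1e-8)

    def test_reconstruction(self, grm5):
        eigendecompose(grm5)
        D, U = grm5.eigenvalues, grm5.eigenvectors
        rec = (U * D) @ U.T
        rel = np.linalg.norm(rec - grm5.G) / np.linalg.norm(grm5.G)
        assert rel < 1e-6

    def test_values_only_mode_matches(self, grm5):
        eigendecompose(grm5)
        vals = grm5.eigenvalues.copy()
        grm5.eigenvalues = grm5.eigenvectors = None
        eigendecompose(grm5, vectors=False)
        np.testing.assert_allclose(grm5.eigenvalues, vals, atol=1e-10)
        assert grm5.eigenvectors is None

    def test_rejects_nonfinite(self):
        from eigenblup.grm import GRMBundle

        b = GRMBundle(G=np.array([[1.0, np.nan], [np.nan, 1.0]]), animal_ids=np.arange(2))
        with pytest.raises(ValueError, match="finite"):
            eigendecompose(b)


class TestVarianceProfile:
    def test_hand_computed_counts(self):
        D = np.array([4.0, 3.0, 2.0, 1.0])
        counts, cum = variance_explained_profile(D, [0.7])
        assert counts[0.7] == 2  # 7/10 >= 0.7
        assert cum[-1] == pytest.approx(1.0)
        assert np.all(np.diff(cum) >= 0)

    def test_flat_spectrum(self):
        counts, _ = variance_explained_profile(np.ones(100), [0.5])
        assert counts[0.5] == 50

    def test_counts_nondecreasing_in_threshold(self, grm5):
        eigendecompose(grm5)
        ts = [0.1, 0.3, 0.5, 0.7, 0.9, 0.98]
        counts, _ = variance_explained_profile(grm5.eigenvalues, ts)
        vals = [counts[t] for t in ts]
        assert vals == sorted(vals)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_rejects_bad_threshold(self, bad):
        with pytest.raises(ValueError):
            variance_explained_profile(np.ones(3), [bad])


class TestTruncation:
    def test_full_rank_recovers_g(self, grm5):
        eigendecompose(grm5)
        G_eig = truncate_grm(grm5, grm5.n_animals)
        rel = np.linalg.norm(G_eig - grm5.G) / np.linalg.norm(grm5.G)
        assert rel < 1e-6

    def test_rank_one_is_leading_outer_product(self, grm5):
        eigendecompose(grm5)
        G1 = truncate_grm(grm5, 1)
        d1, u1 = grm5.eigenvalues[0], grm5.eigenvectors[:, 0]
        np.testing.assert_allclose(G1, d1 * np.outer(u1, u1), atol=1e-12)

    def test_trace_identity(self, grm5):
        eigendecompose(grm5)
        for r in range(1, 6):
            assert truncate_grm(grm5, r).trace() == pytest.approx(
                grm5.eigenvalues[:r].sum(), rel=1e-8
            )

    def test_eckart_young_beats_random_rank_r(self, grm5):
        eigendecompose(grm5)
        rng = np.random.default_rng(0)
        for r in (1, 2, 3):
            best = np.linalg.norm(grm5.G - truncate_grm(grm5, r))
            for _ in range(25):
                B = rng.normal(size=(5, r))
                cand = B @ B.T * np.sign(rng.normal())
                # symmetric rank-<=r candidate, rescaled to the same trace
                if cand.trace() != 0:
                    cand *= grm5.G.trace() / cand.trace()
                assert best <= np.linalg.norm(grm5.G - cand) + 1e-12

    @pytest.mark.parametrize("r", [0, 6, -1])
    def test_rejects_out_of_range_rank(self, grm5, r):
        eigendecompose(grm5)
        with pytest.raises(ValueError):
            truncate_grm(grm5, r)


class TestBlend:
    def test_zero_matrix(self):
        np.testing.assert_allclose(blend(np.zeros((3, 3)), 0.01), 0.01 * np.eye(3))

    def test_shifts_spectrum_to_positive_definite(self, grm5):
        eigendecompose(grm5)
        for r in (1, 3, 5):
            Gb = blend(truncate_grm(grm5, r), 0.01)
            np.linalg.cholesky(Gb)  # raises if not PD
            assert np.linalg.eigvalsh(Gb).min() >= 0.01 - 1e-8

    def test_unblended_rank_deficient_inversion_refused(self):
        bundle = random_grm(8, 3, seed=9)  # rank <= 3 < 8
        bundle.blend_epsilon = 0.0
        with pytest.raises(ValueError, match="positive definite"):
            grm_inverse_standard(bundle)


class TestCoreSelection:
    def test_all_animals(self):
        ids = np.arange(7)
        core = select_core_random(ids, 7, np.random.default_rng(0))
        assert sorted(core) == list(ids)

    def test_deterministic_under_seed(self):
        ids = np.arange(100)
        a = select_core_random(ids, 10, np.random.default_rng(5))
        b = select_core_random(ids, 10, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_size_and_uniqueness(self):
        core = select_core_random(np.arange(6000), 1000, np.random.default_rng(1))
        assert len(core) == 1000
        assert len(np.unique(core)) == 1000

    @pytest.mark.parametrize("n_core", [0, 8])
    def test_rejects_out_of_range(self, n_core):
        with pytest.raises(ValueError):
            select_core_random(np.arange(7), n_core, np.random.default_rng(0))


def apy_block_oracle(G: np.ndarray, core: list[int]) -> np.ndarray:
    """Textbook block-formula evaluation with plain inv() calls."""
    n = G.shape[0]
    noncore = [i for i in range(n) if i not in core]
    order = core + noncore
    Gp = G[np.ix_(order, order)]
    nc = len(core)
    Gcc, Gcn = Gp[:nc, :nc], Gp[:nc, nc:]
    Gnc, Gnn = Gp[nc:, :nc], Gp[nc:, nc:]
    iGcc = np.linalg.inv(Gcc)
    m = np.diag(np.diag(Gnn - Gnc @ iGcc @ Gcn))
    top = np.zeros((n, n))
    top[:nc, :nc] = iGcc
    wings = np.vstack([-iGcc @ Gcn, np.eye(n - nc)])
    apy = top + wings @ np.linalg.inv(m) @ wings.T
    inv_order = np.argsort(order)
    return apy[np.ix_(inv_order, inv_order)]


class TestApyInverse:
    def test_all_core_equals_dense_inverse(self, grm5):
        apy = apy_inverse(grm5, grm5.animal_ids)
        dense = np.linalg.inv(grm5.blended())
        rel = np.linalg.norm(apy.matrix() - dense) / np.linalg.norm(dense)
        assert rel < 1e-6

    def test_matches_block_formula_oracle(self, grm5):
        core = [4, 1, 2]  # unordered subset on purpose
        apy = apy_inverse(grm5, grm5.animal_ids[core])
        expected = apy_block_oracle(grm5.blended(), core)
        np.testing.assert_allclose(apy.matrix(), expected, atol=1e-10)

    def test_assembled_inverse_symmetric_and_mnn_positive(self, grm5):
        apy = apy_inverse(grm5, grm5.animal_ids[:2])
        assert np.all(apy.m_nn > 0)
        M = apy.matrix()
        np.testing.assert_allclose(M, M.T, atol=1e-10)

    def test_exact_when_core_spans_row_space(self):
        # rank-3 G; with 3 core animals spanning the row space the APY
        # recursion loses nothing on the core block of the blended matrix
        bundle = random_grm(6, 3, seed=21)
        eigendecompose(bundle)
        assert np.sum(bundle.eigenvalues > 1e-8) == 3
        core = [0, 2, 4]
        apy = apy_inverse(bundle, bundle.animal_ids[core])
        prod = apy.matrix() @ bundle.blended()
        np.testing.assert_allclose(
            prod[np.ix_(core, core)], np.eye(3), atol=1e-4
        )

    def test_rejects_nonpositive_residual(self):
        # duplicated animal fully explained by the core, unblended
        values = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0], [1, 0, 1, 2]])
        bundle = build_grm(GenotypeMatrix(values, np.arange(4), np.arange(4)))
        with pytest.raises(ValueError, match="core too small|animal"):
            apy_inverse(bundle, bundle.animal_ids[:1], blended=False)
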