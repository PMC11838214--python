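import numpy as np
import pytest

import clonedeconv as cd
from clonedeconv import ilp_core
from clonedeconv.data_model import compute_pi, resolve_regularizers

from _brute import c_step_enumerate, u_step_grid
from conftest import random_micro_instance


class TestUStep:
    def test_single_clone_identity(self):
        rng = np.random.default_rng(0)
        C = rng.integers(0, 4, size=(1, 6)).astype(float)
        F = np.vstack([C[0]] * 3)
        U, obj1 = ilp_core.solve_u_step(F, C)
        assert np.allclose(U, 1.0)
        assert obj1 == pytest.approx(0.0, abs=1e-8)

    def test_exact_two_clone_mixture(self):
        rng = np.random.default_rng(1)
        C = rng.integers(0, 4, size=(2, 8)).astype(float)
        F = (0.3 * C[0] + 0.7 * C[1])[None, :]
        U, obj1 = ilp_core.solve_u_step(F, C)
        assert obj1 == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(np.sort(U[0]), [0.3, 0.7], atol=1e-6)

    def test_matches_simplex_grid_search(self):
        rng = np.random.default_rng(2)
        C = rng.integers(0, 3, size=(3, 10)).astype(float)
        F = rng.uniform(0, 2, size=(2, 10))
        U, obj1 = ilp_core.solve_u_step(F, C)
        grid = u_step_grid(F, C, step=0.01)
        assert obj1 <= grid + 1e-9          # LP at least as good as the grid
        assert obj1 == pytest.approx(grid, abs=0.02)

    def test_rows_sum_to_one_and_uniform_bound(self):
        rng = np.random.default_rng(3)
        C = rng.integers(0, 3, size=(3, 12)).astype(float)
        F = rng.uniform(0, 2, size=(4, 12))
        U, obj1 = ilp_core.solve_u_step(F, C)
        assert np.allclose(U.sum(axis=1), 1.0, atol=1e-6)
        U0 = np.full_like(U, 1 / 3)
        assert obj1 <= np.abs(F - U0 @ C).sum() + 1e-9


def build_micro_model(seed, m=2, c_max=2):
    bulk, rna, U = random_micro_instance(seed, m=m)
    cfg = cd.DescentConfig(n=3, c_max=c_max)
    dims = cd.validate_problem(bulk, rna, cfg)
    reg = resolve_regularizers(dims, cfg)
    return bulk, rna, U, dims, reg, cfg


class TestCStepStructure:
    def test_variable_counts(self, tiny_noise_free):
        bulk, rna, truth = tiny_noise_free
        cfg = cd.DescentConfig(n=3, c_max=6)
        dims = cd.validate_problem(bulk, rna, cfg)
        reg = resolve_regularizers(dims, cfg)
        U = np.full((dims.m, 3), 1 / 3)
        model = ilp_core.build_c_step(bulk, rna, U, dims, reg, cfg)
        n_mut = dims.n_mut
        assert model.var_counts["C"] == 3 * dims.K
        assert model.var_counts["M"] == 9
        assert model.var_counts["E"] == 9
        assert model.var_counts["A"] == 9
        assert model.var_counts["W"] == 9 * n_mut
        assert model.var_counts["D"] == n_mut
        assert model.var_counts["auxiliary"] > 0

    def test_n3_tree_is_forced_chain(self, tiny_noise_free):
        """With one leaf, one internal node and the root, the only valid
        tree is root -> internal -> leaf."""
        bulk, rna, truth = tiny_noise_free
        cfg = cd.DescentConfig(n=3, c_max=6)
        dims = cd.validate_problem(bulk, rna, cfg)
        reg = resolve_regularizers(dims, cfg)
        U = np.full((dims.m, 3), 1 / 3)
        model = ilp_core.build_c_step(bulk, rna, U, dims, reg, cfg)
        sol, _ = ilp_core.solve_c_step(model)
        expected = np.zeros((3, 3), dtype=int)
        expected[2, 1] = expected[1, 0] = 1
        assert np.array_equal(sol.E, expected)

    def test_root_genotype_and_invariants(self, tiny_noisy):
        bulk, rna, truth = tiny_noisy
        cfg = cd.DescentConfig(n=3, c_max=6)
        dims = cd.validate_problem(bulk, rna, cfg)
        reg = resolve_regularizers(dims, cfg)
        rng = np.random.default_rng(5)
        U = rng.dirichlet(np.ones(3), size=dims.m)
        model = ilp_core.build_c_step(bulk, rna, U, dims, reg, cfg)
        sol, _ = ilp_core.solve_c_step(model)
        n_mut = dims.n_mut
        # root row: no mutations, diploid segments
        assert np.all(sol.C[2, :n_mut] == 0)
        assert np.all(sol.C[2, n_mut:] == 1)
        # M is a permutation
        assert np.all(sol.M.sum(axis=0) == 1) and np.all(sol.M.sum(axis=1) == 1)
        # E has n-1 edges, A is its reachability closure
        assert sol.E.sum() == 2
        assert np.array_equal(sol.A, ilp_core.ancestry_closure(sol.E))
        # Dollo: every mutation placed on exactly one tree edge
        assert np.all(sol.W.sum(axis=(0, 1)) == 1)
        assert np.all(sol.W <= sol.E[:, :, None])
        # gain-edge child is ancestor-or-self of every carrier
        for k in range(n_mut):
            i, j = np.argwhere(sol.W[:, :, k] == 1)[0]
            carriers = np.nonzero(sol.C[:, k] >= 1)[0]
            for p in carriers:
                assert p == j or sol.A[j, p] == 1
        # allele-gated copy-number bound
        seg_of = np.argmax(bulk.Q, axis=1)
        for p in range(3):
            for b in range(n_mut):
                allele = int(sol.D[b])
                col = n_mut + (0 if allele == 1 else dims.r) + seg_of[b]
                assert sol.C[p, b] <= sol.C[p, col]

    def test_crna_row_permutation_absorbed_by_m(self):
        """Permuting RNA clone rows leaves the optimal objective unchanged."""
        bulk, rna, U, dims, reg, cfg = build_micro_model(seed=9)
        model = ilp_core.build_c_step(bulk, rna, U, dims, reg, cfg)
        _, obj = ilp_core.solve_c_step(model)
        rna_p = cd.RnaCloneProfile(C_rna=rna.C_rna[[2, 0, 1]])
        model_p = ilp_core.build_c_step(bulk, rna_p, U, dims, reg, cfg)
        _, obj_p = ilp_core.solve_c_step(model_p)
        assert obj == pytest.approx(obj_p, abs=1e-6)

    def test_zero_residual_on_planted_input(self, tiny_noise_free):
        """With exact F, CRNA from truth, and U fixed at U*, the C-step fits
        the data perfectly (residual terms 0) and recovers the segment block."""
        bulk, rna, truth = tiny_noise_free
        cfg = cd.DescentConfig(n=3, c_max=6)
        dims = cd.validate_problem(bulk, rna, cfg)
        reg = resolve_regularizers(dims, cfg)
        model = ilp_core.build_c_step(bulk, rna, truth.U, dims, reg, cfg)
        sol, _ = ilp_core.solve_c_step(model)
        t = sol.term_breakdown
        assert t["data_fit"] == pytest.approx(0.0, abs=1e-6)
        assert t["rna_fit"] == pytest.approx(0.0, abs=1e-6)
        assert np.array_equal(sol.C[:, dims.n_mut:], truth.C[:, dims.n_mut:])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_c_step_matches_enumeration(self, seed):
        """ILP optimum equals exhaustive enumeration on n=3, l=2, g=2, r=2,
        c_max=2 instances."""
        bulk, rna, U, dims, reg, cfg = build_micro_model(seed)
        pi = compute_pi(bulk, c_max=cfg.c_max)
        model = ilp_core.build_c_step(bulk, rna, U, dims, reg, cfg, pi=pi)
        _, obj = ilp_core.solve_c_step(model)
        brute = c_step_enumerate(bulk.F, U, rna.C_rna, bulk.Q, pi.pi, pi.valid,
                                 reg.lambda1, reg.lambda2, c_max=cfg.c_max)
        assert obj == pytest.approx(brute, abs=1e-6)
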