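import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clonedeconv as cd
from clonedeconv.data_model import ProblemDims, ValidationError, compute_lambdas


def make_consistent_inputs(n=3, m=2, l=4, g=4, r=3):
    K = l + g + 2 * r
    Q = np.zeros((l + g, r), dtype=int)
    Q[np.arange(l + g), np.arange(l + g) % r] = 1
    G = np.zeros((l, l), dtype=int)
    for k in range(l // 2):
        G[2 * k, 2 * k + 1] = G[2 * k + 1, 2 * k] = 1
    F = np.abs(np.random.default_rng(0).normal(1, 0.3, size=(m, K)))
    C_rna = np.ones((n, 2 * r), dtype=int)
    return cd.BulkProfile(F=F, Q=Q, G=G, l=l, g=g, r=r), cd.RnaCloneProfile(C_rna=C_rna)


class TestValidateProblem:
    def test_consistent_case(self):
        bulk, rna = make_consistent_inputs()
        dims = cd.validate_problem(bulk, rna, cd.DescentConfig(n=3))
        assert (dims.n, dims.m, dims.l, dims.g, dims.r) == (3, 2, 4, 4, 3)
        assert dims.n_prime == 1

    def test_even_n_rejected(self):
        bulk, rna = make_consistent_inputs()
        rna4 = cd.RnaCloneProfile(C_rna=np.ones((4, 6), dtype=int))
        with pytest.raises(ValidationError, match="odd"):
            cd.validate_problem(bulk, rna4, cd.DescentConfig(n=4))

    def test_unpaired_breakpoint_rejected(self):
        bulk, rna = make_consistent_inputs()
        bulk.G[0, 1] = bulk.G[1, 0] = 0
        with pytest.raises(ValidationError, match="unpaired"):
            cd.validate_problem(bulk, rna, cd.DescentConfig(n=3))

    def test_q_not_one_hot_rejected(self):
        bulk, rna = make_consistent_inputs()
        bulk.Q[0] = 0
        with pytest.raises(ValidationError, match="one-hot"):
            cd.validate_problem(bulk, rna, cd.DescentConfig(n=3))

    def test_idempotent(self):
        bulk, rna = make_consistent_inputs()
        cfg = cd.DescentConfig(n=3)
        F_before = bulk.F.copy()
        d1 = cd.validate_problem(bulk, rna, cfg)
        d2 = cd.validate_problem(bulk, rna, cfg)
        assert d1 == d2
        assert np.array_equal(bulk.F, F_before)


class TestLambdas:
    def test_printed_formula_values(self):
        # l=80, g=40, r=20, m=2, n=5: lambda1 = (160*2)/(2*40*5) = 0.8,
        # lambda2 = 160/(2*120) = 2/3
        dims = ProblemDims(n=5, m=2, l=80, g=40, r=20)
        reg = compute_lambdas(dims)
        assert reg.lambda1 == pytest.approx(0.8)
        assert reg.lambda2 == pytest.approx(160 / 240)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(g=st.integers(1, 200), l_half=st.integers(0, 100),
           r=st.integers(1, 50), m=st.integers(1, 10))
    def test_lambda2_scale_identity(self, g, l_half, r, m):
        """lambda2 * (l+g) = (l+g+2r)/2 exactly, for any problem size."""
        dims = ProblemDims(n=3, m=m, l=2 * l_half, g=g, r=r)
        reg = compute_lambdas(dims)
        assert reg.lambda2 * (dims.l + dims.g) == pytest.approx(dims.K / 2)

    def test_snv_only_problem_defined(self):
        reg = compute_lambdas(ProblemDims(n=3, m=1, l=0, g=5, r=2))
        assert np.isfinite(reg.lambda1) and np.isfinite(reg.lambda2)


class TestPiRatios:
    def make_bulk(self, F, l=2, g=1, r=2):
        Q = np.zeros((l + g, r), dtype=int)
        Q[0, 0] = Q[1, 1] = Q[2, 0] = 1
        G = np.array([[0, 1], [1, 0]])
        return cd.BulkProfile(F=np.asarray(F, float), Q=Q, G=G, l=l, g=g, r=r)

    def test_ratio_arithmetic(self):
        # breakpoint CN 1.0 over segment alleles 1.2 + 0.8 -> pi = 0.5
        F = [[1.0, 0.3, 0.2, 1.2, 1.0, 0.8, 1.0]]
        pi = cd.compute_pi(self.make_bulk(F))
        assert pi.pi[0, 0] == pytest.approx(0.5)
        assert pi.valid[0, 0]

    def test_zero_numerator(self):
        F = [[0.0, 0.3, 0.2, 1.2, 1.0, 0.8, 1.0]]
        pi = cd.compute_pi(self.make_bulk(F))
        assert pi.pi[0, 0] == 0.0 and pi.valid[0, 0]

    def test_zero_denominator_flagged(self):
        F = [[1.0, 0.3, 0.2, 0.0, 1.0, 0.0, 1.0]]
        pi = cd.compute_pi(self.make_bulk(F))
        assert not pi.valid[0, 0]
        assert pi.valid[0, 1]

    def test_commutes_with_sample_permutation(self):
        rng = np.random.default_rng(3)
        F = rng.uniform(0, 2, size=(4, 7))
        bulk = self.make_bulk(F)
        pi = cd.compute_pi(bulk)
        perm = [2, 0, 3, 1]
        bulk_p = self.make_bulk(F[perm])
        pi_p = cd.compute_pi(bulk_p)
        assert np.allclose(pi.pi[perm], pi_p.pi)
        assert np.array_equal(pi.valid[perm], pi_p.valid)

    def test_clipped_to_cmax(self):
        F = [[5.0, 0.0, 0.0, 0.2, 1.0, 0.2, 1.0]]
        pi = cd.compute_pi(self.make_bulk(F), c_max=4)
        assert pi.pi[0, 0] == 4.0
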