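import numpy as np
import pytest

import clonedeconv as cd
from clonedeconv import ilp_core
from clonedeconv import simulator as sim
from clonedeconv.data_model import resolve_regularizers


class TestTreeAndGenotypes:
    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_tree_shape(self, n):
        rng = np.random.default_rng(0)
        for _ in range(10):
            E = sim.simulate_tree(n, rng)
            n_prime = (n - 1) // 2
            assert E.sum() == n - 1
            assert np.all(E[:, n - 1] == 0)                 # root has no parent
            assert np.all(E[:n_prime].sum(axis=1) == 0)     # leaves childless
            assert np.all(E[:, :n - 1].sum(axis=0) == 1)    # in-degree 1
            assert np.all(E[n_prime:].sum(axis=1) >= 1)     # internal has child
            assert np.all(E.sum(axis=1) <= 2)
            A = ilp_core.ancestry_closure(E)
            assert np.all(A[n - 1, :n - 1] == 1)            # root ancestral to all

    def test_root_genotype_is_normal(self, tiny_noise_free):
        _, _, truth = tiny_noise_free
        d = truth.dims
        assert np.all(truth.C[d.root, :d.n_mut] == 0)
        assert np.all(truth.C[d.root, d.n_mut:] == 1)

    def test_event_type_frequencies(self):
        """Empirical amplification:inversion:deletion:translocation draws
        match the 2:1:2:1 weights within 2% at 10,000 draws."""
        kinds = sim.draw_event_kinds(10_000, rng=1)
        freq = np.bincount(kinds, minlength=4) / 10_000
        assert np.allclose(freq, [1 / 3, 1 / 6, 1 / 3, 1 / 6], atol=0.02)

    def test_sv_length_mean(self):
        lengths = sim.draw_sv_lengths(10_000, rng=2)
        assert abs(lengths.mean() - 5_745_000) / 5_745_000 < 0.001

    def test_planted_solution_feasible_for_ilp(self, tiny_noise_free):
        bulk, rna, truth = tiny_noise_free
        cfg = cd.DescentConfig(n=3, c_max=6)
        dims = cd.validate_problem(bulk, rna, cfg)
        reg = resolve_regularizers(dims, cfg)
        model = ilp_core.build_c_step(bulk, rna, truth.U, dims, reg, cfg)
        x = model.pack(truth.C, np.eye(3, dtype=int), truth.E, truth.W, truth.D)
        assert model.model.max_violation(x) < 1e-9


class TestBulkNoise:
    def test_noise_free_limit(self, tiny_noise_free):
        bulk, _, truth = tiny_noise_free
        assert np.allclose(bulk.F, truth.U @ truth.C)

    def test_zero_frequency_clone_contributes_nothing(self, tiny_cfg):
        rng = np.random.default_rng(0)
        truth = sim.simulate_tree_and_genotypes(tiny_cfg, rng)
        truth.U = np.array([[0.0, 0.6, 0.4], [0.0, 0.2, 0.8]])
        bulk = sim.simulate_bulk_reads(truth, tiny_cfg, rng, noise=False)
        U_alt = truth.U.copy()
        C_alt = truth.C.copy()
        C_alt[0] = 99  # clone 0 genotype is irrelevant at frequency 0
        assert np.allclose(bulk.F, U_alt @ truth.C)
        assert np.allclose(bulk.F, U_alt @ C_alt)

    def test_depth_mean(self):
        depths = sim.draw_segment_depths(10_000, 50.0, rng=3)
        assert abs(depths.mean() - 50) / 50 < 0.01

    def test_noise_shrinks_with_depth(self, tiny_cfg):
        import dataclasses
        errs = []
        for depth in (50.0, 5000.0):
            cfg = dataclasses.replace(tiny_cfg, depth_mean=depth)
            bulk, _, truth = sim.simulate_instance(cfg, noise=True)
            errs.append(np.abs(bulk.F - truth.U @ truth.C).sum())
        assert errs[1] < errs[0]

    def test_seed_reproducibility(self, tiny_cfg):
        b1, r1, t1 = sim.simulate_instance(tiny_cfg)
        b2, r2, t2 = sim.simulate_instance(tiny_cfg)
        assert np.array_equal(b1.F, b2.F)
        assert np.array_equal(r1.C_rna, r2.C_rna)
        assert np.array_equal(t1.E, t2.E) and np.array_equal(t1.C, t2.C)


class TestScRna:
    def test_diploid_transcript_mean(self):
        t = sim.draw_transcript_counts(10_000, cn=(1, 1), mean=50.0, rng=4)
        per_gene_total = t.sum(axis=1)
        assert abs(per_gene_total.mean() - 50) / 50 < 0.01

    def test_diploid_clone_normalizes_to_one(self):
        """Averaging many per-gene draws for a diploid segment gives allele
        copy number ~1 after renormalization."""
        t = sim.draw_transcript_counts(10_000, cn=(1, 1), mean=50.0, rng=5)
        est = t.mean(axis=0) / 25.0
        assert np.allclose(est, 1.0, atol=0.02)

    def test_homozygous_deletion_gives_zero(self, tiny_cfg):
        rng = np.random.default_rng(1)
        truth = sim.simulate_tree_and_genotypes(tiny_cfg, rng)
        d = truth.dims
        truth.C[0, d.n_mut] = 0          # delete both alleles of segment 0
        truth.C[0, d.n_mut + d.r] = 0
        rna = sim.simulate_scrna(truth, tiny_cfg, rng, noise=True)
        assert rna.C_rna[0, 0] == 0 and rna.C_rna[0, d.r] == 0

    def test_noise_free_recovers_truth_segments(self, tiny_noise_free):
        _, rna, truth = tiny_noise_free
        assert np.array_equal(rna.C_rna, truth.C[:, truth.dims.n_mut:])

    def test_sc_read_depth_scaling(self):
        ref, alt = sim.simulate_sc_reads(np.full(10_000, 0.4), 120.0, rng=6)
        total = ref + alt
        assert abs(total.mean() - 120) / 120 < 0.01
        assert abs(alt.mean() / total.mean() - 0.4) < 0.01
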