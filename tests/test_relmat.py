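"""Relationship matrices: textbook A values, VanRaden closed forms, the
transmission HMM against exhaustive enumeration, and the two exact limits
of the linkage-analysis matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gblend as gb
from gblend.relmat import _forward_backward, haldane_r
from tests.conftest import make_pedigree


def geno(counts, cM=None, chrom=None):
    counts = np.asarray(counts, dtype=np.int8)
    m = counts.shape[1]
    markers = pd.DataFrame(
        {
            "marker": [f"m{k}" for k in range(m)],
            "chrom": chrom if chrom is not None else 1,
            "cM": cM if cM is not None else np.arange(m, dtype=float),
            "bp": np.arange(1, m + 1),
        }
    )
    return gb.GenotypeMatrix(np.arange(1, len(counts) + 1), counts, markers)


class TestBuildA:
    def test_parent_offspring(self, trio):
        A = gb.build_A(trio).values
        assert A[0, 2] == 0.5 and A[1, 2] == 0.5
        assert A[2, 2] == 1.0 and A[0, 1] == 0.0

    def test_full_and_half_sibs(self):
        ped = make_pedigree(
            [(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 1, 2), (5, 1, 2), (6, 1, 3)]
        )
        A = gb.build_A(ped).values
        assert A[3, 4] == 0.5  # full sibs
        assert A[3, 5] == 0.25  # half sibs
        assert A[3, 3] == 1.0

    def test_full_sib_mating_inbreeding(self):
        ped = make_pedigree(
            [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)]
        )
        A = gb.build_A(ped).values
        assert A[4, 4] == pytest.approx(1.25)


class TestBuildGLD:
    def test_single_marker_closed_forms(self):
        g = geno([[1], [0], [2], [1]])  # p = 0.5
        G = gb.build_GLD(g).values
        assert G[0, 0] == pytest.approx(0.0)  # heterozygote z = 0
        assert G[1, 1] == pytest.approx(2.0)  # z^2 / 2pq = 1 / 0.5
        assert G[2, 2] == pytest.approx(2.0)

    def test_invariant_to_marker_order_and_allele_swap(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        G = gb.build_GLD(geno(counts)).values
        perm = rng.permutation(40)
        assert np.allclose(gb.build_GLD(geno(counts[:, perm])).values, G)
        flipped = counts.copy()
        flipped[:, :10] = 2 - flipped[:, :10]
        assert np.allclose(gb.build_GLD(geno(flipped)).values, G)

    def test_missing_genotypes_contribute_zero(self):
        counts = np.array([[1, 2], [0, -1], [2, 0], [1, 1]], dtype=np.int8)
        G = gb.build_GLD(geno(counts)).values
        # individual 1's second-marker term must vanish from its diagonal:
        # only the first marker (freq from non-missing calls) contributes
        p0 = (1 + 0 + 2 + 1) / 8
        expected = ((0 - 2 * p0) ** 2 / (2 * p0 * (1 - p0))) / 2
        assert G[1, 1] == pytest.approx(expected)

    def test_all_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gb.build_GLD(geno([[2, 0], [2, 0], [2, 0]]))

    def test_unrelated_hwe_expectation(self):
        """Mean diagonal ~1 and mean off-diagonal ~0 under HWE."""
        rng = np.random.default_rng(42)
        p = rng.uniform(0.1, 0.9, size=2000)
        counts = rng.binomial(2, p, size=(400, 2000)).astype(np.int8)
        G = gb.build_GLD(geno(counts)).values
        offdiag = G[~np.eye(400, dtype=bool)]
        assert np.abs(G.diagonal().mean() - 1.0) < 0.02
        assert np.abs(offdiag.mean()) < 0.01


class TestTransmissionHmm:
    def test_homozygous_parent_gives_uninformative_posteriors(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        counts = np.array([[2, 0, 2], [1, 1, 1], [1, 1, 1]], dtype=np.int8)
        g = geno(counts)
        tr = gb.infer_transmissions(ped, g)
        assert np.allclose(tr.t_sire[2], 0.5)
        assert tr.uninformative_meioses >= 1

    def test_forward_backward_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        L = 8
        e1 = rng.uniform(0.05, 1.0, size=(3, L))
        e2 = rng.uniform(0.05, 1.0, size=(3, L))
        r = rng.uniform(0.01, 0.45, size=L - 1)
        post = _forward_backward(e1, e2, r)
        for row in range(3):
            probs = np.zeros(L)
            total = 0.0
            for mask in range(2**L):
                path = [(mask >> k) & 1 for k in range(L)]
                pr = 0.5 * (e1[row, 0] if path[0] == 0 else e2[row, 0])
                for k in range(1, L):
                    pr *= r[k - 1] if path[k] != path[k - 1] else 1 - r[k - 1]
                    pr *= e1[row, k] if path[k] == 0 else e2[row, k]
                total += pr
                for k in range(L):
                    if path[k] == 0:
                        probs[k] += pr
            assert np.allclose(post[row], probs / total, atol=1e-12)

    def test_informative_meiosis_recovers_true_haplotype(self):
        """Dense phased markers, no recombination: posterior > 0.99."""
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        L = 40
        hap = np.zeros((3, 2, L), dtype=np.int8)
        hap[0, 0] = 1  # sire: haplotype 1 all ones, haplotype 2 all zeros
        hap[2, 0] = 1  # child received sire haplotype 1 intact
        counts = hap.sum(axis=1)
        g = geno(counts, cM=np.linspace(0, 5, L))
        tr = gb.infer_transmissions(ped, g, phase=hap)
        assert (tr.t_sire[2] > 0.99).all()


class TestBuildGLA:
    def test_uninformative_markers_collapse_to_A(self, toy_pop, toy_A):
        tr = gb.infer_transmissions(toy_pop.pedigree, toy_pop.marker_genotypes())
        tr.t_sire[:] = 0.5
        tr.t_dam[:] = 0.5
        gla = gb.build_GLA(toy_pop.pedigree, tr, loci=np.arange(3))
        assert np.allclose(gla.values, toy_A.values, atol=5e-7)

    def test_founder_block_is_identity(self):
        cfg = gb.SimulationConfig(
            n_founders=12, n_generations=1, n_chromosomes=1,
            markers_per_chromosome=30, n_qtl=5, seed=3,
        )
        pop = gb.drop_genomes(gb.simulate_pedigree(cfg), cfg)
        tr = gb.infer_transmissions(pop.pedigree, pop.marker_genotypes(True))
        gla = gb.build_GLA(pop.pedigree, tr)
        assert np.allclose(gla.values, np.eye(12))

    @staticmethod
    def _informative_cfg():
        return gb.SimulationConfig(
            n_founders=40, n_generations=3, n_sires_per_gen=6,
            n_dams_per_gen=15, offspring_per_dam=4, n_chromosomes=2,
            markers_per_chromosome=400, map_length_cM=50.0,
            founder_maf_range=(0.3, 0.5), n_qtl=10, hatch_week_levels=3,
            seed=7,
        )

    @staticmethod
    def _true_transmissions(pop):
        """Exact transmission indicators from the gene-drop truth."""
        ped = pop.pedigree
        org = pop.founder_origin
        n, _, L = org.shape
        ts = np.full((n, L), 0.5)
        td = np.full((n, L), 0.5)
        for i in np.flatnonzero(~ped.is_founder):
            f, m = ped.sire_idx[i], ped.dam_idx[i]
            ts[i] = np.where(org[i, 0] == org[f, 0], 1.0, 0.0)
            td[i] = np.where(org[i, 1] == org[m, 0], 1.0, 0.0)
        return gb.TransmissionPosteriors(ped.ids, ts, td)

    def test_fully_informative_markers_recover_true_ibd(self):
        """With transmissions known exactly at every locus, the per-locus
        kinship recursion reproduces the realized gene-drop IBD matrix."""
        cfg = self._informative_cfg()
        pop = gb.simulate_population(cfg)
        gla = gb.build_GLA(pop.pedigree, self._true_transmissions(pop))
        T = gb.true_ibd_matrix(pop)
        assert np.abs(gla.values - T.values).max() <= 0.02

    def test_hmm_posteriors_with_truth_phase_near_true_ibd(self):
        """Dense truth-phased markers: HMM-driven G_LA tracks realized IBD
        closely; residual error is confined to uninformative stretches."""
        cfg = self._informative_cfg()
        pop = gb.simulate_population(cfg)
        g = pop.marker_genotypes(include_qtl=True)
        tr = gb.infer_transmissions(pop.pedigree, g, phase=pop.haplotypes)
        gla = gb.build_GLA(pop.pedigree, tr)
        T = gb.true_ibd_matrix(pop)
        err = np.abs(gla.values - T.values)
        assert err.mean() <= 0.005
        assert np.quantile(err, 0.99) <= 0.02

    def test_entries_in_valid_range(self, toy_pop):
        tr = gb.infer_transmissions(toy_pop.pedigree, toy_pop.marker_genotypes())
        gla = gb.build_GLA(
            toy_pop.pedigree, tr, loci=np.arange(0, tr.t_sire.shape[1], 10)
        )
        assert gla.values.min() >= 0.0
        assert gla.values.max() <= 2.0 + 1e-9


class TestBlend:
    def test_endpoints_are_exact(self, toy_A):
        G = gb.RelationshipMatrix(
            toy_A.ids, toy_A.values * 0.9 + np.eye(toy_A.n) * 0.1, "GLD"
        )
        assert np.array_equal(gb.blend(G, toy_A, 1.0).values, G.values)
        assert np.array_equal(gb.blend(G, toy_A, 0.0).values, toy_A.values)

    def test_halfway_arithmetic(self):
        ids = np.array([1, 2])
        M1 = gb.RelationshipMatrix(ids, np.eye(2), "A")
        M2 = gb.RelationshipMatrix(ids, np.array([[1, 0.5], [0.5, 1]]), "A")
        out = gb.blend(M1, M2, 0.5)
        assert np.allclose(out.values, [[1, 0.25], [0.25, 1]])
        assert out.kind == "composite"
        assert out.provenance["lambda"] == 0.5

    @given(lam=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_reflection_symmetry(self, lam):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(6, 6))
        ids = np.arange(6)
        M1 = gb.RelationshipMatrix(ids, W @ W.T, "GLD")
        M2 = gb.RelationshipMatrix(ids, np.eye(6), "A")
        assert np.allclose(
            gb.blend(M1, M2, lam).values, gb.blend(M2, M1, 1.0 - lam).values
        )

    def test_composite_of_psd_inputs_is_psd(self, toy_pop, toy_A):
        G = gb.build_GLD(toy_pop.marker_genotypes())
        for lam in (0.0, 0.3, 0.7, 1.0):
            M = gb.blend(G, toy_A, lam)
            assert np.linalg.eigvalsh(M.values).min() >= -1e-8

    def test_id_mismatch_raises(self, toy_A):
        other = gb.RelationshipMatrix(toy_A.ids[::-1], toy_A.values, "A")
        with pytest.raises(ValueError, match="id"):
            gb.blend(toy_A, other, 0.5)


def test_haldane_map_function_limits():
    assert haldane_r(np.array([0.0]))[0] == 0.0
    assert haldane_r(np.array([1e9]))[0] == pytest.approx(0.5)
    assert haldane_r(np.array([0.01]))[0] == pytest.approx(0.0099, abs=1e-4)
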