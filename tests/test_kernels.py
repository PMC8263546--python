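import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clonalgp as cg
from clonalgp.kernels import incidence_matrix


def freq_triples(min_component=0.0):
    """Genotype-frequency triples summing to one."""
    return (
        st.tuples(
            st.floats(min_component, 1.0),
            st.floats(min_component, 1.0),
            st.floats(min_component, 1.0),
        )
        .filter(lambda t: sum(t) > 1e-6)
        .map(lambda t: tuple(x / sum(t) for x in t))
    )


class TestAdditiveCoeffs:
    def test_symmetric_frequencies(self):
        np.testing.assert_allclose(
            cg.noia_additive_coeffs([(0.25, 0.5, 0.25)])[0], [1.0, 0.0, -1.0]
        )

    def test_monomorphic_reference(self):
        np.testing.assert_allclose(
            cg.noia_additive_coeffs([(1.0, 0.0, 0.0)])[0], [0.0, -1.0, -2.0]
        )

    @settings(deadline=None, derandomize=True)
    @given(freq_triples())
    def test_weighted_mean_zero(self, freqs):
        h = cg.noia_additive_coeffs([freqs])[0]
        assert abs(np.dot(freqs, h)) < 1e-10


class TestDominanceCoeffs:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.25, 0.5, 0.25), (-0.5, 0.5, -0.5)),
        ((0.5, 0.25, 0.25), (-0.18182, 0.72727, -0.36364)),
    ])
    def test_hand_values(self, freqs, expected):
        h, deg = cg.noia_dominance_coeffs([freqs])
        assert not deg[0]
        np.testing.assert_allclose(h[0], expected, atol=5e-6)

    def test_no_homozygotes_degenerate(self):
        h, deg = cg.noia_dominance_coeffs([(0.0, 1.0, 0.0)])
        assert deg[0]
        np.testing.assert_array_equal(h[0], [0.0, 0.0, 0.0])

    @settings(deadline=None, derandomize=True)
    @given(freq_triples(min_component=0.01))
    def test_weighted_mean_zero(self, freqs):
        h, deg = cg.noia_dominance_coeffs([freqs])
        if not deg[0]:
            assert abs(np.dot(freqs, h[0])) < 1e-8

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.05, 0.95))
    def test_orthogonal_to_additive_under_hwe(self, p):
        """Additive and dominance coefficient vectors are orthogonal under
        the genotype-frequency weights when frequencies are p^2, 2pq, q^2."""
        q = 1.0 - p
        freqs = (p * p, 2 * p * q, q * q)
        ha = cg.noia_additive_coeffs([freqs])[0]
        hd, deg = cg.noia_dominance_coeffs([freqs])
        assert not deg[0]
        assert abs(np.sum(np.array(freqs) * ha * hd[0])) < 1e-10


class TestGrm:
    def test_hand_case(self):
        H = cg.IncidenceMatrix("additive", np.array([[1.0, 1], [0, 0], [-1, -1]]),
                               np.empty((2, 3)), np.zeros(2, bool))
        G = cg.build_grm(H, ["a", "b", "c"])
        np.testing.assert_allclose(np.diag(G.values), [1.5, 0.0, 1.5])
        np.testing.assert_allclose(G.values[0, 2], -1.5)

    def test_mean_diagonal_one(self, small_kernels):
        for k in small_kernels.values():
            assert abs(np.mean(np.diag(k.values)) - 1.0) < 1e-10

    def test_symmetric_psd(self, small_kernels):
        for k in small_kernels.values():
            np.testing.assert_allclose(k.values, k.values.T, atol=1e-10)
            w = np.linalg.eigvalsh(k.values)
            assert w[0] > -1e-8 * max(w[-1], 1.0)

    def test_duplicate_rows_give_equal_entries(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((4, 6))
        vals[1] = vals[0]
        H = cg.IncidenceMatrix("additive", vals, np.empty((6, 3)), np.zeros(6, bool))
        G = cg.build_grm(H, list("abcd")).values
        assert np.isclose(G[0, 1], G[0, 0])
        np.testing.assert_allclose(G[0], G[1])

    def test_brute_force_oracle(self, tiny_genotypes):
        """G equals an explicit double loop over clone pairs."""
        H = incidence_matrix(tiny_genotypes, "additive")
        G = cg.build_grm(H, tiny_genotypes.clone_ids).values
        n = tiny_genotypes.n_clones
        cross = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                cross[i, j] = sum(H.values[i, l] * H.values[j, l]
                                  for l in range(tiny_genotypes.n_snps))
        denom = sum(cross[i, i] for i in range(n)) / n
        np.testing.assert_allclose(G, cross / denom, atol=1e-12)

    def test_all_zero_incidence_raises(self):
        H = cg.IncidenceMatrix("additive", np.zeros((3, 2)), np.empty((2, 3)),
                               np.ones(2, bool))
        with pytest.raises(ValueError, match="degenerate"):
            cg.build_grm(H, list("abc"))


class TestHadamard:
    def test_hand_case(self):
        vals = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        G = cg.KernelMatrix("G_A", vals, list("abc"))
        GG = cg.hadamard_kernel(G, G)
        np.testing.assert_allclose(np.diag(GG.values), 1.0)
        np.testing.assert_allclose(GG.values[0, 1], 0.25)

    def test_identity_pattern_kills_off_diagonal(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((4, 4))
        A = A @ A.T
        A /= np.trace(A) / 4
        G = cg.KernelMatrix("G_A", A, list("abcd"))
        I = cg.KernelMatrix("G0", np.eye(4), list("abcd"))
        H = cg.hadamard_kernel(G, I)
        off = H.values[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_mismatched_clone_order(self):
        A = cg.KernelMatrix("G_A", np.eye(2), ["a", "b"])
        B = cg.KernelMatrix("G_D", np.eye(2), ["b", "a"])
        with pytest.raises(ValueError, match="clone order"):
            cg.hadamard_kernel(A, B)

    def test_composable_higher_order(self, small_kernels):
        gaa = small_kernels["G_AA"]
        gaaa = cg.hadamard_kernel(gaa, small_kernels["G_A"])
        assert abs(np.mean(np.diag(gaaa.values)) - 1.0) < 1e-10


class TestHeterozygosity:
    @staticmethod
    def _hwe_genotypes(rng, n, p_loci):
        codes = np.empty((n, len(p_loci)), dtype=int)
        for j, p in enumerate(p_loci):
            probs = [p * p, 2 * p * (1 - p), (1 - p) ** 2]
            codes[:, j] = rng.choice(3, size=n, p=probs)
        return codes

    def test_fully_heterozygous_clone_scores_one(self):
        # frequencies exactly at HWE with p=0.5: 1 AA, 2 Aa, 1 aa per locus
        base = np.array([[0], [1], [1], [2]])
        codes = np.tile(base, (1, 5))
        g = cg.GenotypeMatrix([f"c{i}" for i in range(4)],
                              [f"s{j}" for j in range(5)], codes)
        het = cg.heterozygosity(g)
        assert het.values[1] == pytest.approx(1.0)
        # fully homozygous clones at p = 0.5 score -1
        assert het.values[0] == pytest.approx(-1.0)
        assert het.values[3] == pytest.approx(-1.0)

    def test_frequency_weighted_centering(self, small_sim):
        _, g, _, _ = small_sim
        hd = incidence_matrix(g, "dominance")
        # column means over clones vanish because frequencies are empirical
        np.testing.assert_allclose(hd.values.mean(axis=0), 0.0, atol=1e-10)
        het = cg.heterozygosity(g, hd)
        assert abs(het.values.mean()) < 1e-10

    def test_all_monomorphic_raises(self):
        g = cg.GenotypeMatrix(list("ab"), ["s"], np.zeros((2, 1), dtype=int))
        with pytest.raises(ValueError, match="monomorphic"):
            cg.heterozygosity(g)


class TestGaussianKernel:
    def test_identical_rows(self):
        codes = np.tile([0, 1, 2, 1], (2, 1))
        g = cg.GenotypeMatrix(["a", "b"], [f"s{j}" for j in range(4)], codes)
        K = cg.gaussian_kernel(g, 2.0)
        np.testing.assert_allclose(K.values, 1.0)

    def test_zero_bandwidth(self, tiny_genotypes):
        K = cg.gaussian_kernel(tiny_genotypes, 0.0)
        np.testing.assert_allclose(K.values, 1.0)

    def test_maximal_distance_value(self):
        codes = np.array([[0] * 6, [2] * 6])
        g = cg.GenotypeMatrix(["a", "b"], [f"s{j}" for j in range(6)], codes)
        K = cg.gaussian_kernel(g, 1.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-4.0), abs=1e-9)

    def test_bounds_and_diagonal(self, tiny_genotypes):
        K = cg.gaussian_kernel(tiny_genotypes, 0.7).values
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert (K > 0).all() and (K <= 1).all()

    def test_monotone_in_bandwidth(self, tiny_genotypes):
        hs = [0.1, 0.5, 1.0, 2.5, 5.0, 10.0]
        prev = None
        for h in hs:
            K = cg.gaussian_kernel(tiny_genotypes, h).values
            off = K[0, 2]
            if prev is not None:
                assert off < prev
            prev = off
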