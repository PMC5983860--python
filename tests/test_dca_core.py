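import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepdca.alignment_io import MSA, PROTEIN_ALPHABET
from pepdca.dca_core import (
    SingularCorrelationError,
    compute_frequencies,
    compute_weights,
    direct_information,
    frequencies_from_rows,
    mean_field_couplings,
    rank_pairs,
    top_fraction_count,
)


def brute_force_identity(msa):
    """Independent O(M^2 L) oracle for pairwise identity fractions."""
    M, L = msa.matrix.shape
    ident = np.zeros((M, M))
    for a in range(M):
        for b in range(M):
            ident[a, b] = np.mean(msa.matrix[a] == msa.matrix[b])
    return ident


class TestComputeWeights:
    def test_five_identical_sequences(self):
        msa = MSA.from_sequences([f"s{i}" for i in range(5)], ["ACDE"] * 5)
        w = compute_weights(msa, 0.8)
        assert list(w.m) == [5] * 5
        assert w.meff == pytest.approx(1.0)

    def test_derived_three_sequence_example(self):
        # identities: (AAAA,AAAT)=0.75, others 0 -> all below 0.8 -> m=(1,1,1)
        msa = MSA.from_sequences(["a", "b", "c"], ["AAAA", "AAAT", "CCCC"])
        w = compute_weights(msa, 0.8)
        assert list(w.m) == [1, 1, 1]
        assert w.meff == pytest.approx(3.0)

    def test_single_sequence(self):
        msa = MSA.from_sequences(["a"], ["ACDE"])
        assert compute_weights(msa, 0.8).meff == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, random_msa_factory):
        msa = random_msa_factory(n_seq=30, n_col=5, q=3, seed=3)
        ident = brute_force_identity(msa)
        expected_m = (ident >= 0.8).sum(axis=1)
        w = compute_weights(msa, 0.8)
        assert np.array_equal(w.m, expected_m)

    def test_gaps_compared_as_symbols(self):
        msa = MSA.from_sequences(["a", "b"], ["A---", "A---"])
        w = compute_weights(msa, 0.8)
        assert list(w.m) == [2, 2]

    def test_meff_bounds(self, random_msa_factory):
        msa = random_msa_factory(n_seq=25, n_col=4, q=3, seed=7)
        w = compute_weights(msa, 0.8)
        assert 1.0 <= w.meff <= msa.n_sequences
        assert (w.m >= 1).all()

    def test_permutation_invariance(self, random_msa_factory):
        msa = random_msa_factory(n_seq=15, n_col=6, q=4, seed=11)
        rng = np.random.default_rng(0)
        perm = rng.permutation(msa.n_sequences)
        shuffled = MSA([msa.sequence_ids[i] for i in perm], msa.matrix[perm], msa.alphabet)
        assert compute_weights(msa, 0.8).meff == pytest.approx(compute_weights(shuffled, 0.8).meff)


class TestComputeFrequencies:
    def test_single_sequence_hand_formula(self):
        # one sequence "AC", lambda = Meff = 1, q = 21: f_0(A) = (1/21 + 1)/2
        msa = MSA.from_sequences(["a"], ["AC"])
        f = compute_frequencies(msa)
        a_idx = PROTEIN_ALPHABET.index("A")
        assert f.fi[0, a_idx] == pytest.approx((1 / 21 + 1) / 2)
        assert f.fi[0, PROTEIN_ALPHABET.index("C")] == pytest.approx((1 / 21) / 2)

    def test_zero_pseudocount_gives_empirical(self):
        msa = MSA.from_sequences(["a", "b", "c", "d"], ["AA", "AC", "CA", "CC"])
        f = compute_frequencies(msa, pseudocount=0.0)
        a_idx = PROTEIN_ALPHABET.index("A")
        assert f.fi[0, a_idx] == pytest.approx(0.5)

    def test_normalization_invariants(self, random_msa_factory):
        msa = random_msa_factory(n_seq=12, n_col=5, q=4, seed=2)
        f = compute_frequencies(msa)
        assert np.allclose(f.fi.sum(axis=1), 1.0, atol=1e-10)
        pair_sums = f.fij.sum(axis=(2, 3))
        assert np.allclose(pair_sums, 1.0, atol=1e-10)

    def test_pairwise_symmetry(self, random_msa_factory):
        msa = random_msa_factory(n_seq=10, n_col=4, q=3, seed=5)
        f = compute_frequencies(msa)
        assert np.allclose(f.fij, f.fij.transpose(1, 0, 3, 2))

    def test_all_entries_positive_with_pseudocount(self, random_msa_factory):
        msa = random_msa_factory(n_seq=8, n_col=3, q=3, seed=6)
        f = compute_frequencies(msa)
        assert (f.fi > 0).all()
        off_diag = [f.fij[i, j] for i in range(3) for j in range(3) if i != j]
        assert all((b > 0).all() for b in off_diag)

    def test_diagonal_closure(self, random_msa_factory):
        msa = random_msa_factory(n_seq=8, n_col=3, q=3, seed=8)
        f = compute_frequencies(msa)
        for i in range(3):
            assert np.allclose(f.fij[i, i], np.diag(f.fi[i]))

    def test_permutation_invariance(self, random_msa_factory):
        msa = random_msa_factory(n_seq=10, n_col=4, q=4, seed=9)
        perm = np.random.default_rng(1).permutation(msa.n_sequences)
        shuffled = MSA([msa.sequence_ids[i] for i in perm], msa.matrix[perm], msa.alphabet)
        f1 = compute_frequencies(msa)
        f2 = compute_frequencies(shuffled)
        assert np.allclose(f1.fi, f2.fi)
        assert np.allclose(f1.fij, f2.fij)


def factorized_frequency_model(fi, q):
    """FrequencyModel with exactly factorized pair frequencies (oracle input)."""
    L = fi.shape[0]
    fij = fi[:, None, :, None] * fi[None, :, None, :]
    for i in range(L):
        fij[i, i] = np.diag(fi[i])
    from pepdca.dca_core import FrequencyModel

    return FrequencyModel(fi=fi, fij=fij, q=q, pseudocount=0.0, meff=1.0)


class TestMeanFieldCouplings:
    def test_factorized_frequencies_give_zero_couplings(self):
        rng = np.random.default_rng(0)
        fi = rng.dirichlet(np.ones(3), size=4)
        f = factorized_frequency_model(fi, 3)
        c = mean_field_couplings(f)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert np.allclose(c.e[i, j], 0.0, atol=1e-9)

    def test_two_column_two_letter_closed_form(self):
        # q=2 -> one reduced state per column; C is an analytic 2x2 matrix
        from pepdca.dca_core import FrequencyModel

        f0, f1, f01 = 0.6, 0.3, 0.25  # P(A at 0), P(A at 1), P(A, A)
        fi = np.array([[f0, 1 - f0], [f1, 1 - f1]])
        fij = np.empty((2, 2, 2, 2))
        fij[0, 1] = np.array([[f01, f0 - f01], [f1 - f01, 1 - f0 - f1 + f01]])
        fij[1, 0] = fij[0, 1].T
        fij[0, 0] = np.diag(fi[0])
        fij[1, 1] = np.diag(fi[1])
        f = FrequencyModel(fi=fi, fij=fij, q=2, pseudocount=0.0, meff=1.0)
        c = mean_field_couplings(f)
        c11 = f0 * (1 - f0)
        c22 = f1 * (1 - f1)
        c12 = f01 - f0 * f1
        expected_e12 = c12 / (c11 * c22 - c12**2)  # -(C^-1)_12 for 2x2 C
        assert c.e[0, 1][0, 0] == pytest.approx(expected_e12)

    def test_symmetry_on_random_frequencies(self, random_msa_factory):
        msa = random_msa_factory(n_seq=15, n_col=5, q=4, seed=12)
        f = compute_frequencies(msa)
        c = mean_field_couplings(f)
        assert np.allclose(c.e, c.e.transpose(1, 0, 3, 2))

    def test_diagonal_blocks_zero(self, random_msa_factory):
        msa = random_msa_factory(n_seq=15, n_col=4, q=4, seed=13)
        c = mean_field_couplings(compute_frequencies(msa))
        for i in range(4):
            assert np.allclose(c.e[i, i], 0.0)

    def test_singular_matrix_diagnosed(self):
        # zero pseudocount + duplicated column -> singular correlation matrix
        msa = MSA.from_sequences(["a", "b"], ["AA", "CC"])
        f = compute_frequencies(msa, pseudocount=0.0)
        with pytest.raises((SingularCorrelationError, np.linalg.LinAlgError)):
            mean_field_couplings(f)

    def test_reduced_dimension(self, random_msa_factory):
        msa = random_msa_factory(n_seq=10, n_col=5, q=6, seed=14)
        c = mean_field_couplings(compute_frequencies(msa))
        assert c.e.shape == (5, 5, 5, 5)  # (L, L, q-1, q-1)


def two_site_oracle(e_full, fi, fj):
    """Closed-form two-site model for q=2 via the odds-ratio quadratic.

    The marginal-matched distribution P ~ exp(e) h_i h_j with q=2 is the
    unique 2x2 table with marginals (fi, fj) and odds ratio
    theta = exp(e00 + e11 - e01 - e10): solve the quadratic for P[0, 0].
    """
    theta = np.exp(e_full[0, 0] + e_full[1, 1] - e_full[0, 1] - e_full[1, 0])
    p, q_ = fi[0], fj[0]
    if abs(theta - 1) < 1e-12:
        p00 = p * q_
    else:
        a = theta - 1
        b = -(1 + (p + q_) * (theta - 1))
        c = theta * p * q_
        disc = np.sqrt(b * b - 4 * a * c)
        p00 = (-b - disc) / (2 * a)
    P = np.array([[p00, p - p00], [q_ - p00, 1 - p - q_ + p00]])
    return P


class TestDirectInformation:
    def test_zero_couplings_give_zero_di(self):
        rng = np.random.default_rng(1)
        fi = rng.dirichlet(np.ones(3), size=4)
        f = factorized_frequency_model(fi, 3)
        c = mean_field_couplings(f)
        di = direct_information(c, f)
        assert np.allclose(di.di, 0.0, atol=1e-8)

    def test_two_letter_coupled_toy_matches_oracle(self):
        from pepdca.dca_core import CouplingModel, FrequencyModel

        fi = np.array([[0.6, 0.4], [0.3, 0.7]])
        fij = np.empty((2, 2, 2, 2))
        fij[0, 1] = np.array([[0.25, 0.35], [0.05, 0.35]])
        fij[1, 0] = fij[0, 1].T
        fij[0, 0] = np.diag(fi[0])
        fij[1, 1] = np.diag(fi[1])
        f = FrequencyModel(fi=fi, fij=fij, q=2, pseudocount=0.0, meff=1.0)
        e = np.zeros((2, 2, 1, 1))
        e[0, 1, 0, 0] = e[1, 0, 0, 0] = 1.7  # strong coupling on the reduced state
        c = CouplingModel(e=e, q=2, gauge_state=1)
        di = direct_information(c, f, tol=1e-10, max_iter=5000)
        P = two_site_oracle(c.pair_matrix(0, 1), fi[0], fi[1])
        expected = np.sum(P * np.log(P / np.outer(fi[0], fi[1])))
        assert di.di[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_symmetry_and_nonnegativity(self, random_msa_factory):
        msa = random_msa_factory(n_seq=20, n_col=5, q=4, seed=15)
        f = compute_frequencies(msa)
        di = direct_information(mean_field_couplings(f), f)
        assert np.allclose(di.di, di.di.T)
        assert (di.di >= 0).all()
        assert np.allclose(np.diag(di.di), 0.0)

    def test_uncorrelated_product_alignment_small_di(self):
        # exact product alignment over 3 letters: empirical pair frequencies
        # factorize exactly, so DI -> 0 as the pseudocount vanishes
        # 3-letter alphabet without a gap: the gauge state ('D') is populated,
        # so the correlation matrix stays well-conditioned as lambda -> 0
        rows = ["".join(t) for t in itertools.product("ACD", repeat=3)]
        msa = MSA.from_sequences([f"s{i}" for i in range(len(rows))], rows, alphabet="ACD")
        f = compute_frequencies(msa, pseudocount=1e-6)
        di = direct_information(mean_field_couplings(f), f, tol=1e-8, max_iter=5000)
        assert di.di.max() < 1e-6


class TestRankPairs:
    def test_separation_boundary(self):
        di = np.zeros((20, 20))
        di[10, 14] = 5.0
        di[10, 15] = 4.0
        ranked = rank_pairs(di, min_separation=4)
        pairs = {(i, j) for i, j, _ in ranked}
        assert (10, 14) not in pairs
        assert (10, 15) in pairs

    def test_top_fraction_helper(self):
        assert top_fraction_count(178, 0.25) == 44

    def test_tie_break_lexicographic(self):
        di = np.zeros((12, 12))
        for i, j in [(0, 6), (0, 7), (1, 8)]:
            di[i, j] = di[j, i] = 1.0
        ranked = rank_pairs(di, min_separation=4, top_k=3)
        assert [(i, j) for i, j, _ in ranked] == [(0, 6), (0, 7), (1, 8)]

    def test_scores_non_increasing(self, random_msa_factory):
        rng = np.random.default_rng(3)
        di = rng.random((15, 15))
        di = (di + di.T) / 2
        ranked = rank_pairs(di, min_separation=2)
        scores = [s for _, _, s in ranked]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_top_k_truncation(self):
        di = np.random.default_rng(4).random((10, 10))
        di = (di + di.T) / 2
        assert len(rank_pairs(di, 0, top_k=5)) == 5


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=2, max_value=12), st.integers(min_value=2, max_value=5), st.integers(0, 10_000))
def test_frequency_normalization_property(n_seq, n_col, seed):
    rng = np.random.default_rng(seed)
    alphabet = "ACD-"
    mat = rng.integers(0, 4, size=(n_seq, n_col))
    msa = MSA([f"s{i}" for i in range(n_seq)], mat, alphabet)
    f = compute_frequencies(msa)
    assert np.allclose(f.fi.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(f.fij.sum(axis=(2, 3)), 1.0, atol=1e-10)
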