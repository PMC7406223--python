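"""Gaussian DCA: reweighting, frequencies, couplings, APC, contact extraction."""

import numpy as np
import pytest
from naive_dca import naive_score_matrix

from ecfcoev.dca import (
    GAP_STATE,
    PairedFamilyAlignment,
    auto_theta,
    couplings,
    extract_interprotein_contacts,
    fit_dca,
    frobenius_apc,
    sequence_weights,
    weighted_frequencies,
)


def _encode(rows):
    return PairedFamilyAlignment(
        ids=[f"r{i}" for i in range(len(rows))], rows=rows, n_ecf=1
    ).encoded()


class TestSequenceWeights:
    def test_identical_rows_meff_one(self):
        X = _encode(["ACD"] * 5)
        w, meff = sequence_weights(X, 0.46)
        assert np.allclose(w, 0.2)
        assert meff == pytest.approx(1.0)

    def test_all_distant_rows_unweighted(self):
        X = _encode(["AAA", "CCC", "DDD"])
        w, meff = sequence_weights(X, 0.46)
        assert np.allclose(w, 1.0)
        assert meff == pytest.approx(3.0)

    def test_matches_pairwise_oracle(self, rng):
        rows = [
            "".join("ACDE"[k] for k in rng.integers(4, size=8)) for _ in range(5)
        ]
        X = _encode(rows)
        theta = 0.5
        w, meff = sequence_weights(X, theta)
        for m in range(5):
            cnt = sum(
                1
                for mm in range(5)
                if np.mean([a != b for a, b in zip(rows[m], rows[mm])]) < theta
            )
            assert w[m] == pytest.approx(1.0 / cnt)
        assert meff == pytest.approx(w.sum())

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            sequence_weights(_encode(["AC", "AD"]), 1.5)


class TestWeightedFrequencies:
    def test_alpha_near_one_approaches_uniform(self):
        X = _encode(["AC", "AC"])
        fi, _ = weighted_frequencies(X, np.ones(2), alpha=0.999)
        assert np.allclose(fi, 1 / 21, atol=1e-3)

    def test_single_row_alpha_near_zero(self):
        X = _encode(["AC"])
        fi, _ = weighted_frequencies(X, np.ones(1), alpha=1e-9)
        assert fi[0, 0] == pytest.approx(1.0)  # A at column 1
        assert fi[1, 1] == pytest.approx(1.0)  # C at column 2

    def test_hand_tallied_blend(self):
        # 4 rows, 2 columns over {A, C}, alpha = 0.5, uniform weights
        X = _encode(["AA", "AC", "CA", "CC"])
        w = np.ones(4)
        alpha, q = 0.5, 21
        fi, fij = weighted_frequencies(X, w, alpha=alpha)
        assert fi[0, 0] == pytest.approx((1 - alpha) * 0.5 + alpha / q)
        assert fi[0, 1] == pytest.approx((1 - alpha) * 0.5 + alpha / q)
        assert fi[0, 2] == pytest.approx(alpha / q)  # D never observed
        # joint (col0=A, col1=C) observed once in 4 rows
        assert fij[0, 1, 0, 1] == pytest.approx((1 - alpha) * 0.25 + alpha / q**2)
        # diagonal block keeps joint-equals-marginal consistency
        assert fij[0, 0, 0, 0] == pytest.approx(fi[0, 0])
        assert fij[0, 0, 0, 1] == 0.0

    def test_gap_mass_unassigned(self):
        X = _encode(["A-", "A-"])
        fi, _ = weighted_frequencies(X, np.ones(2), alpha=0.2)
        # gapped column: all 20 residue states sit at the pseudocount floor
        assert np.allclose(fi[1], 0.2 / 21)


class TestCouplings:
    def test_independent_columns_zero_off_diagonal(self):
        # product frequencies: fij = fi * fj exactly
        rng = np.random.default_rng(0)
        N = 3
        fi = rng.dirichlet(np.ones(20) * 5, size=N) * 0.95  # leave mass for gap
        fij = np.empty((N, N, 20, 20))
        for i in range(N):
            for j in range(N):
                fij[i, j] = np.outer(fi[i], fi[j]) if i != j else np.diag(fi[i])
        J = couplings(fi, fij)
        blocks = J.reshape(N, 20, N, 20)
        for i in range(N):
            for j in range(N):
                if i != j:
                    assert np.allclose(blocks[i, :, j, :], 0.0, atol=1e-8)

    def test_column_permutation_equivariance(self):
        rows = ["ACDA", "ACCA", "CADD", "CDCA", "DACC"]
        msa1 = PairedFamilyAlignment([f"r{i}" for i in range(5)], rows, n_ecf=2)
        swapped = [r[1] + r[0] + r[2:] for r in rows]  # swap columns 1 and 2
        msa2 = PairedFamilyAlignment([f"r{i}" for i in range(5)], swapped, n_ecf=2)
        m1 = fit_dca(msa1, theta=0.8, alpha=0.5)
        m2 = fit_dca(msa2, theta=0.8, alpha=0.5)
        perm = [1, 0, 2, 3]
        assert np.allclose(m2.S, m1.S[np.ix_(perm, perm)], atol=1e-10)


class TestFrobeniusAPC:
    def test_constant_couplings_give_zero_apc(self):
        # every off-diagonal block identical -> constant F -> APC annihilates it
        N = 5
        rng = np.random.default_rng(1)
        K = rng.normal(size=(20, 20))
        J = np.zeros((N * 20, N * 20))
        for i in range(N):
            for j in range(N):
                if i != j:
                    J[i * 20 : (i + 1) * 20, j * 20 : (j + 1) * 20] = K if i < j else K.T
        F, S = frobenius_apc(J, N)
        off = ~np.eye(N, dtype=bool)
        assert np.allclose(F[off], F[off][0])
        assert np.allclose(S, 0.0, atol=1e-9)

    def test_single_dominant_block_tops_apc(self):
        N = 4
        rng = np.random.default_rng(2)
        J = np.zeros((N * 20, N * 20))
        K = rng.normal(size=(20, 20)) * 10
        J[0:20, 40:60] = K
        J[40:60, 0:20] = K.T
        _, S = frobenius_apc(J, N)
        i, j = np.unravel_index(np.argmax(S), S.shape)
        assert {i, j} == {0, 2}

    def test_apc_matches_loop_arithmetic(self):
        # independent elementwise recomputation of the correction from F
        N = 4
        rng = np.random.default_rng(3)
        J = rng.normal(size=(N * 20, N * 20))
        J = (J + J.T) / 2
        F, S = frobenius_apc(J, N)
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                mi = sum(F[i, k] for k in range(N) if k != i) / (N - 1)
                mj = sum(F[k, j] for k in range(N) if k != j) / (N - 1)
                mean = sum(
                    F[a, b] for a in range(N) for b in range(N) if a != b
                ) / (N * (N - 1))
                assert S[i, j] == pytest.approx(F[i, j] - mi * mj / mean)

    def test_dominant_entry_ranks_first(self):
        rows = ["AC" + "DD", "AC" + "DD", "CA" + "DD", "CA" + "DD", "AD" + "CD"]
        msa = PairedFamilyAlignment([f"r{i}" for i in range(5)], rows, n_ecf=2)
        model = fit_dca(msa, theta=0.9, alpha=0.5)
        F = model.F
        i, j = np.unravel_index(np.argmax(F - np.eye(4) * F), F.shape)
        assert {i, j} == {0, 1}  # the covarying column pair dominates


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_straight_line_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        M, N = rng.integers(4, 11), rng.integers(3, 7)
        rows = ["".join("ACD"[k] for k in rng.integers(3, size=N)) for _ in range(M)]
        msa = PairedFamilyAlignment([f"r{i}" for i in range(M)], rows, n_ecf=N // 2 or 1)
        theta, alpha = 0.4, 0.6
        model = fit_dca(msa, theta=theta, alpha=alpha)
        S_oracle = naive_score_matrix(rows, theta, alpha)
        np.fill_diagonal(S_oracle, 0.0)
        assert np.max(np.abs(model.S - S_oracle)) < 1e-8


class TestRowDuplication:
    def test_duplicating_all_rows_changes_nothing(self):
        rows = ["ACDA", "ACCA", "CADD", "CDCA", "DACC"]
        msa1 = PairedFamilyAlignment([f"r{i}" for i in range(5)], rows, n_ecf=2)
        msa2 = PairedFamilyAlignment(
            [f"r{i}" for i in range(10)], rows + rows, n_ecf=2
        )
        m1 = fit_dca(msa1, theta=0.3, alpha=0.5)
        m2 = fit_dca(msa2, theta=0.3, alpha=0.5)
        assert m2.meff == pytest.approx(m1.meff)
        assert np.allclose(m2.fi, m1.fi)
        assert np.allclose(m2.S, m1.S, atol=1e-10)


class TestContactExtraction:
    def _msa(self):
        rows = ["ACDEFG", "AC-EFG", "ACDEFG"]
        return PairedFamilyAlignment(["ref", "b", "c"], rows, n_ecf=3, reference_row_id="ref")

    def test_interprotein_filter_and_ranking(self):
        msa = self._msa()
        S = np.zeros((6, 6))
        S[0, 1] = S[1, 0] = 9.0  # intra-ECF: must be ignored
        S[2, 4] = S[4, 2] = 5.0
        S[0, 3] = S[3, 0] = 7.0
        out = extract_interprotein_contacts(S, msa)
        assert [(c.col_i, c.col_j) for c in out[:2]] == [(1, 4), (3, 5)]
        assert [c.rank for c in out[:2]] == [1, 2]
        assert all(c.interprotein for c in out)

    def test_reference_mapping_and_regions(self):
        msa = self._msa()
        S = np.zeros((6, 6))
        S[2, 3] = S[3, 2] = 4.0
        regions = {("ecf", 3): "s2.1", ("asdi", 1): "H4"}
        out = extract_interprotein_contacts(S, msa, top_n=1, regions=regions)
        (c,) = out
        assert (c.ecf_residue, c.asdi_residue) == (3, 1)
        assert (c.ecf_region, c.asdi_region) == ("s2.1", "H4")

    def test_reference_gap_is_unmapped(self):
        rows = ["AC-EFG", "ACDEFG", "ACDEFG"]
        msa = PairedFamilyAlignment(["ref", "b", "c"], rows, n_ecf=3, reference_row_id="ref")
        S = np.zeros((6, 6))
        S[2, 3] = S[3, 2] = 4.0
        (c,) = extract_interprotein_contacts(S, msa, top_n=1)
        assert c.ecf_residue is None and not c.mapped

    def test_cutoff_above_max_is_empty(self):
        msa = self._msa()
        S = np.ones((6, 6))
        assert extract_interprotein_contacts(S, msa, score_cutoff=2.0) == []

    def test_score_tie_breaks_lexicographic(self):
        msa = self._msa()
        S = np.zeros((6, 6))
        for i, j in [(0, 3), (0, 4), (1, 3)]:
            S[i, j] = S[j, i] = 1.0
        out = extract_interprotein_contacts(S, msa, top_n=3)
        assert [(c.col_i, c.col_j) for c in out] == [(1, 4), (1, 5), (2, 4)]


class TestPlantedRecovery:
    def test_planted_pairs_dominate_top_predictions(self, planted_dca_run):
        aln, truth = planted_dca_run
        model = fit_dca(aln)
        top8 = extract_interprotein_contacts(model.S, aln, top_n=8)
        planted = set(truth.planted_global_pairs(aln.n_ecf))
        hits = sum((c.col_i, c.col_j) in planted for c in top8)
        assert hits >= 6

    def test_auto_theta_is_mean_hamming(self, small_paired_alignment):
        aln, _ = small_paired_alignment
        X = aln.encoded()
        from scipy.spatial.distance import pdist

        assert auto_theta(X) == pytest.approx(pdist(X, "hamming").mean())
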