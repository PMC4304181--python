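"""Tests for the coupling-analysis core, checked against straight-loop oracles."""

import math

import numpy as np
import pytest

from sectorscan.background import BACKGROUND_FREQS, SECTOR_PALETTE
from sectorscan.sca import (
    CouplingMatrix,
    binary_relative_entropy,
    compute_frequencies,
    coupling_matrix,
    coupling_tensor,
    define_sectors,
    encode_alignment,
    independent_components,
    positional_conservation,
    run_sca,
    sequence_correlation,
    shuffle_within_columns,
    spectral_significance,
    weight_gradient,
    weighting_phi,
)
from sectorscan.simulate import PlantedSector, PlantedSectorSpec, generate_planted_alignment
from tests.conftest import make_alignment, random_alignment
from tests.oracles import oracle_conservation, oracle_ctilde, oracle_f1, oracle_f2, oracle_phi

Q = BACKGROUND_FREQS


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

class TestFrequencies:
    def test_identical_copies_regularization_formula(self):
        lam = 0.03
        aln = make_alignment(["AC"] * 10, reference_index=None)
        fm = compute_frequencies(aln, lam=lam)
        qA, qC = Q[0], Q[1]
        assert fm.f1[0, 0] == pytest.approx(1 - lam + lam * qA, abs=1e-12)
        assert fm.f2[0, 0, 1, 1] == pytest.approx((1 - lam) + lam * qA * qC, abs=1e-12)

    def test_unregularized_direct_count(self):
        aln = make_alignment(["A", "A", "C", "C"], reference_index=None)
        fm = compute_frequencies(aln, lam=0.0)
        assert fm.f1[0, 0] == pytest.approx(0.5)
        assert fm.f1[0, 1] == pytest.approx(0.5)

    def test_pairwise_symmetry_random(self, rng):
        aln = random_alignment(rng, M=5, L=4)
        fm = compute_frequencies(aln)
        f2 = fm.f2
        assert np.allclose(f2, np.transpose(f2, (2, 3, 0, 1)), atol=1e-12)

    def test_diagonal_block_invariant(self, rng):
        aln = random_alignment(rng, M=6, L=3)
        fm = compute_frequencies(aln)
        for i in range(3):
            assert np.allclose(fm.f2[i, :, i, :], np.diag(fm.f1[i]), atol=1e-12)

    def test_gap_column_rejected(self):
        aln = make_alignment(["A-", "C-"], reference_index=None)
        with pytest.raises(ValueError, match="entirely gaps"):
            compute_frequencies(aln)

    def test_entries_in_unit_interval(self, rng):
        aln = random_alignment(rng, M=10, L=5, gap_fraction=0.2)
        fm = compute_frequencies(aln)
        assert np.all(fm.f1 >= 0) and np.all(fm.f1 <= 1)
        assert np.all(fm.f2_flat >= 0) and np.all(fm.f2_flat <= 1)

    def test_matches_loop_oracle(self, rng):
        aln = random_alignment(rng, M=8, L=4)
        rows = [r.residues for r in aln.records]
        fm = compute_frequencies(aln, lam=0.03)
        assert np.allclose(fm.f1, np.array(oracle_f1(rows, list(Q), 0.03)), atol=1e-12)
        oracle = np.array(oracle_f2(rows, list(Q), 0.03)).transpose(0, 2, 1, 3)
        assert np.allclose(fm.f2, oracle, atol=1e-12)


# ---------------------------------------------------------------------------
# conservation and weights
# ---------------------------------------------------------------------------

class TestConservation:
    def test_zero_at_background(self):
        assert binary_relative_entropy(0.05, 0.05) == pytest.approx(0.0, abs=1e-14)

    def test_analytic_spot_value(self):
        # 0.9*ln(18) + 0.1*ln(0.1/0.95) = 2.3762 nats
        expected = 0.9 * math.log(0.9 / 0.05) + 0.1 * math.log(0.1 / 0.95)
        assert expected == pytest.approx(2.3762, abs=5e-5)
        assert binary_relative_entropy(0.9, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_everywhere(self, rng):
        f = rng.uniform(0.01, 0.99, size=200)
        q = rng.uniform(0.01, 0.99, size=200)
        assert np.all(np.asarray(binary_relative_entropy(f, q)) >= -1e-15)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            binary_relative_entropy(0.0, 0.05)

    def test_profile_matches_oracle(self, rng):
        aln = random_alignment(rng, M=10, L=4)
        fm = compute_frequencies(aln)
        prof = positional_conservation(fm)
        expected = oracle_conservation(fm.f1.tolist(), list(Q))
        assert np.allclose(prof.D_ia, np.array(expected), atol=1e-12)
        assert np.all(prof.D_ia >= -1e-12)

    def test_kl_summary(self, rng):
        aln = random_alignment(rng, M=10, L=4)
        fm = compute_frequencies(aln)
        prof = positional_conservation(fm)
        manual = (fm.f1 * np.log(fm.f1 / Q[None, :])).sum(axis=1)
        assert np.allclose(prof.D_i, manual)


class TestWeights:
    def test_zero_at_background(self):
        assert weight_gradient(0.05, 0.05) == pytest.approx(0.0, abs=1e-14)

    def test_analytic_spot_value(self):
        # |ln(0.9*0.95 / (0.05*0.1))| = ln(171) = 5.1417
        assert math.log(171) == pytest.approx(5.1417, abs=5e-5)
        assert weight_gradient(0.9, 0.05) == pytest.approx(math.log(171), abs=1e-12)

    def test_complement_symmetry(self, rng):
        f = rng.uniform(0.01, 0.99, size=100)
        q = rng.uniform(0.01, 0.99, size=100)
        assert np.allclose(
            np.asarray(weight_gradient(f, q)),
            np.asarray(weight_gradient(1 - f, 1 - q)),
            atol=1e-12,
        )

    def test_matrix_matches_oracle(self, rng):
        aln = random_alignment(rng, M=10, L=4)
        fm = compute_frequencies(aln)
        assert np.allclose(
            weighting_phi(fm), np.array(oracle_phi(fm.f1.tolist(), list(Q))), atol=1e-12
        )


# ---------------------------------------------------------------------------
# coupling matrix
# ---------------------------------------------------------------------------

class TestCouplingMatrix:
    def test_independent_columns_zero_coupling(self):
        # all four combinations equally often: exact independence at lam=0
        aln = make_alignment(["AA", "AC", "CA", "CC"], reference_index=None)
        fm = compute_frequencies(aln, lam=0.0)
        cm = coupling_matrix(fm)
        assert cm.Ctilde[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_covariation_matches_tensor_oracle(self):
        aln = make_alignment(["AA", "AA", "CC", "CC"], reference_index=None)
        rows = [r.residues for r in aln.records]
        fm = compute_frequencies(aln, lam=0.03)
        cm = coupling_matrix(fm)
        expected = oracle_ctilde(rows, list(Q), 0.03)
        assert cm.Ctilde[0, 1] > 1.0  # strong coupling, sanity
        assert np.allclose(cm.Ctilde, np.array(expected), atol=1e-10)

    def test_symmetric_nonnegative_random(self, rng):
        aln = random_alignment(rng, M=12, L=6)
        cm = coupling_matrix(compute_frequencies(aln))
        assert np.allclose(cm.Ctilde, cm.Ctilde.T, atol=1e-12)
        assert np.all(cm.Ctilde >= 0)

    def test_matches_loop_oracle_random(self, rng):
        aln = random_alignment(rng, M=9, L=5)
        rows = [r.residues for r in aln.records]
        cm = coupling_matrix(compute_frequencies(aln, lam=0.03))
        assert np.allclose(cm.Ctilde, np.array(oracle_ctilde(rows, list(Q), 0.03)), atol=1e-10)

    def test_tensor_frobenius_consistency(self, rng):
        aln = random_alignment(rng, M=9, L=4)
        fm = compute_frequencies(aln)
        tensor = coupling_tensor(fm)
        cm = coupling_matrix(fm)
        assert np.allclose(
            cm.Ctilde, np.sqrt((tensor**2).sum(axis=(1, 3))), atol=1e-12
        )

    def test_sequence_correlation_shape_and_diagonal(self, rng):
        aln = random_alignment(rng, M=7, L=10)
        sim = sequence_correlation(aln)
        assert sim.shape == (7, 7)
        assert np.allclose(np.diag(sim), 1.0)


# ---------------------------------------------------------------------------
# spectral significance
# ---------------------------------------------------------------------------

def _small_planted(seed=3, rho=0.95):
    spec = PlantedSectorSpec(
        L=40,
        M=300,
        sectors=[PlantedSector(columns=list(range(5, 15)), rho=rho)],
        seed=seed,
    )
    return generate_planted_alignment(spec)


class TestSpectralSignificance:
    def test_seed_required(self, rng):
        aln = random_alignment(rng, M=10, L=5)
        cm = coupling_matrix(compute_frequencies(aln))
        with pytest.raises(ValueError, match="seed"):
            spectral_significance(cm, aln, n_rand=10)

    def test_contract_shapes_and_sorting(self, rng):
        aln = random_alignment(rng, M=30, L=8)
        cm = coupling_matrix(compute_frequencies(aln))
        spectral_significance(cm, aln, n_rand=10, seed=0)
        assert cm.random_spectra.shape == (10, 8)
        assert np.all(np.diff(cm.eigenvalues) <= 1e-12)
        assert np.all(np.diff(cm.random_spectra, axis=1) <= 1e-12)
        assert 0 <= cm.k_star <= 8

    def test_shuffle_preserves_column_counts(self, rng):
        aln = random_alignment(rng, M=20, L=10, gap_fraction=0.1)
        X = encode_alignment(aln)
        Xp = shuffle_within_columns(X, rng)
        for i in range(X.shape[1]):
            assert np.array_equal(
                np.sort(X[:, i]), np.sort(Xp[:, i])
            ), f"column {i} composition changed"

    def test_planted_sector_significant(self):
        aln, _ = _small_planted()
        cm = coupling_matrix(compute_frequencies(aln))
        spectral_significance(cm, aln, n_rand=20, seed=11)
        assert cm.k_star >= 1

    def test_deterministic_given_seed(self, rng):
        aln = random_alignment(rng, M=20, L=6)
        cm1 = coupling_matrix(compute_frequencies(aln))
        cm2 = coupling_matrix(compute_frequencies(aln))
        spectral_significance(cm1, aln, n_rand=10, seed=5)
        spectral_significance(cm2, aln, n_rand=10, seed=5)
        assert np.array_equal(cm1.random_spectra, cm2.random_spectra)


# ---------------------------------------------------------------------------
# ICA and sector definition
# ---------------------------------------------------------------------------

class TestIndependentComponents:
    def test_single_component_is_oriented_eigenvector(self):
        aln, _ = _small_planted()
        cm = coupling_matrix(compute_frequencies(aln))
        spectral_significance(cm, aln, n_rand=10, seed=1)
        cm.k_star = 1  # force the single-component path
        independent_components(cm, seed=1)
        v = cm.eigenvectors[:, 0]
        s = cm.ic_loadings[:, 0]
        assert np.allclose(np.abs(s), np.abs(v), atol=1e-12)
        assert s[np.argmax(np.abs(s))] > 0

    def test_eigenvectors_orthonormal(self):
        aln, _ = _small_planted()
        cm = coupling_matrix(compute_frequencies(aln))
        spectral_significance(cm, aln, n_rand=10, seed=1)
        V = cm.eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-6)

    def test_requires_significance(self, rng):
        aln = random_alignment(rng, M=10, L=5)
        cm = coupling_matrix(compute_frequencies(aln))
        with pytest.raises(ValueError, match="spectral_significance"):
            independent_components(cm)

    def test_two_sector_components_separate(self):
        spec = PlantedSectorSpec(
            L=60,
            M=400,
            sectors=[
                PlantedSector(columns=list(range(5, 15)), rho=0.9, residue_pair=("E", "K")),
                PlantedSector(columns=list(range(30, 40)), rho=0.9, residue_pair=("L", "F")),
            ],
            seed=21,
        )
        aln, truth = generate_planted_alignment(spec)
        cm = coupling_matrix(compute_frequencies(aln))
        spectral_significance(cm, aln, n_rand=20, seed=2)
        assert cm.k_star == 2
        independent_components(cm, seed=2)
        S = np.abs(cm.ic_loadings)
        sector1 = np.flatnonzero(truth == 1)
        sector2 = np.flatnonzero(truth == 2)
        # each planted sector loads dominantly on a single distinct component
        comp1 = np.argmax(S[sector1].sum(axis=0))
        comp2 = np.argmax(S[sector2].sum(axis=0))
        assert comp1 != comp2
        assert S[sector1, comp1].min() > 5 * S[sector1, 1 - comp1].max()


class TestDefineSectors:
    def test_empty_when_no_significance(self, rng):
        cm = CouplingMatrix(Ctilde=np.eye(5))
        cm.k_star = 0
        assignment = define_sectors(cm)
        assert assignment.sectors == []
        assert assignment.unassigned == [1, 2, 3, 4, 5]

    def test_palette_order(self):
        spec = PlantedSectorSpec(
            L=60,
            M=400,
            sectors=[
                PlantedSector(columns=list(range(5, 15)), rho=0.9, residue_pair=("E", "K")),
                PlantedSector(columns=list(range(30, 40)), rho=0.9, residue_pair=("L", "F")),
            ],
            seed=21,
        )
        aln, _ = generate_planted_alignment(spec)
        _, _, assignment = run_sca(aln, seed=4, n_rand=20)
        labels = [s.label for s in assignment.sectors]
        assert labels == list(SECTOR_PALETTE[: len(labels)])

    def test_members_exceed_cutoff_and_disjoint(self):
        aln, _ = _small_planted()
        _, cm, assignment = run_sca(aln, seed=9, n_rand=20)
        seen = set()
        for sector in assignment.sectors:
            assert not (seen & set(sector.columns))
            seen |= set(sector.columns)
            for col in sector.columns:
                assert sector.loadings[col] > sector.cutoff

    def test_empirical_cutoff_mode(self):
        aln, _ = _small_planted()
        fm = compute_frequencies(aln)
        cm = coupling_matrix(fm)
        spectral_significance(cm, aln, n_rand=20, seed=3)
        if cm.k_star >= 1:
            independent_components(cm, seed=3)
        assignment = define_sectors(cm, cutoff_quantile=0.9, cutoff_method="empirical")
        for sector in assignment.sectors:
            assert len(sector.columns) <= int(0.1 * cm.L) + 1

    def test_unknown_cutoff_method_rejected(self):
        aln, _ = _small_planted()
        _, cm, _ = run_sca(aln, seed=9, n_rand=20)
        with pytest.raises(ValueError, match="cutoff method"):
            define_sectors(cm, cutoff_method="bogus")
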