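"""Sequence/structure residue descriptors and the 920-d pair vectors."""

from __future__ import annotations

import numpy as np
import pytest

from tetraface import (
    PhyschemTable,
    aaacf,
    aaipf,
    chain_residue_vectors,
    neighbor_order,
    neighbor_weights,
    pair_vector,
    racf,
    residue_vector,
    rho,
    ripf,
)
from tetraface.pair_features import (
    N_PAIR_FEATURES,
    N_RESIDUE_FEATURES,
    physchem_sequences,
)

from conftest import make_chain, random_chain


class TestSequenceFeatures:
    def test_physchem_lookup(self):
        table = PhyschemTable.default()
        seqs = physchem_sequences(make_chain("AAAA" * 6), table)
        assert seqs.shape == (5, 24)
        np.testing.assert_allclose(seqs[0], 1.8)  # hydrophobicity(A)

    def test_unknown_letter_named_in_error(self):
        chain = make_chain("AXAA" * 6)
        with pytest.raises(KeyError, match="X"):
            physchem_sequences(chain, PhyschemTable.default())

    def test_interval_products_by_direct_substitution(self):
        seq = [1, 2, 3, 4, 5]
        fwd, bwd = aaipf(seq, 2, 2)
        assert (fwd, bwd) == (3 * 1 / 2, 3 * 5 / 2)

    def test_interval_products_wrap_circularly(self):
        seq = [1, 2, 3, 4, 5]
        _, bwd = aaipf(seq, 4, 2)
        assert bwd == 5 * 2 / 2  # wraps to position 1 (0-based index 1)
        fwd, _ = aaipf(seq, 0, 3)
        assert fwd == 1 * 3 / 3  # wraps to the tail

    def test_constant_sequence_closed_form(self):
        seq = [4.0] * 9
        for k in (1, 5, 10):
            fwd, bwd = aaipf(seq, 3, k)
            assert fwd == bwd == pytest.approx(16.0 / k)
            assert aaacf(seq, 3, k) == pytest.approx(4.0)

    def test_window_mean_examples(self):
        seq = [1, 2, 3, 4, 5]
        assert aaacf(seq, 2, 1) == pytest.approx(3.0)
        assert aaacf(seq, 0, 1) == pytest.approx((5 + 1 + 2) / 3)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            aaipf([1, 2, 3], 0, 11)
        with pytest.raises(ValueError):
            aaacf([1, 2, 3], 0, 0)

    def test_matches_exhaustive_circular_oracle(self, rng):
        """Brute-force modular indexing over every (j, k) of short sequences."""
        for L in range(2, 13):
            seq = rng.normal(size=L)
            for j in range(L):
                for k in range(1, 11):
                    fwd, bwd = aaipf(seq, j, k)
                    assert fwd == pytest.approx(seq[j] * seq[(j - k) % L] / k)
                    assert bwd == pytest.approx(seq[j] * seq[(j + k) % L] / k)
                    window = [seq[(j + o) % L] for o in range(-k, k + 1)]
                    assert aaacf(seq, j, k) == pytest.approx(
                        sum(window) / (2 * k + 1)
                    )


class TestNeighborOrder:
    def test_collinear_example(self):
        coords = np.zeros((24, 3))
        coords[:, 0] = np.concatenate([[0, 1, 3, 6], 50 + np.arange(20) * 4])
        order = neighbor_order(make_chain("A" * 24, coords), 0)
        assert order.lambda_[:3].tolist() == [1, 2, 3]
        np.testing.assert_allclose(order.d[:3], [1, 3, 6])

    def test_equidistant_neighbors_order_by_position(self):
        coords = np.zeros((25, 3))
        coords[:, 0] = np.arange(25) * 5.0
        coords[10, 0] = 0.0
        coords[10, 1] = 5.0  # residues 1 and 10 both at distance 5 from 0
        order = neighbor_order(make_chain("A" * 25, coords), 0)
        first_two = order.lambda_[:2].tolist()
        assert first_two == [1, 10]

    def test_too_few_neighbors_rejected(self):
        chain, _ = random_chain(np.random.default_rng(0), 21)
        with pytest.raises(ValueError, match="21 other residues"):
            neighbor_order(chain, 0)

    def test_matches_exhaustive_sort_oracle(self, rng):
        for _ in range(50):
            chain, _ = random_chain(rng, int(rng.integers(23, 40)))
            j = int(rng.integers(len(chain)))
            order = neighbor_order(chain, j)
            d = np.linalg.norm(chain.ca_coords - chain.ca_coords[j], axis=1)
            expected = sorted(
                (i for i in range(len(chain)) if i != j),
                key=lambda i: (d[i], i),
            )
            assert order.lambda_.tolist() == expected
            assert np.all(np.diff(order.d) >= 0)


class TestStructureFactors:
    @staticmethod
    def _chain_order(rng, L=30):
        chain, profile = random_chain(rng, L)
        return chain, profile, neighbor_order(chain, 4)

    def test_interval_product_direct(self, rng):
        chain, profile, order = self._chain_order(rng)
        phi = np.arange(30, dtype=float)
        expected = phi[4] * phi[order.lambda_[2]] / 3
        assert ripf(phi, 4, order, 3) == pytest.approx(expected)

    def test_constant_profile_closed_forms(self, rng):
        chain, _, order = self._chain_order(rng)
        phi = np.full(30, 3.0)
        for k in (1, 10, 20):
            assert ripf(phi, 4, order, k) == pytest.approx(9.0 / k)
            assert racf(phi, 4, order, k) == pytest.approx(3.0)

    def test_cumulation_equals_neighborhood_mean(self, rng):
        chain, profile, order = self._chain_order(rng)
        phi = profile.column("ASA")
        for k in (1, 7, 20):
            members = np.r_[phi[4], phi[order.lambda_[:k]]]
            assert racf(phi, 4, order, k) == pytest.approx(members.mean())

    def test_equal_distances_give_weight_e_inverse(self):
        # 24 points on a circle around the center: all equidistant
        angles = np.linspace(0, 2 * np.pi, 25)[:-1]
        coords = np.zeros((25, 3))
        coords[1:, 0] = 9.0 * np.cos(angles)
        coords[1:, 1] = 9.0 * np.sin(angles)
        order = neighbor_order(make_chain("A" * 25, coords), 0)
        w = neighbor_weights(order)
        np.testing.assert_allclose(w, np.exp(-1.0))
        phi = np.full(25, 2.5)
        np.testing.assert_allclose(rho(phi, order), 2.5 * np.exp(-1.0))

    def test_weights_decrease_with_distance(self, rng):
        chain, _, order = self._chain_order(rng)
        w = neighbor_weights(order)
        # same normalizing sum for all xi: monotone non-increasing in d
        assert np.all(np.diff(w) <= 1e-15)

    def test_zero_distance_rejected(self):
        coords = np.zeros((25, 3))
        coords[1:, 0] = np.arange(24) * 4.0  # residue 1 sits on residue 0
        order = neighbor_order(make_chain("A" * 25, coords), 0)
        with pytest.raises(ValueError, match="duplicate"):
            neighbor_weights(order)


class TestResidueVectors:
    def test_feature_counts(self, rng):
        chain, profile = random_chain(rng, 28)
        table = PhyschemTable.default()
        seqs = physchem_sequences(chain, table)
        u = residue_vector(chain, seqs, profile, 3)
        assert u.shape == (N_RESIDUE_FEATURES,)
        assert N_RESIDUE_FEATURES == 155 + 305 == 460
        assert np.all(np.isfinite(u))

    def test_pair_vector_is_order_sensitive(self, rng):
        chain, profile = random_chain(rng, 28)
        seqs = physchem_sequences(chain, PhyschemTable.default())
        u1 = residue_vector(chain, seqs, profile, 3)
        u2 = residue_vector(chain, seqs, profile, 9)
        pv = pair_vector(u1, u2, label=1)
        assert pv.vector.shape == (N_PAIR_FEATURES,)
        assert not np.array_equal(pv.vector, pair_vector(u2, u1).vector)
        np.testing.assert_array_equal(pv.vector[:460], u1)

    def test_vectorized_matches_reference_per_residue(self, rng):
        chain, profile = random_chain(rng, 26)
        table = PhyschemTable.default()
        U = chain_residue_vectors(chain, profile, table)
        seqs = physchem_sequences(chain, table)
        for j in (0, 7, 25):
            np.testing.assert_allclose(
                U[j], residue_vector(chain, seqs, profile, j), atol=1e-10
            )

    def test_structure_features_rigid_motion_invariant(self, rng):
        from scipy.spatial.transform import Rotation

        chain, profile = random_chain(rng, 30)
        table = PhyschemTable.default()
        U = chain_residue_vectors(chain, profile, table)
        R = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = make_chain(
            chain.sequence, chain.ca_coords @ R.T + np.array([5.0, -3.0, 12.0])
        )
        U2 = chain_residue_vectors(moved, profile, table)
        np.testing.assert_allclose(U, U2, atol=1e-8)
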