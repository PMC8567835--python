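"""Path broadcasting strength, nodal strengths and broadcasting aggregates."""

import math

import numpy as np
import pytest

from bnit import (
    FunctionalConnectome,
    StructuralConnectome,
    all_pairs_shortest_paths,
    broadcast_strengths,
    compute_pbs,
    pbs_matrix,
    structural_strength,
    top_regions,
)
from bnit.io import ValidationError
from bnit.paths import ShortestPath
from bnit.pbs import BroadcastStrengths, PBSMatrix
from bnit.pps import RegimeLabels
from conftest import (
    TOY_LEN_AE,
    TOY_RAW_PBS_AE,
    TOY_W,
    pbs_product_form,
    random_connected_lengths,
    random_mi_matrix,
)


class TestStructuralStrength:
    def test_mask_excludes_nonstructural_mi(self):
        """MI over absent structural edges never enters the strength."""
        sc = np.zeros((3, 3))
        sc[0, 1] = sc[1, 0] = 5.0
        sc[0, 2] = sc[2, 0] = 5.0
        mi = np.array([[3.0, 0.5, 0.25], [0.5, 3.0, 9.9], [0.25, 9.9, 3.0]])
        w = structural_strength(FunctionalConnectome(mi), StructuralConnectome(sc))
        assert w[0] == pytest.approx(0.75)
        assert w[1] == pytest.approx(0.5)  # the 9.9 on the absent edge is ignored

    def test_isolated_node_zero(self):
        sc = np.zeros((3, 3))
        sc[0, 1] = sc[1, 0] = 5.0
        mi = random_mi_matrix(3, np.random.default_rng(0))
        w = structural_strength(FunctionalConnectome(mi), StructuralConnectome(sc))
        assert w[2] == 0.0

    def test_complete_sc_equals_unmasked_strength(self):
        rng = np.random.default_rng(1)
        n = 6
        mi = random_mi_matrix(n, rng)
        dense = np.full((n, n), 7.0)
        np.fill_diagonal(dense, 0.0)
        w = structural_strength(FunctionalConnectome(mi), StructuralConnectome(dense))
        unmasked = mi.sum(axis=1) - np.diagonal(mi)
        np.testing.assert_allclose(w, unmasked)

    def test_toy_strengths(self, toy):
        sc, fc, _ = toy
        np.testing.assert_allclose(structural_strength(fc, sc), TOY_W)


class TestComputePBS:
    def test_worked_two_edge_example(self):
        """Edge MIs {1, 0.5} with strengths {2, 2} over 10 mm give
        -log2(0.5 * 0.25) = 3 bits, 0.3 bits/mm."""
        mi = np.zeros((3, 3))
        mi[0, 1] = mi[1, 0] = 1.0
        mi[1, 2] = mi[2, 1] = 0.5
        fc = FunctionalConnectome(mi)
        w = np.array([2.0, 2.0, 2.0])
        raw, norm = compute_pbs(ShortestPath((0, 1, 2), 10.0), fc, w)
        assert raw == pytest.approx(3.0, abs=1e-12)
        assert norm == pytest.approx(0.3, abs=1e-12)

    def test_direct_path_fully_specific_routing_is_zero_bits(self):
        mi = np.zeros((2, 2))
        mi[0, 1] = mi[1, 0] = 0.8
        raw, _ = compute_pbs(
            ShortestPath((0, 1), 5.0), FunctionalConnectome(mi), np.array([0.8, 0.8])
        )
        assert raw == pytest.approx(0.0, abs=1e-12)

    def test_zero_mi_edge_gives_infinite_marker(self):
        mi = np.zeros((3, 3))
        mi[0, 1] = mi[1, 0] = 0.5
        raw, norm = compute_pbs(
            ShortestPath((0, 1, 2), 10.0),
            FunctionalConnectome(mi),
            np.array([1.0, 1.0, 1.0]),
        )
        assert math.isinf(raw) and math.isinf(norm)

    def test_toy_answer_sheet(self, toy):
        sc, fc, _ = toy
        table = all_pairs_shortest_paths(sc)
        raw, norm = compute_pbs(table.get(0, 4), fc, TOY_W)
        assert raw == pytest.approx(TOY_RAW_PBS_AE, abs=1e-12)
        assert norm == pytest.approx(TOY_RAW_PBS_AE / TOY_LEN_AE, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_product_form_oracle(self, seed):
        """Sum-of-logs PBS equals the literal -log2 of the ratio product."""
        rng = np.random.default_rng(seed)
        n = 6
        lengths = random_connected_lengths(n, density=0.4, rng=rng)
        sc = StructuralConnectome(lengths)
        mi = random_mi_matrix(n, rng)
        fc = FunctionalConnectome(mi)
        w = structural_strength(fc, sc)
        table = all_pairs_shortest_paths(sc)
        for s, t, p in table.pairs():
            raw, _ = compute_pbs(p, fc, w)
            assert raw == pytest.approx(pbs_product_form(p.nodes, mi, w), abs=1e-10)

    def test_nonnegative_raw_pbs(self):
        """Each path-edge MI is part of its tail node's masked strength, so
        every ratio is <= 1 and raw PBS >= 0."""
        rng = np.random.default_rng(77)
        lengths = random_connected_lengths(8, density=0.5, rng=rng)
        sc = StructuralConnectome(lengths)
        fc = FunctionalConnectome(random_mi_matrix(8, rng))
        pbs = pbs_matrix(all_pairs_shortest_paths(sc), fc, sc=sc)
        defined = pbs.raw[np.isfinite(pbs.raw)]
        assert (defined >= -1e-12).all()

    def test_additivity_over_hops(self):
        rng = np.random.default_rng(21)
        n = 7
        lengths = random_connected_lengths(n, density=0.4, rng=rng)
        sc = StructuralConnectome(lengths)
        fc = FunctionalConnectome(random_mi_matrix(n, rng))
        w = structural_strength(fc, sc)
        table = all_pairs_shortest_paths(sc)
        for s, t, p in table.pairs():
            total, _ = compute_pbs(p, fc, w)
            hops = sum(
                compute_pbs(
                    ShortestPath((a, b), lengths[a, b]), fc, w
                )[0]
                for a, b in zip(p.nodes[:-1], p.nodes[1:])
            )
            assert total == pytest.approx(hops, abs=1e-10)

    def test_exclude_arrival_variant_divides_by_reduced_strength(self):
        mi = np.zeros((3, 3))
        mi[0, 1] = mi[1, 0] = 0.5
        mi[1, 2] = mi[2, 1] = 0.25
        fc = FunctionalConnectome(mi)
        w = np.array([1.0, 1.0, 1.0])
        raw, _ = compute_pbs(ShortestPath((0, 1, 2), 10.0), fc, w, mode="exclude_arrival")
        expected = -math.log2(0.5 / 1.0) - math.log2(0.25 / (1.0 - 0.5))
        assert raw == pytest.approx(expected, abs=1e-12)


class TestPBSMatrix:
    def test_matches_per_pair_calls(self, toy):
        sc, fc, _ = toy
        table = all_pairs_shortest_paths(sc)
        w = structural_strength(fc, sc)
        pbs = pbs_matrix(table, fc, w=w)
        for s, t, p in table.pairs():
            raw, norm = compute_pbs(p, fc, w)
            assert pbs.raw[s, t] == raw
            assert pbs.norm[s, t] == norm
        assert np.isnan(np.diagonal(pbs.raw)).all()

    def test_star_graph_symmetry(self):
        """Equal-weight star: PBS(s->t) = PBS(t->s) by symmetry."""
        n = 5
        lengths = np.zeros((n, n))
        for leaf in range(1, n):
            lengths[0, leaf] = lengths[leaf, 0] = 10.0
        mi = np.zeros((n, n))
        for leaf in range(1, n):
            mi[0, leaf] = mi[leaf, 0] = 0.5
        np.fill_diagonal(mi, 2.0)
        sc = StructuralConnectome(lengths)
        fc = FunctionalConnectome(mi)
        pbs = pbs_matrix(all_pairs_shortest_paths(sc), fc, sc=sc)
        for s in range(1, n):
            for t in range(1, n):
                if s != t:
                    assert pbs.raw[s, t] == pytest.approx(pbs.raw[t, s], abs=1e-12)

    def test_length_scaling_halves_normalized_only(self, toy):
        sc, fc, _ = toy
        pbs1 = pbs_matrix(all_pairs_shortest_paths(sc), fc, sc=sc)
        sc2 = StructuralConnectome(sc.lengths * 2.0, list(sc.region_ids))
        pbs2 = pbs_matrix(all_pairs_shortest_paths(sc2), fc, sc=sc2)
        mask = np.isfinite(pbs1.raw)
        np.testing.assert_allclose(pbs2.raw[mask], pbs1.raw[mask], atol=1e-12)
        np.testing.assert_allclose(pbs2.norm[mask], pbs1.norm[mask] / 2.0, atol=1e-12)


class TestBroadcastStrengths:
    def _labels(self, n, code):
        codes = np.full((n, n), code, dtype=np.int8)
        np.fill_diagonal(codes, -1)
        return RegimeLabels(codes)

    def test_single_pair(self):
        n = 4
        norm = np.full((n, n), np.nan)
        norm[0, 2] = 0.7
        codes = np.zeros((n, n), dtype=np.int8)
        np.fill_diagonal(codes, -1)
        codes[0, 2] = 3  # relay
        bs = broadcast_strengths(
            PBSMatrix(norm.copy(), norm), RegimeLabels(codes), "relay"
        )
        assert bs.wbs_sender[0] == 0.7
        assert bs.wbs_receiver[2] == 0.7
        assert bs.wbs[0] == 0.35
        assert bs.wbs_sender[[1, 2, 3]].sum() == 0

    def test_symmetric_matrix_sender_equals_receiver(self):
        rng = np.random.default_rng(4)
        n = 5
        norm = rng.uniform(0, 1, (n, n))
        norm = (norm + norm.T) / 2
        np.fill_diagonal(norm, np.nan)
        bs = broadcast_strengths(
            PBSMatrix(norm.copy(), norm), self._labels(n, 3), "relay"
        )
        np.testing.assert_allclose(bs.wbs_sender, bs.wbs_receiver)

    def test_masked_row_column_sum_oracle(self):
        rng = np.random.default_rng(6)
        n = 6
        norm = rng.uniform(0, 2, (n, n))
        np.fill_diagonal(norm, np.nan)
        codes = rng.integers(2, 5, size=(n, n)).astype(np.int8)  # absent/relay/transducted
        np.fill_diagonal(codes, -1)
        labels = RegimeLabels(codes)
        bs = broadcast_strengths(PBSMatrix(norm.copy(), norm), labels, "transducted")
        mask = (codes == 4) & np.isfinite(norm)
        np.testing.assert_allclose(bs.wbs_sender, np.where(mask, norm, 0).sum(axis=1))
        np.testing.assert_allclose(bs.wbs_receiver, np.where(mask, norm, 0).sum(axis=0))

    def test_wbs_identity_exact(self):
        rng = np.random.default_rng(8)
        n = 7
        norm = rng.uniform(0, 3, (n, n))
        np.fill_diagonal(norm, np.nan)
        for regime in ("direct", "relay", "transducted"):
            code = {"direct": 1, "relay": 3, "transducted": 4}[regime]
            bs = broadcast_strengths(
                PBSMatrix(norm.copy(), norm), self._labels(n, code), regime
            )
            np.testing.assert_array_equal(bs.wbs, (bs.wbs_sender + bs.wbs_receiver) / 2)

    def test_infinite_entries_excluded_and_counted(self):
        n = 3
        norm = np.full((n, n), 1.0)
        np.fill_diagonal(norm, np.nan)
        norm[0, 1] = np.inf
        bs = broadcast_strengths(
            PBSMatrix(norm.copy(), norm), self._labels(n, 3), "relay"
        )
        assert bs.n_excluded == 1
        assert np.isfinite(bs.wbs).all()

    def test_unknown_regime_rejected(self):
        norm = np.ones((2, 2))
        with pytest.raises(ValidationError, match="regime"):
            broadcast_strengths(PBSMatrix(norm, norm), self._labels(2, 3), "absent")


class TestTopRegions:
    def _bs(self, wbs):
        wbs = np.asarray(wbs, dtype=float)
        return BroadcastStrengths(wbs, wbs, wbs, "relay")

    def test_planted_broadcaster_ranks_first(self):
        bs = self._bs([0.1, 0.2, 5.0, 0.3])
        table = top_regions(bs, 2)
        assert table.loc[0, "region"] == "region_2"

    def test_all_equal_ties_resolve_by_index(self):
        bs = self._bs([1.0, 1.0, 1.0, 1.0])
        table = top_regions(bs, 3)
        assert list(table["region"]) == ["region_0", "region_1", "region_2"]

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            top_regions(self._bs([1.0]), 2)
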