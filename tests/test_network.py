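import numpy as np
import pytest
from scipy import stats

from _oracles import pearson_oracle
from fluctnet.deltas import DeltaPanel
from fluctnet.errors import ValidationError
from fluctnet.network import (
    FluctuatingNetwork,
    NetworkParams,
    build_visual_edges,
    enumerate_candidate_pairs,
    panel_pearson,
    pearson_across_panel,
    select_couplings,
    select_fluctuating_atoms,
)


def make_panel(delta_rmsf, pair_list=None, delta_pcc=None, excluded=None):
    delta_rmsf = np.asarray(delta_rmsf, float)
    L = delta_rmsf.shape[0]
    if pair_list is None:
        pair_list = np.zeros((0, 2), int)
        delta_pcc = np.zeros((L, 0))
    if excluded is None:
        excluded = np.zeros_like(np.asarray(delta_pcc), dtype=bool)
    return DeltaPanel(
        ligand_ids=[f"L{k}" for k in range(L)],
        atom_indices=np.arange(delta_rmsf.shape[1]),
        delta_rmsf=delta_rmsf,
        pair_list=np.asarray(pair_list, int).reshape(-1, 2),
        delta_pcc=np.asarray(delta_pcc, float),
        pair_excluded=np.asarray(excluded, bool),
    )


class TestPearson:
    def test_perfect_positive(self):
        eff = np.array([0.0, 20.0, 40.0, 100.0])
        assert pearson_across_panel(eff, eff) == pytest.approx(1.0)

    def test_perfect_negative(self):
        eff = np.array([0.0, 20.0, 40.0, 100.0])
        assert pearson_across_panel(-eff + 7.0, eff) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        assert pearson_across_panel([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]) is None
        assert pearson_across_panel([0.0, 1.0, 2.0], [5.0, 5.0, 5.0]) is None

    def test_matches_definition_oracle(self):
        values = [1.0, 2.0, 3.0, 5.0]
        eff = [0.0, 20.0, 40.0, 100.0]
        r = pearson_across_panel(values, eff)
        assert abs(r - pearson_oracle(values, eff)) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pearson_across_panel([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_panel_pearson_nan_for_constant_column(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        r = panel_pearson(X, [0.0, 1.0, 2.0])
        assert np.isnan(r[0]) and r[1] == pytest.approx(1.0)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            NetworkParams(correlation_threshold=0.0)
        with pytest.raises(ValidationError):
            NetworkParams(distance_cutoff=-1.0)
        with pytest.raises(ValidationError):
            NetworkParams(correlation_mode="sideways")

    def test_signed_mode_ignores_negative(self):
        p_abs = NetworkParams(correlation_mode="absolute")
        p_pos = NetworkParams(correlation_mode="signed_positive")
        assert p_abs.passes(-0.9) and not p_pos.passes(-0.9)
        assert p_pos.passes(0.9)


class TestSelectFluctuatingAtoms:
    def test_linear_atoms_selected(self):
        eff = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        rmsf = np.stack([eff / 50.0, -eff / 80.0, np.ones(5)], axis=1)
        panel = make_panel(rmsf)
        out = select_fluctuating_atoms(panel, eff, NetworkParams())
        assert [a for a, _ in out] == [0, 1]
        assert out[0][1] == pytest.approx(1.0)
        assert out[1][1] == pytest.approx(-1.0)

    def test_constant_column_never_selected(self):
        panel = make_panel(np.ones((4, 1)))
        assert select_fluctuating_atoms(panel, [0.0, 1.0, 2.0, 3.0], NetworkParams()) == []

    def test_threshold_above_one_empty(self):
        eff = np.array([0.0, 50.0, 100.0])
        panel = make_panel(np.stack([eff], axis=1))
        out = select_fluctuating_atoms(
            panel, eff, NetworkParams(correlation_threshold=1.01)
        )
        assert out == []

    def test_monotone_in_threshold(self, rng):
        eff = rng.uniform(0, 100, size=8)
        panel = make_panel(rng.normal(size=(8, 30)))
        previous = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            sel = {a for a, _ in select_fluctuating_atoms(panel, eff, NetworkParams(correlation_threshold=thr))}
            if previous is not None:
                assert sel <= previous
            previous = sel


class TestCandidatePairs:
    def test_star_around_single_fluct_atom(self):
        ref = np.zeros((5, 3))
        ref[1:] = [[1, 0, 0], [0, 2, 0], [0, 0, 3], [2, 2, 0]]
        pairs = enumerate_candidate_pairs([0], range(5), ref, NetworkParams())
        assert pairs.shape == (4, 2)
        assert set(map(tuple, pairs)) == {(0, 1), (0, 2), (0, 3), (0, 4)}

    def test_tiny_cutoff_empty(self):
        ref = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        pairs = enumerate_candidate_pairs(
            [0], range(3), ref, NetworkParams(distance_cutoff=0.1)
        )
        assert pairs.shape == (0, 2)

    def test_hand_geometry_3_11_13(self):
        ref = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 11.0, 0], [0.0, 0, 13.0]])
        pairs = enumerate_candidate_pairs([0], range(4), ref, NetworkParams())
        assert set(map(tuple, pairs)) == {(0, 1), (0, 2)}

    def test_empty_fluctuating_set(self):
        assert enumerate_candidate_pairs([], range(4), np.zeros((4, 3)), NetworkParams()).size == 0

    def test_no_self_pairs_and_sorted(self, rng):
        ref = rng.uniform(0, 5, size=(8, 3))
        pairs = enumerate_candidate_pairs([3, 5], range(8), ref, NetworkParams())
        assert all(i < j for i, j in pairs)
        assert np.all(np.diff(pairs[:, 0] * 100 + pairs[:, 1]) > 0)


class TestSelectCouplings:
    def test_planted_pair_selected(self):
        eff = np.linspace(0, 100, 6)
        dpcc = np.stack([eff / 60.0, np.zeros(6)], axis=1)
        panel = make_panel(np.zeros((6, 1)), [(0, 1), (0, 2)], dpcc)
        out = select_couplings(panel, eff, NetworkParams(), np.array([(0, 1), (0, 2)]))
        assert len(out) == 1 and out[0][:2] == (0, 1) and out[0][2] > 0.99

    def test_degenerate_pair_excluded(self):
        eff = np.linspace(0, 100, 6)
        dpcc = np.stack([eff / 60.0], axis=1)
        excl = np.zeros((6, 1), bool)
        excl[2, 0] = True
        panel = make_panel(np.zeros((6, 1)), [(0, 1)], dpcc, excl)
        assert select_couplings(panel, eff, NetworkParams(), np.array([(0, 1)])) == []

    def test_missing_pair_column_rejected(self):
        eff = np.linspace(0, 100, 6)
        panel = make_panel(np.zeros((6, 1)), [(0, 1)], np.zeros((6, 1)))
        with pytest.raises(ValidationError):
            select_couplings(panel, eff, NetworkParams(), np.array([(5, 9)]))

    def test_empty_candidates(self):
        panel = make_panel(np.zeros((4, 1)), [(0, 1)], np.zeros((4, 1)))
        assert select_couplings(panel, np.arange(4.0), NetworkParams(), np.zeros((0, 2), int)) == []

    def test_noise_pair_rate_matches_null(self):
        """A pure-noise pair is selected at ~ the analytic |r|>0.6 tail (n=14)."""
        n, thr = 14, 0.6
        t_stat = thr * np.sqrt((n - 2) / (1.0 - thr**2))
        p_analytic = 2.0 * stats.t.sf(t_stat, n - 2)
        rng = np.random.default_rng(2024)
        eff = np.asarray(
            [100, 99.14, 100, 100, 100, 100, 100, 100, 96.77, 93.52, 43.35, 15.48, 0, 0],
            float,
        )
        n_pairs = 500
        dpcc = rng.normal(size=(n, n_pairs))
        pair_list = np.array([(0, k + 1) for k in range(n_pairs)])
        panel = make_panel(np.zeros((n, 1)), pair_list, dpcc)
        hits = select_couplings(panel, eff, NetworkParams(), pair_list)
        rate = len(hits) / n_pairs
        assert rate < 0.03
        assert abs(rate - p_analytic) < 0.025  # loose MC bound at 500 trials


class TestVisualEdges:
    @pytest.fixture
    def topology(self, toy_receptor):
        return toy_receptor[0]

    def net(self, topology, atoms, couplings, ref=None):
        ref = np.zeros((topology.n_atoms, 3)) if ref is None else ref
        return FluctuatingNetwork(
            params=NetworkParams(),
            fluctuating_atoms=[(a, 0.9) for a in atoms],
            couplings=[(i, j, 0.9) for i, j in couplings],
            reference_coords=ref,
        )

    def test_both_fluctuating_same_segment_kept(self, topology):
        # atoms 30 and 33 are both in segment H3
        edges = build_visual_edges(self.net(topology, [30, 33], [(30, 33)]), topology)
        assert len(edges) == 1
        assert edges[0].color_class == "both_fluctuating"
        assert {edges[0].endpoint_a, edges[0].endpoint_b} == {30, 33}

    def test_substituted_same_segment_dropped(self, topology):
        # 30 fluctuating, 33 not; both in H3 -> substituted edge dropped
        edges = build_visual_edges(self.net(topology, [30], [(30, 33)]), topology)
        assert edges == []

    def test_substituted_cross_segment_merged_weight3(self, topology):
        # 3 couplings from fluctuating atom 30 (H3) to the 3 atoms of
        # residue 16 (H4) -> one substituted edge to residue 16's C-alpha
        res16 = [a.atom_index for a in topology.atoms if a.residue_number == 16]
        ca16 = topology.calpha_index(16)
        edges = build_visual_edges(
            self.net(topology, [30], [(30, k) for k in res16]), topology
        )
        assert len(edges) == 1
        e = edges[0]
        assert e.color_class == "one_fluctuating"
        assert e.weight == 3
        assert {e.endpoint_a, e.endpoint_b} == {30, ca16}

    def test_network_validate_catches_violations(self, topology, rng):
        ref = rng.uniform(0, 50, size=(topology.n_atoms, 3))
        bad = FluctuatingNetwork(
            params=NetworkParams(),
            fluctuating_atoms=[(0, 0.9)],
            couplings=[(1, 2, 0.9)],  # no fluctuating endpoint
            reference_coords=ref,
        )
        with pytest.raises(ValidationError):
            bad.validate()
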