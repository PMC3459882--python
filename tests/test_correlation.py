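"""Pair selection, correlation matrices, projection and correlation factors."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icnet.correlation import (PairSelection, correlation_factor,
                               distance_shell_profile, pair_correlation,
                               project_to_residues,
                               residue_correlation_matrix, select_pairs,
                               ResidueCorrelationMatrix)
from icnet.energy import EnergyTrajectory, pair_universe
from icnet.synthetic import (PlantedNetwork, generate_energy_trajectory,
                             generate_toy_complex)
from conftest import pearson_oracle


def _traj_from_columns(n_residues, columns):
    """Trajectory with explicit per-pair time series (dict pair -> list)."""
    pairs = pair_universe(n_residues)
    n_frames = len(next(iter(columns.values())))
    values = np.zeros((n_frames, len(pairs)))
    for k, p in enumerate(pairs):
        if p in columns:
            values[:, k] = columns[p]
    return EnergyTrajectory(n_residues, values, pairs=pairs)


class TestSelectPairs:
    def test_background_below_cutoff_gives_empty_selection(self):
        net = PlantedNetwork(8)  # background only, baseline -2
        traj = generate_energy_trajectory(net, 100, seed=1)
        assert len(select_pairs(traj, cutoff=10.0)) == 0

    def test_exactly_planted_pairs_selected(self, two_group_trajectory,
                                            two_group_network):
        sel = select_pairs(two_group_trajectory, cutoff=10.0)
        assert sel.pairs == two_group_network.planted_pairs()

    def test_vacuous_cutoff_selects_all_pairs(self, two_group_trajectory):
        sel = select_pairs(two_group_trajectory, cutoff=0.001)
        assert sel.pairs == two_group_trajectory.pairs

    def test_nonpositive_cutoff_rejected(self, two_group_trajectory):
        with pytest.raises(ValueError):
            select_pairs(two_group_trajectory, cutoff=0.0)

    def test_selection_order_deterministic(self, two_group_trajectory):
        sel = select_pairs(two_group_trajectory, cutoff=10.0)
        assert sel.pairs == sorted(sel.pairs)


class TestPairCorrelation:
    def test_series_against_itself_and_negation(self):
        traj = _traj_from_columns(6, {(1, 3): [1.0, -2.0, 3.5, 0.0],
                                      (2, 4): [-1.0, 2.0, -3.5, 0.0]})
        sel = PairSelection([(1, 3), (2, 4)], 0.1, {})
        C = pair_correlation(traj, sel)
        assert C.values[0, 0] == pytest.approx(1.0)
        assert C.values[0, 1] == pytest.approx(-1.0)

    def test_three_frame_hand_example(self):
        traj = _traj_from_columns(6, {(1, 3): [1, 2, 3], (2, 4): [1, 3, 5],
                                      (3, 5): [2, 2, 2]})
        sel = PairSelection([(1, 3), (2, 4), (3, 5)], 0.1, {})
        with pytest.warns(UserWarning, match="zero-variance"):
            C = pair_correlation(traj, sel)
        assert C.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C.values[0, 2] == 0.0
        assert C.zero_variance == [(3, 5)]

    def test_fewer_than_two_frames_rejected(self):
        traj = _traj_from_columns(6, {(1, 3): [1.0]})
        with pytest.raises(ValueError):
            pair_correlation(traj, PairSelection([(1, 3)], 0.1, {}))

    def test_empty_selection_rejected(self, two_group_trajectory):
        with pytest.raises(ValueError):
            pair_correlation(two_group_trajectory, PairSelection([], 1.0, {}))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_pearson_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(30, 2))
        traj = _traj_from_columns(6, {(1, 3): x[:, 0], (2, 4): x[:, 1]})
        C = pair_correlation(traj, PairSelection([(1, 3), (2, 4)], 0.1, {}))
        assert C.values[0, 1] == pytest.approx(
            pearson_oracle(x[:, 0], x[:, 1]), abs=1e-12)


def _projection_oracle(C, sel_pairs, n):
    """Quadruple loop over pair-of-pairs with the membership constraint."""
    M = np.zeros((n, n))
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i == j:
                continue
            total = 0.0
            for m, pm in enumerate(sel_pairs):
                for q in range(m + 1, len(sel_pairs)):
                    pn = sel_pairs[q]
                    if (i in pm and j in pn) or (i in pn and j in pm):
                        total += abs(C[m, q])
            M[i - 1, j - 1] = total
    return M


class TestProjection:
    def test_single_term_absolute_value(self):
        sel = PairSelection([(1, 3), (2, 4)], 0.1, {})
        C = np.array([[1.0, -0.6], [-0.6, 1.0]])
        from icnet.correlation import PairCorrelationMatrix
        M = project_to_residues(PairCorrelationMatrix(sel.pairs, C), sel, 5,
                                "raw-sum")
        assert M.values[0, 1] == pytest.approx(0.6)   # residues 1 and 2
        assert M.values[2, 3] == pytest.approx(0.6)   # residues 3 and 4

    def test_unselected_residue_row_is_zero(self, two_group_trajectory):
        M = residue_correlation_matrix(two_group_trajectory, cutoff=10.0)
        # residue 2 is in no selected pair
        assert not M.values[1].any()

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(42)
        n = 6
        pairs = pair_universe(n)
        values = rng.normal(size=(60, len(pairs))) * 3
        traj = EnergyTrajectory(n, values, pairs=pairs)
        sel = select_pairs(traj, cutoff=0.001)
        C = pair_correlation(traj, sel)
        M = project_to_residues(C, sel, n, "raw-sum")
        oracle = _projection_oracle(C.values, sel.pairs, n)
        np.testing.assert_allclose(M.values, oracle, atol=1e-12)

    def test_count_normalized_bounded_by_one(self, two_group_trajectory):
        M = residue_correlation_matrix(two_group_trajectory, cutoff=10.0,
                                       mode="count-normalized")
        assert M.values.max() <= 1.0 + 1e-12

    def test_max_normalized_in_unit_interval(self, two_group_trajectory):
        M = residue_correlation_matrix(two_group_trajectory, cutoff=10.0,
                                       mode="max-normalized")
        assert 0.0 <= M.values.min() and M.values.max() == pytest.approx(1.0)

    def test_symmetry_nonnegativity_zero_diagonal(self, two_group_trajectory):
        M = residue_correlation_matrix(two_group_trajectory, cutoff=10.0)
        np.testing.assert_allclose(M.values, M.values.T, atol=1e-12)
        assert (M.values >= 0).all()
        assert not np.diag(M.values).any()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        n = 7
        pairs = pair_universe(n)
        values = rng.normal(size=(80, len(pairs))) * 3
        traj = EnergyTrajectory(n, values, pairs=pairs)
        M = residue_correlation_matrix(traj, cutoff=0.001).values
        # relabel residues by reversal: residue r -> n + 1 - r
        perm = np.arange(n)[::-1]
        remapped = np.zeros_like(values)
        for k, (i, j) in enumerate(pairs):
            ri, rj = sorted((n + 1 - i, n + 1 - j))
            remapped[:, pairs.index((ri, rj))] = values[:, k]
        M_perm = residue_correlation_matrix(
            EnergyTrajectory(n, remapped, pairs=pairs), cutoff=0.001).values
        np.testing.assert_allclose(M_perm, M[np.ix_(perm, perm)], atol=1e-10)

    def test_noiseless_single_factor_block_structure(self):
        net = PlantedNetwork(
            10, ({(1, 3): 2.0, (5, 7): 2.0}, {(2, 4): 2.0, (6, 8): 2.0}),
            noise_sd={(1, 3): 0.0, (5, 7): 0.0, (2, 4): 0.0, (6, 8): 0.0})
        traj = generate_energy_trajectory(net, 500, seed=9)
        M = residue_correlation_matrix(traj, cutoff=10.0).values
        # within-group couplings all equal the single |C| = 1 term
        for i, j in [(1, 5), (1, 7), (3, 5), (3, 7)]:
            assert M[i - 1, j - 1] == pytest.approx(1.0, abs=1e-9)
        # cross-group couplings vanish (independent factors, no noise)
        for i, j in [(1, 2), (1, 6), (3, 4), (5, 8)]:
            assert abs(M[i - 1, j - 1]) < 0.2

    def test_offgroup_entries_shrink_with_more_frames(self):
        net = PlantedNetwork(8, ({(1, 3): 2.0}, {(4, 6): 2.0}))
        cross = []
        for n_frames in (100, 6400):
            vals = []
            for seed in range(3):
                traj = generate_energy_trajectory(net, n_frames, seed=seed)
                M = residue_correlation_matrix(traj, cutoff=10.0).values
                vals.append(M[0, 3])  # residues 1 and 4, different groups
            cross.append(np.mean(vals))
        assert cross[1] < cross[0]


class TestCorrelationFactor:
    def test_singleton_group_equals_matrix_entry(self):
        M = ResidueCorrelationMatrix(np.array([[0, .2, .3],
                                               [.2, 0, .5],
                                               [.3, .5, 0]]), "raw-sum")
        assert correlation_factor(M, 1, [3]) == pytest.approx(0.3)

    def test_zero_matrix_gives_zero(self):
        M = ResidueCorrelationMatrix(np.zeros((4, 4)), "raw-sum")
        assert correlation_factor(M, 2, [1, 3, 4]) == 0.0

    def test_hand_row_sum_excludes_self(self):
        M = ResidueCorrelationMatrix(np.array([[0, .2, .3, .4],
                                               [.2, 0, .1, 0],
                                               [.3, .1, 0, .6],
                                               [.4, 0, .6, 0]]), "raw-sum")
        assert correlation_factor(M, 1, [1, 2, 3, 4]) == pytest.approx(0.9)

    def test_empty_group_rejected(self):
        M = ResidueCorrelationMatrix(np.zeros((3, 3)), "raw-sum")
        with pytest.raises(ValueError):
            correlation_factor(M, 1, [])


class TestDistanceShellProfile:
    def test_single_infinite_shell_equals_correlation_factor(self):
        complex = generate_toy_complex(10, n_guide=2, seed=5)
        rng = np.random.default_rng(1)
        v = np.abs(rng.normal(size=(12, 12)))
        v = np.triu(v, 1) + np.triu(v, 1).T
        M = ResidueCorrelationMatrix(v, "raw-sum")
        protein = list(range(1, 11))
        df = distance_shell_profile(M, complex, [11, 12], protein,
                                    [0.0, np.inf], reference_residue=11)
        f11 = df[df.probe == 11].F.iloc[0]
        assert f11 == pytest.approx(correlation_factor(M, 11, protein))

    def test_reference_normalizes_to_one(self):
        complex = generate_toy_complex(10, n_guide=2, seed=5)
        rng = np.random.default_rng(2)
        v = np.abs(rng.normal(size=(12, 12))) + 0.5
        v = np.triu(v, 1) + np.triu(v, 1).T
        M = ResidueCorrelationMatrix(v, "raw-sum")
        df = distance_shell_profile(M, complex, [11, 12], list(range(1, 11)),
                                    [0.0, 20.0, np.inf], reference_residue=11)
        ref = df[df.probe == 11]
        assert all(row.F_norm == pytest.approx(1.0)
                   for _, row in ref.iterrows() if row.F > 0)

    def test_far_planted_coupling_lands_in_far_shells(self):
        complex = generate_toy_complex(50, n_guide=1, seed=7)
        probe = 51
        from icnet.correlation import min_heavy_atom_distances
        protein = list(range(1, 51))
        d = min_heavy_atom_distances(complex, probe, protein)
        candidates = [r for r, dist in zip(protein, d)
                      if dist >= 30.0 and r <= 49]
        far = []
        for r in candidates:         # keep a mutually non-adjacent subset
            if not far or r - far[-1] > 1:
                far.append(r)
            if len(far) == 4:
                break
        assert len(far) >= 2
        pairs = {(min(probe, r), max(probe, r)): 2.0 for r in far}
        pairs.update({(far[0], far[1]): 2.0})
        net = PlantedNetwork(51, (pairs,), background_noise_sd=0.2)
        traj = generate_energy_trajectory(net, 2000, seed=3)
        M = residue_correlation_matrix(traj, cutoff=10.0)
        df = distance_shell_profile(M, complex, [probe], protein,
                                    [0.0, 30.0, np.inf],
                                    reference_residue=probe)
        near = df[(df.probe == probe) & (df.shell_lo == 0.0)].F.iloc[0]
        far_f = df[(df.probe == probe) & (df.shell_lo == 30.0)].F.iloc[0]
        assert far_f >= 0.9 * (near + far_f)

    def test_errors(self):
        complex = generate_toy_complex(6, seed=0)
        M = ResidueCorrelationMatrix(np.zeros((6, 6)), "raw-sum")
        with pytest.raises(ValueError, match="reference"):
            distance_shell_profile(M, complex, [1], [2, 3], [0, 10], 5)
        with pytest.raises(ValueError, match="shell"):
            distance_shell_profile(M, complex, [1], [2, 3], [0.0], 1)
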