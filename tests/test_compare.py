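"""Similarity score, bootstrap null, difference matrices and sensors."""

import itertools

import numpy as np
import pytest

from icnet.compare import (bootstrap_null, difference_matrix,
                           identify_sensors, n_distinct_correlations,
                           rms_aggregate, similarity_score, zscore_normalize)
from icnet.correlation import ResidueCorrelationMatrix


def _sym(n, fill, seed=None):
    """Symmetric zero-diagonal matrix from an upper-triangle value list."""
    v = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    v[iu] = fill
    v[(iu[1], iu[0])] = fill
    return v


def test_distinct_offdiagonal_count():
    assert n_distinct_correlations(685) == 234270
    assert n_distinct_correlations(3) == 3


class TestZscoreNormalize:
    def test_off_diagonal_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        v = _sym(8, rng.exponential(size=28))
        z = zscore_normalize(v).values
        ut = z[np.triu_indices(8, k=1)]
        assert ut.mean() == pytest.approx(0.0, abs=1e-12)
        assert ut.std() == pytest.approx(1.0, abs=1e-12)
        assert not np.diag(z).any()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        v = _sym(6, rng.normal(size=15))
        once = zscore_normalize(v).values
        twice = zscore_normalize(zscore_normalize(v)).values
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_hand_three_by_three(self):
        # off-diagonal values {1, 2, 3}: mean 2, population SD sqrt(2/3)
        v = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        z = zscore_normalize(v).values
        sd = np.sqrt(2.0 / 3.0)
        assert z[0, 1] == pytest.approx((1 - 2) / sd)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert z[1, 2] == pytest.approx((3 - 2) / sd)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(_sym(5, 2.0))


class TestSimilarityScore:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(3)
        v = _sym(10, rng.normal(size=45))
        r = similarity_score(v, v)
        assert r.score == 1.0
        assert r.threshold_a == r.threshold_b

    def test_disjoint_top_sets_score_zero(self):
        n = 8
        iu = np.triu_indices(n, k=1)
        base = np.linspace(0.0, 0.5, len(iu[0]))
        a_fill = base.copy()
        b_fill = base.copy()
        a_fill[0] = 10.0   # A's unique top cell
        b_fill[-1] = 10.0  # B's unique top cell
        r = similarity_score(_sym(n, a_fill), _sym(n, b_fill),
                             quantile=0.97)
        assert r.score == 0.0

    def test_hand_enumerated_six_by_six(self):
        # 15 distinct upper-triangle values per matrix; quantile 0.83 puts
        # the threshold between the 3rd and 4th largest, so each top set has
        # exactly 3 cells; the sets share 2 cells, union 4 -> S = 0.5
        low = np.linspace(0.1, 1.2, 12)
        a_fill = np.concatenate([[9.0, 8.0, 7.0], low])        # top: cells 0,1,2
        b_fill = np.concatenate([[9.0, 8.0], low, [7.0]])      # top: cells 0,1,14
        A, B = _sym(6, a_fill), _sym(6, b_fill)
        r = similarity_score(A, B, quantile=0.83)
        assert r.n_both == 2 and r.n_either == 4
        assert r.score == pytest.approx(0.5)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        A = _sym(9, rng.normal(size=36))
        B = _sym(9, rng.normal(size=36))
        assert similarity_score(A, B).score == similarity_score(B, A).score

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_score(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_constant_matrices_flagged_undefined(self):
        r = similarity_score(_sym(4, 1.0), _sym(4, 1.0))
        assert not r.defined and np.isnan(r.score)


def _exhaustive_null_mean(A, B, quantile):
    """Average S over all N^N x N^N symmetric profile resamplings."""
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)

    def _tops(v):
        tops = []
        for r in itertools.product(range(n), repeat=n):
            res = v[np.ix_(r, r)]
            ut = res[iu]
            t = np.quantile(ut, quantile)
            tops.append(ut > t)
        return np.asarray(tops)

    ta, tb = _tops(A), _tops(B)
    both = (ta[:, None, :] & tb[None, :, :]).sum(axis=-1).astype(float)
    either = (ta[:, None, :] | tb[None, :, :]).sum(axis=-1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(either > 0, both / np.maximum(either, 1), np.nan)
    return np.nanmean(scores)


class TestBootstrapNull:
    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_null(np.zeros((4, 4)), np.zeros((4, 4)), replicates=0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        A = _sym(6, rng.normal(size=15))
        B = _sym(6, rng.normal(size=15))
        d1 = bootstrap_null(A, B, replicates=50, seed=42)
        d2 = bootstrap_null(A, B, replicates=50, seed=42)
        np.testing.assert_array_equal(d1.scores, d2.scores)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        A = _sym(4, rng.normal(size=6))
        B = _sym(4, rng.normal(size=6))
        quantile = 0.7
        exact = _exhaustive_null_mean(A, B, quantile)
        null = bootstrap_null(A, B, replicates=4000, quantile=quantile,
                              seed=7)
        se = null.sd / np.sqrt(null.replicates)
        assert abs(null.mean - exact) <= 3 * se

    def test_independent_axes_mode_runs(self):
        rng = np.random.default_rng(8)
        A = _sym(5, rng.normal(size=10))
        null = bootstrap_null(A, A, replicates=20, seed=1,
                              resample="independent-axes")
        assert len(null.scores) == 20


class TestDifferenceAndAggregate:
    def _z(self, seed, n=5):
        rng = np.random.default_rng(seed)
        return zscore_normalize(_sym(n, rng.normal(size=n * (n - 1) // 2)))

    def test_self_difference_is_zero(self):
        z = self._z(0)
        assert not difference_matrix(z, z).any()

    def test_antisymmetry(self):
        a, b = self._z(1), self._z(2)
        np.testing.assert_allclose(difference_matrix(a, b),
                                   -difference_matrix(b, a), atol=1e-14)

    def test_hand_three_by_three(self):
        a = zscore_normalize(np.array([[0., 1, 2], [1, 0, 3], [2, 3, 0]]))
        b = zscore_normalize(np.array([[0., 3, 2], [3, 0, 1], [2, 1, 0]]))
        d = difference_matrix(a, b)
        np.testing.assert_allclose(d, a.values - b.values, atol=1e-14)

    def test_unnormalized_inputs_rejected(self):
        raw = ResidueCorrelationMatrix(np.zeros((3, 3)), "raw-sum")
        with pytest.raises(ValueError, match="z-normalized"):
            difference_matrix(raw, raw)

    def test_rms_single_matrix_is_absolute_value(self):
        d = np.array([[0.0, -2.5], [-2.5, 0.0]])
        np.testing.assert_allclose(rms_aggregate([d]), np.abs(d))

    def test_rms_hand_value(self):
        d1 = np.full((2, 2), 3.0)
        d2 = np.full((2, 2), -4.0)
        np.testing.assert_allclose(rms_aggregate([d1, d2]),
                                   np.full((2, 2), np.sqrt(12.5)))

    def test_rms_zero_and_empty(self):
        assert not rms_aggregate([np.zeros((3, 3))]).any()
        with pytest.raises(ValueError):
            rms_aggregate([])


class TestIdentifySensors:
    def test_uniform_columns_give_no_sensors(self):
        d = np.ones((6, 6)) - np.eye(6)
        with pytest.warns(UserWarning, match="constant"):
            report = identify_sensors(d)
        assert report.sensors == []

    def test_single_inflated_column_flagged(self):
        rng = np.random.default_rng(9)
        n = 100
        base = np.abs(rng.normal(size=(n, n))) * 0.1
        d = np.triu(base, 1)
        d = d + d.T
        d[:, 42] = d[42, :] = 5.0
        d[42, 42] = 0.0
        report = identify_sensors(d, k=2.0)
        assert report.sensors == [43]  # 1-based

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            identify_sensors(np.zeros((3, 3)), k=0.0)
        with pytest.raises(ValueError):
            identify_sensors(-np.ones((3, 3)))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        n = 30
        base = np.abs(rng.normal(size=(n, n)))
        d = np.triu(base, 1)
        d = d + d.T
        d[:, 5] = d[5, :] = 20.0
        d[5, 5] = 0.0
        report = identify_sensors(d)
        perm = rng.permutation(n)
        report_p = identify_sensors(d[np.ix_(perm, perm)])
        mapped = sorted(int(np.flatnonzero(perm == s - 1)[0]) + 1
                        for s in report.sensors)
        assert report_p.sensors == mapped
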