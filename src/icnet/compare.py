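"""Comparing residue correlation matrices across conditions.

Two matched analyses of the same system (e.g. one with a fully matched
guide-target duplex and one with a single mismatch) produce residue
correlation matrices A and B.  Their *similarity score*

    S = #{(i,j): A_ij > t_A and B_ij > t_B} / #{(i,j): A_ij > t_A or B_ij > t_B}

counts, over upper-triangle cells, how many of the strong correlations
(those strictly above the per-matrix quantile threshold, default the
92.6th percentile, i.e. the top 7.4%) are preserved between the two
matrices.  Significance is assessed against a bootstrap null built by
resampling residue profiles: one index vector per matrix, drawn with
replacement and applied to rows and columns alike, preserves symmetry
while scrambling which residue owns which correlation profile.

*Sensor residues* are found from z-normalized matrices: per perturbation
the signed difference dM = M_perturbed - M_reference is formed, the cell-wise
root mean square across perturbations aggregates them, the columns of the
aggregate are summed into an involvement vector v, and residues with
|v_i - mean(v)| > k * SD(v) (default k = 2) are the sensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .correlation import ResidueCorrelationMatrix


def n_distinct_correlations(n_residues: int) -> int:
    """Number of distinct off-diagonal cells of a symmetric N x N matrix."""
    return n_residues * (n_residues - 1) // 2


def _values(M) -> np.ndarray:
    if isinstance(M, ResidueCorrelationMatrix):
        return M.values
    v = np.asarray(M, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("expected a square matrix")
    return v


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def zscore_normalize(M) -> ResidueCorrelationMatrix:
    """Standardize off-diagonal cells to units of SD from the element mean.

    Mean and SD are taken over the distinct off-diagonal values (upper
    triangle); the transformed matrix stays symmetric with zero diagonal.
    Idempotent up to floating point.  Raises on a constant matrix.
    """
    v = _values(M).copy()
    ut = _upper(v)
    if ut.size < 2 or np.unique(ut).size < 2:
        raise ValueError("matrix has < 2 distinct off-diagonal values")
    mean, sd = ut.mean(), ut.std()
    iu = np.triu_indices(v.shape[0], k=1)
    z = (v[iu] - mean) / sd
    out = np.zeros_like(v)
    out[iu] = z
    out[(iu[1], iu[0])] = z
    return ResidueCorrelationMatrix(out, "zscore")


@dataclass
class SimilarityResult:
    """Similarity score between two matrices' strong-correlation sets."""

    score: float
    threshold_a: float
    threshold_b: float
    n_both: int
    n_either: int
    quantile: float
    defined: bool = True


def similarity_score(A, B, quantile: float = 0.926) -> SimilarityResult:
    """Fraction of shared top-quantile cells between two matrices.

    Thresholds are the per-matrix ``quantile`` of the distinct off-diagonal
    (upper-triangle) values, with linear interpolation; membership in the
    strong set is strict (>).  If no cell exceeds either threshold the
    score is undefined and flagged (score NaN).
    """
    va, vb = _values(A), _values(B)
    if va.shape != vb.shape:
        raise ValueError("matrices must have the same shape")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    ua, ub = _upper(va), _upper(vb)
    t_a = float(np.quantile(ua, quantile))
    t_b = float(np.quantile(ub, quantile))
    above_a = ua > t_a
    above_b = ub > t_b
    n_both = int(np.sum(above_a & above_b))
    n_either = int(np.sum(above_a | above_b))
    if n_either == 0:
        return SimilarityResult(float("nan"), t_a, t_b, 0, 0, quantile,
                                defined=False)
    return SimilarityResult(n_both / n_either, t_a, t_b, n_both, n_either,
                            quantile)


@dataclass
class NullDistribution:
    """Bootstrap null of the similarity score under profile resampling."""

    scores: np.ndarray
    replicates: int
    quantile: float
    seed: int | None
    resample: str

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.scores))


def _resample_symmetric(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = rng.integers(v.shape[0], size=v.shape[0])
    return v[np.ix_(r, r)]


def _resample_independent_axes(v: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    r = rng.integers(v.shape[0], size=v.shape[0])
    c = rng.integers(v.shape[0], size=v.shape[0])
    return v[np.ix_(r, c)]


def bootstrap_null(A, B, replicates: int = 1000, quantile: float = 0.926,
                   seed: int | None = None,
                   resample: str = "symmetric") -> NullDistribution:
    """Null distribution of S between row/column-resampled matrices.

    Per replicate an index vector of length N is drawn with replacement
    independently for A and for B; in the default ``symmetric`` mode the
    same vector is applied to rows and columns of its matrix (randomly
    reassigning whole residue correlation profiles while preserving
    symmetry).  ``independent-axes`` draws separate row and column vectors
    per matrix instead.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    va, vb = _values(A), _values(B)
    if va.shape != vb.shape:
        raise ValueError("matrices must have the same shape")
    if va.shape[0] < 2:
        raise ValueError("need at least 2 residues")
    try:
        resampler = {"symmetric": _resample_symmetric,
                     "independent-axes": _resample_independent_axes}[resample]
    except KeyError:
        raise ValueError(f"unknown resample mode {resample!r}") from None
    rng = np.random.default_rng(seed)
    scores = np.empty(replicates)
    for k in range(replicates):
        a_prime = resampler(va, rng)
        b_prime = resampler(vb, rng)
        scores[k] = similarity_score(a_prime, b_prime, quantile).score
    return NullDistribution(scores, replicates, quantile, seed, resample)


def difference_matrix(M_perturbed, M_reference) -> np.ndarray:
    """Signed element-wise difference of two z-normalized matrices."""
    for M in (M_perturbed, M_reference):
        if not (isinstance(M, ResidueCorrelationMatrix)
                and M.mode == "zscore"):
            raise ValueError("difference_matrix expects z-normalized "
                             "ResidueCorrelationMatrix inputs")
    a, b = M_perturbed.values, M_reference.values
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    return a - b


def rms_aggregate(deltas) -> np.ndarray:
    """Cell-wise root mean square across a list of difference matrices."""
    deltas = [np.asarray(d, dtype=float) for d in deltas]
    if not deltas:
        raise ValueError("empty list of difference matrices")
    shape = deltas[0].shape
    if any(d.shape != shape for d in deltas):
        raise ValueError("difference matrices must share a shape")
    stacked = np.stack(deltas)
    return np.sqrt(np.mean(stacked * stacked, axis=0))


@dataclass
class SensorReport:
    """Residues whose network coupling shifts most under perturbation."""

    delta_rms: np.ndarray
    column_sums: np.ndarray
    mean: float
    sd: float
    sensors: list[int]          # 1-based residue indices
    sd_multiplier: float


def identify_sensors(delta_rms: np.ndarray, k: float = 2.0) -> SensorReport:
    """Flag residues whose column involvement deviates > k SD from the mean.

    v_i is the column sum of the RMS difference matrix; sensors are the
    residues with |v_i - mean(v)| > k * SD(v).  A constant v (SD = 0)
    yields an empty sensor set with a warning.
    """
    if k <= 0:
        raise ValueError("SD multiplier k must be > 0")
    d = np.asarray(delta_rms, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("delta_rms must be square")
    if np.any(d < 0):
        raise ValueError("delta_rms entries must be nonnegative")
    v = d.sum(axis=0)
    mean, sd = float(v.mean()), float(v.std())
    if sd == 0.0:
        warnings.warn("constant involvement vector; no sensors identified",
                      stacklevel=2)
        return SensorReport(d, v, mean, sd, [], k)
    sensors = [int(i) + 1 for i in np.flatnonzero(np.abs(v - mean) > k * sd)]
    return SensorReport(d, v, mean, sd, sensors, k)
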