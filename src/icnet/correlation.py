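"""From energy trajectories to residue correlation matrices.

The analysis proceeds in three steps:

1. *Pair selection*: keep the residue pairs whose time-averaged interaction
   energy has magnitude at or above a cutoff (default 10 kcal/mol).  The
   absolute value matters because nonbonded interaction energies are
   predominantly negative (attractive).
2. *Pair correlation matrix* C: the Pearson correlation, over trajectory
   frames, between the energy time series of every two selected pairs.
3. *Residue correlation matrix* M: the projection of C back onto residues.
   M_ij aggregates |C_mn| over all unordered combinations of two distinct
   selected pairs m, n with residue i in one and residue j in the other.
   Anticorrelation counts as coupling (absolute value), so M is nonnegative
   and, once max-normalized, lives on the 0 (uncorrelated) to 1 (fully
   correlated) scale used for display.

The *correlation factor* F(i, G) = sum_{j in G, j != i} M_ij measures how
strongly residue i couples into a residue group G, optionally resolved into
distance shells around i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energy import EnergyTrajectory

Pair = tuple[int, int]

NORMALIZATION_MODES = ("raw-sum", "count-normalized", "max-normalized")


@dataclass
class PairSelection:
    """Residue pairs retained by the mean-energy cutoff, in (i, j) order."""

    pairs: list[Pair]
    cutoff: float
    mean_energy: dict[Pair, float]

    def __len__(self) -> int:
        return len(self.pairs)


def select_pairs(traj: EnergyTrajectory, cutoff: float = 10.0) -> PairSelection:
    """Select pairs with |time-mean total energy| >= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    means = traj.mean_energy()
    keep = np.abs(means) >= cutoff
    pairs = [p for p, k in zip(traj.pairs, keep) if k]
    mean_map = {p: float(m) for p, m, k in zip(traj.pairs, means, keep) if k}
    return PairSelection(pairs, float(cutoff), mean_map)


@dataclass
class PairCorrelationMatrix:
    """Pearson correlations between selected pair energy series.

    ``values[p, q]`` is the correlation of the time series of selected pair
    p with that of q; unit diagonal; zero-variance series are flagged and
    their correlations set to 0.
    """

    pairs: list[Pair]
    values: np.ndarray
    zero_variance: list[Pair] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.pairs), len(self.pairs)):
            raise ValueError("correlation matrix shape mismatch")
        self.values = v


def pair_correlation(traj: EnergyTrajectory,
                     sel: PairSelection) -> PairCorrelationMatrix:
    """Correlate the energy time series of every two selected pairs."""
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames to correlate")
    if not sel.pairs:
        raise ValueError("empty pair selection")
    cols = [traj.pair_column(i, j) for i, j in sel.pairs]
    x = traj.values[:, cols]
    centered = x - x.mean(axis=0)
    sd = centered.std(axis=0)
    zero_var = sd == 0.0
    safe_sd = np.where(zero_var, 1.0, sd)
    z = centered / safe_sd
    corr = (z.T @ z) / x.shape[0]
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    flagged = [p for p, zv in zip(sel.pairs, zero_var) if zv]
    if flagged:
        warnings.warn(f"{len(flagged)} zero-variance energy series; "
                      "their correlations are set to 0", stacklevel=2)
    return PairCorrelationMatrix(list(sel.pairs), corr, flagged)


@dataclass
class ResidueCorrelationMatrix:
    """N x N symmetric nonnegative coupling matrix with zero diagonal.

    ``mode`` records the aggregation applied in the projection: "raw-sum",
    "count-normalized", "max-normalized", or "zscore" after standardization
    (see :func:`icnet.compare.zscore_normalize`).
    """

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("residue correlation matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("residue correlation matrix must be symmetric")
        self.values = v

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def project_to_residues(C: PairCorrelationMatrix, sel: PairSelection,
                        n_residues: int,
                        mode: str = "raw-sum") -> ResidueCorrelationMatrix:
    """Project the pair correlation matrix onto residues.

    M_ij = aggregate over unordered {m, n} of distinct selected pairs with
    i in m and j in n of |C_mn|; the diagonal is 0.  Modes: "raw-sum";
    "count-normalized" divides each cell by its number of contributing
    terms (0 if none); "max-normalized" rescales the raw sum so the largest
    off-diagonal entry is 1.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    idx = np.asarray(sel.pairs, dtype=int)
    if len(idx) and idx.max() > n_residues:
        raise ValueError("selection refers to residues beyond n_residues")
    # incidence matrix: B[r, p] = 1 iff residue r+1 belongs to selected pair p
    B = np.zeros((n_residues, len(sel.pairs)))
    if len(idx):
        cols = np.arange(len(sel.pairs))
        B[idx[:, 0] - 1, cols] = 1.0
        B[idx[:, 1] - 1, cols] = 1.0
    absC = np.abs(C.values)
    # Ordered double sum over (m, n) minus the m = n terms equals the
    # unordered sum with the membership constraint: for i != j and m != n at
    # most one of the two orientations (i in m, j in n) can hold, because two
    # distinct pairs share at most one residue.
    co_membership = B @ B.T          # pairs containing both i and j
    raw = B @ absC @ B.T - co_membership
    np.fill_diagonal(raw, 0.0)
    raw = np.maximum(raw, 0.0)      # clip -0.0 / rounding dust
    if mode == "raw-sum":
        values = raw
    elif mode == "count-normalized":
        degree = B.sum(axis=1)
        counts = np.outer(degree, degree) - co_membership
        np.fill_diagonal(counts, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(counts > 0, raw / np.maximum(counts, 1), 0.0)
    else:  # max-normalized
        peak = raw.max()
        values = raw / peak if peak > 0 else raw
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return ResidueCorrelationMatrix(values, mode)


def residue_correlation_matrix(traj: EnergyTrajectory, cutoff: float = 10.0,
                               mode: str = "raw-sum") -> ResidueCorrelationMatrix:
    """Convenience composition: select -> correlate -> project."""
    sel = select_pairs(traj, cutoff)
    C = pair_correlation(traj, sel)
    return project_to_residues(C, sel, traj.n_residues, mode)


def correlation_factor(M: ResidueCorrelationMatrix, i: int,
                       G) -> float:
    """F(i, G) = sum of M_ij over j in G, j != i (1-based indices)."""
    G = [int(j) for j in G]
    if not G:
        raise ValueError("empty residue group G")
    if min(G) < 1 or max(G) > M.n_residues or not 1 <= i <= M.n_residues:
        raise IndexError("residue index out of range")
    js = [j - 1 for j in G if j != i]
    return float(M.values[i - 1, js].sum())


def min_heavy_atom_distances(complex, i: int, targets) -> np.ndarray:
    """Minimum heavy-atom distance from residue i to each target residue."""
    def _coords(res):
        return np.asarray([a.coord for a in res.atoms
                           if not a.element.startswith("H")])
    ci = _coords(complex.residues[i - 1])
    out = np.empty(len(targets))
    for k, j in enumerate(targets):
        out[k] = cdist(ci, _coords(complex.residues[j - 1])).min()
    return out


def distance_shell_profile(M: ResidueCorrelationMatrix, complex,
                           probe_residues, G, shells,
                           reference_residue: int) -> pd.DataFrame:
    """Correlation factor per probe residue and distance shell.

    ``shells`` is an ordered sequence of boundaries b0 < b1 < ... defining
    half-open shells [b_k, b_{k+1}); the factor of each probe is computed
    over the members of G whose minimum heavy-atom distance to the probe
    falls in the shell.  ``F_norm`` divides by the reference residue's value
    in the same shell (NaN where that value is 0).

    Returns a DataFrame with columns probe, shell_lo, shell_hi, F, F_norm.
    """
    shells = [float(b) for b in shells]
    if len(shells) < 2:
        raise ValueError("need at least two shell boundaries")
    if any(b1 <= b0 for b0, b1 in zip(shells, shells[1:])):
        raise ValueError("shell boundaries must be strictly increasing")
    probes = [int(p) for p in probe_residues]
    if reference_residue not in probes:
        raise ValueError("reference residue must be among the probes")
    G = [int(j) for j in G]
    if not G:
        raise ValueError("empty residue group G")
    n_shells = len(shells) - 1
    raw = np.zeros((len(probes), n_shells))
    for pi, probe in enumerate(probes):
        dists = min_heavy_atom_distances(complex, probe, G)
        for si in range(n_shells):
            members = [j for j, d in zip(G, dists)
                       if shells[si] <= d < shells[si + 1] and j != probe]
            raw[pi, si] = (correlation_factor(M, probe, members)
                           if members else 0.0)
    ref_row = raw[probes.index(reference_residue)]
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(ref_row > 0, raw / np.where(ref_row > 0, ref_row, 1.0),
                        np.nan)
    records = []
    for pi, probe in enumerate(probes):
        for si in range(n_shells):
            records.append((probe, shells[si], shells[si + 1],
                            raw[pi, si], norm[pi, si]))
    return pd.DataFrame(records,
                        columns=["probe", "shell_lo", "shell_hi", "F",
                                 "F_norm"])
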