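"""Residue-residue nonbonded interaction energies.

The elementary observable of the whole pipeline is the per-frame residue
interaction energy matrix E: for every unordered residue pair (i, j) with
|i - j| > 1 (adjacent, covalently bonded neighbours are excluded wholesale),
E_ij is the sum of the pairwise Coulomb and Lennard-Jones energies over all
atoms of residue i against all atoms of residue j, in kcal/mol.  No distance
cutoff, no periodic images and a uniform dielectric of 1 are used, so the
electrostatic term dominates, as it does with real force-field energies.

A trajectory of such matrices is stored in pair-indexed form: the "pair
universe" is every (i, j) with i < j and j - i > 1, and energies are a
(n_frames, n_pairs) array.  This keeps 10^3-10^4 frame trajectories of toy
systems comfortably in memory and makes the correlation stage a plain
column-wise operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Coulomb constant in kcal*Angstrom/(mol*e^2), AMBER convention.
COULOMB_CONSTANT = 332.0636


def pair_universe(n_residues: int) -> list[tuple[int, int]]:
    """All unordered residue pairs (i, j), 1-based, with j - i > 1.

    Adjacent residues are covalently bonded and excluded from the analysis.
    The list is sorted by (i, j), which fixes the column order of every
    pair-indexed array in the package.
    """
    return [
        (i, j)
        for i in range(1, n_residues + 1)
        for j in range(i + 2, n_residues + 1)
    ]


class EnergyDecomposition(NamedTuple):
    """Nonbonded interaction energy between two atom sets, kcal/mol."""

    electrostatic: float
    lennard_jones: float
    total: float


def pair_energy(atoms_a: Sequence, atoms_b: Sequence) -> EnergyDecomposition:
    """Nonbonded interaction energy between two disjoint atom sets.

    Electrostatics: sum of k_e * q_a * q_b / r over all cross pairs with
    k_e = 332.0636 kcal*A/(mol*e^2).  Lennard-Jones:
    4*eps_ab*[(sigma_ab/r)^12 - (sigma_ab/r)^6] with Lorentz-Berthelot
    combining (sigma arithmetic mean, eps geometric mean).  No cutoff.

    Parameters
    ----------
    atoms_a, atoms_b
        Objects with ``coord`` (length-3, Angstrom), ``charge`` (e),
        ``lj_epsilon`` (kcal/mol) and ``lj_sigma`` (Angstrom) attributes.

    Raises
    ------
    ValueError
        If an atom appears in both sets, any cross distance is zero, or a
        parameter is missing / non-finite.
    """
    shared = {id(a) for a in atoms_a} & {id(b) for b in atoms_b}
    if shared:
        raise ValueError("atom sets must be disjoint")

    def _arrays(atoms):
        xyz = np.asarray([a.coord for a in atoms], dtype=float)
        q = np.asarray([a.charge for a in atoms], dtype=float)
        eps = np.asarray([a.lj_epsilon for a in atoms], dtype=float)
        sig = np.asarray([a.lj_sigma for a in atoms], dtype=float)
        if not (np.isfinite(xyz).all() and np.isfinite(q).all()
                and np.isfinite(eps).all() and np.isfinite(sig).all()):
            raise ValueError("missing or non-finite atom parameters")
        return xyz, q, eps, sig

    xyz_a, q_a, eps_a, sig_a = _arrays(atoms_a)
    xyz_b, q_b, eps_b, sig_b = _arrays(atoms_b)
    elec, lj = _block_energy(xyz_a, q_a, eps_a, sig_a, xyz_b, q_b, eps_b, sig_b)
    return EnergyDecomposition(elec, lj, elec + lj)


def _block_energy(xyz_a, q_a, eps_a, sig_a, xyz_b, q_b, eps_b, sig_b):
    diff = xyz_a[:, None, :] - xyz_b[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=-1))
    if np.any(r == 0.0):
        raise ValueError("coincident atoms (zero interatomic distance)")
    elec = COULOMB_CONSTANT * np.outer(q_a, q_b) / r
    sigma = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps = np.sqrt(np.outer(eps_a, eps_b))
    sr6 = (sigma / r) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    return float(elec.sum()), float(lj.sum())


@dataclass
class FrameEnergyMatrix:
    """Symmetric N x N interaction energy matrix for one trajectory frame.

    Entries for excluded pairs (|i - j| <= 1, including the diagonal) are
    stored as exactly 0 and are not part of the pair universe.
    """

    frame_index: int
    total: np.ndarray
    electrostatic: np.ndarray | None = None
    lennard_jones: np.ndarray | None = None

    @property
    def n_residues(self) -> int:
        return self.total.shape[0]

    def __post_init__(self) -> None:
        t = np.asarray(self.total, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("energy matrix must be square")
        if not np.isfinite(t).all():
            raise ValueError("energy matrix has non-finite entries")
        if not np.allclose(t, t.T):
            raise ValueError("energy matrix must be symmetric")
        self.total = t


def frame_energy_matrix(complex, coordinates: np.ndarray | None = None,
                        frame_index: int = 0) -> FrameEnergyMatrix:
    """Evaluate the residue interaction energy matrix of a structure.

    Parameters
    ----------
    complex
        A :class:`~icnet.synthetic.ToyComplex` (or any object with a
        ``residues`` list of atom records carrying coordinates, charges and
        LJ parameters).
    coordinates
        Optional (n_atoms, 3) array overriding the stored coordinates, in
        the order the atoms appear residue by residue; this is how per-frame
        coordinate sets are fed in.
    """
    residues = complex.residues
    n = len(residues)
    atoms = [a for r in residues for a in r.atoms]
    if coordinates is None:
        xyz = np.asarray([a.coord for a in atoms], dtype=float)
    else:
        xyz = np.asarray(coordinates, dtype=float)
        if xyz.shape != (len(atoms), 3):
            raise ValueError(
                f"coordinates must have shape {(len(atoms), 3)}, "
                f"got {xyz.shape}")
    q = np.asarray([a.charge for a in atoms], dtype=float)
    eps = np.asarray([a.lj_epsilon for a in atoms], dtype=float)
    sig = np.asarray([a.lj_sigma for a in atoms], dtype=float)
    if not (np.isfinite(xyz).all() and np.isfinite(q).all()
            and np.isfinite(eps).all() and np.isfinite(sig).all()):
        raise ValueError("missing or non-finite atom parameters")

    # residue -> slice of the flat atom arrays (atoms are stored contiguously)
    bounds = np.cumsum([0] + [len(r.atoms) for r in residues])
    total = np.zeros((n, n))
    elec_m = np.zeros((n, n))
    lj_m = np.zeros((n, n))
    for i in range(n):
        sl_i = slice(bounds[i], bounds[i + 1])
        for j in range(i + 2, n):
            sl_j = slice(bounds[j], bounds[j + 1])
            e, v = _block_energy(xyz[sl_i], q[sl_i], eps[sl_i], sig[sl_i],
                                 xyz[sl_j], q[sl_j], eps[sl_j], sig[sl_j])
            elec_m[i, j] = elec_m[j, i] = e
            lj_m[i, j] = lj_m[j, i] = v
            total[i, j] = total[j, i] = e + v
    return FrameEnergyMatrix(frame_index, total, elec_m, lj_m)


@dataclass
class EnergyTrajectory:
    """Time series of residue interaction energy matrices in pair form.

    ``values[t, p]`` is the total interaction energy of pair ``pairs[p]``
    (1-based residue indices, i < j, j - i > 1) at frame ``t``.  The pair
    axis always covers the full pair universe of ``n_residues`` in
    :func:`pair_universe` order.
    """

    n_residues: int
    values: np.ndarray
    electrostatic: np.ndarray | None = None
    lennard_jones: np.ndarray | None = None
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            self.pairs = pair_universe(self.n_residues)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.pairs):
            raise ValueError("values must be (n_frames, n_pairs)")
        if self.values.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite energies in trajectory")
        self._pair_index = {p: k for k, p in enumerate(self.pairs)}

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    def pair_column(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        try:
            return self._pair_index[(i, j)]
        except KeyError:
            raise KeyError(f"pair ({i}, {j}) not in the pair universe "
                           f"(adjacent or out of range)") from None

    def series(self, i: int, j: int) -> np.ndarray:
        """Energy time series of one residue pair, shape (n_frames,)."""
        return self.values[:, self.pair_column(i, j)]

    def mean_energy(self) -> np.ndarray:
        """Time-averaged total energy per pair, shape (n_pairs,)."""
        return self.values.mean(axis=0)

    def mean_energy_map(self) -> dict[tuple[int, int], float]:
        means = self.mean_energy()
        return {p: float(means[k]) for k, p in enumerate(self.pairs)}

    def frame_matrix(self, t: int) -> FrameEnergyMatrix:
        """Dense symmetric N x N matrix of frame ``t`` (excluded pairs 0)."""
        n = self.n_residues
        m = np.zeros((n, n))
        idx = np.asarray(self.pairs) - 1
        m[idx[:, 0], idx[:, 1]] = self.values[t]
        m[idx[:, 1], idx[:, 0]] = self.values[t]
        return FrameEnergyMatrix(t, m)


def trajectory_from_frames(frames: Iterable[FrameEnergyMatrix]) -> EnergyTrajectory:
    """Assemble an :class:`EnergyTrajectory` from dense per-frame matrices."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    n = frames[0].n_residues
    if any(f.n_residues != n for f in frames):
        raise ValueError("inconsistent residue count across frames")
    pairs = pair_universe(n)
    idx = np.asarray(pairs) - 1
    values = np.stack([f.total[idx[:, 0], idx[:, 1]] for f in frames])

    def _component(attr):
        comps = [getattr(f, attr) for f in frames]
        if any(c is None for c in comps):
            return None
        return np.stack([c[idx[:, 0], idx[:, 1]] for c in comps])

    return EnergyTrajectory(n, values, _component("electrostatic"),
                            _component("lennard_jones"), pairs)


# ---------------------------------------------------------------------------
# energy-table serialization: TSV with one row per included pair per frame
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["frame", "res_i", "res_j", "E_elec", "E_vdw", "E_total"]


def write_energy_table(traj: EnergyTrajectory, path) -> None:
    """Write a trajectory as a TSV energy table.

    Columns: frame, res_i, res_j, E_elec, E_vdw, E_total.  When the
    trajectory carries no component decomposition, E_elec is set equal to
    E_total and E_vdw to 0 so that the component-sum identity holds on file.
    A ``# n_residues:`` comment records the residue count.
    """
    nf, npair = traj.values.shape
    idx = np.asarray(traj.pairs)
    frame_col = np.repeat(np.arange(nf), npair)
    res_i = np.tile(idx[:, 0], nf)
    res_j = np.tile(idx[:, 1], nf)
    total = traj.values.ravel()
    elec = (traj.electrostatic.ravel() if traj.electrostatic is not None
            else total)
    vdw = (traj.lennard_jones.ravel() if traj.lennard_jones is not None
           else np.zeros_like(total))
    df = pd.DataFrame({
        "frame": frame_col, "res_i": res_i, "res_j": res_j,
        "E_elec": elec, "E_vdw": vdw, "E_total": total,
    })
    with open(path, "w") as fh:
        fh.write(f"# icnet energy table\n# n_residues: {traj.n_residues}\n")
        # %.17g guarantees exact float64 round-tripping
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_energy_table(path) -> EnergyTrajectory:
    """Read a TSV energy table written by :func:`write_energy_table`.

    Rejects rows violating the adjacency exclusion (|i - j| <= 1) and
    frames with inconsistent pair sets.
    """
    n_residues = None
    with open(path) as fh:
        header_lines = []
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            header_lines.append(line)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        for hl in header_lines:
            if "n_residues:" in hl:
                n_residues = int(hl.split("n_residues:")[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed energy table, missing columns {missing}")
    if df[["res_i", "res_j"]].min().min() < 1:
        raise ValueError("residue indices must be 1-based")
    ii = df["res_i"].to_numpy()
    jj = df["res_j"].to_numpy()
    if np.any(np.abs(ii - jj) <= 1):
        bad = df[np.abs(ii - jj) <= 1].iloc[0]
        raise ValueError(
            f"pair ({int(bad.res_i)}, {int(bad.res_j)}) violates the "
            "adjacency exclusion |i-j|>1")
    if n_residues is None:
        n_residues = int(max(ii.max(), jj.max()))
    pairs = pair_universe(n_residues)
    pair_idx = {p: k for k, p in enumerate(pairs)}
    frames = np.sort(df["frame"].unique())
    nf = len(frames)
    frame_ord = {f: t for t, f in enumerate(frames)}
    values = np.full((nf, len(pairs)), np.nan)
    elec = np.full((nf, len(pairs)), np.nan)
    vdw = np.full((nf, len(pairs)), np.nan)
    t_col = np.vectorize(frame_ord.__getitem__)(df["frame"].to_numpy())
    try:
        p_col = [pair_idx[(min(i, j), max(i, j))] for i, j in zip(ii, jj)]
    except KeyError as exc:
        raise ValueError(f"pair {exc} outside the pair universe") from None
    values[t_col, p_col] = df["E_total"].to_numpy()
    elec[t_col, p_col] = df["E_elec"].to_numpy()
    vdw[t_col, p_col] = df["E_vdw"].to_numpy()
    seen = ~np.isnan(values)
    if not seen.all():
        if not (seen == seen[0]).all():
            raise ValueError("inconsistent pair sets across frames")
        # a consistent subset of the universe: fill the rest with zeros
        values[~seen] = 0.0
        elec[~seen] = 0.0
        vdw[~seen] = 0.0
    return EnergyTrajectory(n_residues, values, elec, vdw, pairs)
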