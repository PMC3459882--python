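"""Synthetic toy complexes and energy trajectories with planted networks.

Real interaction-correlation studies post-process MD trajectories of a
protein/nucleic-acid complex.  This module replaces the simulation with a
generative model whose ground truth is known, so every downstream stage
(pair selection, correlation, projection, similarity, sensor detection)
can be validated against what was planted.

The energy model is a one-factor-per-group linear model evaluated
independently per frame: each factor group g owns a set of residue pairs,
a latent standard-normal scalar z_g(t) is redrawn every frame, and the
energy of a planted pair p in g is

    E_p(t) = baseline_p + loading_p * z_g(t) + noise_sd_p * eps_p(t)

with eps_p(t) ~ N(0, 1) i.i.d.  Pairs outside any group get baseline plus
noise only.  Two pairs sharing a factor with loading L and noise sd s have
population correlation L^2 / (L^2 + s^2); pairs in different groups are
uncorrelated.  Planted baselines default to -15 kcal/mol so planted pairs
pass the 10 kcal/mol selection cutoff, background pairs sit at -2 kcal/mol
and do not.

A "mismatch" style perturbation edits group membership or loadings of a
chosen pair subset, leaving every other pair's generating parameters
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .energy import EnergyTrajectory, pair_universe

Pair = tuple[int, int]

#: residue names by formal charge; the named atom carries the charge
_NEGATIVE = [("ASP", "OD1"), ("GLU", "OE1")]
_POSITIVE = [("LYS", "NZ"), ("ARG", "NH1")]
_NEUTRAL = [("ALA", "CB"), ("SER", "OG"), ("LEU", "CD1"),
            ("GLY", "CA2"), ("VAL", "CG1"), ("THR", "OG1")]
_GUIDE_NAMES = ["DA", "DT", "DG", "DC"]   # DNA guide strand
_TARGET_NAMES = ["A", "U", "G", "C"]      # RNA target strand

_CHAIN_IDS = {"protein": "A", "guide": "B", "target": "C"}
_ROLE_BY_CHAIN = {v: k for k, v in _CHAIN_IDS.items()}


@dataclass
class Atom:
    """One toy atom: name, coordinates (A), charge (e), LJ parameters."""

    name: str
    coord: np.ndarray
    charge: float
    lj_epsilon: float
    lj_sigma: float

    @property
    def element(self) -> str:
        for ch in self.name:
            if ch.isalpha():
                return ch.upper()
        return "C"


@dataclass
class Residue:
    index: int          # 1-based sequential
    name: str
    chain_role: str     # protein | guide | target
    atoms: list[Atom]

    def centroid(self) -> np.ndarray:
        return np.mean([a.coord for a in self.atoms], axis=0)


@dataclass
class ToyComplex:
    """Minimal structure: ordered residues, each with parameterized atoms."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        for k, r in enumerate(self.residues, start=1):
            if r.index != k:
                raise ValueError("residue indices must be contiguous from 1")
            for a in r.atoms:
                if not np.isfinite(np.asarray(a.coord, dtype=float)).all():
                    raise ValueError("non-finite atom coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def centroids(self) -> np.ndarray:
        return np.stack([r.centroid() for r in self.residues])

    def residues_with_role(self, role: str) -> list[int]:
        return [r.index for r in self.residues if r.chain_role == role]

    # -- serialization ----------------------------------------------------

    def write_pdb(self, path) -> None:
        """Write ATOM records; chain IDs A/B/C encode protein/guide/target."""
        st = gemmi.Structure()
        st.name = "icnet-toy"
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        for res in self.residues:
            cid = _CHAIN_IDS[res.chain_role]
            if cid not in chains:
                chains[cid] = gemmi.Chain(cid)
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.pos = gemmi.Position(*map(float, atom.coord))
                ga.element = gemmi.Element(atom.element)
                gres.add_atom(ga)
            chains[cid].add_residue(gres)
        for cid in sorted(chains):
            model.add_chain(chains[cid])
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))

    def write_parameters(self, path) -> None:
        """Sidecar TSV: atom serial, charge, LJ epsilon, LJ sigma."""
        rows = []
        serial = 0
        for res in self.residues:
            for atom in res.atoms:
                serial += 1
                rows.append((serial, atom.charge, atom.lj_epsilon,
                             atom.lj_sigma))
        pd.DataFrame(rows, columns=["serial", "charge", "lj_epsilon",
                                    "lj_sigma"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def load_complex(pdb_path, params_path) -> ToyComplex:
    """Rebuild a :class:`ToyComplex` from a PDB file and its sidecar TSV."""
    st = gemmi.read_structure(str(pdb_path))
    params = pd.read_csv(params_path, sep="\t")
    residues: list[Residue] = []
    serial = 0
    flat = []
    for model in st:
        for chain in model:
            role = _ROLE_BY_CHAIN.get(chain.name, "protein")
            for gres in chain:
                flat.append((gres.seqid.num, gres.name, role, list(gres)))
        break
    flat.sort(key=lambda t: t[0])
    for idx, name, role, gatoms in flat:
        atoms = []
        for ga in gatoms:
            row = params.iloc[serial]
            serial += 1
            atoms.append(Atom(ga.name,
                              np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                              float(row.charge), float(row.lj_epsilon),
                              float(row.lj_sigma)))
        residues.append(Residue(idx, name, role, atoms))
    return ToyComplex(residues)


def generate_toy_complex(n_protein: int, n_guide: int = 0, n_target: int = 0,
                         seed: int = 0,
                         charge_freqs: tuple[float, float, float] = (0.25, 0.5, 0.25),
                         ) -> ToyComplex:
    """Generate a toy protein/guide/target complex on a coarse helix.

    Protein residues are laid out on a self-avoiding helix (radius 7 A,
    rise 1.4 A/residue, 100 degrees/residue) so that pairwise centroid
    distances span tens of Angstroms; guide and target strands run as
    straight chains alongside.  Protein charges are drawn from {-1, 0, +1}
    with ``charge_freqs`` (negative, neutral, positive); the residue name is
    chosen to match the charge so that structure-level annotation (salt
    bridges, SASA) works on the same toys.  Nucleotides carry -1 on their
    phosphate.

    Deterministic for a fixed seed.
    """
    if n_protein < 4:
        raise ValueError("n_protein must be >= 4")
    if n_guide < 0 or n_target < 0:
        raise ValueError("chain sizes must be >= 0")
    freqs = np.asarray(charge_freqs, dtype=float)
    if freqs.min() < 0 or not math.isclose(freqs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("charge_freqs must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    index = 0

    def _add_residue(name, role, center, charged_atom, charge):
        nonlocal index
        index += 1
        jitter = rng.normal(scale=0.3, size=(3, 3))
        atoms = [
            Atom("CA" if role == "protein" else "C1'",
                 center + jitter[0], 0.0, 0.10, 3.4),
            Atom("CB" if role == "protein" else "N1",
                 center + np.array([0.0, 0.0, 1.2]) + jitter[1],
                 0.0, 0.12, 3.3),
            Atom(charged_atom,
                 center + np.array([1.5, 0.0, 0.0]) + jitter[2],
                 charge, 0.15, 3.2),
        ]
        residues.append(Residue(index, name, role, atoms))

    # protein helix
    radius, rise, turn = 7.0, 1.4, math.radians(100.0)
    for k in range(n_protein):
        center = np.array([radius * math.cos(turn * k),
                           radius * math.sin(turn * k),
                           rise * k])
        charge = float(rng.choice([-1.0, 0.0, 1.0], p=freqs))
        if charge < 0:
            name, catom = _NEGATIVE[int(rng.integers(len(_NEGATIVE)))]
        elif charge > 0:
            name, catom = _POSITIVE[int(rng.integers(len(_POSITIVE)))]
        else:
            name, catom = _NEUTRAL[int(rng.integers(len(_NEUTRAL)))]
        _add_residue(name, "protein", center, catom, charge)

    # guide / target strands run parallel to the helix axis
    z0 = 0.5 * rise * max(n_protein - 1, 1) - 1.7 * max(n_guide, n_target)
    for k in range(n_guide):
        center = np.array([radius + 6.0, 0.0, z0 + 3.4 * k])
        _add_residue(_GUIDE_NAMES[k % 4], "guide", center, "P", -1.0)
    for k in range(n_target):
        center = np.array([radius + 12.0, 0.0, z0 + 3.4 * k])
        _add_residue(_TARGET_NAMES[k % 4], "target", center, "P", -1.0)
    return ToyComplex(residues)


# ---------------------------------------------------------------------------
# planted correlation networks
# ---------------------------------------------------------------------------


def _check_pair(pair: Pair, n_residues: int) -> Pair:
    i, j = int(pair[0]), int(pair[1])
    if i > j:
        i, j = j, i
    if i < 1 or j > n_residues or j - i <= 1:
        raise ValueError(f"pair ({i}, {j}) outside the pair universe "
                         f"(need 1 <= i, j <= {n_residues} and |i-j| > 1)")
    return (i, j)


@dataclass
class PlantedNetwork:
    """Generating parameters of a synthetic interaction-energy trajectory.

    ``groups`` is a tuple of factor groups, each a mapping pair -> loading
    (kcal/mol per unit latent factor).  A pair may belong to at most one
    group.  ``baselines`` / ``noise_sd`` override the defaults for
    individual pairs.
    """

    n_residues: int
    groups: tuple[dict[Pair, float], ...] = ()
    baselines: dict[Pair, float] = field(default_factory=dict)
    noise_sd: dict[Pair, float] = field(default_factory=dict)
    planted_baseline: float = -15.0
    background_baseline: float = -2.0
    background_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        seen: set[Pair] = set()
        groups = []
        for g in self.groups:
            clean = {}
            for pair, loading in g.items():
                pair = _check_pair(pair, self.n_residues)
                if pair in seen:
                    raise ValueError(f"pair {pair} planted in two groups")
                if not math.isfinite(loading):
                    raise ValueError("non-finite loading")
                seen.add(pair)
                clean[pair] = float(loading)
            groups.append(clean)
        self.groups = tuple(groups)
        self.baselines = {_check_pair(p, self.n_residues): float(v)
                          for p, v in self.baselines.items()}
        for p, v in self.noise_sd.items():
            if v < 0:
                raise ValueError("noise SD must be >= 0")
        self.noise_sd = {_check_pair(p, self.n_residues): float(v)
                         for p, v in self.noise_sd.items()}

    # -- parameter lookup --------------------------------------------------

    def group_of(self, pair: Pair) -> int | None:
        pair = _check_pair(pair, self.n_residues)
        for gi, g in enumerate(self.groups):
            if pair in g:
                return gi
        return None

    def loading(self, pair: Pair) -> float:
        gi = self.group_of(pair)
        if gi is None:
            return 0.0
        return self.groups[gi][_check_pair(pair, self.n_residues)]

    def baseline(self, pair: Pair) -> float:
        pair = _check_pair(pair, self.n_residues)
        if pair in self.baselines:
            return self.baselines[pair]
        return (self.planted_baseline if self.group_of(pair) is not None
                else self.background_baseline)

    def noise(self, pair: Pair) -> float:
        pair = _check_pair(pair, self.n_residues)
        return self.noise_sd.get(pair, self.background_noise_sd)

    def planted_pairs(self) -> list[Pair]:
        return sorted(p for g in self.groups for p in g)


@dataclass(frozen=True)
class PairPerturbation:
    """One edit to a planted pair.

    mode:
      * ``remove-from-factor`` -- detach the pair from its group (baseline
        and noise are pinned to their current values, so selection status
        is unchanged).
      * ``add-to-factor`` -- attach the pair to group ``group`` with
        ``loading``.
      * ``rescale-loading`` -- multiply the pair's loading by ``scale``.
    """

    pair: Pair
    mode: str
    group: int | None = None
    loading: float | None = None
    scale: float | None = None


@dataclass(frozen=True)
class PerturbationSpec:
    """A set of pair edits; the synthetic analogue of a guide-target mismatch."""

    perturbations: tuple[PairPerturbation, ...] = ()

    def __iter__(self):
        return iter(self.perturbations)


def apply_perturbation(net: PlantedNetwork,
                       spec: PerturbationSpec) -> PlantedNetwork:
    """Return a new network with the spec's pair edits applied.

    Pairs outside the spec keep identical generating parameters.
    """
    groups = [dict(g) for g in net.groups]
    baselines = dict(net.baselines)
    noise_sd = dict(net.noise_sd)
    for pert in spec:
        pair = _check_pair(pert.pair, net.n_residues)
        gi = None
        for k, g in enumerate(groups):
            if pair in g:
                gi = k
                break
        if pert.mode == "remove-from-factor":
            if gi is None:
                raise ValueError(f"pair {pair} is not in any factor group")
            baselines.setdefault(pair, net.baseline(pair))
            noise_sd.setdefault(pair, net.noise(pair))
            del groups[gi][pair]
        elif pert.mode == "add-to-factor":
            if pert.group is None or pert.loading is None:
                raise ValueError("add-to-factor needs group and loading")
            if gi is not None:
                del groups[gi][pair]
            if not 0 <= pert.group < len(groups):
                raise ValueError(f"unknown factor group {pert.group}")
            groups[pert.group][pair] = float(pert.loading)
        elif pert.mode == "rescale-loading":
            if pert.scale is None or not math.isfinite(pert.scale):
                raise ValueError("rescale-loading needs a finite scale")
            if gi is None:
                raise ValueError(f"pair {pair} is not in any factor group")
            groups[gi][pair] *= pert.scale
        else:
            raise ValueError(f"unknown perturbation mode {pert.mode!r}")
    return PlantedNetwork(net.n_residues, tuple(groups), baselines, noise_sd,
                          net.planted_baseline, net.background_baseline,
                          net.background_noise_sd)


def generate_energy_trajectory(net: PlantedNetwork, n_frames: int,
                               seed: int = 0) -> EnergyTrajectory:
    """Draw a synthetic energy trajectory from a planted network.

    Latent factors are redrawn independently every frame (the downstream
    analysis uses equal-time correlations only, so no autocorrelation is
    modelled).  Bit-identical for identical inputs and seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    pairs = pair_universe(net.n_residues)
    col = {p: k for k, p in enumerate(pairs)}
    baseline = np.empty(len(pairs))
    sd = np.empty(len(pairs))
    for k, p in enumerate(pairs):
        baseline[k] = net.baseline(p)
        sd[k] = net.noise(p)
    values = np.tile(baseline, (n_frames, 1))
    for g in net.groups:
        z = rng.standard_normal(n_frames)
        for pair, loading in sorted(g.items()):
            values[:, col[pair]] += loading * z
    values += sd * rng.standard_normal((n_frames, len(pairs)))
    return EnergyTrajectory(net.n_residues, values, pairs=pairs)
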