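"""Structural annotation of residues: SASA, salt bridges, sensor classes.

Sensor residues are interpreted through their structural context: a sensor
in the nucleic-acid binding groove can modulate substrate binding, a
solvent-exposed sensor (SASA > 70 A^2 by convention) is a candidate
allosteric interface for partner proteins, and the rest are buried.

SASA uses the Shrake-Rupley algorithm: each heavy atom's solvent-accessible
sphere (van der Waals radius + 1.4 A probe) is sampled with a deterministic
point set and points buried inside any neighbour's sphere are discarded.
Salt bridges are detected geometrically from acidic-oxygen / basic-nitrogen
distances (cutoff 3.2 A).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

#: Bondi-type van der Waals radii (Angstrom), by element.  Overridable per
#: call; hydrogens are ignored throughout (crystal structures lack them).
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

#: atoms carrying the formal charge of acidic / basic side chains
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_ATOMS = ("ND1", "NE2")

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class StructureResidue:
    index: int                       # author residue number
    name: str
    chain: str
    atom_names: list[str]
    coords: np.ndarray               # (n_atoms, 3)
    elements: list[str]


@dataclass
class Structure:
    """Light-weight heavy-atom structure used by the annotation routines."""

    residues: list[StructureResidue]

    @classmethod
    def from_pdb(cls, path) -> "Structure":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        residues = []
        model = st[0]
        for chain in model:
            for res in chain:
                names, xyz, elements = [], [], []
                for atom in res:
                    el = atom.element.name.upper()
                    if el == "H" or el == "D":
                        continue
                    names.append(atom.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements.append(el)
                if names:
                    residues.append(StructureResidue(
                        res.seqid.num, res.name, chain.name, names,
                        np.asarray(xyz), elements))
        return cls(residues)

    @classmethod
    def from_complex(cls, complex) -> "Structure":
        """Adapt a :class:`icnet.synthetic.ToyComplex`."""
        from .synthetic import _CHAIN_IDS
        residues = []
        for r in complex.residues:
            residues.append(StructureResidue(
                r.index, r.name, _CHAIN_IDS[r.chain_role],
                [a.name for a in r.atoms],
                np.asarray([a.coord for a in r.atoms], dtype=float),
                [a.element for a in r.atoms]))
        return cls(residues)


def _as_structure(structure) -> Structure:
    if isinstance(structure, Structure):
        return structure
    return Structure.from_complex(structure)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n_points, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(structure, probe_radius: float = 1.4, n_points: int = 960,
         radii: dict[str, float] | None = None) -> dict[int, float]:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Hydrogens are ignored; atoms of unknown element fall back to the carbon
    radius.  Returns a mapping of author residue number to SASA.
    """
    struct = _as_structure(structure)
    table = VDW_RADII if radii is None else radii
    atoms_xyz, atoms_r, atoms_res = [], [], []
    for res in struct.residues:
        for el, xyz in zip(res.elements, res.coords):
            if el.startswith("H"):
                continue
            atoms_xyz.append(xyz)
            atoms_r.append(table.get(el, table.get("C", 1.70)))
            atoms_res.append(res.index)
    if not atoms_xyz:
        raise ValueError("structure has no heavy atoms with coordinates")
    xyz = np.asarray(atoms_xyz)
    if not np.isfinite(xyz).all():
        raise ValueError("missing or non-finite coordinates")
    r_ext = np.asarray(atoms_r) + probe_radius
    sphere = fibonacci_sphere(n_points)
    out: dict[int, float] = {res.index: 0.0 for res in struct.residues}
    # neighbour lists via a single distance matrix; fine at toy scale
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    reach = r_ext[:, None] + r_ext[None, :]
    for i in range(len(xyz)):
        neighbours = np.flatnonzero((dist[i] < reach[i]) &
                                    (np.arange(len(xyz)) != i))
        pts = xyz[i] + r_ext[i] * sphere
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d = pts - xyz[j]
            accessible &= (d * d).sum(-1) > r_ext[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        out[atoms_res[i]] += frac * 4.0 * math.pi * r_ext[i] ** 2
    return out


def salt_bridges(structure, cutoff: float = 3.2,
                 include_histidine: bool = False) -> list[tuple[int, int]]:
    """Salt bridges as (i, j) residue-number pairs, i < j, O-N <= cutoff.

    Acidic partners: Asp OD1/OD2, Glu OE1/OE2, and any C-terminal
    carboxylate oxygen (OXT).  Basic partners: Lys NZ, Arg NE/NH1/NH2, plus
    His ND1/NE2 when ``include_histidine``.  Residues with amino-acid-like
    charged atom names under an unknown residue name are skipped with a
    warning.
    """
    struct = _as_structure(structure)
    acidic: list[tuple[int, np.ndarray]] = []
    basic: list[tuple[int, np.ndarray]] = []
    warned: set[str] = set()
    for res in struct.residues:
        name = res.name.upper()
        o_names = ACIDIC_ATOMS.get(name, ())
        n_names = BASIC_ATOMS.get(name, ())
        if include_histidine and name == "HIS":
            n_names = HIS_ATOMS
        if name not in _AMINO_ACIDS and name not in ACIDIC_ATOMS \
                and name not in BASIC_ATOMS:
            charged_like = set(res.atom_names) & {
                a for v in (*ACIDIC_ATOMS.values(), *BASIC_ATOMS.values())
                for a in v}
            if charged_like and name not in warned:
                warnings.warn(f"unknown residue name {name!r}; skipped in "
                              "salt-bridge detection", stacklevel=2)
                warned.add(name)
            continue
        for an, xyz in zip(res.atom_names, res.coords):
            if an in o_names or an == "OXT":
                acidic.append((res.index, xyz))
            elif an in n_names:
                basic.append((res.index, xyz))
    bridges: set[tuple[int, int]] = set()
    for ia, xa in acidic:
        for ib, xb in basic:
            if ia == ib:
                continue
            if np.linalg.norm(xa - xb) <= cutoff:
                bridges.add((min(ia, ib), max(ia, ib)))
    return sorted(bridges)


def salt_bridge_partners(structure, cutoff: float = 3.2,
                         include_histidine: bool = False) -> dict[int, list[int]]:
    """Symmetric residue -> partner-list map built from :func:`salt_bridges`."""
    partners: dict[int, list[int]] = {}
    for i, j in salt_bridges(structure, cutoff, include_histidine):
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)
    return {k: sorted(v) for k, v in partners.items()}


def annotate_structure(structure, probe_radius: float = 1.4,
                       cutoff: float = 3.2) -> pd.DataFrame:
    """Per-residue annotation table: index, type, SASA, salt-bridge partners."""
    struct = _as_structure(structure)
    areas = sasa(struct, probe_radius)
    partners = salt_bridge_partners(struct, cutoff)
    rows = []
    for res in struct.residues:
        rows.append((res.index, res.name, areas[res.index],
                     ",".join(str(p) for p in partners.get(res.index, []))))
    return pd.DataFrame(rows, columns=["residue", "type", "sasa",
                                       "salt_bridges"])


def classify_sensors(sensors, annotations: pd.DataFrame, groove,
                     sasa_threshold: float = 70.0) -> pd.DataFrame:
    """Categorize sensor residues: binding-groove / surface / buried-other.

    ``groove`` is the user-supplied binding-groove residue set (region
    definitions are structure-specific); groove membership takes precedence,
    then SASA strictly above the threshold marks a surface sensor.
    Accepts a :class:`icnet.compare.SensorReport` or an iterable of residue
    numbers.
    """
    indices = list(getattr(sensors, "sensors", sensors))
    groove = {int(g) for g in groove}
    ann = annotations.set_index("residue")
    rows = []
    for i in indices:
        if i not in ann.index:
            raise KeyError(f"sensor residue {i} has no annotation")
        rec = ann.loc[i]
        if i in groove:
            category = "binding-groove"
        elif float(rec.sasa) > sasa_threshold:
            category = "surface"
        else:
            category = "buried-other"
        rows.append((i, rec.type, float(rec.sasa), rec.salt_bridges,
                     category))
    return pd.DataFrame(rows, columns=["residue", "type", "sasa",
                                       "salt_bridges", "category"])
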