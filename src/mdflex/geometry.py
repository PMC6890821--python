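"""Interaction distances, dihedral measurement, circular averaging, and
charged-residue distance matrices."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .structure_io import SelectionError, StructureModel
from .traj_metrics import Trajectory

__all__ = [
    "AtomSpec",
    "RingSpec",
    "DistanceSeries",
    "DihedralRestraint",
    "DistanceMatrixReport",
    "atom_distance_series",
    "ring_com_distance_series",
    "measure_dihedral",
    "circular_mean_angles",
    "derive_dihedral_restraints",
    "charged_distance_matrix",
    "export_restraints",
]

# default masses for mass-weighted ring centers (heavy atoms only)
_ELEMENT_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}


@dataclass(frozen=True)
class AtomSpec:
    """Atom addressed by residue number + atom name (+ optional chain).

    A backbone amide endpoint should use the amide nitrogen 'N': donor
    hydrogens are not reliably present in crystal-derived inputs.
    """

    residue_number: int
    atom_name: str
    chain: Optional[str] = None

    def resolve(self, model: StructureModel) -> int:
        try:
            return model.find_atom(self.residue_number, self.atom_name, self.chain)
        except SelectionError as exc:
            raise SelectionError(f"cannot resolve {self}: {exc}") from exc


@dataclass(frozen=True)
class RingSpec:
    """A ring addressed by its member atom names within one residue/ligand."""

    residue_number: int
    atom_names: tuple[str, ...]
    chain: Optional[str] = None

    def __post_init__(self):
        if len(self.atom_names) < 3:
            raise ValueError("a ring needs at least 3 atoms")
        object.__setattr__(self, "atom_names", tuple(self.atom_names))

    def resolve(self, model: StructureModel) -> list[int]:
        return [AtomSpec(self.residue_number, n, self.chain).resolve(model)
                for n in self.atom_names]


@dataclass
class DistanceSeries:
    times: np.ndarray
    values: np.ndarray
    endpoint_a: object
    endpoint_b: object


@dataclass(frozen=True)
class DihedralRestraint:
    """Dihedral restraint: atom quadruple, equilibrium angle, force constant."""

    atoms: tuple[str, str, str, str]
    equilibrium_angle: float           # degrees in (-180, 180]
    force_constant: float = 4184.0     # kJ/(mol rad)
    source_structures: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.atoms)) != 4:
            raise ValueError("restraint requires four distinct atoms")
        if not -180.0 < self.equilibrium_angle <= 180.0:
            raise ValueError("equilibrium angle must lie in (-180, 180]")


@dataclass
class DistanceMatrixReport:
    residue_keys: list[str]
    matrix: np.ndarray

    def discrepancy(self, other: "DistanceMatrixReport") -> float:
        """Root-mean-square of element-wise differences between two reports."""
        if self.matrix.shape != other.matrix.shape:
            raise ValueError("reports have different dimensions")
        return float(np.sqrt(np.mean((self.matrix - other.matrix) ** 2)))


# ---------------------------------------------------------------------------

def _meta(traj: Trajectory) -> StructureModel:
    if traj.atom_meta is None:
        raise ValueError("trajectory lacks atom metadata")
    return traj.atom_meta


def atom_distance_series(traj: Trajectory, a: AtomSpec, b: AtomSpec) -> DistanceSeries:
    """Euclidean distance between two atoms, per frame."""
    meta = _meta(traj)
    ia = a.resolve(meta)
    ib = b.resolve(meta)
    if ia == ib:
        raise ValueError(f"endpoints resolve to the same atom: {a} and {b}")
    d = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    return DistanceSeries(times=traj.times, values=d, endpoint_a=a, endpoint_b=b)


def ring_com_distance_series(
    traj: Trajectory,
    ring_a: RingSpec,
    ring_b: RingSpec,
    mass_weighted: bool = False,
) -> DistanceSeries:
    """Distance between two ring centers per frame.

    Centers are unweighted geometric centroids by default; pass
    ``mass_weighted=True`` for element-mass weighting.
    """
    meta = _meta(traj)
    ia = ring_a.resolve(meta)
    ib = ring_b.resolve(meta)

    def center(idx: list[int]) -> np.ndarray:
        pts = traj.coords[:, idx]  # frames x k x 3
        if not mass_weighted:
            return pts.mean(axis=1)
        w = np.array([
            _ELEMENT_MASSES.get(meta.atoms[i].element.upper() or meta.atoms[i].name[:1], 12.0)
            for i in idx
        ])
        return (pts * w[None, :, None]).sum(axis=1) / w.sum()

    d = np.linalg.norm(center(ia) - center(ib), axis=1)
    return DistanceSeries(times=traj.times, values=d, endpoint_a=ring_a, endpoint_b=ring_b)


def dihedral_from_coords(p: np.ndarray) -> float:
    """Signed dihedral (degrees) of four points, IUPAC convention:
    cis = 0, positive counterclockwise looking from j toward k."""
    p = np.asarray(p, dtype=float)
    b0 = p[0] - p[1]
    b1 = p[2] - p[1]
    b2 = p[3] - p[2]
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("degenerate dihedral: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValueError("undefined dihedral: collinear atom triple")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def measure_dihedral(
    model: StructureModel,
    quad: Sequence[Union[AtomSpec, str]],
    residue_number: Optional[int] = None,
    alias: Optional[dict[str, str]] = None,
) -> float:
    """Dihedral angle over an atom quadruple of a structure, in degrees.

    ``quad`` may hold AtomSpecs, or bare atom-name strings together with
    ``residue_number`` (handy for ligands). ``alias`` optionally maps the
    supplied names onto the structure's chemical-component atom names.
    """
    if len(quad) != 4:
        raise ValueError("dihedral requires exactly four atoms")
    idx = []
    for q in quad:
        if isinstance(q, str):
            if residue_number is None:
                raise ValueError("bare atom names require residue_number")
            name = alias.get(q, q) if alias else q
            q = AtomSpec(residue_number, name)
        idx.append(q.resolve(model))
    if len(set(idx)) != 4:
        raise ValueError("dihedral atoms must be distinct")
    return dihedral_from_coords(model.coords[idx])


def circular_mean_angles(angles: Sequence[float]) -> float:
    """Vector (circular) mean of angles in degrees, result in (-180, 180]."""
    a = np.radians(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle list")
    s = np.mean(np.sin(a))
    c = np.mean(np.cos(a))
    if math.hypot(s, c) < 1e-9:
        raise ValueError("circular mean undefined for antipodal inputs")
    ang = math.degrees(math.atan2(s, c))
    if ang <= -180.0:
        ang += 360.0
    return ang


def derive_dihedral_restraints(
    models: dict[str, StructureModel],
    quads: Sequence[tuple[str, str, str, str]],
    ligand_residue_number: int,
    alias: Optional[dict[str, str]] = None,
    force_constant: float = 4184.0,
) -> list[DihedralRestraint]:
    """Equilibrium dihedral angles as circular means over source structures.

    ``models`` maps accession label -> structure; each quadruple is
    measured in every structure (via the user-supplied atom-name alias
    map when ligand naming differs) and averaged circularly.
    """
    out = []
    for quad in quads:
        vals = [
            measure_dihedral(m, list(quad), residue_number=ligand_residue_number,
                             alias=alias)
            for m in models.values()
        ]
        out.append(DihedralRestraint(
            atoms=tuple(quad),
            equilibrium_angle=circular_mean_angles(vals),
            force_constant=force_constant,
            source_structures=tuple(models.keys()),
        ))
    return out


def export_restraints(restraints: Sequence[DihedralRestraint],
                      path: Union[str, Path]) -> None:
    """Write restraints as TSV (a_i, a_j, a_k, a_l, phi_deg, force_constant)."""
    rows = [
        {"a_i": r.atoms[0], "a_j": r.atoms[1], "a_k": r.atoms[2], "a_l": r.atoms[3],
         "phi_deg": r.equilibrium_angle, "force_constant": r.force_constant}
        for r in restraints
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.2f")


def charged_distance_matrix(
    model: StructureModel,
    residues: pd.DataFrame,
    representative: str = "calpha",
) -> DistanceMatrixReport:
    """All-to-all distance matrix over a charged-residue list.

    ``residues`` is a (residue_number, residue_name) table; the matrix is
    ordered as listed. The representative point per residue is the Calpha
    by default; ``representative='centroid'`` switches to the residue's
    heavy-atom centroid.
    """
    if representative not in ("calpha", "centroid"):
        raise ValueError(f"unknown representative {representative!r}")
    keys = []
    points = []
    missing = []
    atoms_by_res: dict[int, list[int]] = {}
    for i, a in enumerate(model.atoms):
        atoms_by_res.setdefault(a.residue_number, []).append(i)
    for _, row in residues.iterrows():
        rn = int(row["residue_number"])
        name = str(row["residue_name"])
        if rn not in atoms_by_res:
            missing.append(f"{name}{rn}")
            continue
        idx = atoms_by_res[rn]
        if representative == "calpha":
            ca = [i for i in idx if model.atoms[i].name == "CA"]
            if not ca:
                missing.append(f"{name}{rn} (no CA)")
                continue
            points.append(model.atoms[ca[0]].coords)
        else:
            heavy = [i for i in idx if not model.atoms[i].name.startswith("H")]
            points.append(model.coords[heavy].mean(axis=0))
        keys.append(f"{name}{rn}")
    if missing:
        raise SelectionError(f"residues absent from model: {', '.join(missing)}")
    pts = np.array(points)
    diff = pts[:, None, :] - pts[None, :, :]
    mat = np.sqrt((diff ** 2).sum(axis=2))
    return DistanceMatrixReport(residue_keys=keys, matrix=mat)
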