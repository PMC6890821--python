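"""Structure and trajectory I/O, atom selection, and construct bookkeeping.

PDB reading/writing is deliberately self-contained: the parser enforces
the error contract used throughout the package (line-numbered parse
errors, explicit model lookup failures, deterministic altloc resolution)
and round-trips exactly at the format's fixed-column precision.
Binary trajectory formats (DCD/XTC) are adapted through MDAnalysis when
it is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "SelectionSpec",
    "ChargeCensus",
    "PDBParseError",
    "ModelNotFoundError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "select_atoms",
    "charge_census",
    "sequence_diff",
    "load_residue_table",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: residue names treated as solvent/ions and dropped unless requested
SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "SOL", "NA", "CL", "NA+", "CL-", "K", "K+", "MG", "ZN"}
)

RESIDUE_CHARGES = {"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1}

STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER
    THR TRP TYR VAL""".split()
)

CAP_RESNAMES = frozenset({"ACE", "NME", "NMA"})


class PDBParseError(ValueError):
    """Malformed record in a PDB-format file; message names the line."""


class ModelNotFoundError(KeyError):
    """Requested MODEL index absent from a multi-model file."""


class SelectionError(ValueError):
    """Atom selection is invalid or resolves to no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure model (coordinates in Angstrom)."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    coords: np.ndarray
    element: str = ""
    hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class StructureModel:
    """An ordered collection of atoms (one MODEL of a PDB file)."""

    atoms: list[AtomRecord]
    model_id: int = 1
    caps: Optional[tuple[str, str]] = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the model with replaced coordinates (same atom table)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({len(self.atoms)}, 3)"
            )
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms=atoms, model_id=self.model_id, caps=self.caps)

    def residue_sequence(self) -> dict[tuple[str, int], str]:
        """Map (chain, residue_number) -> residue_name, first atom wins."""
        seq: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seq.setdefault((a.chain, a.residue_number), a.residue_name)
        return seq

    def find_atom(self, residue_number: int, atom_name: str,
                  chain: Optional[str] = None) -> int:
        """Index of the first atom matching residue number and atom name."""
        for i, a in enumerate(self.atoms):
            if (a.residue_number == residue_number and a.name == atom_name
                    and (chain is None or a.chain == chain)):
                return i
        raise SelectionError(
            f"no atom {atom_name!r} in residue {residue_number}"
            + (f" chain {chain!r}" if chain else "")
        )


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection.

    mode: 'backbone' (N, CA, C, O), 'calpha', 'all', or 'names'
    (explicit atom-name set). residue_range is an inclusive author-numbered
    [lo, hi] pair, or None for all residues.
    """

    mode: str = "all"
    residue_range: Optional[tuple[int, int]] = None
    atom_names: Optional[frozenset[str]] = None

    def __post_init__(self):
        if self.mode not in {"backbone", "calpha", "all", "names"}:
            raise SelectionError(f"unknown selection mode {self.mode!r}")
        if self.mode == "names" and not self.atom_names:
            raise SelectionError("mode 'names' requires a non-empty atom_names set")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise SelectionError(f"residue_range [{lo}, {hi}] has lo > hi")
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))


@dataclass
class ChargeCensus:
    """Integer formal-charge bookkeeping for a construct."""

    per_residue_charge: dict[tuple[str, int], int]
    net_charge: int
    counterion_species: str
    counterion_count: int


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    return AtomRecord(
        serial=serial, name=name, residue_name=resname, chain=chain,
        residue_number=resnum, coords=np.array([x, y, z]),
        element=element or (name[:1] if name else ""),
        hetero=line.startswith("HETATM"), occupancy=occupancy, altloc=altloc,
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy altloc per (chain, resnum, atom name);
    ties broken by altloc letter order."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.residue_number, a.residue_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[key] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> int:
    # higher rank wins ties; earlier letters preferred => invert ordinal
    return -ord(altloc) if altloc else 1


def read_structure(
    path: Union[str, Path],
    model_index: Union[int, str] = "all",
    keep_solvent: bool = False,
) -> Union[StructureModel, list[StructureModel]]:
    """Read a (multi-model) PDB file.

    Parameters
    ----------
    path:
        PDB-format file with ATOM/HETATM and optional MODEL/ENDMDL records.
    model_index:
        1-based MODEL number to return, or ``"all"`` for every model.
        Files without MODEL records yield a single model with id 1.
    keep_solvent:
        Retain water and monatomic-ion HETATM records (dropped by default).

    Returns
    -------
    StructureModel or list of StructureModel, in file order.
    """
    path = Path(path)
    models: list[StructureModel] = []
    current: list[AtomRecord] = []
    current_id: Optional[int] = None
    seen_model_record = False
    caps_seen: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model_record = True
                if current:
                    models.append(_finish_model(current, current_id or 1, caps_seen))
                    current = []
                try:
                    current_id = int(line.split()[1])
                except (IndexError, ValueError) as exc:
                    raise PDBParseError(f"line {lineno}: malformed MODEL record") from exc
            elif rec == "ENDMDL":
                models.append(_finish_model(current, current_id or len(models) + 1, caps_seen))
                current = []
                current_id = None
            elif rec in ("ATOM", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom.hetero and not keep_solvent and atom.residue_name in SOLVENT_RESNAMES:
                    continue
                if atom.residue_name in CAP_RESNAMES:
                    caps_seen.add(atom.residue_name)
                current.append(atom)

    if current:
        current_id = current_id if current_id is not None else (
            len(models) + 1 if seen_model_record else 1
        )
        models.append(_finish_model(current, current_id, caps_seen))

    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    if model_index == "all":
        return models
    for m in models:
        if m.model_id == model_index:
            return m
    raise ModelNotFoundError(
        f"model {model_index} not in {path} (available: {[m.model_id for m in models]})"
    )


def _finish_model(atoms: list[AtomRecord], model_id: int, caps_seen: set[str]) -> StructureModel:
    atoms = _resolve_altlocs(atoms)
    serials = [a.serial for a in atoms]
    if len(set(serials)) != len(serials):
        # renumber duplicated serials rather than fail: common in dialects
        atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
    caps = None
    if "ACE" in caps_seen and caps_seen & {"NME", "NMA"}:
        caps = ("ACE", "NME" if "NME" in caps_seen else "NMA")
    return StructureModel(atoms=atoms, model_id=model_id, caps=caps)


def _format_atom_line(a: AtomRecord) -> str:
    rec = "HETATM" if a.hetero else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{rec}{a.serial:>5d} {name:<4.4s}{a.altloc or ' ':1.1s}{a.residue_name:>3.3s} "
        f"{a.chain:1.1s}{a.residue_number:>4d}    "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
    )


def write_structure(
    model: Union[StructureModel, Sequence[StructureModel]],
    path: Union[str, Path],
) -> None:
    """Write one model or a sequence of models as a (multi-model) PDB file."""
    models = [model] if isinstance(model, StructureModel) else list(model)
    if not models or any(len(m) == 0 for m in models):
        raise ValueError("cannot write an empty structure model")
    multi = len(models) > 1
    with open(path, "w") as fh:
        for m in models:
            if multi:
                fh.write(f"MODEL     {m.model_id:>4d}\n")
            for a in m.atoms:
                fh.write(_format_atom_line(a) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(
    path: Union[str, Path],
    topology: Optional[Union[str, Path, StructureModel]] = None,
    frame_interval: float = 0.1,
):
    """Read a trajectory into a :class:`mdflex.traj_metrics.Trajectory`.

    Multi-model PDB files are read natively; DCD/XTC files require a
    topology (PDB path) and the optional MDAnalysis dependency.
    Coordinates are returned in Angstrom.
    """
    from .traj_metrics import Trajectory

    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        models = read_structure(path, model_index="all")
        if isinstance(models, StructureModel):
            models = [models]
        coords = np.stack([m.coords for m in models])
        return Trajectory(coords=coords, frame_interval=frame_interval,
                          atom_meta=models[0])
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            f"reading {path.suffix} trajectories requires MDAnalysis"
        ) from exc
    if topology is None:
        raise ValueError("binary trajectory formats require a topology file")
    if isinstance(topology, StructureModel):
        raise ValueError("pass the topology as a PDB path for binary trajectories")
    u = mda.Universe(str(topology), str(path))
    coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(float)
    ref = read_structure(topology, model_index="all")
    ref = ref[0] if isinstance(ref, list) else ref
    return Trajectory(coords=coords, frame_interval=frame_interval, atom_meta=ref)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_atoms(model: StructureModel, spec: SelectionSpec) -> list[int]:
    """Resolve a :class:`SelectionSpec` to an ordered atom-index list.

    Deterministic and order-preserving; raises :class:`SelectionError`
    rather than returning an empty selection.
    """
    if spec.mode == "backbone":
        names: Optional[frozenset] = BACKBONE_ATOMS
    elif spec.mode == "calpha":
        names = frozenset({"CA"})
    elif spec.mode == "names":
        names = spec.atom_names
    else:
        names = None

    lo, hi = spec.residue_range if spec.residue_range is not None else (None, None)
    out = []
    for i, a in enumerate(model.atoms):
        if names is not None and a.name not in names:
            continue
        if lo is not None and not (lo <= a.residue_number <= hi):
            continue
        out.append(i)
    if not out:
        raise SelectionError(f"selection {spec} matched no atoms")
    return out


# ---------------------------------------------------------------------------
# Bookkeeping
# ---------------------------------------------------------------------------

def charge_census(
    residues: Iterable[tuple[str, int]],
    caps_present: bool = False,
) -> ChargeCensus:
    """Formal-charge census over a residue list.

    ARG/LYS count +1, ASP/GLU count -1, HIS and everything else 0.
    With capped termini (ACE/NME) the chain ends contribute no charge,
    which is already the convention here, so ``caps_present`` only
    suppresses the would-be terminal warning. Unknown residue codes are
    logged and treated as neutral. The counterion species neutralizes the
    net charge: sodium for a net-negative construct, chloride otherwise.
    """
    per: dict[tuple[str, int], int] = {}
    net = 0
    for name, number in residues:
        name = str(name).upper()
        if name in CAP_RESNAMES:
            q = 0
        elif name in RESIDUE_CHARGES:
            q = RESIDUE_CHARGES[name]
        elif name in STANDARD_AMINO_ACIDS:
            q = 0
        else:
            logger.warning("charge_census: unknown residue %s%s treated as neutral",
                           name, number)
            q = 0
        per[(name, int(number))] = q
        net += q
    species = "sodium" if net < 0 else "chloride"
    return ChargeCensus(
        per_residue_charge=per,
        net_charge=net,
        counterion_species=species,
        counterion_count=abs(net),
    )


def sequence_diff(
    a: StructureModel, b: StructureModel
) -> list[tuple[int, str, str]]:
    """Residue-level differences between two models over shared positions.

    Positions are compared only where both models define a residue;
    chains are matched by label. Returns (residue_number, code_a, code_b)
    tuples sorted by position.
    """
    seq_a = a.residue_sequence()
    seq_b = b.residue_sequence()
    diffs = []
    for key in sorted(set(seq_a) & set(seq_b), key=lambda k: (k[0], k[1])):
        if seq_a[key] != seq_b[key]:
            diffs.append((key[1], seq_a[key], seq_b[key]))
    diffs.sort(key=lambda t: t[0])
    return diffs


def load_residue_table(path: Union[str, Path]) -> pd.DataFrame:
    """Load a TSV of (residue_number, residue_name) rows."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue_number", "residue_name"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df["residue_number"] = df["residue_number"].astype(int)
    df["residue_name"] = df["residue_name"].astype(str).str.upper()
    return df
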