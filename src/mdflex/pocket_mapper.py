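"""Sphere-intersection classification of solvent-mapping probe clusters.

Each probe cluster and each pocket's lining residues are reduced to
bounding spheres; the analytic sphere-sphere intersection volume (with a
0.75 scaling on the pocket-sphere radius) decides which pocket a cluster
belongs to. Consensus strength S is the number of probe clusters landing
in a pocket within one snapshot; S >= 16 marks a pocket druggable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .structure_io import SelectionError, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "PROBE_TYPES",
    "DRUGGABILITY_THRESHOLD",
    "POCKET_RADIUS_SCALE",
    "ProbeCluster",
    "Sphere",
    "PocketDefinition",
    "PocketAssignment",
    "PocketReport",
    "load_probe_clusters",
    "write_probe_clusters",
    "load_pocket_registry",
    "bounding_sphere",
    "intersect_volume",
    "pocket_sphere",
    "classify_clusters",
    "aggregate_report",
]

#: the 16-probe vocabulary of the solvent-mapping protocol
PROBE_TYPES = frozenset({
    "acetamide", "acetonitrile", "acetone", "acetaldehyde", "methylamine",
    "benzaldehyde", "benzene", "isobutanol", "cyclohexane",
    "dimethylformamide", "dimethylether", "ethanol", "ethane", "phenol",
    "isopropanol", "urea",
})

DRUGGABILITY_THRESHOLD = 16
POCKET_RADIUS_SCALE = 0.75
SINGLETON_RADIUS_FLOOR = 0.5  # Angstrom


@dataclass
class ProbeCluster:
    cluster_id: int
    probe_type: str
    coords: np.ndarray        # (n_atoms, 3), Angstrom
    snapshot_time: float = 0.0  # ns

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] < 1 or self.coords.shape[1] != 3:
            raise ValueError("cluster needs >= 1 atom with 3-D coordinates")
        pt = self.probe_type.lower().replace(" ", "").replace("-", "")
        if pt not in PROBE_TYPES:
            logger.warning("unknown probe type %r; recording as 'unknown'",
                           self.probe_type)
            pt = "unknown"
        self.probe_type = pt


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,):
            raise ValueError("sphere center must be a 3-vector")
        object.__setattr__(self, "center", c)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3


@dataclass(frozen=True)
class PocketDefinition:
    name: str
    lining_residues: tuple[int, ...]
    atp_site: bool = False

    def __post_init__(self):
        if not self.lining_residues:
            raise ValueError(f"pocket {self.name}: needs >= 1 lining residue")
        object.__setattr__(self, "lining_residues", tuple(self.lining_residues))


@dataclass
class PocketAssignment:
    cluster_id: int
    pocket: Optional[str]       # merged label (ATP for atp_site pockets); None = unassigned
    volume: float               # max intersecting volume V_o
    d: float
    r1: float
    r2: float
    snapshot_time: float = 0.0


@dataclass
class PocketReport:
    """Consensus strengths and occurrence counts across an ensemble.

    ``strengths[pocket]`` maps snapshot time -> S (cluster count in that
    snapshot); ``occurrences[pocket]`` is the pooled count, None when the
    pocket never occurs; ``druggable[pocket]`` is True when any snapshot
    reaches S >= threshold (or, in pooled mode, the pooled count does).
    """

    strengths: dict[str, dict[float, int]]
    occurrences: dict[str, Optional[int]]
    druggable: dict[str, bool]
    n_unassigned: int
    threshold: int = DRUGGABILITY_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.occurrences:
            occ = self.occurrences[name]
            rows.append({
                "pocket_name": name,
                "occurrences": "N/A" if occ is None else occ,
                "max_strength": max(self.strengths[name].values(), default=0),
                "druggable": self.druggable[name],
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _probe_from_tokens(tokens: Sequence[str]) -> str:
    for tok in tokens:
        t = tok.lower().replace("-", "").replace("_", "")
        if t in PROBE_TYPES:
            return t
    return "unknown"


def load_probe_clusters(path: Union[str, Path]) -> list[ProbeCluster]:
    """Parse a solvent-mapping PDB dialect into probe clusters.

    Cluster blocks are introduced by HEADER/REMARK lines (the probe name
    is picked out of the header tokens when present); a headerless file
    is treated as a single cluster with a warning. Returns clusters in
    file order; an empty file yields an empty list.
    """
    path = Path(path)
    clusters: list[ProbeCluster] = []
    cur_coords: list[list[float]] = []
    cur_probe = "unknown"
    cur_time = 0.0
    saw_header = False

    def flush():
        nonlocal cur_coords
        if cur_coords:
            clusters.append(ProbeCluster(
                cluster_id=len(clusters), probe_type=cur_probe,
                coords=np.array(cur_coords), snapshot_time=cur_time,
            ))
            cur_coords = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("HEADER", "REMARK"):
                flush()
                saw_header = True
                tokens = line.split()
                cur_probe = _probe_from_tokens(tokens[1:])
                for tok in tokens:
                    if tok.startswith("t=") or tok.startswith("time="):
                        try:
                            cur_time = float(tok.split("=", 1)[1])
                        except ValueError:
                            pass
            elif rec in ("ATOM", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ValueError(f"{path} line {lineno}: bad coordinates") from exc
                cur_coords.append([x, y, z])
    if cur_coords and not saw_header:
        logger.warning("%s: no cluster headers; treating file as one cluster", path)
    flush()
    return clusters


def write_probe_clusters(clusters: Sequence[ProbeCluster],
                         path: Union[str, Path]) -> None:
    """Write clusters back out in the header-delimited PDB dialect."""
    with open(path, "w") as fh:
        serial = 1
        for cl in clusters:
            fh.write(f"HEADER cluster {cl.cluster_id} {cl.probe_type} "
                     f"t={cl.snapshot_time:g}\n")
            for xyz in cl.coords:
                fh.write(
                    f"ATOM  {serial:>5d}  C   PRB A{cl.cluster_id % 9999 + 1:>4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"{'':10s}{'C':>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def load_pocket_registry(path: Union[str, Path]) -> list[PocketDefinition]:
    """Load a pocket registry TSV: (pocket_name, lining_residues, [atp_site]).

    ``lining_residues`` is a comma-separated residue-number list. Names
    must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pocket_name", "lining_residues"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns pocket_name, lining_residues")
    out = []
    seen = set()
    for _, row in df.iterrows():
        name = row["pocket_name"].strip()
        if name in seen:
            raise ValueError(f"{path}: duplicate pocket name {name!r}")
        seen.add(name)
        residues = tuple(int(t) for t in str(row["lining_residues"]).split(","))
        atp = False
        if "atp_site" in df.columns and str(row.get("atp_site", "0")).strip() not in ("", "0", "nan", "False"):
            atp = True
        out.append(PocketDefinition(name=name, lining_residues=residues, atp_site=atp))
    return out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def bounding_sphere(points: np.ndarray, minimal: bool = False) -> Sphere:
    """Bounding sphere of a point set.

    Default: centroid center with max-distance radius (deterministic and
    cheap; the downstream 0.75 pocket scaling counteracts the slight
    overestimate). ``minimal=True`` switches to Ritter's approximate
    minimal enclosing sphere. Singletons get a 0.5 A radius floor.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1 or pts.shape[1] != 3:
        raise ValueError("need >= 1 three-dimensional point")
    if not minimal:
        center = pts.mean(axis=0)
        radius = float(np.max(np.linalg.norm(pts - center, axis=1)))
    else:
        i = int(np.argmax(np.linalg.norm(pts - pts[0], axis=1)))
        j = int(np.argmax(np.linalg.norm(pts - pts[i], axis=1)))
        center = 0.5 * (pts[i] + pts[j])
        radius = 0.5 * float(np.linalg.norm(pts[i] - pts[j]))
        for p in pts:
            d = float(np.linalg.norm(p - center))
            if d > radius:
                radius = 0.5 * (radius + d)
                center = center + (d - radius) / d * (p - center)
        radius = float(radius)
    return Sphere(center=center, radius=max(radius, SINGLETON_RADIUS_FLOOR))


def intersect_volume(s1: Sphere, s2: Sphere, scale_r2: float = POCKET_RADIUS_SCALE) -> float:
    """Analytic intersection volume of two spheres, in cubic Angstrom.

    The second sphere's radius is first multiplied by ``scale_r2``
    (default 0.75, damping pocket-sphere overestimation). With d the
    center distance and r1, r2 the (scaled) radii:

    * 0                                       for d >= r1 + r2
    * pi/(12 d) (r1+r2-d)^2
      (d^2 + 2d(r1+r2) - 3(r1-r2)^2)          for |r1-r2| < d < r1+r2
    * 4/3 pi min(r1, r2)^3                    for 0 <= d <= |r1-r2|
    """
    r1 = float(s1.radius)
    r2 = float(s2.radius) * float(scale_r2)
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    d = float(np.linalg.norm(s1.center - s2.center))
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 4.0 / 3.0 * math.pi * min(r1, r2) ** 3
    return (math.pi / (12.0 * d) * (r1 + r2 - d) ** 2
            * (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2))


def pocket_sphere(model: StructureModel, pocket: PocketDefinition) -> Sphere:
    """Bounding sphere over all heavy atoms of the pocket's lining residues."""
    wanted = set(pocket.lining_residues)
    pts = [a.coords for a in model.atoms
           if a.residue_number in wanted and not a.name.startswith("H")]
    present = {a.residue_number for a in model.atoms if a.residue_number in wanted}
    missing = wanted - present
    if missing:
        raise SelectionError(
            f"pocket {pocket.name}: lining residues missing from model: "
            f"{sorted(missing)}"
        )
    return bounding_sphere(np.array(pts))


# ---------------------------------------------------------------------------
# Classification and aggregation
# ---------------------------------------------------------------------------

def classify_clusters(
    clusters: Sequence[ProbeCluster],
    model: StructureModel,
    registry: Sequence[PocketDefinition],
    scale_r2: float = POCKET_RADIUS_SCALE,
) -> list[PocketAssignment]:
    """Assign each probe cluster to the pocket with maximal intersection volume.

    Pocket spheres are computed once from the model. A cluster with zero
    intersection against every pocket is unassigned. Pockets flagged as
    ATP-site members report under the merged label ``"ATP"``. Ties go to
    the earlier registry entry, with a warning.
    """
    if not registry:
        raise ValueError("empty pocket registry")
    spheres = [(p, pocket_sphere(model, p)) for p in registry]
    out = []
    for cl in clusters:
        cs = bounding_sphere(cl.coords)
        best_v = 0.0
        best: Optional[PocketDefinition] = None
        best_geom = (float("nan"),) * 3
        tied = False
        for p, ps in spheres:
            v = intersect_volume(cs, ps, scale_r2=scale_r2)
            if v > best_v + 1e-12:
                best_v, best, tied = v, p, False
                best_geom = (float(np.linalg.norm(cs.center - ps.center)),
                             cs.radius, ps.radius)
            elif best is not None and abs(v - best_v) <= 1e-12 and v > 0:
                tied = True
        if tied:
            logger.warning("cluster %d: tied intersection volumes; keeping "
                           "registry-order winner %s", cl.cluster_id, best.name)
        label = None
        if best is not None:
            label = "ATP" if best.atp_site else best.name
        out.append(PocketAssignment(
            cluster_id=cl.cluster_id, pocket=label, volume=best_v,
            d=best_geom[0], r1=best_geom[1], r2=best_geom[2],
            snapshot_time=cl.snapshot_time,
        ))
    return out


def aggregate_report(
    assignments_by_snapshot: Mapping[float, Sequence[PocketAssignment]],
    registry: Sequence[PocketDefinition],
    threshold: int = DRUGGABILITY_THRESHOLD,
    pooled: bool = False,
) -> PocketReport:
    """Consensus strength S per pocket per snapshot plus pooled occurrences.

    Pocket labels follow the merged convention of
    :func:`classify_clusters` (ATP-site pockets collapse into ``"ATP"``).
    Druggability is judged per snapshot by default (any snapshot with
    S >= threshold); ``pooled=True`` judges the pooled cluster count.
    Pockets that never occur report ``None`` occurrences (the table's
    N/A convention).
    """
    if not assignments_by_snapshot:
        raise ValueError("no snapshots")
    labels: list[str] = []
    for p in registry:
        lab = "ATP" if p.atp_site else p.name
        if lab not in labels:
            labels.append(lab)

    strengths: dict[str, dict[float, int]] = {lab: {} for lab in labels}
    n_unassigned = 0
    for snap, assigns in assignments_by_snapshot.items():
        counts = {lab: 0 for lab in labels}
        for a in assigns:
            if a.pocket is None:
                n_unassigned += 1
            elif a.pocket in counts:
                counts[a.pocket] += 1
            else:
                logger.warning("assignment to pocket %r absent from registry", a.pocket)
        for lab, c in counts.items():
            if c > 0:
                strengths[lab][float(snap)] = c

    occurrences: dict[str, Optional[int]] = {}
    druggable: dict[str, bool] = {}
    for lab in labels:
        pooled_count = sum(strengths[lab].values())
        occurrences[lab] = pooled_count if pooled_count > 0 else None
        if pooled:
            druggable[lab] = pooled_count >= threshold
        else:
            druggable[lab] = any(s >= threshold for s in strengths[lab].values())
    return PocketReport(
        strengths=strengths, occurrences=occurrences, druggable=druggable,
        n_unassigned=n_unassigned, threshold=threshold,
    )
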