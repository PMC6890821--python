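"""Seeded generators with known ground truth for every pipeline stage.

A toy two-domain protein stands in for the two-lobe kinase architecture:
trajectories plant a hinge ("butterfly") mode, a twist mode, localized
loop flexibility and Gaussian thermal noise; probe clusters are planted
near defined pocket sites; observable tables follow a known linear
relation with controlled noise and outliers. All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .nmr_compare import ShiftRecord
from .pocket_mapper import PocketDefinition, ProbeCluster, pocket_sphere
from .structure_io import AtomRecord, StructureModel
from .traj_metrics import Trajectory, kabsch_superpose

__all__ = [
    "ToyProteinSpec",
    "MotionSpec",
    "TrajectoryTruth",
    "generate_toy_structure",
    "generate_chain_structure",
    "generate_trajectory",
    "mode_fields",
    "motion_for_variances",
    "interdomain_angle_series",
    "toy_pocket_registry",
    "plant_probe_clusters",
    "generate_observables",
    "generate_shift_snapshots",
]


@dataclass(frozen=True)
class ToyProteinSpec:
    """Two pseudo-domains of Calpha-like residues plus flexible loops."""

    n_residues: tuple[int, int] = (60, 60)
    domain_radius: float = 10.0
    inter_domain_distance: float = 30.0
    loop_regions: tuple[tuple[int, int], ...] = ()
    atoms_per_residue: int = 1

    def __post_init__(self):
        if min(self.n_residues) < 3:
            raise ValueError("each domain needs >= 3 residues")
        if self.inter_domain_distance <= 0:
            raise ValueError("inter_domain_distance must be positive")
        for lo, hi in self.loop_regions:
            if lo > hi:
                raise ValueError(f"loop region [{lo}, {hi}] inverted")


@dataclass(frozen=True)
class MotionSpec:
    """Planted kinematics: sinusoidal hinge + twist, loop and global noise."""

    hinge_amplitude: float = 5.0    # degrees
    twist_amplitude: float = 2.0    # degrees
    loop_sigma: float = 0.0         # Angstrom, extra displacement in loops
    global_sigma: float = 0.0       # Angstrom, isotropic per coordinate
    n_frames: int = 200
    seed: int = 0
    hinge_cycles: int = 7           # full cycles over the trajectory
    twist_cycles: int = 17
    frame_interval: float = 0.1     # ns

    def __post_init__(self):
        if self.hinge_amplitude < 0 or self.twist_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.loop_sigma < 0 or self.global_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass
class TrajectoryTruth:
    """Ground truth planted by :func:`generate_trajectory`."""

    hinge_mode: np.ndarray          # unit 3N-vector
    twist_mode: np.ndarray          # unit 3N-vector
    hinge_angles: np.ndarray        # degrees per frame
    twist_angles: np.ndarray        # degrees per frame
    hinge_variance: float           # planted displacement variance, A^2
    twist_variance: float           # planted displacement variance, A^2
    noise_variance: float           # total noise variance (all coordinates), A^2
    pivot: np.ndarray
    hinge_axis: np.ndarray
    twist_axis: np.ndarray


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _blob(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    # uniform-in-sphere points, recentered so the centroid is exact
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    pts = u * r[:, None]
    return pts - pts.mean(axis=0)


def generate_toy_structure(spec: ToyProteinSpec = ToyProteinSpec(),
                           seed: int = 0) -> StructureModel:
    """Deterministic two-domain Calpha model; residues numbered 1..N.

    Domain 1 is centered at the origin, domain 2 at
    (inter_domain_distance, 0, 0); each domain's centroid is exact.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = spec.n_residues
    c1 = np.zeros(3)
    c2 = np.array([spec.inter_domain_distance, 0.0, 0.0])
    pts = np.vstack([_blob(rng, n1, spec.domain_radius) + c1,
                     _blob(rng, n2, spec.domain_radius) + c2])
    atoms = []
    serial = 1
    for i, p in enumerate(pts):
        atoms.append(AtomRecord(
            serial=serial, name="CA", residue_name="GLY", chain="A",
            residue_number=i + 1, coords=p, element="C",
        ))
        serial += 1
    return StructureModel(atoms=atoms, model_id=1)


def generate_chain_structure(
    n_residues: int = 354,
    residue_names: Optional[Mapping[int, str]] = None,
    seed: int = 0,
    jitter: float = 0.3,
) -> StructureModel:
    """A single-chain Calpha model laid out on a loose helix.

    Useful as a stand-in full-length construct: any residue numbering is
    present from 1..n_residues, with names overridden per position via
    ``residue_names`` (default GLY).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues, dtype=float)
    coords = np.stack([
        8.0 * np.cos(t * 0.6), 8.0 * np.sin(t * 0.6), 1.5 * t
    ], axis=1)
    coords += rng.normal(scale=jitter, size=coords.shape)
    atoms = []
    for i in range(n_residues):
        rn = i + 1
        name = (residue_names or {}).get(rn, "GLY")
        atoms.append(AtomRecord(
            serial=i + 1, name="CA", residue_name=name, chain="A",
            residue_number=rn, coords=coords[i], element="C",
        ))
    return StructureModel(atoms=atoms, model_id=1)


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return (np.eye(3) + math.sin(angle_rad) * k
            + (1 - math.cos(angle_rad)) * (k @ k))


def _domain_masks(structure: StructureModel,
                  spec: ToyProteinSpec) -> tuple[np.ndarray, np.ndarray]:
    n1 = spec.n_residues[0] * spec.atoms_per_residue
    idx = np.arange(len(structure))
    return idx < n1, idx >= n1


def _remove_rigid_component(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Project the rigid-body (translation + rotation) subspace out of a
    flattened displacement field; alignment removes exactly that subspace."""
    n = coords.shape[0]
    center = coords.mean(axis=0)
    rel = coords - center
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
    for k in range(3):
        omega = np.zeros(3)
        omega[k] = 1.0
        basis.append(np.cross(omega, rel).ravel())
    out = field.astype(float).copy()
    # Gram-Schmidt on the rigid basis, then subtract projections
    ortho: list[np.ndarray] = []
    for b in basis:
        for q in ortho:
            b = b - (q @ b) * q
        nb = np.linalg.norm(b)
        if nb > 1e-12:
            ortho.append(b / nb)
    for q in ortho:
        out -= (q @ out) * q
    return out


def mode_fields(structure: StructureModel, spec: ToyProteinSpec
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unnormalized hinge and twist derivative fields (A per radian).

    The hinge rotates each domain in antisymmetric halves about the z
    axis through its own centroid; the twist does the same about the
    inter-domain (x) axis through the midpoint. Rigid-body components
    (which superposition removes) are projected out of both fields.
    Returns (v_hinge, v_twist, pivot) with the fields flattened to 3N
    vectors.
    """
    m1, m2 = _domain_masks(structure, spec)
    coords = structure.coords
    pivot = np.array([spec.inter_domain_distance / 2.0, 0.0, 0.0])
    c1 = coords[m1].mean(axis=0)
    c2 = coords[m2].mean(axis=0)
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    v_h = np.where(m1[:, None],
                   np.cross(z, coords - c1), -np.cross(z, coords - c2)) * 0.5
    rel = coords - pivot
    v_t = np.where(m1[:, None], np.cross(x, rel), -np.cross(x, rel)) * 0.5
    v_h = _remove_rigid_component(v_h.ravel(), coords)
    v_t = _remove_rigid_component(v_t.ravel(), coords)
    return v_h, v_t, pivot


def motion_for_variances(
    structure: StructureModel,
    spec: ToyProteinSpec,
    hinge_variance: float,
    twist_variance: float,
    **kwargs,
) -> MotionSpec:
    """MotionSpec whose sinusoidal amplitudes plant the requested
    displacement variances (A^2, to first order in the rotation angle)."""
    v_h, v_t, _ = mode_fields(structure, spec)
    nh = np.linalg.norm(v_h)
    nt = np.linalg.norm(v_t)
    # Var(A sin) = A^2/2 over whole cycles; displacement = angle * |v|
    a_h = math.degrees(math.sqrt(2.0 * hinge_variance) / nh) if hinge_variance > 0 else 0.0
    a_t = math.degrees(math.sqrt(2.0 * twist_variance) / nt) if twist_variance > 0 else 0.0
    return MotionSpec(hinge_amplitude=a_h, twist_amplitude=a_t, **kwargs)


def generate_trajectory(
    structure: StructureModel,
    motion: MotionSpec,
    spec: ToyProteinSpec = ToyProteinSpec(),
) -> tuple[Trajectory, TrajectoryTruth]:
    """Apply planted hinge/twist sinusoids plus noise to a toy structure.

    Frame t rotates the two domains antisymmetrically by
    ``A_h sin(2 pi f_h t / n)`` about the hinge (z) axis and by
    ``A_t sin(2 pi f_t t / n + pi/3)`` about the twist (x) axis, adds
    extra Gaussian displacement to loop residues and isotropic global
    noise, and records the exact planted angles and unit mode vectors.
    """
    rng = np.random.default_rng(motion.seed)
    coords0 = structure.coords
    n_atoms = len(structure)
    m1, m2 = _domain_masks(structure, spec)
    v_h, v_t, pivot = mode_fields(structure, spec)

    t = np.arange(motion.n_frames)
    th = np.radians(motion.hinge_amplitude) * np.sin(
        2 * np.pi * motion.hinge_cycles * t / motion.n_frames)
    tw = np.radians(motion.twist_amplitude) * np.sin(
        2 * np.pi * motion.twist_cycles * t / motion.n_frames + np.pi / 3)

    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    loop_mask = np.zeros(n_atoms, dtype=bool)
    for lo, hi in spec.loop_regions:
        for i, a in enumerate(structure.atoms):
            if lo <= a.residue_number <= hi:
                loop_mask[i] = True

    c1 = coords0[m1].mean(axis=0)
    c2 = coords0[m2].mean(axis=0)
    frames = np.empty((motion.n_frames, n_atoms, 3))
    for k in range(motion.n_frames):
        frame = coords0.copy()
        # hinge: antisymmetric rotation of each domain about its own centroid
        frame[m1] = (frame[m1] - c1) @ _rotation(z, th[k] / 2.0).T + c1
        frame[m2] = (frame[m2] - c2) @ _rotation(z, -th[k] / 2.0).T + c2
        # twist: antisymmetric rotation about the inter-domain axis
        frame[m1] = (frame[m1] - pivot) @ _rotation(x, tw[k] / 2.0).T + pivot
        frame[m2] = (frame[m2] - pivot) @ _rotation(x, -tw[k] / 2.0).T + pivot
        if motion.loop_sigma > 0 and loop_mask.any():
            frame[loop_mask] += rng.normal(scale=motion.loop_sigma,
                                           size=(int(loop_mask.sum()), 3))
        if motion.global_sigma > 0:
            frame += rng.normal(scale=motion.global_sigma, size=frame.shape)
        frames[k] = frame

    nh = np.linalg.norm(v_h)
    nt = np.linalg.norm(v_t)
    hinge_var = float(np.var(th) * nh ** 2)
    twist_var = float(np.var(tw) * nt ** 2)
    noise_var = float(3 * n_atoms * motion.global_sigma ** 2
                      + 3 * loop_mask.sum() * motion.loop_sigma ** 2)
    truth = TrajectoryTruth(
        hinge_mode=v_h / nh, twist_mode=v_t / nt,
        hinge_angles=np.degrees(th), twist_angles=np.degrees(tw),
        hinge_variance=hinge_var, twist_variance=twist_var,
        noise_variance=noise_var, pivot=pivot, hinge_axis=z, twist_axis=x,
    )
    traj = Trajectory(coords=frames, frame_interval=motion.frame_interval,
                      atom_meta=structure)
    return traj, truth


def interdomain_angle_series(
    traj: Trajectory,
    spec: ToyProteinSpec,
    reference: Optional[StructureModel] = None,
    axis: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Signed relative rotation angle (degrees) between the two domains.

    Per frame, each domain is Kabsch-fitted to the reference; the
    rotation of domain 1 relative to domain 2 is converted to an
    axis-angle, signed by projection onto ``axis`` (default: hinge z).
    """
    ref = (reference.coords if reference is not None
           else traj.atom_meta.coords if traj.atom_meta is not None
           else traj.coords[0])
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    m1, m2 = _split_masks(traj.n_atoms, spec)
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.coords):
        r1 = kabsch_superpose(ref[m1], frame[m1]).rotation
        r2 = kabsch_superpose(ref[m2], frame[m2]).rotation
        rel = r1 @ r2.T
        ax = np.array([rel[2, 1] - rel[1, 2],
                       rel[0, 2] - rel[2, 0],
                       rel[1, 0] - rel[0, 1]])
        sin_a = 0.5 * np.linalg.norm(ax)       # |sin| of the rotation angle
        cos_a = (np.trace(rel) - 1.0) / 2.0
        ang = math.degrees(math.atan2(sin_a, cos_a))
        if np.dot(ax, axis) < 0:
            ang = -ang
        out[k] = ang
    return out


def _split_masks(n: int, spec: ToyProteinSpec):
    n1 = spec.n_residues[0] * spec.atoms_per_residue
    idx = np.arange(n)
    return idx < n1, idx >= n1


# ---------------------------------------------------------------------------
# Pockets and probes
# ---------------------------------------------------------------------------

def toy_pocket_registry(
    structure: StructureModel,
    spec: ToyProteinSpec = ToyProteinSpec(),
    residues_per_pocket: int = 5,
) -> tuple[list[PocketDefinition], dict[str, np.ndarray]]:
    """Three toy pockets: one per domain core plus the inter-domain cleft.

    Lining residues are the ``residues_per_pocket`` residues nearest each
    anchor point; returns (registry, site centers from the resulting
    pocket spheres).
    """
    coords = structure.coords
    m1, m2 = _domain_masks(structure, spec)
    anchors = {
        "siteA": coords[m1].mean(axis=0),
        "siteB": coords[m2].mean(axis=0),
        "cleft": np.array([spec.inter_domain_distance / 2.0, 0.0, 0.0]),
    }
    registry = []
    for name, anchor in anchors.items():
        d = np.linalg.norm(coords - anchor, axis=1)
        nearest = np.argsort(d, kind="stable")[:residues_per_pocket]
        residues = tuple(sorted(structure.atoms[i].residue_number for i in nearest))
        registry.append(PocketDefinition(name=name, lining_residues=residues))
    centers = {p.name: pocket_sphere(structure, p).center for p in registry}
    return registry, centers


def plant_probe_clusters(
    structure: StructureModel,
    sites: Mapping[str, np.ndarray],
    n_clusters: int = 20,
    spread: float = 1.0,
    outlier_fraction: float = 0.1,
    seed: int = 0,
    atoms_per_cluster: int = 8,
) -> tuple[list[ProbeCluster], list[Optional[str]]]:
    """Gaussian probe clusters around named sites, plus far-away outliers.

    Non-outlier clusters cycle through the sites; outlier clusters are
    placed well beyond the structure's bounding sphere so they intersect
    no pocket. Returns (clusters, truth labels) with ``None`` marking
    outliers.
    """
    if not sites:
        raise ValueError("no sites given")
    rng = np.random.default_rng(seed)
    site_names = list(sites)
    n_out = int(round(n_clusters * outlier_fraction))
    coords = structure.coords
    center = coords.mean(axis=0)
    reach = float(np.max(np.linalg.norm(coords - center, axis=1)))
    probes = sorted(p for p in
                    {"ethanol", "benzene", "acetone", "urea", "phenol"})

    clusters: list[ProbeCluster] = []
    labels: list[Optional[str]] = []
    for i in range(n_clusters):
        if i < n_clusters - n_out:
            name = site_names[i % len(site_names)]
            c = np.asarray(sites[name], dtype=float)
            labels.append(name)
        else:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            c = center + u * (reach + 50.0 + 10.0 * rng.random())
            labels.append(None)
        pts = c + rng.normal(scale=spread, size=(atoms_per_cluster, 3))
        clusters.append(ProbeCluster(
            cluster_id=i, probe_type=probes[i % len(probes)], coords=pts,
        ))
    return clusters, labels


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def generate_observables(
    keys: Sequence[object],
    slope: float = 1.0,
    intercept: float = 0.0,
    sigma: float = 0.5,
    n_outliers: int = 0,
    outlier_scale: float = 5.0,
    seed: int = 0,
    x_range: tuple[float, float] = (-10.0, 10.0),
) -> tuple[dict, dict, dict]:
    """Simulated/experimental observable pair with a known linear relation.

    exp = slope * sim + intercept + N(0, sigma); ``n_outliers`` randomly
    chosen keys are displaced from the line by exactly
    ``outlier_scale * sigma`` (random sign, replacing their noise term).
    Returns (sim, exp, truth) where truth records the relation and the
    planted outlier keys.
    """
    keys = list(keys)
    if n_outliers > len(keys):
        raise ValueError("more outliers than keys")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=len(keys))
    noise = rng.normal(scale=sigma, size=len(keys)) if sigma > 0 else np.zeros(len(keys))
    y = slope * x + intercept + noise
    outlier_idx = rng.choice(len(keys), size=n_outliers, replace=False)
    for i in outlier_idx:
        y[i] = (slope * x[i] + intercept
                + outlier_scale * sigma * (1.0 if rng.random() < 0.5 else -1.0))
    sim = {k: float(v) for k, v in zip(keys, x)}
    exp = {k: float(v) for k, v in zip(keys, y)}
    truth = {
        "slope": slope, "intercept": intercept, "sigma": sigma,
        "outlier_keys": [keys[i] for i in outlier_idx],
    }
    return sim, exp, truth


def generate_shift_snapshots(
    keys: Sequence[tuple[int, str]],
    true_values: Mapping[tuple[int, str], float],
    sigma: float,
    n_snapshots: int,
    seed: int = 0,
) -> list[ShiftRecord]:
    """Predicted shift records over snapshots: truth + per-key Gaussian noise."""
    rng = np.random.default_rng(seed)
    records = []
    for s in range(n_snapshots):
        for rn, atom in keys:
            records.append(ShiftRecord(
                residue_number=rn, atom_type=atom,
                shift=float(true_values[(rn, atom)] + rng.normal(scale=sigma)),
                source="predicted", snapshot_time=float(s),
            ))
    return records
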