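"""Essential-dynamics PCA of combined conformational ensembles.

The ensemble is built from Calpha coordinates of one or more
trajectories, each frame rigid-body aligned to a common reference, and
decomposed into orthonormal collective modes by eigendecomposition of
the positional covariance. Projections, variance accounting, extreme
structures, linear morphs and cross-ensemble mode similarity live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .structure_io import SelectionSpec, StructureModel, select_atoms
from .traj_metrics import Trajectory, kabsch_superpose

__all__ = [
    "EnsembleMatrix",
    "PCAModel",
    "ProjectionSeries",
    "ModeOverlapMatrix",
    "build_combined_ensemble",
    "fit_pca",
    "project",
    "variance_explained",
    "extreme_structures",
    "morph",
    "mode_overlap",
]

CALPHA_SPEC = SelectionSpec(mode="calpha")


@dataclass
class EnsembleMatrix:
    """Aligned, flattened Calpha coordinates: (n_frames, 3*n_atoms)."""

    matrix: np.ndarray
    labels: list[str]
    reference: np.ndarray  # (n_atoms, 3) alignment reference
    residue_numbers: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] % 3 != 0:
            raise ValueError("ensemble matrix must be (frames, 3*n_atoms)")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[1] // 3


@dataclass
class PCAModel:
    mean: np.ndarray           # (3n,)
    eigenvectors: np.ndarray   # (3n, n_modes), orthonormal columns
    eigenvalues: np.ndarray    # (n_modes,), Angstrom^2, descending
    n_frames: int
    residue_numbers: Optional[np.ndarray] = None

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class ProjectionSeries:
    coordinates: np.ndarray    # (n_frames, n_modes)
    labels: list[str]


@dataclass
class ModeOverlapMatrix:
    values: np.ndarray         # |inner products|, in [0, 1]


# ---------------------------------------------------------------------------

def build_combined_ensemble(
    trajs: Sequence[Trajectory],
    reference: StructureModel,
    labels: Optional[Sequence[str]] = None,
) -> EnsembleMatrix:
    """Kabsch-align every frame of every trajectory to the reference Calphas
    and concatenate them into one labeled ensemble matrix."""
    if not trajs:
        raise ValueError("no trajectories given")
    labels = list(labels) if labels is not None else [f"run{i}" for i in range(len(trajs))]
    if len(labels) != len(trajs):
        raise ValueError("one label per trajectory required")

    ref_idx = np.asarray(select_atoms(reference, CALPHA_SPEC))
    ref_ca = reference.coords[ref_idx]
    resnums = np.array([reference.atoms[i].residue_number for i in ref_idx])

    rows = []
    row_labels = []
    for traj, label in zip(trajs, labels):
        meta = traj.atom_meta if traj.atom_meta is not None else reference
        idx = np.asarray(select_atoms(meta, CALPHA_SPEC))
        if len(idx) != len(ref_idx):
            raise ValueError(
                f"trajectory {label!r} has {len(idx)} Calphas, reference has {len(ref_idx)}"
            )
        for frame in traj.coords:
            ca = frame[idx]
            sup = kabsch_superpose(ca, ref_ca)
            rows.append(sup.apply(ca).ravel())
            row_labels.append(label)
    return EnsembleMatrix(
        matrix=np.array(rows), labels=row_labels, reference=ref_ca,
        residue_numbers=resnums,
    )


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    # make the largest-magnitude element of each column positive
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def fit_pca(ensemble: EnsembleMatrix, mass_weighted: bool = False) -> PCAModel:
    """Eigendecomposition of the coordinate covariance about the mean.

    Uses the symmetric 3n x 3n solver for small systems and the SVD route
    on the centered data matrix otherwise; the two agree to 1e-6. No mass
    weighting by default (``mass_weighted`` is reserved; Calpha-only
    ensembles make it a uniform rescaling).
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA requires at least 2 frames")
    x = ensemble.matrix
    mean = x.mean(axis=0)
    xc = x - mean
    n, p = xc.shape
    if p <= 3000:
        cov = xc.T @ xc / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
    else:
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        evals = s ** 2 / (n - 1)
        evecs = vt.T
    evecs = _fix_signs(evecs)
    return PCAModel(mean=mean, eigenvectors=evecs, eigenvalues=evals,
                    n_frames=n, residue_numbers=ensemble.residue_numbers)


def _as_rows(coords: Union[np.ndarray, Trajectory]) -> np.ndarray:
    if isinstance(coords, Trajectory):
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        return coords[None, :]
    if coords.ndim == 2 and coords.shape[1] == 3:
        return coords.reshape(1, -1)
    if coords.ndim == 2:
        return coords
    if coords.ndim == 3:
        return coords.reshape(coords.shape[0], -1)
    raise ValueError(f"cannot interpret coordinates of shape {coords.shape}")


def project(
    model: PCAModel,
    coords: Union[np.ndarray, Trajectory, StructureModel],
    align: bool = True,
    labels: Optional[Sequence[str]] = None,
) -> ProjectionSeries:
    """Project conformations into the model's eigenvector basis.

    Accepts a flattened row matrix, an (n_atoms, 3) frame, a trajectory,
    or a StructureModel (its Calphas are extracted; residues absent from
    the model's Calpha set are excluded pairwise, in which case alignment
    and projection use the shared subset only).
    """
    if isinstance(coords, StructureModel):
        rows = _project_structure_rows(model, coords)
    else:
        rows = _as_rows(coords)
        if rows.shape[1] != model.mean.size:
            raise ValueError(
                f"dimension mismatch: {rows.shape[1]} != {model.mean.size}"
            )
        if align:
            ref = model.mean.reshape(-1, 3)
            aligned = []
            for row in rows:
                sup = kabsch_superpose(row.reshape(-1, 3), ref)
                aligned.append(sup.apply(row.reshape(-1, 3)).ravel())
            rows = np.array(aligned)
    proj = (rows - model.mean) @ model.eigenvectors
    lab = list(labels) if labels is not None else [""] * len(proj)
    return ProjectionSeries(coordinates=proj, labels=lab)


def _project_structure_rows(model: PCAModel, structure: StructureModel) -> np.ndarray:
    if model.residue_numbers is None:
        raise ValueError("model lacks residue metadata for structure projection")
    idx = select_atoms(structure, CALPHA_SPEC)
    by_res = {structure.atoms[i].residue_number: i for i in idx}
    shared = [j for j, rn in enumerate(model.residue_numbers) if rn in by_res]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared residues between structure and model")
    if len(shared) < len(model.residue_numbers):
        # pairwise exclusion: fit on shared residues, fill missing with mean
        sub_ref = model.mean.reshape(-1, 3)[shared]
        sub = structure.coords[[by_res[model.residue_numbers[j]] for j in shared]]
        sup = kabsch_superpose(sub, sub_ref)
        row = model.mean.reshape(-1, 3).copy()
        row[shared] = sup.apply(sub)
        return row.reshape(1, -1)
    order = [by_res[rn] for rn in model.residue_numbers]
    ca = structure.coords[order]
    sup = kabsch_superpose(ca, model.mean.reshape(-1, 3))
    return sup.apply(ca).reshape(1, -1)


def variance_explained(model: PCAModel, k: int) -> float:
    """Fraction of total positional variance captured by the top-k modes."""
    if not 1 <= k <= model.n_modes:
        raise ValueError(f"k must be in [1, {model.n_modes}]")
    total = float(model.eigenvalues.sum())
    if total == 0:
        return 1.0
    return float(model.eigenvalues[:k].sum() / total)


def extreme_structures(
    model: PCAModel,
    series: ProjectionSeries,
    traj: Trajectory,
    pc: int = 0,
) -> tuple[StructureModel, StructureModel]:
    """Frames attaining the min and max projection on one PC.

    Returns (minus-axis, plus-axis) structures; ties broken by the
    earliest frame index. The trajectory must be the one the series was
    computed from.
    """
    if not 0 <= pc < model.n_modes:
        raise ValueError(f"pc index {pc} out of range")
    if series.coordinates.shape[0] != traj.n_frames:
        raise ValueError("projection series does not match trajectory length")
    vals = series.coordinates[:, pc]
    i_min = int(np.argmin(vals))  # argmin/argmax return first occurrence
    i_max = int(np.argmax(vals))
    meta = traj.atom_meta
    if meta is None:
        raise ValueError("trajectory lacks atom metadata")
    ca_idx = np.asarray(select_atoms(meta, CALPHA_SPEC))
    mean_ca = model.mean.reshape(-1, 3)
    out = []
    for mid, i in ((1, i_min), (2, i_max)):
        frame = traj.coords[i]
        if len(ca_idx) == mean_ca.shape[0]:
            sup = kabsch_superpose(frame[ca_idx], mean_ca)
            frame = sup.apply(frame)
        m = meta.with_coords(frame)
        m.model_id = mid
        out.append(m)
    return out[0], out[1]


def morph(a: StructureModel, b: StructureModel, n_steps: int = 10) -> Trajectory:
    """Linear Cartesian interpolation from a to b after Calpha alignment.

    b is first rigid-body aligned onto a (fitted on Calphas when present,
    otherwise on all atoms); endpoints are reproduced exactly up to that
    alignment. Frame-to-frame RMSD along the path is constant.
    """
    if len(a) != len(b):
        raise ValueError("morph endpoints must share topology")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    try:
        fit_idx = select_atoms(a, CALPHA_SPEC)
    except Exception:
        fit_idx = list(range(len(a)))
    ca = a.coords
    cb = b.coords
    sup = kabsch_superpose(cb[fit_idx], ca[fit_idx])
    cb = sup.apply(cb)
    ts = np.linspace(0.0, 1.0, n_steps)
    frames = np.array([(1 - t) * ca + t * cb for t in ts])
    return Trajectory(coords=frames, frame_interval=1.0, atom_meta=a)


def mode_overlap(a: PCAModel, b: PCAModel, k: int = 2) -> ModeOverlapMatrix:
    """|inner product| between the top-k eigenvectors of two models."""
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("models have different coordinate dimensions")
    k = min(k, a.n_modes, b.n_modes)
    vals = np.abs(a.eigenvectors[:, :k].T @ b.eigenvectors[:, :k])
    return ModeOverlapMatrix(values=np.clip(vals, 0.0, 1.0))
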