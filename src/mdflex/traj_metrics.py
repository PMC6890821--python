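"""Superposition and flexibility metrics for conformational ensembles.

Implements least-squares rigid-body superposition (Kabsch), per-frame
RMSD series, all-to-all RMSD convergence matrices, per-residue RMSF
profiles, probability-density estimates, and flexible-region reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .structure_io import SelectionSpec, StructureModel, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "SuperpositionResult",
    "RMSDSeries",
    "RMSDMatrix",
    "RMSFProfile",
    "RegionFlexibilityReport",
    "DensityEstimate",
    "DEFAULT_FLEXIBLE_REGIONS",
    "DEFAULT_TERMINAL_EXCLUSION",
    "kabsch_superpose",
    "rmsd_series",
    "all_to_all_rmsd",
    "rmsf",
    "density_estimate",
    "region_flexibility",
]

#: named flexible regions of the two-lobe kinase architecture
DEFAULT_FLEXIBLE_REGIONS: dict[str, tuple[int, int]] = {
    "glycine_rich_loop": (30, 38),
    "L6_loop": (93, 99),
    "alphaD_helix": (113, 119),
    "activation_loop": (169, 183),
    "MAP_kinase_insert": (243, 261),
    "L16_loop": (305, 330),
}

#: floppy terminal stretches excluded from RMSF reporting by default
DEFAULT_TERMINAL_EXCLUSION: tuple[tuple[int, int], ...] = ((4, 13), (345, 354))

DEFAULT_FIT_SPEC = SelectionSpec(mode="backbone", residue_range=(14, 344))


@dataclass
class Trajectory:
    """Ordered conformations of one atom set.

    coords has shape (n_frames, n_atoms, 3) in Angstrom; frame_interval is
    the saved-frame spacing in nanoseconds (default 0.1 ns).
    """

    coords: np.ndarray
    frame_interval: float = 0.1
    atom_meta: Optional[StructureModel] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.atom_meta is not None and len(self.atom_meta) != self.coords.shape[1]:
            raise ValueError(
                f"atom_meta has {len(self.atom_meta)} atoms but frames have "
                f"{self.coords.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDSeries:
    times: np.ndarray
    values: np.ndarray
    fit_selection: SelectionSpec
    measure_selection: SelectionSpec


@dataclass
class RMSDMatrix:
    stride: float
    matrix: np.ndarray
    times: np.ndarray


@dataclass
class RMSFProfile:
    residue_numbers: np.ndarray
    values: np.ndarray


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    method: str


@dataclass
class RegionFlexibilityReport:
    regions: dict[str, tuple[int, int]]
    mean_rmsf: dict[str, float]
    protein_mean_rmsf: float
    flags: dict[str, bool]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Optional[Sequence[int]] = None,
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (Kabsch).

    Fits ``mobile[fit_indices]`` onto ``reference[fit_indices]`` and
    reports the post-fit RMSD over the fit atoms. The reflection branch
    of the SVD solution is corrected so the rotation determinant is +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    if len(idx) < 3:
        raise ValueError("need at least 3 fit atoms")
    x = mobile[idx]
    y = reference[idx]

    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # degenerate (collinear) point sets have rank-deficient covariance
    if np.linalg.matrix_rank(x0, tol=1e-9) < 2 or np.linalg.matrix_rank(y0, tol=1e-9) < 2:
        raise ValueError("fit atoms are collinear or degenerate")

    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _resolve_pair(traj: Trajectory, reference: StructureModel,
                  spec: SelectionSpec) -> np.ndarray:
    meta = traj.atom_meta if traj.atom_meta is not None else reference
    idx_t = select_atoms(meta, spec)
    idx_r = select_atoms(reference, spec)
    if len(idx_t) != len(idx_r):
        raise ValueError(
            f"selection resolves to {len(idx_t)} trajectory atoms but "
            f"{len(idx_r)} reference atoms"
        )
    return np.asarray(idx_t), np.asarray(idx_r)


def rmsd_series(
    traj: Trajectory,
    reference: StructureModel,
    fit: SelectionSpec = DEFAULT_FIT_SPEC,
    measure: Optional[SelectionSpec] = None,
) -> RMSDSeries:
    """Per-frame RMSD against a reference structure.

    Each frame is rigid-body fitted to the reference over the ``fit``
    selection (default: backbone atoms of residues 14-344), then the RMSD
    is measured over the ``measure`` selection (default: same as fit).
    """
    measure = measure if measure is not None else fit
    fit_t, fit_r = _resolve_pair(traj, reference, fit)
    mea_t, mea_r = _resolve_pair(traj, reference, measure)
    ref = reference.coords
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        sup = kabsch_superpose(frame[fit_t], ref[fit_r])
        values[i] = _rmsd(sup.apply(frame[mea_t]), ref[mea_r])
    return RMSDSeries(times=traj.times, values=values,
                      fit_selection=fit, measure_selection=measure)


def all_to_all_rmsd(
    traj: Trajectory,
    fit: SelectionSpec = DEFAULT_FIT_SPEC,
    stride: float = 1.0,
) -> RMSDMatrix:
    """Symmetric all-to-all RMSD matrix with pairwise fitting.

    ``stride`` (ns) subsamples the trajectory; it must be a positive
    multiple of the frame interval. Entry (i, j) is the RMSD after
    fitting frame j onto frame i over the fit selection.
    """
    if stride < traj.frame_interval:
        raise ValueError(
            f"stride {stride} ns is below the frame interval {traj.frame_interval} ns"
        )
    step = stride / traj.frame_interval
    if abs(step - round(step)) > 1e-9:
        raise ValueError("stride must be a multiple of the frame interval")
    step = int(round(step))
    sub = traj.coords[::step]
    times = traj.times[::step]

    if traj.atom_meta is not None:
        idx = np.asarray(select_atoms(traj.atom_meta, fit))
    else:
        idx = np.arange(traj.n_atoms)
    n = len(sub)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(sub[j][idx], sub[i][idx]).rmsd
            mat[i, j] = mat[j, i] = r
    return RMSDMatrix(stride=stride, matrix=mat, times=times)


def rmsf(
    traj: Trajectory,
    fit: SelectionSpec = DEFAULT_FIT_SPEC,
    measure: Optional[SelectionSpec] = None,
    reference: Optional[StructureModel] = None,
    trim_termini: bool = True,
) -> RMSFProfile:
    """Per-residue RMSF about time-average positions on the aligned trajectory.

    Frames are fitted to the reference (default: frame 0) over ``fit``.
    Each residue's value is the root-mean-square over its selected atoms
    and all frames of the deviation from the atom-wise mean position.
    With ``trim_termini`` (default), residues 4-13 and 345-354 are
    dropped from the profile; pass False to keep the full range.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    measure = measure if measure is not None else fit
    meta = traj.atom_meta
    if meta is None:
        raise ValueError("rmsf requires trajectory atom metadata")
    ref_coords = reference.coords if reference is not None else traj.coords[0]
    fit_idx = np.asarray(select_atoms(meta, fit))
    mea_idx = np.asarray(select_atoms(meta, measure))

    aligned = np.empty((traj.n_frames, len(mea_idx), 3))
    for i, frame in enumerate(traj.coords):
        sup = kabsch_superpose(frame[fit_idx], ref_coords[fit_idx])
        aligned[i] = sup.apply(frame[mea_idx])

    mean_pos = aligned.mean(axis=0)
    sq_dev = np.sum((aligned - mean_pos) ** 2, axis=2)  # frames x atoms

    res_of_atom = np.array([meta.atoms[i].residue_number for i in mea_idx])
    residues = []
    values = []
    for resnum in sorted(set(res_of_atom.tolist())):
        if trim_termini and any(lo <= resnum <= hi for lo, hi in DEFAULT_TERMINAL_EXCLUSION):
            continue
        cols = res_of_atom == resnum
        residues.append(resnum)
        values.append(float(np.sqrt(np.mean(sq_dev[:, cols]))))
    if not residues:
        raise ValueError("no residues left after terminal exclusion")
    return RMSFProfile(residue_numbers=np.array(residues), values=np.array(values))


# ---------------------------------------------------------------------------
# Densities and region reports
# ---------------------------------------------------------------------------

def density_estimate(
    samples: Sequence[float],
    method: str = "kernel",
    n_grid: int = 512,
) -> DensityEstimate:
    """Probability-density estimate of a 1-D sample.

    Gaussian KDE with Scott's bandwidth by default; a histogram is used
    on request or as the fallback for degenerate (all-identical) input.
    The returned density is non-negative and integrates to 1 over the
    grid to within 1e-3.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("density_estimate requires at least 2 finite samples")
    if method not in ("kernel", "histogram"):
        raise ValueError(f"unknown method {method!r}")

    if method == "kernel":
        if np.ptp(x) < 1e-12:
            logger.warning("degenerate sample for KDE; falling back to histogram")
            method = "histogram"
        else:
            kde = stats.gaussian_kde(x, bw_method="scott")
            pad = 3.0 * x.std()
            grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
            dens = kde(grid)
            dens = np.clip(dens, 0.0, None)
            dens /= np.trapezoid(dens, grid)
            return DensityEstimate(grid=grid, density=dens, method="kernel")

    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        lo, hi = lo - 0.5, hi + 0.5
    hist, edges = np.histogram(x, bins=min(64, max(8, len(x) // 4)),
                               range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = np.trapezoid(hist, centers)
    if area > 0:
        hist = hist / area  # renormalize on the center grid
    return DensityEstimate(grid=centers, density=hist, method="histogram")


def region_flexibility(
    profile: RMSFProfile,
    regions: Optional[dict[str, tuple[int, int]]] = None,
) -> RegionFlexibilityReport:
    """Mean RMSF per named region, flagged when above the profile mean.

    The packaged default region set covers the six flexible elements of
    the two-lobe kinase: glycine-rich loop 30-38, L6 loop 93-99, alphaD
    helix 113-119, activation loop 169-183, MAP kinase insert 243-261,
    L16 loop 305-330.
    """
    regions = regions if regions is not None else dict(DEFAULT_FLEXIBLE_REGIONS)
    resnums = profile.residue_numbers
    overall = float(np.mean(profile.values))
    means: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for name, (lo, hi) in regions.items():
        mask = (resnums >= lo) & (resnums <= hi)
        if not mask.any():
            raise ValueError(f"region {name} [{lo}, {hi}] outside profile domain")
        means[name] = float(np.mean(profile.values[mask]))
        flags[name] = means[name] > overall
    return RegionFlexibilityReport(
        regions=regions, mean_rmsf=means, protein_mean_rmsf=overall, flags=flags
    )
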