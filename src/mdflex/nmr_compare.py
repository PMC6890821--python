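"""Comparison of simulated ensembles against experimental NMR observables.

Record matching is strictly by key intersection; ensemble averaging,
ordinary least-squares regression reports with ranked outliers, and
per-snapshot Pearson-correlation densities are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .traj_metrics import DensityEstimate, density_estimate

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftRecord",
    "RDCRecord",
    "RegressionReport",
    "CorrelationDensity",
    "ALIGNMENT_MEDIUM_METADATA",
    "load_observable_table",
    "ensemble_average",
    "regress_observables",
    "per_snapshot_correlation",
]

SHIFT_ATOM_TYPES = frozenset({"CA", "CB", "C", "N", "H"})

#: provenance only — alignment-medium settings under which the packaged
#: experimental RDCs were measured/back-calculated; never used numerically.
ALIGNMENT_MEDIUM_METADATA = {
    "medium": "bacteriophage Pf1",
    "concentration_mg_per_ml": 20.0,
    "pH": 6.0,
    "NaCl_M": 0.2,
}


@dataclass(frozen=True)
class ShiftRecord:
    residue_number: int
    atom_type: str
    shift: float                     # ppm
    source: str = "experimental"     # or "predicted"
    snapshot_time: Optional[float] = None  # ns, predicted only

    def __post_init__(self):
        if self.atom_type not in SHIFT_ATOM_TYPES:
            raise ValueError(f"atom_type must be one of {sorted(SHIFT_ATOM_TYPES)}")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")


@dataclass(frozen=True)
class RDCRecord:
    residue_number: int
    residue_name: str
    rdc: float                       # Hz

    def __post_init__(self):
        if not np.isfinite(self.rdc):
            raise ValueError("rdc must be finite")


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    outliers: list[tuple[object, float]]  # (key, absolute residual), descending
    n_unmatched_sim: int = 0
    n_unmatched_exp: int = 0


@dataclass
class CorrelationDensity:
    r_values: np.ndarray
    density: DensityEstimate


# ---------------------------------------------------------------------------

def load_observable_table(
    path: Union[str, Path], kind: str
) -> list[Union[ShiftRecord, RDCRecord]]:
    """Load a TSV observable table into typed records.

    ``kind='rdc'`` expects columns (residue_number, residue_name, rdc_hz);
    ``kind='shifts'`` expects (residue_number, atom_type, shift_ppm) plus
    optional (source, snapshot_time). Duplicate keys are rejected;
    non-numeric values raise a parse error naming the data line.
    """
    if kind not in ("shifts", "rdc"):
        raise ValueError(f"unknown observable kind {kind!r}")
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        logger.warning("%s: empty observable table", path)
        return []
    header = lines[0].split("\t")
    records: list = []
    seen: set = set()
    for lineno, line in enumerate(lines[1:], start=2):
        row = dict(zip(header, line.split("\t")))
        try:
            if kind == "rdc":
                rec = RDCRecord(
                    residue_number=int(row["residue_number"]),
                    residue_name=str(row["residue_name"]).upper(),
                    rdc=float(row["rdc_hz"]),
                )
                key = rec.residue_number
            else:
                st = row.get("snapshot_time", "")
                rec = ShiftRecord(
                    residue_number=int(row["residue_number"]),
                    atom_type=str(row["atom_type"]).upper(),
                    shift=float(row["shift_ppm"]),
                    source=row.get("source", "experimental"),
                    snapshot_time=float(st) if st not in ("", None) else None,
                )
                key = (rec.residue_number, rec.atom_type, rec.snapshot_time)
        except KeyError as exc:
            raise ValueError(f"{path}: missing column {exc} for kind {kind!r}") from exc
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc
        if key in seen:
            raise ValueError(f"{path} line {lineno}: duplicate key {key}")
        seen.add(key)
        records.append(rec)
    return records


def ensemble_average(
    predicted: Sequence[ShiftRecord],
    return_counts: bool = False,
):
    """Arithmetic mean of predicted shifts per (residue, atom) over snapshots.

    With ``return_counts=True`` also returns the per-key count of
    contributing snapshots.
    """
    if not predicted:
        raise ValueError("no predicted records")
    sums: dict[tuple[int, str], float] = {}
    counts: dict[tuple[int, str], int] = {}
    for rec in predicted:
        key = (rec.residue_number, rec.atom_type)
        sums[key] = sums.get(key, 0.0) + rec.shift
        counts[key] = counts.get(key, 0) + 1
    means = {k: sums[k] / counts[k] for k in sums}
    if return_counts:
        return means, counts
    return means


def regress_observables(
    sim: Mapping[object, float],
    exp: Mapping[object, float],
    top_k: int = 6,
) -> RegressionReport:
    """OLS regression of experimental (y) on simulated (x) observables.

    Only keys present on both sides enter the fit; unmatched records are
    counted and logged, never silently included. r-squared is the squared
    Pearson correlation; outliers are the top-k keys by absolute residual
    from the fitted line, largest first.
    """
    keys = sorted(set(sim) & set(exp), key=repr)
    n_unmatched_sim = len(set(sim) - set(exp))
    n_unmatched_exp = len(set(exp) - set(sim))
    if n_unmatched_sim or n_unmatched_exp:
        logger.info("regress_observables: %d sim-only and %d exp-only keys ignored",
                    n_unmatched_sim, n_unmatched_exp)
    if len(keys) < 2:
        raise ValueError(f"need >= 2 matched keys, got {len(keys)}")
    x = np.array([sim[k] for k in keys], dtype=float)
    y = np.array([exp[k] for k in keys], dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate fit: zero variance in simulated values")
    res = stats.linregress(x, y)
    resid = np.abs(y - (res.slope * x + res.intercept))
    order = np.argsort(-resid, kind="stable")
    k = min(top_k, len(keys))
    outliers = [(keys[i], float(resid[i])) for i in order[:k]]
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        n_points=len(keys),
        outliers=outliers,
        n_unmatched_sim=n_unmatched_sim,
        n_unmatched_exp=n_unmatched_exp,
    )


def per_snapshot_correlation(
    sim_by_snapshot: Mapping[object, Mapping[object, float]],
    exp: Mapping[object, float],
    density_method: str = "kernel",
) -> CorrelationDensity:
    """Pearson R between each snapshot's simulated values and experiment,
    with a probability-density estimate of the R distribution."""
    if not sim_by_snapshot:
        raise ValueError("no snapshots")
    r_values = []
    for snap in sorted(sim_by_snapshot, key=repr):
        sim = sim_by_snapshot[snap]
        keys = sorted(set(sim) & set(exp), key=repr)
        if len(keys) < 2:
            raise ValueError(f"snapshot {snap!r} has fewer than 2 matched keys")
        x = np.array([sim[k] for k in keys], dtype=float)
        y = np.array([exp[k] for k in keys], dtype=float)
        if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
            r = 0.0
        else:
            r = float(stats.pearsonr(x, y).statistic)
        r_values.append(r)
    r_arr = np.clip(np.array(r_values), -1.0, 1.0)
    if len(r_arr) >= 2 and np.ptp(r_arr) > 1e-12:
        dens = density_estimate(r_arr, method=density_method)
    else:
        dens = density_estimate(np.concatenate([r_arr, r_arr]), method="histogram")
    return CorrelationDensity(r_values=r_arr, density=dens)
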