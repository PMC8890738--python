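"""Landmark-RMSE accuracy, robustness, and the multi-method benchmark.

Registration accuracy is scored as the root mean squared Euclidean distance
(in mm) between the fixed-image fiducials and the moving-image fiducials
mapped into fixed space.  Because the registration transform follows the
resampling convention (fixed-domain points into moving space), the moving
landmarks are mapped through its inverse.  Robustness is the fraction of
registration attempts that produced a valid result.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .rigid_transform import RigidTransform, invert, transform_points
from .volume_model import LandmarkSet

__all__ = [
    "TrialRecord",
    "RobustnessReport",
    "landmark_rmse",
    "robustness",
    "run_benchmark",
    "summarize_benchmark",
]


def landmark_rmse(T: RigidTransform, fixed_lms: LandmarkSet,
                  moving_lms: LandmarkSet) -> float:
    """RMSE in mm between fixed landmarks and inverse-mapped moving ones.

    ``T`` maps fixed-domain points into the moving image, so the moving
    landmarks come back through ``invert(T)``.  Landmark sets are matched
    by label; a mismatch raises with the offending labels listed.
    """
    missing = [l for l in fixed_lms.labels if l not in moving_lms.labels]
    extra = [l for l in moving_lms.labels if l not in fixed_lms.labels]
    if missing or extra:
        raise ValueError(
            f"landmark label mismatch: missing from moving {missing}, "
            f"unmatched in moving {extra}"
        )
    if len(fixed_lms) == 0:
        raise ValueError("cannot score an empty landmark set")
    moving_pts = np.array([moving_lms[l] for l in fixed_lms.labels])
    mapped = transform_points(invert(T), moving_pts)
    sq = np.sum((mapped - fixed_lms.points) ** 2, axis=1)
    return float(np.sqrt(np.mean(sq)))


@dataclass
class RobustnessReport:
    n_success: int
    n_fail: int

    @property
    def ratio(self) -> float:
        return robustness(self.n_success, self.n_fail)


def robustness(n_success: int, n_fail: int) -> float:
    """Fraction of attempts with a valid result: Ns / (Ns + Nf)."""
    if n_success < 0 or n_fail < 0:
        raise ValueError("counts must be non-negative")
    total = n_success + n_fail
    if total == 0:
        raise ValueError("robustness undefined for zero attempts")
    return n_success / total


@dataclass
class TrialRecord:
    pair_id: str
    group: str
    method: str
    repeat: int
    rmse_mm: Optional[float]
    elapsed_s: float
    status: str

    def __post_init__(self):
        if (self.rmse_mm is not None) != (self.status == "success"):
            raise ValueError("rmse must be present exactly when status is success")


def run_benchmark(pairs, methods, repeats: int = 3, config=None,
                  seed: int = 0) -> pd.DataFrame:
    """Register every (pair, method, repeat) and tabulate the outcomes.

    Each repeat re-runs the stochastic registration with a distinct seed
    under the same iteration budget; individual failures are recorded as
    rows with status "failed" and no RMSE, never aborting the sweep.
    Returns one row per trial; see :func:`summarize_benchmark` for the
    per-method / per-group roll-up.
    """
    from .pipeline import RegistrationConfig, register

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    base = config or RegistrationConfig()
    rows = []
    for pair in pairs:
        for method in methods:
            for rep in range(repeats):
                cfg = base.with_updates(
                    optimizer=method,
                    seed=(seed + 10_000 * rep
                          + zlib.crc32(pair.pair_id.encode()) % 9973)
                    % (2 ** 31 - 1),
                )
                t0 = time.perf_counter()
                result = register(pair.fixed, pair.moving,
                                  pair.fixed_seed_point,
                                  pair.moving_seed_point, cfg)
                elapsed = time.perf_counter() - t0
                ok = result.status == "success"
                rmse = (landmark_rmse(result.transform, pair.fixed_lms,
                                      pair.moving_lms) if ok else None)
                rows.append(TrialRecord(
                    pair_id=pair.pair_id, group="-".join(pair.group),
                    method=method, repeat=rep, rmse_mm=rmse,
                    elapsed_s=elapsed, status=result.status,
                ).__dict__)
    return pd.DataFrame(rows)


def summarize_benchmark(records: pd.DataFrame,
                        reference: str = "slbfgs") -> pd.DataFrame:
    """Per-method summary: N, mean/SD RMSE, mean time, robustness, p-value.

    A pure function of the trial table (recomputable bit-exactly from its
    CSV).  RMSE statistics are over successful trials after averaging the
    repeats of each pair, mirroring a repeated-measures protocol; the
    p-value is a two-sided Welch t-test of each method's per-trial RMSE
    against the reference method (reporting only).
    """
    out = []
    ref_vals = records.query("method == @reference").dropna(subset=["rmse_mm"])
    for method, grp in records.groupby("method", sort=False):
        ok = grp.dropna(subset=["rmse_mm"])
        per_pair = ok.groupby("pair_id")["rmse_mm"].mean()
        n_success = int((grp.status == "success").sum())
        n_fail = int((grp.status != "success").sum())
        if method == reference or len(ok) < 2 or len(ref_vals) < 2:
            pval = np.nan
        else:
            pval = stats.ttest_ind(ok.rmse_mm, ref_vals.rmse_mm,
                                   equal_var=False).pvalue
        out.append({
            "method": method,
            "n_trials": len(grp),
            "rmse_mean_mm": per_pair.mean() if len(per_pair) else np.nan,
            "rmse_sd_mm": per_pair.std(ddof=1) if len(per_pair) > 1 else np.nan,
            "time_mean_s": grp.elapsed_s.mean(),
            "robustness": robustness(n_success, n_fail),
            "p_vs_reference": pval,
        })
    return pd.DataFrame(out)
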