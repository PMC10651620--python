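"""Per-subject annual rates of change and the four decline phenotypes.

Each subject's annual rate of change in verbal memory (CVLT points/year) and
usual gait speed (m/s/year) is the ordinary least-squares slope of the
outcome on time across their eligible visits.  Subjects are then classified
by the lowest tertile of each slope distribution: in the lowest tertile of
both → ``dual_decline``; of memory only → ``memory_decline_only``; of gait
only → ``gait_decline_only``; of neither → ``no_decline``.

All logic uses signed slopes: a published "decline of 0.67 points/year"
corresponds to the signed cut-point −0.67, and a subject declines on an
outcome iff slope ≤ cut (ties fall in the declining tertile).  For subjects
with a dementia onset time, visits at and after onset are excluded by
default, since the phenotype targets pre-diagnosis decline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset

__all__ = [
    "SlopeEstimate",
    "Cutpoints",
    "estimate_annual_slopes",
    "tertile_cutpoints",
    "classify_phenotypes",
]

LABELS = ["no_decline", "memory_decline_only", "gait_decline_only", "dual_decline"]


@dataclass(frozen=True)
class Cutpoints:
    """Signed slope cut-points at the lower tertile boundary."""

    memory_cut: float  # points/year
    gait_cut: float    # m/s/year

    def __post_init__(self) -> None:
        if not (np.isfinite(self.memory_cut) and np.isfinite(self.gait_cut)):
            raise ValueError("cut-points must be finite")


@dataclass(frozen=True)
class SlopeEstimate:
    subject_id: str
    memory_slope: float
    gait_slope: float
    n_points_memory: int
    n_points_gait: int


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Simple linear regression slope b = Σ(t−t̄)(y−ȳ) / Σ(t−t̄)²."""
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        return np.nan
    return float(tc @ (y - y.mean()) / denom)


def estimate_annual_slopes(
    dataset: CohortDataset,
    min_visits: int = 2,
    exclude_post_dementia: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject OLS slopes of memory and gait on time.

    Returns ``(slopes, log)``: one row per subject with both slopes
    estimable from at least ``min_visits`` eligible points, and a log of
    omitted subjects with reasons.  With ``exclude_post_dementia``, visits at
    time ≥ the subject's dementia onset are dropped first.
    """
    if min_visits < 2:
        raise ValueError("min_visits must be at least 2")
    onset = dataset.subjects.set_index("subject_id")["dementia_onset_time"]
    out, omitted = [], []
    for sid, g in dataset.visits.groupby("subject_id", sort=True):
        if exclude_post_dementia and pd.notna(onset.get(sid, np.nan)):
            g = g[g["time_years"] < onset[sid]]
        res = {}
        for col, key in (("memory_score", "memory"), ("gait_speed_mps", "gait")):
            gg = g.dropna(subset=[col])
            t = gg["time_years"].to_numpy(float)
            y = gg[col].to_numpy(float)
            if len(t) < min_visits:
                res[key] = (np.nan, len(t), f"{key}: fewer than {min_visits} points")
                continue
            b = _ols_slope(t, y)
            if np.isnan(b):
                res[key] = (np.nan, len(t), f"{key}: all visits at identical time")
            else:
                res[key] = (b, len(t), None)
        reasons = [r for _, _, r in res.values() if r]
        if reasons:
            omitted.append({"subject_id": sid, "reason": "; ".join(reasons)})
        else:
            out.append(
                {
                    "subject_id": sid,
                    "memory_slope": res["memory"][0],
                    "gait_slope": res["gait"][0],
                    "n_points_memory": res["memory"][1],
                    "n_points_gait": res["gait"][1],
                }
            )
    slopes = pd.DataFrame(
        out, columns=["subject_id", "memory_slope", "gait_slope", "n_points_memory", "n_points_gait"]
    )
    log = pd.DataFrame(omitted, columns=["subject_id", "reason"])
    return slopes, log


def tertile_cutpoints(slopes: pd.DataFrame) -> Cutpoints:
    """33⅓rd empirical percentile (linear interpolation) of each signed slope."""
    if len(slopes) < 3:
        raise ValueError("at least 3 subjects are required to form tertiles")
    mem = np.quantile(slopes["memory_slope"].to_numpy(float), 1.0 / 3.0)
    gait = np.quantile(slopes["gait_slope"].to_numpy(float), 1.0 / 3.0)
    return Cutpoints(memory_cut=float(mem), gait_cut=float(gait))


def classify_phenotypes(
    slopes: pd.DataFrame, cutpoints: Cutpoints
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each subject one of the four phenotype labels.

    Memory-declining iff ``memory_slope ≤ memory_cut``; gait-declining iff
    ``gait_slope ≤ gait_cut``.  The four labels partition all classified
    subjects.  Subjects with a missing slope are omitted and logged.
    """
    rows, omitted = [], []
    for rec in slopes.itertuples(index=False):
        ms, gs = rec.memory_slope, rec.gait_slope
        if not (np.isfinite(ms) and np.isfinite(gs)):
            omitted.append({"subject_id": rec.subject_id, "reason": "missing slope"})
            continue
        mem_dec = ms <= cutpoints.memory_cut
        gait_dec = gs <= cutpoints.gait_cut
        if mem_dec and gait_dec:
            label = "dual_decline"
        elif mem_dec:
            label = "memory_decline_only"
        elif gait_dec:
            label = "gait_decline_only"
        else:
            label = "no_decline"
        rows.append({"subject_id": rec.subject_id, "label": label})
    labels = pd.DataFrame(rows, columns=["subject_id", "label"])
    log = pd.DataFrame(omitted, columns=["subject_id", "reason"])
    return labels, log
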