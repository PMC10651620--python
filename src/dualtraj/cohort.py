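"""Cohort data model, file I/O, validation, and baseline eligibility filtering.

The study object is a :class:`CohortDataset`: a table of subjects (one row
each, with baseline covariates), a long table of visits (memory score, gait
speed, calendar year on a per-subject time axis in years), and a
:class:`MetabolitePanel` holding visit-aligned metabolite concentrations in
µM together with per-metabolite class labels and limits of detection (LOD).

Concentrations are stored as measured (µM); log2 transformation, censored
imputation and all modeling live downstream.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "IntegrityError",
    "NoEligibleSubjectsError",
    "MetabolitePanel",
    "CohortDataset",
    "read_cohort",
    "write_cohort",
    "apply_baseline_filters",
    "write_results",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "sex",
    "race",
    "education_years",
    "apoe4_carrier",
    "baseline_age_years",
    "dementia_onset_time",
]
VISIT_COLUMNS = [
    "subject_id",
    "time_years",
    "calendar_year",
    "gait_speed_mps",
    "memory_score",
]
MEMORY_RANGE = (0.0, 80.0)  # CVLT immediate-recall total score range


class SchemaError(ValueError):
    """A required column is missing or has an unusable type."""


class IntegrityError(ValueError):
    """Referential integrity between tables is violated."""


class NoEligibleSubjectsError(ValueError):
    """Baseline filtering removed every subject."""


@dataclass
class MetabolitePanel:
    """Visit-aligned quantified metabolite panel.

    Parameters
    ----------
    concentrations
        DataFrame indexed by ``(subject_id, time_years)`` with one column per
        metabolite, values in µM (``>= 0``).  Rows correspond one-to-one to
        visits at which metabolomics was assayed.
    meta
        DataFrame indexed by metabolite name with columns ``class_label``
        (Biocrates-style class) and ``lod`` (µM, ``> 0``).
    below_lod
        Boolean DataFrame, same shape as ``concentrations``; True marks a
        left-censored (below-LOD) measurement.
    """

    concentrations: pd.DataFrame
    meta: pd.DataFrame
    below_lod: pd.DataFrame

    @property
    def metabolites(self) -> list[str]:
        return list(self.concentrations.columns)

    def validate(self) -> None:
        if list(self.concentrations.columns) != list(self.meta.index):
            raise SchemaError("panel columns do not match metabolite metadata rows")
        for col in ("class_label", "lod"):
            if col not in self.meta.columns:
                raise SchemaError(f"metabolite metadata missing column {col!r}")
        lod = self.meta["lod"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lod)) or np.any(lod <= 0):
            raise SchemaError("every LOD must be finite and positive")
        if self.below_lod.shape != self.concentrations.shape:
            raise SchemaError("below_lod mask shape mismatch")
        vals = self.concentrations.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise SchemaError("negative concentration encountered")

    def copy(self) -> "MetabolitePanel":
        return MetabolitePanel(
            self.concentrations.copy(), self.meta.copy(), self.below_lod.copy()
        )

    def equals(self, other: "MetabolitePanel") -> bool:
        try:
            pd.testing.assert_frame_equal(self.concentrations, other.concentrations)
            pd.testing.assert_frame_equal(self.meta, other.meta)
            pd.testing.assert_frame_equal(self.below_lod, other.below_lod)
        except AssertionError:
            return False
        return True


@dataclass
class CohortDataset:
    """Subjects + visits + metabolite panel: the single in-memory study object."""

    subjects: pd.DataFrame
    visits: pd.DataFrame
    panel: MetabolitePanel | None = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "CohortDataset":
        for col in SUBJECT_COLUMNS:
            if col not in self.subjects.columns:
                raise SchemaError(f"subjects table missing column {col!r}")
        for col in VISIT_COLUMNS:
            if col not in self.visits.columns:
                raise SchemaError(f"visits table missing column {col!r}")
        if self.subjects["subject_id"].duplicated().any():
            dup = self.subjects.loc[self.subjects["subject_id"].duplicated(), "subject_id"]
            raise IntegrityError(f"duplicate subject_id: {sorted(set(dup))}")
        if not np.all(np.isfinite(self.subjects["baseline_age_years"].to_numpy(float))):
            raise SchemaError("baseline_age_years must be finite")
        known = set(self.subjects["subject_id"])
        orphan = set(self.visits["subject_id"]) - known
        if orphan:
            raise IntegrityError(f"visits reference unknown subjects: {sorted(orphan)}")
        if self.visits.duplicated(["subject_id", "time_years"]).any():
            raise IntegrityError("duplicate (subject_id, time_years) visit")
        mem = self.visits["memory_score"].dropna()
        if ((mem < MEMORY_RANGE[0]) | (mem > MEMORY_RANGE[1])).any():
            raise SchemaError(
                f"memory_score outside instrument range {MEMORY_RANGE}"
            )
        gait = self.visits["gait_speed_mps"].dropna()
        if (gait <= 0).any():
            raise SchemaError("gait_speed_mps must be positive")
        if self.panel is not None:
            self.panel.validate()
            visit_keys = set(
                zip(self.visits["subject_id"], self.visits["time_years"])
            )
            panel_keys = set(self.panel.concentrations.index)
            missing = panel_keys - visit_keys
            if missing:
                raise IntegrityError(
                    f"panel rows reference visits not in visit table: {sorted(missing)[:5]}"
                )
        return self

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            self.subjects.copy(),
            self.visits.copy(),
            None if self.panel is None else self.panel.copy(),
            dict(self.provenance),
        )

    def equals(self, other: "CohortDataset") -> bool:
        """Field-level equality of the three tables (provenance ignored)."""
        try:
            pd.testing.assert_frame_equal(
                self.subjects.reset_index(drop=True),
                other.subjects.reset_index(drop=True),
            )
            pd.testing.assert_frame_equal(
                self.visits.reset_index(drop=True),
                other.visits.reset_index(drop=True),
            )
        except AssertionError:
            return False
        if (self.panel is None) != (other.panel is None):
            return False
        if self.panel is not None and not self.panel.equals(other.panel):
            return False
        return True


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _read_table(path: str | os.PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{os.path.basename(str(path))}: missing column {col!r}")
    return df


def read_cohort(
    subjects_path: str | os.PathLike,
    visits_path: str | os.PathLike,
    panel_path: str | os.PathLike | None = None,
    meta_path: str | os.PathLike | None = None,
) -> CohortDataset:
    """Read and validate a cohort from delimited text files.

    ``subjects_path`` and ``visits_path`` follow the documented schemas
    (:data:`SUBJECT_COLUMNS`, :data:`VISIT_COLUMNS`).  ``panel_path`` is a wide
    table (``subject_id``, ``time_years``, one column per metabolite);
    ``meta_path`` maps metabolite name to class label and LOD.  Delimiter is
    inferred from the extension (``.tsv``/``.txt`` tab, otherwise comma).
    Below-LOD flags are set wherever a concentration falls below that
    metabolite's LOD.
    """
    subjects = _read_table(subjects_path, [c for c in SUBJECT_COLUMNS if c != "dementia_onset_time"])
    if "dementia_onset_time" not in subjects.columns:
        subjects["dementia_onset_time"] = np.nan
    subjects = subjects[SUBJECT_COLUMNS].astype(
        {
            "subject_id": str,
            "sex": str,
            "race": str,
            "education_years": float,
            "apoe4_carrier": bool,
            "baseline_age_years": float,
            "dementia_onset_time": float,
        }
    )
    visits = _read_table(visits_path, VISIT_COLUMNS)[VISIT_COLUMNS].astype(
        {
            "subject_id": str,
            "time_years": float,
            "calendar_year": float,
            "gait_speed_mps": float,
            "memory_score": float,
        }
    )

    panel = None
    if panel_path is not None:
        if meta_path is None:
            raise SchemaError("panel_path given without meta_path")
        conc = _read_table(panel_path, ["subject_id", "time_years"])
        conc["subject_id"] = conc["subject_id"].astype(str)
        conc = conc.set_index(["subject_id", "time_years"])
        conc = conc.astype(float)
        meta = _read_table(meta_path, ["metabolite", "class_label", "lod"])
        meta = meta.set_index("metabolite")
        meta.index = meta.index.astype(str)
        missing = [m for m in conc.columns if m not in meta.index]
        if missing:
            raise SchemaError(f"metabolite metadata missing entries for {missing[:5]}")
        meta = meta.loc[list(conc.columns), ["class_label", "lod"]]
        below = conc.lt(meta["lod"], axis=1)
        panel = MetabolitePanel(conc, meta, below)

    ds = CohortDataset(
        subjects,
        visits,
        panel,
        provenance={"subjects_path": str(subjects_path), "visits_path": str(visits_path)},
    )
    return ds.validate()


def write_cohort(dataset: CohortDataset, out_dir: str | os.PathLike, sep: str = ",") -> dict[str, str]:
    """Write a cohort to ``subjects/visits/metabolites/metabolite_meta`` files.

    Returns a mapping of table name to written path.  Output round-trips
    through :func:`read_cohort` with field-level equality.
    """
    os.makedirs(out_dir, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame, index: bool) -> None:
        path = os.path.join(str(out_dir), name + ext)
        df.to_csv(path, sep=sep, index=index)
        paths[name] = path

    _write("subjects", dataset.subjects, index=False)
    _write("visits", dataset.visits, index=False)
    if dataset.panel is not None:
        _write("metabolites", dataset.panel.concentrations.reset_index(), index=False)
        meta = dataset.panel.meta.reset_index().rename(columns={"index": "metabolite"})
        if "metabolite" not in meta.columns:
            meta = meta.rename(columns={meta.columns[0]: "metabolite"})
        _write("metabolite_meta", meta, index=False)
    return paths


def _baseline_visits(dataset: CohortDataset) -> pd.DataFrame:
    """First visit per subject with concurrent metabolomics, memory, and gait.

    Returns one row per subject that has such a visit, with columns of the
    visit table plus ``age_at_baseline``.
    """
    if dataset.panel is not None:
        panel_keys = set(dataset.panel.concentrations.index)
        has_metab = [
            (s, t) in panel_keys
            for s, t in zip(dataset.visits["subject_id"], dataset.visits["time_years"])
        ]
    else:
        has_metab = [True] * len(dataset.visits)
    v = dataset.visits.loc[
        np.asarray(has_metab)
        & dataset.visits["memory_score"].notna().to_numpy()
        & dataset.visits["gait_speed_mps"].notna().to_numpy()
    ]
    v = v.sort_values(["subject_id", "time_years"])
    base = v.groupby("subject_id", as_index=False).first()
    age0 = dataset.subjects.set_index("subject_id")["baseline_age_years"]
    base["age_at_baseline"] = (
        age0.reindex(base["subject_id"]).to_numpy() + base["time_years"].to_numpy()
    )
    return base


def apply_baseline_filters(
    dataset: CohortDataset,
    min_age: float = 50.0,
    min_gait: float = 0.6,
    require_covariates: bool = True,
) -> tuple[CohortDataset, pd.DataFrame]:
    """Apply the cohort's baseline eligibility criteria.

    "Baseline" is each subject's first visit with concurrent metabolomics,
    memory and gait data.  A subject is excluded when no such visit exists,
    when age at baseline is below ``min_age`` (default 50), when baseline gait
    speed is below ``min_gait`` (default 0.6 m/s), or — with
    ``require_covariates`` — when any baseline covariate is missing.  Visits
    before a subject's baseline are dropped.  Returns the filtered copy and an
    exclusion log with one row per removed subject and the reasons.

    Idempotent: filtering a filtered cohort changes nothing.
    """
    dataset.validate()
    base = _baseline_visits(dataset).set_index("subject_id")
    reasons: dict[str, list[str]] = {}
    covar_cols = ["sex", "race", "education_years", "apoe4_carrier", "baseline_age_years"]
    subj = dataset.subjects.set_index("subject_id")
    for sid in dataset.subjects["subject_id"]:
        r: list[str] = []
        if sid not in base.index:
            r.append("no concurrent baseline")
        else:
            row = base.loc[sid]
            if row["gait_speed_mps"] < min_gait:
                r.append(f"gait<{min_gait:g}")
            if row["age_at_baseline"] < min_age:
                r.append(f"age<{min_age:g}")
        if require_covariates:
            srow = subj.loc[sid, covar_cols]
            if srow.isna().any() or any(
                isinstance(x, str) and x.strip() == "" for x in srow
            ):
                r.append("missing covariates")
        if r:
            reasons[sid] = r

    keep = [s for s in dataset.subjects["subject_id"] if s not in reasons]
    if not keep:
        raise NoEligibleSubjectsError("no eligible subjects after baseline filtering")

    out = dataset.copy()
    out.subjects = out.subjects[out.subjects["subject_id"].isin(keep)].reset_index(drop=True)
    base_time = base["time_years"]
    vmask = out.visits["subject_id"].isin(keep) & (
        out.visits["time_years"].to_numpy()
        >= base_time.reindex(out.visits["subject_id"]).to_numpy()
    )
    out.visits = out.visits[vmask].reset_index(drop=True)
    if out.panel is not None:
        vkeys = set(zip(out.visits["subject_id"], out.visits["time_years"]))
        rmask = [k in vkeys for k in out.panel.concentrations.index]
        out.panel = MetabolitePanel(
            out.panel.concentrations.loc[rmask],
            out.panel.meta,
            out.panel.below_lod.loc[rmask],
        )
    log = pd.DataFrame(
        {
            "subject_id": list(reasons),
            "reason": ["; ".join(v) for v in reasons.values()],
        }
    )
    out.provenance = dict(dataset.provenance, baseline_filtered=True)
    return out.validate(), log


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    manifest: Mapping | None = None,
) -> dict[str, str]:
    """Write result tables as TSV with stable column order plus a JSON manifest."""
    if not tables:
        raise ValueError("no tables to write")
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    for name, df in tables.items():
        path = os.path.join(str(out_dir), f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    if manifest is not None:
        mpath = os.path.join(str(out_dir), "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=str)
        paths["manifest"] = mpath
    return paths
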