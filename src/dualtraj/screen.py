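"""Per-metabolite longitudinal mixed-effects screening with FDR control.

Each log2 metabolite (or log2 ratio) is regressed on phenotypic group,
time, and group×time interactions, adjusting for baseline age, sex, race,
education, APOE ε4 carrier status, baseline gait speed, baseline memory,
and calendar year, with a subject-level random intercept (REML).  Time is
anchored so each subject's most recent metabolomics assessment is 0 and
earlier visits are negative years; the group×time coefficient is therefore
the group's extra annual rate of change relative to ``no_decline``.

Tests reported per metabolite:

* omnibus — joint 6-df Wald chi-square that all three group main effects
  and all three group×time interactions are zero (cross-sectional plus
  longitudinal differences);
* pairwise — Wald z on each declining group's interaction coefficient.

Benjamini–Hochberg step-up q-values are computed within each test family
across all kept metabolites; non-converged fits carry NA p-values and do
not count toward the family size.  Ratio biomarkers go through the same
models but are judged at raw p < 0.05 without FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .cohort import CohortDataset, _baseline_visits
from .phenotype import LABELS

__all__ = [
    "anchor_time",
    "LongitudinalDesign",
    "build_design",
    "FittedLME",
    "fit_metabolite_lme",
    "omnibus_group_test",
    "pairwise_longitudinal_contrast",
    "bh_adjust",
    "screen_all",
]

CONTRAST_GROUPS = ["memory_decline_only", "gait_decline_only", "dual_decline"]


def anchor_time(
    frame: pd.DataFrame,
    time_col: str = "time_years",
    group_col: str = "subject_id",
) -> pd.DataFrame:
    """Shift each subject's times so the most recent is 0 (earlier negative).

    Idempotent: anchoring an anchored table changes nothing.
    """
    out = frame.copy()
    out[time_col] = out[time_col] - out.groupby(group_col)[time_col].transform("max")
    return out


@dataclass
class LongitudinalDesign:
    """Fixed-effects design shared by every response in a screen.

    ``exog`` rows align with the metabolomics visits (the index of the
    processed panel); ``groups`` holds the subject id per row for the random
    intercept.  ``omnibus_columns`` lists the 3 group-main and 3 group×time
    columns; ``interaction_column`` maps each declining group to its
    group×time column.
    """

    exog: pd.DataFrame
    groups: np.ndarray
    omnibus_columns: list[str]
    interaction_column: dict[str, str]


def build_design(
    dataset: CohortDataset,
    labels: pd.DataFrame,
    panel_index: pd.MultiIndex,
    anchor: bool = True,
) -> LongitudinalDesign:
    """Assemble the fixed-effects matrix for the metabolomics visits.

    ``labels`` is the phenotype table (``subject_id``, ``label``); subjects
    without a label are dropped from the design.  Race enters as a
    categorical factor with the largest level as reference; calendar year is
    centered at its sample mean.
    """
    rows = pd.DataFrame(
        {"subject_id": panel_index.get_level_values(0),
         "time_years": panel_index.get_level_values(1)}
    )
    if anchor:
        rows = anchor_time(rows)
    lab = labels.set_index("subject_id")["label"]
    rows["group"] = lab.reindex(rows["subject_id"]).to_numpy()

    subj = dataset.subjects.set_index("subject_id")
    base = _baseline_visits(dataset).set_index("subject_id")
    v = dataset.visits.set_index(["subject_id", "time_years"])
    rows["calendar_year"] = v["calendar_year"].reindex(panel_index).to_numpy()
    for col in ("baseline_age_years", "education_years"):
        rows[col] = subj[col].reindex(rows["subject_id"]).to_numpy()
    rows["male"] = (subj["sex"].reindex(rows["subject_id"]) == "male").to_numpy(float)
    rows["apoe4"] = subj["apoe4_carrier"].reindex(rows["subject_id"]).to_numpy(float)
    rows["race"] = subj["race"].reindex(rows["subject_id"]).to_numpy()
    rows["baseline_gait"] = base["gait_speed_mps"].reindex(rows["subject_id"]).to_numpy()
    rows["baseline_memory"] = base["memory_score"].reindex(rows["subject_id"]).to_numpy()

    keep = rows["group"].notna().to_numpy()
    rows = rows[keep]

    exog = pd.DataFrame(index=rows.index)
    exog["Intercept"] = 1.0
    omnibus_cols: list[str] = []
    inter_col: dict[str, str] = {}
    for g in CONTRAST_GROUPS:
        col = f"group[{g}]"
        exog[col] = (rows["group"] == g).to_numpy(float)
        omnibus_cols.append(col)
    exog["time"] = rows["time_years"].to_numpy(float)
    for g in CONTRAST_GROUPS:
        col = f"group[{g}]:time"
        exog[col] = exog[f"group[{g}]"] * exog["time"]
        omnibus_cols.append(col)
        inter_col[g] = col
    # continuous covariates are mean-centered: the group and group×time
    # estimates are invariant to this, and the REML optimizer is much
    # better conditioned
    def _centered(x: np.ndarray) -> np.ndarray:
        return x - np.nanmean(x)

    exog["baseline_age"] = _centered(rows["baseline_age_years"].to_numpy(float))
    exog["male"] = rows["male"].to_numpy(float)
    race_levels = rows["race"].value_counts().index.tolist()  # largest = reference
    for lev in race_levels[1:]:
        exog[f"race[{lev}]"] = (rows["race"] == lev).to_numpy(float)
    exog["education"] = _centered(rows["education_years"].to_numpy(float))
    exog["apoe4"] = rows["apoe4"].to_numpy(float)
    exog["baseline_gait"] = _centered(rows["baseline_gait"].to_numpy(float))
    exog["baseline_memory"] = _centered(rows["baseline_memory"].to_numpy(float))
    exog["calendar_year_c"] = _centered(rows["calendar_year"].to_numpy(float))

    return LongitudinalDesign(
        exog=exog,
        groups=rows["subject_id"].to_numpy(),
        omnibus_columns=omnibus_cols,
        interaction_column=inter_col,
    )


@dataclass
class FittedLME:
    """REML fit of one response: coefficients, covariance, variance components."""

    params: pd.Series
    cov_params: pd.DataFrame
    var_subject: float
    var_residual: float
    converged: bool
    n_obs: int
    n_subjects: int
    omnibus_columns: list[str] = field(default_factory=list)
    interaction_column: dict[str, str] = field(default_factory=dict)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    _, _, piv = sla.qr(X, pivoting=True, mode="economic")
    return [names[j] for j in sorted(piv[r:])]


def fit_metabolite_lme(
    response: np.ndarray | pd.Series,
    design: LongitudinalDesign,
) -> FittedLME:
    """REML linear mixed model with a subject random intercept.

    Raises on a singular fixed-effects design (naming the aliased columns);
    a fit that fails to converge is returned with ``converged=False`` so the
    caller can exclude it from the FDR family.
    """
    import statsmodels.api as sm

    y = np.asarray(response, float)
    mask = np.isfinite(y)
    X = design.exog.to_numpy(float)[mask]
    groups = design.groups[mask]
    y = y[mask]
    names = list(design.exog.columns)
    if len(y) < 4 or len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 subjects with visits to fit the model")
    aliased = _aliased_columns(X, names)
    if aliased:
        raise ValueError(f"singular design; aliased columns: {aliased}")

    if np.ptp(y) == 0.0 and y[0] == 0.0:
        # degenerate all-zero response: exact answer, nothing to estimate
        k = len(names)
        return FittedLME(
            params=pd.Series(np.zeros(k), index=names),
            cov_params=pd.DataFrame(np.zeros((k, k)), index=names, columns=names),
            var_subject=0.0, var_residual=0.0, converged=True,
            n_obs=len(y), n_subjects=len(np.unique(groups)),
            omnibus_columns=design.omnibus_columns,
            interaction_column=design.interaction_column,
        )

    model = sm.MixedLM(y, X, groups=groups)
    res = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=[method])
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged:
                res, converged = cand, True
                break
            if res is None:
                res = cand  # keep best-effort fit in case nothing converges
    if res is None:
        k = len(names)
        return FittedLME(
            params=pd.Series(np.full(k, np.nan), index=names),
            cov_params=pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names),
            var_subject=np.nan, var_residual=np.nan, converged=False,
            n_obs=len(y), n_subjects=len(np.unique(groups)),
            omnibus_columns=design.omnibus_columns,
            interaction_column=design.interaction_column,
        )
    k = len(names)
    params = pd.Series(np.asarray(res.params)[:k], index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k], index=names, columns=names)
    return FittedLME(
        params=params,
        cov_params=cov,
        var_subject=float(np.asarray(res.cov_re).ravel()[0]),
        var_residual=float(res.scale),
        converged=converged,
        n_obs=len(y),
        n_subjects=len(np.unique(groups)),
        omnibus_columns=design.omnibus_columns,
        interaction_column=design.interaction_column,
    )


def omnibus_group_test(fitted: FittedLME) -> float:
    """Joint Wald chi-square p-value (6 df) for any group difference.

    Tests that the three group main effects and three group×time
    interactions are all zero, i.e. no cross-sectional or longitudinal
    difference among the four phenotypic groups.
    """
    cols = fitted.omnibus_columns
    if not cols or any(c not in fitted.params.index for c in cols):
        raise ValueError("model does not contain the group and group:time terms")
    beta = fitted.params[cols].to_numpy()
    V = fitted.cov_params.loc[cols, cols].to_numpy()
    if not np.all(np.isfinite(beta)):
        return np.nan
    if np.allclose(beta, 0.0):
        return 1.0
    try:
        stat = float(beta @ np.linalg.solve(V, beta))
    except np.linalg.LinAlgError:
        return np.nan
    return float(stats.chi2.sf(stat, len(cols)))


def pairwise_longitudinal_contrast(fitted: FittedLME, group: str) -> tuple[float, float]:
    """Wald z test on one declining group's group×time coefficient.

    Returns ``(β, p)``: β is the group's additional annual log2 change
    relative to ``no_decline``.
    """
    if group not in fitted.interaction_column:
        raise ValueError(
            f"group {group!r} not among contrast groups {list(fitted.interaction_column)}"
        )
    col = fitted.interaction_column[group]
    beta = float(fitted.params[col])
    se = float(np.sqrt(fitted.cov_params.loc[col, col]))
    if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return beta, np.nan
    z = beta / se
    return beta, float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(pvalues: np.ndarray | pd.Series, m_total: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    ``q_(i) = min_{j ≥ i} m·p_(j)/j`` over the p-values sorted ascending,
    capped at 1 and mapped back to input order; tied p-values share a q.
    ``m_total`` sets the family size, allowing a printed subset of a larger
    family to be adjusted (``m_total ≥`` the number of supplied p-values);
    defaults to the number of finite p-values.  NaN entries pass through as
    NaN and do not count toward the default family size.
    """
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    pf = p[finite]
    if ((pf < 0) | (pf > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(pf)
    if n == 0:
        return out
    m = n if m_total is None else int(m_total)
    if m < n:
        raise ValueError(f"m_total={m} smaller than number of p-values ({n})")
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    qf = np.empty(n)
    qf[order] = q_sorted
    out[finite] = qf
    return out


def screen_all(
    log2_panel: pd.DataFrame,
    design: LongitudinalDesign,
    apply_bh: bool = True,
    m_total: int | None = None,
) -> pd.DataFrame:
    """Fit every column of ``log2_panel`` and assemble the screening table.

    Returns one row per metabolite with the omnibus p, each pairwise
    group×time β and p, and — with ``apply_bh`` — q-values computed within
    each family across all converged fits (family size ``m_total`` or the
    converged count).
    """
    records = []
    for m in log2_panel.columns:
        fitted = fit_metabolite_lme(log2_panel[m].to_numpy(), design)
        rec: dict[str, object] = {
            "metabolite": m,
            "converged": fitted.converged,
            "n_obs": fitted.n_obs,
            "var_subject": fitted.var_subject,
            "var_residual": fitted.var_residual,
            "p_omnibus": omnibus_group_test(fitted) if fitted.converged else np.nan,
        }
        for g in CONTRAST_GROUPS:
            if fitted.converged:
                b, pv = pairwise_longitudinal_contrast(fitted, g)
                se = float(np.sqrt(fitted.cov_params.loc[
                    fitted.interaction_column[g], fitted.interaction_column[g]]))
            else:
                b, pv, se = np.nan, np.nan, np.nan
            rec[f"beta_{g}"] = b
            rec[f"se_{g}"] = se
            rec[f"p_{g}"] = pv
        records.append(rec)
    table = pd.DataFrame(records)
    if apply_bh:
        fam = m_total if m_total is not None else int(table["p_omnibus"].notna().sum())
        table["q_omnibus"] = bh_adjust(table["p_omnibus"].to_numpy(), fam)
        for g in CONTRAST_GROUPS:
            famg = m_total if m_total is not None else int(table[f"p_{g}"].notna().sum())
            table[f"q_{g}"] = bh_adjust(table[f"p_{g}"].to_numpy(), famg)
    return table.sort_values("p_omnibus", na_position="last").reset_index(drop=True)
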