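import numpy as np
import pandas as pd
import pytest

from dualtraj import simulate as sim
from dualtraj.cohort import CohortDataset, MetabolitePanel
from dualtraj.screen import CONTRAST_GROUPS, LongitudinalDesign


@pytest.fixture(scope="session")
def smoke_cohort():
    """Small simulated cohort shared by read-only tests."""
    params = sim.default_params("smoke", seed=11)
    return sim.generate_cohort(params)


@pytest.fixture()
def tiny_cohort():
    """Hand-built 3-subject / 8-visit cohort with a 2-metabolite panel."""
    subjects = pd.DataFrame(
        {
            "subject_id": ["A", "B", "C"],
            "sex": ["male", "female", "female"],
            "race": ["White", "Black", "White"],
            "education_years": [16.0, 12.0, 18.0],
            "apoe4_carrier": [False, True, False],
            "baseline_age_years": [70.0, 65.0, 58.0],
            "dementia_onset_time": [np.nan, np.nan, 4.0],
        }
    )
    visits = pd.DataFrame(
        {
            "subject_id": ["A", "A", "A", "B", "B", "C", "C", "C"],
            "time_years": [0.0, 1.5, 3.0, 0.0, 2.0, 0.0, 2.5, 5.0],
            "calendar_year": [2008.0, 2009.5, 2011.0, 2010.0, 2012.0, 2012.0, 2014.5, 2017.0],
            "gait_speed_mps": [1.2, 1.15, 1.1, 0.9, 0.85, 1.3, 1.25, 1.2],
            "memory_score": [50.0, 48.0, 46.0, 40.0, 39.0, 55.0, 54.0, 52.0],
        }
    )
    idx = pd.MultiIndex.from_frame(visits[["subject_id", "time_years"]])
    rng = np.random.default_rng(5)
    conc = pd.DataFrame(
        {"Met1": rng.uniform(5, 10, 8), "Met2": rng.uniform(0.5, 2.0, 8)}, index=idx
    )
    meta = pd.DataFrame(
        {"class_label": ["Amino acids", "Ceramides"], "lod": [0.1, 0.05]},
        index=pd.Index(["Met1", "Met2"], name="metabolite"),
    )
    panel = MetabolitePanel(conc, meta, conc.lt(meta["lod"], axis=1))
    return CohortDataset(subjects, visits, panel).validate()


def minimal_design(rng, n_subjects=150, effect=None, visit_probs=(0.5, 0.35, 0.15)):
    """Group + time + group×time design with random-intercept response.

    Returns ``(y, design, truth_beta)`` where ``effect`` plants an extra
    annual slope on the dual-decline group (None -> pure null).
    """
    labels = rng.choice(
        ["no_decline", *CONTRAST_GROUPS], size=n_subjects, p=[0.47, 0.20, 0.20, 0.13]
    )
    sid, times = [], []
    for i in range(n_subjects):
        k = rng.choice([2, 3, 4], p=list(visit_probs))
        t = np.cumsum(rng.uniform(1.0, 2.5, k))
        t -= t[-1]  # anchored: most recent visit at 0
        sid += [i] * k
        times += list(t)
    sid = np.asarray(sid)
    t = np.asarray(times)
    exog = pd.DataFrame({"Intercept": np.ones(len(sid))})
    omnibus, inter = [], {}
    for g in CONTRAST_GROUPS:
        col = f"group[{g}]"
        exog[col] = (labels[sid] == g).astype(float)
        omnibus.append(col)
    exog["time"] = t
    for g in CONTRAST_GROUPS:
        col = f"group[{g}]:time"
        exog[col] = exog[f"group[{g}]"] * t
        omnibus.append(col)
        inter[g] = col
    design = LongitudinalDesign(
        exog=exog, groups=sid.astype(str), omnibus_columns=omnibus,
        interaction_column=inter,
    )
    beta = 0.0 if effect is None else effect
    y = (
        rng.normal(0.0, 0.5, n_subjects)[sid]
        + beta * exog[inter["dual_decline"]].to_numpy()
        + rng.normal(0.0, 0.5, len(sid))
    )
    return y, design, beta
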