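import numpy as np
import pandas as pd
import pytest

from dualtraj.cohort import CohortDataset
from dualtraj.phenotype import (
    Cutpoints,
    classify_phenotypes,
    estimate_annual_slopes,
    tertile_cutpoints,
)


def _cohort_from_series(series: dict[str, tuple[list, list, list]]) -> CohortDataset:
    """series: subject -> (times, memory, gait)."""
    subjects = pd.DataFrame(
        {
            "subject_id": list(series),
            "sex": "male",
            "race": "White",
            "education_years": 16.0,
            "apoe4_carrier": False,
            "baseline_age_years": 70.0,
            "dementia_onset_time": np.nan,
        }
    )
    rows = []
    for sid, (t, mem, gait) in series.items():
        for ti, mi, gi in zip(t, mem, gait):
            rows.append((sid, ti, 2010.0 + ti, gi, mi))
    visits = pd.DataFrame(
        rows, columns=["subject_id", "time_years", "calendar_year",
                       "gait_speed_mps", "memory_score"]
    )
    return CohortDataset(subjects, visits).validate()


def grid_refined_slope(t, y, lo=-1000.0, hi=1000.0, rounds=8, width=2001):
    """Independent slope oracle: grid search of the SSE minimizer, refined.

    For a candidate slope b the optimal intercept is ȳ − b·t̄, so
    SSE(b) = Σ((y−ȳ) − b(t−t̄))²; the grid is repeatedly narrowed around
    the minimizer to 1e-7 resolution.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc, yc = t - t.mean(), y - y.mean()
    for _ in range(rounds):
        grid = np.linspace(lo, hi, width)
        sse = ((yc[None, :] - grid[:, None] * tc[None, :]) ** 2).sum(axis=1)
        k = int(np.argmin(sse))
        step = grid[1] - grid[0]
        lo, hi = grid[k] - 2 * step, grid[k] + 2 * step
    return grid[k]


class TestSlopes:
    def test_exact_line(self):
        ds = _cohort_from_series({"A": ([0, 1, 2], [10, 9, 8], [1.2, 1.2, 1.2])})
        slopes, _ = estimate_annual_slopes(ds)
        assert slopes.loc[0, "memory_slope"] == pytest.approx(-1.0)
        assert slopes.loc[0, "gait_slope"] == pytest.approx(0.0)

    def test_constant_series_zero_slope(self):
        ds = _cohort_from_series({"A": ([0, 2, 4], [50, 50, 50], [1.2, 1.2, 1.2])})
        slopes, _ = estimate_annual_slopes(ds)
        assert slopes.loc[0, "gait_slope"] == 0.0

    def test_matches_grid_refinement_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(3, 8)
            t = np.sort(rng.uniform(0, 10, n))
            y = rng.uniform(20, 60, n)
            ds = _cohort_from_series({"A": (t, y, np.full(n, 1.0))})
            slopes, _ = estimate_annual_slopes(ds)
            assert slopes.loc[0, "memory_slope"] == pytest.approx(
                grid_refined_slope(t, y), abs=1e-6
            )

    def test_post_dementia_points_excluded(self):
        ds = _cohort_from_series(
            {"A": ([0, 1, 2, 3, 4], [50, 49, 48, 20, 10], [1.0] * 5)}
        )
        ds.subjects.loc[0, "dementia_onset_time"] = 3.0
        slopes, _ = estimate_annual_slopes(ds)
        assert slopes.loc[0, "memory_slope"] == pytest.approx(-1.0)
        assert slopes.loc[0, "n_points_memory"] == 3
        with_all, _ = estimate_annual_slopes(ds, exclude_post_dementia=False)
        assert with_all.loc[0, "memory_slope"] < -1.0

    def test_too_few_visits_omitted_with_reason(self):
        ds = _cohort_from_series({"A": ([0], [50], [1.0]),
                                  "B": ([0, 1], [50, 49], [1.0, 1.0])})
        slopes, log = estimate_annual_slopes(ds, min_visits=2)
        assert set(slopes["subject_id"]) == {"B"}
        assert "fewer than 2" in log.set_index("subject_id").loc["A", "reason"]

    def test_identical_times_undefined_slope(self):
        subjects = pd.DataFrame(
            {"subject_id": ["A"], "sex": ["male"], "race": ["White"],
             "education_years": [16.0], "apoe4_carrier": [False],
             "baseline_age_years": [70.0], "dementia_onset_time": [np.nan]}
        )
        visits = pd.DataFrame(
            {"subject_id": ["A", "A"], "time_years": [1.0, 1.0],
             "calendar_year": [2010.0, 2010.0], "gait_speed_mps": [1.0, 1.0],
             "memory_score": [50.0, 49.0]}
        )
        # bypass validate(): duplicate times violate the visit invariant, but
        # the slope estimator must still fail gracefully on malformed input
        ds = CohortDataset(subjects, visits)
        slopes, log = estimate_annual_slopes(ds)
        assert len(slopes) == 0
        assert "identical time" in log.loc[0, "reason"]


class TestCutpoints:
    def test_interpolated_lower_tertile(self):
        s = pd.DataFrame({"subject_id": list("abcdefghi"),
                          "memory_slope": [-3, -2, -1, 0, 1, 2, 3, 4, 5],
                          "gait_slope": [-3, -2, -1, 0, 1, 2, 3, 4, 5]})
        cuts = tertile_cutpoints(s)
        # oracle: sort, then linear interpolation at fractional index (n-1)/3;
        # here (9-1)/3 = 8/3 falls 2/3 of the way from -1 to 0
        expected = -1.0 + (8 / 3 - 2) * (0.0 - (-1.0))
        assert cuts.memory_cut == pytest.approx(expected)
        assert cuts.gait_cut == pytest.approx(expected)

    def test_degenerate_all_equal(self):
        s = pd.DataFrame({"subject_id": list("abc"),
                          "memory_slope": [2.0, 2.0, 2.0],
                          "gait_slope": [0.1, 0.1, 0.1]})
        cuts = tertile_cutpoints(s)
        assert cuts.memory_cut == 2.0 and cuts.gait_cut == 0.1

    def test_requires_three_subjects(self):
        s = pd.DataFrame({"subject_id": ["a", "b"],
                          "memory_slope": [0.0, 1.0], "gait_slope": [0.0, 1.0]})
        with pytest.raises(ValueError):
            tertile_cutpoints(s)

    def test_published_cuts_usable_as_override(self):
        cuts = Cutpoints(memory_cut=-0.67, gait_cut=-0.022)
        s = pd.DataFrame({"subject_id": ["x"], "memory_slope": [-0.8],
                          "gait_slope": [-0.01]})
        labels, _ = classify_phenotypes(s, cuts)
        assert labels.loc[0, "label"] == "memory_decline_only"


class TestClassification:
    CUTS = Cutpoints(memory_cut=-0.67, gait_cut=-0.022)

    @pytest.mark.parametrize(
        "mem,gait,expected",
        [
            (-0.8, -0.01, "memory_decline_only"),
            (-0.8, -0.03, "dual_decline"),
            (-0.1, -0.03, "gait_decline_only"),
            (-0.1, -0.01, "no_decline"),
            (-0.67, -0.022, "dual_decline"),  # ties fall in the declining tertile
        ],
    )
    def test_rule(self, mem, gait, expected):
        s = pd.DataFrame({"subject_id": ["x"], "memory_slope": [mem],
                          "gait_slope": [gait]})
        labels, _ = classify_phenotypes(s, self.CUTS)
        assert labels.loc[0, "label"] == expected

    def test_missing_slope_omitted_and_logged(self):
        s = pd.DataFrame({"subject_id": ["x", "y"],
                          "memory_slope": [np.nan, -1.0],
                          "gait_slope": [-0.03, -0.03]})
        labels, log = classify_phenotypes(s, self.CUTS)
        assert set(labels["subject_id"]) == {"y"}
        assert log.loc[0, "subject_id"] == "x"

    def test_agrees_with_brute_force_on_random_instances(self):
        """1000 random slope pairs against an exhaustive truth-table labeler."""
        rng = np.random.default_rng(77)
        mem = rng.normal(-0.5, 1.0, 1000)
        gait = rng.normal(-0.02, 0.05, 1000)
        # a few exact ties to exercise the boundary
        mem[:5] = self.CUTS.memory_cut
        gait[2:7] = self.CUTS.gait_cut
        s = pd.DataFrame({"subject_id": [f"s{i}" for i in range(1000)],
                          "memory_slope": mem, "gait_slope": gait})
        labels, _ = classify_phenotypes(s, self.CUTS)
        table = {
            (True, True): "dual_decline",
            (True, False): "memory_decline_only",
            (False, True): "gait_decline_only",
            (False, False): "no_decline",
        }
        expected = [
            table[(m <= self.CUTS.memory_cut, g <= self.CUTS.gait_cut)]
            for m, g in zip(mem, gait)
        ]
        assert list(labels["label"]) == expected

    def test_four_groups_partition_sample(self):
        rng = np.random.default_rng(8)
        s = pd.DataFrame({"subject_id": [f"s{i}" for i in range(200)],
                          "memory_slope": rng.normal(size=200),
                          "gait_slope": rng.normal(size=200)})
        cuts = tertile_cutpoints(s)
        labels, _ = classify_phenotypes(s, cuts)
        assert len(labels) == 200  # no one dropped, no one duplicated
        assert labels["subject_id"].is_unique
        # internally computed tertile -> about one third declining on memory
        n_mem = (labels["label"].isin(["dual_decline", "memory_decline_only"])).sum()
        assert 200 // 3 <= n_mem <= 200 // 3 + 2
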