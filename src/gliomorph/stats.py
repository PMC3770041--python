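"""Group statistics: summaries, pooled t-tests, grade correlation.

The statistical layer works on per-sample mean parameters.  Group
differences use the unpaired pooled-variance Student t-test (two-sided,
df = n1 + n2 - 2), which — unlike Welch — reproduces published
morphometry tables computed from summary statistics.  Correlation with
WHO grade (controls coded 0) uses the Pearson coefficient with the exact
t-based two-sided P value, plus an ordinary least-squares regression
line.  No multiple-testing correction is applied, matching the reference
analysis; this is a documented limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import InvalidParameterError

logger = logging.getLogger("gliomorph")

ALPHA = 0.05

#: Analysis parameters, in report order, with the SampleRecord attribute.
PARAMETERS = {
    "MAJX": "mean_majx",
    "MINX": "mean_minx",
    "NA": "mean_na",
    "NP": "mean_np",
    "NR": "mean_nr",
    "ND": "mean_nd",
    "TNA": "mean_tna",
}

GROUP_PAIRS = (("CG", "LGG"), ("CG", "HGG"), ("LGG", "HGG"))

#: Diagnosis label -> WHO grade code (controls are coded grade 0).
_DIAGNOSIS_GRADES = {
    "CG": 0, "CONTROL": 0,
    "DA": 2, "OA": 2,
    "AA": 3,
    "GBM": 4,
}


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass
class SampleRecord:
    """Per-case mean nuclear parameters with group and grade labels."""

    sample_id: str
    group: str
    grade_code: int
    mean_majx: float
    mean_minx: float
    mean_na: float
    mean_np: float
    mean_nr: float
    mean_nd: float
    mean_tna: float
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.grade_code not in (0, 2, 3, 4):
            raise InvalidParameterError(f"grade_code {self.grade_code} invalid")
        if (self.group == "CG") != (self.grade_code == 0):
            raise InvalidParameterError("CG if and only if grade_code == 0")


@dataclass
class GroupSummary:
    parameter: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class TTestResult:
    parameter: str
    group_pair: tuple[str, str]
    t_statistic: float
    df: int
    p_value: float
    significant: bool


@dataclass
class CorrelationResult:
    parameter: str
    r: float
    p_value: float
    slope: float | None = None
    intercept: float | None = None


def grade_code(label: str) -> int:
    """WHO grade code for a diagnosis or group label (controls -> 0)."""
    try:
        return _DIAGNOSIS_GRADES[label.upper()]
    except KeyError:
        raise InvalidParameterError(f"unknown diagnosis label {label!r}") from None


def group_summary(values, name: str = "") -> GroupSummary:
    """Mean, sample SD (n-1 denominator) and range of one group."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 values for a group summary")
    return GroupSummary(parameter=name, n=int(v.size), mean=float(v.mean()),
                        sd=float(v.std(ddof=1)), min=float(v.min()),
                        max=float(v.max()))


def t_test_pooled(m1: float, s1: float, n1: int, m2: float, s2: float,
                  n2: int, parameter: str = "",
                  group_pair: tuple[str, str] = ("", "")) -> TTestResult:
    """Unpaired pooled-variance Student t-test from summary statistics.

    t = (m2 - m1) / (sp * sqrt(1/n1 + 1/n2)) with the pooled variance
    sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2); two-sided P on
    n1 + n2 - 2 degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 in both groups")
    if s1 < 0 or s2 < 0:
        raise InvalidParameterError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            raise InvalidParameterError(
                "degenerate test: zero variance and equal means")
        logger.warning("zero pooled variance with unequal means: P = 0")
        return TTestResult(parameter, group_pair,
                           float(np.inf) * np.sign(m2 - m1), df, 0.0, True)
    t, p = sps.ttest_ind_from_stats(m2, s2, n2, m1, s1, n1, equal_var=True)
    return TTestResult(parameter=parameter, group_pair=group_pair,
                       t_statistic=float(t), df=df, p_value=float(p),
                       significant=bool(p < ALPHA))


def t_test_pooled_raw(x1, x2, parameter: str = "",
                      group_pair: tuple[str, str] = ("", "")) -> TTestResult:
    """Pooled t-test from raw per-sample vectors.

    Computes the group summaries and delegates to :func:`t_test_pooled`,
    so the raw-vector and summary-statistic paths are identical by
    construction.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise InsufficientDataError("need n >= 2 in both groups")
    return t_test_pooled(float(x1.mean()), float(x1.std(ddof=1)), x1.size,
                         float(x2.mean()), float(x2.std(ddof=1)), x2.size,
                         parameter=parameter, group_pair=group_pair)


def t_test_welch(m1, s1, n1, m2, s2, n2, parameter: str = "",
                 group_pair: tuple[str, str] = ("", "")) -> TTestResult:
    """Welch's unequal-variance alternative (not the default)."""
    t, p = sps.ttest_ind_from_stats(m2, s2, n2, m1, s1, n1, equal_var=False)
    nu = (s1**2 / n1 + s2**2 / n2) ** 2 / (
        (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
    return TTestResult(parameter=parameter, group_pair=group_pair,
                       t_statistic=float(t), df=int(np.floor(nu)),
                       p_value=float(p), significant=bool(p < ALPHA))


def pearson_with_p(x, y, parameter: str = "") -> CorrelationResult:
    """Pearson r with the exact two-sided P value on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need equal-length vectors of >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidParameterError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(parameter=parameter, r=float(res.statistic),
                             p_value=float(res.pvalue))


def linear_fit(x, y) -> tuple[float, float]:
    """Least-squares regression line; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need equal-length vectors of >= 3 points")
    if np.ptp(x) == 0:
        raise InvalidParameterError("regression undefined for constant x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


@dataclass
class GroupAnalysis:
    """Full statistical report: the summary-table layout plus correlations."""

    summaries: dict[str, dict[str, GroupSummary]]
    ttests: dict[str, dict[tuple[str, str], TTestResult]]
    grade_correlations: dict[str, CorrelationResult]
    density_correlations: dict[str, CorrelationResult]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for param, per_group in self.summaries.items():
            for group, s in per_group.items():
                rows.append({"parameter": param, "group": group, "n": s.n,
                             "mean": s.mean, "sd": s.sd,
                             "min": s.min, "max": s.max})
        return pd.DataFrame(rows)

    def ttest_frame(self) -> pd.DataFrame:
        rows = []
        for param, per_pair in self.ttests.items():
            for pair, t in per_pair.items():
                rows.append({"parameter": param,
                             "pair": f"{pair[0]}_vs_{pair[1]}",
                             "t": t.t_statistic, "df": t.df,
                             "p_value": t.p_value,
                             "significant": t.significant})
        return pd.DataFrame(rows)

    def correlation_frame(self) -> pd.DataFrame:
        rows = []
        for param, c in self.grade_correlations.items():
            rows.append({"x": "grade", "parameter": param, "r": c.r,
                         "p_value": c.p_value, "slope": c.slope,
                         "intercept": c.intercept})
        for param, c in self.density_correlations.items():
            rows.append({"x": "ND", "parameter": param, "r": c.r,
                         "p_value": c.p_value, "slope": c.slope,
                         "intercept": c.intercept})
        return pd.DataFrame(rows)


def run_group_analysis(samples: list[SampleRecord],
                       groups: tuple[str, ...] = ("CG", "LGG", "HGG"),
                       ) -> GroupAnalysis:
    """The full per-parameter report over a three-group study.

    For each of the seven parameters (plus age when available): one
    summary per group, the three pairwise pooled t-tests, and the
    Pearson correlation/regression against WHO grade; plus correlations
    of ND with NA and NP across all samples.
    """
    by_group: dict[str, list[SampleRecord]] = {g: [] for g in groups}
    for s in samples:
        if s.group in by_group:
            by_group[s.group].append(s)
    missing = [g for g, lst in by_group.items() if len(lst) < 2]
    if missing:
        raise InsufficientDataError(
            f"need >= 2 samples per group; missing or short: {missing}")

    params = dict(PARAMETERS)
    if all(s.age_years is not None for s in samples):
        params["Age"] = "age_years"

    summaries: dict[str, dict[str, GroupSummary]] = {}
    ttests: dict[str, dict[tuple[str, str], TTestResult]] = {}
    grade_corr: dict[str, CorrelationResult] = {}
    grades = [s.grade_code for s in samples]
    for param, attr in params.items():
        summaries[param] = {
            g: group_summary([getattr(s, attr) for s in by_group[g]], param)
            for g in groups
        }
        ttests[param] = {}
        for g1, g2 in GROUP_PAIRS:
            if g1 in by_group and g2 in by_group:
                ttests[param][(g1, g2)] = t_test_pooled_raw(
                    [getattr(s, attr) for s in by_group[g1]],
                    [getattr(s, attr) for s in by_group[g2]],
                    parameter=param, group_pair=(g1, g2))
        values = [getattr(s, attr) for s in samples]
        try:
            corr = pearson_with_p(grades, values, parameter=param)
        except InvalidParameterError:
            # constant parameter: correlation undefined, regression flat
            corr = CorrelationResult(parameter=param, r=float("nan"),
                                     p_value=float("nan"))
        corr.slope, corr.intercept = linear_fit(grades, values)
        grade_corr[param] = corr

    density_corr: dict[str, CorrelationResult] = {}
    nd = [s.mean_nd for s in samples]
    for param, attr in (("NA", "mean_na"), ("NP", "mean_np")):
        values = [getattr(s, attr) for s in samples]
        try:
            corr = pearson_with_p(nd, values, parameter=param)
            corr.slope, corr.intercept = linear_fit(nd, values)
        except InvalidParameterError:
            corr = CorrelationResult(parameter=param, r=float("nan"),
                                     p_value=float("nan"))
        density_corr[param] = corr

    return GroupAnalysis(summaries=summaries, ttests=ttests,
                         grade_correlations=grade_corr,
                         density_correlations=density_corr)


def pairwise_tests_from_summaries(
        summaries: dict[str, dict[str, tuple[float, float, int]]],
        ) -> dict[str, dict[tuple[str, str], TTestResult]]:
    """Pairwise pooled t-tests straight from printed (mean, sd, n) cells.

    ``summaries[parameter][group] = (mean, sd, n)``.  This is the path
    that verifies a published summary table without any raw data.
    """
    out: dict[str, dict[tuple[str, str], TTestResult]] = {}
    for param, per_group in summaries.items():
        out[param] = {}
        for g1, g2 in GROUP_PAIRS:
            if g1 in per_group and g2 in per_group:
                m1, s1, n1 = per_group[g1]
                m2, s2, n2 = per_group[g2]
                out[param][(g1, g2)] = t_test_pooled(
                    m1, s1, n1, m2, s2, n2,
                    parameter=param, group_pair=(g1, g2))
    return out
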