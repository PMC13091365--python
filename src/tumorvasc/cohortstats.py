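"""Longitudinal cohort statistics for the two-group tumor study.

Implements the study's analysis plan: caliper volume formula, baseline
normalization, Shapiro-Wilk screening, exact small-sample Wilcoxon
signed-rank and Mann-Whitney tests (full enumeration for the n = 6 cohort
sizes, with large-sample approximations as fallback), paired/unpaired
t-tests, Pearson correlation, per-group summary tables and the
microvessel-density normalization.  All tests are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "mvd_per_area",
    "normalize_to_baseline",
    "pearson_correlation",
    "route_test",
    "run_group_tests",
    "shapiro_wilk",
    "summarize",
    "t_test",
    "tumor_volume",
    "wilcoxon_signed_rank",
]

log = logging.getLogger(__name__)

#: Largest sample sizes for which the exact null distributions are enumerated.
EXACT_WILCOXON_MAX_N = 12
EXACT_MANNWHITNEY_MAX_NM = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (always two-sided)."""

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def tumor_volume(a: float, b: float) -> float:
    """Caliper tumor volume V = a*b^2/2 (mm^3); ``a`` is the longer axis.

    If the arguments arrive swapped (a < b) they are exchanged, since the
    formula is defined with ``a`` as the length.
    """
    if a <= 0 or b <= 0:
        raise ValueError("tumor axes must be positive")
    if a < b:
        log.info("tumor_volume: axes swapped (a=%g < b=%g)", a, b)
        a, b = b, a
    return a * b * b / 2.0


def normalize_to_baseline(
    data: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Divide each animal's series by its first-day value per variable.

    Expects tidy columns (animal_id, group, day, variable, value).  Animals
    whose baseline is missing or zero are excluded for that variable; the
    number of exclusions is returned alongside the normalized frame.
    """
    required = {"animal_id", "day", "variable", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"tidy frame must have columns {sorted(required)}")
    df = data.copy()
    if variables is not None:
        df = df[df["variable"].isin(variables)]
    out = []
    n_excluded = 0
    for (animal, var), grp in df.groupby(["animal_id", "variable"], sort=False):
        grp = grp.sort_values("day")
        first_day = grp["day"].min()
        base = grp.loc[grp["day"] == first_day, "value"]
        if base.empty or base.iloc[0] == 0 or not np.isfinite(base.iloc[0]):
            n_excluded += 1
            log.warning(
                "normalize_to_baseline: excluding animal %s variable %s "
                "(missing or zero baseline)",
                animal,
                var,
            )
            continue
        grp = grp.assign(value=grp["value"] / base.iloc[0])
        out.append(grp)
    if not out:
        return df.iloc[0:0], n_excluded
    return pd.concat(out, ignore_index=True), n_excluded


def shapiro_wilk(sample) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 50)."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= x.size <= 50):
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 50")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test is degenerate")
    w, p = sps.shapiro(x)
    return TestResult("shapiro-wilk", float(w), float(p), (x.size,))


def _two_sided_from_cdf(cdf_le: float, cdf_ge: float) -> float:
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped.  For n <= 12 remaining pairs the exact
    two-sided p-value is computed by enumerating all 2^n sign assignments of
    the observed |difference| ranks (average ranks under ties); larger
    samples use the continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 4:
        raise ValueError("need at least 4 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        # Null: each rank is positive with probability 1/2 independently.
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        cdf_le = np.mean(sums <= w_pos + 1e-9)
        cdf_ge = np.mean(sums >= w_pos - 1e-9)
        p = _two_sided_from_cdf(cdf_le, cdf_ge)
        return TestResult("wilcoxon-signed-rank", w_pos, p, (n,), exact=True)
    res = sps.wilcoxon(d, correction=True, method="approx")
    return TestResult(
        "wilcoxon-signed-rank", float(res.statistic), float(res.pvalue), (n,)
    )


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, obs: float) -> float:
    """Exact two-sided p for the rank-sum of ``n_x`` items from ``ranks``.

    Enumerates all C(n, n_x) subsets (doubled ranks kept as floats to honor
    average ranks under ties).
    """
    total = 0
    le = 0
    ge = 0
    eps = 1e-9
    for comb in combinations(range(ranks.size), n_x):
        s = ranks[list(comb)].sum()
        total += 1
        if s <= obs + eps:
            le += 1
        if s >= obs - eps:
            ge += 1
    return _two_sided_from_cdf(le / total, ge / total)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) test for two groups.

    Exact by enumeration of rank assignments for n+m <= 20 (ties handled via
    average ranks); otherwise the tie-corrected normal approximation.
    The statistic reported is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 3 or m < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = float(ranks[:n].sum())
    u_x = r_x - n * (n + 1) / 2.0
    if n + m <= EXACT_MANNWHITNEY_MAX_NM:
        p = _exact_rank_sum_p(ranks, n, r_x)
        return TestResult("mann-whitney", u_x, p, (n, m), exact=True)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue), (n, m))


def t_test(x, y, paired: bool = False, welch: bool = True) -> TestResult:
    """Two-sided t-test; unpaired defaults to Welch's unequal-variance form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired t-test needs equal-length samples")
        if x.size < 3:
            raise ValueError("need n >= 3")
        if np.ptp(x - y) == 0 and np.all(x == y):
            return TestResult("t-paired", 0.0, 1.0, (x.size,))
        res = sps.ttest_rel(x, y)
        return TestResult(
            "t-paired", float(res.statistic), float(res.pvalue), (x.size,)
        )
    if x.size < 3 or y.size < 3:
        raise ValueError("need n >= 3 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    name = "t-welch" if welch else "t-pooled"
    return TestResult(name, float(res.statistic), float(res.pvalue), (x.size, y.size))


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p from the t-transform; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance sample")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def summarize(data: pd.DataFrame, variable: str, day=None) -> pd.DataFrame:
    """Per-group summary rows: n, mean, SD, SEM, median, quartiles, min, max.

    Quartiles use linear interpolation between order statistics.  Single
    observations report SD/SEM as NaN with ``zero_df`` flagged.
    """
    df = data[data["variable"] == variable]
    if day is not None:
        df = df[df["day"] == day]
    if df.empty:
        raise ValueError(f"no data for variable={variable!r} day={day!r}")
    rows = []
    for (group, d), grp in df.groupby(["group", "day"]):
        v = grp["value"].to_numpy(dtype=float)
        n = v.size
        sd = float(np.std(v, ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "group": group,
                "day": d,
                "variable": variable,
                "n": n,
                "mean": float(np.mean(v)),
                "sd": sd,
                "sem": sd / np.sqrt(n) if n > 1 else np.nan,
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
                "min": float(v.min()),
                "max": float(v.max()),
                "zero_df": n == 1,
            }
        )
    return pd.DataFrame(rows)


def mvd_per_area(vessel_count: int, n_fields: int, field_area: float) -> float:
    """Microvessel density: total count / (n_fields * field_area), vessels/mm^2."""
    if n_fields <= 0 or field_area <= 0:
        raise ValueError("field count and area must be positive")
    if vessel_count < 0:
        raise ValueError("vessel count cannot be negative")
    return vessel_count / (n_fields * field_area)


#: Analysis-plan routing: tumor volume uses nonparametric tests, every other
#: endpoint uses t-tests.
NONPARAMETRIC_VARIABLES = ("volume",)


def route_test(variable: str) -> str:
    """Return 'nonparametric' or 'parametric' per the study's analysis plan."""
    return "nonparametric" if variable in NONPARAMETRIC_VARIABLES else "parametric"


def run_group_tests(data: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Between-group test per day plus within-group test vs baseline.

    Routing follows the analysis plan: Mann-Whitney / Wilcoxon for tumor
    volume, unpaired / paired t-tests for all other endpoints.  Returns one
    tidy row per performed test.
    """
    df = data[data["variable"] == variable]
    if df.empty:
        raise ValueError(f"no data for variable {variable!r}")
    route = route_test(variable)
    days = sorted(df["day"].unique())
    baseline_day = days[0]
    rows = []

    def pivot(group: str) -> pd.DataFrame:
        sub = df[df["group"] == group]
        return sub.pivot_table(index="animal_id", columns="day", values="value")

    wide = {g: pivot(g) for g in sorted(df["group"].unique())}
    for day in days:
        samples = {
            g: w[day].dropna().to_numpy() for g, w in wide.items() if day in w.columns
        }
        if len(samples) == 2:
            (ga, xa), (gb, xb) = samples.items()
            try:
                res = (
                    mann_whitney(xa, xb)
                    if route == "nonparametric"
                    else t_test(xa, xb, paired=False)
                )
                rows.append(
                    {
                        "variable": variable,
                        "day": day,
                        "comparison": f"{ga}-vs-{gb}",
                        "method": res.method,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "exact": res.exact,
                    }
                )
            except ValueError as err:
                log.warning("between-group test skipped (day %s): %s", day, err)
        if day == baseline_day:
            continue
        for g, w in wide.items():
            if baseline_day not in w.columns or day not in w.columns:
                continue
            pair = w[[baseline_day, day]].dropna()
            try:
                res = (
                    wilcoxon_signed_rank(pair[day], pair[baseline_day])
                    if route == "nonparametric"
                    else t_test(pair[day], pair[baseline_day], paired=True)
                )
                rows.append(
                    {
                        "variable": variable,
                        "day": day,
                        "comparison": f"{g}-vs-baseline",
                        "method": res.method,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "exact": res.exact,
                    }
                )
            except ValueError as err:
                log.warning("baseline test skipped (%s day %s): %s", g, day, err)
    return pd.DataFrame(rows)
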