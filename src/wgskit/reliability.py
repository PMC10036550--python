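"""Rater-reliability statistics for ordinal gait-scale scores.

Implements the analysis plan used to validate the computerised scale:
descriptive statistics per rater and session; inter-rater agreement via the
two-way random-effects intraclass correlation for absolute agreement
(McGraw & Wong convention), with the conventional interpretation bands
(poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent); Bland-Altman
limits of agreement (mean difference +/- 1.96 SD of differences);
Kruskal-Wallis comparisons across raters and Wilcoxon signed-rank
test-retest comparisons; and the finite-population minimum-sample-size
formula

    Nmin = NP * (alpha^2 * f * (1 - f)) / (NP * e^2 + alpha^2 * f * (1 - f))

where NP is the population size, alpha the normal quantile for the
confidence level (e.g. 1.96), f the assumed fraction and e the accepted
maximum error.

The single-measures absolute-agreement ICC of an n x k score matrix is

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the two-way ANOVA mean squares for rows (subjects),
columns (raters) and residual; the average-measures form is

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n).

A constant matrix has no between-subject variance to agree about, so the
ICC is reported as an explicit undefined-ICC error, never silently 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import IccUndefinedError, StatsError
from .panel import RatingsPanel

__all__ = [
    "DescriptiveStats",
    "ICCResult",
    "BlandAltmanResult",
    "TestResult",
    "ItemReport",
    "ReliabilityReport",
    "descriptive_stats",
    "icc_absolute_agreement",
    "icc_two_way_random_absolute",
    "icc_test_retest",
    "icc_category",
    "bland_altman",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "min_sample_size",
    "reliability_report",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    median: float
    min: float
    max: float
    q1: float
    q3: float
    sd: float  # sample SD (n-1); NaN when n == 1


@dataclass(frozen=True)
class ICCResult:
    value: float
    unit: str  # "single" | "average"
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int
    category: str


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    within_fraction: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: Union[int, tuple[int, ...]]


def descriptive_stats(values: Sequence[float]) -> DescriptiveStats:
    """Mean, median, min, max, quartiles (linear interpolation), sample SD."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise StatsError("descriptive statistics need at least one value")
    if not np.all(np.isfinite(x)):
        raise StatsError("descriptive statistics need finite values")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")
    return DescriptiveStats(
        n=int(x.size),
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        q1=float(np.quantile(x, 0.25)),  # linear interpolation
        q3=float(np.quantile(x, 0.75)),
        sd=sd,
    )


def icc_category(value: float) -> str:
    """Interpretation band of an ICC value (boundaries to the upper band)."""
    if not value <= 1.0:
        raise StatsError(f"ICC cannot exceed 1, got {value}")
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_absolute_agreement(matrix, unit: str = "single") -> ICCResult:
    """Two-way random-effects, absolute-agreement ICC of an n x k matrix.

    Rows are subjects, columns raters; the matrix must be complete. ``unit``
    selects single-measures ICC(A,1) or average-measures ICC(A,k).
    """
    if unit not in ("single", "average"):
        raise StatsError(f"unit must be 'single' or 'average', got {unit!r}")
    x = np.asarray(pd.DataFrame(matrix).to_numpy(), dtype=float)
    if x.ndim != 2:
        raise StatsError("ICC needs a 2-D score matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise StatsError(f"ICC needs at least 2 subjects and 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        cells = [tuple(map(int, c)) for c in np.argwhere(np.isnan(x))]
        raise StatsError(f"ICC needs a complete matrix; missing cells (row, col): {cells}")
    grand = x.mean()
    sst = float(np.sum((x - grand) ** 2))
    scale = max(1.0, abs(grand)) ** 2
    if sst <= _REL_TOL * scale * x.size:
        raise IccUndefinedError(
            "ICC is undefined for a constant score matrix (zero total variance)"
        )
    msr, msc, mse = _mean_squares(x)
    # mean squares that are pure float dust relative to the dominant one are
    # zero in exact arithmetic (e.g. perfect agreement on fractional totals)
    tiny = 1e-12 * max(msr, msc, mse)
    msr, msc, mse = (0.0 if m < tiny else m for m in (msr, msc, mse))
    if unit == "single":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (msc - mse) / n
    if abs(denom) <= _REL_TOL * scale:
        raise IccUndefinedError("ICC denominator is zero; agreement is undefined")
    value = (msr - mse) / denom
    # single-measures ICC is algebraically <= 1; clamp float overshoot. The
    # average-measures form can exceed 1 when its denominator turns negative
    # (between-subject variance swamped by rater variance); that degenerate
    # regime indicates agreement no better than chance and is labelled poor.
    if 1.0 < value < 1.0 + 1e-9:
        value = 1.0
    category = icc_category(float(value)) if value <= 1.0 else "poor"
    return ICCResult(
        value=float(value),
        unit=unit,
        model="two-way random effects, absolute agreement",
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n_subjects=n,
        k_raters=k,
        category=category,
    )


def icc_two_way_random_absolute(
    panel: RatingsPanel, item: str | int, session: int, unit: str = "single"
) -> ICCResult:
    """Inter-rater ICC for one item and session (subjects x raters)."""
    return icc_absolute_agreement(panel.matrix(item, session), unit=unit)


def icc_test_retest(
    panel: RatingsPanel, item: str | int, rater: str, unit: str = "single"
) -> ICCResult:
    """Intra-rater (test-retest) ICC for one item and rater (subjects x sessions)."""
    return icc_absolute_agreement(panel.matrix_across_sessions(item, rater), unit=unit)


def bland_altman(x1: Sequence[float], x2: Sequence[float]) -> BlandAltmanResult:
    """Limits of agreement: mean difference +/- 1.96 SD of the differences."""
    a = np.asarray(list(x1), dtype=float)
    b = np.asarray(list(x2), dtype=float)
    if a.shape != b.shape:
        raise StatsError(f"paired lists must have equal length, got {a.size} and {b.size}")
    if a.size < 2:
        raise StatsError("Bland-Altman needs at least 2 pairs")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(
        n=int(d.size), mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
        within_fraction=within,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank-based Kruskal-Wallis H with tie correction.

    All observations identical across every group gives H = 0 and p = 1
    (no rank differences at all) instead of the library error.
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise StatsError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in gs):
        raise StatsError("Kruskal-Wallis groups must be non-empty")
    sizes = tuple(int(g.size) for g in gs)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "Kruskal-Wallis H (all observations identical)", sizes)
    h, p = sps.kruskal(*gs)
    return TestResult(float(h), float(p), "Kruskal-Wallis H (tie-corrected)", sizes)


def wilcoxon_signed_rank(
    session1: Sequence[float], session2: Sequence[float]
) -> TestResult:
    """Paired Wilcoxon signed-rank test with the classical zero handling.

    Zero differences are dropped; if every pair is tied the test is
    maximally non-significant (p = 1.0) by convention. The exact null
    distribution is used for up to 25 untied non-zero pairs, the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(list(session1), dtype=float)
    b = np.asarray(list(session2), dtype=float)
    if a.shape != b.shape:
        raise StatsError(f"paired lists must have equal length, got {a.size} and {b.size}")
    if a.size < 1:
        raise StatsError("Wilcoxon needs at least one pair")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, "Wilcoxon signed-rank (all differences zero)", 0)
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=False, method=method)
    label = "exact" if method == "exact" else "normal approximation, tie-corrected"
    return TestResult(
        float(res.statistic), float(res.pvalue), f"Wilcoxon signed-rank ({label})",
        int(nz.size),
    )


def min_sample_size(NP: float, alpha: float, f: float, e: float) -> int:
    """Finite-population minimum sample size, rounded up to an integer.

    ``alpha`` is the normal quantile for the confidence level (1.96 for
    95 %), ``f`` the assumed population fraction and ``e`` the accepted
    maximum error. As NP grows the value converges to alpha^2 f(1-f)/e^2.
    """
    if not NP > 0:
        raise StatsError(f"population size NP must be > 0, got {NP}")
    if not 0 < f < 1:
        raise StatsError(f"fraction f must lie strictly between 0 and 1, got {f}")
    if not e > 0:
        raise StatsError(f"maximum error e must be > 0, got {e}")
    if not alpha > 0:
        raise StatsError(f"confidence quantile alpha must be > 0, got {alpha}")
    a2f = alpha * alpha * f * (1.0 - f)
    nmin = NP * a2f / (NP * e * e + a2f)
    return int(math.ceil(nmin - 1e-9))


# ---------------------------------------------------------------------------
# full reliability report
# ---------------------------------------------------------------------------

Entry = Union[ICCResult, str]


@dataclass
class ItemReport:
    """All reliability analyses for one item (or the total score)."""

    item: str
    descriptives: dict[str, DescriptiveStats] = field(default_factory=dict)
    inter_rater_icc: dict[str, Entry] = field(default_factory=dict)
    intra_rater_icc: dict[str, Entry] = field(default_factory=dict)
    kruskal_by_session: dict[str, TestResult] = field(default_factory=dict)
    wilcoxon_by_rater: dict[str, Union[TestResult, str]] = field(default_factory=dict)
    bland_altman_rater_pairs: dict[str, Union[BlandAltmanResult, str]] = field(
        default_factory=dict
    )
    bland_altman_sessions: dict[str, Union[BlandAltmanResult, str]] = field(
        default_factory=dict
    )


@dataclass
class ReliabilityReport:
    items: dict[str, ItemReport]
    raters: list[str]
    sessions: list[int]
    unit: str
    n_tests: int  # number of hypothesis tests performed (no correction applied)


def _icc_entry(fn, *args, **kwargs) -> Entry:
    try:
        return fn(*args, **kwargs)
    except (IccUndefinedError, StatsError) as e:
        return f"undefined: {e}"


def reliability_report(panel: RatingsPanel, unit: str = "single") -> ReliabilityReport:
    """Run the complete reliability analysis over a ratings panel.

    Per item and for the total score: inter-rater ICC per session,
    intra-rater ICC per rater, Kruskal-Wallis across raters per session,
    Wilcoxon per rater across sessions, descriptive statistics per
    rater/session, and Bland-Altman limits per rater pair (within session)
    and per rater (across sessions). Degenerate analyses (constant or
    incomplete matrices) are recorded as explanatory strings.

    No multiple-testing correction is applied; ``n_tests`` counts the
    hypothesis tests so readers can judge the familywise context.
    """
    raters, sessions = panel.raters, panel.sessions
    if len(raters) < 2:
        raise StatsError(
            "reliability report needs >= 2 raters; inter-rater analyses cannot run"
        )
    if len(sessions) < 2:
        raise StatsError(
            "reliability report needs >= 2 sessions; test-retest analyses cannot run"
        )
    items: dict[str, ItemReport] = {}
    n_tests = 0
    for item in panel.items:
        rep = ItemReport(item=item)
        for s in sessions:
            rep.inter_rater_icc[str(s)] = _icc_entry(
                icc_two_way_random_absolute, panel, item, s, unit
            )
            try:
                groups = [panel.scores(item, r, s).to_numpy() for r in raters]
                rep.kruskal_by_session[str(s)] = kruskal_wallis(groups)
                n_tests += 1
            except StatsError as e:
                rep.kruskal_by_session[str(s)] = f"skipped: {e}"  # type: ignore[assignment]
        for r in raters:
            rep.intra_rater_icc[r] = _icc_entry(icc_test_retest, panel, item, r, unit)
            m = panel.matrix_across_sessions(item, r).dropna()
            if m.shape[1] >= 2 and len(m) >= 1:
                rep.wilcoxon_by_rater[r] = wilcoxon_signed_rank(
                    m.iloc[:, 0].to_numpy(), m.iloc[:, 1].to_numpy()
                )
                n_tests += 1
            else:
                rep.wilcoxon_by_rater[r] = "skipped: fewer than 2 sessions with pairs"
            try:
                rep.bland_altman_sessions[r] = bland_altman(
                    m.iloc[:, 0].to_numpy(), m.iloc[:, 1].to_numpy()
                )
            except (StatsError, IndexError) as e:
                rep.bland_altman_sessions[r] = f"skipped: {e}"
            for s in sessions:
                vals = panel.scores(item, r, s).to_numpy()
                if vals.size:
                    rep.descriptives[f"{r}|{s}"] = descriptive_stats(vals)
        for s in sessions:
            try:
                mat = panel.matrix(item, s)
            except StatsError:
                continue
            for i, r1 in enumerate(raters):
                for r2 in raters[i + 1 :]:
                    if r1 not in mat.columns or r2 not in mat.columns:
                        continue
                    sub = mat[[r1, r2]].dropna()
                    try:
                        rep.bland_altman_rater_pairs[f"{r1}|{r2}|{s}"] = bland_altman(
                            sub[r1].to_numpy(), sub[r2].to_numpy()
                        )
                    except StatsError as e:
                        rep.bland_altman_rater_pairs[f"{r1}|{r2}|{s}"] = f"skipped: {e}"
        items[item] = rep
    return ReliabilityReport(
        items=items, raters=raters, sessions=sessions, unit=unit, n_tests=n_tests
    )
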