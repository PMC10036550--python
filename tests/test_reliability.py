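"""Reliability statistics against independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import wgskit as w
from wgskit.errors import IccUndefinedError, StatsError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def anova_icc_oracle(x: np.ndarray, unit: str = "single") -> float:
    """Two-way ANOVA mean squares from first principles (explicit loops)."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i]) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (x[i][j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    if unit == "single":
        return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return (msr - mse) / (msr + (msc - mse) / n)


def kruskal_oracle(groups) -> float:
    """Tie-corrected H from the textbook formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n_tot**3 - n_tot)
    return h / correction


def wilcoxon_exact_oracle(d: np.ndarray) -> float:
    """Two-sided exact p by enumerating every sign assignment of the ranks."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = len(d)
    ws = [
        sum(ranks[i] for i in range(n) if mask >> i & 1) for mask in range(2**n)
    ]
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


class TestDescriptives:
    def test_three_point_set(self):
        d = w.descriptive_stats([16.1, 19.1, 26.1])
        assert (d.median, d.min, d.max) == (19.1, 16.1, 26.1)

    def test_constant_list_has_zero_sd(self):
        assert w.descriptive_stats([5.0] * 8).sd == 0.0

    def test_empty_errors(self):
        with pytest.raises(StatsError):
            w.descriptive_stats([])

    def test_matches_direct_formulas(self, rng):
        x = rng.uniform(13.35, 42.0, size=200)
        d = w.descriptive_stats(x)
        n = len(x)
        mean = sum(x) / n
        assert abs(d.mean - mean) < 1e-12
        assert abs(d.sd - math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))) < 1e-12
        xs = sorted(x)
        for q, got in ((0.25, d.q1), (0.5, d.median), (0.75, d.q3)):
            h = (n - 1) * q  # linear interpolation between order statistics
            lo = math.floor(h)
            expected = xs[lo] + (h - lo) * (xs[min(lo + 1, n - 1)] - xs[lo])
            assert abs(got - expected) < 1e-12


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


class TestICC:
    def test_perfect_agreement_is_one(self):
        m = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        assert w.icc_absolute_agreement(m).value == 1.0

    def test_constant_matrix_is_undefined(self):
        with pytest.raises(IccUndefinedError):
            w.icc_absolute_agreement(np.full((4, 3), 2.0))

    def test_missing_cells_listed(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 2.0]])
        with pytest.raises(StatsError, match=r"\(1, 0\)"):
            w.icc_absolute_agreement(m)

    def test_matches_loop_oracle_on_random_matrices(self, rng):
        for _ in range(150):
            n = int(rng.integers(3, 16))
            k = int(rng.integers(2, 6))
            x = rng.integers(1, 6, size=(n, k)).astype(float)
            if np.ptp(x) == 0:
                continue
            for unit in ("single", "average"):
                assert w.icc_absolute_agreement(x, unit).value == pytest.approx(
                    anova_icc_oracle(x, unit), abs=1e-10
                )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(20):
            n, k = int(rng.integers(5, 12)), int(rng.integers(2, 5))
            x = rng.normal(2, 1, size=(n, k))
            df = pd.DataFrame(
                {
                    "subj": np.repeat(np.arange(n), k),
                    "rater": list(range(k)) * n,
                    "score": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(
                df, targets="subj", raters="rater", ratings="score"
            ).set_index("Type")["ICC"]
            assert w.icc_absolute_agreement(x, "single").value == pytest.approx(
                ref["ICC(A,1)"], abs=1e-9
            )
            assert w.icc_absolute_agreement(x, "average").value == pytest.approx(
                ref["ICC(A,k)"], abs=1e-9
            )

    def test_invariant_to_shift_and_positive_scaling(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, size=(8, 3))
            base = w.icc_absolute_agreement(x).value
            assert w.icc_absolute_agreement(x + 7.5).value == pytest.approx(base, abs=1e-9)
            assert w.icc_absolute_agreement(x * 3.2).value == pytest.approx(base, abs=1e-9)

    def test_panel_wrappers(self):
        panel = w.simulate_panel(w.PanelSpec(rater_noise=0.0, session_drift=0.0, seed=2))
        inter = w.icc_two_way_random_absolute(panel, "total", session=1)
        intra = w.icc_test_retest(panel, "total", rater="R1")
        assert inter.value == 1.0 and intra.value == 1.0
        assert inter.k_raters == 3 and intra.k_raters == 2
        assert inter.category == "excellent"

    def test_mean_squares_reported(self, rng):
        x = rng.normal(size=(6, 3))
        res = w.icc_absolute_agreement(x)
        msr, msc, mse = res.ms_rows, res.ms_cols, res.ms_error
        assert res.value == pytest.approx(
            (msr - mse) / (msr + 2 * mse + (3 / 6) * (msc - mse))
        )


class TestCategory:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.39, "poor"), (0.40, "fair"), (0.59, "fair"),
            (0.60, "good"), (0.74, "good"), (0.75, "excellent"),
            (1.0, "excellent"), (-0.2, "poor"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert w.icc_category(value) == expected

    def test_above_one_rejected(self):
        with pytest.raises(StatsError):
            w.icc_category(1.001)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_identical_lists_collapse(self):
        r = w.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.loa_low, r.loa_high) == (0.0, 0.0)
        assert r.within_fraction == 1.0

    def test_constant_difference_collapses_at_offset(self):
        r = w.bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert (r.mean_diff, r.loa_low, r.loa_high) == (1.0, 1.0, 1.0)

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            w.bland_altman([1.0], [1.0, 2.0])

    def test_limits_are_mean_pm_196_sd(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        r = w.bland_altman(a, b)
        d = a - b
        assert r.mean_diff == pytest.approx(d.mean())
        assert r.sd_diff == pytest.approx(d.std(ddof=1))
        assert r.loa_low == pytest.approx(r.mean_diff - 1.96 * r.sd_diff)
        assert r.loa_high == pytest.approx(r.mean_diff + 1.96 * r.sd_diff)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_identical_groups_p_one(self):
        r = w.kruskal_wallis([[2, 2, 2], [2, 2, 2], [2, 2, 2]])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_separated_groups_significant_and_permutation_confirms(self, rng):
        groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
        r = w.kruskal_wallis(groups)
        assert r.p_value < 0.05
        # permutation oracle: resample group labels, compare H
        pooled = np.concatenate([np.asarray(g, float) for g in groups])
        sizes = [len(g) for g in groups]
        h_obs = kruskal_oracle(groups)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            if kruskal_oracle(parts) >= h_obs - 1e-12:
                count += 1
        assert count / n_perm < 0.05

    def test_heavy_ties_match_formula(self, rng):
        for _ in range(30):
            groups = [rng.integers(1, 4, size=rng.integers(4, 9)) for _ in range(3)]
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                continue
            r = w.kruskal_wallis(groups)
            assert r.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-12)
            assert r.p_value == pytest.approx(
                sps.chi2.sf(r.statistic, len(groups) - 1), abs=1e-12
            )

    def test_fewer_than_two_groups(self):
        with pytest.raises(StatsError):
            w.kruskal_wallis([[1, 2, 3]])


class TestWilcoxon:
    def test_identical_pairs_p_one(self):
        r = w.wilcoxon_signed_rank([1, 2, 3, 2], [1, 2, 3, 2])
        assert r.p_value == 1.0
        assert r.n == 0

    def test_single_differing_pair_matches_enumeration(self):
        r = w.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 2.0])
        assert r.p_value == pytest.approx(wilcoxon_exact_oracle(np.array([1.0])))

    def test_matches_enumeration_on_small_samples(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 11))
            d = rng.normal(size=n)
            r = w.wilcoxon_signed_rank(d, np.zeros(n))
            assert r.p_value == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)

    def test_constant_shift_on_twenty_pairs_significant(self, rng):
        x = rng.normal(size=20)
        r = w.wilcoxon_signed_rank(x, x + 0.5)
        assert r.p_value < 0.01

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            w.wilcoxon_signed_rank([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------


class TestMinSampleSize:
    def test_reference_case(self):
        assert w.min_sample_size(1000, 1.96, 0.5, 0.05) == 278

    def test_monotone_decreasing_in_error(self):
        vals = [w.min_sample_size(1000, 1.96, 0.5, e) for e in (0.01, 0.05, 0.1, 0.3)]
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] < 15

    def test_infinite_population_limit(self):
        limit = 1.96**2 * 0.25 / 0.05**2
        assert abs(w.min_sample_size(1e12, 1.96, 0.5, 0.05) - limit) <= 1.0

    @pytest.mark.parametrize(
        "kwargs", [dict(NP=0), dict(f=0.0), dict(f=1.0), dict(e=0.0), dict(alpha=-1)]
    )
    def test_parameter_validation(self, kwargs):
        args = dict(NP=1000, alpha=1.96, f=0.5, e=0.05)
        args.update(kwargs)
        with pytest.raises(StatsError):
            w.min_sample_size(**args)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


class TestReliabilityReport:
    def test_noise_free_panel_perfect_agreement(self):
        panel = w.simulate_panel(w.PanelSpec(rater_noise=0.0, session_drift=0.0, seed=6))
        rep = w.reliability_report(panel)
        for item, r in rep.items.items():
            for entry in itertools.chain(
                r.inter_rater_icc.values(), r.intra_rater_icc.values()
            ):
                if isinstance(entry, str):
                    assert "undefined" in entry  # constant item: explicitly flagged
                else:
                    assert entry.value == 1.0
            for t in r.wilcoxon_by_rater.values():
                assert t.p_value == 1.0

    def test_insufficient_raters_names_skipped_analysis(self):
        panel = w.simulate_panel(w.PanelSpec(n_raters=1, seed=0))
        with pytest.raises(StatsError, match="inter-rater"):
            w.reliability_report(panel)

    def test_insufficient_sessions_names_skipped_analysis(self):
        panel = w.simulate_panel(w.PanelSpec(n_sessions=1, seed=0))
        with pytest.raises(StatsError, match="test-retest"):
            w.reliability_report(panel)

    def test_all_sections_populated(self):
        panel = w.simulate_panel(w.PanelSpec(seed=12))
        rep = w.reliability_report(panel)
        assert set(rep.items) == {str(i) for i in range(1, 15)} | {"total"}
        assert rep.n_tests > 0
        r = rep.items["total"]
        assert set(r.inter_rater_icc) == {"1", "2"}
        assert set(r.intra_rater_icc) == {"R1", "R2", "R3"}
        assert len(r.descriptives) == 6  # 3 raters x 2 sessions
        assert len(r.bland_altman_rater_pairs) == 6  # 3 pairs x 2 sessions
        assert len(r.bland_altman_sessions) == 3
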