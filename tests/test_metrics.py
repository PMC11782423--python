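import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cadeval.annotations import CadFinding, Cohort, NoduleAnnotation, ScanMeta, VoxelMask
from cadeval.matching import MatchConfig, build_match_table
from cadeval.metrics import (
    CIConfig,
    clopper_pearson_ci,
    compare_covariates,
    detection_summary,
    froc,
    rao_scott_ci,
    roc_pr_curves,
    subgroup_sensitivity,
    wilson_ci,
)

# every category-level Wilson CI printed in the reference results, 1 d.p. percent
WILSON_CASES = [
    (104, 121, 78.6, 91.0),
    (121, 142, 78.4, 90.1),
    (104, 125, 75.7, 88.7),
    (16, 42, 25.0, 53.2),
    (5, 5, 56.6, 100.0),
    (81, 82, 93.4, 99.8),
    (18, 25, 52.4, 85.7),
    (6, 8, 40.9, 92.9),
    (13, 15, 62.1, 96.3),
    (137, 149, 86.5, 95.3),
    (123, 149, 75.7, 87.8),
    (141, 149, 89.8, 97.3),
]


class TestWilson:
    @pytest.mark.parametrize("k,n,lo,hi", WILSON_CASES)
    def test_reference_intervals(self, k, n, lo, hi):
        ci = wilson_ci(k, n)
        assert round(100 * ci.lower, 1) == lo
        assert round(100 * ci.upper, 1) == hi

    def test_zero_numerator(self):
        ci = wilson_ci(0, 10)
        assert ci.lower == 0.0
        assert ci.estimate == 0.0

    def test_n_zero_raises(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)

    @given(k=st.integers(0, 50), n=st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_bounds_bracket_estimate(self, k, n):
        if k > n:
            k = n
        ci = wilson_ci(k, n)
        assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0

    def test_width_decreases_in_n(self):
        widths = [
            wilson_ci(int(0.3 * n), n).upper - wilson_ci(int(0.3 * n), n).lower
            for n in (10, 50, 200, 1000)
        ]
        assert widths == sorted(widths, reverse=True)


def _cp_oracle(k, n, alpha=0.05, tol=1e-10):
    """Bisection on binomial tail probabilities (independent of beta.ppf)."""

    def tail_ge(p):  # P(X >= k)
        return 1.0 - stats.binom.cdf(k - 1, n, p)

    def tail_le(p):  # P(X <= k)
        return stats.binom.cdf(k, n, p)

    def bisect(f, target, lo, hi, increasing):
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    lower = 0.0 if k == 0 else bisect(tail_ge, alpha / 2.0, 0.0, 1.0, increasing=True)
    upper = 1.0 if k == n else bisect(tail_le, alpha / 2.0, 0.0, 1.0, increasing=False)
    return lower, upper


class TestClopperPearson:
    def test_zero_numerator_closed_form(self):
        ci = clopper_pearson_ci(0, 20)
        assert ci.lower == 0.0
        assert ci.upper == pytest.approx(1.0 - 0.025 ** (1.0 / 20.0))

    def test_full_numerator(self):
        assert clopper_pearson_ci(7, 7).upper == 1.0

    def test_against_bisection_oracle(self):
        ci = clopper_pearson_ci(7, 10)
        lo, hi = _cp_oracle(7, 10)
        assert ci.lower == pytest.approx(lo, abs=1e-8)
        assert ci.upper == pytest.approx(hi, abs=1e-8)

    def test_contains_wilson_estimate(self):
        for k, n in [(3, 11), (0, 5), (5, 5), (17, 40)]:
            cp = clopper_pearson_ci(k, n)
            assert cp.lower <= k / n <= cp.upper


def _rao_scott_oracle(clusters, level=0.95):
    """Explicit ratio-estimator formula, written independently."""
    m = len(clusters)
    K = sum(k for k, _ in clusters)
    N = sum(n for _, n in clusters)
    p = K / N
    v = m / (m - 1) * sum((k - p * n) ** 2 for k, n in clusters) / N**2
    d = v / (p * (1 - p) / N)
    n_eff = N / d
    z = stats.norm.ppf((1 + level) / 2)
    pe = p
    denom = 1 + z**2 / n_eff
    center = (pe + z**2 / (2 * n_eff)) / denom
    half = z * math.sqrt(pe * (1 - pe) / n_eff + z**2 / (4 * n_eff**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


class TestRaoScott:
    def test_three_cluster_oracle(self):
        clusters = [(2, 2), (0, 2), (1, 1)]
        ci = rao_scott_ci(clusters)
        lo, hi = _rao_scott_oracle(clusters)
        assert ci.lower == pytest.approx(lo, abs=1e-12)
        assert ci.upper == pytest.approx(hi, abs=1e-12)

    def test_singleton_clusters_near_wilson(self):
        # all n_i = 1: design effect reduces to n/(n-1)
        k, n = 37, 120
        clusters = [(1, 1)] * k + [(0, 1)] * (n - k)
        rs = rao_scott_ci(clusters)
        w = wilson_ci(k, n)
        assert rs.lower == pytest.approx(w.lower, abs=0.01)
        assert rs.upper == pytest.approx(w.upper, abs=0.01)

    def test_singleton_clusters_converge_to_wilson(self):
        n = 10_000
        k = 3_000
        clusters = [(1, 1)] * k + [(0, 1)] * (n - k)
        rs = rao_scott_ci(clusters)
        w = wilson_ci(k, n)
        assert abs(rs.lower - w.lower) < 1e-3
        assert abs(rs.upper - w.upper) < 1e-3

    def test_identical_proportions_under_dispersion(self):
        # every cluster at exactly p: ratio variance 0 -> warned, deff kept < 1
        clusters = [(1, 2)] * 6
        with pytest.warns(UserWarning):
            ci = rao_scott_ci(clusters)
        w = wilson_ci(6, 12)
        assert ci.upper - ci.lower < w.upper - w.lower

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            rao_scott_ci([(1, 3)])

    def test_degenerate_all_success(self):
        ci = rao_scott_ci([(2, 2), (3, 3)])
        assert ci.estimate == 1.0
        assert ci.upper == 1.0


class TestDetectionSummary:
    def test_paper_operating_point(self, paper_match_table):
        ds = detection_summary(paper_match_table)
        assert (ds.scan_sensitivity.numerator, ds.scan_sensitivity.denominator) == (104, 121)
        assert round(ds.f1, 3) == 0.846
        assert ds.scan_fppi == pytest.approx(21 / 121)
        assert ds.fp_per_nodule_scan == pytest.approx(49 / 121)
        assert (ds.nodule_sensitivity.numerator, ds.nodule_sensitivity.denominator) == (
            149,
            183,
        )
        assert ds.f1_ci_bootstrap is not None
        lo, hi = ds.f1_ci_bootstrap
        assert lo < ds.f1 < hi

    def test_zero_tp_gives_zero_f1(self, block_factory):
        mask = block_factory((2, 2, 2), (2, 2, 2), (64, 64, 64))
        far = block_factory((40, 40, 40), (2, 2, 2), (64, 64, 64))
        cohort = Cohort(
            scans=[ScanMeta("s1", True), ScanMeta("s2", False)],
            gt_nodules=[
                NoduleAnnotation("s1", "n1", mask, "solid", False, False, "middle", 5.0,
                                 mask.volume_mm3)
            ],
            findings=[
                CadFinding("s1", "f1", far, 0.5, "solid", False, False, "middle", 5.0,
                           far.volume_mm3)
            ],
        )
        ds = detection_summary(build_match_table(cohort), bootstrap_f1=0)
        assert ds.f1 == 0.0


class TestRocPr:
    def test_perfect_separation(self):
        r = roc_pr_curves([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert r.auc_roc == 1.0
        assert r.auc_pr == pytest.approx(1.0)
        assert r.auc_roc_var == 0.0

    def test_all_ties(self):
        r = roc_pr_curves([0.5] * 10, [True] * 5 + [False] * 5)
        assert r.auc_roc == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_pr_curves([0.1, 0.2], [True, True])

    def test_auc_equals_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            truths = rng.random(n) < 0.5
            if truths.all() or not truths.any():
                continue
            r = roc_pr_curves(scores, truths)
            pos, neg = scores[truths], scores[~truths]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert r.auc_roc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_delong_against_independent_placement(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=25) + np.repeat([1.0, 0.0], [10, 15])
        truths = np.repeat([True, False], [10, 15])
        r = roc_pr_curves(scores, truths)
        pos, neg = scores[:10], scores[10:]
        # placement values computed by explicit pairwise comparison
        v01 = np.array([np.mean([(p > q) + 0.5 * (p == q) for q in neg]) for p in pos])
        v10 = np.array([np.mean([(p > q) + 0.5 * (p == q) for p in pos]) for q in neg])
        var = np.var(v01, ddof=1) / 10 + np.var(v10, ddof=1) / 15
        assert r.auc_roc_var == pytest.approx(var, abs=1e-9)

    def test_average_precision_matches_sklearn(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(2)
        scores = rng.random(40)
        truths = rng.random(40) < 0.4
        r = roc_pr_curves(scores, truths)
        assert r.auc_pr == pytest.approx(average_precision_score(truths, scores), abs=1e-12)


def _toy_froc_cohort(block_factory):
    g = (64, 64, 64)
    m1 = block_factory((2, 2, 2), (3, 3, 3), g)
    m2 = block_factory((20, 20, 20), (3, 3, 3), g)
    far = block_factory((50, 50, 50), (2, 2, 2), g)
    scans = [ScanMeta("s1", True), ScanMeta("s2", False)]
    nod = lambda nid, m: NoduleAnnotation("s1", nid, m, "solid", False, False, "middle",
                                          5.0, m.volume_mm3)
    fnd = lambda fid, m, c: CadFinding("s1" if fid != "f3" else "s2", fid, m, c, "solid",
                                       False, False, "middle", 5.0, m.volume_mm3)
    return Cohort(
        scans=scans,
        gt_nodules=[nod("n1", m1), nod("n2", m2)],
        findings=[fnd("f1", m1, 0.9), fnd("f2", m2, 0.6), fnd("f3", far, 0.3)],
    )


class TestFroc:
    def test_hand_enumerated_staircase(self, block_factory):
        curve = froc(_toy_froc_cohort(block_factory), denominator="all")
        # thresholds 0.9, 0.6, 0.3 over 2 scans, 2 GT nodules
        assert curve.points[0] == (0.0, 0.0, float("inf"))
        assert curve.points[1] == pytest.approx((0.0, 0.5, 0.9))
        assert curve.points[2] == pytest.approx((0.0, 1.0, 0.6))
        assert curve.points[3] == pytest.approx((0.5, 1.0, 0.3))

    def test_monotone(self, block_factory):
        curve = froc(_toy_froc_cohort(block_factory))
        fps = [p[0] for p in curve.points]
        sens = [p[1] for p in curve.points]
        assert fps == sorted(fps)
        assert sens == sorted(sens)

    def test_no_findings(self):
        cohort = Cohort(scans=[ScanMeta("s1", False)])
        curve = froc(cohort)
        assert curve.points == [(0.0, 0.0, float("inf"))]

    def test_nodule_containing_denominator(self, block_factory):
        curve = froc(_toy_froc_cohort(block_factory), denominator="nodule_containing")
        assert curve.points[-1][0] == pytest.approx(1.0)  # 1 FP / 1 nodule scan


class TestSubgroups:
    def test_paper_age_strata(self, paper_fixture, paper_match_table):
        out = subgroup_sensitivity(paper_match_table, paper_fixture.cohort, "age_group")
        assert set(out) == {"under_55", "55_plus"}
        total_k = sum(ci.numerator for ci in out.values())
        total_n = sum(ci.denominator for ci in out.values())
        assert total_k == 149 and total_n == 183

    def test_single_stratum_reproduces_overall(self, paper_fixture, paper_match_table):
        out = subgroup_sensitivity(paper_match_table, paper_fixture.cohort, "slice_thickness_mm")
        (ci,) = out.values()
        assert ci.numerator == 149 and ci.denominator == 183

    def test_unknown_variable(self, paper_fixture, paper_match_table):
        with pytest.raises(ValueError):
            subgroup_sensitivity(paper_match_table, paper_fixture.cohort, "nope")


class TestCompareCovariates:
    def test_proportional_table_is_independent(self):
        scans = []
        i = 0
        for contains in (True, False):
            for sex in ("male", "female"):
                for _ in range(10):
                    scans.append(ScanMeta(f"s{i}", contains, sex=sex))
                    i += 1
        out = compare_covariates(scans, ["sex"])
        assert out["sex"].statistic == pytest.approx(0.0)
        assert out["sex"].p_value == pytest.approx(1.0)

    def test_paper_age_table(self, paper_fixture):
        out = compare_covariates(paper_fixture.cohort.scans, ["age_group"])
        c = out["age_group"]
        table = {tuple(row) for row in c.table.tolist()}
        assert table == {(24.0, 78.0), (97.0, 64.0)}
        assert c.p_value < 0.001

    def test_three_by_two_against_cell_sum_oracle(self):
        rng = np.random.default_rng(4)
        scans = []
        i = 0
        for machine in ("A", "B", "C"):
            for contains in (True, False):
                for _ in range(int(rng.integers(5, 20))):
                    scans.append(ScanMeta(f"s{i}", contains, machine_type=machine))
                    i += 1
        c = compare_covariates(scans, ["machine_type"])["machine_type"]
        obs = c.table
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row @ col / obs.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        assert c.statistic == pytest.approx(stat, abs=1e-10)
        assert c.dof == 2

    def test_missing_group_raises(self):
        scans = [ScanMeta("s1", True), ScanMeta("s2", True)]
        with pytest.raises(ValueError):
            compare_covariates(scans)
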