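"""Detection performance statistics and confidence intervals.

Implements the interval machinery used throughout the evaluation:

* Wilson score interval (no continuity correction) for plain proportions;
* Clopper-Pearson exact interval (beta tail inversion);
* Rao-Scott cluster-adjusted interval for within-scan correlated binary
  outcomes (design-effect-scaled effective sample size fed into Wilson);
* empirical ROC with DeLong AUC variance, step-wise average-precision PR;
* FROC (lesion sensitivity vs. average FP per scan over score thresholds);
* per-stratum subgroup sensitivity and chi-square covariate comparison.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .annotations import Cohort, ScanMeta
from .matching import MatchConfig, MatchTable, build_match_table

__all__ = [
    "CIConfig",
    "ProportionCI",
    "wilson_ci",
    "clopper_pearson_ci",
    "rao_scott_ci",
    "DetectionSummary",
    "detection_summary",
    "RocPrResult",
    "roc_pr_curves",
    "FrocCurve",
    "froc",
    "subgroup_sensitivity",
    "CovariateComparison",
    "compare_covariates",
]


@dataclass(frozen=True)
class CIConfig:
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence_level < 1.0):
            raise ValueError(f"confidence_level must be in (0, 1), got {self.confidence_level}")

    @property
    def z(self) -> float:
        """Standard-normal quantile at (1 + level) / 2 (1.959964 at 0.95)."""
        return float(stats.norm.ppf((1.0 + self.confidence_level) / 2.0))

    @property
    def alpha(self) -> float:
        return 1.0 - self.confidence_level


@dataclass(frozen=True)
class ProportionCI:
    numerator: float
    denominator: float
    estimate: float
    lower: float
    upper: float
    method: str

    def as_percent(self, digits: int = 1) -> str:
        return (
            f"{100 * self.estimate:.{digits}f} "
            f"({100 * self.lower:.{digits}f}-{100 * self.upper:.{digits}f})"
        )


def wilson_ci(k: float, n: float, config: CIConfig = CIConfig()) -> ProportionCI:
    """Wilson score interval (score-test inversion, no continuity correction).

    ``k`` may be fractional: the Rao-Scott adjustment reuses this formula at
    an effective (non-integer) sample size.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    z = config.z
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # the score bounds are exactly 0/1 at the boundaries; snap roundoff
    lower = 0.0 if p == 0.0 else max(0.0, center - half)
    upper = 1.0 if p == 1.0 else min(1.0, center + half)
    return ProportionCI(
        numerator=k,
        denominator=n,
        estimate=p,
        lower=lower,
        upper=upper,
        method="wilson",
    )


def clopper_pearson_ci(k: int, n: int, config: CIConfig = CIConfig()) -> ProportionCI:
    """Exact (Clopper-Pearson) interval from beta tail quantiles."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    a = config.alpha / 2.0
    lower = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return ProportionCI(
        numerator=k,
        denominator=n,
        estimate=k / n,
        lower=lower,
        upper=upper,
        method="clopper_pearson",
    )


def rao_scott_ci(
    cluster_counts: Sequence[tuple[float, float]], config: CIConfig = CIConfig()
) -> ProportionCI:
    """Cluster-adjusted proportion interval for correlated binary data.

    The ratio estimate ``p = sum(k_i) / sum(n_i)`` gets a with-replacement
    ratio-estimator variance with the m/(m-1) small-sample factor (m =
    number of clusters).  The design effect (ratio-estimator variance over
    binomial variance) rescales the sample size, and a Wilson interval is
    built at the effective counts.  A design effect below 1 is kept as
    computed, with a warning.
    """
    clusters = [(float(k), float(n)) for k, n in cluster_counts]
    if any(n < 1 for _, n in clusters):
        raise ValueError("every cluster needs n_i >= 1")
    m = len(clusters)
    if m < 2:
        raise ValueError("Rao-Scott variance needs at least 2 clusters")
    K = sum(k for k, _ in clusters)
    N = sum(n for _, n in clusters)
    p = K / N

    if p == 0.0 or p == 1.0:
        deff = 1.0  # ratio and binomial variances both vanish
    else:
        v_ratio = (m / (m - 1.0)) * sum((k - p * n) ** 2 for k, n in clusters) / (N * N)
        v_binom = p * (1.0 - p) / N
        deff = v_ratio / v_binom
        if deff < 1.0:
            warnings.warn(
                f"Rao-Scott design effect {deff:.3f} < 1 (under-dispersed clusters); "
                "kept as computed",
                stacklevel=2,
            )
    if deff == 0.0:
        deff = 1.0 / N  # all-identical proportions: degenerate variance, cap n_eff
    n_eff = N / deff
    ci = wilson_ci(p * n_eff, n_eff, config)
    return ProportionCI(
        numerator=K,
        denominator=N,
        estimate=p,
        lower=ci.lower,
        upper=ci.upper,
        method="rao_scott",
    )


# ---------------------------------------------------------------------------
# Operating-point summary
# ---------------------------------------------------------------------------

@dataclass
class DetectionSummary:
    scan_sensitivity: ProportionCI
    scan_specificity: ProportionCI | None
    scan_precision: ProportionCI | None
    f1: float
    f1_ci_clopper: tuple[float, float] | None
    f1_ci_bootstrap: tuple[float, float] | None
    scan_fppi: float
    nodule_sensitivity: ProportionCI
    fp_per_nodule_scan: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def ci(c: ProportionCI | None):
            return None if c is None else vars(c)

        return {
            "scan_sensitivity": ci(self.scan_sensitivity),
            "scan_specificity": ci(self.scan_specificity),
            "scan_precision": ci(self.scan_precision),
            "f1": self.f1,
            "f1_ci_clopper": self.f1_ci_clopper,
            "f1_ci_bootstrap": self.f1_ci_bootstrap,
            "scan_fppi": self.scan_fppi,
            "nodule_sensitivity": ci(self.nodule_sensitivity),
            "fp_per_nodule_scan": self.fp_per_nodule_scan,
            "undefined": self.undefined,
        }


def _f1_from_counts(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2.0 * p * r / (p + r)


def detection_summary(
    match_table: MatchTable,
    config: CIConfig = CIConfig(),
    bootstrap_f1: int = 1000,
    bootstrap_seed: int = 0,
) -> DetectionSummary:
    """Operating-point summary at both scan and nodule level.

    The F1 interval is reported two ways: a Clopper-Pearson heuristic on
    ``(round(F1 * n), n)`` with ``n = TP + (FP + FN) / 2`` (the paper-style
    construction, which F1 does not strictly license) and a percentile
    bootstrap over scans (recommended).
    """
    tp = match_table.scan_count("TP")
    fn = match_table.scan_count("FN")
    fp = match_table.scan_count("FP")
    tn = match_table.scan_count("TN")
    undefined: list[str] = []

    n_pos = tp + fn
    n_neg = fp + tn
    if n_pos == 0:
        raise ValueError("no nodule-containing scans; sensitivity undefined")
    sens = wilson_ci(tp, n_pos, config)
    spec = wilson_ci(tn, n_neg, config) if n_neg > 0 else None
    if spec is None:
        undefined.append("scan_specificity")
    prec = wilson_ci(tp, tp + fp, config) if (tp + fp) > 0 else None
    if prec is None:
        undefined.append("scan_precision")

    f1 = _f1_from_counts(tp, fp, fn)
    f1_cp = None
    if tp + fp + fn > 0:
        n_eff = int(round(tp + (fp + fn) / 2.0))
        if n_eff > 0:
            ci = clopper_pearson_ci(int(round(f1 * n_eff)), n_eff, config)
            f1_cp = (ci.lower, ci.upper)

    f1_boot = None
    if bootstrap_f1 and (tp + fp + fn) > 0:
        rng = np.random.default_rng(bootstrap_seed)
        labels = np.array(list(match_table.scan_labels.values()))
        n_scans = labels.size
        stats_ = []
        for _ in range(bootstrap_f1):
            sample = labels[rng.integers(0, n_scans, n_scans)]
            btp = int((sample == "TP").sum())
            bfp = int((sample == "FP").sum())
            bfn = int((sample == "FN").sum())
            if btp + bfp + bfn == 0:
                continue
            stats_.append(_f1_from_counts(btp, bfp, bfn))
        if stats_:
            lo, hi = np.quantile(stats_, [config.alpha / 2.0, 1.0 - config.alpha / 2.0])
            f1_boot = (float(lo), float(hi))

    scan_fppi = fp / n_pos

    # nodule level: scans (with >= 1 GT nodule) are the clusters
    clusters: dict[str, list[int]] = {}
    for p in match_table.pairs:
        sid = match_table.pair_scan[p.nodule_id]
        clusters.setdefault(sid, [0, 0])
        clusters[sid][0] += 1
        clusters[sid][1] += 1
    for nid in match_table.fn_nodules:
        sid = match_table.fn_scan[nid]
        clusters.setdefault(sid, [0, 0])
        clusters[sid][1] += 1
    cluster_counts = [(k, n) for k, n in clusters.values()]
    if len(cluster_counts) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nod_sens = rao_scott_ci(cluster_counts, config)
    elif cluster_counts:
        k, n = cluster_counts[0]
        nod_sens = wilson_ci(k, n, config)
        undefined.append("nodule_sensitivity_cluster_ci")
    else:
        raise ValueError("no GT nodules; nodule-level sensitivity undefined")

    fp_nodule_scans = match_table.n_fp_in_nodule_scans / n_pos

    return DetectionSummary(
        scan_sensitivity=sens,
        scan_specificity=spec,
        scan_precision=prec,
        f1=f1,
        f1_ci_clopper=f1_cp,
        f1_ci_bootstrap=f1_boot,
        scan_fppi=scan_fppi,
        nodule_sensitivity=nod_sens,
        fp_per_nodule_scan=fp_nodule_scans,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Empirical AUC (Mann-Whitney with half-credit ties) and its DeLong
    variance from placement values."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    tz = _midrank(allv)
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m  # placement of each negative among positives
    s = 0.0
    if m > 1:
        s += np.var(v01, ddof=1) / m
    if n > 1:
        s += np.var(v10, ddof=1) / n
    return float(auc), float(s)


@dataclass
class RocPrResult:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    auc_roc: float
    auc_roc_var: float
    auc_roc_ci: tuple[float, float]
    recall: np.ndarray
    precision: np.ndarray
    auc_pr: float


def roc_pr_curves(
    scores: Sequence[float], truths: Sequence[bool], config: CIConfig = CIConfig()
) -> RocPrResult:
    """Empirical ROC (AUC + DeLong CI) and PR (average precision) curves
    from one score/label pair per scan."""
    y = np.asarray(truths, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    auc, var = _delong_auc_variance(pos, neg)
    z = config.z
    half = z * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # empirical ROC staircase over distinct thresholds (descending)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [s.size - 1]])
    tps = np.cumsum(y_sorted)[cut]
    fps = np.cumsum(~y_sorted)[cut]
    tpr = np.concatenate([[0.0], tps / pos.size])
    fpr = np.concatenate([[0.0], fps / neg.size])
    thr = np.concatenate([[np.inf], s_sorted[cut]])

    # PR: step-wise average precision (no interpolation)
    prec = tps / (tps + fps)
    rec = tps / pos.size
    rec_full = np.concatenate([[0.0], rec])
    auc_pr = float(np.sum((rec_full[1:] - rec_full[:-1]) * prec))

    return RocPrResult(
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=thr,
        auc_roc=auc,
        auc_roc_var=var,
        auc_roc_ci=ci,
        recall=np.concatenate([[0.0], rec]),
        precision=np.concatenate([[1.0], prec]),
        auc_pr=auc_pr,
    )


def scan_scores(cohort: Cohort) -> tuple[list[float], list[bool]]:
    """Per-scan ROC input: max finding confidence (0 if none) vs truth."""
    best: dict[str, float] = {s.scan_id: 0.0 for s in cohort.scans}
    for f in cohort.findings:
        best[f.scan_id] = max(best[f.scan_id], f.confidence)
    scores = [best[s.scan_id] for s in cohort.scans]
    truths = [s.contains_nodule for s in cohort.scans]
    return scores, truths


# ---------------------------------------------------------------------------
# FROC
# ---------------------------------------------------------------------------

@dataclass
class FrocCurve:
    points: list[tuple[float, float, float]]  # (avg_fp_per_scan, sensitivity, threshold)
    denominator_scans: str  # 'all' or 'nodule_containing'


def froc(
    cohort: Cohort,
    match_config: MatchConfig = MatchConfig(),
    denominator: str = "all",
) -> FrocCurve:
    """Free-response ROC: at each distinct confidence threshold (descending),
    rematch the findings with confidence >= threshold and record lesion
    sensitivity against average false positives per scan."""
    if denominator not in ("all", "nodule_containing"):
        raise ValueError("denominator must be 'all' or 'nodule_containing'")
    n_gt = len(cohort.gt_nodules)
    if denominator == "all":
        n_scans = len(cohort.scans)
    else:
        n_scans = sum(1 for s in cohort.scans if s.contains_nodule)
    if n_scans == 0:
        raise ValueError("no scans in the FROC denominator")
    points: list[tuple[float, float, float]] = [(0.0, 0.0, float("inf"))]
    if not cohort.findings:
        return FrocCurve(points=points, denominator_scans=denominator)
    thresholds = sorted({f.confidence for f in cohort.findings}, reverse=True)
    for t in thresholds:
        sub = Cohort(
            scans=cohort.scans,
            gt_nodules=cohort.gt_nodules,
            findings=[f for f in cohort.findings if f.confidence >= t],
        )
        mt = build_match_table(sub, match_config)
        sens = mt.n_tp_nodules / n_gt if n_gt else 0.0
        fp = len(mt.fp_findings) / n_scans
        points.append((fp, sens, t))
    return FrocCurve(points=points, denominator_scans=denominator)


# ---------------------------------------------------------------------------
# Subgroups and covariates
# ---------------------------------------------------------------------------

def subgroup_sensitivity(
    match_table: MatchTable,
    cohort: Cohort,
    variable: str,
    config: CIConfig = CIConfig(),
) -> dict[str, ProportionCI]:
    """Nodule-level sensitivity per stratum of a scan-level covariate, with
    Rao-Scott intervals (scans as clusters).  Strata with no nodules are
    omitted with a warning; single-cluster strata fall back to Wilson."""
    if variable not in ScanMeta.__dataclass_fields__:
        raise ValueError(f"unknown grouping variable {variable!r}")
    meta = cohort.scan_map()
    matched = match_table.matched_nodule_ids()
    strata: dict[str, dict[str, list[int]]] = {}
    for n in cohort.gt_nodules:
        level = str(getattr(meta[n.scan_id], variable))
        per_scan = strata.setdefault(level, {})
        cell = per_scan.setdefault(n.scan_id, [0, 0])
        cell[1] += 1
        if n.nodule_id in matched:
            cell[0] += 1
    out: dict[str, ProportionCI] = {}
    for level in sorted(strata):
        clusters = [(k, n) for k, n in strata[level].values()]
        if not clusters:
            warnings.warn(f"stratum {level!r} has no nodules; omitted", stacklevel=2)
            continue
        if len(clusters) == 1:
            k, n = clusters[0]
            out[level] = wilson_ci(k, n, config)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[level] = rao_scott_ci(clusters, config)
    return out


@dataclass
class CovariateComparison:
    variable: str
    levels: list[str]
    table: np.ndarray  # levels x (nodule, non-nodule)
    statistic: float
    dof: int
    p_value: float
    expected_cell_warning: bool


def compare_covariates(
    scans: Sequence[ScanMeta], variables: Sequence[str] | None = None
) -> dict[str, CovariateComparison]:
    """Pearson chi-square (no continuity correction) of each covariate
    against nodule-containing status."""
    if variables is None:
        variables = ["age_group", "sex", "other_abnormality", "machine_type", "scan_type"]
    groups = [s for s in scans if s.contains_nodule], [s for s in scans if not s.contains_nodule]
    if not groups[0] or not groups[1]:
        raise ValueError("both scan groups (nodule / non-nodule) must be present")
    out: dict[str, CovariateComparison] = {}
    for var in variables:
        if var not in ScanMeta.__dataclass_fields__:
            raise ValueError(f"unknown covariate {var!r}")
        levels = sorted({str(getattr(s, var)) for s in scans})
        if len(levels) < 2:
            warnings.warn(f"covariate {var!r} has a single level; skipped", stacklevel=2)
            continue
        table = np.zeros((len(levels), 2), dtype=float)
        for col, grp in enumerate(groups):
            for s in grp:
                table[levels.index(str(getattr(s, var))), col] += 1
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        out[var] = CovariateComparison(
            variable=var,
            levels=levels,
            table=table,
            statistic=float(chi2),
            dof=int(dof),
            p_value=float(p),
            expected_cell_warning=bool((expected == 0).any()),
        )
    return out
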