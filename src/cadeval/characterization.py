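"""Concordance of predicted nodule characteristics on matched pairs,
stratified size-error summaries, and Bland-Altman agreement.

All comparisons use only matched (correctly detected) nodules: missed
nodules carry no prediction.  The sign convention throughout is
``difference = prediction - ground truth``, so a positive bias means the
detector over-measures.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import Cohort, LOBES, TEXTURES
from .matching import MatchTable
from .metrics import CIConfig, ProportionCI, wilson_ci

__all__ = [
    "ATTRIBUTES",
    "ConcordanceRow",
    "ConcordanceTable",
    "concordance",
    "missed_vs_detected_profile",
    "MaeResult",
    "mae_stratified",
    "BlandAltmanResult",
    "bland_altman",
    "matched_value_pairs",
    "DIAMETER_EDGES_MM",
    "VOLUME_EDGES_MM3",
]

ATTRIBUTES = ("texture", "calcification", "spiculation", "lobe")

DIAMETER_EDGES_MM = (6.0, 8.0)
VOLUME_EDGES_MM3 = (100.0, 250.0)


def _attr_levels(attribute: str) -> list:
    if attribute == "texture":
        return list(TEXTURES)
    if attribute == "lobe":
        return list(LOBES)
    return [True, False]


def _matched_records(match_table: MatchTable, cohort: Cohort):
    nodules = {(n.scan_id, n.nodule_id): n for n in cohort.gt_nodules}
    findings = {(f.scan_id, f.finding_id): f for f in cohort.findings}
    for p in match_table.pairs:
        sid = match_table.pair_scan[p.nodule_id]
        yield nodules[(sid, p.nodule_id)], findings[(sid, p.finding_id)]


@dataclass(frozen=True)
class ConcordanceRow:
    gt_class: str
    n_detected: int
    n_correct: int
    sensitivity: ProportionCI | None  # None when no detected nodules in the class


@dataclass
class ConcordanceTable:
    attribute: str
    rows: list[ConcordanceRow]
    overall_n: int
    overall_correct: int
    overall_sensitivity: ProportionCI


def concordance(
    match_table: MatchTable,
    cohort: Cohort,
    attribute: str,
    config: CIConfig = CIConfig(),
) -> ConcordanceTable:
    """Per-GT-class fraction of matched nodules whose predicted class equals
    the GT class, with Wilson intervals, plus the overall fraction."""
    if attribute not in ATTRIBUTES:
        raise ValueError(f"attribute must be one of {ATTRIBUTES}, got {attribute!r}")
    counts: dict = {level: [0, 0] for level in _attr_levels(attribute)}
    total = correct = 0
    for n, f in _matched_records(match_table, cohort):
        gt_val = getattr(n, attribute)
        pred_val = getattr(f, attribute)
        counts[gt_val][0] += 1
        total += 1
        if gt_val == pred_val:
            counts[gt_val][1] += 1
            correct += 1
    rows = []
    for level, (n_det, n_cor) in counts.items():
        ci = wilson_ci(n_cor, n_det, config) if n_det > 0 else None
        rows.append(
            ConcordanceRow(
                gt_class=str(level), n_detected=n_det, n_correct=n_cor, sensitivity=ci
            )
        )
    if total == 0:
        raise ValueError("no matched pairs: concordance undefined")
    return ConcordanceTable(
        attribute=attribute,
        rows=rows,
        overall_n=total,
        overall_correct=correct,
        overall_sensitivity=wilson_ci(correct, total, config),
    )


def _bin_label(value: float, edges: tuple[float, float], unit: str) -> str:
    lo, hi = edges
    if value < lo:
        return f"<{lo:g}{unit}"
    if value <= hi:
        return f"{lo:g}-{hi:g}{unit}"
    return f">{hi:g}{unit}"


def missed_vs_detected_profile(match_table: MatchTable, cohort: Cohort):
    """Characteristic distribution of GT nodules among CAD-detected and
    CAD-missed, as a tidy DataFrame (characteristic, level, detected,
    missed, detected_pct, missed_pct), including diameter and volume bins."""
    import pandas as pd

    matched = match_table.matched_nodule_ids()
    rows: list[dict] = []

    def levels_for(n):
        yield "texture", n.texture
        yield "calcification", "yes" if n.calcification else "no"
        yield "spiculation", "yes" if n.spiculation else "no"
        yield "lobe", n.lobe
        yield "diameter", _bin_label(n.avg_diameter_mm, DIAMETER_EDGES_MM, " mm")
        yield "volume", _bin_label(n.volume_mm3, VOLUME_EDGES_MM3, " mm3")

    order: list[tuple[str, str]] = []
    tally: dict[tuple[str, str], list[int]] = {}
    for n in cohort.gt_nodules:
        col = 0 if n.nodule_id in matched else 1
        for char, level in levels_for(n):
            key = (char, str(level))
            if key not in tally:
                tally[key] = [0, 0]
                order.append(key)
            tally[key][col] += 1
    n_det = len(matched)
    n_miss = len(cohort.gt_nodules) - n_det
    for (char, level) in order:
        det, miss = tally[(char, level)]
        rows.append(
            {
                "characteristic": char,
                "level": level,
                "detected": det,
                "missed": miss,
                "detected_pct": 100.0 * det / n_det if n_det else float("nan"),
                "missed_pct": 100.0 * miss / n_miss if n_miss else 0.0,
            }
        )
    return pd.DataFrame(rows)


def matched_value_pairs(
    match_table: MatchTable, cohort: Cohort, quantity: str
) -> tuple[np.ndarray, np.ndarray]:
    """(gt, predicted) arrays of diameters (mm) or volumes (mm3) over
    matched pairs."""
    if quantity not in ("diameter", "volume"):
        raise ValueError("quantity must be 'diameter' or 'volume'")
    attr = "avg_diameter_mm" if quantity == "diameter" else "volume_mm3"
    gt, pred = [], []
    for n, f in _matched_records(match_table, cohort):
        gt.append(getattr(n, attr))
        pred.append(getattr(f, attr))
    return np.asarray(gt, dtype=float), np.asarray(pred, dtype=float)


@dataclass(frozen=True)
class MaeResult:
    stratum: str
    n: int
    mae: float
    ci_lower: float
    ci_upper: float


def mae_stratified(
    match_table: MatchTable,
    cohort: Cohort,
    quantity: str,
    edges: tuple[float, float] | None = None,
    config: CIConfig = CIConfig(),
    method: str = "t",
    bootstrap_iters: int = 2000,
    bootstrap_seed: int = 0,
) -> dict[str, MaeResult]:
    """Mean absolute error of predicted vs GT size, overall and per GT-size
    stratum.  The CI is a t-interval on the absolute errors by default
    (``method='t'``); a percentile bootstrap is available (``'bootstrap'``).
    Empty strata are omitted with a warning; singleton strata get NaN CIs.
    """
    if method not in ("t", "bootstrap"):
        raise ValueError("method must be 't' or 'bootstrap'")
    if edges is None:
        edges = DIAMETER_EDGES_MM if quantity == "diameter" else VOLUME_EDGES_MM3
    unit = " mm" if quantity == "diameter" else " mm3"
    gt, pred = matched_value_pairs(match_table, cohort, quantity)
    abs_err = np.abs(pred - gt)

    strata: dict[str, np.ndarray] = {"overall": abs_err}
    labels = np.array([_bin_label(v, edges, unit) for v in gt])
    for label in (f"<{edges[0]:g}{unit}", f"{edges[0]:g}-{edges[1]:g}{unit}", f">{edges[1]:g}{unit}"):
        sel = abs_err[labels == label]
        if sel.size == 0:
            warnings.warn(f"stratum {label!r} is empty; omitted", stacklevel=2)
            continue
        strata[label] = sel

    rng = np.random.default_rng(bootstrap_seed)
    out: dict[str, MaeResult] = {}
    for label, errs in strata.items():
        n = errs.size
        mae = float(errs.mean())
        if n < 2:
            lo = hi = float("nan")
        elif method == "t":
            se = errs.std(ddof=1) / math.sqrt(n)
            tq = stats.t.ppf(1.0 - config.alpha / 2.0, n - 1)
            lo, hi = mae - tq * se, mae + tq * se
        else:
            means = rng.choice(errs, size=(bootstrap_iters, n), replace=True).mean(axis=1)
            lo, hi = (
                float(np.quantile(means, config.alpha / 2.0)),
                float(np.quantile(means, 1.0 - config.alpha / 2.0)),
            )
        out[label] = MaeResult(stratum=label, n=n, mae=mae, ci_lower=float(lo), ci_upper=float(hi))
    return out


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    units: str = ""


def bland_altman(
    gt, predicted, config: CIConfig = CIConfig(), units: str = ""
) -> BlandAltmanResult:
    """Bland-Altman agreement of predicted vs ground-truth values.

    Differences are ``predicted - gt``.  Limits of agreement are
    ``bias +/- z * sd`` (z = 1.96 at the default level).  The bias CI is a
    t-interval with SE ``sd / sqrt(n)``; each LoA CI is a t-interval with
    the large-sample SE ``sd * sqrt(1/n + z^2 / (2(n-1)))``.
    """
    gt = np.asarray(gt, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if gt.shape != predicted.shape:
        raise ValueError("paired arrays must have equal length")
    n = gt.size
    if n < 3:
        raise ValueError("Bland-Altman analysis needs n >= 3 pairs")
    d = predicted - gt
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = config.z
    loa_lo = bias - z * sd
    loa_hi = bias + z * sd
    tq = float(stats.t.ppf(1.0 - config.alpha / 2.0, n - 1))
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(1.0 / n + z * z / (2.0 * (n - 1)))
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        ci_bias=(bias - tq * se_bias, bias + tq * se_bias),
        ci_loa_lower=(loa_lo - tq * se_loa, loa_lo + tq * se_loa),
        ci_loa_upper=(loa_hi - tq * se_loa, loa_hi + tq * se_loa),
        units=units,
    )


def bland_altman_plot(gt, predicted, result: BlandAltmanResult, path, title: str = ""):
    """Scatter of differences vs means with shaded bias/LoA bands (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gt = np.asarray(gt, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    mean = (gt + predicted) / 2.0
    diff = predicted - gt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=12, alpha=0.6, color="k")
    for value, ci, color in (
        (result.bias, result.ci_bias, "tab:blue"),
        (result.loa_upper, result.ci_loa_upper, "tab:green"),
        (result.loa_lower, result.ci_loa_lower, "tab:red"),
    ):
        ax.axhline(value, color=color, linestyle="--")
        ax.axhspan(ci[0], ci[1], color=color, alpha=0.15)
    ax.set_xlabel(f"mean of GT and prediction {result.units}".strip())
    ax.set_ylabel(f"prediction - GT {result.units}".strip())
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
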