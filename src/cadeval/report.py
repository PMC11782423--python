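"""Pipeline orchestration and human-readable report rendering.

``run_pipeline`` executes read -> match -> evaluate -> characterize and
writes a JSON metrics bundle plus CSV tables shaped like the published
ones (covariate comparison, subgroup sensitivity, detected-vs-missed
profile, characterization concordance, reader-vs-CAD cross-tab) and curve
data files.  Rendered percentages are half-up at 1 decimal place; full
precision is retained in the JSON bundle.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from . import __version__
from .annotations import Cohort, read_cohort_dir
from .adjudication import ReaderAnnotationSet, detection_cross_tab, reader_performance
from .characterization import (
    ATTRIBUTES,
    bland_altman,
    concordance,
    mae_stratified,
    matched_value_pairs,
    missed_vs_detected_profile,
)
from .matching import MatchConfig, MatchTable, build_match_table
from .metrics import (
    CIConfig,
    compare_covariates,
    detection_summary,
    froc,
    roc_pr_curves,
    scan_scores,
    subgroup_sensitivity,
)

__all__ = ["RunConfig", "run_pipeline", "render_tables", "round_half_up"]

log = logging.getLogger("cadeval")


def round_half_up(value: float, digits: int = 1) -> str:
    """Decimal half-up rounding at the printed precision (0.38095 -> '38.1'
    as a percentage at 1 d.p.)."""
    q = Decimal(10) ** -digits
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_ci(ci, digits: int = 1, scale: float = 100.0) -> str:
    return (
        f"{round_half_up(scale * ci.estimate, digits)} "
        f"({round_half_up(scale * ci.lower, digits)}-{round_half_up(scale * ci.upper, digits)})"
    )


@dataclasses.dataclass
class RunConfig:
    cohort_dir: str
    out_dir: str
    match: MatchConfig = dataclasses.field(default_factory=MatchConfig)
    ci: CIConfig = dataclasses.field(default_factory=CIConfig)
    seed: int = 0
    curves: bool = True
    plots: bool = False
    r1_file: str | None = None


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def evaluate_cohort(
    cohort: Cohort,
    match_config: MatchConfig = MatchConfig(),
    ci_config: CIConfig = CIConfig(),
    seed: int = 0,
    curves: bool = True,
    r1: ReaderAnnotationSet | None = None,
    cross_tab_scope: list[str] | None = None,
) -> dict:
    """Full metrics bundle for a cohort with findings (pure function of the
    inputs, the configs and the seed)."""
    mt = build_match_table(cohort, match_config)
    summary = detection_summary(mt, ci_config, bootstrap_seed=seed)
    bundle: dict = {
        "match": mt.summary(),
        "detection": summary.to_dict(),
        "covariates": {
            v: {
                "levels": c.levels,
                "table": c.table.tolist(),
                "statistic": c.statistic,
                "dof": c.dof,
                "p_value": c.p_value,
            }
            for v, c in compare_covariates(cohort.scans).items()
        },
        "subgroups": {
            var: {level: dataclasses.asdict(ci) for level, ci in
                  subgroup_sensitivity(mt, cohort, var, ci_config).items()}
            for var in ("age_group", "sex", "other_abnormality", "machine_type", "scan_type")
        },
    }

    if mt.pairs:
        bundle["characterization"] = {}
        for attr in ATTRIBUTES:
            tab = concordance(mt, cohort, attr, ci_config)
            bundle["characterization"][attr] = {
                "overall": {
                    "n": tab.overall_n,
                    "correct": tab.overall_correct,
                    "sensitivity": dataclasses.asdict(tab.overall_sensitivity),
                },
                "per_class": [dataclasses.asdict(r) for r in tab.rows],
            }
        bundle["profile"] = missed_vs_detected_profile(mt, cohort).to_dict(orient="records")
        bundle["size_agreement"] = {}
        for quantity, units in (("diameter", "mm"), ("volume", "mm3")):
            gt, pred = matched_value_pairs(mt, cohort, quantity)
            entry = {
                "mae": {k: dataclasses.asdict(v) for k, v in
                        mae_stratified(mt, cohort, quantity, config=ci_config).items()},
            }
            if gt.size >= 3:
                entry["bland_altman"] = dataclasses.asdict(
                    bland_altman(gt, pred, ci_config, units=units)
                )
            bundle["size_agreement"][quantity] = entry

    if curves:
        scores, truths = scan_scores(cohort)
        if any(truths) and not all(truths):
            roc = roc_pr_curves(scores, truths, ci_config)
            bundle["roc"] = {
                "auc_roc": roc.auc_roc,
                "auc_roc_ci": roc.auc_roc_ci,
                "auc_pr": roc.auc_pr,
                "fpr": roc.fpr.tolist(),
                "tpr": roc.tpr.tolist(),
                "recall": roc.recall.tolist(),
                "precision": roc.precision.tolist(),
            }
        fr = froc(cohort, match_config, denominator="all")
        bundle["froc"] = {"denominator": fr.denominator_scans, "points": fr.points}

    if r1 is not None:
        perf = reader_performance(cohort.gt_nodules, r1, mt, ci_config, match_config)
        bundle["reader"] = dataclasses.asdict(perf)
        if cross_tab_scope:
            ct = detection_cross_tab(cohort.gt_nodules, r1, mt, cross_tab_scope, match_config)
            bundle["cross_tab"] = {
                "counts": ct.counts,
                "per_characteristic": ct.per_characteristic,
            }
    bundle["_match_table"] = mt  # in-memory only; stripped before writing
    return bundle


def render_tables(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write one CSV per published-style table from a metrics bundle.
    Missing sections are skipped with a warning."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: "pd.DataFrame"):
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    if "covariates" in bundle:
        rows = []
        for var, c in bundle["covariates"].items():
            for i, level in enumerate(c["levels"]):
                n_nod, n_neg = c["table"][i]
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "nodule_scans": int(n_nod),
                        "nonnodule_scans": int(n_neg),
                        "p_value": round_half_up(c["p_value"], 3),
                    }
                )
        emit("table1_covariates.csv", pd.DataFrame(rows))
    else:
        log.warning("covariates section missing; table skipped")

    if "subgroups" in bundle:
        rows = []
        for var, levels in bundle["subgroups"].items():
            for level, ci in levels.items():
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "n_nodules": int(ci["denominator"]),
                        "sensitivity_pct": round_half_up(100 * ci["estimate"]),
                        "ci": f"{round_half_up(100 * ci['lower'])}-"
                        f"{round_half_up(100 * ci['upper'])}",
                    }
                )
        emit("table2_subgroup_sensitivity.csv", pd.DataFrame(rows))

    if "profile" in bundle:
        emit("table3_detected_vs_missed.csv", pd.DataFrame(bundle["profile"]))
    else:
        log.warning("detected/missed profile missing; table skipped")

    if "characterization" in bundle:
        rows = []
        for attr, section in bundle["characterization"].items():
            for row in section["per_class"]:
                ci = row["sensitivity"]
                rows.append(
                    {
                        "characteristic": attr,
                        "gt_class": row["gt_class"],
                        "n_detected": row["n_detected"],
                        "n_correct": row["n_correct"],
                        "sensitivity_pct_ci": (
                            f"{round_half_up(100 * ci['estimate'])} "
                            f"({round_half_up(100 * ci['lower'])}-"
                            f"{round_half_up(100 * ci['upper'])})"
                            if ci
                            else ""
                        ),
                    }
                )
            overall = section["overall"]
            ci = overall["sensitivity"]
            rows.append(
                {
                    "characteristic": attr,
                    "gt_class": "overall",
                    "n_detected": overall["n"],
                    "n_correct": overall["correct"],
                    "sensitivity_pct_ci": f"{round_half_up(100 * ci['estimate'])} "
                    f"({round_half_up(100 * ci['lower'])}-{round_half_up(100 * ci['upper'])})",
                }
            )
        emit("table4_characterization.csv", pd.DataFrame(rows))

    if "cross_tab" in bundle:
        rows = [
            {
                "characteristic": "all",
                "level": "all",
                "total": sum(bundle["cross_tab"]["counts"].values()),
                **bundle["cross_tab"]["counts"],
            }
        ]
        for char, levels in bundle["cross_tab"]["per_characteristic"].items():
            for level, cells in levels.items():
                rows.append(
                    {
                        "characteristic": char,
                        "level": level,
                        "total": sum(cells.values()),
                        **cells,
                    }
                )
        emit("table5_cross_tab.csv", pd.DataFrame(rows))

    if "roc" in bundle:
        emit("curve_roc.csv", pd.DataFrame({"fpr": bundle["roc"]["fpr"], "tpr": bundle["roc"]["tpr"]}))
        emit(
            "curve_pr.csv",
            pd.DataFrame(
                {"recall": bundle["roc"]["recall"], "precision": bundle["roc"]["precision"]}
            ),
        )
    if "froc" in bundle:
        pts = bundle["froc"]["points"]
        emit(
            "curve_froc.csv",
            pd.DataFrame(pts, columns=["avg_fp_per_scan", "sensitivity", "threshold"]),
        )
    return written


def run_pipeline(config: RunConfig, r1: ReaderAnnotationSet | None = None) -> dict:
    """Execute the full evaluation over a cohort directory and write the
    report bundle (metrics.json + CSV tables + match exports + log)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cohort = read_cohort_dir(config.cohort_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'read' failed for {config.cohort_dir}: {exc}") from exc
    log.info(
        "matching with criterion=%s threshold=%s  <- criterion choice changes results",
        config.match.criterion,
        config.match.iou_threshold,
    )
    try:
        bundle = evaluate_cohort(
            cohort, config.match, config.ci, seed=config.seed, curves=config.curves, r1=r1
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    mt: MatchTable = bundle.pop("_match_table")
    mt.to_json(out / "match.json")
    mt.to_csv(out / "match")

    config_payload = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=_json_default
    )
    bundle["run"] = {
        "cadeval_version": __version__,
        "config": json.loads(config_payload),
        "config_sha256": hashlib.sha256(config_payload.encode()).hexdigest(),
    }
    (out / "metrics.json").write_text(json.dumps(bundle, indent=2, default=_json_default))
    render_tables(bundle, out)
    return bundle
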