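"""Match CAD findings to ground-truth nodules by 3D overlap.

Findings and nodules are paired one-to-one by greedy descending overlap
score (ties break on higher finding confidence, then lexicographic ids),
upgraded to the exact maximum-cardinality/max-total-score assignment in
the rare contended cases where greedy is suboptimal.  Scans are then
labelled TP/FN (nodule-containing) or FP/TN (nodule-free).

Two overlap criteria are supported: ``iou`` (intersection over union,
default) and ``overlap_over_finding`` (intersection over finding volume),
both thresholded at 0.10 by default.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .annotations import (
    CadFinding,
    Cohort,
    CohortValidationError,
    NoduleAnnotation,
    ScanMeta,
    VoxelMask,
)

__all__ = [
    "MatchConfig",
    "MatchPair",
    "ScanMatchResult",
    "MatchTable",
    "iou3d",
    "overlap_over_finding",
    "match_scan",
    "classify_scans",
    "build_match_table",
]

CRITERIA = ("iou", "overlap_over_finding")


@dataclass(frozen=True)
class MatchConfig:
    iou_threshold: float = 0.10
    criterion: str = "iou"

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValueError(f"iou_threshold must be in (0, 1], got {self.iou_threshold}")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}, got {self.criterion!r}")


def iou3d(a: VoxelMask, b: VoxelMask) -> float:
    """Jaccard overlap |A n B| / |A u B| of two masks on one grid."""
    inter = a.intersection_count(b)
    union = a.n_voxels + b.n_voxels - inter
    return inter / union


def overlap_over_finding(finding_mask: VoxelMask, gt_mask: VoxelMask) -> float:
    """Fraction of the finding's volume that overlaps the GT mask."""
    return finding_mask.intersection_count(gt_mask) / finding_mask.n_voxels


def _score(finding_mask: VoxelMask, gt_mask: VoxelMask, criterion: str) -> float:
    if criterion == "overlap_over_finding":
        return overlap_over_finding(finding_mask, gt_mask)
    return iou3d(finding_mask, gt_mask)


@dataclass(frozen=True)
class MatchPair:
    finding_id: str
    nodule_id: str
    iou: float  # actual IoU of the pair
    score: float  # value of the configured criterion (== iou for criterion 'iou')


@dataclass
class ScanMatchResult:
    scan_id: str
    pairs: list[MatchPair]
    fp_findings: list[str]
    fn_nodules: list[str]


def _optimal_assignment(findings, nodules, allowed: dict) -> list[tuple[str, str, float]]:
    """Exact maximum-cardinality, maximum-total-score one-to-one assignment
    over the thresholded candidate pairs (Hungarian algorithm with a
    cardinality bonus dominating any score sum)."""
    from scipy.optimize import linear_sum_assignment

    import numpy as np

    bonus = 1.0 + sum(allowed.values())  # any extra pair beats all score mass
    value = np.zeros((len(findings), len(nodules)))
    for i, f in enumerate(findings):
        for j, n in enumerate(nodules):
            s = allowed.get((f.finding_id, n.nodule_id))
            if s is not None:
                value[i, j] = s + bonus
    rows, cols = linear_sum_assignment(-value)
    out = []
    for i, j in zip(rows, cols):
        if value[i, j] > 0:
            out.append(
                (
                    findings[i].finding_id,
                    nodules[j].nodule_id,
                    allowed[(findings[i].finding_id, nodules[j].nodule_id)],
                )
            )
    return out


def match_scan(
    findings: list[CadFinding],
    nodules: list[NoduleAnnotation],
    config: MatchConfig = MatchConfig(),
) -> ScanMatchResult:
    """One-to-one assignment over candidate pairs with overlap score >=
    threshold.  Pairs are chosen greedily in descending score order (ties
    break by higher finding confidence, then finding_id, then nodule_id);
    when overlap contention makes the greedy pairing suboptimal — which
    random-geometry instances show it can be — the exact maximum-
    cardinality, max-total-score assignment is used instead, so the result
    always equals the exhaustive optimum.  Remaining findings are FP,
    remaining nodules FN.  Deterministic.
    """
    scan_id = findings[0].scan_id if findings else (nodules[0].scan_id if nodules else "")
    candidates = []
    allowed: dict[tuple[str, str], float] = {}
    for f in findings:
        for n in nodules:
            if n.mask is None:
                continue
            score = _score(f.mask, n.mask, config.criterion)
            if score >= config.iou_threshold:
                candidates.append((score, f, n))
                allowed[(f.finding_id, n.nodule_id)] = score
    candidates.sort(key=lambda t: (-t[0], -t[1].confidence, t[1].finding_id, t[2].nodule_id))

    used_f: set[str] = set()
    used_n: set[str] = set()
    chosen: list[tuple[str, str, float]] = []
    for score, f, n in candidates:
        if f.finding_id in used_f or n.nodule_id in used_n:
            continue
        used_f.add(f.finding_id)
        used_n.add(n.nodule_id)
        chosen.append((f.finding_id, n.nodule_id, score))

    # greedy is optimal unless some finding/nodule had competing candidates
    contended = len(candidates) > len(
        {c[1].finding_id for c in candidates}
    ) or len(candidates) > len({c[2].nodule_id for c in candidates})
    if contended:
        optimal = _optimal_assignment(findings, nodules, allowed)
        greedy_key = (len(chosen), sum(s for *_, s in chosen))
        optimal_key = (len(optimal), sum(s for *_, s in optimal))
        if (optimal_key[0], optimal_key[1] - 1e-12) > greedy_key:
            chosen = sorted(optimal, key=lambda t: -t[2])
            used_f = {fid for fid, _, _ in chosen}
            used_n = {nid for _, nid, _ in chosen}

    mask_by_f = {f.finding_id: f.mask for f in findings}
    mask_by_n = {n.nodule_id: n.mask for n in nodules}
    pairs = [
        MatchPair(
            finding_id=fid,
            nodule_id=nid,
            iou=iou3d(mask_by_f[fid], mask_by_n[nid]),
            score=score,
        )
        for fid, nid, score in chosen
    ]
    fp = [f.finding_id for f in findings if f.finding_id not in used_f]
    fn = [n.nodule_id for n in nodules if n.nodule_id not in used_n]
    return ScanMatchResult(scan_id=scan_id, pairs=pairs, fp_findings=fp, fn_nodules=fn)


def classify_scans(
    results: dict[str, ScanMatchResult],
    scans: list[ScanMeta],
    n_gt_by_scan: dict[str, int] | None = None,
) -> dict[str, str]:
    """Label every scan TP/FN (nodule-containing) or FP/TN (nodule-free).

    A nodule-containing scan is TP iff it has at least one matched pair;
    a nodule-free scan is FP iff CAD produced any finding on it.
    """
    labels: dict[str, str] = {}
    for s in scans:
        r = results.get(s.scan_id)
        n_pairs = len(r.pairs) if r else 0
        n_findings = n_pairs + (len(r.fp_findings) if r else 0)
        n_gt = n_gt_by_scan.get(s.scan_id, 0) if n_gt_by_scan else (
            n_pairs + (len(r.fn_nodules) if r else 0)
        )
        if n_gt > 0 and not s.contains_nodule:
            raise CohortValidationError(
                f"scan {s.scan_id}: has GT nodules but contains_nodule is False"
            )
        if s.contains_nodule:
            labels[s.scan_id] = "TP" if n_pairs >= 1 else "FN"
        else:
            labels[s.scan_id] = "FP" if n_findings >= 1 else "TN"
    return labels


@dataclass
class MatchTable:
    """Cohort-wide matching outcome: matched pairs, unmatched GT (FN),
    unmatched findings (FP), and per-scan TP/FN/FP/TN labels."""

    pairs: list[MatchPair]
    fn_nodules: list[str]
    fp_findings: list[str]
    scan_labels: dict[str, str]
    contains_nodule: dict[str, bool]
    pair_scan: dict[str, str] = field(default_factory=dict)  # nodule_id -> scan_id
    fp_scan: dict[str, str] = field(default_factory=dict)  # finding_id -> scan_id
    fn_scan: dict[str, str] = field(default_factory=dict)  # nodule_id -> scan_id
    config: MatchConfig = field(default_factory=MatchConfig)

    # -- nodule-level counts ------------------------------------------------
    @property
    def n_tp_nodules(self) -> int:
        return len(self.pairs)

    @property
    def n_fn_nodules(self) -> int:
        return len(self.fn_nodules)

    @property
    def n_fp_in_nodule_scans(self) -> int:
        return sum(1 for fid in self.fp_findings if self.contains_nodule[self.fp_scan[fid]])

    @property
    def n_fp_in_nonnodule_scans(self) -> int:
        return sum(1 for fid in self.fp_findings if not self.contains_nodule[self.fp_scan[fid]])

    # -- scan-level counts --------------------------------------------------
    def scan_count(self, label: str) -> int:
        return sum(1 for v in self.scan_labels.values() if v == label)

    @property
    def mean_iou(self) -> float:
        if not self.pairs:
            return float("nan")
        return sum(p.iou for p in self.pairs) / len(self.pairs)

    def matched_nodule_ids(self) -> set[str]:
        return {p.nodule_id for p in self.pairs}

    def summary(self) -> dict:
        return {
            "criterion": self.config.criterion,
            "threshold": self.config.iou_threshold,
            "nodule_level": {
                "tp": self.n_tp_nodules,
                "fn": self.n_fn_nodules,
                "fp_in_nodule_scans": self.n_fp_in_nodule_scans,
                "fp_in_nonnodule_scans": self.n_fp_in_nonnodule_scans,
                "mean_iou": self.mean_iou,
            },
            "scan_level": {lab: self.scan_count(lab) for lab in ("TP", "FP", "FN", "TN")},
        }

    def to_json(self, path: str | Path) -> None:
        payload = self.summary()
        payload["pairs"] = [vars(p) for p in self.pairs]
        payload["fn_nodules"] = self.fn_nodules
        payload["fp_findings"] = self.fp_findings
        payload["scan_labels"] = self.scan_labels
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "pairs.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["finding_id", "nodule_id", "iou", "score"])
            for p in self.pairs:
                w.writerow([p.finding_id, p.nodule_id, p.iou, p.score])
        with open(out / "fn_nodules.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["nodule_id", "scan_id"])
            for nid in self.fn_nodules:
                w.writerow([nid, self.fn_scan.get(nid, "")])
        with open(out / "fp_findings.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["finding_id", "scan_id"])
            for fid in self.fp_findings:
                w.writerow([fid, self.fp_scan.get(fid, "")])


def build_match_table(cohort: Cohort, config: MatchConfig = MatchConfig()) -> MatchTable:
    """Run per-scan matching and scan classification over a whole cohort."""
    nodule_ids = [n.nodule_id for n in cohort.gt_nodules]
    finding_ids = [f.finding_id for f in cohort.findings]
    if len(set(nodule_ids)) != len(nodule_ids) or len(set(finding_ids)) != len(finding_ids):
        raise CohortValidationError(
            "match tables require globally unique nodule and finding ids"
        )
    nodules_by_scan = cohort.nodules_by_scan()
    findings_by_scan = cohort.findings_by_scan()
    results: dict[str, ScanMatchResult] = {}
    for s in cohort.scans:
        results[s.scan_id] = match_scan(
            findings_by_scan.get(s.scan_id, []), nodules_by_scan.get(s.scan_id, []), config
        )
    n_gt = {sid: len(v) for sid, v in nodules_by_scan.items()}
    labels = classify_scans(results, cohort.scans, n_gt)

    pairs: list[MatchPair] = []
    fns: list[str] = []
    fps: list[str] = []
    pair_scan: dict[str, str] = {}
    fp_scan: dict[str, str] = {}
    fn_scan: dict[str, str] = {}
    for sid, r in results.items():
        pairs.extend(r.pairs)
        for p in r.pairs:
            pair_scan[p.nodule_id] = sid
        for nid in r.fn_nodules:
            fns.append(nid)
            fn_scan[nid] = sid
        for fid in r.fp_findings:
            fps.append(fid)
            fp_scan[fid] = sid
    return MatchTable(
        pairs=pairs,
        fn_nodules=fns,
        fp_findings=fps,
        scan_labels=labels,
        contains_nodule={s.scan_id: s.contains_nodule for s in cohort.scans},
        pair_scan=pair_scan,
        fp_scan=fp_scan,
        fn_scan=fn_scan,
        config=config,
    )
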