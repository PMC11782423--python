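"""Reference-standard construction from a report-derived nodule list, a
blinded annotating reader (R1), and an arbitrating reader (R2).

Nodules present in both sources (paired by the same 3D-IoU matcher used
for CAD scoring, or by lobe + nearest diameter when a source carries no
masks) are concordant and enter the reference standard directly.  Each
unpaired candidate becomes a discrepancy record; R2's accept/reject
decisions — an external input, not an algorithm — finalize the standard.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .annotations import NoduleAnnotation, ScanMeta
from .matching import MatchConfig, MatchTable, iou3d
from .metrics import CIConfig, ProportionCI, wilson_ci

__all__ = [
    "ReaderAnnotationSet",
    "AdjudicationRecord",
    "DiscrepancyResult",
    "DetectionCrossTab",
    "ReaderPerformance",
    "find_discrepancies",
    "apply_decisions",
    "load_decisions_csv",
    "write_decisions_csv",
    "finalize_reference",
    "match_reader_to_gt",
    "detection_cross_tab",
    "reader_performance",
]

#: relative diameter tolerance for approximate (mask-less) candidate pairing
APPROX_DIAMETER_RTOL = 0.5

CROSS_TAB_CELLS = ("both", "only_r1", "only_cad", "neither")


@dataclass
class ReaderAnnotationSet:
    reader_id: str
    nodules: list[NoduleAnnotation]

    def __post_init__(self) -> None:
        ids = [(n.scan_id, n.nodule_id) for n in self.nodules]
        if len(ids) != len(set(ids)):
            raise ValueError(f"reader {self.reader_id}: duplicate nodule ids")

    def by_scan(self) -> dict[str, list[NoduleAnnotation]]:
        out: dict[str, list[NoduleAnnotation]] = {}
        for n in self.nodules:
            out.setdefault(n.scan_id, []).append(n)
        return out


@dataclass
class AdjudicationRecord:
    scan_id: str
    candidate: NoduleAnnotation
    source: str  # 'r1_only' | 'report_only'
    r2_decision: str | None = None  # 'accept' | 'reject'
    approximate_pairing: bool = False


@dataclass
class DiscrepancyResult:
    records: list[AdjudicationRecord]
    concordant_nodules: list[NoduleAnnotation]
    discrepant_scan_ids: set[str]


def _pair_source_sets(
    report: list[NoduleAnnotation],
    r1: list[NoduleAnnotation],
    matcher: MatchConfig,
) -> tuple[list[tuple[NoduleAnnotation, NoduleAnnotation, bool]], list, list]:
    """Greedy one-to-one pairing of report vs R1 nodules on one scan.

    Mask-bearing pairs use the IoU criterion; if either side lacks a mask
    the pair is approximate: same lobe and relative diameter difference
    within ``APPROX_DIAMETER_RTOL``, scored by diameter closeness.
    """
    candidates = []
    for i, a in enumerate(report):
        for j, b in enumerate(r1):
            if a.mask is not None and b.mask is not None:
                score = iou3d(a.mask, b.mask)
                if score >= matcher.iou_threshold:
                    candidates.append((score, 0, i, j, False))
            else:
                if a.lobe != b.lobe:
                    continue
                ref = max(a.avg_diameter_mm, b.avg_diameter_mm)
                rel = abs(a.avg_diameter_mm - b.avg_diameter_mm) / ref if ref > 0 else 0.0
                if rel <= APPROX_DIAMETER_RTOL:
                    candidates.append((1.0 - rel, 1, i, j, True))
    # exact (mask) pairings take precedence over approximate ones
    candidates.sort(key=lambda t: (t[1], -t[0], t[2], t[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for score, _, i, j, approx in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((report[i], r1[j], approx))
    rest_a = [a for i, a in enumerate(report) if i not in used_a]
    rest_b = [b for j, b in enumerate(r1) if j not in used_b]
    return pairs, rest_a, rest_b


def find_discrepancies(
    report_nodules: ReaderAnnotationSet,
    r1: ReaderAnnotationSet,
    matcher: MatchConfig = MatchConfig(),
) -> DiscrepancyResult:
    """Pair the report-derived and R1 nodule lists scan by scan; every
    unpaired candidate becomes an :class:`AdjudicationRecord`.  Concordant
    nodules take R1's annotation (the detailed segmentation source)."""
    rep_by_scan = report_nodules.by_scan()
    r1_by_scan = r1.by_scan()
    records: list[AdjudicationRecord] = []
    concordant: list[NoduleAnnotation] = []
    discrepant: set[str] = set()
    for sid in sorted(set(rep_by_scan) | set(r1_by_scan)):
        pairs, rep_rest, r1_rest = _pair_source_sets(
            rep_by_scan.get(sid, []), r1_by_scan.get(sid, []), matcher
        )
        for rep_n, r1_n, approx in pairs:
            concordant.append(r1_n if r1_n.mask is not None else rep_n)
        for a in rep_rest:
            records.append(
                AdjudicationRecord(
                    scan_id=sid, candidate=a, source="report_only",
                    approximate_pairing=a.mask is None,
                )
            )
            discrepant.add(sid)
        for b in r1_rest:
            records.append(
                AdjudicationRecord(
                    scan_id=sid, candidate=b, source="r1_only",
                    approximate_pairing=b.mask is None,
                )
            )
            discrepant.add(sid)
    return DiscrepancyResult(
        records=records, concordant_nodules=concordant, discrepant_scan_ids=discrepant
    )


def apply_decisions(
    records: Iterable[AdjudicationRecord], decisions: dict[tuple[str, str], str]
) -> list[AdjudicationRecord]:
    """Attach R2 decisions, keyed by (scan_id, candidate nodule_id)."""
    out = []
    for r in records:
        key = (r.scan_id, r.candidate.nodule_id)
        if key not in decisions:
            raise ValueError(f"no decision for candidate {key}")
        decision = decisions[key]
        if decision not in ("accept", "reject"):
            raise ValueError(f"decision for {key} must be accept/reject, got {decision!r}")
        out.append(replace(r, r2_decision=decision))
    return out


def load_decisions_csv(path: str | Path) -> dict[tuple[str, str], str]:
    decisions: dict[tuple[str, str], str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            decisions[(row["scan_id"], row["candidate_id"])] = row["decision"]
    return decisions


def write_decisions_csv(records: Sequence[AdjudicationRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["scan_id", "candidate_id", "source", "decision"])
        for r in records:
            w.writerow([r.scan_id, r.candidate.nodule_id, r.source, r.r2_decision or ""])


def finalize_reference(
    concordant_nodules: Sequence[NoduleAnnotation],
    records: Sequence[AdjudicationRecord],
    scans: Sequence[ScanMeta],
) -> tuple[list[NoduleAnnotation], list[ScanMeta]]:
    """Accepted candidates join the concordant set; ``contains_nodule`` is
    recomputed for every scan.  Raises on any undecided record.
    Idempotent: re-running with zero new records changes nothing."""
    undecided = [r for r in records if r.r2_decision is None]
    if undecided:
        raise ValueError(
            f"{len(undecided)} adjudication record(s) lack an R2 decision "
            f"(first: {undecided[0].scan_id}/{undecided[0].candidate.nodule_id})"
        )
    gt = list(concordant_nodules) + [r.candidate for r in records if r.r2_decision == "accept"]
    with_nodule = {n.scan_id for n in gt}
    updated = [replace(s, contains_nodule=s.scan_id in with_nodule) for s in scans]
    return gt, updated


# ---------------------------------------------------------------------------
# Reader-vs-CAD cross tabulation
# ---------------------------------------------------------------------------

def match_reader_to_gt(
    gt_nodules: Sequence[NoduleAnnotation],
    reader: ReaderAnnotationSet,
    matcher: MatchConfig = MatchConfig(),
) -> set[str]:
    """GT nodule ids found by the reader, using the same pairing rules as
    report/R1 reconciliation (IoU when masks exist, else lobe+diameter)."""
    gt_by_scan: dict[str, list[NoduleAnnotation]] = {}
    for n in gt_nodules:
        gt_by_scan.setdefault(n.scan_id, []).append(n)
    reader_by_scan = reader.by_scan()
    found: set[str] = set()
    for sid, gts in gt_by_scan.items():
        pairs, _, _ = _pair_source_sets(gts, reader_by_scan.get(sid, []), matcher)
        # _pair_source_sets pairs (report=gts, r1=reader); keep GT-side ids
        for gt_n, _, _ in pairs:
            found.add(gt_n.nodule_id)
    return found


def _characteristic_levels(n: NoduleAnnotation):
    from .characterization import DIAMETER_EDGES_MM, VOLUME_EDGES_MM3, _bin_label

    yield "texture", n.texture
    yield "calcification", "yes" if n.calcification else "no"
    yield "spiculation", "yes" if n.spiculation else "no"
    yield "lobe", n.lobe
    yield "diameter", _bin_label(n.avg_diameter_mm, DIAMETER_EDGES_MM, " mm")
    yield "volume", _bin_label(n.volume_mm3, VOLUME_EDGES_MM3, " mm3")


@dataclass
class DetectionCrossTab:
    counts: dict[str, int]  # cell -> count over the in-scope GT nodules
    per_characteristic: dict[str, dict[str, dict[str, int]]]
    nodule_cells: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["characteristic", "level", "total", *CROSS_TAB_CELLS])
            w.writerow(
                ["all", "all", self.total, *[self.counts[c] for c in CROSS_TAB_CELLS]]
            )
            for char, levels in self.per_characteristic.items():
                for level, cells in levels.items():
                    w.writerow(
                        [
                            char,
                            level,
                            sum(cells.values()),
                            *[cells.get(c, 0) for c in CROSS_TAB_CELLS],
                        ]
                    )


def detection_cross_tab(
    gt_nodules: Sequence[NoduleAnnotation],
    r1: ReaderAnnotationSet,
    cad_match_table: MatchTable,
    scope_scan_ids: Sequence[str] | set[str],
    matcher: MatchConfig = MatchConfig(),
) -> DetectionCrossTab:
    """Label every in-scope GT nodule both / only_r1 / only_cad / neither and
    tabulate overall and per characteristic level."""
    scope = set(scope_scan_ids)
    known_scans = set(cad_match_table.scan_labels)
    missing = scope - known_scans
    if missing:
        raise ValueError(f"scope scans absent from the match table: {sorted(missing)[:5]}")
    in_scope = [n for n in gt_nodules if n.scan_id in scope]
    r1_found = match_reader_to_gt(in_scope, r1, matcher)
    cad_found = cad_match_table.matched_nodule_ids()

    counts = {c: 0 for c in CROSS_TAB_CELLS}
    per_char: dict[str, dict[str, dict[str, int]]] = {}
    cells: dict[str, str] = {}
    for n in in_scope:
        by_r1 = n.nodule_id in r1_found
        by_cad = n.nodule_id in cad_found
        cell = (
            "both" if by_r1 and by_cad
            else "only_r1" if by_r1
            else "only_cad" if by_cad
            else "neither"
        )
        counts[cell] += 1
        cells[n.nodule_id] = cell
        for char, level in _characteristic_levels(n):
            per_char.setdefault(char, {}).setdefault(str(level), {c: 0 for c in CROSS_TAB_CELLS})
            per_char[char][str(level)][cell] += 1
    return DetectionCrossTab(counts=counts, per_characteristic=per_char, nodule_cells=cells)


@dataclass
class ReaderPerformance:
    r1_sensitivity: ProportionCI
    cad_sensitivity: ProportionCI
    uplift: float | None  # (GT found only by CAD) / (GT found by R1)
    n_only_cad: int
    n_r1_found: int
    n_r1_fp: int
    undefined: list[str] = field(default_factory=list)


def reader_performance(
    gt_nodules: Sequence[NoduleAnnotation],
    r1: ReaderAnnotationSet,
    cad_match_table: MatchTable,
    config: CIConfig = CIConfig(),
    matcher: MatchConfig = MatchConfig(),
) -> ReaderPerformance:
    """R1 and CAD nodule-level sensitivities over the full reference
    standard, plus the second-reader uplift fraction."""
    n_gt = len(gt_nodules)
    if n_gt == 0:
        raise ValueError("empty reference standard")
    r1_found = match_reader_to_gt(gt_nodules, r1, matcher)
    cad_found = cad_match_table.matched_nodule_ids() & {n.nodule_id for n in gt_nodules}
    only_cad = len(cad_found - r1_found)
    undefined: list[str] = []
    uplift: float | None
    if r1_found:
        uplift = only_cad / len(r1_found)
    else:
        uplift = None
        undefined.append("uplift")
    n_r1_fp = len(r1.nodules) - len(
        match_reader_to_gt(gt_nodules, r1, matcher)
        # reader annotations pairing to no GT nodule are reader FPs
    )
    return ReaderPerformance(
        r1_sensitivity=wilson_ci(len(r1_found), n_gt, config),
        cad_sensitivity=wilson_ci(len(cad_found), n_gt, config),
        uplift=uplift,
        n_only_cad=only_cad,
        n_r1_found=len(r1_found),
        n_r1_fp=n_r1_fp,
        undefined=undefined,
    )
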