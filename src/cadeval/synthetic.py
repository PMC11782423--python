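"""Synthetic cohorts, a parameterized imperfect detector and reader, and a
deterministic fixture that reproduces a full published-style contingency.

The generator emulates the statistical structure of a 263-scan validation
cohort: scan-level covariate marginals, a zero-truncated-Poisson nodule
count law capped at 10, texture/calcification/spiculation/lobe marginals,
a truncated log-normal diameter law, ellipsoidal voxel masks on a 64^3
grid (lobes are synthetic axis-aligned boxes, not anatomy), per-texture
detection sensitivity, Poisson false positives, localization jitter
calibrated to a target IoU distribution, characterization confusion, and
additive size noise.  Everything is reproducible from a single seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotations import (
    AGE_GROUPS,
    Cohort,
    CadFinding,
    LOBES,
    NoduleAnnotation,
    ScanMeta,
    SEXES,
    TEXTURES,
    VoxelMask,
    measure_nodule,
    rasterize_ellipsoid,
)
from .adjudication import ReaderAnnotationSet

__all__ = [
    "DetectorProfile",
    "ReaderProfile",
    "SyntheticConfig",
    "generate_cohort",
    "simulate_cad",
    "simulate_reader",
    "PaperFixture",
    "build_paper_fixture",
]

GRID = (64, 64, 64)
SPACING = (1.0, 1.0, 1.0)

# synthetic lobe boxes on the 64^3 grid: (x_lo, x_hi, z_lo, z_hi); y spans the grid
_LOBE_BOXES = {
    "left_upper": (0, 32, 32, 64),
    "left_lower": (0, 32, 0, 32),
    "right_upper": (32, 64, 42, 64),
    "middle": (32, 64, 21, 42),
    "right_lower": (32, 64, 0, 21),
}

_MACHINES = (
    "SOMATOM Edge Plus",
    "SOMATOM Definition Edge",
    "SOMATOM Force",
    "SOMATOM Drive",
    "Others",
)


def _validated_probs(values: Sequence[float], name: str) -> tuple[float, ...]:
    v = tuple(float(x) for x in values)
    if abs(sum(v) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {sum(v)}")
    if any(x < 0 for x in v):
        raise ValueError(f"{name} must be nonnegative")
    return v


@dataclass(frozen=True)
class DetectorProfile:
    """Knobs of the simulated detector (defaults follow the validation
    cohort's reported operating point)."""

    sensitivity_by_texture: dict = field(
        default_factory=lambda: {"solid": 0.872, "part_solid": 0.894, "ground_glass": 0.595}
    )
    fp_rate_lambda: float = 72.0 / 263.0
    #: TP localization jitter: translation as a fraction of diameter,
    #: U(lo, hi); calibrated so the induced IoU has mean ~0.42 and
    #: support above the 0.10 match floor.
    shift_frac_range: tuple[float, float] = (0.08, 0.52)
    min_tp_iou: float = 0.10
    confidence_tp_beta: tuple[float, float] = (5.0, 2.0)
    confidence_fp_beta: tuple[float, float] = (2.0, 5.0)
    #: row-stochastic GT-texture -> predicted-texture confusion
    texture_confusion: dict = field(
        default_factory=lambda: {
            "solid": (0.988, 0.012, 0.0),
            "part_solid": (0.619, 0.381, 0.0),
            "ground_glass": (0.28, 0.0, 0.72),
        }
    )
    calcification_accuracy: float = 0.919
    spiculation_accuracy: float = 0.826
    lobe_accuracy: float = 0.946
    diameter_bias_mm: float = 0.47
    diameter_sd_mm: float = 1.24
    volume_bias_mm3: float = 61.8
    volume_sd_mm3: float = 392.0

    def __post_init__(self) -> None:
        for t, row in self.texture_confusion.items():
            _validated_probs(row, f"texture_confusion[{t!r}]")
        for t, s in self.sensitivity_by_texture.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"sensitivity_by_texture[{t!r}] outside [0, 1]")
        for name in ("calcification_accuracy", "spiculation_accuracy", "lobe_accuracy"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.fp_rate_lambda < 0:
            raise ValueError("fp_rate_lambda must be nonnegative")


@dataclass(frozen=True)
class ReaderProfile:
    sensitivity: float = 165.0 / 183.0
    fp_total_rate: float = 39.0 / 263.0  # reader FPs per scan

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("reader sensitivity outside [0, 1]")
        if self.fp_total_rate < 0:
            raise ValueError("fp_total_rate must be nonnegative")


@dataclass(frozen=True)
class SyntheticConfig:
    n_scans: int = 263
    prevalence: float = 121.0 / 263.0
    mean_nodules_per_scan: float = 1.51  # conditional on containing >= 1
    max_nodules_per_scan: int = 10
    texture_marginals: tuple[float, float, float] = (94 / 183, 47 / 183, 42 / 183)
    calcification_rate: float = 8.0 / 183.0
    spiculation_rate: float = 9.0 / 183.0
    lobe_marginals: tuple[float, ...] = (59 / 183, 17 / 183, 36 / 183, 37 / 183, 34 / 183)
    #: log-diameter normal (mu, sigma) truncated to diameter_range_mm;
    #: defaults hit bin targets {<6: ~54%, 6-8: ~20%, >8: ~26%}
    log_diameter_mu: float = 1.5686
    log_diameter_sigma: float = 0.6153
    diameter_range_mm: tuple[float, float] = (3.1, 25.0)
    age_under55_rate: float = 102.0 / 263.0
    male_rate: float = 130.0 / 263.0
    other_abnormality_rate: float = 125.0 / 263.0
    machine_marginals: tuple[float, ...] = (91 / 263, 61 / 263, 62 / 263, 44 / 263, 5 / 263)
    noncontrast_rate: float = 167.0 / 263.0
    detector: DetectorProfile = field(default_factory=DetectorProfile)
    reader: ReaderProfile = field(default_factory=ReaderProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        _validated_probs(self.texture_marginals, "texture_marginals")
        _validated_probs(self.lobe_marginals, "lobe_marginals")
        _validated_probs(self.machine_marginals, "machine_marginals")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.ztp_mu() is None:
            raise ValueError(
                f"mean_nodules_per_scan {self.mean_nodules_per_scan} infeasible for a "
                "zero-truncated Poisson"
            )

    def ztp_mu(self) -> float | None:
        """Poisson rate whose zero-truncated mean equals the configured mean."""
        target = self.mean_nodules_per_scan
        if target <= 1.0:
            return None
        lo, hi = 1e-9, 50.0
        f = lambda m: m / (1.0 - math.exp(-m)) - target
        if f(hi) < 0:
            return None
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2.0


def _sample_ztp(rng: np.random.Generator, mu: float, cap: int) -> int:
    while True:
        k = int(rng.poisson(mu))
        if 1 <= k <= cap:
            return k


def _sample_diameter(rng: np.random.Generator, config: SyntheticConfig) -> float:
    lo, hi = config.diameter_range_mm
    while True:
        d = float(np.exp(rng.normal(config.log_diameter_mu, config.log_diameter_sigma)))
        if lo < d < hi:
            return d


def _place_nodule(
    rng: np.random.Generator,
    lobe: str,
    diameter_mm: float,
    existing: list[tuple[np.ndarray, float, float]],  # (center, max semi-axis, diameter)
) -> tuple[VoxelMask, np.ndarray, float]:
    """Rasterize an ellipsoid of roughly the requested measured diameter with
    its center uniform in the lobe box, inside the grid.

    Nodules in one scan are kept far enough apart that a jittered detector
    mask of one nodule cannot reach another (separation beyond both radii
    plus the maximum jitter shift); otherwise a missed nodule could be
    "rescued" by its neighbour's finding, biasing sensitivity recovery.
    """
    x_lo, x_hi, z_lo, z_hi = _LOBE_BOXES[lobe]
    # voxel-corner Feret measurement adds ~1 voxel; compensate
    axes = max(diameter_mm - 1.0, 2.2) / 2.0 * rng.uniform(0.9, 1.1, size=3)
    amax = float(axes.max())
    margin = amax + 1.0
    center = None
    for attempt in range(80):
        cx = rng.uniform(max(x_lo, margin), min(x_hi, GRID[0] - margin))
        cy = rng.uniform(margin, GRID[1] - margin)
        cz = rng.uniform(max(z_lo, margin), min(z_hi, GRID[2] - margin))
        center = np.array([cx, cy, cz])
        ok = all(
            np.linalg.norm(center - c0) >= amax + a0 + 0.55 * max(diameter_mm, d0)
            for c0, a0, d0 in existing
        )
        if ok:
            break
    mask = rasterize_ellipsoid(center, axes, GRID, SPACING)
    return mask, center, diameter_mm


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a ground-truth-only cohort (scans + nodules, no findings).

    Reproducible: the same config (including seed) yields an identical
    cohort.  All annotation-module invariants hold on the output.
    """
    rng = np.random.default_rng(config.seed)
    mu = config.ztp_mu()
    scans: list[ScanMeta] = []
    nodules: list[NoduleAnnotation] = []
    width = len(str(config.n_scans))
    for i in range(config.n_scans):
        sid = f"S{i + 1:0{width}d}"
        contains = bool(rng.random() < config.prevalence)
        scans.append(
            ScanMeta(
                scan_id=sid,
                contains_nodule=contains,
                age_group=AGE_GROUPS[0] if rng.random() < config.age_under55_rate else AGE_GROUPS[1],
                sex=SEXES[0] if rng.random() < config.male_rate else SEXES[1],
                other_abnormality=bool(rng.random() < config.other_abnormality_rate),
                machine_type=_MACHINES[int(rng.choice(5, p=config.machine_marginals))],
                scan_type="noncontrast" if rng.random() < config.noncontrast_rate else "contrast",
                slice_thickness_mm=1.0,
                grid_shape=GRID,
                voxel_spacing_mm=SPACING,
            )
        )
        if not contains:
            continue
        count = _sample_ztp(rng, mu, config.max_nodules_per_scan)
        placed: list[tuple[np.ndarray, float, float]] = []
        for j in range(count):
            texture = TEXTURES[int(rng.choice(3, p=config.texture_marginals))]
            lobe = LOBES[int(rng.choice(5, p=config.lobe_marginals))]
            d = _sample_diameter(rng, config)
            mask, center, _ = _place_nodule(rng, lobe, d, placed)
            placed.append((center, d / 2.0, d))
            avg_d, volume = measure_nodule(mask)
            lo, hi = 3.0, 30.0
            avg_d = min(max(avg_d, lo + 1e-6), hi - 1e-6)  # voxelization guard
            nodules.append(
                NoduleAnnotation(
                    scan_id=sid,
                    nodule_id=f"{sid}_n{j + 1}",
                    mask=mask,
                    texture=texture,
                    calcification=bool(rng.random() < config.calcification_rate),
                    spiculation=bool(rng.random() < config.spiculation_rate),
                    lobe=lobe,
                    avg_diameter_mm=avg_d,
                    volume_mm3=volume,
                )
            )
    return Cohort(scans=scans, gt_nodules=nodules)


def _jittered_mask(
    rng: np.random.Generator, mask: VoxelMask, diameter_mm: float, profile: DetectorProfile
) -> VoxelMask:
    """Translate the GT mask by a random offset; rejection-sample (halving
    the shift) until the IoU with GT clears the configured floor."""
    from .matching import iou3d

    lo, hi = profile.shift_frac_range
    frac = rng.uniform(lo, hi)
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    for _ in range(20):
        offset = np.rint(direction * frac * diameter_mm / np.array(SPACING)).astype(int)
        try:
            shifted = mask.translate(offset)
            if iou3d(shifted, mask) >= profile.min_tp_iou:
                return shifted
        except Exception:
            pass
        frac *= 0.5
    return mask  # zero-jitter fallback (IoU 1)


def _random_fp_mask(
    rng: np.random.Generator, gt_masks: list[VoxelMask], radius_range=(1.5, 4.0)
) -> VoxelMask | None:
    for _ in range(50):
        r = rng.uniform(*radius_range)
        center = rng.uniform(r + 1.0, np.array(GRID) - r - 1.0)
        mask = rasterize_ellipsoid(center, (r, r, r), GRID, SPACING)
        if all(mask.intersection_count(m) == 0 for m in gt_masks):
            return mask
    return None


def simulate_cad(
    cohort: Cohort, profile: DetectorProfile | None = None, seed: int = 0
) -> list[CadFinding]:
    """Run the simulated detector over a GT cohort.

    Each nodule is detected with its texture's sensitivity; TP masks are
    jittered copies of the GT mask with IoU above the match floor by
    construction; per-scan false positives are Poisson and disjoint from
    GT; characteristics pass through the confusion/accuracy knobs; sizes
    get additive bias + noise.
    """
    profile = profile or DetectorProfile()
    rng = np.random.default_rng(seed)
    findings: list[CadFinding] = []
    nodules_by_scan = cohort.nodules_by_scan()
    for s in cohort.scans:
        gts = nodules_by_scan.get(s.scan_id, [])
        gt_masks = [n.mask for n in gts if n.mask is not None]
        k = 0
        for n in gts:
            if rng.random() >= profile.sensitivity_by_texture[n.texture]:
                continue
            k += 1
            mask = _jittered_mask(rng, n.mask, n.avg_diameter_mm, profile)
            conf_row = profile.texture_confusion[n.texture]
            pred_texture = TEXTURES[int(rng.choice(3, p=conf_row))]
            pred_calc = (
                n.calcification
                if rng.random() < profile.calcification_accuracy
                else not n.calcification
            )
            pred_spic = (
                n.spiculation
                if rng.random() < profile.spiculation_accuracy
                else not n.spiculation
            )
            if rng.random() < profile.lobe_accuracy:
                pred_lobe = n.lobe
            else:
                others = [l for l in LOBES if l != n.lobe]
                pred_lobe = others[int(rng.integers(len(others)))]
            pred_d = max(0.1, n.avg_diameter_mm + profile.diameter_bias_mm
                         + rng.normal(0.0, profile.diameter_sd_mm))
            pred_v = max(1.0, n.volume_mm3 + profile.volume_bias_mm3
                         + rng.normal(0.0, profile.volume_sd_mm3))
            findings.append(
                CadFinding(
                    scan_id=s.scan_id,
                    finding_id=f"{s.scan_id}_f{k}",
                    mask=mask,
                    confidence=float(rng.beta(*profile.confidence_tp_beta)),
                    texture=pred_texture,
                    calcification=bool(pred_calc),
                    spiculation=bool(pred_spic),
                    lobe=pred_lobe,
                    avg_diameter_mm=float(pred_d),
                    volume_mm3=float(pred_v),
                )
            )
        n_fp = int(rng.poisson(profile.fp_rate_lambda))
        for _ in range(n_fp):
            mask = _random_fp_mask(rng, gt_masks)
            if mask is None:
                continue
            k += 1
            d, v = measure_nodule(mask)
            findings.append(
                CadFinding(
                    scan_id=s.scan_id,
                    finding_id=f"{s.scan_id}_f{k}",
                    mask=mask,
                    confidence=float(rng.beta(*profile.confidence_fp_beta)),
                    texture=TEXTURES[int(rng.integers(3))],
                    calcification=bool(rng.random() < 0.05),
                    spiculation=bool(rng.random() < 0.05),
                    lobe=LOBES[int(rng.integers(5))],
                    avg_diameter_mm=float(d),
                    volume_mm3=float(v),
                )
            )
    return findings


def simulate_reader(
    cohort: Cohort, profile: ReaderProfile | None = None, seed: int = 0,
    reader_id: str = "R1",
) -> ReaderAnnotationSet:
    """Simulate a human reader: each GT nodule found with the configured
    sensitivity (mask copied exactly); false marks at the configured rate."""
    profile = profile or ReaderProfile()
    rng = np.random.default_rng(seed)
    nodules_by_scan = cohort.nodules_by_scan()
    out: list[NoduleAnnotation] = []
    for s in cohort.scans:
        gts = nodules_by_scan.get(s.scan_id, [])
        gt_masks = [n.mask for n in gts if n.mask is not None]
        k = 0
        for n in gts:
            if rng.random() < profile.sensitivity:
                k += 1
                out.append(replace(n, nodule_id=f"{reader_id}_{n.nodule_id}"))
        for _ in range(int(rng.poisson(profile.fp_total_rate))):
            mask = _random_fp_mask(rng, gt_masks)
            if mask is None:
                continue
            k += 1
            d, v = measure_nodule(mask)
            out.append(
                NoduleAnnotation(
                    scan_id=s.scan_id,
                    nodule_id=f"{reader_id}_{s.scan_id}_x{k}",
                    mask=mask,
                    texture=TEXTURES[int(rng.integers(3))],
                    calcification=False,
                    spiculation=False,
                    lobe=LOBES[int(rng.integers(5))],
                    avg_diameter_mm=max(3.05, float(d)),
                    volume_mm3=float(v),
                )
            )
    return ReaderAnnotationSet(reader_id=reader_id, nodules=out)


# ---------------------------------------------------------------------------
# Deterministic published-contingency fixture
# ---------------------------------------------------------------------------

@dataclass
class PaperFixture:
    """A hand-constructed cohort whose evaluation reproduces, exactly, the
    reference contingency of the validation study this pipeline models:
    263 scans (121 with nodules), 183 GT nodules, 149 matched + 34 missed,
    49 + 23 false positives, 104/21/17/121 scan-level TP/FP/FN/TN, the
    per-class characterization counts, and the reader-vs-CAD cross-tab
    {only_r1: 2, only_cad: 12, both: 7, neither: 6} on 27 conflicting-scan
    nodules."""

    cohort: Cohort  # final reference standard + CAD findings
    r1: ReaderAnnotationSet
    report: ReaderAnnotationSet
    decisions: dict  # (scan_id, candidate_id) -> accept/reject
    conflicting_scan_ids: list[str]
    conflicting_nodule_scan_ids: list[str]


def _expand(counts: Sequence[int], values: Sequence) -> list:
    out: list = []
    for c, v in zip(counts, values):
        out.extend([v] * c)
    return out


# volume-bin representative masks (1 mm spacing): cuboid dims -> exact volume
_VOL_SHAPES = {60.0: (5, 4, 3), 150.0: (5, 6, 5), 400.0: (8, 10, 5)}
_DIAM_VALUES = (4.5, 7.0, 10.0)
_VOL_VALUES = (60.0, 150.0, 400.0)


def _cuboid_mask(origin: tuple[int, int, int], volume: float) -> VoxelMask:
    dx, dy, dz = _VOL_SHAPES[volume]
    ox, oy, oz = origin
    coords = [
        (ox + a, oy + b, oz + c) for a in range(dx) for b in range(dy) for c in range(dz)
    ]
    return VoxelMask.from_coords(coords, GRID, SPACING)


def _single_voxel(coord: tuple[int, int, int]) -> VoxelMask:
    return VoxelMask.from_coords([coord], GRID, SPACING)


@dataclass
class _GroupSpec:
    """Attribute marginals of one nodule group (independent per column)."""

    n: int
    texture: tuple[int, int, int]
    calcified: int
    spiculated: int
    lobe: tuple[int, int, int, int, int]
    diam_bins: tuple[int, int, int]
    vol_bins: tuple[int, int, int]

    def build(self) -> list[dict]:
        assert sum(self.texture) == self.n and sum(self.lobe) == self.n
        assert sum(self.diam_bins) == self.n and sum(self.vol_bins) == self.n
        tex = _expand(self.texture, TEXTURES)
        calc = [True] * self.calcified + [False] * (self.n - self.calcified)
        spic = [True] * self.spiculated + [False] * (self.n - self.spiculated)
        lobe = _expand(self.lobe, LOBES)
        diam = _expand(self.diam_bins, _DIAM_VALUES)
        vol = _expand(self.vol_bins, _VOL_VALUES)
        return [
            {
                "texture": tex[i],
                "calcification": calc[i],
                "spiculation": spic[i],
                "lobe": lobe[i],
                "avg_diameter_mm": diam[i],
                "volume_mm3": vol[i],
            }
            for i in range(self.n)
        ]


# Groups: (A) concordant detected, (B) concordant missed, and the four
# conflicting-scan cross-tab cells (C only_cad, D both, E only_r1, F neither).
# Marginals per group are the published detected/missed columns minus the
# conflicting-scan contributions, so every table is reproduced exactly.
_GROUPS = {
    "A": _GroupSpec(130, (68, 39, 23), 5, 6, (49, 10, 25, 28, 18), (63, 27, 40), (24, 29, 77)),
    "B": _GroupSpec(26, (6, 5, 15), 2, 1, (7, 2, 2, 6, 9), (13, 8, 5), (8, 7, 11)),
    "C": _GroupSpec(12, (8, 2, 2), 0, 1, (0, 3, 6, 0, 3), (9, 1, 2), (5, 5, 2)),
    "D": _GroupSpec(7, (6, 1, 0), 0, 1, (1, 2, 3, 1, 0), (6, 1, 0), (4, 1, 2)),
    "E": _GroupSpec(2, (2, 0, 0), 0, 0, (0, 0, 0, 0, 2), (2, 0, 0), (2, 0, 0)),
    "F": _GroupSpec(6, (4, 0, 2), 1, 0, (2, 0, 0, 2, 2), (6, 0, 0), (2, 4, 0)),
}

# per-GT-class correct prediction counts among the 149 detected nodules
_TEXTURE_CORRECT = {"solid": 81, "part_solid": 16, "ground_glass": 18}
_CALC_CORRECT = {True: 5, False: 132}
_SPIC_CORRECT = {True: 6, False: 117}
_LOBE_CORRECT = {
    "right_upper": 49, "middle": 13, "right_lower": 33, "left_upper": 26, "left_lower": 20,
}


def _wrong_texture(t: str) -> str:
    return {"solid": "part_solid", "part_solid": "solid", "ground_glass": "solid"}[t]


def _wrong_lobe(lobe: str) -> str:
    i = LOBES.index(lobe)
    return LOBES[(i + 1) % len(LOBES)]


def _assign_predictions(detected: list[dict]) -> None:
    """Mark, per characteristic and GT class, the last (n - n_correct)
    detected nodules as misclassified; earlier ones predict the GT value."""
    for key, correct_map, wrong in (
        ("texture", _TEXTURE_CORRECT, _wrong_texture),
        ("calcification", _CALC_CORRECT, lambda v: not v),
        ("spiculation", _SPIC_CORRECT, lambda v: not v),
        ("lobe", _LOBE_CORRECT, _wrong_lobe),
    ):
        per_class: dict = {}
        for rec in detected:
            per_class.setdefault(rec[key], []).append(rec)
        for cls, recs in per_class.items():
            n_correct = correct_map[cls]
            for i, rec in enumerate(recs):
                rec["pred_" + key] = rec[key] if i < n_correct else wrong(rec[key])


def build_paper_fixture() -> PaperFixture:
    """Deterministically construct the published-contingency cohort together
    with the report/R1/R2 adjudication inputs that reproduce it."""
    n_scans = 263
    scan_roles: list[str] = (
        ["concordant_tp"] * 90      # idx 0-89: nodule scans, CAD finds >= 1
        + ["concordant_fn"] * 13    # idx 90-102: nodule scans, all missed
        + ["conflict_tp"] * 14      # idx 103-116: conflicting nodule scans, CAD TP
        + ["conflict_fn"] * 4       # idx 117-120: conflicting nodule scans, CAD FN
        + ["concordant_neg"] * 127  # idx 121-247
        + ["conflict_neg"] * 15     # idx 248-262
    )
    assert len(scan_roles) == n_scans
    scan_ids = [f"S{i + 1:03d}" for i in range(n_scans)]

    # --- covariates: assign published marginals independently per variable
    nodule_idx = [i for i, r in enumerate(scan_roles) if r.endswith(("tp", "fn"))]
    neg_idx = [i for i, r in enumerate(scan_roles) if r.endswith("neg")]
    assert len(nodule_idx) == 121 and len(neg_idx) == 142

    def marginal(indices, counts, values):
        return dict(zip(indices, _expand(counts, values)))

    age = {**marginal(nodule_idx, (24, 97), AGE_GROUPS), **marginal(neg_idx, (78, 64), AGE_GROUPS)}
    sex = {**marginal(nodule_idx, (63, 58), SEXES), **marginal(neg_idx, (67, 75), SEXES)}
    abn = {
        **marginal(nodule_idx, (66, 55), (True, False)),
        **marginal(neg_idx, (59, 83), (True, False)),
    }
    machine = {
        **marginal(nodule_idx, (42, 27, 34, 15, 3), _MACHINES),
        **marginal(neg_idx, (49, 34, 28, 29, 2), _MACHINES),
    }
    ctype = {
        **marginal(nodule_idx, (71, 50), ("noncontrast", "contrast")),
        **marginal(neg_idx, (96, 46), ("noncontrast", "contrast")),
    }

    scans = [
        ScanMeta(
            scan_id=scan_ids[i],
            contains_nodule=scan_roles[i].endswith(("tp", "fn")),
            age_group=age[i],
            sex=sex[i],
            other_abnormality=abn[i],
            machine_type=machine[i],
            scan_type=ctype[i],
            slice_thickness_mm=1.0,
            grid_shape=GRID,
            voxel_spacing_mm=SPACING,
        )
        for i in range(n_scans)
    ]

    # --- nodule groups and their scan layout
    groups = {g: spec.build() for g, spec in _GROUPS.items()}
    layout: list[tuple[int, list[dict]]] = []  # (scan index, records on that scan)

    def spread(records: list[dict], scan_indices: list[int], per_scan: list[int]):
        assert sum(per_scan) == len(records)
        pos = 0
        for idx, cnt in zip(scan_indices, per_scan):
            layout.append((idx, records[pos:pos + cnt]))
            pos += cnt

    # 90 concordant TP scans: first 40 hold 2 detected nodules, rest 1
    spread(groups["A"], list(range(0, 90)), [2] * 40 + [1] * 50)
    # 13 concordant FN scans: 2 missed nodules each
    spread(groups["B"], list(range(90, 103)), [2] * 13)
    # 14 conflicting TP scans: 19 CAD-detected nodules (C then D)
    spread(groups["C"] + groups["D"], list(range(103, 117)), [2] * 5 + [1] * 9)
    # 4 conflicting FN scans: 8 CAD-missed nodules (E then F)
    spread(groups["E"] + groups["F"], list(range(117, 121)), [2] * 4)

    # tag group membership for downstream role decisions
    for g, recs in groups.items():
        for rec in recs:
            rec["group"] = g
    detected = groups["A"] + groups["C"] + groups["D"]
    _assign_predictions(detected)

    nodule_origins = [(4, 4, 4), (40, 40, 40)]  # disjoint sub-boxes per scan
    gt_nodules: list[NoduleAnnotation] = []
    findings: list[CadFinding] = []
    r1_nodules: list[NoduleAnnotation] = []
    report_nodules: list[NoduleAnnotation] = []
    decisions: dict[tuple[str, str], str] = {}

    for idx, recs in layout:
        sid = scan_ids[idx]
        for j, rec in enumerate(recs):
            nid = f"{sid}_n{j + 1}"
            mask = _cuboid_mask(nodule_origins[j], rec["volume_mm3"])
            nodule = NoduleAnnotation(
                scan_id=sid,
                nodule_id=nid,
                mask=mask,
                texture=rec["texture"],
                calcification=rec["calcification"],
                spiculation=rec["spiculation"],
                lobe=rec["lobe"],
                avg_diameter_mm=rec["avg_diameter_mm"],
                volume_mm3=rec["volume_mm3"],
            )
            gt_nodules.append(nodule)
            group = rec["group"]
            if group in ("A", "C", "D"):  # CAD-detected: identical-mask finding
                findings.append(
                    CadFinding(
                        scan_id=sid,
                        finding_id=f"{sid}_f{j + 1}",
                        mask=mask,
                        confidence=0.9,
                        texture=rec["pred_texture"],
                        calcification=rec["pred_calcification"],
                        spiculation=rec["pred_spiculation"],
                        lobe=rec["pred_lobe"],
                        avg_diameter_mm=rec["avg_diameter_mm"],
                        volume_mm3=rec["volume_mm3"],
                    )
                )
            # reader/report membership per group
            if group in ("A", "B"):  # concordant: both sources list the nodule
                r1_nodules.append(replace(nodule, nodule_id=f"r1_{nid}"))
                report_nodules.append(replace(nodule, nodule_id=f"rep_{nid}"))
            elif group in ("D", "E"):  # R1-only candidates, accepted by R2
                r1_nodules.append(replace(nodule, nodule_id=f"r1_{nid}"))
                decisions[(sid, f"r1_{nid}")] = "accept"
            elif group in ("C", "F"):  # report-only candidates, accepted by R2
                report_nodules.append(replace(nodule, nodule_id=f"rep_{nid}"))
                decisions[(sid, f"rep_{nid}")] = "accept"

    # --- CAD false positives: 39 on concordant nodule scans, 10 on
    # conflicting nodule scans, 23 on 21 nodule-free scans (2+2+1*19)
    fp_corner = (60, 60, 60)
    fp_corner2 = (60, 56, 60)

    def add_cad_fp(idx: int, tag: int, coord):
        sid = scan_ids[idx]
        findings.append(
            CadFinding(
                scan_id=sid,
                finding_id=f"{sid}_fp{tag}",
                mask=_single_voxel(coord),
                confidence=0.3,
                texture="solid",
                calcification=False,
                spiculation=False,
                lobe="right_upper",
                avg_diameter_mm=4.0,
                volume_mm3=1.0,
            )
        )

    for idx in range(0, 39):
        add_cad_fp(idx, 1, fp_corner)
    for idx in range(103, 113):
        add_cad_fp(idx, 1, fp_corner)
    for idx in (121, 122):
        add_cad_fp(idx, 1, fp_corner)
        add_cad_fp(idx, 2, fp_corner2)
    for idx in range(123, 142):
        add_cad_fp(idx, 1, fp_corner)

    # --- R1 false marks: 39 total, all on conflicting scans (2 on each of
    # the 15 nodule-free conflicting scans + 1 on 9 conflicting nodule scans),
    # every one rejected by R2
    r1_fp_coords = [(0, 60, 60), (0, 56, 60)]

    def add_r1_fp(idx: int, tag: int):
        sid = scan_ids[idx]
        nid = f"r1fp_{sid}_{tag}"
        r1_nodules.append(
            NoduleAnnotation(
                scan_id=sid,
                nodule_id=nid,
                mask=_single_voxel(r1_fp_coords[tag - 1]),
                texture="solid",
                calcification=False,
                spiculation=False,
                lobe="left_upper",
                avg_diameter_mm=4.0,
                volume_mm3=1.0,
            )
        )
        decisions[(sid, nid)] = "reject"

    for idx in range(248, 263):
        add_r1_fp(idx, 1)
        add_r1_fp(idx, 2)
    for idx in range(103, 112):
        add_r1_fp(idx, 1)

    cohort = Cohort(scans=scans, gt_nodules=gt_nodules, findings=findings)
    cohort.validate(strict=False)
    conflicting = [scan_ids[i] for i in range(103, 121)] + [scan_ids[i] for i in range(248, 263)]
    return PaperFixture(
        cohort=cohort,
        r1=ReaderAnnotationSet(reader_id="R1", nodules=r1_nodules),
        report=ReaderAnnotationSet(reader_id="report", nodules=report_nodules),
        decisions=decisions,
        conflicting_scan_ids=conflicting,
        conflicting_nodule_scan_ids=[scan_ids[i] for i in range(103, 121)],
    )
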