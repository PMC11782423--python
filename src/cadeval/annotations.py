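"""Domain model and I/O for nodule annotations, CAD findings, and scan metadata.

The exchange formats are deliberately plain: one CSV row per scan for
metadata, one JSON-lines record per nodule/finding with an inline
run-length-encoded voxel mask (or ellipsoid parameters rasterized on
read), and optionally one NIfTI label volume per scan.  All masks for a
scan live on a single voxel grid so volumetric overlap is well defined.
"""
from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TEXTURES",
    "LOBES",
    "AGE_GROUPS",
    "SEXES",
    "SCAN_TYPES",
    "DIAMETER_RANGE_MM",
    "CohortValidationError",
    "IntegrityError",
    "EmptyMaskError",
    "GridMismatchError",
    "VoxelMask",
    "ScanMeta",
    "NoduleAnnotation",
    "CadFinding",
    "Cohort",
    "rasterize_ellipsoid",
    "measure_nodule",
    "read_cohort",
    "write_cohort",
    "read_cohort_dir",
]

TEXTURES = ("solid", "part_solid", "ground_glass")
LOBES = ("right_upper", "middle", "right_lower", "left_upper", "left_lower")
AGE_GROUPS = ("under_55", "55_plus")
SEXES = ("male", "female")
SCAN_TYPES = ("contrast", "noncontrast")

#: Fleischner nodule definition: lesion sized 3-30 mm in average diameter.
DIAMETER_RANGE_MM = (3.0, 30.0)

MAX_NODULES_PER_SCAN = 10
MAX_SLICE_THICKNESS_MM = 5.0


class CohortValidationError(ValueError):
    """A record violates a domain invariant (field named in the message)."""


class IntegrityError(CohortValidationError):
    """Referential-integrity violation (orphan scan id, duplicate id)."""


class EmptyMaskError(ValueError):
    """A mask operation produced or received zero voxels."""


class GridMismatchError(ValueError):
    """Two masks do not share a voxel grid (shape and spacing)."""


# ---------------------------------------------------------------------------
# Voxel masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class VoxelMask:
    """A set of voxels on a regular grid, stored as sorted flat indices.

    Flat indices use C order over axes (x, y, z) with z the slice axis:
    ``flat = (x * ny + y) * nz + z``.  The physical center of voxel
    (i, j, k) is at ``(i + 0.5, j + 0.5, k + 0.5) * spacing``.
    """

    grid_shape: tuple[int, int, int]
    voxel_spacing_mm: tuple[float, float, float]
    idx: np.ndarray  # 1-D sorted unique int64 flat indices

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise CohortValidationError(f"grid_shape must be a positive triple, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise CohortValidationError(f"voxel_spacing_mm must be positive, got {spacing}")
        idx = np.unique(np.asarray(self.idx, dtype=np.int64).ravel())
        if idx.size == 0:
            raise EmptyMaskError("mask has no voxels")
        n = int(np.prod(shape))
        if idx[0] < 0 or idx[-1] >= n:
            raise CohortValidationError("mask indices fall outside the grid")
        object.__setattr__(self, "grid_shape", shape)
        object.__setattr__(self, "voxel_spacing_mm", spacing)
        object.__setattr__(self, "idx", idx)
        idx.setflags(write=False)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray | Sequence[Sequence[int]],
        grid_shape: Sequence[int],
        voxel_spacing_mm: Sequence[float],
    ) -> "VoxelMask":
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
        shape = tuple(int(s) for s in grid_shape)
        if coords.size and (coords.min() < 0 or (coords >= np.array(shape)).any()):
            raise CohortValidationError("voxel coordinates fall outside the grid")
        flat = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), shape)
        return cls(shape, tuple(float(s) for s in voxel_spacing_mm), flat)

    # -- basic geometry -----------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(self.idx.size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def coords(self) -> np.ndarray:
        """(N, 3) array of integer (x, y, z) voxel indices."""
        x, y, z = np.unravel_index(self.idx, self.grid_shape)
        return np.column_stack([x, y, z])

    def same_grid(self, other: "VoxelMask") -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(
            self.voxel_spacing_mm, other.voxel_spacing_mm
        )

    def intersection_count(self, other: "VoxelMask") -> int:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.grid_shape}/{self.voxel_spacing_mm} vs "
                f"{other.grid_shape}/{other.voxel_spacing_mm}"
            )
        return int(np.intersect1d(self.idx, other.idx, assume_unique=True).size)

    def translate(self, offset_voxels: Sequence[int]) -> "VoxelMask":
        """Shift the mask by whole voxels, dropping voxels that leave the grid."""
        c = self.coords() + np.asarray(offset_voxels, dtype=np.int64)
        inside = ((c >= 0) & (c < np.array(self.grid_shape))).all(axis=1)
        c = c[inside]
        if c.size == 0:
            raise EmptyMaskError("translation moved the mask entirely off the grid")
        return VoxelMask.from_coords(c, self.grid_shape, self.voxel_spacing_mm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelMask):
            return NotImplemented
        return (
            self.grid_shape == other.grid_shape
            and self.voxel_spacing_mm == other.voxel_spacing_mm
            and self.idx.size == other.idx.size
            and bool(np.array_equal(self.idx, other.idx))
        )

    def __hash__(self) -> int:  # pragma: no cover - identity-level hashing
        return hash((self.grid_shape, self.voxel_spacing_mm, self.idx.size, int(self.idx[0])))


def rasterize_ellipsoid(
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    grid_shape: Sequence[int],
    voxel_spacing_mm: Sequence[float],
) -> VoxelMask:
    """Voxelize an axis-aligned ellipsoid: a voxel is included iff its center
    lies inside the ellipsoid.  Deterministic; raises :class:`EmptyMaskError`
    if the ellipsoid misses every voxel center.
    """
    center = np.asarray(center_mm, dtype=float)
    axes = np.asarray(semi_axes_mm, dtype=float)
    if (axes <= 0).any():
        raise CohortValidationError(f"semi-axes must be positive, got {axes.tolist()}")
    shape = np.asarray(grid_shape, dtype=int)
    sp = np.asarray(voxel_spacing_mm, dtype=float)

    lo = np.maximum(np.floor((center - axes) / sp - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((center + axes) / sp - 0.5).astype(int) + 1, shape)
    if (hi <= lo).any():
        raise EmptyMaskError("ellipsoid lies entirely outside the grid")

    ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
    # normalized squared distance of voxel centers from the ellipsoid center
    dist = [(((r + 0.5) * sp[a] - center[a]) / axes[a]) ** 2 for a, r in enumerate(ranges)]
    inside = (
        dist[0][:, None, None] + dist[1][None, :, None] + dist[2][None, None, :]
    ) <= 1.0
    xs, ys, zs = np.nonzero(inside)
    if xs.size == 0:
        raise EmptyMaskError("ellipsoid does not contain any voxel center")
    coords = np.column_stack([xs + lo[0], ys + lo[1], zs + lo[2]])
    return VoxelMask.from_coords(coords, tuple(shape), tuple(sp))


def measure_nodule(mask: VoxelMask) -> tuple[float, float]:
    """Measure (avg_diameter_mm, volume_mm3) of a mask.

    Volume is exact: voxel count x voxel volume.  The diameter is the mean
    of the long axis (maximum Feret diameter of the voxel footprint on the
    axial slice of largest in-plane area) and the short axis (maximum
    extent perpendicular to the long axis on the same slice).  Feret
    extents are computed over voxel corners, so a single voxel has the
    extent of its own footprint.
    """
    volume = mask.volume_mm3
    coords = mask.coords()
    sx, sy, _ = mask.voxel_spacing_mm

    # axial slice (fixed z) with the largest in-plane area
    zs, counts = np.unique(coords[:, 2], return_counts=True)
    z_best = zs[np.argmax(counts)]
    inplane = coords[coords[:, 2] == z_best][:, :2].astype(float)

    # voxel footprint corners in physical mm
    centers = (inplane + 0.5) * np.array([sx, sy])
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]]) * np.array([sx, sy])
    pts = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)

    if pts.shape[0] > 32:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass

    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    long_axis = float(np.sqrt(d2[i, j]))
    if long_axis == 0.0:
        long_axis = short_axis = float(np.hypot(sx, sy)) / np.sqrt(2.0)
    else:
        u = (pts[j] - pts[i]) / long_axis
        perp = np.array([-u[1], u[0]])
        proj = pts @ perp
        short_axis = float(proj.max() - proj.min())
    return (long_axis + short_axis) / 2.0, volume


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanMeta:
    scan_id: str
    contains_nodule: bool
    age_group: str = "55_plus"
    sex: str = "male"
    other_abnormality: bool = False
    machine_type: str = "unknown"
    scan_type: str = "noncontrast"
    slice_thickness_mm: float = 1.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )


@dataclass(frozen=True)
class NoduleAnnotation:
    """One ground-truth nodule.  ``mask`` may be None only for report-derived
    candidates that were never segmented (adjudication input)."""

    scan_id: str
    nodule_id: str
    mask: VoxelMask | None
    texture: str
    calcification: bool
    spiculation: bool
    lobe: str
    avg_diameter_mm: float
    volume_mm3: float


@dataclass(frozen=True)
class CadFinding:
    """One CAD detection with its predicted characteristics."""

    scan_id: str
    finding_id: str
    mask: VoxelMask
    confidence: float
    texture: str
    calcification: bool
    spiculation: bool
    lobe: str
    avg_diameter_mm: float
    volume_mm3: float


@dataclass
class Cohort:
    scans: list[ScanMeta]
    gt_nodules: list[NoduleAnnotation] = field(default_factory=list)
    findings: list[CadFinding] = field(default_factory=list)

    def scan_map(self) -> dict[str, ScanMeta]:
        return {s.scan_id: s for s in self.scans}

    def nodules_by_scan(self) -> dict[str, list[NoduleAnnotation]]:
        out: dict[str, list[NoduleAnnotation]] = {s.scan_id: [] for s in self.scans}
        for n in self.gt_nodules:
            out.setdefault(n.scan_id, []).append(n)
        return out

    def findings_by_scan(self) -> dict[str, list[CadFinding]]:
        out: dict[str, list[CadFinding]] = {s.scan_id: [] for s in self.scans}
        for f in self.findings:
            out.setdefault(f.scan_id, []).append(f)
        return out

    def validate(self, strict: bool = True) -> list[str]:
        """Check every cohort invariant.

        Referential-integrity and schema errors always raise; range
        violations raise in strict mode and are downgraded to warnings
        otherwise.  Returns the list of warning messages.
        """
        hard: list[str] = []
        soft: list[str] = []
        ids = [s.scan_id for s in self.scans]
        seen = set()
        for sid in ids:
            if sid in seen:
                hard.append(f"duplicate scan_id {sid!r}")
            seen.add(sid)

        for s in self.scans:
            if s.age_group not in AGE_GROUPS:
                hard.append(f"scan {s.scan_id}: invalid age_group {s.age_group!r}")
            if s.sex not in SEXES:
                hard.append(f"scan {s.scan_id}: invalid sex {s.sex!r}")
            if s.scan_type not in SCAN_TYPES:
                hard.append(f"scan {s.scan_id}: invalid scan_type {s.scan_type!r}")
            if s.slice_thickness_mm > MAX_SLICE_THICKNESS_MM:
                soft.append(
                    f"scan {s.scan_id}: slice_thickness_mm {s.slice_thickness_mm} exceeds "
                    f"{MAX_SLICE_THICKNESS_MM} (exclusion rule)"
                )

        per_scan: dict[str, int] = {}
        nid_seen: set[tuple[str, str]] = set()
        for n in self.gt_nodules:
            if n.scan_id not in seen:
                hard.append(f"nodule {n.nodule_id}: orphan scan_id {n.scan_id!r}")
                continue
            key = (n.scan_id, n.nodule_id)
            if key in nid_seen:
                hard.append(f"duplicate nodule_id {n.nodule_id!r} in scan {n.scan_id}")
            nid_seen.add(key)
            per_scan[n.scan_id] = per_scan.get(n.scan_id, 0) + 1
            if n.texture not in TEXTURES:
                hard.append(f"nodule {n.nodule_id}: invalid texture {n.texture!r}")
            if n.lobe not in LOBES:
                hard.append(f"nodule {n.nodule_id}: invalid lobe {n.lobe!r}")
            lo, hi = DIAMETER_RANGE_MM
            if not (lo < n.avg_diameter_mm < hi):
                soft.append(
                    f"nodule {n.nodule_id}: avg_diameter_mm {n.avg_diameter_mm} outside "
                    f"({lo}, {hi})"
                )
            if n.volume_mm3 <= 0:
                hard.append(f"nodule {n.nodule_id}: volume_mm3 must be positive")
            if n.mask is not None:
                if n.volume_mm3 > 0 and abs(n.mask.volume_mm3 - n.volume_mm3) > 0.01 * n.volume_mm3:
                    soft.append(
                        f"nodule {n.nodule_id}: volume_mm3 {n.volume_mm3:.2f} differs from "
                        f"mask volume {n.mask.volume_mm3:.2f} by more than 1%"
                    )
                meta = self.scan_map().get(n.scan_id)
                if meta is not None and n.mask.grid_shape != meta.grid_shape:
                    hard.append(
                        f"nodule {n.nodule_id}: mask grid {n.mask.grid_shape} differs from "
                        f"scan grid {meta.grid_shape}"
                    )
        for sid, cnt in per_scan.items():
            if cnt > MAX_NODULES_PER_SCAN:
                soft.append(f"scan {sid}: {cnt} nodules exceed the {MAX_NODULES_PER_SCAN} cap")

        fid_seen: set[tuple[str, str]] = set()
        for f in self.findings:
            if f.scan_id not in seen:
                hard.append(f"finding {f.finding_id}: orphan scan_id {f.scan_id!r}")
                continue
            key = (f.scan_id, f.finding_id)
            if key in fid_seen:
                hard.append(f"duplicate finding_id {f.finding_id!r} in scan {f.scan_id}")
            fid_seen.add(key)
            if not (0.0 <= f.confidence <= 1.0):
                hard.append(f"finding {f.finding_id}: confidence {f.confidence} outside [0, 1]")
            if f.texture not in TEXTURES:
                hard.append(f"finding {f.finding_id}: invalid texture {f.texture!r}")
            if f.lobe not in LOBES:
                hard.append(f"finding {f.finding_id}: invalid lobe {f.lobe!r}")

        if hard:
            raise IntegrityError("; ".join(hard)) if any(
                "orphan" in h or "duplicate" in h for h in hard
            ) else CohortValidationError("; ".join(hard))
        if soft and strict:
            raise CohortValidationError("; ".join(soft))
        for msg in soft:
            warnings.warn(msg, stacklevel=2)
        return soft


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _rle_encode(idx: np.ndarray) -> list[list[int]]:
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [[int(idx[s]), int(e - s + 1)] for s, e in zip(starts, ends)]


def _rle_decode(runs: Iterable[Sequence[int]]) -> np.ndarray:
    parts = [np.arange(start, start + length, dtype=np.int64) for start, length in runs]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def _mask_to_json(mask: VoxelMask | None) -> dict | None:
    if mask is None:
        return None
    return {
        "grid_shape": list(mask.grid_shape),
        "voxel_spacing_mm": list(mask.voxel_spacing_mm),
        "rle": _rle_encode(mask.idx),
    }


def _mask_from_json(obj: dict | None, meta: ScanMeta | None, where: str) -> VoxelMask | None:
    if obj is None:
        return None
    if "rle" in obj:
        shape = tuple(obj.get("grid_shape") or (meta.grid_shape if meta else ()))
        spacing = tuple(obj.get("voxel_spacing_mm") or (meta.voxel_spacing_mm if meta else ()))
        if not shape:
            raise CohortValidationError(f"{where}: mask missing grid_shape")
        return VoxelMask(shape, spacing, _rle_decode(obj["rle"]))
    if "ellipsoid" in obj:
        if meta is None:
            raise CohortValidationError(f"{where}: ellipsoid mask requires scan metadata")
        e = obj["ellipsoid"]
        return rasterize_ellipsoid(
            e["center_mm"], e["semi_axes_mm"], meta.grid_shape, meta.voxel_spacing_mm
        )
    raise CohortValidationError(f"{where}: unrecognized mask payload {sorted(obj)}")


_META_FIELDS = [
    "scan_id",
    "contains_nodule",
    "age_group",
    "sex",
    "other_abnormality",
    "machine_type",
    "scan_type",
    "slice_thickness_mm",
    "grid_shape",
    "voxel_spacing_mm",
]

_NODULE_FIELDS = [
    "scan_id",
    "nodule_id",
    "texture",
    "calcification",
    "spiculation",
    "lobe",
    "avg_diameter_mm",
    "volume_mm3",
]

_FINDING_FIELDS = [
    "scan_id",
    "finding_id",
    "confidence",
    "texture",
    "calcification",
    "spiculation",
    "lobe",
    "avg_diameter_mm",
    "volume_mm3",
]


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, bool):
        return value
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise CohortValidationError(f"{where}: cannot parse boolean from {value!r}")


def _parse_triple(value, cast, where: str) -> tuple:
    if isinstance(value, (list, tuple)):
        items = value
    else:
        items = str(value).replace("x", ",").split(",")
    if len(items) != 3:
        raise CohortValidationError(f"{where}: expected a triple, got {value!r}")
    return tuple(cast(v) for v in items)


def _read_meta_csv(path: Path) -> list[ScanMeta]:
    scans = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return scans
        for i, row in enumerate(reader, start=2):
            where = f"{path.name} row {i}"
            try:
                scans.append(
                    ScanMeta(
                        scan_id=row["scan_id"],
                        contains_nodule=_parse_bool(row.get("contains_nodule", "false"), where),
                        age_group=row.get("age_group", "55_plus"),
                        sex=row.get("sex", "male"),
                        other_abnormality=_parse_bool(row.get("other_abnormality", "false"), where),
                        machine_type=row.get("machine_type", "unknown"),
                        scan_type=row.get("scan_type", "noncontrast"),
                        slice_thickness_mm=float(row.get("slice_thickness_mm", 1.0)),
                        grid_shape=_parse_triple(row.get("grid_shape", "64x64x64"), int, where),
                        voxel_spacing_mm=_parse_triple(
                            row.get("voxel_spacing_mm", "1x1x1"), float, where
                        ),
                    )
                )
            except KeyError as exc:
                raise CohortValidationError(f"{where}: missing field {exc}") from exc
    return scans


def _iter_records(path: Path):
    """Yield (lineno, dict) from a JSON-lines or CSV table; empty file -> nothing."""
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        return
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        for i, line in enumerate(text.splitlines(), start=1):
            if line.strip():
                yield i, json.loads(line)
    else:
        reader = csv.DictReader(text.splitlines())
        for i, row in enumerate(reader, start=2):
            yield i, row


def _record_mask(row: dict, meta: ScanMeta | None, where: str) -> VoxelMask | None:
    if "mask" in row and row["mask"] is not None:
        return _mask_from_json(row["mask"], meta, where)
    # CSV convention: inline ellipsoid parameter columns
    cols = ("center_x_mm", "center_y_mm", "center_z_mm", "semi_x_mm", "semi_y_mm", "semi_z_mm")
    if all(row.get(c) not in (None, "") for c in cols):
        if meta is None:
            raise CohortValidationError(f"{where}: ellipsoid mask requires scan metadata")
        center = [float(row[c]) for c in cols[:3]]
        axes = [float(row[c]) for c in cols[3:]]
        return rasterize_ellipsoid(center, axes, meta.grid_shape, meta.voxel_spacing_mm)
    return None


def read_cohort(
    annotation_path: str | Path,
    findings_path: str | Path,
    meta_path: str | Path,
    strict: bool = True,
) -> Cohort:
    """Read a cohort from an annotation table, a findings table, and a scan
    metadata table.  Tables are JSON-lines (inline RLE or ellipsoid masks) or
    CSV (ellipsoid parameter columns).  Raises on missing files, schema
    violations (named with file and row), and orphan scan ids.
    """
    annotation_path, findings_path, meta_path = (
        Path(annotation_path),
        Path(findings_path),
        Path(meta_path),
    )
    for p in (annotation_path, findings_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(p)
    scans = _read_meta_csv(meta_path)
    meta_map = {s.scan_id: s for s in scans}

    nodules: list[NoduleAnnotation] = []
    for i, row in _iter_records(annotation_path):
        where = f"{annotation_path.name} row {i}"
        try:
            meta = meta_map.get(row["scan_id"])
            mask = _record_mask(row, meta, where)
            nodules.append(
                NoduleAnnotation(
                    scan_id=row["scan_id"],
                    nodule_id=row["nodule_id"],
                    mask=mask,
                    texture=row["texture"],
                    calcification=_parse_bool(row["calcification"], where),
                    spiculation=_parse_bool(row["spiculation"], where),
                    lobe=row["lobe"],
                    avg_diameter_mm=float(row["avg_diameter_mm"]),
                    volume_mm3=float(row["volume_mm3"]),
                )
            )
        except KeyError as exc:
            raise CohortValidationError(f"{where}: missing field {exc}") from exc

    findings: list[CadFinding] = []
    for i, row in _iter_records(findings_path):
        where = f"{findings_path.name} row {i}"
        try:
            meta = meta_map.get(row["scan_id"])
            mask = _record_mask(row, meta, where)
            if mask is None:
                raise CohortValidationError(f"{where}: finding requires a mask")
            findings.append(
                CadFinding(
                    scan_id=row["scan_id"],
                    finding_id=row["finding_id"],
                    mask=mask,
                    confidence=float(row["confidence"]),
                    texture=row["texture"],
                    calcification=_parse_bool(row["calcification"], where),
                    spiculation=_parse_bool(row["spiculation"], where),
                    lobe=row["lobe"],
                    avg_diameter_mm=float(row["avg_diameter_mm"]),
                    volume_mm3=float(row["volume_mm3"]),
                )
            )
        except KeyError as exc:
            raise CohortValidationError(f"{where}: missing field {exc}") from exc

    cohort = Cohort(scans=scans, gt_nodules=nodules, findings=findings)
    cohort.validate(strict=strict)
    return cohort


def write_cohort(
    cohort: Cohort, out_dir: str | Path, mask_format: str = "rle"
) -> dict:
    """Write a cohort to ``out_dir`` (scans.csv, nodules.jsonl, findings.jsonl,
    manifest.json) and return the manifest.  ``mask_format`` is ``"rle"``
    (inline, lossless, text) or ``"nifti"`` (one label volume per scan).
    Round-trips exactly under ``"rle"``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "scans.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_META_FIELDS)
        writer.writeheader()
        for s in cohort.scans:
            writer.writerow(
                {
                    "scan_id": s.scan_id,
                    "contains_nodule": s.contains_nodule,
                    "age_group": s.age_group,
                    "sex": s.sex,
                    "other_abnormality": s.other_abnormality,
                    "machine_type": s.machine_type,
                    "scan_type": s.scan_type,
                    "slice_thickness_mm": s.slice_thickness_mm,
                    "grid_shape": "x".join(map(str, s.grid_shape)),
                    "voxel_spacing_mm": "x".join(map(repr, s.voxel_spacing_mm)),
                }
            )

    mask_files: dict[str, str] = {}
    if mask_format == "nifti":
        mask_files = _write_nifti_masks(cohort, out)

    def _dump(records, fields, path):
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                row = {f: getattr(r, f) for f in fields}
                row["mask"] = _mask_to_json(r.mask)
                fh.write(json.dumps(row) + "\n")

    if mask_format == "nifti":
        _write_tables_nifti(cohort, out, mask_files)
    else:
        _dump(cohort.gt_nodules, _NODULE_FIELDS, out / "nodules.jsonl")
        _dump(cohort.findings, _FINDING_FIELDS, out / "findings.jsonl")

    manifest = {
        "format": "cadeval-cohort/1",
        "mask_format": mask_format,
        "files": {
            "meta": "scans.csv",
            "annotations": "nodules.jsonl",
            "findings": "findings.jsonl",
        },
        "counts": {
            "scans": len(cohort.scans),
            "gt_nodules": len(cohort.gt_nodules),
            "findings": len(cohort.findings),
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort_dir(path: str | Path, strict: bool = True) -> Cohort:
    """Read a cohort directory produced by :func:`write_cohort`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        files = manifest["files"]
        if manifest.get("mask_format") == "nifti":
            return _read_cohort_nifti(path, files, strict=strict)
        return read_cohort(
            path / files["annotations"], path / files["findings"], path / files["meta"],
            strict=strict,
        )
    return read_cohort(
        path / "nodules.jsonl", path / "findings.jsonl", path / "scans.csv", strict=strict
    )


# ---------------------------------------------------------------------------
# NIfTI mask support (optional path; masks as unsigned-integer label volumes)
# ---------------------------------------------------------------------------

def _write_nifti_masks(cohort: Cohort, out: Path) -> dict:
    import nibabel as nib

    (out / "masks").mkdir(exist_ok=True)
    refs: dict[tuple[str, str], dict] = {}
    for kind, records, id_field in (
        ("gt", cohort.gt_nodules, "nodule_id"),
        ("cad", cohort.findings, "finding_id"),
    ):
        by_scan: dict[str, list] = {}
        for r in records:
            if r.mask is not None:
                by_scan.setdefault(r.scan_id, []).append(r)
        for scan_id, recs in by_scan.items():
            shape = recs[0].mask.grid_shape
            spacing = recs[0].mask.voxel_spacing_mm
            vol = np.zeros(shape, dtype=np.uint16)
            flat = vol.reshape(-1)
            for label, r in enumerate(recs, start=1):
                if (flat[r.mask.idx] != 0).any():
                    raise CohortValidationError(
                        f"scan {scan_id}: overlapping {kind} masks cannot share one label "
                        "volume; use mask_format='rle'"
                    )
                flat[r.mask.idx] = label
                refs[(scan_id, getattr(r, id_field))] = {
                    "nifti": f"masks/{scan_id}_{kind}.nii.gz",
                    "label": label,
                }
            affine = np.diag(list(spacing) + [1.0])
            nib.save(nib.Nifti1Image(vol, affine), out / f"masks/{scan_id}_{kind}.nii.gz")
    return refs


def _write_tables_nifti(cohort: Cohort, out: Path, refs: dict) -> None:
    with open(out / "nodules.jsonl", "w", encoding="utf-8") as fh:
        for n in cohort.gt_nodules:
            row = {f: getattr(n, f) for f in _NODULE_FIELDS}
            row["mask"] = refs.get((n.scan_id, n.nodule_id))
            fh.write(json.dumps(row) + "\n")
    with open(out / "findings.jsonl", "w", encoding="utf-8") as fh:
        for f_ in cohort.findings:
            row = {f: getattr(f_, f) for f in _FINDING_FIELDS}
            row["mask"] = refs.get((f_.scan_id, f_.finding_id))
            fh.write(json.dumps(row) + "\n")


def _load_nifti_mask(base: Path, ref: dict, meta: ScanMeta) -> VoxelMask:
    import nibabel as nib

    img = nib.load(base / ref["nifti"])
    data = np.asarray(img.dataobj)
    flat = np.nonzero(data.reshape(-1) == ref["label"])[0]
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return VoxelMask(tuple(data.shape), spacing, flat)


def _read_cohort_nifti(path: Path, files: dict, strict: bool) -> Cohort:
    scans = _read_meta_csv(path / files["meta"])
    meta_map = {s.scan_id: s for s in scans}
    nodules, findings = [], []
    for i, row in _iter_records(path / files["annotations"]):
        mask = _load_nifti_mask(path, row["mask"], meta_map[row["scan_id"]])
        nodules.append(
            NoduleAnnotation(
                scan_id=row["scan_id"],
                nodule_id=row["nodule_id"],
                mask=mask,
                texture=row["texture"],
                calcification=bool(row["calcification"]),
                spiculation=bool(row["spiculation"]),
                lobe=row["lobe"],
                avg_diameter_mm=float(row["avg_diameter_mm"]),
                volume_mm3=float(row["volume_mm3"]),
            )
        )
    for i, row in _iter_records(path / files["findings"]):
        mask = _load_nifti_mask(path, row["mask"], meta_map[row["scan_id"]])
        findings.append(
            CadFinding(
                scan_id=row["scan_id"],
                finding_id=row["finding_id"],
                mask=mask,
                confidence=float(row["confidence"]),
                texture=row["texture"],
                calcification=bool(row["calcification"]),
                spiculation=bool(row["spiculation"]),
                lobe=row["lobe"],
                avg_diameter_mm=float(row["avg_diameter_mm"]),
                volume_mm3=float(row["volume_mm3"]),
            )
        )
    cohort = Cohort(scans=scans, gt_nodules=nodules, findings=findings)
    cohort.validate(strict=strict)
    return cohort
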