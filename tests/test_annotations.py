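import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cadeval.annotations import (
    CadFinding,
    Cohort,
    CohortValidationError,
    EmptyMaskError,
    GridMismatchError,
    IntegrityError,
    NoduleAnnotation,
    ScanMeta,
    VoxelMask,
    measure_nodule,
    rasterize_ellipsoid,
    read_cohort,
    read_cohort_dir,
    write_cohort,
)


def _nodule(scan_id, nodule_id, mask, **kw):
    defaults = dict(
        texture="solid",
        calcification=False,
        spiculation=False,
        lobe="right_upper",
        avg_diameter_mm=5.0,
        volume_mm3=mask.volume_mm3 if mask is not None else 50.0,
    )
    defaults.update(kw)
    return NoduleAnnotation(scan_id=scan_id, nodule_id=nodule_id, mask=mask, **defaults)


class TestVoxelMask:
    def test_volume_is_count_times_voxel_volume(self, mask_factory):
        m = mask_factory([(0, 0, 0), (1, 0, 0), (2, 5, 7)], spacing=(0.5, 0.5, 2.0))
        assert m.volume_mm3 == pytest.approx(3 * 0.5 * 0.5 * 2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            VoxelMask((8, 8, 8), (1, 1, 1), np.empty(0, dtype=np.int64))

    def test_out_of_grid_rejected(self):
        with pytest.raises(CohortValidationError):
            VoxelMask.from_coords([(8, 0, 0)], (8, 8, 8), (1, 1, 1))

    def test_coords_roundtrip(self, mask_factory):
        coords = [(3, 4, 5), (0, 0, 0), (31, 31, 31)]
        m = mask_factory(coords)
        assert set(map(tuple, m.coords())) == set(coords)

    def test_equality(self, mask_factory):
        a = mask_factory([(1, 2, 3), (4, 5, 6)])
        b = mask_factory([(4, 5, 6), (1, 2, 3)])
        c = mask_factory([(1, 2, 3)])
        assert a == b
        assert a != c

    def test_translate_drops_outside(self, mask_factory):
        m = mask_factory([(0, 0, 0), (5, 5, 5)])
        shifted = m.translate((-1, 0, 0))
        assert shifted.n_voxels == 1
        with pytest.raises(EmptyMaskError):
            mask_factory([(0, 0, 0)]).translate((-1, 0, 0))

    def test_grid_mismatch(self, mask_factory):
        a = mask_factory([(0, 0, 0)])
        b = VoxelMask.from_coords([(0, 0, 0)], (16, 16, 16), (1, 1, 1))
        with pytest.raises(GridMismatchError):
            a.intersection_count(b)


class TestRasterizeEllipsoid:
    def test_sphere_volume_close_to_analytic(self):
        # radius 5 mm on 1 mm isotropic grid: (4/3) pi 125 ~ 524 voxels
        m = rasterize_ellipsoid((16, 16, 16), (5, 5, 5), (32, 32, 32), (1, 1, 1))
        assert abs(m.n_voxels - 4.0 / 3.0 * math.pi * 125) <= 0.1 * 4.0 / 3.0 * math.pi * 125

    def test_tiny_ellipsoid_single_voxel(self):
        # voxel (8,8,8) center is at 8.5 mm
        m = rasterize_ellipsoid((8.5, 8.5, 8.5), (0.4, 0.4, 0.4), (32, 32, 32), (1, 1, 1))
        assert m.n_voxels == 1
        assert tuple(m.coords()[0]) == (8, 8, 8)

    def test_deterministic(self):
        a = rasterize_ellipsoid((10.2, 11.7, 9.9), (3, 4, 2), (32, 32, 32), (1, 1, 1))
        b = rasterize_ellipsoid((10.2, 11.7, 9.9), (3, 4, 2), (32, 32, 32), (1, 1, 1))
        assert a == b

    def test_outside_grid_raises(self):
        with pytest.raises(EmptyMaskError):
            rasterize_ellipsoid((-50, -50, -50), (2, 2, 2), (32, 32, 32), (1, 1, 1))

    @given(
        base=st.floats(min_value=1.0, max_value=4.0),
        extra=st.floats(min_value=0.0, max_value=4.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_semi_axes(self, base, extra):
        small = rasterize_ellipsoid((16, 16, 16), (base,) * 3, (32, 32, 32), (1, 1, 1))
        big = rasterize_ellipsoid((16, 16, 16), (base + extra,) * 3, (32, 32, 32), (1, 1, 1))
        assert np.isin(small.idx, big.idx).all()


class TestMeasureNodule:
    def test_volume_definition(self, mask_factory):
        m = mask_factory([(i, 0, 0) for i in range(10)])
        _, vol = measure_nodule(m)
        assert vol == pytest.approx(10.0)

    def test_sphere_diameter(self):
        m = rasterize_ellipsoid((16, 16, 16), (4, 4, 4), (32, 32, 32), (1, 1, 1))
        avg_d, _ = measure_nodule(m)
        assert avg_d == pytest.approx(8.0, abs=1.0)

    def test_axial_ellipse_feret_axes(self):
        # semi-axes 6 x 4 mm in-plane: long 12, short 8 -> avg 10
        m = rasterize_ellipsoid((16, 16, 16), (6, 4, 2), (32, 32, 32), (1, 1, 1))
        avg_d, _ = measure_nodule(m)
        assert avg_d == pytest.approx(10.0, abs=1.0)

    def test_single_voxel(self, mask_factory):
        avg_d, vol = measure_nodule(mask_factory([(5, 5, 5)]))
        assert vol == pytest.approx(1.0)
        assert 0 < avg_d <= math.sqrt(2.0)


class TestCohortValidation:
    def test_diameter_out_of_range(self, mask_factory):
        scans = [ScanMeta("s1", True, grid_shape=(32, 32, 32))]
        nod = _nodule("s1", "n1", mask_factory([(0, 0, 0)]), avg_diameter_mm=35.0,
                      volume_mm3=1.0)
        cohort = Cohort(scans=scans, gt_nodules=[nod])
        with pytest.raises(CohortValidationError):
            cohort.validate(strict=True)

    def test_permissive_downgrades_range_violations(self, mask_factory):
        scans = [ScanMeta("s1", True, grid_shape=(32, 32, 32))]
        nod = _nodule("s1", "n1", mask_factory([(0, 0, 0)]), avg_diameter_mm=35.0,
                      volume_mm3=1.0)
        cohort = Cohort(scans=scans, gt_nodules=[nod])
        with pytest.warns(UserWarning):
            msgs = cohort.validate(strict=False)
        assert msgs

    def test_orphan_scan_id(self, mask_factory):
        cohort = Cohort(
            scans=[ScanMeta("s1", True, grid_shape=(32, 32, 32))],
            gt_nodules=[_nodule("ghost", "n1", mask_factory([(0, 0, 0)]), volume_mm3=1.0)],
        )
        with pytest.raises(IntegrityError):
            cohort.validate()

    def test_nodule_cap(self, mask_factory):
        scans = [ScanMeta("s1", True, grid_shape=(32, 32, 32))]
        nods = [
            _nodule("s1", f"n{i}", mask_factory([(i, 0, 0)]), volume_mm3=1.0)
            for i in range(11)
        ]
        with pytest.raises(CohortValidationError):
            Cohort(scans=scans, gt_nodules=nods).validate()

    def test_volume_mask_consistency(self, mask_factory):
        scans = [ScanMeta("s1", True, grid_shape=(32, 32, 32))]
        nod = _nodule("s1", "n1", mask_factory([(0, 0, 0), (1, 0, 0)]), volume_mm3=50.0)
        with pytest.raises(CohortValidationError):
            Cohort(scans=scans, gt_nodules=[nod]).validate()


class TestIO:
    def _small_cohort(self, block_factory):
        scans = [
            ScanMeta("s1", True, grid_shape=(32, 32, 32)),
            ScanMeta("s2", False, grid_shape=(32, 32, 32)),
        ]
        n1 = _nodule("s1", "n1", block_factory((2, 2, 2), (4, 4, 4)), volume_mm3=64.0)
        f1 = CadFinding(
            scan_id="s1",
            finding_id="f1",
            mask=block_factory((2, 2, 2), (4, 4, 2)),
            confidence=0.7,
            texture="part_solid",
            calcification=False,
            spiculation=True,
            lobe="middle",
            avg_diameter_mm=4.0,
            volume_mm3=32.0,
        )
        return Cohort(scans=scans, gt_nodules=[n1], findings=[f1])

    def test_roundtrip_identity(self, tmp_path, block_factory):
        cohort = self._small_cohort(block_factory)
        write_cohort(cohort, tmp_path)
        back = read_cohort_dir(tmp_path)
        assert back.scans == cohort.scans
        assert back.gt_nodules == cohort.gt_nodules
        assert back.findings == cohort.findings

    def test_roundtrip_paper_fixture(self, tmp_path, paper_fixture):
        write_cohort(paper_fixture.cohort, tmp_path)
        back = read_cohort_dir(tmp_path, strict=False)
        assert back.gt_nodules == paper_fixture.cohort.gt_nodules
        assert back.findings == paper_fixture.cohort.findings
        assert back.scans == paper_fixture.cohort.scans

    def test_nifti_roundtrip_voxel_counts(self, tmp_path, block_factory):
        cohort = self._small_cohort(block_factory)
        write_cohort(cohort, tmp_path, mask_format="nifti")
        back = read_cohort_dir(tmp_path)
        # independent re-count: voxel counts and coordinates survive
        for orig, re in zip(cohort.gt_nodules, back.gt_nodules):
            assert re.mask.n_voxels == orig.mask.n_voxels
            assert re.mask == orig.mask
        assert back.findings[0].mask == cohort.findings[0].mask

    def test_empty_cohort_roundtrip(self, tmp_path):
        cohort = Cohort(scans=[ScanMeta("s1", False, grid_shape=(32, 32, 32))])
        write_cohort(cohort, tmp_path)
        back = read_cohort_dir(tmp_path)
        assert len(back.scans) == 1
        assert back.gt_nodules == [] and back.findings == []

    def test_empty_findings_file(self, tmp_path):
        (tmp_path / "scans.csv").write_text(
            "scan_id,contains_nodule,grid_shape,voxel_spacing_mm\ns1,false,32x32x32,1x1x1\n"
        )
        (tmp_path / "nodules.jsonl").write_text("")
        (tmp_path / "findings.jsonl").write_text("")
        cohort = read_cohort(
            tmp_path / "nodules.jsonl", tmp_path / "findings.jsonl", tmp_path / "scans.csv"
        )
        assert len(cohort.scans) == 1
        assert not cohort.gt_nodules and not cohort.findings

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_cohort(tmp_path / "a.jsonl", tmp_path / "b.jsonl", tmp_path / "c.csv")

    def test_csv_ellipsoid_annotations(self, tmp_path):
        (tmp_path / "scans.csv").write_text(
            "scan_id,contains_nodule,grid_shape,voxel_spacing_mm\ns1,true,32x32x32,1x1x1\n"
        )
        (tmp_path / "nodules.csv").write_text(
            "scan_id,nodule_id,texture,calcification,spiculation,lobe,avg_diameter_mm,"
            "volume_mm3,center_x_mm,center_y_mm,center_z_mm,semi_x_mm,semi_y_mm,semi_z_mm\n"
            "s1,n1,solid,false,false,middle,8.0,552,16,16,16,5,5,5\n"
        )
        (tmp_path / "findings.jsonl").write_text("")
        cohort = read_cohort(
            tmp_path / "nodules.csv", tmp_path / "findings.jsonl", tmp_path / "scans.csv",
            strict=False,
        )
        expected = rasterize_ellipsoid((16, 16, 16), (5, 5, 5), (32, 32, 32), (1, 1, 1))
        assert cohort.gt_nodules[0].mask == expected

    def test_schema_violation_names_row(self, tmp_path):
        (tmp_path / "scans.csv").write_text(
            "scan_id,contains_nodule,grid_shape,voxel_spacing_mm\ns1,true,32x32x32,1x1x1\n"
        )
        (tmp_path / "nodules.jsonl").write_text('{"scan_id": "s1"}\n')
        (tmp_path / "findings.jsonl").write_text("")
        with pytest.raises(CohortValidationError, match="row 1"):
            read_cohort(
                tmp_path / "nodules.jsonl", tmp_path / "findings.jsonl", tmp_path / "scans.csv"
            )
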