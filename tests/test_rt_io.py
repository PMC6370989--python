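"""DICOM-RT interface: fixtures, parsing, round-trips, rasterization."""

import numpy as np
import pytest

from mlcdose import rt_io
from mlcdose.fixtures import generate_fixtures, water_box_ct
from mlcdose.rt_io import (ContourError, DoseGrid, GeometryError,
                           MissingMLCError, UnsupportedDeviceError,
                           plans_equal, read_ct_and_structures, read_dose,
                           read_plan, roi_mask, write_dose, write_plan)


class TestPlanReading:
    def test_vmat_fixture_shape(self, fixture_sets):
        plan = read_plan(fixture_sets["water_vmat"]["plan"])
        assert plan.technique == "VMAT"
        assert plan.n_control_points() == 160
        g = [cp.gantry_angle for cp in plan.beams[0].control_points]
        assert max(g) - min(g) >= 359.0  # gantry spans the full arc

    def test_imrt_fixture_constant_gantry(self, fixture_sets):
        plan = read_plan(fixture_sets["water_imrt"]["plan"])
        assert plan.technique == "IMRT"
        g = {cp.gantry_angle for cp in plan.beams[0].control_points}
        assert g == {0.0}

    def test_cumulative_weights_monotone_all_fixtures(self, fixture_sets):
        for kind, paths in fixture_sets.items():
            plan = read_plan(paths["plan"])
            for beam in plan.beams:
                w = [cp.cumulative_meterset_weight for cp in beam.control_points]
                assert np.all(np.diff(w) >= 0), kind
                assert w[-1] == pytest.approx(1.0)

    def test_write_read_roundtrip_exact(self, fixture_sets, tmp_path):
        for kind, paths in fixture_sets.items():
            plan = read_plan(paths["plan"])
            out = tmp_path / f"{kind}.dcm"
            write_plan(plan, out, seed=3)
            assert plans_equal(plan, read_plan(out)), kind

    def test_missing_mlc_sequence_is_structured_error(self, fixture_sets,
                                                      tmp_path):
        import pydicom
        ds = pydicom.dcmread(str(fixture_sets["closed_mlc"]["plan"]))
        for cp in ds.BeamSequence[0].ControlPointSequence:
            cp.BeamLimitingDevicePositionSequence = [
                e for e in cp.BeamLimitingDevicePositionSequence
                if not e.RTBeamLimitingDeviceType.startswith("MLC")]
        p = tmp_path / "no_mlc.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        with pytest.raises(MissingMLCError) as err:
            read_plan(p)
        assert "MLC" in str(err.value) and "300A" in str(err.value)

    def test_non_120_leaf_device_rejected(self, fixture_sets, tmp_path):
        import pydicom
        ds = pydicom.dcmread(str(fixture_sets["closed_mlc"]["plan"]))
        for bld in ds.BeamSequence[0].BeamLimitingDeviceSequence:
            if bld.RTBeamLimitingDeviceType == "MLCX":
                bld.NumberOfLeafJawPairs = 40
        p = tmp_path / "wrong_mlc.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        with pytest.raises(UnsupportedDeviceError):
            read_plan(p)


class TestCTAndStructures:
    def test_volume_matches_fixture_spec(self, fixture_sets):
        ct, _ = read_ct_and_structures(fixture_sets["closed_mlc"]["ct_dir"],
                                       fixture_sets["closed_mlc"]["structures"])
        assert ct.shape == (50, 128, 128)
        assert ct.spacing == (2.5, 2.5, 4.0)

    def test_body_mask_equals_box_interior(self, fixture_sets):
        paths = fixture_sets["closed_mlc"]
        ct, ss = read_ct_and_structures(paths["ct_dir"], paths["structures"])
        mask = roi_mask(ss, "BODY", ct)
        # analytic box: +-120 mm in x/y on a 2.5 mm grid, all 50 slices
        per_slice = (240 / 2.5) ** 2
        analytic = 50 * per_slice
        perimeter_layer = 50 * 4 * (240 / 2.5)
        assert abs(mask.sum() - analytic) <= perimeter_layer

    def test_empty_directory_is_geometry_error(self, tmp_path):
        with pytest.raises(GeometryError):
            read_ct_and_structures(tmp_path)

    def test_inconsistent_slice_spacing_rejected(self, tmp_path):
        import pydicom
        ct = water_box_ct()
        rt_io.write_ct(ct, tmp_path, seed=0)
        p = sorted(tmp_path.glob("*.dcm"))[10]
        ds = pydicom.dcmread(str(p))
        ds.ImagePositionPatient[2] = float(ds.ImagePositionPatient[2]) + 1.7
        ds.save_as(str(p), enforce_file_format=True)
        with pytest.raises(GeometryError):
            read_ct_and_structures(tmp_path)

    def test_contour_off_grid_is_contour_error(self, tmp_path):
        from mlcdose.fixtures import water_structures
        ct = water_box_ct()
        rt_io.write_ct(ct, tmp_path / "ct", seed=0)
        ss = water_structures(ct)
        ss.rois[1].contours.append((999.0, ss.rois[1].contours[0][1]))
        rt_io.write_structures(ss, tmp_path / "rs.dcm", seed=0)
        with pytest.raises(ContourError):
            read_ct_and_structures(tmp_path / "ct", tmp_path / "rs.dcm")


class TestDoseRoundtrip:
    def _grid(self, data):
        return DoseGrid(dose=data, uncertainty=None, origin=(-10.0, -10.0, -10.0),
                        spacing=(2.0, 2.0, 2.0))

    def test_uniform_grid_quantization_bound(self, tmp_path):
        g = self._grid(np.full((10, 10, 10), 1.0))
        write_dose(g, tmp_path / "d.dcm")
        back = read_dose(tmp_path / "d.dcm")
        quantum = 1.0 / (2**32 - 1)
        assert np.max(np.abs(back.dose - g.dose)) <= quantum
        assert back.spacing == g.spacing and back.origin == g.origin

    def test_zero_grid_roundtrip_identity(self, tmp_path):
        g = self._grid(np.zeros((4, 5, 6)))
        write_dose(g, tmp_path / "z.dcm")
        assert np.all(read_dose(tmp_path / "z.dcm").dose == 0.0)

    def test_random_grid_roundtrip_within_quantum(self, tmp_path):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 8.74, size=(8, 9, 10))
        g = self._grid(data)
        write_dose(g, tmp_path / "r.dcm")
        back = read_dose(tmp_path / "r.dcm")
        assert np.max(np.abs(back.dose - data)) <= data.max() / (2**32 - 1)

    def test_fixture_reference_dose_geometry(self, fixture_sets):
        d = read_dose(fixture_sets["water_vmat"]["reference_dose"])
        assert d.spacing == (4.0, 4.0, 4.0)
        assert d.dose.max() <= 1.59


class TestFixtures:
    def test_closed_mlc_all_pairs_abut(self, fixture_sets):
        plan = read_plan(fixture_sets["closed_mlc"]["plan"])
        for cp in plan.beams[0].control_points:
            a = cp.leaf_positions[:60]
            b = cp.leaf_positions[60:]
            assert np.all(b - a == 0.0)

    def test_open_10x10_aperture_area(self, fixture_sets):
        plan = read_plan(fixture_sets["open_10x10"]["plan"])
        cp = plan.beams[0].control_points[0]
        a, b = cp.leaf_positions[:60], cp.leaf_positions[60:]
        widths = np.array([10.0] * 10 + [5.0] * 40 + [10.0] * 10)
        x1, x2, y1, y2 = cp.jaw_positions
        gap = np.clip(np.minimum(b, x2) - np.maximum(a, x1), 0, None)
        bounds = np.concatenate([[-200.0], -200.0 + np.cumsum(widths)])
        # only pairs whose gap interval lies inside the open jaw x-range count
        in_x = (b >= x1) & (a <= x2) & (b > a)
        area_mm2 = float((gap * widths)[in_x].sum())
        assert area_mm2 == pytest.approx(100.0 * 100.0)  # 100 cm^2
        del bounds

    def test_fixture_sets_are_byte_reproducible(self, tmp_path):
        a = generate_fixtures("closed_mlc", tmp_path / "a", seed=42)
        b = generate_fixtures("closed_mlc", tmp_path / "b", seed=42)
        assert a["plan"].read_bytes() == b["plan"].read_bytes()
        assert a["structures"].read_bytes() == b["structures"].read_bytes()
        ca = sorted((tmp_path / "a" / "ct").glob("*.dcm"))
        cb = sorted((tmp_path / "b" / "ct").glob("*.dcm"))
        assert all(x.read_bytes() == y.read_bytes() for x, y in zip(ca, cb))

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_fixtures("nope", tmp_path)
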