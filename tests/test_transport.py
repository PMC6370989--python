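"""Transport engine: source sampling, phase space, attenuation physics,
statistics and determinism."""

import numpy as np
import pytest

from mlcdose.fixtures import _static_plan, open_10x10_plan
from mlcdose.materials import VoxelPhantom
from mlcdose.transport import (PhaseSpaceError, SourceModel, TransportSettings,
                               collimator_transmission_map, csda_range_water,
                               make_phase_space, phsp_roundtrip,
                               read_phase_space, replay_records, sample_rays,
                               sample_source, simulate_dose,
                               write_phase_space, _rng_for)


def _open_plan(jaw_half=80.0, mu=100.0):
    leaves = np.r_[np.full(60, -100.0), np.full(60, 100.0)]
    return _static_plan("open", jaw_half, leaves, mu)


def _slab_phantom(half_mm=100.0, depth_mm=200.0, voxel=4.0):
    """Water slab with its entrance surface on the isocenter plane."""
    n = int(2 * half_mm / voxel)
    ny = int(depth_mm / voxel)
    origin = (-half_mm + voxel / 2, voxel / 2, -half_mm + voxel / 2)
    return VoxelPhantom.water_box((n, ny, n), (voxel, voxel, voxel), origin)


class TestSource:
    def test_delta_spectrum(self):
        src = SourceModel.monoenergetic(2.0)
        e = src.sample_energies(_rng_for(0, 1), 10_000)
        assert np.all(e == 2.0)

    def test_two_line_spectrum_binomial_bound(self):
        src = SourceModel(np.array([1.0, 5.0]), np.array([0.3, 0.7]))
        n = 1_000_000
        e = src.sample_energies(_rng_for(0, 2), n)
        frac1 = np.mean(e == 1.0)
        sigma = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac1 - 0.3) < 3 * sigma

    def test_zero_focal_spot_identical_origins(self, machine):
        src = SourceModel.monoenergetic(2.0, focal_spot_sigma=0.0)
        o, d, e, w = sample_rays(src, _rng_for(0, 3), 1000,
                                 (-50, 50, -50, 50), 1000.0)
        assert np.all(o == 0.0)

    def test_spectrum_normalization_enforced(self):
        src = SourceModel(np.array([1.0, 2.0]), np.array([2.0, 6.0]))
        assert src.spectrum_probabilities.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            SourceModel(np.array([1.0, -2.0]), np.array([0.5, 0.5]))

    def test_inverse_square_fluence_ratio(self, machine):
        # photons through a central patch at 50 cm vs 100 cm from the source
        src = SourceModel.monoenergetic(2.0, focal_spot_sigma=0.0)
        n = 400_000
        o, d, e, w = sample_rays(src, _rng_for(0, 4), n,
                                 (-100, 100, -100, 100), 1000.0)
        half = 10.0  # patch half-side at 100 cm

        def count_at(z):
            t = z / d[:, 2]
            x = d[:, 0] * t
            y = d[:, 1] * t
            s = half * z / 1000.0  # same solid angle patch
            del s
            return np.count_nonzero((np.abs(x) <= half) & (np.abs(y) <= half))

        n_far = count_at(1000.0)
        n_near = count_at(500.0)
        ratio = n_near / n_far
        p = n_far / n
        sigma = np.sqrt(p * (1 - p) / n) / p  # relative binomial error
        assert ratio == pytest.approx(4.0, rel=4 * sigma + 0.01)


class TestPhaseSpace:
    def _records(self, n=1000):
        rng = np.random.default_rng(8)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        return make_phase_space(rng.uniform(0.1, 6.0, n),
                                rng.uniform(-50, 50, n), rng.uniform(-50, 50, n),
                                u[:, 0], u[:, 1], u[:, 2],
                                rng.uniform(0.1, 2.0, n))

    def test_roundtrip_identity(self, tmp_path):
        rec = self._records()
        back = phsp_roundtrip(rec, tmp_path / "a.phsp", plane_z=508.0)
        assert np.array_equal(rec, back)

    def test_reuse_factor_replays_each_record(self, tmp_path):
        rec = self._records(100)
        replayed = replay_records(rec, 2)
        assert len(replayed) == 200
        assert np.array_equal(replayed[:100], rec)
        assert np.array_equal(replayed[100:], rec)

    def test_empty_file_is_empty_list(self, tmp_path):
        p = tmp_path / "empty.phsp"
        write_phase_space(self._records(0), p, plane_z=500.0)
        rec, z = read_phase_space(p)
        assert len(rec) == 0 and z == 500.0

    def test_truncated_file_raises_structured_error(self, tmp_path):
        p = tmp_path / "trunc.phsp"
        write_phase_space(self._records(10), p, plane_z=500.0)
        data = p.read_bytes()
        p.write_bytes(data[:-13])
        with pytest.raises(PhaseSpaceError, match="truncated"):
            read_phase_space(p)

    def test_source_records_on_phsp_plane(self, machine):
        src = SourceModel.default_6mv()
        rec = sample_source(src, _rng_for(0, 5), 500, machine)
        norm = rec["u"] ** 2 + rec["v"] ** 2 + rec["w"] ** 2
        assert np.allclose(norm, 1.0, atol=1e-9)
        assert np.all(rec["weight"] > 0)


class TestTransmissionMap:
    def test_open_aperture_map_is_unity_inside(self, machine):
        plan = _open_plan(jaw_half=50.0)
        cp = plan.beams[0].control_points[0]
        m = collimator_transmission_map(cp, machine, resolution=2.0)
        inside = (np.abs(m.x[None, :]) < 40) & (np.abs(m.y[:, None]) < 40)
        assert np.all(m.values[inside] == 1.0)

    def test_closed_mlc_midline_ridge(self, machine):
        from mlcdose.fixtures import closed_mlc_plan
        cp = closed_mlc_plan().beams[0].control_points[0]
        m = collimator_transmission_map(cp, machine, resolution=0.5)
        # at a leaf-center row, the midline beats off-midline columns
        iy = int(np.argmin(np.abs(m.y - 2.5)))
        ix0 = int(np.argmin(np.abs(m.x)))
        row = m.values[iy]
        assert row[ix0] == row.max()
        assert row[ix0] > 10 * row[int(np.argmin(np.abs(m.x - 30)))]

    def test_mirrored_aperture_mirrors_map(self, machine):
        leaves = np.full(120, -80.0)
        leaves[:60][25:35] = -30.0
        leaves[60:][25:35] = 10.0
        from mlcdose.rt_io import ControlPoint
        cp = ControlPoint(0, 0.0, 0.0, (-50, 50, -50, 50), leaves, 0.0)
        mirrored = ControlPoint(0, 0.0, 0.0, (-50, 50, -50, 50),
                                np.r_[-leaves[60:], -leaves[:60]], 0.0)
        a = collimator_transmission_map(cp, machine, resolution=1.0)
        b = collimator_transmission_map(mirrored, machine, resolution=1.0)
        assert np.max(np.abs(a.values - b.values[:, ::-1])) < 1e-12


class TestPhantomTransport:
    def test_primary_attenuation_slope(self, machine):
        # broad monoenergetic beam; after removing the inverse-square
        # factor the central-axis primary dose decays at exactly mu(E)
        energy = 2.0
        src = SourceModel.monoenergetic(energy, focal_spot_sigma=0.0)
        plan = _open_plan(jaw_half=80.0)
        ph = _slab_phantom(half_mm=100.0, depth_mm=200.0, voxel=4.0)
        st = TransportSettings(n_histories=300_000, seed=5,
                               mode="raytrace_primary", batch_count=2,
                               electron_spread="off")
        g = simulate_dose(plan, ph, src, st, machine)
        nz, ny, nx = g.shape
        c = nx // 2
        dose = g.dose[c - 2:c + 2, :, c - 2:c + 2].mean(axis=(0, 2))
        depth = g.origin[1] + np.arange(ny) * g.spacing[1]
        r = 1000.0 + depth
        corrected = np.log(dose * (r / 1000.0) ** 2)
        sel = (depth > 10) & (depth < 190)
        slope, _ = np.polyfit(depth[sel], corrected[sel], 1)
        from mlcdose.xsec import WATER, AttenuationTable
        mu = AttenuationTable(WATER).mass_attenuation(energy) / 10.0  # 1/mm
        assert slope == pytest.approx(-mu, rel=5e-3)

    def test_fixed_seed_bit_identical(self, machine, small_water_phantom):
        plan = open_10x10_plan()
        src = SourceModel.default_6mv()
        st = TransportSettings(n_histories=100_000, seed=11, batch_count=3)
        a = simulate_dose(plan, small_water_phantom, src, st, machine)
        b = simulate_dose(plan, small_water_phantom, src, st, machine)
        assert np.array_equal(a.dose, b.dose)
        assert np.array_equal(a.uncertainty, b.uncertainty)

    def test_energy_bookkeeping(self, machine, small_water_phantom):
        plan = open_10x10_plan()
        src = SourceModel.default_6mv()
        st = TransportSettings(n_histories=100_000, seed=1, batch_count=2)
        g = simulate_dose(plan, small_water_phantom, src, st, machine)
        info = g.run_info
        assert 0 < info.deposited_energy_mev < info.emitted_energy_mev

    def test_uncertainty_scales_inverse_sqrt(self, machine):
        from mlcdose.analysis import voxel_uncertainty_summary
        plan = _open_plan(jaw_half=50.0)
        src = SourceModel.default_6mv()
        ph = _slab_phantom(half_mm=60.0, depth_mm=100.0, voxel=5.0)
        region = np.zeros(ph.shape, dtype=bool)
        region[ph.shape[0] // 2 - 4:ph.shape[0] // 2 + 4, 2:12,
               ph.shape[2] // 2 - 4:ph.shape[2] // 2 + 4] = True
        u = []
        for n in (150_000, 300_000):
            st = TransportSettings(n_histories=n, seed=21, batch_count=10)
            g = simulate_dose(plan, ph, src, st, machine)
            u.append(voxel_uncertainty_summary(g, region))
        assert u[1] / u[0] == pytest.approx(1 / np.sqrt(2), rel=0.15)

    def test_closed_jaws_block_everything(self, machine, small_water_phantom):
        src = SourceModel.default_6mv()
        leaves = np.r_[np.full(60, -100.0), np.full(60, 100.0)]
        open_plan = _static_plan("open", 50.0, leaves, 100.0)
        blocked = _static_plan("blocked", 50.0, leaves, 100.0)
        for cp in blocked.beams[0].control_points:
            cp.jaw_positions = (0.0, 0.0, 0.0, 0.0)
        st = TransportSettings(n_histories=150_000, seed=2, batch_count=2)
        g_open = simulate_dose(open_plan, small_water_phantom, src, st, machine)
        g_blk = simulate_dose(blocked, small_water_phantom, src, st, machine)
        assert g_blk.dose.sum() < 1e-3 * g_open.dose.sum()

    def test_mc_without_secondaries_matches_primary_kerma(self, machine):
        src = SourceModel.monoenergetic(2.0, focal_spot_sigma=0.0)
        plan = _open_plan(jaw_half=50.0)
        ph = _slab_phantom(half_mm=60.0, depth_mm=100.0, voxel=5.0)
        st_mc = TransportSettings(n_histories=400_000, seed=3, batch_count=4,
                                  follow_scatter=False, enable_pair=False,
                                  electron_spread="off")
        st_rt = TransportSettings(n_histories=400_000, seed=4, batch_count=2,
                                  mode="raytrace_primary",
                                  electron_spread="off")
        g_mc = simulate_dose(plan, ph, src, st_mc, machine)
        g_rt = simulate_dose(plan, ph, src, st_rt, machine)
        sel = g_rt.dose > 0.3 * g_rt.dose.max()
        ratio = g_mc.dose[sel].sum() / g_rt.dose[sel].sum()
        assert ratio == pytest.approx(1.0, abs=0.03)

    def test_cutoff_above_spectrum_refused(self, machine, small_water_phantom):
        src = SourceModel.monoenergetic(0.3)
        st = TransportSettings(n_histories=1000, seed=0, energy_cutoff=0.5,
                               batch_count=2)
        with pytest.raises(ValueError):
            simulate_dose(open_10x10_plan(), small_water_phantom, src, st,
                          machine)


def test_csda_range_interpolation_monotone():
    e = np.linspace(0.05, 6.0, 200)
    r = csda_range_water(e)
    assert np.all(np.diff(r) > 0)
    assert csda_range_water(1.0) == pytest.approx(0.4367, rel=1e-6)
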