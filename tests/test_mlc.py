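"""MLC geometry: tip thickness, projection, transmission, LP statistics."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from mlcdose import mlc
from mlcdose.fixtures import closed_mlc_plan, open_10x10_plan, water_vmat_plan
from mlcdose.mlc import (Jaws, LeafSpec, MachineConfigError, TipProfile,
                         leaf_pair_distance_stats, project_leaf_positions,
                         ray_transmission, unproject_leaf_positions)


def _curve_oracle(profile: TipProfile, n=400_001):
    """Independent boundary-curve sampler: walks the parametric tip
    boundary (arc / flat / arc) at fine resolution and interpolates
    depth -> half-thickness, without using the analytic inversion."""
    rc = profile.central_radius
    th_c = np.radians(profile.central_angle_deg)
    h2 = profile.height / 2.0
    us, zs = [], []
    a = np.linspace(0, th_c, n // 3)
    us.append(rc * (1 - np.cos(a)))
    zs.append(rc * np.sin(a))
    if profile.flat_length > 0:
        t = np.linspace(0, profile.flat_length, n // 3)
        us.append(us[-1][-1] + t * np.sin(th_c))
        zs.append(zs[-1][-1] + t * np.cos(th_c))
    if profile.side_arc_radius > 0 and profile.side_arc_angle_deg > 0:
        rs = profile.side_arc_radius
        cu = us[-1][-1] + rs * np.cos(th_c)
        cz = zs[-1][-1] - rs * np.sin(th_c)
        a = np.linspace(th_c, min(th_c + np.radians(profile.side_arc_angle_deg),
                                  np.pi / 2), n // 3)
        us.append(cu - rs * np.cos(a))
        zs.append(cz + rs * np.sin(a))
    u = np.concatenate(us)
    z = np.minimum(np.concatenate(zs), h2)
    keep = np.concatenate([[True], np.diff(u) > 0])
    u, z = u[keep], z[keep]

    def thickness(d):
        d = np.asarray(d, dtype=float)
        out = 2 * np.interp(d, u, z, left=0.0, right=h2)
        out[d <= 0] = 0.0
        out[d > u[-1]] = profile.height
        return np.minimum(out, profile.height)

    return thickness


class TestTipProfile:
    def test_apex_is_zero_and_body_saturates(self, machine):
        prof = machine.bank.pairs[30].tip_profile()
        assert prof.thickness(0.0) == 0.0
        assert prof.thickness(-5.0) == 0.0
        assert prof.thickness(50.0) == prof.height

    def test_monotone_nondecreasing(self, machine):
        prof = machine.bank.pairs[0].tip_profile()
        d = np.linspace(-2, 30, 2000)
        t = prof.thickness(d)
        assert np.all(np.diff(t) >= -1e-12)

    def test_pure_circular_chord(self):
        # radius/height chosen so the chord stays below the leaf height
        prof = TipProfile.pure_circular(radius=40.0, height=80.0)
        d = 20.0  # tip_radius / 2
        chord = 2 * np.sqrt(40.0**2 - (40.0 - d) ** 2)
        assert prof.thickness(d) == pytest.approx(chord, abs=1e-9)

    @pytest.mark.parametrize("leaf_type,width", [("full", 5.0), ("half", 10.0),
                                                 ("outboard", 10.0)])
    def test_composite_matches_curve_oracle(self, leaf_type, width):
        spec = LeafSpec(leaf_type=leaf_type, width_at_iso=width,
                        physical_height=67.0, tip_radius=80.0,
                        tip_central_angle_deg=18.0, tip_flat_length=6.0,
                        tip_side_arc_radius=12.0, tip_side_arc_angle_deg=45.0)
        prof = spec.tip_profile()
        oracle = _curve_oracle(prof)
        d = np.linspace(-0.5, prof.full_depth + 2.0, 3000)
        assert np.max(np.abs(prof.thickness(d) - oracle(d))) < 5e-4  # 0.5 um

    def test_radius_must_span_height(self):
        with pytest.raises(MachineConfigError):
            TipProfile.pure_circular(radius=20.0, height=67.0)


class TestProjection:
    def test_central_axis_fixed_point(self, machine):
        assert project_leaf_positions(np.zeros(120), machine.bank).tolist() \
            == [0.0] * 120

    def test_stated_ratio(self, machine):
        bank = mlc.MLCBank(pairs=machine.bank.pairs, source_to_mlc_distance=500.0,
                           sad=1000.0)
        out = project_leaf_positions(np.full(120, 50.0), bank)
        assert np.allclose(out, 25.0)

    def test_similar_triangles_oracle_and_inverse(self, machine):
        rng = np.random.default_rng(11)
        iso = rng.uniform(-150, 150, 120)
        phys = project_leaf_positions(iso, machine.bank)
        # geometric oracle: the ray from the source through (iso, SAD)
        # crosses the MLC plane at iso * z_mlc / SAD
        z = machine.bank.source_to_mlc_distance
        oracle = iso * z / machine.bank.sad
        assert np.max(np.abs(phys - oracle)) < 1e-12
        back = unproject_leaf_positions(phys, machine.bank)
        assert np.max(np.abs(back - iso)) < 1e-12


class TestRayTransmission:
    def test_open_field_center(self, machine):
        leaf = np.r_[np.full(60, -50.0), np.full(60, 50.0)]
        t = ray_transmission([0, 0, 0], [0, 0, 1], 2.0, machine,
                             Jaws.square(75), leaf)
        assert t == 1.0

    def test_full_leaf_body_closed_form(self, machine):
        # perpendicular ray deep behind a bank-A tip: path = leaf height
        leaf = np.r_[np.full(60, 45.0), np.full(60, 50.0)]
        energy = 2.0
        # central leaf row, far from interleaf boundaries, depth >> tip region
        t = ray_transmission([2.5e-3 * 509 / 1000 * 0, 0, 0],  # central axis-ish
                             [0.0, 2.5 / 1000.0, 1.0], energy, machine,
                             Jaws.square(75), leaf)
        mu = machine._mlc_atten.linear_attenuation(energy)  # 1/cm
        obliq = np.sqrt(1 + (2.5 / 1000.0) ** 2)
        expected = np.exp(-mu * 6.7 * obliq)
        assert t == pytest.approx(expected, rel=1e-12)

    def test_abutment_midline_brighter_than_body(self, machine):
        closed = np.zeros(120)
        e = 2.0
        t_mid = ray_transmission([0, 0, 0], [0.2 / 1000, 2.5 / 1000, 1.0], e,
                                 machine, Jaws.square(75), closed)
        t_body = ray_transmission([0, 0, 0], [30.0 / 1000, 2.5 / 1000, 1.0], e,
                                  machine, Jaws.square(75), closed)
        assert t_mid > t_body

    def test_bounds_and_monotonicity_in_depth(self, machine):
        # one fixed ray; pushing the bank-A tip further past it grows the
        # tungsten path, so transmission must never increase
        ts = []
        for tip in np.linspace(0.0, 40.0, 41):
            leaf = np.r_[np.full(60, tip), np.full(60, 100.0)]
            ts.append(ray_transmission([0, 0, 0], [0, 2.5 / 1000.0, 1.0], 2.0,
                                       machine, Jaws.square(75), leaf))
        ts = np.array(ts)
        assert np.all((ts >= 0) & (ts <= 1))
        assert np.all(np.diff(ts) <= 1e-15)

    def test_collimator_rotation_is_rigid(self, machine):
        # map(theta) at (x, y) equals map(0) at the back-rotated point
        leaf = np.full(120, -80.0)
        sel = slice(20, 40)
        leaf[:60][sel] = -30.0
        leaf_b = leaf.copy()
        leaf_b[60:][sel] = 10.0  # asymmetric aperture
        theta = 30.0
        rng = np.random.default_rng(5)
        pts = rng.uniform(-40, 40, size=(200, 2))
        c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
        back = np.column_stack([c * pts[:, 0] + s * pts[:, 1],
                                -s * pts[:, 0] + c * pts[:, 1]])
        jaws = Jaws.square(150.0)  # jaws out of the way (they do not rotate here)
        e = np.full(len(pts), 2.0)
        o = np.zeros((len(pts), 3))

        def dirs(p):
            return np.column_stack([p / 1000.0, np.ones(len(p))])

        t_rot = ray_transmission(o, dirs(pts), e, machine, jaws, leaf_b,
                                 collimator_angle=theta)
        t_ref = ray_transmission(o, dirs(back), e, machine, jaws, leaf_b,
                                 collimator_angle=0.0)
        assert np.max(np.abs(t_rot - t_ref)) < 1e-9

    @hyp_settings(max_examples=25, deadline=None)
    @given(gap=st.floats(0.0, 60.0), x=st.floats(-70.0, 70.0),
           y=st.floats(-90.0, 90.0))
    def test_transmission_always_in_unit_interval(self, machine, gap, x, y):
        leaf = np.r_[np.full(60, -gap / 2), np.full(60, gap / 2)]
        t = ray_transmission([0, 0, 0], [x / 1000.0, y / 1000.0, 1.0], 1.5,
                             machine, Jaws.square(60), leaf)
        assert 0.0 <= t <= 1.0


class TestLeafPairDistances:
    def test_closed_fixture_all_zero_ratio_one(self):
        stats = leaf_pair_distance_stats(closed_mlc_plan(), threshold=10.0)
        assert np.all(stats.distances == 0.0)
        assert stats.ratio == 1.0

    def test_open_10x10_in_field_ratio_zero(self):
        stats = leaf_pair_distance_stats(open_10x10_plan(), threshold=10.0)
        assert stats.ratio == 0.0

    def test_ratio_matches_counting_oracle(self):
        plan = water_vmat_plan()
        thr = 10.0
        stats = leaf_pair_distance_stats(plan, threshold=thr)
        # brute force over every (control point, pair)
        count = total = 0
        widths = stats.distances  # shape check only
        row = 0
        bounds = np.concatenate([[-200.0], -200.0 + np.cumsum(
            [10.0] * 10 + [5.0] * 40 + [10.0] * 10)])
        for beam in plan.beams:
            for cp in beam.control_points:
                a = cp.leaf_positions[:60]
                b = cp.leaf_positions[60:]
                x1, x2, y1, y2 = cp.jaw_positions
                for p in range(60):
                    in_y = bounds[p + 1] > y1 and bounds[p] < y2
                    in_x = b[p] >= x1 and a[p] <= x2
                    if in_y and in_x:
                        total += 1
                        if b[p] - a[p] < thr:
                            count += 1
                row += 1
        assert widths.shape == (plan.n_control_points(), 60)
        assert stats.ratio == pytest.approx(count / total)
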