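"""WSS, probes, streamlines and helicity on constructed and solved fields."""

import numpy as np
import pytest

from aortohemo.geometry import AortaSpec, build_aorta, voxelize
from aortohemo.postprocess import (
    HelicityMap,
    extract_probes,
    pswss_extrema,
    streamlines_and_lnh,
    wall_shear_stress,
)
from aortohemo.solver import FlowField
from aortohemo.units import MMHG_TO_PA

from conftest import TUBE_Q_ML_S


def make_field(domain, fill_u=0.0, fill_w=0.0, p=0.0, t=0.0):
    """Constructed field with uniform face values inside the fluid."""
    shape = domain.shape
    u = np.zeros((shape[0] + 1, shape[1], shape[2]))
    v = np.zeros((shape[0], shape[1] + 1, shape[2]))
    w = np.zeros((shape[0], shape[1], shape[2] + 1))
    F = domain.fluid
    u[:-1][F] = fill_u
    w[:, :, :-1][F] = fill_w
    pf = np.zeros(shape)
    pf[F] = p
    return FlowField(u, v, w, pf, t, domain)


@pytest.fixture(scope="module")
def small_tube():
    import warnings
    geom = build_aorta(AortaSpec.straight_tube(16.0, 32.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return voxelize(geom, 2.0)


class TestWallShearStress:
    def test_zero_flow_gives_zero_stress(self, small_tube):
        wss = wall_shear_stress(make_field(small_tube), small_tube)
        assert np.all(wss.tau == 0.0)
        assert len(wss) > 0

    def test_poiseuille_wall_shear_matches_analytic(self, tube_run, tube_domain):
        """τ_w = 4μQ/(πR³) for developed laminar tube flow, within 15%."""
        wss = wall_shear_stress(tube_run.field, tube_domain)
        centers = tube_domain.cell_centers(wss.cells)
        mid = (centers[:, 2] > 20.0) & (centers[:, 2] < 40.0)
        tau_mean = wss.tau[mid].mean()
        analytic = 4 * 0.004 * TUBE_Q_ML_S * 1e-6 / (np.pi * 0.008 ** 3)
        assert tau_mean == pytest.approx(analytic, rel=0.15)

    def test_stress_scales_linearly_with_flow_in_stokes_regime(self, small_tube):
        """At creeping-flow Reynolds number, doubling Q doubles every WSS."""
        from aortohemo.solver import SolverControls, simulate_case
        from aortohemo.synthetic_cohort import ConstantWaveform
        from conftest import TUBE_PARAMS

        taus = []
        for q in (0.01, 0.02):  # ml/s → Re ≈ 0.3
            controls = SolverControls(n_cycles=1, dt=2e-3, steady_tol=1e-9,
                                      min_time=0.15, inlet_profile="parabolic")
            res = simulate_case(small_tube, ConstantWaveform(q, 0.1),
                                {"DAo": TUBE_PARAMS}, controls=controls)
            taus.append(wall_shear_stress(res.field, small_tube).tau)
        nz = taus[0] > 1e-12
        ratio = taus[1][nz] / taus[0][nz]
        np.testing.assert_allclose(ratio, 2.0, rtol=0.02)

    def test_every_wall_face_appears_once(self, small_tube):
        wss = wall_shear_stress(make_field(small_tube), small_tube)
        keys = set(map(tuple, np.c_[wss.cells, wss.axis, wss.side]))
        assert len(keys) == len(wss)


class TestExtrema:
    def test_constructed_maximum_face_is_returned(self, small_tube):
        field = make_field(small_tube, fill_w=0.1)
        wss = wall_shear_stress(field, small_tube)
        # plant a known extremum away from the caps
        centers = small_tube.cell_centers(wss.cells)
        interior = (centers[:, 2] > 14) & (centers[:, 2] < 18)
        i_target = int(np.nonzero(interior)[0][0])
        wss.tau[i_target] = wss.tau.max() * 10 + 1.0
        out = pswss_extrema(wss, small_tube)
        assert out["max_tau_Pa"] == pytest.approx(wss.tau[i_target])
        assert out["max_region"] == wss.region[i_target]

    def test_extrema_invariant_under_face_permutation(self, small_tube):
        field = make_field(small_tube, fill_w=0.1)
        wss = wall_shear_stress(field, small_tube)
        rng = np.random.default_rng(0)
        wss.tau = wss.tau + rng.uniform(0, 1, len(wss))
        ref = pswss_extrema(wss, small_tube)
        perm = rng.permutation(len(wss))
        for name in ("cells", "axis", "side", "tau", "region", "quadrant"):
            setattr(wss, name, getattr(wss, name)[perm])
        out = pswss_extrema(wss, small_tube)
        assert out == ref

    def test_empty_map_rejected(self, small_tube):
        wss = wall_shear_stress(make_field(small_tube), small_tube)
        for name in ("cells", "axis", "side", "tau", "region", "quadrant"):
            setattr(wss, name, getattr(wss, name)[:0])
        with pytest.raises(ValueError):
            pswss_extrema(wss, small_tube)


class TestProbes:
    def test_uniform_pressure_converts_exactly_to_mmhg(self, small_tube):
        field = make_field(small_tube, p=100.0 * MMHG_TO_PA)
        res = extract_probes([field], small_tube.geom, small_tube)
        assert res.psp_mmHg == pytest.approx(100.0, abs=1e-12)

    def test_poiseuille_psv_reads_twice_mean_velocity(self, tube_run, tube_domain):
        res = extract_probes([tube_run.field], tube_domain.geom, tube_domain)
        mean_v = TUBE_Q_ML_S * 1e-6 / (np.pi * 0.008 ** 2)  # m/s
        assert res.psv_cm_s == pytest.approx(2.0 * mean_v * 100.0, rel=0.05)

    def test_peak_times_track_the_series(self, small_tube):
        fields = [make_field(small_tube, fill_w=w, p=pp, t=t)
                  for t, w, pp in [(0.0, 0.1, 10.0), (0.1, 0.5, 40.0), (0.2, 0.2, 20.0)]]
        res = extract_probes(fields, small_tube.geom, small_tube)
        assert res.psv_time_s == 0.1 and res.psp_time_s == 0.1
        shifted = [FlowField(f.u, f.v, f.w, f.p, f.t + 0.3, f.domain) for f in fields]
        res2 = extract_probes(shifted, small_tube.geom, small_tube)
        assert res2.psv_time_s == pytest.approx(0.4)

    def test_empty_series_rejected(self, small_tube):
        with pytest.raises(ValueError):
            extract_probes([], small_tube.geom, small_tube)


class TestStreamlinesAndLNH:
    def test_uniform_flow_has_zero_helicity_and_straight_lines(self, small_tube):
        field = make_field(small_tube, fill_w=0.5)
        center = np.array([0.0, 0.0, 6.0])
        hel = streamlines_and_lnh(field, center[None])
        finite = np.isfinite(hel.lnh)
        assert np.all(np.abs(hel.lnh[finite]) < 1e-9)
        line = hel.streamlines[0]
        assert len(line) > 5
        # straight: x and y stay put
        np.testing.assert_allclose(line[:, 0], center[0], atol=1e-6)
        np.testing.assert_allclose(line[:, 1], center[1], atol=1e-6)

    def test_solid_body_rotation_plus_axial_flow_is_helical(self, small_tube):
        """u = (−yΩ, xΩ, w): ω = (0,0,2Ω) so LNH → sign(Ω·w) near the axis."""
        dom = small_tube
        omega, w_ax = 30.0, 0.5
        shape = dom.shape
        u = np.zeros((shape[0] + 1, shape[1], shape[2]))
        v = np.zeros((shape[0], shape[1] + 1, shape[2]))
        w = np.full((shape[0], shape[1], shape[2] + 1), w_ax)

        def face_xy(axis):
            # physical coordinates of face centers for that velocity component
            idx = np.indices((shape[0] + (axis == 0), shape[1] + (axis == 1),
                              shape[2] + (axis == 2))).astype(float)
            off = np.array([0.5, 0.5, 0.5])
            off[axis] = 0.0
            x = dom.origin[0] + (idx[0] + off[0]) * dom.h
            y = dom.origin[1] + (idx[1] + off[1]) * dom.h
            return x, y

        xu, yu = face_xy(0)
        u[:] = -yu * omega * 1e-3  # mm → m
        xv, yv = face_xy(1)
        v[:] = xv * omega * 1e-3
        field = FlowField(u, v, w, np.zeros(shape), 0.0, dom)
        hel = streamlines_and_lnh(field, np.array([[0.0, 0.0, 16.0]]))
        # near-axis fluid cells
        cells = np.argwhere(dom.fluid)
        pts = dom.cell_centers(cells)
        near = (np.linalg.norm(pts[:, :2], axis=1) < 3.0) & (np.abs(pts[:, 2] - 16) < 6)
        vals = hel.lnh[tuple(cells[near].T)]
        assert np.all(vals > 0.9)  # sign(Ω·w) = +1 and nearly pure helix on-axis

    def test_seed_outside_fluid_warns_and_skips(self, small_tube):
        field = make_field(small_tube, fill_w=0.5)
        with pytest.warns(UserWarning, match="outside the fluid"):
            hel = streamlines_and_lnh(field, np.array([[50.0, 50.0, 50.0]]))
        assert hel.streamlines == []


class TestAortaLocalization:
    """Qualitative flow-feature checks on the pulsatile cohort-mean aorta."""

    def test_helicity_stronger_in_arch_than_descending(self, aorta_run, aorta_domain):
        field = aorta_run.peak_field
        hel = streamlines_and_lnh(field, np.zeros((0, 3)))
        cells = np.argwhere(aorta_domain.fluid)
        pts = aorta_domain.cell_centers(cells)
        region, _ = aorta_domain.geom.classify_wall_points(pts)
        arch = np.zeros(aorta_domain.shape, bool)
        arch[tuple(cells[region == "arch"].T)] = True
        dao = np.zeros(aorta_domain.shape, bool)
        dao[tuple(cells[region == "dao"].T)] = True
        assert hel.mean_abs_lnh(arch) > hel.mean_abs_lnh(dao)
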