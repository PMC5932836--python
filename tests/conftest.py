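"""Shared fixtures.

The two expensive CFD fixtures (a steady Poiseuille tube and a pulsatile
cohort-mean aorta) are session-scoped: several analytic-limit and
localization tests read different aspects of the same solved fields.
"""

import warnings

import numpy as np
import pytest

from aortohemo import windkessel as wk
from aortohemo.geometry import AortaSpec, build_aorta, voxelize
from aortohemo.solver import SolverControls, simulate_case
from aortohemo.synthetic_cohort import ConstantWaveform, FlowWaveform

TUBE_D_MM = 16.0
TUBE_L_MM = 60.0
TUBE_Q_ML_S = 60.0
TUBE_PARAMS = wk.WindkesselParams(0.02, 0.10, 0.4, "tube")


@pytest.fixture(scope="session")
def tube_domain():
    geom = build_aorta(AortaSpec.straight_tube(TUBE_D_MM, TUBE_L_MM))
    return voxelize(geom, 1.0)  # 16 cells across the diameter


@pytest.fixture(scope="session")
def tube_run(tube_domain):
    """Steady parabolic-inlet tube flow with a Windkessel outlet."""
    wave = ConstantWaveform(TUBE_Q_ML_S, period=0.5)
    controls = SolverControls(n_cycles=1, inlet_profile="parabolic",
                              steady_tol=1e-7, min_time=0.4)
    return simulate_case(tube_domain, wave, {"DAo": TUBE_PARAMS}, controls=controls)


@pytest.fixture(scope="session")
def coarse_tube_domain():
    """Small 8-cells-across tube for cheap solver behavior tests."""
    geom = build_aorta(AortaSpec.straight_tube(16.0, 32.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return voxelize(geom, 2.0)


@pytest.fixture(scope="session")
def aorta_domain():
    geom = build_aorta(AortaSpec.cohort_mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return voxelize(geom, 0.85)


@pytest.fixture(scope="session")
def aorta_run(aorta_domain):
    """Two cardiac cycles on the cohort-mean aorta, four Windkessel outlets.

    The inlet is the cohort-mean waveform: heart rate 110 bpm, peak plug
    velocity 110 cm/s, systolic fraction 0.3.
    """
    T = 60.0 / 110.0
    area_cm2 = np.pi * (0.05 * 19.2) ** 2
    q_peak = 110.0 * area_cm2
    sv = 2.0 * q_peak * 0.3 * T / np.pi
    wave = FlowWaveform(period=T, systolic_time=0.3 * T, stroke_volume=sv)
    geom = aorta_domain.geom
    outlets = {l: wk.default_params(l) for l in geom.outlet_labels}
    controls = SolverControls(n_cycles=2)
    return simulate_case(aorta_domain, wave, outlets, controls=controls)
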