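"""Seeded virtual-patient cohorts for end-to-end pipeline validation.

No patient data ships with a study like this, so the cohort generator
produces virtual cases with the statistical structure of the reference
25-infant cohort: aortic diameters drawn from truncated Gaussians matched to
the reported cohort summary (AscAo 19.2 ± 6.0 mm, AI 12.1 ± 3.5 mm,
DAo 10.9 ± 2.6 mm), pulsatile half-sine inlet waveforms with TTE-like peak
systolic velocities (~70–250 cm/s), and catheter-like peak systolic pressures
(~75–140 mmHg).  "Measured" values are the pipeline's true values plus
additive Gaussian noise, so the agreement statistics can be exercised end to
end with a known ground truth.

Two pipelines can fill a case's true PSV/PSP: the reduced-order
Windkessel-junction model (:func:`run_case_lumped`, milliseconds per case,
used for cohort-scale statistics) and the full 3D solver
(:func:`aortohemo.solver.simulate_case`, used for field quantities).

Each case draws from its own counter-indexed substream of the cohort seed, so
extending a cohort does not reshuffle existing cases.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import windkessel as wk
from .geometry import AortaSpec, build_aorta

__all__ = [
    "FlowWaveform",
    "CohortSpec",
    "VirtualCase",
    "make_inlet_waveform",
    "generate_cohort",
    "run_case_lumped",
    "add_measurement_noise",
    "cohort_measurement_table",
    "save_cohort",
    "load_cohort",
]

#: Ratio of the plane-maximum (TTE-like) velocity to the inlet plug velocity:
#: a partially developed profile between plug (1.0) and Poiseuille (2.0).
PSV_PROFILE_FACTOR = 1.3


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic volumetric inflow: half-sine systole, zero diastolic flow.

    Q(t) = Q_peak · sin(π t / t_sys) for t < t_sys, else 0, with
    Q_peak = π·SV / (2·t_sys) so the integral over one period is the stroke
    volume.  Units: s and ml/s.
    """

    period: float
    systolic_time: float
    stroke_volume: float

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if not (0.0 < self.systolic_time < self.period):
            raise ValueError("systolic_time must be in (0, period)")
        if self.stroke_volume < 0:
            raise ValueError("stroke_volume must be >= 0")

    @property
    def peak_flow(self) -> float:
        """Q_peak, ml/s."""
        return np.pi * self.stroke_volume / (2.0 * self.systolic_time)

    @property
    def peak_time(self) -> float:
        """Instant of peak systole within the cycle, s."""
        return 0.5 * self.systolic_time

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow (cardiac output per cycle / period), ml/s."""
        return self.stroke_volume / self.period

    @property
    def is_constant(self) -> bool:
        return False

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period)
        q = np.where(phase < self.systolic_time,
                     self.peak_flow * np.sin(np.pi * phase / self.systolic_time), 0.0)
        return q if q.ndim else float(q)


@dataclass(frozen=True)
class ConstantWaveform:
    """Steady inflow stand-in with the waveform interface (ml/s)."""

    flow: float
    period: float = 1.0

    @property
    def peak_flow(self) -> float:
        return self.flow

    @property
    def peak_time(self) -> float:
        return 0.0

    @property
    def mean_flow(self) -> float:
        return self.flow

    @property
    def is_constant(self) -> bool:
        return True

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        q = np.full_like(t, self.flow)
        return q if q.ndim else float(q)


def make_inlet_waveform(heart_rate: float, stroke_volume: float,
                        systolic_fraction: float = 0.3) -> FlowWaveform:
    """Half-sine systolic inflow for a given heart rate (bpm) and SV (ml)."""
    if heart_rate <= 0 or stroke_volume < 0:
        raise ValueError("heart_rate must be > 0 and stroke_volume >= 0")
    if not (0.0 < systolic_fraction < 1.0):
        raise ValueError("systolic_fraction must be in (0, 1)")
    T = 60.0 / heart_rate
    return FlowWaveform(period=T, systolic_time=systolic_fraction * T,
                        stroke_volume=stroke_volume)


@dataclass(frozen=True)
class CohortSpec:
    """Virtual-cohort sampling distributions (defaults = study conditions).

    Diameters are independent truncated Gaussians matched to the reference
    cohort summary.  The inlet is parameterized by a TTE-like peak plug
    velocity; stroke volume follows from it and the sampled inlet area, which
    keeps the joint diameter/PSV distribution in the clinically reported
    ranges.  Measurement noise SDs default to the reference limits of
    agreement half-widths divided by 1.96.
    """

    n: int = 25
    seed: int = 0
    ascao_mm: tuple[float, float] = (19.2, 6.0)
    ai_mm: tuple[float, float] = (12.1, 3.5)
    dao_mm: tuple[float, float] = (10.9, 2.6)
    min_diameter_mm: float = 3.0
    heart_rate_bpm: tuple[float, float] = (90.0, 130.0)
    # stroke volume: allometric in aortic size with lognormal flow spread,
    # SV = ref · (d/19.2 mm)^1.5 · exp(N(0, sd)), clamped to an infant range
    stroke_volume_ref_ml: float = 25.0
    stroke_volume_log_sd: float = 0.30
    stroke_volume_bounds_ml: tuple[float, float] = (8.0, 55.0)
    systolic_fraction: float = 0.3
    distal_pressure_mmHg: tuple[float, float] = (60.0, 90.0)
    psv_noise_cm_s: float = 11.6
    psp_noise_mmHg: float = 4.4
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("ascao_mm", "ai_mm", "dao_mm"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if self.psv_noise_cm_s < 0 or self.psp_noise_mmHg < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class VirtualCase:
    """One virtual patient: geometry spec, inlet waveform, true + noisy values."""

    case_id: int
    aorta: AortaSpec
    waveform: FlowWaveform
    distal_pressure_mmHg: float
    psv_true_cm_s: float | None = None
    psp_true_mmHg: float | None = None
    psv_tte_cm_s: float | None = None
    psp_cc_mmHg: float | None = None


def _case_rng(seed: int, case_id: int) -> np.random.Generator:
    """Counter-indexed substream: stable per case under cohort extension."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(case_id,)))


def _trunc_normal(rng, mean, sd, lo, hi=np.inf, max_retries=100) -> float:
    for _ in range(max_retries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError(
        f"could not sample a value in ({lo}, {hi}) from N({mean}, {sd}²) "
        f"in {max_retries} draws")


def _aorta_spec_from_diameters(d_asc: float, d_ai: float, d_dao: float) -> AortaSpec:
    return AortaSpec(
        inlet_diameter=d_asc,
        dao_diameter=d_dao,
        ai_diameter=d_ai,
        branch_diameters={"BA": 0.50 * d_asc, "LCCA": 0.40 * d_asc, "LSA": 0.42 * d_asc},
        arch_radius=0.75 * d_asc,
        ascending_length=1.3 * d_asc,
        descending_length=2.3 * d_asc,
        branch_length=0.9 * d_asc,
    )


def generate_cohort(spec: CohortSpec) -> list[VirtualCase]:
    """Sample a deterministic cohort of buildable virtual cases."""
    cases = []
    for cid in range(spec.n):
        rng = _case_rng(spec.seed, cid)
        # independent truncated-Gaussian marginals; local bulges (AI or DAo
        # slightly exceeding AscAo) are anatomically odd but buildable, so no
        # ordering is enforced and the marginals stay unbiased
        d_asc = _trunc_normal(rng, *spec.ascao_mm, spec.min_diameter_mm,
                              max_retries=spec.max_retries)
        d_ai = _trunc_normal(rng, *spec.ai_mm, spec.min_diameter_mm,
                             max_retries=spec.max_retries)
        d_dao = _trunc_normal(rng, *spec.dao_mm, spec.min_diameter_mm,
                              max_retries=spec.max_retries)
        hr = rng.uniform(*spec.heart_rate_bpm)
        sv = (spec.stroke_volume_ref_ml * (d_asc / 19.2) ** 1.5
              * np.exp(rng.normal(0.0, spec.stroke_volume_log_sd)))
        sv = float(np.clip(sv, *spec.stroke_volume_bounds_ml))
        wave = make_inlet_waveform(hr, sv, spec.systolic_fraction)
        p_distal = rng.uniform(*spec.distal_pressure_mmHg)
        aorta = _aorta_spec_from_diameters(d_asc, d_ai, d_dao)
        cases.append(VirtualCase(cid, aorta, wave, p_distal))
    return cases


def run_case_lumped(case: VirtualCase, n_cycles: int = 6,
                    steps_per_cycle: int = 400) -> VirtualCase:
    """Fill true PSV/PSP from the reduced-order Windkessel-junction model.

    The aorta is treated as a lossless junction feeding the four outlets:
    each backward-Euler step the common junction pressure P and the per-outlet
    flows Q_k solve the linear system {P = a_k Q_k + b_k, Σ Q_k = Q_in},
    where a_k, b_k are the outlet's discrete Windkessel coefficients.  PSP is
    the last-cycle maximum of P plus the case's distal reference pressure;
    PSV is the TTE-like plane maximum, PSV_PROFILE_FACTOR × the peak inlet
    plug velocity.
    """
    wave = case.waveform
    geom = build_aorta(case.aorta)
    labels = geom.outlet_labels
    params = {l: wk.default_params(l) for l in labels}
    dt = wave.period / steps_per_cycle

    g_tot = sum(1.0 / params[l].total_resistance for l in labels)
    P0 = wave.mean_flow / g_tot
    states = {l: wk.WindkesselState(P=P0, Q=P0 / params[l].total_resistance, t=0.0)
              for l in labels}

    n_steps = n_cycles * steps_per_cycle
    P_trace = np.empty(n_steps)
    for n in range(n_steps):
        t_next = (n + 1) * dt
        Q_in = float(wave(t_next))
        a, b = {}, {}
        for l in labels:
            p = params[l]
            beta = p.R2 * p.C / dt
            a[l] = (p.R1 + p.R2 + p.R1 * beta) / (1.0 + beta)
            b[l] = (-p.R1 * beta * states[l].Q + beta * states[l].P) / (1.0 + beta)
        P = (Q_in + sum(b[l] / a[l] for l in labels)) / sum(1.0 / a[l] for l in labels)
        for l in labels:
            Q_l = (P - b[l]) / a[l]
            states[l] = wk.step(params[l], states[l], Q_l, dt)
        P_trace[n] = P

    psp = float(P_trace[-steps_per_cycle:].max()) + case.distal_pressure_mmHg
    area_cm2 = np.pi * (0.05 * case.aorta.inlet_diameter) ** 2
    psv = PSV_PROFILE_FACTOR * wave.peak_flow / area_cm2
    case.psv_true_cm_s = psv
    case.psp_true_mmHg = psp
    return case


def add_measurement_noise(case: VirtualCase, seed: int,
                          psv_sd_cm_s: float = 11.6,
                          psp_sd_mmHg: float = 4.4) -> VirtualCase:
    """Draw the noisy 'TTE' PSV and 'catheter' PSP for a case (seeded once)."""
    if case.psv_true_cm_s is None or case.psp_true_mmHg is None:
        raise ValueError("case has no true PSV/PSP; run a pipeline first")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(case.case_id, 1)))
    case.psv_tte_cm_s = case.psv_true_cm_s + rng.normal(0.0, psv_sd_cm_s)
    case.psp_cc_mmHg = case.psp_true_mmHg + rng.normal(0.0, psp_sd_mmHg)
    return case


def run_cohort(spec: CohortSpec) -> list[VirtualCase]:
    """Generate, simulate (reduced-order) and 'measure' a full cohort."""
    cases = generate_cohort(spec)
    for c in cases:
        run_case_lumped(c)
        add_measurement_noise(c, spec.seed, spec.psv_noise_cm_s, spec.psp_noise_mmHg)
    return cases


def cohort_measurement_table(cases: list[VirtualCase]) -> pd.DataFrame:
    """Per-case table mirroring the reference measurement-table layout."""
    return pd.DataFrame({
        "case": [c.case_id for c in cases],
        "psv_tte_cm_s": [c.psv_tte_cm_s for c in cases],
        "psv_cfd_cm_s": [c.psv_true_cm_s for c in cases],
        "psp_cc_mmHg": [c.psp_cc_mmHg for c in cases],
        "psp_cfd_mmHg": [c.psp_true_mmHg for c in cases],
    })


# ---------------------------------------------------------------------------
# serialization


def _plain(obj):
    """Recursively convert tuples to lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _case_to_dict(c: VirtualCase) -> dict:
    return _plain(asdict(c))


def save_cohort(cases: list[VirtualCase], spec: CohortSpec, outdir) -> None:
    """Serialize a cohort as a directory of YAML/CSV files."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "cohort.yaml", "w") as f:
        yaml.safe_dump({"spec": _plain(asdict(spec))}, f)
    for c in cases:
        cdir = out / f"case_{c.case_id:02d}"
        cdir.mkdir(exist_ok=True)
        with open(cdir / "spec.yaml", "w") as f:
            yaml.safe_dump(_case_to_dict(c), f)
        t = np.linspace(0.0, c.waveform.period, 201)
        pd.DataFrame({"t_s": t, "Q_ml_s": c.waveform(t)}).to_csv(
            cdir / "inlet.csv", index=False)
    tbl = cohort_measurement_table(cases)
    tbl.to_csv(out / "measurements.csv", index=False)


def load_cohort(outdir) -> tuple[list[VirtualCase], CohortSpec]:
    """Inverse of :func:`save_cohort` (waveforms rebuilt from parameters)."""
    import pathlib

    out = pathlib.Path(outdir)
    with open(out / "cohort.yaml") as f:
        spec = CohortSpec(**yaml.safe_load(f)["spec"])
    cases = []
    for cdir in sorted(out.glob("case_*")):
        with open(cdir / "spec.yaml") as f:
            d = yaml.safe_load(f)
        aorta = AortaSpec(**d["aorta"])
        wave = FlowWaveform(**d["waveform"])
        cases.append(VirtualCase(
            case_id=d["case_id"], aorta=aorta, waveform=wave,
            distal_pressure_mmHg=d["distal_pressure_mmHg"],
            psv_true_cm_s=d["psv_true_cm_s"], psp_true_mmHg=d["psp_true_mmHg"],
            psv_tte_cm_s=d["psv_tte_cm_s"], psp_cc_mmHg=d["psp_cc_mmHg"]))
    return cases, spec
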