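"""Three-element Windkessel (lumped-parameter) outlet model.

Each aortic outlet (brachiocephalic artery BA, left common carotid LCCA, left
subclavian LSA, descending aorta DAo) is terminated by an RCR circuit: a
characteristic resistance ``R1`` in series with the parallel combination of a
peripheral resistance ``R2`` and a compliance ``C``.  Pressure and flow at the
outlet are related by the first-order ODE

    P = (R1 + R2) Q − R2 C dP/dt + R1 R2 C dQ/dt

which this module integrates with a backward-Euler update.  With
``beta = R2 C / dt`` the discrete update is

    P[n+1] = ((R1 + R2 + R1*beta) Q[n+1] − R1*beta Q[n] + beta P[n]) / (1 + beta)

Native units are clinical: pressure in mmHg, flow in ml/s, so the published
parameter sets can be used verbatim; conversion to SI happens only at the 3D
solver coupling boundary (see :mod:`aortohemo.units`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_cohort import FlowWaveform

__all__ = [
    "WindkesselParams",
    "WindkesselState",
    "DEFAULT_OUTLETS",
    "default_params",
    "steady_pressure",
    "step",
    "replay",
    "simulate",
    "read_params",
    "write_params",
    "states_to_frame",
]


@dataclass(frozen=True)
class WindkesselParams:
    """RCR parameter triple for one outlet.

    R1, R2 in mmHg·s/ml; C in ml/mmHg.
    """

    R1: float
    R2: float
    C: float
    label: str = "custom"

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "C"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {getattr(self, name)!r}")

    @property
    def total_resistance(self) -> float:
        """Steady (DC) resistance R1 + R2, mmHg·s/ml."""
        return self.R1 + self.R2

    @property
    def tau(self) -> float:
        """Relaxation time constant R2·C, s."""
        return self.R2 * self.C


@dataclass(frozen=True)
class WindkesselState:
    """Instantaneous outlet state: pressure P (mmHg), flow Q (ml/s), time t (s)."""

    P: float
    Q: float
    t: float = 0.0


#: Published outlet parameter sets for the four aortic outlets
#: (R1, R2 in mmHg·s/ml; C in ml/mmHg).
DEFAULT_OUTLETS: dict[str, WindkesselParams] = {
    "BA": WindkesselParams(0.100, 2.480, 0.466, "BA"),
    "LCCA": WindkesselParams(0.110, 2.510, 0.443, "LCCA"),
    "LSA": WindkesselParams(0.150, 2.624, 0.437, "LSA"),
    "DAo": WindkesselParams(0.120, 2.118, 0.421, "DAo"),
}


def default_params(label: str) -> WindkesselParams:
    """Return the packaged default RCR triple for a named outlet.

    Parameters
    ----------
    label:
        One of ``"BA"``, ``"LCCA"``, ``"LSA"``, ``"DAo"``.
    """
    try:
        return DEFAULT_OUTLETS[label]
    except KeyError:
        valid = ", ".join(sorted(DEFAULT_OUTLETS))
        raise KeyError(f"unknown outlet label {label!r}; valid labels: {{{valid}}}") from None


def steady_pressure(params: WindkesselParams, Q: float) -> float:
    """Steady-state pressure (mmHg) for constant flow Q (ml/s): (R1+R2)·Q."""
    if not np.isfinite(Q):
        raise ValueError(f"Q must be finite, got {Q!r}")
    return params.total_resistance * Q


def step(
    params: WindkesselParams,
    state: WindkesselState,
    Q_next: float,
    dt: float,
) -> WindkesselState:
    """Advance the outlet ODE one backward-Euler step of size dt (s).

    Returns the state at ``state.t + dt`` with the new pressure and
    ``Q = Q_next``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    beta = params.R2 * params.C / dt
    P_next = (
        (params.R1 + params.R2 + params.R1 * beta) * Q_next
        - params.R1 * beta * state.Q
        + beta * state.P
    ) / (1.0 + beta)
    return WindkesselState(P=P_next, Q=Q_next, t=state.t + dt)


def replay(
    params: WindkesselParams,
    Q: np.ndarray,
    dt: float,
    P0: float,
    t0: float = 0.0,
) -> np.ndarray:
    """Integrate the outlet ODE over a recorded flow trace.

    ``Q[0]`` is the flow at the initial instant (pressure ``P0``); one
    backward-Euler step is taken per subsequent sample.  Returns the pressure
    trace (mmHg) aligned with ``Q``.  This is the exact discrete map the 3D
    solver applies when coupling an outlet, so a solver run can be audited
    offline from its recorded flux trace.
    """
    Q = np.asarray(Q, dtype=float)
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    P = np.empty_like(Q)
    P[0] = P0
    st = WindkesselState(P=P0, Q=float(Q[0]), t=t0)
    for n in range(1, len(Q)):
        st = step(params, st, float(Q[n]), dt)
        P[n] = st.P
    return P


def write_params(path, params: dict[str, WindkesselParams]) -> None:
    """Write outlet parameter sets as a YAML block keyed by outlet label."""
    import yaml

    payload = {label: {"R1": p.R1, "R2": p.R2, "C": p.C}
               for label, p in params.items()}
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=True)


def read_params(path) -> dict[str, WindkesselParams]:
    """Inverse of :func:`write_params`; values are validated on load."""
    import yaml

    with open(path) as f:
        payload = yaml.safe_load(f)
    return {label: WindkesselParams(label=label, **triple)
            for label, triple in payload.items()}


def states_to_frame(states: list[WindkesselState]):
    """Pressure trace as a DataFrame with columns t_s, Q_ml_s, P_mmHg."""
    import pandas as pd

    return pd.DataFrame({
        "t_s": [s.t for s in states],
        "Q_ml_s": [s.Q for s in states],
        "P_mmHg": [s.P for s in states],
    })


def simulate(
    params: WindkesselParams,
    waveform: "FlowWaveform",
    dt: float,
    n_cycles: int = 1,
    P0: float | None = None,
) -> list[WindkesselState]:
    """Integrate the outlet ODE against a periodic inflow waveform.

    Samples the waveform every ``dt`` over ``n_cycles`` periods.  ``P0``
    defaults to the steady pressure at the cycle-mean flow, which removes most
    of the start-up transient.
    """
    T = waveform.period
    if dt >= T:
        raise ValueError(f"dt={dt!r} must be smaller than the waveform period T={T!r}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    n_steps = int(round(n_cycles * T / dt))
    t = np.arange(n_steps + 1) * dt
    Q = waveform(t)
    if P0 is None:
        P0 = steady_pressure(params, waveform.mean_flow)
    P = replay(params, Q, dt, P0)
    return [WindkesselState(P=float(p), Q=float(q), t=float(tt)) for p, q, tt in zip(P, Q, t)]
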