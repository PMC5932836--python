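"""Unit conversion constants.

Clinical hemodynamics mixes unit systems: lumped outlet models and catheter
readings live in mmHg and ml/s, TTE velocities in cm/s, while the flow solver
works in SI (Pa, m/s, m). All conversions in the package go through the
constants defined here.
"""

MMHG_TO_PA = 133.322
"""1 mmHg in Pa."""

PA_TO_MMHG = 1.0 / MMHG_TO_PA

ML_S_TO_M3_S = 1e-6
"""1 ml/s in m^3/s."""

M3_S_TO_ML_S = 1e6

CM_S_TO_M_S = 0.01
M_S_TO_CM_S = 100.0

MM_TO_M = 1e-3
M_TO_MM = 1e3
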