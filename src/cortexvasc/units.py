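"""Unit conventions and conversions.

All internal quantities are CGS: lengths in cm, areas in cm^2, pressures in
dyn/cm^2, flows in cm^3/s, viscosity in poise, time in s.  Clinical units
(mmHg, ml/min, micrometres) appear only at I/O boundaries.
"""

MMHG = 1333.22  # dyn/cm^2 per mmHg
ML_PER_MIN = 1.0 / 60.0  # cm^3/s per ml/min
UM = 1.0e-4  # cm per micrometre


def mmhg_to_cgs(p_mmhg):
    return p_mmhg * MMHG


def cgs_to_mmhg(p_dyn_cm2):
    return p_dyn_cm2 / MMHG


def mlmin_to_cgs(q_ml_min):
    return q_ml_min * ML_PER_MIN


def cgs_to_mlmin(q_cm3_s):
    return q_cm3_s / ML_PER_MIN


def um_to_cm(r_um):
    return r_um * UM


def cm_to_um(r_cm):
    return r_cm / UM
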