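"""Physical constants and unit-conversion factors.

Internal unit conventions:

========================  =========================
quantity                  unit
========================  =========================
distance                  angstrom (A)
energy                    kJ/mol
time (trajectories)       ns
time (pull records)       ps
pulling velocity          m/s
friction (molar)          kg mol^-1 s^-1
temperature               K
========================  =========================

Conversions are applied exactly once, at the I/O boundary.
"""

#: molar gas constant, kJ mol^-1 K^-1
R_KJ_MOL_K = 8.31446261815324e-3

#: calorie in joules (thermochemical)
CAL_TO_J = 4.184

ANGSTROM_PER_NM = 10.0
NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_METER = 1.0e10
METER_PER_ANGSTROM = 1.0e-10
PS_PER_NS = 1000.0
NS_PER_PS = 1.0e-3
PS_PER_S = 1.0e12

#: 1 m/s expressed in A/ps
M_PER_S_TO_A_PER_PS = ANGSTROM_PER_METER / PS_PER_S  # = 0.01

#: 1 kg mol^-1 s^-1 = 1 J mol^-1 s m^-2 -> kJ mol^-1 ps A^-2
#: (1e-3 kJ/J) * (1e12 ps/s)^... ; s m^-2 -> ps A^-2 is 1e12 ps / 1e20 A^2
KG_MOL_S_TO_KJ_MOL_PS_A2 = 1.0e-3 * PS_PER_S / ANGSTROM_PER_METER**2  # = 1e-11

#: inverse of the above
KJ_MOL_PS_A2_TO_KG_MOL_S = 1.0 / KG_MOL_S_TO_KJ_MOL_PS_A2

#: 1 kJ mol^-1 s m^-2 = 1e3 J mol^-1 s m^-2 = 1e3 kg mol^-1 s^-1
KJ_MOL_S_M2_TO_KG_MOL_S = 1.0e3


def kT(temperature: float) -> float:
    """Thermal energy k_B*T per mole, kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_MOL_K * temperature
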