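"""Physical constants and unit-conversion factors (CODATA 2018).

All internal quantities in this package use a single unit system:

    energy      kcal mol^-1          (thermochemical calorie, 1 cal = 4.184 J)
    length      angstrom
    mass        amu
    time        fs

Conversions happen only at boundaries (I/O, user-facing spring constants,
spectroscopy output).
"""

from __future__ import annotations

# --- CODATA 2018 base constants (SI) ---
N_A = 6.02214076e23          # mol^-1 (exact, 2019 SI)
HARTREE_J = 4.3597447222071e-18   # J
EV_J = 1.602176634e-19       # J (exact)
BOHR_M = 0.529177210903e-10  # m
AMU_KG = 1.66053906660e-27   # kg
KB_J = 1.380649e-23          # J K^-1 (exact)
C_M_S = 2.99792458e8         # m s^-1 (exact)
CAL_J = 4.184                # J (thermochemical calorie, exact by definition)

# --- derived, in internal units ---
HARTREE_TO_KCALMOL = HARTREE_J * N_A / (CAL_J * 1000.0)   # 627.5094740631...
EV_TO_KCALMOL = EV_J * N_A / (CAL_J * 1000.0)             # 23.060547830...
BOHR_TO_ANGSTROM = BOHR_M * 1e10                          # 0.529177210903
KB_KCALMOL = KB_J * N_A / (CAL_J * 1000.0)                # 0.0019872042... kcal mol^-1 K^-1

# Acceleration conversion: force [kcal mol^-1 A^-1] / mass [amu] -> [A fs^-2].
# a = F * 4184 J/kcal / (N_A * amu_kg) per metre ... collapsed to one factor.
FORCE_PER_AMU_TO_ACC = CAL_J * 1000.0 * 1e-30 * 1e10 / (N_A * AMU_KG) * 1e10
# sanity: = 4184e-30*1e20/(N_A*AMU_KG) = 4.18399999...e-4

# Mass-weighted Hessian eigenvalue [kcal mol^-1 A^-2 amu^-1] -> angular
# frequency squared [fs^-2]; identical factor by dimensional analysis.
MW_EIGVAL_TO_OMEGA_SQ = FORCE_PER_AMU_TO_ACC

C_CM_FS = C_M_S * 100.0 * 1e-15   # speed of light in cm fs^-1 (2.99792458e-5)

# Isotopically averaged atomic masses, amu (IUPAC 2021 standard weights).
ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.002602,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "S": 32.06,
    "Cl": 35.45,
}

# Covalent radii (angstrom), Cordero et al. consensus values; used only for
# fallback bond detection in the MD stability check.
COVALENT_RADII = {
    "H": 0.31,
    "He": 0.28,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "S": 1.05,
    "Cl": 1.02,
}
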