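"""Physical constants and unit conversions used package-wide.

Internal units are Angstrom, femtosecond and elementary charge; SI enters
only inside the spectral normalization (susceptibility prefactors).
"""

import math

# SI
SPEED_OF_LIGHT_CM_S = 2.99792458e10  # cm/s
BOLTZMANN_J_K = 1.380649e-23  # J/K
VACUUM_PERMITTIVITY = 8.8541878128e-12  # C^2 / (J m)
ELEMENTARY_CHARGE_C = 1.602176634e-19  # C
ATOMIC_MASS_KG = 1.66053906660e-27  # kg

# derived, in internal units
SPEED_OF_LIGHT_CM_FS = SPEED_OF_LIGHT_CM_S * 1e-15  # cm/fs = 2.9979e-5
#: k_B in u A^2 / fs^2 / K  (1 u A^2/fs^2 = 1.66054e-17 J)
BOLTZMANN_U_A2_FS2 = BOLTZMANN_J_K / (ATOMIC_MASS_KG * 1e-20 / 1e-30)

# pseudopotential core charges used for dipole assembly (valence charges of
# the dual-space pseudopotentials; Wannier centers are doubly occupied).
DEFAULT_CHARGE_MAP = {"H": 1.0, "O": 6.0, "Cl": 7.0, "X": -2.0}

KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca X D".split()
)


def kT_u_A2_fs2(temperature: float) -> float:
    """Thermal energy k_B*T in u A^2 / fs^2."""
    return BOLTZMANN_U_A2_FS2 * temperature


def wavenumber_from_time(tau_fs: float) -> float:
    """Convert a period tau (fs) to a wavenumber 1/(c*tau) in cm^-1."""
    if tau_fs <= 0:
        raise ValueError(f"period must be positive, got {tau_fs}")
    return 1.0 / (SPEED_OF_LIGHT_CM_FS * tau_fs)


def time_from_wavenumber(nu_cm: float) -> float:
    """Convert a wavenumber (cm^-1) to the corresponding period in fs."""
    if nu_cm <= 0:
        raise ValueError(f"wavenumber must be positive, got {nu_cm}")
    return 1.0 / (SPEED_OF_LIGHT_CM_FS * nu_cm)


def transfer_path_wavenumber(tau_tp_fs: float) -> float:
    """Spectral peak position predicted from a mean transfer-path time.

    A proton crossing a barrier in time tau_TP completes half an oscillation
    period, so the associated band sits at f_TP = 1/(2*tau_TP), i.e. at
    1/(2*c*tau_TP) in cm^-1.
    """
    if tau_tp_fs <= 0:
        raise ValueError(f"transfer-path time must be positive, got {tau_tp_fs}")
    return 1.0 / (2.0 * SPEED_OF_LIGHT_CM_FS * tau_tp_fs)


def angular_frequency_rad_fs(nu_cm: float) -> float:
    """Angular frequency (rad/fs) of a wavenumber in cm^-1."""
    return 2.0 * math.pi * SPEED_OF_LIGHT_CM_FS * nu_cm
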