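"""Unit conventions and physical constants.

Internal units throughout the package: length nm, time ps, temperature K,
energy kJ mol^-1.  Moduli are therefore carried internally as

* area compressibility   kJ mol^-1 nm^-2
* bending / Gaussian     kJ mol^-1
* stress (pressure)      kJ mol^-1 nm^-3

and converted to SI (J m^-2) or k_B T only at reporting boundaries.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (molar gas constant / 1000).
KB = 0.0083145

#: 1 kJ mol^-1 in joules (1000 / Avogadro).
KJ_PER_MOL_IN_J = 1.66054e-21

#: 1 kJ mol^-1 nm^-2 expressed in J m^-2.
KJ_PER_MOL_NM2_IN_J_M2 = KJ_PER_MOL_IN_J / 1e-18  # = 1.66054e-3

#: 1 nm^2 ps^-1 expressed in cm^2 s^-1.
NM2_PER_PS_IN_CM2_PER_S = 1e-2


def ka_to_si(ka_internal: float) -> float:
    """kJ mol^-1 nm^-2  ->  J m^-2."""
    return ka_internal * KJ_PER_MOL_NM2_IN_J_M2


def ka_from_si(ka_si: float) -> float:
    """J m^-2  ->  kJ mol^-1 nm^-2."""
    return ka_si / KJ_PER_MOL_NM2_IN_J_M2


def energy_in_kbt(e_kj_mol: float, temperature: float) -> float:
    """kJ mol^-1  ->  multiples of k_B T at the given temperature (K)."""
    return e_kj_mol / (KB * temperature)


def diffusion_to_cm2_s(d_nm2_ps: float) -> float:
    """nm^2 ps^-1  ->  cm^2 s^-1."""
    return d_nm2_ps * NM2_PER_PS_IN_CM2_PER_S


def diffusion_from_cm2_s(d_cm2_s: float) -> float:
    """cm^2 s^-1  ->  nm^2 ps^-1."""
    return d_cm2_s / NM2_PER_PS_IN_CM2_PER_S


def percent_deviation(value: float, reference: float) -> float:
    """Percent relative deviation of ``value`` from ``reference``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * abs(value - reference) / abs(reference)
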