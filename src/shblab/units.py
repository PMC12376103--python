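"""Unit conventions used throughout the package.

Lengths are in angstrom (A), energies in eV, masses in amu, times in fs,
temperatures in K.  Under these conventions one amu*A^2/fs^2 equals
103.6427 eV, which enters the ring-polymer spring constants.
"""

KB_EV_PER_K = 8.617333262e-5
"""Boltzmann constant, eV/K."""

HBAR_EV_FS = 0.6582119569
"""Reduced Planck constant, eV*fs."""

AMU_TO_EV_FS2_PER_A2 = 103.6427
"""Conversion: 1 amu = 103.6427 eV*fs^2/A^2."""


def kT(temperature_K: float) -> float:
    """Thermal energy k_B*T in eV."""
    return KB_EV_PER_K * temperature_K
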