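"""Physical constants (CODATA 2018 via scipy) and derived EPR quantities."""

from scipy import constants as _c

#: Planck constant, J s
PLANCK = _c.h
#: Bohr magneton, J/T
BOHR_MAGNETON = _c.physical_constants["Bohr magneton"][0]
#: free-electron g-factor (magnitude)
G_ELECTRON = -_c.physical_constants["electron g factor"][0]

#: gyromagnetic ratios, MHz/T (deuteron from its magnetic moment, nu/B =
#: mu_d/(I h) with I = 1: 6.536 MHz/T)
GAMMA_MHZ_PER_T = {
    "1H": _c.physical_constants["proton gyromag. ratio in MHz/T"][0],
    "2H": _c.physical_constants["deuteron mag. mom."][0] / (1.0 * PLANCK) / 1e6,
}

#: electron-electron dipolar constant nu_perp * r^3 for two free-electron
#: spins, in MHz nm^3:  mu0/(4 pi) * g^2 mu_B^2 / h  ~= 52.04
DIPOLAR_MHZ_NM3 = (
    _c.mu_0 / (4.0 * _c.pi) * (G_ELECTRON * BOHR_MAGNETON) ** 2 / PLANCK * 1e27 / 1e6
)


def magnetic_field_tesla(spectrometer_freq_ghz: float, g_value: float) -> float:
    """Resonance field B = h nu / (g mu_B) for an electron at the given
    microwave frequency and g-value."""
    if spectrometer_freq_ghz <= 0:
        raise ValueError("spectrometer frequency must be positive")
    if g_value <= 0:
        raise ValueError("g-value must be positive")
    return PLANCK * spectrometer_freq_ghz * 1e9 / (g_value * BOHR_MAGNETON)
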