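"""Physical constants and unit conversions.

Internal unit convention: energies in meV, momentum transfer Q in 1/Å,
translational diffusion coefficients in Å²/ps, residence times in ps.
Linewidths quoted in meV are related to rates in 1/ps through ħ.
"""

#: Reduced Planck constant, meV·ps (CODATA: 6.582119569e-16 eV·s).
HBAR_MEV_PS: float = 0.6582119569

#: One unit of the conventional diffusion-coefficient scale 1e-5 cm²/s,
#: expressed in Å²/ps:  1e-5 cm²/s = 1e11 Å²/s = 0.1 Å²/ps.
A2_PER_PS_PER_1E5_CM2_S: float = 0.1

#: Conversion between a Gaussian FWHM and its standard deviation.
FWHM_TO_SIGMA: float = 1.0 / 2.3548200450309493


def d_to_reported_scale(d_a2_ps: float) -> float:
    """Convert a diffusion coefficient from Å²/ps to the 1e-5 cm²/s scale."""
    return d_a2_ps / A2_PER_PS_PER_1E5_CM2_S


def d_from_reported_scale(d_1e5_cm2_s: float) -> float:
    """Convert a diffusion coefficient from the 1e-5 cm²/s scale to Å²/ps."""
    return d_1e5_cm2_s * A2_PER_PS_PER_1E5_CM2_S
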