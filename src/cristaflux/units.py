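"""Unit system and physical constants.

Canonical units throughout the package: length in μm, time in ms,
concentration in mM, electrical potential in mV, temperature in K.
Membrane flux densities are molecules·ms⁻¹·μm⁻².

1 mM corresponds to 602,214 molecules per μm³ (Avogadro's number scaled
to these units), so volumetric rates in mM/ms convert to molecules/ms/μm³
by multiplying with :data:`MOLECULES_PER_UM3_PER_MM`.
"""

from __future__ import annotations

#: Faraday constant, C/mol.
FARADAY = 96485.33212

#: Molar gas constant, J/(mol·K).
GAS_CONSTANT = 8.31446

#: Molecules per μm³ in a 1 mM solution.
MOLECULES_PER_UM3_PER_MM = 602_214.0


def thermal_voltage_mv(temperature_k: float) -> float:
    """RT/F in millivolts at the given temperature (≈26.71 mV at 310 K)."""
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY


def convert_cell_rate_to_area_flux(
    rate_mm_per_s_per_liter_cells: float,
    mito_vol_frac: float,
    sv_ratio: float,
) -> float:
    """Convert a whole-cell ATP production rate to an inner-membrane flux density.

    Parameters
    ----------
    rate_mm_per_s_per_liter_cells:
        Production rate in mM ATP per second per liter of cells.
    mito_vol_frac:
        Fraction of cell volume occupied by mitochondria (dimensionless).
    sv_ratio:
        Inner-membrane surface-to-volume ratio of the mitochondria, μm²/μm³.

    Returns
    -------
    float
        Flux density in molecules·ms⁻¹·μm⁻² of inner membrane.

    Notes
    -----
    The chain is: per liter of cells → per liter of mitochondria (divide by
    the volume fraction), mM/s → molecules/μm³/ms (Avogadro scaling and
    s → ms), then per μm³ of mitochondria → per μm² of membrane (divide by
    the surface-to-volume ratio). A textbook resting cardiomyocyte rate of
    1.3 mM/s per liter of cells with 30% mitochondrial volume and
    37 μm²/μm³ gives ≈70 molecules·ms⁻¹·μm⁻².
    """
    if rate_mm_per_s_per_liter_cells < 0:
        raise ValueError("rate must be >= 0")
    if mito_vol_frac <= 0 or sv_ratio <= 0:
        raise ValueError("mito_vol_frac and sv_ratio must be > 0")
    rate_mito = rate_mm_per_s_per_liter_cells / mito_vol_frac  # mM/s in mito volume
    rate_molecules = rate_mito * MOLECULES_PER_UM3_PER_MM / 1000.0  # molecules/μm³/ms
    return rate_molecules / sv_ratio
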