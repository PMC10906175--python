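"""Unit conversions.

The solver works in a consistent mm–MPa–tonne–s system: lengths in mm,
stresses in MPa (= N/mm^2), density in tonne/mm^3, time in s.  Energies then
come out in mJ (1 MPa * 1 mm^3 = 1 N*mm = 1 mJ), which is the unit used for
strain-energy traces.  Pressures at the user boundary are in mmHg.
"""

from __future__ import annotations

#: kPa per mmHg, from the definition 760 mmHg = 101.325 kPa.
KPA_PER_MMHG = 101.325 / 760.0

#: Conversion from kg/m^3 to tonne/mm^3 (the solver's density unit).
TONNE_PER_MM3_PER_KG_M3 = 1.0e-12


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to kPa."""
    return p_mmhg * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa: float) -> float:
    """Convert a pressure from kPa to mmHg."""
    return p_kpa / KPA_PER_MMHG


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * KPA_PER_MMHG * 1e3


def mmhg_to_mpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to MPa (solver stress unit)."""
    return p_mmhg * KPA_PER_MMHG * 1e-3


def density_si_to_solver(rho_kg_m3: float) -> float:
    """Convert a density from kg/m^3 to tonne/mm^3."""
    return rho_kg_m3 * TONNE_PER_MM3_PER_KG_M3
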