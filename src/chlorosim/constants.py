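"""Physical constants and default model parameters.

Unit conventions used package-wide: distances in Å, energies in eV,
transition dipoles in Debye.  The dipole–dipole coupling prefactor
``COULOMB_EV_A3_D2`` is 1/(4πε₀) expressed in eV·Å³/D²; it is derived once
from CODATA values and never exposed as a tunable parameter, so couplings
reported in eV, meV and cm⁻¹ are mutually consistent everywhere.
"""

from dataclasses import dataclass

import scipy.constants as _codata

#: 1 Debye in C·m.
DEBYE_SI: float = 1e-21 / _codata.c

#: 1/(4πε₀) · D²/Å³ in eV — the point-dipole coupling prefactor.
COULOMB_EV_A3_D2: float = DEBYE_SI**2 / (
    4.0 * _codata.pi * _codata.epsilon_0 * 1e-30 * _codata.e
)

#: hc in eV·nm (photon energy E = HC_EV_NM / λ).
HC_EV_NM: float = _codata.h * _codata.c / _codata.e * 1e9

#: cm⁻¹ per eV.
EV_TO_WAVENUMBER: float = _codata.e / (_codata.h * _codata.c * 100.0)


@dataclass(frozen=True)
class UnitConstants:
    """Frozen CODATA-derived conversion factors."""

    hc: float = HC_EV_NM
    eV_to_wavenumber: float = EV_TO_WAVENUMBER


UNITS = UnitConstants()

# --- Default physical parameters of the Zn-chlorin aggregate model -------

#: Qy transition dipole of the Zn-chlorin monomer in vacuum, Debye.
VACUUM_DIPOLE_D: float = 5.00
#: Qy transition dipole with implicit THF–hexane solvent, Debye.
SOLVENT_DIPOLE_D: float = 6.18
#: Average monomer site energy in the aggregate, eV (628 nm).
MEAN_SITE_ENERGY_EV: float = 1.973
#: Inhomogeneous Gaussian broadening width σ, eV.
GAUSSIAN_SIGMA_EV: float = 0.0248
#: Solvent screening parameters for a medium with ε ≈ 2 (1% THF–hexane).
SCREENING_A: float = 2.68
SCREENING_BETA: float = 0.27  # per Å
SCREENING_F0: float = 0.54
#: Coupling truncation threshold used to size finite aggregates, eV.
COUPLING_TRUNCATION_EV: float = 0.14e-3
#: Calibration anchor: nearest stacking-direction coupling, eV.
NEAREST_STACK_COUPLING_EV: float = -0.080
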