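"""Frenkel exciton Hamiltonian: assembly, diagonalization, eigenstate
transition dipoles.

Only the one-exciton manifold is represented: with no wave-function
overlap between pigments, the excited manifold of an N-site aggregate is
spanned by the N states in which exactly one pigment is excited, and the
Hamiltonian restricted to it is the N×N matrix with site energies on the
diagonal and pairwise couplings off the diagonal.  Eigenstate e with site
amplitudes C[:, e] carries transition dipole M_e = Σ_m C[m, e]·μ_m; the
dipole strengths |M_e|² weight the stick spectrum.  Because the
coefficient matrix is orthogonal, Σ_e |M_e|² = Σ_m |μ_m|² (sum rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import HC_EV_NM
from .errors import UsageError
from .coupling import CouplingMatrix

__all__ = [
    "ExcitonHamiltonian",
    "ExcitonSolution",
    "assemble_hamiltonian",
    "solve",
    "state_dipoles",
    "eigen_report",
]


@dataclass
class ExcitonHamiltonian:
    """Symmetric N×N one-exciton Hamiltonian in eV."""

    matrix: np.ndarray
    site_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape != (n, n):
            raise UsageError(f"Hamiltonian must be square, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("Hamiltonian has non-finite entries")
        if np.max(np.abs(self.matrix - self.matrix.T), initial=0.0) > 1e-12:
            raise UsageError("Hamiltonian is not symmetric")
        if not self.site_ids:
            self.site_ids = list(range(1, n + 1))

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ExcitonSolution:
    """Eigen-decomposition of an exciton Hamiltonian.

    ``energies`` ascend; column e of ``coefficients`` holds the site
    amplitudes of eigenstate e.  ``state_dipoles`` (N×3, Debye) and
    ``dipole_strengths`` (N, Debye²) are populated once the site dipoles
    are supplied via :func:`state_dipoles`.
    """

    energies: np.ndarray
    coefficients: np.ndarray
    state_dipoles: np.ndarray | None = None
    dipole_strengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float).ravel()
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n = self.energies.size
        if self.coefficients.shape != (n, n):
            raise UsageError("coefficient matrix shape does not match energies")
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("energies must be ascending")

    @property
    def n_states(self) -> int:
        return self.energies.size


def assemble_hamiltonian(
    site_energies, couplings: CouplingMatrix
) -> ExcitonHamiltonian:
    """Place site energies on the diagonal of the coupling matrix."""
    eps = np.asarray(site_energies, dtype=float).ravel()
    if eps.size != couplings.n_sites:
        raise UsageError(
            f"{eps.size} site energies for {couplings.n_sites} coupled sites"
        )
    H = couplings.values.copy()
    np.fill_diagonal(H, eps)
    return ExcitonHamiltonian(H, site_ids=list(couplings.site_ids))


def solve(H: ExcitonHamiltonian) -> ExcitonSolution:
    """Dense symmetric eigendecomposition (energies ascending).

    Dense LAPACK is the right tool at the aggregate sizes this model
    targets; degenerate subspaces may come back in any orthonormal basis,
    and every downstream observable is basis-invariant.
    """
    energies, coefficients = np.linalg.eigh(H.matrix)
    return ExcitonSolution(energies=energies, coefficients=coefficients)


def state_dipoles(
    solution: ExcitonSolution, site_dipoles
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenstate transition dipoles and dipole strengths.

    Returns ``(vectors, strengths)`` with vectors M_e = Σ_m C[m,e]·μ_m in
    Debye and strengths |M_e|² in Debye²; also stores both on *solution*.
    """
    mu = np.asarray(site_dipoles, dtype=float)
    if mu.shape != (solution.n_states, 3):
        raise UsageError(
            f"site dipoles must have shape ({solution.n_states}, 3), got {mu.shape}"
        )
    vectors = solution.coefficients.T @ mu
    strengths = np.einsum("ij,ij->i", vectors, vectors)
    solution.state_dipoles = vectors
    solution.dipole_strengths = strengths
    return vectors, strengths


def participation_ratios(solution: ExcitonSolution) -> np.ndarray:
    """Inverse participation ratio per eigenstate: 1 / Σ_m C[m,e]⁴.

    Ranges from 1 (localized on one site) to N (uniformly delocalized).
    """
    return 1.0 / np.sum(solution.coefficients**4, axis=0)


def eigen_report(solution: ExcitonSolution) -> pd.DataFrame:
    """Tabular eigenstate summary: energy, wavelength, dipole strength,
    participation ratio."""
    if solution.dipole_strengths is None:
        raise UsageError("call state_dipoles() before building the eigen report")
    return pd.DataFrame(
        {
            "state": np.arange(1, solution.n_states + 1),
            "energy_eV": solution.energies,
            "wavelength_nm": HC_EV_NM / solution.energies,
            "dipole_strength_D2": solution.dipole_strengths,
            "participation_ratio": participation_ratios(solution),
        }
    )
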