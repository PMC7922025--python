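"""Synthetic layered aggregates of identical chlorin monomers.

The aggregate is a parallel stack: one monomer template repeated on a
three-direction lattice by rigid translation only (no rotation), so every
site carries the same transition dipole.  The conventional roles of the
three lattice directions are

* direction 1 — in-plane along the Qy dipole axis (head-to-tail, negative
  coupling),
* direction 2 — in-plane perpendicular to the dipole (side-by-side,
  positive coupling: the H-aggregate direction),
* direction 3 — stacking normal to the ring plane, with an in-plane slip
  ("stepped" layering) that makes the nearest stacking coupling negative
  (the J-aggregate direction).

Inter-monomer distances are not taken from experiment; instead the
stacking spacing is *calibrated* so the nearest stacking-direction
coupling matches a target value (−80 meV for the 5.00 D vacuum dipole),
anchoring the synthetic lattice to printed physics rather than to guessed
geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import MEAN_SITE_ENERGY_EV, NEAREST_STACK_COUPLING_EV, VACUUM_DIPOLE_D
from .coupling import CouplingModel, dipole_coupling
from .errors import CalibrationError, UsageError
from .geometry import AtomRecord, ChlorinMonomer, MolecularFrame

__all__ = [
    "LatticeSpec",
    "Aggregate",
    "PRESET_COUNTS",
    "build_aggregate",
    "standard_presets",
    "calibrate_z_spacing",
    "make_toy_monomer",
    "default_lattice_spec",
    "aggregate_to_frame",
    "site_table",
]

#: Named aggregate models, counts (n1, n2, n3): Zn12 … Zn108.
PRESET_COUNTS: dict[str, tuple[int, int, int]] = {
    "Zn12": (4, 1, 3),
    "Zn24": (4, 1, 6),
    "Zn36": (4, 1, 9),
    "Zn72": (4, 2, 9),
    "Zn108": (4, 3, 9),
}

#: Default in-plane lattice constants, Å.  13–14 Å accommodates the
#: chlorin macrocycle plus ligands; both give directional interaction
#: ranges of a few neighbors at the 0.14 meV truncation threshold.
DEFAULT_T1_A = 14.0
DEFAULT_T2_A = 13.0
#: Default in-plane slip of consecutive layers along the dipole axis, Å.
DEFAULT_SLIP_A = 5.0


@dataclass
class LatticeSpec:
    """Geometry and site-energy statistics of a translational lattice.

    ``counts`` are the repeats (n1, n2, n3) along the translation vectors
    ``t_x``, ``t_y``, ``t_z`` (Å).  Site energies are i.i.d. normal with
    mean ``mean_site_energy`` and standard deviation ``site_energy_sd``
    (eV); ``sd = 0`` gives a perfectly ordered lattice.  ``seed`` fixes
    the disorder realisation.
    """

    counts: tuple[int, int, int]
    t_x: np.ndarray
    t_y: np.ndarray
    t_z: np.ndarray
    dipole_magnitude: float = VACUUM_DIPOLE_D
    mean_site_energy: float = MEAN_SITE_ENERGY_EV
    site_energy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.counts = tuple(int(c) for c in self.counts)
        if len(self.counts) != 3 or any(c < 1 for c in self.counts):
            raise ValueError(f"counts must be three positive integers, got {self.counts}")
        self.t_x = np.asarray(self.t_x, dtype=float).reshape(3)
        self.t_y = np.asarray(self.t_y, dtype=float).reshape(3)
        self.t_z = np.asarray(self.t_z, dtype=float).reshape(3)
        if self.site_energy_sd < 0:
            raise ValueError("site_energy_sd must be >= 0")
        if self.dipole_magnitude < 0:
            raise ValueError("dipole_magnitude must be >= 0")
        for name, t, n in (
            ("t_x", self.t_x, self.counts[0]),
            ("t_y", self.t_y, self.counts[1]),
            ("t_z", self.t_z, self.counts[2]),
        ):
            if n > 1 and np.linalg.norm(t) == 0.0:
                raise ValueError(
                    f"{name} is zero but its count is {n}: sites would overlap"
                )
        used = [
            t
            for t, n in ((self.t_x, self.counts[0]), (self.t_y, self.counts[1]), (self.t_z, self.counts[2]))
            if n > 1
        ]
        if len(used) >= 2 and np.linalg.matrix_rank(np.array(used)) < len(used):
            raise ValueError("translation vectors of repeated directions must be linearly independent")

    @property
    def n_sites(self) -> int:
        return self.counts[0] * self.counts[1] * self.counts[2]

    def with_counts(self, counts: tuple[int, int, int]) -> "LatticeSpec":
        return replace(self, counts=counts)


@dataclass
class Aggregate:
    """Ordered collection of pigment sites plus its originating lattice."""

    monomers: list[ChlorinMonomer]
    spec: LatticeSpec | str = "external"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.monomers]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("monomer ids must be consecutive from 1")

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def positions(self) -> np.ndarray:
        """Zn positions, shape (N, 3), Å."""
        return np.array([m.zn for m in self.monomers])

    @property
    def dipoles(self) -> np.ndarray:
        """Site transition dipoles, shape (N, 3), Debye."""
        return np.array([m.dipole for m in self.monomers])

    @property
    def site_energies(self) -> np.ndarray:
        """Site energies, shape (N,), eV."""
        return np.array([m.site_energy for m in self.monomers])


def build_aggregate(template: ChlorinMonomer, spec: LatticeSpec) -> Aggregate:
    """Tile *template* on the lattice defined by *spec*.

    Site (i, j, k) is the template translated by i·t_x + j·t_y + k·t_z;
    ordering is deterministic with k fastest, then j, then i, and ids run
    1..N in that order.  Site energies are drawn in id order from the
    spec's seeded generator, so a given seed is bit-reproducible and
    changing the seed never moves a site.
    """
    n1, n2, n3 = spec.counts
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.n_sites)
    dip_norm = float(np.linalg.norm(template.dipole))
    if dip_norm > 0:
        dipole = template.dipole * (spec.dipole_magnitude / dip_norm)
    else:
        dipole = np.zeros(3)
    monomers: list[ChlorinMonomer] = []
    site = 0
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                shift = i * spec.t_x + j * spec.t_y + k * spec.t_z
                m = template.translated(shift, new_id=site + 1)
                m = replace(
                    m,
                    dipole=dipole.copy(),
                    site_energy=spec.mean_site_energy
                    + spec.site_energy_sd * noise[site],
                )
                monomers.append(m)
                site += 1
    return Aggregate(monomers, spec=spec)


def standard_presets(
    template: ChlorinMonomer, base_spec: LatticeSpec
) -> dict[str, Aggregate]:
    """The five named aggregate models Zn12–Zn108.

    All share the translation vectors, dipole magnitude and site-energy
    statistics of *base_spec*; only the counts differ.
    """
    return {
        name: build_aggregate(template, base_spec.with_counts(counts))
        for name, counts in PRESET_COUNTS.items()
    }


def calibrate_z_spacing(
    template: ChlorinMonomer,
    target_coupling: float,
    coupling_model: CouplingModel,
    slip=(0.0, 0.0, 0.0),
    bracket: tuple[float, float] = (1.0, 15.0),
) -> float:
    """Stacking distance R for which the nearest stacking-direction
    coupling equals *target_coupling* (eV), to within 1e-6 eV.

    The neighbor is the template translated by ``slip + (0, 0, R)``; the
    coupling is assumed strictly monotone in R over the bracket, and the
    root is found by scalar bisection (Brent).  If the target lies outside
    the couplings attainable at the bracket ends — e.g. a negative target
    for an unslipped side-by-side arrangement, which is positive at any
    distance — a :class:`CalibrationError` reports the attainable range.
    """
    slip = np.asarray(slip, dtype=float).reshape(3)
    r_lo, r_hi = float(bracket[0]), float(bracket[1])
    if not 0 < r_lo < r_hi:
        raise UsageError(f"bracket must satisfy 0 < Rlo < Rhi, got {bracket}")

    def residual(R: float) -> float:
        neighbor = template.translated(slip + np.array([0.0, 0.0, R]), new_id=2)
        return dipole_coupling(template, neighbor, coupling_model) - target_coupling

    f_lo, f_hi = residual(r_lo), residual(r_hi)
    if f_lo == 0.0:
        return r_lo
    if f_hi == 0.0:
        return r_hi
    if np.sign(f_lo) == np.sign(f_hi):
        lo_c, hi_c = f_lo + target_coupling, f_hi + target_coupling
        raise CalibrationError(
            f"target {target_coupling:.6g} eV not bracketed: couplings attainable "
            f"at R = {r_lo:g}..{r_hi:g} Å span {min(lo_c, hi_c):.6g} to "
            f"{max(lo_c, hi_c):.6g} eV"
        )
    spacing = float(brentq(residual, r_lo, r_hi, xtol=1e-10, rtol=8.9e-16))
    achieved = residual(spacing) + target_coupling
    if abs(achieved - target_coupling) > 1e-6:
        raise CalibrationError(
            f"calibration did not converge: achieved {achieved:.8g} eV "
            f"for target {target_coupling:.8g} eV"
        )
    return spacing


def make_toy_monomer(
    r21: float,
    r23: float,
    angle_2123: float,
    ring_radius: float = 2.0,
    site_energy: float = MEAN_SITE_ENERGY_EV,
    dipole_magnitude: float = VACUUM_DIPOLE_D,
    monomer_id: int = 1,
) -> ChlorinMonomer:
    """Controlled five-atom geometry with exact Zn–N bond lengths and
    N21–Zn–N23 angle — the knobs the out-of-plane descriptor depends on.

    Zn sits at the origin with the N21/N23 pair in the yz plane, the angle
    bisector along −z; N22/N24 are placed at ±``ring_radius`` along x from
    the N21–N23 midpoint so the four nitrogens are exactly coplanar.  An
    angle of exactly 180° produces an exactly planar geometry (DOOP = 0).
    """
    if r21 <= 0 or r23 <= 0:
        raise ValueError("bond lengths must be positive")
    if not 0.0 < angle_2123 <= 180.0:
        raise ValueError(f"angle must be in (0, 180] degrees, got {angle_2123}")
    if ring_radius <= 0:
        raise ValueError("ring radius must be positive")
    if angle_2123 == 180.0:
        sin_half, cos_half = 1.0, 0.0
    else:
        half = math.radians(angle_2123) / 2.0
        sin_half, cos_half = math.sin(half), math.cos(half)
    zn = np.zeros(3)
    n21 = np.array([0.0, -r21 * sin_half, -r21 * cos_half])
    n23 = np.array([0.0, r23 * sin_half, -r23 * cos_half])
    center = 0.5 * (n21 + n23)
    n22 = center + np.array([-ring_radius, 0.0, 0.0])
    n24 = center + np.array([ring_radius, 0.0, 0.0])
    axis = n23 - n21
    dipole = dipole_magnitude * axis / np.linalg.norm(axis)
    return ChlorinMonomer(
        id=monomer_id,
        zn=zn,
        n21=n21,
        n22=n22,
        n23=n23,
        n24=n24,
        dipole=dipole,
        site_energy=site_energy,
    )


def default_lattice_spec(
    template: ChlorinMonomer,
    coupling_model: CouplingModel | None = None,
    counts: tuple[int, int, int] = (4, 1, 9),
    target_coupling: float = NEAREST_STACK_COUPLING_EV,
    slip_a: float = DEFAULT_SLIP_A,
    dipole_magnitude: float = VACUUM_DIPOLE_D,
    mean_site_energy: float = MEAN_SITE_ENERGY_EV,
    site_energy_sd: float = 0.0,
    seed: int = 0,
) -> LatticeSpec:
    """Lattice spec with the package's default stepped-layer geometry.

    The template's dipole is assumed along +y with the ring in the xy
    plane (as :func:`make_toy_monomer` builds it): direction 1 translates
    along the dipole (y), direction 2 along x, and direction 3 stacks
    along z with a ``slip_a`` offset along y, the stacking distance being
    calibrated so the nearest stacking-direction coupling equals
    *target_coupling*.
    """
    model = coupling_model if coupling_model is not None else CouplingModel()
    tpl = replace(
        template,
        dipole=template.dipole * (dipole_magnitude / np.linalg.norm(template.dipole)),
    )
    slip = np.array([0.0, slip_a, 0.0])
    spacing = calibrate_z_spacing(tpl, target_coupling, model, slip=slip)
    return LatticeSpec(
        counts=counts,
        t_x=np.array([0.0, DEFAULT_T1_A, 0.0]),
        t_y=np.array([DEFAULT_T2_A, 0.0, 0.0]),
        t_z=slip + np.array([0.0, 0.0, spacing]),
        dipole_magnitude=dipole_magnitude,
        mean_site_energy=mean_site_energy,
        site_energy_sd=site_energy_sd,
        seed=seed,
    )


def aggregate_to_frame(agg: Aggregate, comment: str = "") -> MolecularFrame:
    """All atoms (Zn + 4 N per site) of an aggregate as one XYZ frame."""
    atoms: list[AtomRecord] = []
    for m in agg.monomers:
        atoms.extend(m.to_frame().atoms)
    if not comment:
        comment = f"aggregate of {len(agg)} chlorin sites"
    return MolecularFrame(atoms, comment=comment)


def site_table(agg: Aggregate) -> pd.DataFrame:
    """Per-site table: id, Zn position, dipole vector, site energy."""
    return pd.DataFrame(
        {
            "site": [m.id for m in agg.monomers],
            "zn_x_A": [m.zn[0] for m in agg.monomers],
            "zn_y_A": [m.zn[1] for m in agg.monomers],
            "zn_z_A": [m.zn[2] for m in agg.monomers],
            "mu_x_D": [m.dipole[0] for m in agg.monomers],
            "mu_y_D": [m.dipole[1] for m in agg.monomers],
            "mu_z_D": [m.dipole[2] for m in agg.monomers],
            "site_energy_eV": [m.site_energy for m in agg.monomers],
        }
    )
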