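"""Molecular geometry: XYZ I/O, the chlorin local frame, and the DOOP
out-of-plane descriptor.

A chlorin pigment is reduced to the five atoms that define its optical
frame: the central Zn and the four pyrrole nitrogens N21–N24.  The Qy
transition dipole lies along the N21→N23 axis; the ring normal is the z
axis of the local frame.  DOOP measures how far the metal sits out of the
macrocycle plane, estimated from the two trans Zn–N bonds:

    DOOP = (R(Zn–N21) + R(Zn–N23)) / 2 · cos(∠N21–Zn–N23 / 2)

which is zero for a perfectly in-plane metal (angle 180°) and grows as the
metal is pulled out of the plane, e.g. by an axial ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryError, MappingError, XYZFormatError

__all__ = [
    "AtomRecord",
    "MolecularFrame",
    "ChlorinMonomer",
    "read_xyz",
    "write_xyz",
    "monomer_from_frame",
    "local_axes",
    "doop",
]

ROLE_NAMES = ("Zn", "N21", "N22", "N23", "N24")


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinate: {a}")
    return a


@dataclass
class AtomRecord:
    """One atom: chemical symbol plus Cartesian position in Å."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.element or not str(self.element).strip():
            raise ValueError("element symbol must be nonempty")
        self.element = str(self.element).strip()
        self.position = _as_point(self.position)


@dataclass
class MolecularFrame:
    """Ordered atom list as stored in an XYZ file.

    The comment line is free text carried through unmodified; it is never
    parsed for metadata.
    """

    atoms: list[AtomRecord]
    comment: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a molecular frame needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


def read_xyz(path) -> MolecularFrame:
    """Read a standard XYZ file (count line, comment line, atom rows).

    Raises
    ------
    XYZFormatError
        If the count line is not an integer, an atom row cannot be parsed,
        or the file holds fewer atom rows than the count line promises.
        The message names the 1-based line number.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file (line 1: expected atom count)")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise XYZFormatError(
            f"{path}: line 1: expected integer atom count, got {lines[0]!r}"
        ) from None
    if n_atoms < 1:
        raise XYZFormatError(f"{path}: line 1: atom count must be >= 1")
    comment = lines[1] if len(lines) > 1 else ""
    atoms: list[AtomRecord] = []
    for i in range(n_atoms):
        lineno = i + 3
        if lineno - 1 >= len(lines):
            raise XYZFormatError(
                f"{path}: line {lineno}: expected atom row "
                f"({n_atoms} declared, {i} found)"
            )
        fields = lines[lineno - 1].split()
        if len(fields) < 4:
            raise XYZFormatError(
                f"{path}: line {lineno}: expected 'element x y z', "
                f"got {lines[lineno - 1]!r}"
            )
        try:
            pos = [float(v) for v in fields[1:4]]
        except ValueError:
            raise XYZFormatError(
                f"{path}: line {lineno}: unparsable coordinates "
                f"{fields[1:4]!r}"
            ) from None
        atoms.append(AtomRecord(fields[0], pos))
    return MolecularFrame(atoms, comment=comment)


def write_xyz(frame: MolecularFrame, path) -> None:
    """Write *frame* as standard XYZ text; round-trips with :func:`read_xyz`."""
    rows = [str(len(frame)), frame.comment.replace("\n", " ")]
    for atom in frame.atoms:
        x, y, z = atom.position
        rows.append(f"{atom.element} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(rows) + "\n")


@dataclass
class ChlorinMonomer:
    """One pigment site: the Zn/N21–N24 skeleton, the Qy transition dipole
    (Debye) and the site energy (eV).

    The dipole sign convention is N21→N23; couplings and spectra are
    invariant under a global sign flip, so the convention matters only for
    consistency within one aggregate.
    """

    id: int
    zn: np.ndarray
    n21: np.ndarray
    n22: np.ndarray
    n23: np.ndarray
    n24: np.ndarray
    dipole: np.ndarray
    site_energy: float

    def __post_init__(self) -> None:
        self.zn = _as_point(self.zn)
        self.n21 = _as_point(self.n21)
        self.n22 = _as_point(self.n22)
        self.n23 = _as_point(self.n23)
        self.n24 = _as_point(self.n24)
        self.dipole = np.asarray(self.dipole, dtype=float).reshape(3)
        ns = [self.n21, self.n22, self.n23, self.n24]
        for i in range(4):
            for j in range(i + 1, 4):
                if np.array_equal(ns[i], ns[j]):
                    raise DegenerateGeometryError(
                        f"N2{i + 1} and N2{j + 1} coincide"
                    )
        if not self.site_energy > 0:
            raise ValueError(f"site energy must be positive, got {self.site_energy}")

    def translated(self, shift, new_id: int | None = None) -> "ChlorinMonomer":
        """Rigidly translated copy (the dipole, a direction, is unchanged)."""
        t = _as_point(shift)
        return replace(
            self,
            id=self.id if new_id is None else new_id,
            zn=self.zn + t,
            n21=self.n21 + t,
            n22=self.n22 + t,
            n23=self.n23 + t,
            n24=self.n24 + t,
        )

    def to_frame(self, comment: str = "") -> MolecularFrame:
        atoms = [
            AtomRecord("Zn", self.zn),
            AtomRecord("N", self.n21),
            AtomRecord("N", self.n22),
            AtomRecord("N", self.n23),
            AtomRecord("N", self.n24),
        ]
        return MolecularFrame(atoms, comment=comment)


def monomer_from_frame(
    frame: MolecularFrame,
    index_map: Mapping[str, int],
    dipole_magnitude: float,
    site_energy: float,
    monomer_id: int = 1,
) -> ChlorinMonomer:
    """Extract a pigment site from a structure using an explicit role map.

    ``index_map`` maps each role in ``{"Zn","N21","N22","N23","N24"}`` to a
    0-based atom index of *frame*.  Roles are never inferred from element
    symbols: the four nitrogens are chemically distinct and a silent
    misassignment would corrupt the dipole axis.  The transition dipole is
    ``dipole_magnitude`` Debye along the unit vector N21→N23.
    """
    missing = [r for r in ROLE_NAMES if r not in index_map]
    if missing:
        raise MappingError(f"index map missing roles: {missing}")
    idx = [int(index_map[r]) for r in ROLE_NAMES]
    if len(set(idx)) != len(idx):
        raise MappingError(f"duplicate atom indices in role map: {idx}")
    for r, i in zip(ROLE_NAMES, idx):
        if not 0 <= i < len(frame):
            raise MappingError(
                f"role {r}: index {i} out of range for {len(frame)} atoms"
            )
    if dipole_magnitude < 0:
        raise ValueError("dipole magnitude must be >= 0")
    pos = [frame.atoms[i].position for i in idx]
    zn, n21, n22, n23, n24 = pos
    axis = n23 - n21
    norm = float(np.linalg.norm(axis))
    if norm == 0.0:
        raise DegenerateGeometryError("N21 and N23 coincide; dipole axis undefined")
    dipole = dipole_magnitude * axis / norm if dipole_magnitude > 0 else np.zeros(3)
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


def local_axes(monomer: ChlorinMonomer) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal molecular frame (x̂, ŷ, ẑ).

    ŷ points along N21→N23 (the Qy axis), ẑ along
    (N23−N21)×(N24−N22) (the ring normal), and x̂ = ŷ×ẑ completes the
    right-handed triple.  Rotation-equivariant by construction.
    """
    vy = monomer.n23 - monomer.n21
    vx = monomer.n24 - monomer.n22
    ny = float(np.linalg.norm(vy))
    if ny == 0.0:
        raise DegenerateGeometryError("N21 and N23 coincide")
    y_hat = vy / ny
    normal = np.cross(vy, vx)
    nz = float(np.linalg.norm(normal))
    if nz < 1e-12 * max(ny, float(np.linalg.norm(vx)), 1.0):
        raise DegenerateGeometryError(
            "N21–N23 and N22–N24 directions are collinear; ring normal undefined"
        )
    z_hat = normal / nz
    x_hat = np.cross(y_hat, z_hat)
    return x_hat, y_hat, z_hat


def doop(monomer: ChlorinMonomer) -> float:
    """Out-of-plane distance of Zn from the chlorin ring, Å.

    Mean of the two trans Zn–N bond lengths times the cosine of half the
    N21–Zn–N23 angle.  Nonnegative for angles ≤ 180°; exactly zero for a
    perfectly planar coordination (angle 180°).  Invariant under rigid
    motion, since it depends only on two distances and one angle.
    """
    u = monomer.n21 - monomer.zn
    v = monomer.n23 - monomer.zn
    ru = float(np.linalg.norm(u))
    rv = float(np.linalg.norm(v))
    if ru == 0.0 or rv == 0.0:
        raise DegenerateGeometryError("Zn coincides with N21 or N23")
    cos_angle = float(np.clip(np.dot(u, v) / (ru * rv), -1.0, 1.0))
    # cos(θ/2) via the half-angle identity: exact at θ = 180°, and
    # guarantees a nonnegative result without computing θ itself.
    cos_half = np.sqrt(max(0.0, (1.0 + cos_angle) / 2.0))
    return 0.5 * (ru + rv) * cos_half
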