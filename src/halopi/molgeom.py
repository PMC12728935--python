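"""Molecular geometry primitives.

Idealized monomer builders (benzene, halobenzenes), rigid-body transforms,
and ring plane/centroid math.  Coordinate convention used throughout the
package: the acceptor benzene ring lies in the xz-plane with its centroid at
the origin and plane normal +y; donors sit at y > 0.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Molecule",
    "RigidTransform",
    "BOND_LENGTHS",
    "build_benzene",
    "build_halobenzene",
    "apply_transform",
    "plane_and_centroid",
    "rotation_about_axis",
    "read_xyz",
    "write_xyz",
]

#: Default idealized bond lengths in angstrom.  The values are
#: literature-standard; users with their own optimized monomers can read
#: them in via :func:`read_xyz` instead.
BOND_LENGTHS = {
    "C-C": 1.39,
    "C-H": 1.08,
    "C-Cl": 1.74,
    "C-Br": 1.90,
    "C-I": 2.10,
}

HALOGENS = ("Cl", "Br", "I")

# role tags
HALOGEN = "halogen"
IPSO = "ipso_carbon"
ORTHO = "ortho_carbon"
RING_C = "ring_carbon"
RING_H = "ring_hydrogen"


@dataclasses.dataclass
class Molecule:
    """A labeled 3-D point set: element symbols, coordinates (A), role tags."""

    elements: list[str]
    coords: np.ndarray  # (n, 3) float64
    roles: list[str | None]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not (len(self.elements) == len(self.coords) == len(self.roles)):
            raise ValueError("elements, coords and roles must have equal length")

    def __len__(self) -> int:
        return len(self.elements)

    def copy(self) -> "Molecule":
        return Molecule(list(self.elements), self.coords.copy(), list(self.roles))

    def atoms_with_role(self, role: str) -> np.ndarray:
        """Indices of atoms carrying ``role``."""
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def single_atom(self, role: str) -> int:
        idx = self.atoms_with_role(role)
        if len(idx) != 1:
            raise ValueError(f"expected exactly one atom with role {role!r}, found {len(idx)}")
        return int(idx[0])

    def ring_carbon_indices(self) -> np.ndarray:
        """Indices of the aromatic ring carbons (ipso/ortho/ring tags), in build order."""
        return np.array(
            [i for i, r in enumerate(self.roles) if r in (IPSO, ORTHO, RING_C)], dtype=int
        )

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def rotation_about_axis(
    axis: Sequence[float], angle_deg: float, center: Sequence[float] | None = None
) -> RigidTransform:
    """Right-handed rotation by ``angle_deg`` about ``axis`` through ``center``."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    a = a / n
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    if center is None:
        t = np.zeros(3)
    else:
        cvec = np.asarray(center, dtype=float)
        t = cvec - R @ cvec
    return RigidTransform(R, t)


def build_benzene(cc: float | None = None, ch: float | None = None) -> Molecule:
    """Idealized D6h benzene, ring in the xz-plane, centroid at the origin.

    Ring carbon ``k`` sits at angle 60k deg in the xz-plane; each hydrogen is
    placed radially outward from its carbon.
    """
    cc = BOND_LENGTHS["C-C"] if cc is None else cc
    ch = BOND_LENGTHS["C-H"] if ch is None else ch
    elements: list[str] = []
    coords: list[np.ndarray] = []
    roles: list[str | None] = []
    for k in range(6):
        phi = np.radians(60.0 * k)
        u = np.array([np.cos(phi), 0.0, np.sin(phi)])
        elements.append("C")
        coords.append(cc * u)
        roles.append(RING_C)
    for k in range(6):
        phi = np.radians(60.0 * k)
        u = np.array([np.cos(phi), 0.0, np.sin(phi)])
        elements.append("H")
        coords.append((cc + ch) * u)
        roles.append(RING_H)
    return Molecule(elements, np.array(coords), roles)


def build_halobenzene(
    halogen: str,
    cx: float | None = None,
    cc: float | None = None,
    ch: float | None = None,
) -> Molecule:
    """Idealized planar C6H5X in its canonical donor frame.

    The halogen sits at the origin with the ipso carbon straight above it on
    +y (so the C->X bond vector points along -y, i.e. toward an acceptor
    plane placed below).  The phenyl ring lies in the xy-plane; its plane
    normal is +z.
    """
    if halogen not in HALOGENS:
        raise ValueError(f"unknown halogen {halogen!r}; expected one of {HALOGENS}")
    cx = BOND_LENGTHS[f"C-{halogen}"] if cx is None else cx
    cc = BOND_LENGTHS["C-C"] if cc is None else cc
    ch = BOND_LENGTHS["C-H"] if ch is None else ch

    centroid = np.array([0.0, cx + cc, 0.0])
    elements = [halogen]
    coords = [np.zeros(3)]
    roles: list[str | None] = [HALOGEN]
    ring: list[np.ndarray] = []
    for k in range(6):
        phi = np.radians(60.0 * k)
        # phi = 0 is the ipso carbon, pointing from the centroid toward X
        p = centroid + cc * np.array([np.sin(phi), -np.cos(phi), 0.0])
        ring.append(p)
    ring_roles = [IPSO, ORTHO, RING_C, RING_C, RING_C, ORTHO]
    for p, role in zip(ring, ring_roles):
        elements.append("C")
        coords.append(p)
        roles.append(role)
    for k in range(1, 6):  # hydrogens on every non-ipso carbon
        phi = np.radians(60.0 * k)
        u = np.array([np.sin(phi), -np.cos(phi), 0.0])
        elements.append("H")
        coords.append(centroid + (cc + ch) * u)
        roles.append(RING_H)
    return Molecule(elements, np.array(coords), roles)


def apply_transform(mol: Molecule, t: RigidTransform) -> Molecule:
    """Return ``mol`` moved by the rigid transform (isometry)."""
    out = mol.copy()
    out.coords = mol.coords @ t.rotation.T + t.translation
    return out


def plane_and_centroid(
    mol: Molecule, reference_point: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares ring plane normal (unit) and ring centroid.

    Uses the ring-carbon atoms.  When ``reference_point`` is given the normal
    is oriented toward its side of the plane; otherwise the sign is fixed by
    making the largest-magnitude component positive.
    """
    idx = mol.ring_carbon_indices()
    if len(idx) < 3:
        raise ValueError("need at least 3 ring atoms to define a plane")
    pts = mol.coords[idx]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10:
        raise ValueError("ring atoms are collinear; plane is undefined")
    normal = vt[2]
    if reference_point is not None:
        if np.dot(np.asarray(reference_point, dtype=float) - centroid, normal) < 0:
            normal = -normal
    else:
        j = int(np.argmax(np.abs(normal)))
        if normal[j] < 0:
            normal = -normal
    return normal, centroid


# ---------------------------------------------------------------------------
# XYZ I/O (standard 2-line-header format, angstrom)

def write_xyz(mols: Molecule | Iterable[Molecule], path, comment: str = "") -> None:
    if isinstance(mols, Molecule):
        mols = [mols]
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{len(mol)}\n{comment}\n")
            for el, xyz in zip(mol.elements, mol.coords):
                fh.write(f"{el:<3s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}\n")


def read_xyz(path) -> list[Molecule]:
    """Read a (possibly multi-frame) XYZ file.  Roles are left untagged."""
    mols: list[Molecule] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        body = lines[i + 2 : i + 2 + n]
        elements, coords = [], []
        for ln in body:
            parts = ln.split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        mols.append(Molecule(elements, np.array(coords), [None] * n))
        i += 2 + n
    return mols
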