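"""Mining PDB structures for halogen-pi contacts to phenylalanine.

The scan finds hetero-compound ligands carrying Cl/Br/I bonded to a planar
aromatic ring, collects phenylalanine side-chain rings within 5 A of the
halogen, applies the sigma-hole geometry filters (tilt angle < 50 deg,
minimum halogen-ring distance >= 1 A, C-X vector pointing at the plane) and
rebuilds each passing contact as a canonical halobenzene-benzene model
complex that preserves the halogen position, the C-X direction and the two
ring planes (matched-molecular-pair replacement).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from . import features as feat
from .geomgen import ComplexGeometry
from .model import TrainedModel, predict
from .molgeom import Molecule, build_benzene, build_halobenzene

logger = logging.getLogger(__name__)

__all__ = [
    "HaloLigandSite",
    "PDBContact",
    "MMPComplex",
    "find_halogen_aryl_ligands",
    "find_pi_contacts",
    "apply_sigma_filters",
    "build_mmp_complex",
    "five_ring_feature_check",
    "scan_structure",
    "contacts_to_table",
    "percent",
    "PDBSceneWriter",
]

HALOGEN_ELEMENTS = {"CL": "Cl", "BR": "Br", "I": "I"}

#: Covalent radii (A) for distance-based bond perception.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "SE": 1.20, "AS": 1.19,
}
BOND_TOLERANCE = 0.45  # added to the radius sum
RING_PLANARITY_RMS = 0.1  # A
MIN_LIGAND_HEAVY_ATOMS = 6
CONTACT_DISTANCE = 5.0  # A, halogen to nearest PHE ring atom

METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "PT", "PD", "AG", "AU", "W",
    "MO", "V", "CR",
}

PHE_RING_ATOMS = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")  # cyclic order


# ---------------------------------------------------------------------------
# Data records

@dataclasses.dataclass
class HaloLigandSite:
    """A halogen bonded to a carbon of a planar aromatic ring in a ligand."""

    structure_id: str
    ligand_id: str  # resname:chain:resseq
    halogen: str  # Cl | Br | I
    halogen_atom: str
    halogen_pos: np.ndarray
    carbon_atom: str
    carbon_pos: np.ndarray
    ring_size: int
    ring_coords: np.ndarray  # (ring_size, 3), cyclic order
    ring_elements: tuple[str, ...]
    ortho_pos: tuple[np.ndarray, np.ndarray]  # ring neighbors of the bonded carbon


@dataclasses.dataclass
class PDBContact:
    """One (halogen, PHE ring) pair within contact range, with pose measures."""

    site: HaloLigandSite
    residue_id: str  # PHE:chain:resseq
    phe_ring_coords: np.ndarray  # (6, 3) in PHE_RING_ATOMS order
    d_plane: float
    alpha: float
    d_x_aa: float
    directional: bool
    verdict: bool = False


@dataclasses.dataclass
class MMPComplex:
    """Canonical halobenzene-benzene complex rebuilt from a contact."""

    complex: ComplexGeometry
    provenance: dict


# ---------------------------------------------------------------------------
# Structure loading / preprocessing

def load_structure(path):
    """Parse a PDB file; unreadable input raises with file context."""
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            return parser.get_structure(Path(path).stem, str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc


def _heavy_atoms(residue):
    """Residue atoms after preprocessing: no hydrogens, one altloc."""
    out = []
    for atom in residue.get_atoms():  # DisorderedAtom proxies its selected altloc
        el = (atom.element or "").strip().upper()
        if el in ("H", "D"):
            continue
        out.append(atom)
    return out


def _bonded(a_el: str, a_pos, b_el: str, b_pos) -> bool:
    ra = COVALENT_RADII.get(a_el.upper(), 0.77)
    rb = COVALENT_RADII.get(b_el.upper(), 0.77)
    return float(np.linalg.norm(np.asarray(a_pos) - np.asarray(b_pos))) < ra + rb + BOND_TOLERANCE


def _plane_rms(coords: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    dist = centered @ normal
    return float(np.sqrt(np.mean(dist**2))), normal, centroid


def _rings_containing(adj: Mapping[int, set], node: int, sizes=(5, 6)) -> list[list[int]]:
    """Simple cycles through ``node`` of the given sizes (DFS enumeration)."""
    rings: list[list[int]] = []
    seen: set[tuple] = set()
    max_len = max(sizes)

    def walk(path: list[int]) -> None:
        last = path[-1]
        for nxt in adj[last]:
            if nxt == node and len(path) in sizes:
                key = tuple(sorted(path))
                if key not in seen:
                    seen.add(key)
                    rings.append(list(path))
            elif nxt not in path and len(path) < max_len:
                walk(path + [nxt])

    walk([node])
    return rings


def find_halogen_aryl_ligands(structure) -> list[HaloLigandSite]:
    """Hetero ligands (>= 6 heavy atoms) with Cl/Br/I on a planar 5/6-ring.

    Bonds are perceived from covalent radii; metal ions, waters, hydrogens
    and polymer residues are ignored.
    """
    sites: list[HaloLigandSite] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            hetfield = residue.id[0]
            if not hetfield.startswith("H_"):
                continue  # polymer residue or water
            atoms = _heavy_atoms(residue)
            elements = [(a.element or "").strip().upper() for a in atoms]
            if len(atoms) == 1 and elements[0] in METAL_ELEMENTS:
                continue
            if len(atoms) < MIN_LIGAND_HEAVY_ATOMS:
                continue
            halogen_idx = [i for i, el in enumerate(elements) if el in HALOGEN_ELEMENTS]
            if not halogen_idx:
                continue
            coords = np.array([a.coord for a in atoms], dtype=float)
            # adjacency among ligand heavy atoms
            adj: dict[int, set] = {i: set() for i in range(len(atoms))}
            for i in range(len(atoms)):
                for j in range(i + 1, len(atoms)):
                    if _bonded(elements[i], coords[i], elements[j], coords[j]):
                        adj[i].add(j)
                        adj[j].add(i)
            ligand_id = f"{residue.resname.strip()}:{chain.id}:{residue.id[1]}"
            for hi in halogen_idx:
                for ci in adj[hi]:
                    if elements[ci] != "C":
                        continue
                    for ring in _rings_containing(adj, ci):
                        ring_xyz = coords[ring]
                        rms, _, _ = _plane_rms(ring_xyz)
                        if rms >= RING_PLANARITY_RMS:
                            continue
                        pos_in_ring = ring.index(ci)
                        nb1 = ring[(pos_in_ring - 1) % len(ring)]
                        nb2 = ring[(pos_in_ring + 1) % len(ring)]
                        sites.append(
                            HaloLigandSite(
                                structure_id=structure.id,
                                ligand_id=ligand_id,
                                halogen=HALOGEN_ELEMENTS[elements[hi]],
                                halogen_atom=atoms[hi].get_name(),
                                halogen_pos=coords[hi].copy(),
                                carbon_atom=atoms[ci].get_name(),
                                carbon_pos=coords[ci].copy(),
                                ring_size=len(ring),
                                ring_coords=ring_xyz.copy(),
                                ring_elements=tuple(elements[k] for k in ring),
                                ortho_pos=(coords[nb1].copy(), coords[nb2].copy()),
                            )
                        )
                        break  # one ring per halogen attachment
                    else:
                        continue
                    break  # halogen assigned to one aromatic carbon
    return sites


def find_pi_contacts(structure, candidates: Sequence[HaloLigandSite]) -> list[PDBContact]:
    """One contact per (halogen site, PHE ring) with a ring atom within 5 A."""
    contacts: list[PDBContact] = []
    model = next(structure.get_models())
    phe_rings = []
    for chain in model:
        for residue in chain:
            if residue.id[0] != " " or residue.resname.strip() != "PHE":
                continue
            try:
                ring = np.array([residue[a].coord for a in PHE_RING_ATOMS], dtype=float)
            except KeyError:
                logger.warning(
                    "skipping PHE %s:%s with incomplete side chain", chain.id, residue.id[1]
                )
                continue
            phe_rings.append((f"PHE:{chain.id}:{residue.id[1]}", ring))

    for site in candidates:
        for res_id, ring in phe_rings:
            dists = np.linalg.norm(ring - site.halogen_pos, axis=1)
            d_x_aa = float(dists.min())
            if d_x_aa > CONTACT_DISTANCE:
                continue
            _, normal, centroid = _plane_rms(ring)
            if np.dot(site.halogen_pos - centroid, normal) < 0:
                normal = -normal
            d_plane = float(np.dot(site.halogen_pos - centroid, normal))
            xc = site.carbon_pos - site.halogen_pos
            cosang = np.clip(np.dot(xc, normal) / np.linalg.norm(xc), -1.0, 1.0)
            alpha = float(np.degrees(np.arccos(cosang)))
            directional = bool(np.dot(-xc, normal) < 0)  # C->X heads toward the plane
            contact = PDBContact(
                site=site,
                residue_id=res_id,
                phe_ring_coords=ring.copy(),
                d_plane=d_plane,
                alpha=alpha,
                d_x_aa=d_x_aa,
                directional=directional,
            )
            contact.verdict = apply_sigma_filters(contact)
            contacts.append(contact)
    return contacts


def apply_sigma_filters(
    contact: PDBContact, alpha_max: float = 50.0, d_min: float = 1.0
) -> bool:
    """Sigma-hole verdict: alpha < 50 deg, d_X...AA >= 1 A, C-X toward plane."""
    return bool(
        contact.alpha < alpha_max and contact.d_x_aa >= d_min and contact.directional
    )


def contact_from_complex(c: ComplexGeometry) -> PDBContact:
    """Synthesize a contact record directly from an in-memory complex.

    Lets already-canonical complexes re-enter the MMP pipeline (used for
    idempotence checks and for re-scoring generated poses with the scan
    machinery).
    """
    donor = c.donor
    xi = donor.single_atom("halogen")
    ci = donor.single_atom("ipso_carbon")
    ortho = donor.atoms_with_role("ortho_carbon")
    ring_idx = donor.ring_carbon_indices()
    site = HaloLigandSite(
        structure_id="memory",
        ligand_id=f"{c.halogen}BZ:-:0",
        halogen=c.halogen,
        halogen_atom="X1",
        halogen_pos=donor.coords[xi].copy(),
        carbon_atom="C1",
        carbon_pos=donor.coords[ci].copy(),
        ring_size=len(ring_idx),
        ring_coords=donor.coords[ring_idx].copy(),
        ring_elements=("C",) * len(ring_idx),
        ortho_pos=(donor.coords[ortho[0]].copy(), donor.coords[ortho[1]].copy()),
    )
    ring = c.acceptor.coords[c.acceptor.ring_carbon_indices()]
    _, normal, centroid = _plane_rms(ring)
    if np.dot(site.halogen_pos - centroid, normal) < 0:
        normal = -normal
    d_plane = float(np.dot(site.halogen_pos - centroid, normal))
    xc = site.carbon_pos - site.halogen_pos
    cosang = np.clip(np.dot(xc, normal) / np.linalg.norm(xc), -1.0, 1.0)
    alpha = float(np.degrees(np.arccos(cosang)))
    contact = PDBContact(
        site=site,
        residue_id="PHE:-:0",
        phe_ring_coords=ring.copy(),
        d_plane=d_plane,
        alpha=alpha,
        d_x_aa=float(np.linalg.norm(ring - site.halogen_pos, axis=1).min()),
        directional=bool(np.dot(-xc, normal) < 0),
    )
    contact.verdict = apply_sigma_filters(contact)
    return contact


# ---------------------------------------------------------------------------
# Matched-molecular-pair reconstruction

def _optimal_spin(points: np.ndarray, targets: np.ndarray, axis: np.ndarray,
                  center: np.ndarray) -> float:
    """Angle about ``axis`` through ``center`` minimizing sum |R p - q|^2."""
    p = points - center
    q = targets - center
    par = (p @ axis)[:, None] * axis
    perp = p - par
    q_eff = q - par
    a = float(np.sum(q_eff * perp))
    b = float(np.sum(q_eff * np.cross(axis, perp)))
    return float(np.arctan2(b, a))


def _rot(axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(theta), np.sin(theta)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _perp_unit(v: np.ndarray, hint: np.ndarray) -> np.ndarray:
    """Component of ``hint`` perpendicular to unit vector ``v``, normalized."""
    w = hint - np.dot(hint, v) * v
    n = np.linalg.norm(w)
    if n < 1e-8:
        w = np.array([1.0, 0.0, 0.0]) - v[0] * v
        n = np.linalg.norm(w)
        if n < 1e-8:
            w = np.array([0.0, 1.0, 0.0]) - v[1] * v
            n = np.linalg.norm(w)
    return w / n


def build_mmp_complex(contact: PDBContact, structure=None) -> MMPComplex:
    """Replace ligand and PHE by canonical halobenzene and benzene.

    The halogen position is preserved exactly and the C-X direction matched;
    the donor ring plane is aligned to the ligand ring plane with the
    residual in-plane spin minimizing ring-atom RMSD (6-rings; plane-only
    alignment otherwise).  The benzene acceptor is aligned onto the PHE ring
    by centroid, plane normal and minimal-RMSD spin.
    """
    if not contact.verdict:
        raise ValueError("MMP reconstruction requires a passing contact")
    site = contact.site

    # --- donor -------------------------------------------------------------
    donor = build_halobenzene(site.halogen)
    e1 = site.carbon_pos - site.halogen_pos  # X -> C direction
    e1 = e1 / np.linalg.norm(e1)
    _, lig_normal, _ = _plane_rms(site.ring_coords)
    n_p = _perp_unit(e1, lig_normal)
    # canonical frame: X->C along +y, ring normal +z
    R0 = np.column_stack([np.cross(e1, n_p), e1, n_p])
    donor_coords = donor.coords @ R0.T + site.halogen_pos
    ring_idx = donor.ring_carbon_indices()
    if site.ring_size == 6:
        best = None
        lig_ring = site.ring_coords
        start = int(np.argmin(np.linalg.norm(lig_ring - site.carbon_pos, axis=1)))
        for direction in (1, -1):
            order = [(start + direction * k) % site.ring_size for k in range(site.ring_size)]
            targets = lig_ring[order]
            theta = _optimal_spin(
                donor_coords[ring_idx], targets, e1, site.halogen_pos
            )
            R = _rot(e1, theta)
            cand = (donor_coords - site.halogen_pos) @ R.T + site.halogen_pos
            rmsd = float(np.sqrt(np.mean((cand[ring_idx] - targets) ** 2)))
            if best is None or rmsd < best[0]:
                best = (rmsd, cand)
        donor_coords = best[1]
    donor = Molecule(list(donor.elements), donor_coords, list(donor.roles))

    # --- acceptor ----------------------------------------------------------
    acceptor = build_benzene()
    _, phe_normal, phe_centroid = _plane_rms(contact.phe_ring_coords)
    if np.dot(site.halogen_pos - phe_centroid, phe_normal) < 0:
        phe_normal = -phe_normal
    u = _perp_unit(phe_normal, np.array([1.0, 0.0, 0.0]))
    Ra = np.column_stack([u, phe_normal, np.cross(u, phe_normal)])
    acc_coords = acceptor.coords @ Ra.T + phe_centroid
    acc_ring = acceptor.ring_carbon_indices()
    theta = _optimal_spin(
        acc_coords[acc_ring], contact.phe_ring_coords, phe_normal, phe_centroid
    )
    R = _rot(phe_normal, theta)
    acc_coords = (acc_coords - phe_centroid) @ R.T + phe_centroid
    acceptor = Molecule(list(acceptor.elements), acc_coords, list(acceptor.roles))

    cg = ComplexGeometry(
        halogen=site.halogen,
        meta={
            "source": "pdb",
            "structure": site.structure_id,
            "ligand": site.ligand_id,
            "residue": contact.residue_id,
            "d": contact.d_plane,
            "alpha": contact.alpha,
        },
        acceptor=acceptor,
        _donor=donor,
    )
    return MMPComplex(
        complex=cg,
        provenance={
            "structure": site.structure_id,
            "ligand": site.ligand_id,
            "residue": contact.residue_id,
        },
    )


def five_ring_feature_check(
    contacts: Sequence[PDBContact],
    model: TrainedModel,
) -> pd.DataFrame:
    """Prediction shift when using the original 5-ring donor geometry.

    For every passing contact whose ligand ring is 5-membered, features are
    recomputed from the ligand's own ring atoms (halogen, bonded carbon and
    its two ring neighbors) against the reconstructed benzene acceptor, and
    the prediction is compared with the canonical 6-ring reconstruction.
    Returns a per-contact table; ``mean`` / ``sd`` of the difference are in
    ``df.attrs["summary"]``.
    """
    if model.scaler is None:
        raise ValueError("model has no scaler; cannot featurize contacts")
    rows = []
    for contact in contacts:
        if contact.site.ring_size != 5:
            logger.info("skipping %s: donor ring is not 5-membered", contact.site.ligand_id)
            continue
        if not contact.verdict:
            continue
        mmp = build_mmp_complex(contact)
        acc_ring = mmp.complex.acceptor.ring_carbon_indices()
        acc_coords = mmp.complex.acceptor.coords[acc_ring]
        fv6 = feat.extract_features(mmp.complex)
        site = contact.site
        fv5 = feat.features_from_atoms(
            site.halogen_pos, site.carbon_pos, site.ortho_pos[0], site.ortho_pos[1],
            acc_coords,
        )
        p6 = float(predict(model, feat.apply_scaler(fv6, model.scaler))[0])
        p5 = float(predict(model, feat.apply_scaler(fv5, model.scaler))[0])
        rows.append(
            {
                "ligand": site.ligand_id,
                "residue": contact.residue_id,
                "pred_5ring": p5,
                "pred_6ring": p6,
                "difference": p5 - p6,
            }
        )
    df = pd.DataFrame(rows, columns=["ligand", "residue", "pred_5ring", "pred_6ring", "difference"])
    df.attrs["summary"] = {
        "mean": float(df["difference"].mean()) if len(df) else float("nan"),
        "sd": float(df["difference"].std(ddof=1)) if len(df) > 1 else float("nan"),
        "n": len(df),
    }
    return df


# ---------------------------------------------------------------------------
# Drivers and summaries

def scan_structure(path) -> list[PDBContact]:
    structure = load_structure(path)
    candidates = find_halogen_aryl_ligands(structure)
    return find_pi_contacts(structure, candidates)


def contacts_to_table(contacts: Iterable[PDBContact]) -> pd.DataFrame:
    rows = [
        {
            "structure": c.site.structure_id,
            "ligand": c.site.ligand_id,
            "halogen": c.site.halogen,
            "residue": c.residue_id,
            "d_plane": c.d_plane,
            "alpha": c.alpha,
            "d_x_aa": c.d_x_aa,
            "directional": c.directional,
            "verdict": c.verdict,
        }
        for c in contacts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "structure", "ligand", "halogen", "residue",
            "d_plane", "alpha", "d_x_aa", "directional", "verdict",
        ],
    )


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """Share of ``part`` in ``whole`` as a percentage, rounded."""
    if whole == 0:
        raise ValueError("cannot take a percentage of zero")
    return round(100.0 * part / whole, ndigits)


# ---------------------------------------------------------------------------
# Fixture / scene writing (plain-text PDB)

class PDBSceneWriter:
    """Compose a minimal PDB file from molecules (for fixtures and demos)."""

    def __init__(self) -> None:
        self._lines: list[str] = []
        self._serial = 1
        self._resseq = 0

    def _fmt(self, record: str, name: str, resname: str, chain: str,
             resseq: int, pos, element: str) -> str:
        el = element.upper()
        name_f = f"{name:<4s}" if len(name) >= 4 else f" {name:<3s}"
        return (
            f"{record:<6s}{self._serial:5d} {name_f} {resname:<3s} {chain}{resseq:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
        )

    def add_phe(self, ring_coords: np.ndarray, chain: str = "A") -> int:
        """Add a PHE residue whose ring atoms are ``ring_coords`` (cyclic
        CG..CD2 order); CB is placed outward from CG in the ring plane."""
        self._resseq += 1
        ring_coords = np.asarray(ring_coords, dtype=float)
        centroid = ring_coords.mean(axis=0)
        cb = ring_coords[0] + 1.52 * (ring_coords[0] - centroid) / np.linalg.norm(
            ring_coords[0] - centroid
        )
        self._lines.append(self._fmt("ATOM", "CB", "PHE", chain, self._resseq, cb, "C"))
        self._serial += 1
        for name, pos in zip(PHE_RING_ATOMS, ring_coords):
            self._lines.append(self._fmt("ATOM", name, "PHE", chain, self._resseq, pos, "C"))
            self._serial += 1
        return self._resseq

    def add_ligand(self, mol: Molecule, resname: str = "LIG", chain: str = "B") -> int:
        self._resseq += 1
        counts: dict[str, int] = {}
        for el, pos in zip(mol.elements, mol.coords):
            counts[el] = counts.get(el, 0) + 1
            name = f"{el.upper()}{counts[el]}"
            self._lines.append(
                self._fmt("HETATM", name, resname, chain, self._resseq, pos, el)
            )
            self._serial += 1
        return self._resseq

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self._lines) + "\nEND\n")
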