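"""30-component geometric descriptor and min-max scaling.

Layout (schema ``v1``): 24 atom-pair distances (halogen, ipso carbon and the
two ortho carbons, each to the 6 acceptor ring carbons), halogen->ring
centroid, ipso->ring centroid, perpendicular halogen-plane distance, then 3
angles in degrees.  The acceptor ring carbons are ordered by ascending
halogen->carbon distance and every per-carbon block reuses that permutation,
which makes the descriptor invariant to relabeling the benzene carbons.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .geomgen import ComplexGeometry
from .molgeom import plane_and_centroid

__all__ = [
    "SCHEMA_ID",
    "FEATURE_NAMES",
    "FeatureVector",
    "ScalerParams",
    "extract_features",
    "features_from_atoms",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "feature_matrix",
]

SCHEMA_ID = "v1-24pair-3dist-3angle"

FEATURE_NAMES: tuple[str, ...] = (
    *(f"d_X_C{i}" for i in range(1, 7)),
    *(f"d_Cipso_C{i}" for i in range(1, 7)),
    *(f"d_Cortho1_C{i}" for i in range(1, 7)),
    *(f"d_Cortho2_C{i}" for i in range(1, 7)),
    "d_X_centroid",
    "d_Cipso_centroid",
    "d_X_plane",
    "a_CX_CoM",
    "a_CX_normal",
    "a_ortho_normal",
)


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray  # (30,)
    schema_id: str = SCHEMA_ID

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if v.shape != (30,):
            raise ValueError(f"feature vector must have length 30, got {v.shape}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def distances(self) -> np.ndarray:
        return self.values[:27]

    @property
    def angles(self) -> np.ndarray:
        return self.values[27:]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def features_from_atoms(
    x_pos: np.ndarray,
    ipso_pos: np.ndarray,
    ortho1_pos: np.ndarray,
    ortho2_pos: np.ndarray,
    ring_coords: np.ndarray,
    ring_masses: np.ndarray | None = None,
) -> FeatureVector:
    """Descriptor from explicit donor-atom and acceptor-ring coordinates.

    ``ring_coords`` are the acceptor ring carbons (shape (6, 3)).  The
    center of mass used by the first angle defaults to the ring-carbon
    centroid (equal masses), which coincides with the full-benzene CoM for
    the idealized acceptor.
    """
    ring_coords = np.asarray(ring_coords, dtype=float)
    if ring_coords.shape != (6, 3):
        raise ValueError("acceptor ring must have exactly 6 carbons")
    centroid = ring_coords.mean(axis=0)
    if ring_masses is None:
        com = centroid
    else:
        w = np.asarray(ring_masses, dtype=float)
        com = (ring_coords * w[:, None]).sum(axis=0) / w.sum()

    centered = ring_coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10:
        raise ValueError("degenerate acceptor ring")
    normal = vt[2]
    if np.dot(x_pos - centroid, normal) < 0:
        normal = -normal

    d_x = np.linalg.norm(ring_coords - x_pos, axis=1)
    order = np.argsort(d_x, kind="stable")
    blocks = [
        d_x[order],
        np.linalg.norm(ring_coords - ipso_pos, axis=1)[order],
        np.linalg.norm(ring_coords - ortho1_pos, axis=1)[order],
        np.linalg.norm(ring_coords - ortho2_pos, axis=1)[order],
    ]
    d_plane = float(np.dot(x_pos - centroid, normal))
    extras = [
        float(np.linalg.norm(x_pos - centroid)),
        float(np.linalg.norm(ipso_pos - centroid)),
        d_plane,
    ]
    a1 = _angle_deg(ipso_pos - x_pos, com - x_pos)
    a2 = _angle_deg(ipso_pos - x_pos, normal)
    a3 = _angle_deg(ortho2_pos - ortho1_pos, normal)
    values = np.concatenate([np.concatenate(blocks), extras, [a1, a2, a3]])
    return FeatureVector(values)


def extract_features(c: ComplexGeometry) -> FeatureVector:
    """Extract the 30-component descriptor from a donor-acceptor complex."""
    donor = c.donor
    xi = donor.single_atom("halogen")
    ci = donor.single_atom("ipso_carbon")
    ortho = donor.atoms_with_role("ortho_carbon")
    if len(ortho) != 2:
        raise ValueError("donor must carry exactly two ortho_carbon tags")
    ring_idx = c.acceptor.ring_carbon_indices()
    if len(ring_idx) != 6:
        raise ValueError("acceptor must be a 6-carbon ring")
    return features_from_atoms(
        donor.coords[xi],
        donor.coords[ci],
        donor.coords[ortho[0]],
        donor.coords[ortho[1]],
        c.acceptor.coords[ring_idx],
    )


def feature_matrix(complexes: Sequence[ComplexGeometry]) -> np.ndarray:
    """Stack descriptors for many complexes into an (n, 30) array."""
    return np.array([extract_features(c).values for c in complexes])


# ---------------------------------------------------------------------------
# Min-max scaling

@dataclasses.dataclass(frozen=True)
class ScalerParams:
    """Per-feature minima/maxima from the fit (training) set."""

    mins: np.ndarray
    maxs: np.ndarray
    schema_id: str = SCHEMA_ID

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float).reshape(-1)
        maxs = np.asarray(self.maxs, dtype=float).reshape(-1)
        if mins.shape != maxs.shape:
            raise ValueError("mins and maxs must have equal length")
        if np.any(maxs < mins):
            raise ValueError("per-feature max must be >= min")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)

    @property
    def ranges(self) -> np.ndarray:
        return self.maxs - self.mins


def fit_scaler(features: np.ndarray | Sequence[FeatureVector]) -> ScalerParams:
    X = _as_matrix(features)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors to fit the scaler")
    return ScalerParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_scaler(
    features: np.ndarray | FeatureVector | Sequence[FeatureVector], s: ScalerParams
) -> np.ndarray:
    """(x - min) / (max - min) per feature; constant features map to 0.

    No clipping: out-of-domain inputs legitimately fall outside [0, 1] and
    are the applicability module's concern.
    """
    X = _as_matrix(features)
    if X.shape[-1] != len(s.mins):
        raise ValueError(
            f"feature width {X.shape[-1]} does not match scaler width {len(s.mins)}"
        )
    rng = s.ranges
    safe = np.where(rng == 0, 1.0, rng)
    out = (X - s.mins) / safe
    out[..., rng == 0] = 0.0
    return out


def invert_scaler(scaled: np.ndarray, s: ScalerParams) -> np.ndarray:
    """Inverse of :func:`apply_scaler` (constant features recover the min)."""
    scaled = np.asarray(scaled, dtype=float)
    return scaled * s.ranges + s.mins


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureVector):
        return features.values[None, :]
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    arr = [f.values if isinstance(f, FeatureVector) else np.asarray(f, float) for f in features]
    if not arr:
        raise ValueError("empty feature collection")
    return np.array(arr)
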