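"""Synthetic stand-in for quantum-chemical adduct formation energies.

The analytic surrogate reproduces the statistical structure a regressor must
learn from the real data: a directional attractive well centered on the
sigma-hole-aligned pose, halogen depth ordering Cl < Br < I, a steep
short-range repulsive wall, decay to zero at long range, and optional
additive Gaussian noise.  A separate ingestion path converts user-supplied
complex/monomer total energies into adduct formation energies.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .geomgen import ComplexGeometry, GridSpec, RandomSpec, enumerate_systematic, generate_random, measure_pose

__all__ = [
    "HARTREE_TO_KJMOL",
    "SurrogateParams",
    "QMEnergyTriple",
    "surrogate_energy",
    "generate_dataset",
    "adduct_energy",
    "filter_repulsive",
]

#: CODATA conversion factor.
HARTREE_TO_KJMOL = 2625.4996


@dataclasses.dataclass(frozen=True)
class SurrogateParams:
    """Analytic surrogate parameters (energies kJ/mol, lengths A)."""

    well_depth: dict = dataclasses.field(
        default_factory=lambda: {"Cl": 6.0, "Br": 9.0, "I": 13.0}
    )
    optimum_distance: dict = dataclasses.field(
        default_factory=lambda: {"Cl": 3.1, "Br": 3.2, "I": 3.3}
    )
    radial_width: float = 0.45
    lateral_width: float = 1.2
    angular_exponent: int = 2
    # repulsion_range 0.25 keeps the wall steep while leaving every
    # per-halogen optimum attractive (a longer range drowns the Cl well)
    repulsion_amplitude: float = 1e5
    repulsion_range: float = 0.25
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.well_depth
        if not (d["Cl"] < d["Br"] < d["I"]):
            raise ValueError("well depths must be ordered Cl < Br < I")
        if min(self.radial_width, self.lateral_width, self.repulsion_range) <= 0:
            raise ValueError("widths must be positive")


@dataclasses.dataclass(frozen=True)
class QMEnergyTriple:
    """Total energies of the complex and both monomers, unit-tagged."""

    e_complex: float
    e_halobenzene: float
    e_benzene: float
    unit: str = "kJ/mol"  # or "hartree"


def surrogate_energy(
    c: ComplexGeometry,
    p: SurrogateParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Evaluate the surrogate for one pose, in kJ/mol.

    Deterministic for ``noise_sd == 0``; otherwise pass an explicit ``rng``
    (or one is created from ``p.seed``).
    """
    m = measure_pose(c)
    depth = p.well_depth[c.halogen]
    d0 = p.optimum_distance[c.halogen]
    alpha_eff = np.radians(min(m.alpha, 90.0))
    attractive = (
        -depth
        * np.exp(-((m.d_plane - d0) ** 2) / (2.0 * p.radial_width**2))
        * np.cos(alpha_eff) ** p.angular_exponent
        * np.exp(-(m.r_off**2) / (2.0 * p.lateral_width**2))
    )
    diff = c.donor.coords[:, None, :] - c.acceptor.coords[None, :, :]
    rij = np.sqrt((diff * diff).sum(axis=-1))
    repulsive = p.repulsion_amplitude * np.exp(-rij / p.repulsion_range).sum()
    e = attractive + repulsive
    if p.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(p.seed)
        e += rng.normal(0.0, p.noise_sd)
    return float(e)


def generate_dataset(
    spec: GridSpec | RandomSpec,
    params: SurrogateParams,
    halogens: Sequence[str] = ("Cl", "Br", "I"),
    with_features: bool = True,
) -> pd.DataFrame:
    """One row per pose: meta columns, the 30 features, and the energy.

    Fully reproducible: pose sampling is driven by the sampler seed (random
    specs) and the noise stream by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []
    for halogen in halogens:
        if isinstance(spec, GridSpec):
            complexes: Iterable[ComplexGeometry] = enumerate_systematic(spec, halogen)
        else:
            complexes = generate_random(spec, halogen)
        for c in complexes:
            row = {"halogen": halogen, **c.meta}
            if with_features:
                fv = extract_features(c)
                row.update(zip(FEATURE_NAMES, fv.values))
            row["energy"] = surrogate_energy(c, params, rng=rng)
            rows.append(row)
    return pd.DataFrame(rows)


def adduct_energy(t: QMEnergyTriple) -> float:
    """Adduct formation energy: complex minus the sum of monomers, kJ/mol."""
    e = t.e_complex - (t.e_halobenzene + t.e_benzene)
    if t.unit == "kJ/mol":
        return float(e)
    if t.unit == "hartree":
        return float(e * HARTREE_TO_KJMOL)
    raise ValueError(f"unknown energy unit {t.unit!r}")


def adduct_energies_from_table(df: pd.DataFrame) -> pd.Series:
    """Apply :func:`adduct_energy` row-wise to an ingested energy table.

    Expected columns: id, e_complex, e_halobenzene, e_benzene, unit.
    """
    units = set(df["unit"]) if "unit" in df else {"kJ/mol"}
    if len(units) > 1:
        raise ValueError(f"mixed energy units in table: {sorted(units)}")
    out = df.apply(
        lambda r: adduct_energy(
            QMEnergyTriple(r["e_complex"], r["e_halobenzene"], r["e_benzene"], r.get("unit", "kJ/mol"))
        ),
        axis=1,
    )
    out.name = "energy"
    return out


def filter_repulsive(records, threshold: float = 10.0):
    """Drop strongly repulsive records, keeping energies <= ``threshold``.

    Accepts a DataFrame with an ``energy`` column or any iterable of
    (id, energy)-like records with an ``energy`` attribute/field.
    """
    if isinstance(records, pd.DataFrame):
        return records[records["energy"] <= threshold].reset_index(drop=True)
    return [r for r in records if _energy_of(r) <= threshold]


def _energy_of(rec) -> float:
    if hasattr(rec, "energy"):
        return float(rec.energy)
    if isinstance(rec, dict):
        return float(rec["energy"])
    return float(rec)
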