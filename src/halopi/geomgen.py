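"""Systematic and random donor pose generation over a fixed benzene acceptor.

The systematic enumerator walks the full Cartesian product of in-plane
translations, plane distances, donor spins and sigma-hole tilts; the random
sampler draws unique parameter tuples from broad ranges.  Pose construction
for both: start from the sigma-hole-optimal reference (C->X bond along -y,
halogen closest to the plane), spin about the C-X axis, tilt the C-X axis
about a named in-plane axis through the halogen, then translate the halogen
to its target point above the acceptor plane.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterator, Mapping

import numpy as np

from .molgeom import (
    Molecule,
    RigidTransform,
    apply_transform,
    build_benzene,
    build_halobenzene,
    plane_and_centroid,
    rotation_about_axis,
)

__all__ = [
    "GridSpec",
    "RandomSpec",
    "ComplexGeometry",
    "PoseMeasures",
    "TILT_AXES",
    "enumerate_systematic",
    "generate_random",
    "measure_pose",
]

#: In-plane tilt axis directions, keyed by tag.  c45 / c-45 lie at +-45
#: degrees between the x- and z-axes.
TILT_AXES: Mapping[str, np.ndarray] = {
    "x": np.array([1.0, 0.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
    "c45": np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0),
    "c-45": np.array([1.0, 0.0, -1.0]) / np.sqrt(2.0),
}


def _frange(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Parameters of the systematic pose grid (defaults: one grid quadrant,
    x,z in [0, 5] A step 0.25; d in [2.75, 4.5] A step 0.25; spins
    0/45/90/135 deg; four tilt axes each with deviations -40..40 deg step 10).
    """

    x_values: tuple[float, ...] = _frange(0.0, 5.0, 0.25)
    z_values: tuple[float, ...] = _frange(0.0, 5.0, 0.25)
    distances: tuple[float, ...] = _frange(2.75, 4.5, 0.25)
    y_rotations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    tilt_axes: tuple[str, ...] = ("x", "z", "c45", "c-45")
    tilt_deviations: tuple[float, ...] = _frange(-40.0, 40.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("x_values", "z_values", "distances", "y_rotations", "tilt_axes", "tilt_deviations"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"GridSpec.{name} must be non-empty")
        if any(d <= 0 for d in self.distances):
            raise ValueError("plane distances must be positive")
        unknown = set(self.tilt_axes) - set(TILT_AXES)
        if unknown:
            raise ValueError(f"unknown tilt axes: {sorted(unknown)}")

    @property
    def size(self) -> int:
        return (
            len(self.x_values)
            * len(self.z_values)
            * len(self.distances)
            * len(self.y_rotations)
            * len(self.tilt_axes)
            * len(self.tilt_deviations)
        )


@dataclasses.dataclass(frozen=True)
class RandomSpec:
    """Random pose sampling ranges (broad test-set defaults)."""

    n: int = 10000
    x_range: tuple[float, float] = (-5.0, 5.0)
    z_range: tuple[float, float] = (-5.0, 5.0)
    y_range: tuple[float, float] = (1.5, 5.0)
    y_rot_range: tuple[float, float] = (0.0, 360.0)
    alpha_range: tuple[float, float] = (0.0, 60.0)
    azimuth_range: tuple[float, float] = (0.0, 360.0)  # tilt direction, deg
    seed: int = 0
    uniqueness_tol: float = 1e-6
    max_attempts_factor: int = 100

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclasses.dataclass
class ComplexGeometry:
    """A posed halobenzene donor over the canonical benzene acceptor.

    The donor molecule is built lazily from ``meta`` so that plain
    enumeration (e.g. counting a full grid) stays cheap.
    """

    halogen: str
    meta: dict
    acceptor: Molecule = dataclasses.field(default_factory=build_benzene)
    _donor: Molecule | None = dataclasses.field(default=None, repr=False)

    @property
    def donor(self) -> Molecule:
        if self._donor is None:
            self._donor = _build_donor(self.halogen, self.meta)
        return self._donor


def _build_donor(halogen: str, meta: Mapping) -> Molecule:
    base = build_halobenzene(halogen)
    t = RigidTransform.identity()
    y_rot = float(meta.get("y_rot", 0.0))
    if y_rot:
        t = rotation_about_axis([0.0, 1.0, 0.0], y_rot).compose(t)
    dev = float(meta.get("tilt_dev", meta.get("alpha", 0.0)))
    if dev:
        if "tilt_axis" in meta:
            axis = TILT_AXES[meta["tilt_axis"]]
        else:  # random pose: in-plane axis at the sampled azimuth
            phi = np.radians(float(meta.get("tilt_azimuth", 0.0)))
            axis = np.array([np.cos(phi), 0.0, np.sin(phi)])
        t = rotation_about_axis(axis, dev).compose(t)
    target = np.array([meta["x"], meta.get("d", meta.get("y")), meta["z"]], dtype=float)
    t = RigidTransform(np.eye(3), target).compose(t)
    return apply_transform(base, t)


def enumerate_systematic(
    spec: GridSpec, halogen: str, dedupe_zero_tilt: bool = False
) -> Iterator[ComplexGeometry]:
    """Yield every pose of the grid in (x, z, d, y_rot, axis, dev) order.

    Each tilt axis carries its full deviation list including 0 deg, so the
    untilted pose appears once per axis; pass ``dedupe_zero_tilt=True`` to
    emit it for the first axis only.
    """
    acceptor = build_benzene()
    first_axis = spec.tilt_axes[0]
    for x, z, d, y_rot, axis, dev in itertools.product(
        spec.x_values,
        spec.z_values,
        spec.distances,
        spec.y_rotations,
        spec.tilt_axes,
        spec.tilt_deviations,
    ):
        if dedupe_zero_tilt and dev == 0.0 and axis != first_axis:
            continue
        meta = {
            "x": x,
            "z": z,
            "d": d,
            "y_rot": y_rot,
            "tilt_axis": axis,
            "tilt_dev": dev,
        }
        yield ComplexGeometry(halogen=halogen, meta=meta, acceptor=acceptor)


def generate_random(spec: RandomSpec, halogen: str) -> list[ComplexGeometry]:
    """Draw ``spec.n`` unique random poses, reproducible under ``spec.seed``.

    A fresh tuple is rejected if all six parameters agree with a previous
    one within ``uniqueness_tol``; the tilt direction (azimuth of the
    in-plane tilt axis) is sampled uniformly and recorded in meta.
    """
    rng = np.random.default_rng(spec.seed)
    acceptor = build_benzene()
    seen: set[tuple] = set()
    out: list[ComplexGeometry] = []
    decimals = max(0, int(round(-np.log10(spec.uniqueness_tol))))
    max_attempts = spec.max_attempts_factor * spec.n
    attempts = 0
    while len(out) < spec.n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {spec.n} unique pose tuples in {max_attempts} attempts"
            )
        attempts += 1
        params = (
            rng.uniform(*spec.x_range),
            rng.uniform(*spec.z_range),
            rng.uniform(*spec.y_range),
            rng.uniform(*spec.y_rot_range),
            rng.uniform(*spec.alpha_range),
            rng.uniform(*spec.azimuth_range),
        )
        key = tuple(round(p, decimals) for p in params)
        if key in seen:
            continue
        seen.add(key)
        x, z, y, y_rot, alpha, azimuth = params
        meta = {
            "x": x,
            "z": z,
            "y": y,
            "y_rot": y_rot,
            "alpha": alpha,
            "tilt_azimuth": azimuth,
        }
        out.append(ComplexGeometry(halogen=halogen, meta=meta, acceptor=acceptor))
    return out


@dataclasses.dataclass(frozen=True)
class PoseMeasures:
    """Halogen-plane distance (A), C-X tilt angle vs the plane normal (deg,
    0 = ideal sigma-hole alignment), and in-plane foot-point offset (A)."""

    d_plane: float
    alpha: float
    r_off: float


def measure_pose(c: ComplexGeometry) -> PoseMeasures:
    """Re-measure a pose against the acceptor's least-squares ring plane.

    The plane normal is oriented toward the halogen; alpha is the angle
    between the X->C bond direction and that normal, so 0 deg means the C-X
    axis points straight at the plane.
    """
    donor = c.donor
    xi = donor.single_atom("halogen")
    ci = donor.single_atom("ipso_carbon")
    xpos = donor.coords[xi]
    normal, centroid = plane_and_centroid(c.acceptor, reference_point=xpos)
    rel = xpos - centroid
    d_plane = float(np.dot(rel, normal))
    foot = xpos - d_plane * normal
    r_off = float(np.linalg.norm(foot - centroid))
    xc = donor.coords[ci] - xpos
    cosang = np.clip(np.dot(xc, normal) / np.linalg.norm(xc), -1.0, 1.0)
    alpha = float(np.degrees(np.arccos(cosang)))
    return PoseMeasures(d_plane=d_plane, alpha=alpha, r_off=r_off)
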