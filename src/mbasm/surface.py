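"""Molecular vdW-surface point sampling, featurization and medoid selection.

The molecular surface is the outermost boundary of the union of
atom-centred vdW spheres (optionally radius-scaled).  Points are laid down
per atom with Deserno's equal-area spherical lattice, points buried inside
any other atom's sphere are discarded, and each surviving point is
described by a chemical-environment vector: per element species, the sum
over that species' atoms of exp(-d^2/3) with d the point-atom distance in
Angstrom, so nearby atoms dominate.  k-means over these vectors groups
points into chemically similar patches; the member closest to each cluster
centroid (the medoid) becomes a representative interaction point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .molecule import Molecule

__all__ = [
    "SurfacePoint",
    "ChemEnvVector",
    "RepresentativePoint",
    "deserno_sphere_points",
    "map_surface",
    "featurize_point",
    "featurize_surface",
    "select_representative_points",
    "ENV_DECAY_DENOMINATOR",
    "OCCLUSION_TOL",
]

# Decay constant in exp(-d^2 / ENV_DECAY_DENOMINATOR), d in Angstrom.
ENV_DECAY_DENOMINATOR = 3.0
# Points within this of a sphere boundary count as "on" it, not inside.
OCCLUSION_TOL = 1e-6


@dataclass(eq=False)
class ChemEnvVector:
    """Per-species chemical-environment weights for one surface point."""

    species_order: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.species_order = tuple(self.species_order)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.species_order):
            raise ValueError("feature length does not match species order")
        if np.any(self.values < 0):
            raise ValueError("chemical-environment weights must be non-negative")


@dataclass(eq=False)
class SurfacePoint:
    """A point on the molecular vdW surface, attached to its parent atom."""

    position: np.ndarray
    parent_atom: int
    molecule_id: str
    feature: ChemEnvVector | None = field(default=None)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).ravel()


@dataclass(eq=False)
class RepresentativePoint:
    """Cluster medoid over surface points: one representative chemical site."""

    point: SurfacePoint
    cluster_id: int
    cluster_size: int


def deserno_sphere_points(
    n_target: int, radius: float, center: Sequence[float] = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """Quasi-uniform points on a sphere via the equal-area lattice of Deserno.

    The sphere is split into M_theta = round(pi/d) latitude bands, where
    d = sqrt(a) and a = 4*pi*r^2/n_target is the per-point area; each band
    carries a number of azimuthal points proportional to sin(theta).  Fully deterministic; the
    returned count is close to but generally not exactly ``n_target``.

    Returns an (M, 3) array of Cartesian points at distance ``radius`` from
    ``center``.
    """
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float).ravel()
    a = 4.0 * np.pi / n_target  # per-point area on the unit sphere
    d = np.sqrt(a)
    m_theta = max(1, int(round(np.pi / d)))
    d_theta = np.pi / m_theta
    d_phi = a / d_theta
    pts: list[list[float]] = []
    for m in range(m_theta):
        theta = np.pi * (m + 0.5) / m_theta
        m_phi = max(1, int(round(2.0 * np.pi * np.sin(theta) / d_phi)))
        for n in range(m_phi):
            phi = 2.0 * np.pi * n / m_phi
            pts.append(
                [
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ]
            )
    return center + radius * np.asarray(pts)


def map_surface(
    molecule: Molecule,
    points_per_atom: int = 256,
    radius_scale: float = 1.0,
) -> list[SurfacePoint]:
    """Sample the outermost union-of-spheres surface of a molecule.

    For each atom, ``points_per_atom`` Deserno points are generated on its
    (scaled) vdW sphere; a point strictly interior to any other atom's
    scaled sphere is discarded.  Points exactly on two spheres are kept.
    """
    if points_per_atom < 1:
        raise ValueError("sampling budget must be at least 1 point per atom")
    if radius_scale <= 0:
        raise ValueError(f"radius_scale must be positive, got {radius_scale}")
    scaled = radius_scale * molecule.radii
    out: list[SurfacePoint] = []
    for i in range(molecule.n_atoms):
        pts = deserno_sphere_points(points_per_atom, scaled[i], molecule.coords[i])
        others = [j for j in range(molecule.n_atoms) if j != i]
        if others:
            dists = cdist(pts, molecule.coords[others])
            keep = np.all(dists >= scaled[others] - OCCLUSION_TOL, axis=1)
        else:
            keep = np.ones(len(pts), dtype=bool)
        for p in pts[keep]:
            out.append(SurfacePoint(position=p, parent_atom=i, molecule_id=molecule.id))
    return out


def featurize_point(
    point: SurfacePoint, molecule: Molecule, species_order: Sequence[str]
) -> ChemEnvVector:
    """Chemical-environment vector of one surface point.

    ``values[s] = sum over atoms i of species s of exp(-d_i^2 / 3)`` with
    ``d_i`` the Euclidean point-atom distance in Angstrom.
    """
    species_order = tuple(species_order)
    missing = set(molecule.symbols) - set(species_order)
    if missing:
        raise ValueError(f"species {sorted(missing)} present in molecule but not in species_order")
    d2 = np.sum((molecule.coords - point.position) ** 2, axis=1)
    weights = np.exp(-d2 / ENV_DECAY_DENOMINATOR)
    values = np.zeros(len(species_order))
    symbols = np.array(molecule.symbols)
    for k, s in enumerate(species_order):
        values[k] = weights[symbols == s].sum()
    return ChemEnvVector(species_order=species_order, values=values)


def featurize_surface(
    points: Sequence[SurfacePoint], molecule: Molecule, species_order: Sequence[str]
) -> list[SurfacePoint]:
    """Attach chemical-environment vectors to every point, in place."""
    for p in points:
        p.feature = featurize_point(p, molecule, species_order)
    return list(points)


def select_representative_points(
    points: Sequence[SurfacePoint], k: int, seed: int = 0
) -> list[RepresentativePoint]:
    """Cluster featurized surface points and return one medoid per cluster.

    k-means (Lloyd, k-means++ seeding driven by ``seed``) on the feature
    vectors; the representative of each cluster is the member closest to the
    centroid in feature space, ties broken by lowest point index.  Results
    are ordered by cluster id and reproducible bit-for-bit under a fixed seed.
    """
    points = list(points)
    n = len(points)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if any(p.feature is None for p in points):
        raise RuntimeError("all points must be featurized before clustering")
    orders = {p.feature.species_order for p in points}
    if len(orders) != 1:
        raise ValueError("all points must share one species_order")
    X = np.vstack([p.feature.values for p in points])
    if k == n:
        return [
            RepresentativePoint(point=p, cluster_id=i, cluster_size=1)
            for i, p in enumerate(points)
        ]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300, tol=1e-6)
    labels = km.fit_predict(X)
    reps: list[RepresentativePoint] = []
    for cid in range(k):
        members = np.flatnonzero(labels == cid)
        dists = np.linalg.norm(X[members] - km.cluster_centers_[cid], axis=1)
        medoid = members[int(np.argmin(dists))]  # argmin -> lowest index on ties
        reps.append(
            RepresentativePoint(
                point=points[medoid], cluster_id=cid, cluster_size=len(members)
            )
        )
    return reps
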