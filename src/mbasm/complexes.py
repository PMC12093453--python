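"""Rigid-body enumeration of trial analyte-probe complexes.

Trial complexes are built by making a representative surface point of the
probe coincide with a representative surface point of the analyte, then
sweeping the probe through a systematic rotational grid about that shared
contact point.  The analyte never moves; every configuration is exactly
reconstructible from its provenance indices (analyte rep, probe rep,
rotation index) plus the two input molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from .molecule import Molecule
from .surface import RepresentativePoint

__all__ = ["Rotation", "ComplexConfiguration", "rotation_grid", "place_probe", "enumerate_trials"]

_ORTHO_TOL = 1e-10


@dataclass(eq=False)
class Rotation:
    """A proper rotation (3x3 orthogonal, det = +1) with its grid index."""

    matrix: np.ndarray
    grid_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if not np.allclose(self.matrix.T @ self.matrix, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(self.matrix) < 0:
            raise ValueError("rotation matrix is not proper (det must be +1)")


@dataclass(eq=False)
class ComplexConfiguration:
    """One placed analyte-probe pair.

    The analyte pose is the identity; the probe is rotated about its contact
    point and translated so the two contact points coincide.  ``contact``
    stores (analyte rep index, probe rep index, rotation grid index).
    """

    analyte: Molecule
    probe: Molecule
    rotation: Rotation
    translation: np.ndarray
    contact: tuple[int, int, int]
    contact_point: np.ndarray
    placed_probe_coords: np.ndarray
    descriptor: np.ndarray | None = field(default=None)

    @property
    def config_id(self) -> str:
        a, b, r = self.contact
        return f"a{a}_b{b}_r{r}"


def rotation_grid(n_per_axis: int) -> list[Rotation]:
    """Systematic orientation grid from an Euler zyz lattice.

    alpha, gamma in {2*pi*i/n : i < n}; beta in {pi*(j+0.5)/n : j < n}, the
    half-step offset avoiding the gimbal-degenerate poles.  Duplicate
    rotations (Frobenius distance < 1e-8) are removed; ordering is
    deterministic (lexicographic in the Euler indices).
    """
    if n_per_axis < 1:
        raise ValueError(f"n_per_axis must be >= 1, got {n_per_axis}")
    n = n_per_axis
    mats: list[np.ndarray] = []
    for i in range(n):
        alpha = 2.0 * np.pi * i / n
        for j in range(n):
            beta = np.pi * (j + 0.5) / n
            for k in range(n):
                gamma = 2.0 * np.pi * k / n
                m = ScipyRotation.from_euler("zyz", [alpha, beta, gamma]).as_matrix()
                if not any(np.abs(m - prev).max() < 1e-8 for prev in mats):
                    mats.append(m)
    return [Rotation(matrix=m, grid_index=idx) for idx, m in enumerate(mats)]


def place_probe(
    analyte: Molecule,
    analyte_rep: RepresentativePoint,
    probe: Molecule,
    probe_rep: RepresentativePoint,
    rotation: Rotation,
    contact_indices: tuple[int, int] | None = None,
) -> ComplexConfiguration:
    """Place the probe against the analyte at two representative points.

    The probe is rotated about its own contact point, then translated so the
    contact point lands exactly on the analyte's contact point:
    ``x' = R (x - p_probe) + p_analyte``.
    """
    if analyte_rep.point.molecule_id != analyte.id:
        raise ValueError("analyte representative point does not belong to the analyte")
    if probe_rep.point.molecule_id != probe.id:
        raise ValueError("probe representative point does not belong to the probe")
    ap = analyte_rep.point.position
    pp = probe_rep.point.position
    R = rotation.matrix
    placed = (R @ (probe.coords - pp).T).T + ap
    translation = ap - R @ pp
    a_idx, b_idx = contact_indices if contact_indices is not None else (
        analyte_rep.cluster_id,
        probe_rep.cluster_id,
    )
    return ComplexConfiguration(
        analyte=analyte,
        probe=probe,
        rotation=rotation,
        translation=translation,
        contact=(a_idx, b_idx, rotation.grid_index),
        contact_point=ap.copy(),
        placed_probe_coords=placed,
    )


def enumerate_trials(
    analyte: Molecule,
    reps_a: Sequence[RepresentativePoint],
    probe: Molecule,
    reps_b: Sequence[RepresentativePoint],
    rotations: Sequence[Rotation],
) -> Iterator[ComplexConfiguration]:
    """Lazily yield all |reps_a| x |reps_b| x |rotations| trial complexes.

    Deterministic lexicographic order (analyte rep, probe rep, rotation);
    constant memory beyond the configuration being yielded.
    """
    if not reps_a or not reps_b or not rotations:
        raise ValueError("representative lists and rotation grid must be nonempty")
    for ia, ra in enumerate(reps_a):
        for ib, rb in enumerate(reps_b):
            for rot in rotations:
                yield place_probe(analyte, ra, probe, rb, rot, contact_indices=(ia, ib))
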