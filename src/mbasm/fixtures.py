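"""Deterministic toy-molecule generators.

These stand-ins let the whole pipeline run and be tested offline: rigid,
chemically plausible geometries for an amino-acid-like analyte
(``glycine_like``) and a vinyl-acid monomer (``methacrylic_like``), plus
degenerate shapes (single atom, diatomic, planar triatomic) and a seeded
random cluster for stress tests.
"""

from __future__ import annotations

import numpy as np

from .molecule import Molecule, VdwRadiusTable

__all__ = ["make_fixture", "FIXTURE_KINDS"]

# Neutral glycine, H2N-CH2-COOH: amine N-H donors, carbonyl/hydroxyl O acceptors.
_GLYCINE = [
    ("N", (-1.083, 0.296, -0.153)),
    ("H", (-1.866, -0.331, -0.054)),
    ("H", (-1.145, 1.034, 0.534)),
    ("C", (0.150, -0.452, 0.056)),
    ("H", (0.197, -0.870, 1.063)),
    ("H", (0.241, -1.285, -0.648)),
    ("C", (1.343, 0.468, -0.118)),
    ("O", (1.330, 1.636, 0.180)),
    ("O", (2.456, -0.128, -0.568)),
    ("H", (3.161, 0.520, -0.618)),
]

# Methacrylic acid, CH2=C(CH3)-COOH: O-H donor, C=O acceptor.
_METHACRYLIC = [
    ("C", (0.000, 0.000, 0.000)),
    ("C", (-1.310, 0.360, 0.000)),
    ("H", (-2.100, -0.380, 0.000)),
    ("H", (-1.590, 1.400, 0.000)),
    ("C", (0.350, -1.450, 0.000)),
    ("H", (1.430, -1.590, 0.000)),
    ("H", (-0.080, -1.950, 0.870)),
    ("H", (-0.080, -1.950, -0.870)),
    ("C", (1.050, 1.050, 0.000)),
    ("O", (0.800, 2.240, 0.000)),
    ("O", (2.330, 0.640, 0.000)),
    ("H", (2.940, 1.390, 0.000)),
]

FIXTURE_KINDS = (
    "single_atom",
    "diatomic",
    "planar_triatomic",
    "glycine_like",
    "methacrylic_like",
    "random_cluster",
)


def make_fixture(
    kind: str,
    params: dict | None = None,
    seed: int = 0,
    radius_table: VdwRadiusTable | None = None,
) -> Molecule:
    """Build a deterministic fixture molecule.

    Parameters
    ----------
    kind
        One of :data:`FIXTURE_KINDS`.
    params
        Kind-specific options: ``element`` (single_atom), ``elements`` and
        ``bond`` in Angstrom (diatomic), ``elements``/``bond``/``angle_deg``
        (planar_triatomic), ``n``/``element``/``box`` (random_cluster).
    seed
        Seed for ``random_cluster``; ignored by the rigid kinds.
    """
    params = dict(params or {})
    if kind == "single_atom":
        element = params.get("element", "C")
        symbols, coords = [element], [[0.0, 0.0, 0.0]]
    elif kind == "diatomic":
        elements = params.get("elements", ["O", "O"])
        bond = float(params.get("bond", 1.2))
        symbols = list(elements)
        coords = [[0.0, 0.0, 0.0], [bond, 0.0, 0.0]]
    elif kind == "planar_triatomic":
        elements = params.get("elements", ["O", "C", "O"])
        bond = float(params.get("bond", 1.16))
        angle = np.deg2rad(float(params.get("angle_deg", 120.0)))
        symbols = list(elements)
        coords = [
            [bond, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [bond * np.cos(angle), bond * np.sin(angle), 0.0],
        ]
    elif kind == "glycine_like":
        symbols = [s for s, _ in _GLYCINE]
        coords = [list(c) for _, c in _GLYCINE]
    elif kind == "methacrylic_like":
        symbols = [s for s, _ in _METHACRYLIC]
        coords = [list(c) for _, c in _METHACRYLIC]
    elif kind == "random_cluster":
        n = int(params.get("n", 8))
        element = params.get("element", "C")
        box = float(params.get("box", 6.0))
        rng = np.random.default_rng(seed)
        symbols = [element] * n
        coords = (rng.random((n, 3)) - 0.5) * box
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    mol = Molecule.from_symbols_coords(
        symbols, np.asarray(coords, dtype=float), name=kind, radius_table=radius_table
    )
    mol.id = f"{kind}"
    return mol
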