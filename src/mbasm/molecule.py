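"""Rigid-molecule data model, van der Waals radius table, and structure I/O.

Molecules are treated as rigid bodies throughout the package: element
symbols, Cartesian coordinates in Angstrom, and one vdW radius per atom,
resolved from a pinned radius table at load time.  Supported formats are
XYZ (read and write, multi-frame write for ensembles) and a restricted
single-molecule PDB read.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Molecule",
    "VdwRadiusTable",
    "MoleculeError",
    "StructureParseError",
    "UnknownElementError",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "read_pdb",
]


class MoleculeError(ValueError):
    """Invalid molecule contents (empty, non-finite coordinates, ...)."""


class StructureParseError(ValueError):
    """Malformed structure file; the message names the offending line."""


class UnknownElementError(ValueError):
    """Element symbol absent from the active vdW radius table."""


@dataclass(frozen=True)
class VdwRadiusTable:
    """Element -> vdW radius (Angstrom) mapping with a provenance label.

    The default table is the Bondi (1964) set shipped as a plain-text
    package resource; any two-column ``symbol radius`` file can replace it.
    """

    radii: dict[str, float]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        for sym, r in self.radii.items():
            if not (0.5 < r < 3.0):
                raise ValueError(
                    f"vdW radius for {sym!r} out of plausible range (0.5, 3.0): {r}"
                )

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.radii

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.radii[symbol]
        except KeyError:
            raise UnknownElementError(
                f"element {symbol!r} not in vdW radius table ({self.provenance})"
            ) from None

    @classmethod
    def from_file(cls, path: str | Path, provenance: str | None = None) -> "VdwRadiusTable":
        radii: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise StructureParseError(
                    f"{path}: line {lineno}: expected 'symbol radius', got {line!r}"
                )
            radii[parts[0]] = float(parts[1])
        return cls(radii=radii, provenance=provenance or str(path))

    @classmethod
    def default(cls) -> "VdwRadiusTable":
        text = resources.files("mbasm.data").joinpath("vdw_bondi.txt").read_text()
        radii: dict[str, float] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                sym, val = line.split()
                radii[sym] = float(val)
        return cls(radii=radii, provenance="Bondi (1964)")


@dataclass(eq=False)
class Molecule:
    """A rigid molecule: symbols, Cartesian coordinates (A), vdW radii (A)."""

    name: str
    symbols: tuple[str, ...]
    coords: np.ndarray
    radii: np.ndarray
    id: str = field(default="")

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        n = len(self.symbols)
        if n < 1:
            raise MoleculeError("molecule must contain at least one atom")
        if self.coords.shape != (n, 3) or self.radii.shape != (n,):
            raise MoleculeError(
                f"inconsistent sizes: {n} symbols, {self.coords.shape[0]} coordinates, "
                f"{self.radii.shape[0]} radii"
            )
        if not np.all(np.isfinite(self.coords)):
            raise MoleculeError("non-finite coordinates")
        if not np.all(self.radii > 0):
            raise MoleculeError("all vdW radii must be positive")
        if not self.id:
            # Content-derived id keeps manifests reproducible across runs.
            digest = hashlib.sha1(
                "|".join(self.symbols).encode() + np.round(self.coords, 8).tobytes()
            ).hexdigest()[:8]
            self.id = f"{self.name}-{digest}"

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def geometric_center(self) -> np.ndarray:
        """Unweighted mean of the atomic coordinates."""
        return self.coords.mean(axis=0)

    @property
    def species(self) -> tuple[str, ...]:
        """Sorted unique element symbols."""
        return tuple(sorted(set(self.symbols)))

    @classmethod
    def from_symbols_coords(
        cls,
        symbols: Sequence[str],
        coords: np.ndarray,
        name: str = "molecule",
        radius_table: VdwRadiusTable | None = None,
    ) -> "Molecule":
        table = radius_table or VdwRadiusTable.default()
        radii = np.array([table[s] for s in symbols], dtype=float)
        return cls(name=name, symbols=tuple(symbols), coords=coords, radii=radii)


def _parse_xyz_frame(lines: list[str], start: int, path: str) -> tuple[Molecule | None, int]:
    """Parse one XYZ frame starting at ``lines[start]``; returns (frame, next_index)."""
    i = start
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines):
        return None, i
    count_line = lines[i].strip()
    try:
        n = int(count_line)
    except ValueError:
        raise StructureParseError(
            f"{path}: line {i + 1}: expected integer atom count, got {count_line!r}"
        ) from None
    if n < 1:
        raise StructureParseError(f"{path}: line {i + 1}: atom count must be >= 1, got {n}")
    comment = lines[i + 1].rstrip("\n") if i + 1 < len(lines) else ""
    atom_lines = lines[i + 2 : i + 2 + n]
    if len(atom_lines) < n:
        raise StructureParseError(
            f"{path}: line {i + 1}: atom count {n} but only {len(atom_lines)} atom lines follow"
        )
    symbols: list[str] = []
    coords: list[list[float]] = []
    for j, line in enumerate(atom_lines):
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(
                f"{path}: line {i + 3 + j}: expected 'symbol x y z', got {line.rstrip()!r}"
            )
        symbols.append(parts[0])
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise StructureParseError(
                f"{path}: line {i + 3 + j}: malformed coordinate in {line.rstrip()!r}"
            ) from None
    return (symbols, coords, comment), i + 2 + n  # type: ignore[return-value]


def read_xyz(path: str | Path, radius_table: VdwRadiusTable | None = None) -> Molecule:
    """Read a single-frame XYZ file into a :class:`Molecule`.

    Radii are resolved from ``radius_table`` (default: packaged Bondi set);
    an element missing from the table raises :class:`UnknownElementError`.
    """
    frames = read_xyz_frames(path, radius_table)
    return frames[0]


def read_xyz_frames(
    path: str | Path, radius_table: VdwRadiusTable | None = None
) -> list[Molecule]:
    """Read a (possibly multi-frame) XYZ file into a list of molecules."""
    path = Path(path)
    lines = path.read_text().splitlines()
    table = radius_table or VdwRadiusTable.default()
    out: list[Molecule] = []
    i = 0
    while True:
        frame, i = _parse_xyz_frame(lines, i, str(path))
        if frame is None:
            break
        symbols, coords, comment = frame
        name = comment.strip() or path.stem
        out.append(
            Molecule.from_symbols_coords(symbols, np.array(coords), name=name, radius_table=table)
        )
    if not out:
        raise StructureParseError(f"{path}: no frames found")
    return out


def write_xyz(
    molecules: Molecule | Iterable[Molecule],
    path: str | Path,
    comments: Sequence[str] | None = None,
    precision: int = 6,
) -> None:
    """Write one molecule or an ensemble as (multi-frame) XYZ.

    For ensembles each frame's comment line carries the per-frame comment
    (configuration id / descriptor provenance) when ``comments`` is given,
    otherwise the molecule name.
    """
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    molecules = list(molecules)
    lines: list[str] = []
    for k, mol in enumerate(molecules):
        comment = comments[k] if comments is not None else mol.name
        lines.append(str(mol.n_atoms))
        lines.append(comment)
        for sym, (x, y, z) in zip(mol.symbols, mol.coords):
            lines.append(f"{sym:<3s} {x:> 15.{precision}f} {y:> 15.{precision}f} {z:> 15.{precision}f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path, radius_table: VdwRadiusTable | None = None) -> Molecule:
    """Read a small single-model, single-chain molecule from a PDB file.

    Only ATOM/HETATM coordinates and the element column are used.  Multi-model
    or multi-chain files are rejected: the pipeline operates on small rigid
    molecules, not full proteins.
    """
    import gemmi

    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) != 1:
        raise StructureParseError(f"{path}: expected a single model, found {len(st)}")
    model = st[0]
    chains = list(model)
    if len(chains) != 1:
        raise StructureParseError(f"{path}: expected a single chain, found {len(chains)}")
    symbols: list[str] = []
    coords: list[list[float]] = []
    for residue in chains[0]:
        for atom in residue:
            symbols.append(atom.element.name)
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not symbols:
        raise StructureParseError(f"{path}: no atoms found")
    return Molecule.from_symbols_coords(
        symbols, np.array(coords), name=path.stem, radius_table=radius_table
    )
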