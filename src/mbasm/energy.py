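"""Binding-energy bookkeeping for externally computed total energies.

This module never runs a quantum-chemistry code.  It converts component
total energies (hartree) into binding energies, aggregates per-pair minima
into the screening matrix used to rank functional monomers, writes
single-job DFT input files (B3LYP/TZVP, CPCM water, tight convergence),
and parses final single-point energies back out of output files.

Sign convention: ``delta_E = E_complex - (E_analyte + E_probe)`` in
kcal/mol, so a negative value means the complex is more stable than its
separated components - more favorable binding is more negative.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .complexes import ComplexConfiguration
from .molecule import Molecule

__all__ = [
    "HARTREE_TO_KCAL",
    "EnergyRecord",
    "BindingMatrix",
    "binding_energy",
    "aggregate_matrix",
    "write_qm_input",
    "parse_energy_output",
    "read_energy_table",
]

HARTREE_TO_KCAL = 627.5094740631

_DEFAULT_QM_SETTINGS = {
    "charge": 0,
    "multiplicity": 1,
    "functional": "B3LYP",
    "basis": "TZVP",
    "solvent_model": "CPCM(water)",
    "convergence": "TightSCF TightOpt",
    "job": "Opt",
}


def binding_energy(e_complex: float, e_analyte: float, e_probe: float) -> float:
    """Binding energy in kcal/mol from component total energies in hartree.

    ``delta_E = 627.5094740631 * (E_complex - E_analyte - E_probe)``;
    negative iff the complex is below its separated parts.
    """
    for name, e in (("E_complex", e_complex), ("E_analyte", e_analyte), ("E_probe", e_probe)):
        if not math.isfinite(e):
            raise ValueError(f"{name} must be finite, got {e}")
    return HARTREE_TO_KCAL * (e_complex - e_analyte - e_probe)


@dataclass
class EnergyRecord:
    """Component total energies (hartree) and binding energy for one complex."""

    complex_id: str
    analyte: str
    probe: str
    e_complex: float
    e_analyte: float
    e_probe: float
    delta_e: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_e = binding_energy(self.e_complex, self.e_analyte, self.e_probe)


@dataclass
class BindingMatrix:
    """Per-(analyte, probe) minimum binding energies in kcal/mol.

    Backed by a DataFrame with analyte rows and probe columns; pairs without
    records are NaN (flagged absent, never zero-filled).
    """

    table: pd.DataFrame

    def min_delta_e(self, analyte: str, probe: str) -> float:
        return float(self.table.loc[analyte, probe])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.6f")


def aggregate_matrix(records: Sequence[EnergyRecord]) -> BindingMatrix:
    """Minimum delta_E per (analyte, probe) pair - the most stable complex.

    Duplicate complex ids are an error; missing pairs stay NaN.
    """
    records = list(records)
    if not records:
        raise ValueError("record list is empty")
    ids = [r.complex_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate complex_id(s): {dupes}")
    analytes = sorted({r.analyte for r in records})
    probes = sorted({r.probe for r in records})
    table = pd.DataFrame(np.nan, index=analytes, columns=probes, dtype=float)
    for r in records:
        cell = table.loc[r.analyte, r.probe]
        table.loc[r.analyte, r.probe] = r.delta_e if np.isnan(cell) else min(cell, r.delta_e)
    return BindingMatrix(table=table)


def _structure_atoms(obj: ComplexConfiguration | Molecule) -> list[tuple[str, np.ndarray]]:
    if isinstance(obj, Molecule):
        return list(zip(obj.symbols, obj.coords))
    atoms = list(zip(obj.analyte.symbols, obj.analyte.coords))
    atoms += list(zip(obj.probe.symbols, obj.placed_probe_coords))
    return atoms


def write_qm_input(
    obj: ComplexConfiguration | Molecule,
    path: str | Path,
    settings: dict | None = None,
) -> None:
    """Write a single-job DFT input for a molecule or placed complex.

    The keyword line requests B3LYP, the TZVP basis, implicit water via
    CPCM, tight SCF and geometry convergence, and a geometry optimization;
    coordinates are written in Angstrom to 6 decimals.  ``settings`` may
    override charge, multiplicity, functional, basis, solvent_model,
    convergence or job; any other key is an error.
    """
    merged = dict(_DEFAULT_QM_SETTINGS)
    for key, val in (settings or {}).items():
        if key not in merged:
            raise ValueError(f"unknown setting {key!r}; valid keys: {sorted(merged)}")
        merged[key] = val
    atoms = _structure_atoms(obj)
    lines = [
        f"! {merged['functional']} {merged['basis']} {merged['solvent_model']} "
        f"{merged['convergence']} {merged['job']}",
        f"* xyz {merged['charge']} {merged['multiplicity']}",
    ]
    for sym, (x, y, z) in atoms:
        lines.append(f"{sym:<3s} {x:> 13.6f} {y:> 13.6f} {z:> 13.6f}")
    lines.append("*")
    Path(path).write_text("\n".join(lines) + "\n")


_ENERGY_RE = re.compile(r"FINAL SINGLE POINT ENERGY\s+(\S+)")


def parse_energy_output(path: str | Path) -> float:
    """Extract the last final single-point energy (hartree) from an output file."""
    path = Path(path)
    energy: float | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        m = _ENERGY_RE.search(line)
        if m:
            try:
                energy = float(m.group(1))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: malformed energy value {m.group(1)!r}"
                ) from None
    if energy is None:
        raise ValueError(f"{path}: no 'FINAL SINGLE POINT ENERGY' line found")
    return energy


def read_energy_table(path: str | Path) -> list[EnergyRecord]:
    """Read a CSV of component energies into records.

    Required columns: complex_id, analyte, probe, E_complex, E_analyte,
    E_probe (hartree).  delta_E is recomputed, never trusted from the file.
    """
    df = pd.read_csv(path)
    required = ["complex_id", "analyte", "probe", "E_complex", "E_analyte", "E_probe"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        EnergyRecord(
            complex_id=str(row.complex_id),
            analyte=str(row.analyte),
            probe=str(row.probe),
            e_complex=float(row.E_complex),
            e_analyte=float(row.E_analyte),
            e_probe=float(row.E_probe),
        )
        for row in df.itertuples(index=False)
    ]
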