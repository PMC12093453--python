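"""End-to-end orchestration: map -> bind -> filter -> extract -> report.

One :class:`PipelineConfig` holds every tunable; :func:`run_pipeline`
executes the full chain on an analyte/probe pair and writes the ensemble
(multi-frame XYZ), a per-configuration manifest (CSV), a filter report and
a reproducibility record.  A single global seed fans out to per-stage
seeds so stages can be rerun in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .complexes import enumerate_trials, rotation_grid
from .extraction import RepresentativeEnsemble, extract_representatives
from .filtering import FilterParams, FilterReport, run_filters
from .molecule import Molecule, VdwRadiusTable, read_pdb, read_xyz, write_xyz
from .surface import featurize_surface, map_surface, select_representative_points

__all__ = ["PipelineConfig", "RunResult", "PipelineStageError", "run_pipeline", "load_molecule"]

logger = logging.getLogger("mbasm")


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults.

    sigma (overlap scale) and distinctness_threshold (Angstrom) carry the
    values found optimal for monomer-analyte screening; the remaining
    parameters control sampling resolution and ensemble size.
    """

    points_per_atom: int = 256
    radius_scale: float = 1.0
    k_surface: int = 8
    rotation_n_per_axis: int = 6
    sigma: float = 0.5
    distinctness_threshold: float = 0.08
    k_extract: int = 24
    seed: int = 0
    species_order: tuple[str, ...] | None = None
    radius_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.points_per_atom < 1:
            raise ValueError("points_per_atom must be >= 1")
        if self.radius_scale <= 0:
            raise ValueError("radius_scale must be positive")
        if self.k_surface < 1:
            raise ValueError("k_surface must be >= 1")
        if self.rotation_n_per_axis < 1:
            raise ValueError("rotation_n_per_axis must be >= 1")
        if not (0.0 < self.sigma <= 1.0):
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")
        if self.distinctness_threshold <= 0:
            raise ValueError("distinctness_threshold must be positive")
        if self.k_extract < 1:
            raise ValueError("k_extract must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.species_order is not None:
            self.species_order = tuple(self.species_order)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        offsets = {"surface_analyte": 1, "surface_probe": 2, "extract": 3, "embed": 4}
        return (self.seed * 1000003 + offsets[stage]) % (2**31)

    def radius_table(self) -> VdwRadiusTable:
        if self.radius_table_path:
            return VdwRadiusTable.from_file(self.radius_table_path)
        return VdwRadiusTable.default()

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["species_order"] = list(self.species_order) if self.species_order else None
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunResult:
    """Outputs of one pipeline run."""

    ensemble: RepresentativeEnsemble
    report: FilterReport
    config: PipelineConfig
    manifest_path: Path | None = None
    ensemble_path: Path | None = None
    n_reps_analyte: int = 0
    n_reps_probe: int = 0
    n_rotations: int = 0


def load_molecule(path: str | Path, radius_table: VdwRadiusTable | None = None) -> Molecule:
    """Load an XYZ or PDB structure file by extension."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return read_pdb(path, radius_table)
    return read_xyz(path, radius_table)


def _manifest_rows(ensemble: RepresentativeEnsemble) -> list[str]:
    header = (
        "config_id,cluster_id,a_rep,b_rep,rot_index,"
        "d1,d2,d3,d4,d5,d6,d7,d8,d9"
    )
    rows = [header]
    for cid, cfg in enumerate(ensemble.members):
        a, b, r = cfg.contact
        desc = ",".join(f"{v:.10f}" for v in cfg.descriptor)
        rows.append(f"{cfg.config_id},{cid},{a},{b},{r},{desc}")
    return rows


def run_pipeline(
    analyte: Molecule | str | Path,
    probe: Molecule | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Run the full screening chain on one analyte/probe pair.

    Surface mapping and representative-point selection run on both
    molecules; all rep-pair x rotation trials are enumerated, filtered for
    steric overlap and geometric distinctness, and the survivors reduced to
    a medoid ensemble of at most ``k_extract`` members.  With ``outdir``
    set, writes ensemble.xyz, manifest.csv, report.txt and run.yaml.
    Identical (inputs, config, seed) give identical outputs.
    """
    config = config or PipelineConfig()
    table = config.radius_table()
    if not isinstance(analyte, Molecule):
        analyte = load_molecule(analyte, table)
    if not isinstance(probe, Molecule):
        probe = load_molecule(probe, table)
    species = config.species_order or tuple(sorted(set(analyte.symbols) | set(probe.symbols)))

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc

    reps = {}
    for label, mol in (("analyte", analyte), ("probe", probe)):
        points = stage(f"map_surface:{label}", map_surface, mol, config.points_per_atom, config.radius_scale)
        stage(f"featurize:{label}", featurize_surface, points, mol, species)
        k = min(config.k_surface, len(points))
        reps[label] = stage(
            f"representative_points:{label}",
            select_representative_points,
            points,
            k,
            config.stage_seed(f"surface_{label}"),
        )
        logger.info("%s: %d surface points -> %d representative points", label, len(points), k)

    rotations = stage("rotation_grid", rotation_grid, config.rotation_n_per_axis)
    trials = enumerate_trials(analyte, reps["analyte"], probe, reps["probe"], rotations)
    retained, report = stage(
        "filters", run_filters, trials, FilterParams(config.sigma, config.distinctness_threshold)
    )
    logger.info(
        "filters: generated=%d overlap_rejected=%d duplicate_rejected=%d retained=%d",
        report.generated, report.overlap_rejected, report.duplicate_rejected, report.retained,
    )
    if retained:
        ensemble = stage(
            "extract", extract_representatives, retained, config.k_extract,
            config.stage_seed("extract"),
        )
    else:
        logger.warning("no configuration survived filtering; ensemble is empty")
        ensemble = RepresentativeEnsemble(
            members=[], cluster_labels=np.empty(0, dtype=int), k=0,
            seed=config.stage_seed("extract"), inertia=0.0,
        )
    logger.info("extraction: %d retained -> %d representatives", report.retained, len(ensemble.members))

    result = RunResult(
        ensemble=ensemble,
        report=report,
        config=config,
        n_reps_analyte=len(reps["analyte"]),
        n_reps_probe=len(reps["probe"]),
        n_rotations=len(rotations),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = []
        comments = []
        for cfg in ensemble.members:
            symbols = analyte.symbols + probe.symbols
            coords = np.vstack([analyte.coords, cfg.placed_probe_coords])
            radii = np.concatenate([analyte.radii, probe.radii])
            frames.append(
                Molecule(name=cfg.config_id, symbols=symbols, coords=coords, radii=radii,
                         id=f"complex-{cfg.config_id}")
            )
            comments.append(
                f"{cfg.config_id} analyte={analyte.name} probe={probe.name} "
                f"contact=a{cfg.contact[0]}/b{cfg.contact[1]}/r{cfg.contact[2]}"
            )
        write_xyz(frames, outdir / "ensemble.xyz", comments=comments)
        (outdir / "manifest.csv").write_text("\n".join(_manifest_rows(ensemble)) + "\n")
        (outdir / "report.txt").write_text(report.as_text())
        record = asdict(config)
        record["species_order"] = list(species)
        record["package_version"] = __version__
        record["analyte"] = analyte.name
        record["probe"] = probe.name
        (outdir / "run.yaml").write_text(yaml.safe_dump(record, sort_keys=True))
        result.manifest_path = outdir / "manifest.csv"
        result.ensemble_path = outdir / "ensemble.xyz"
    return result
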