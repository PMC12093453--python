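"""Steric-overlap rejection and near-duplicate collapse of trial complexes.

Two filters run in sequence over the enumeration stream:

1. *Non-overlap*: a configuration is rejected if any cross-molecule atom
   pair sits closer than sigma times the sum of the pair's vdW radii
   (strict inequality; sigma defaults to 0.5, which tolerates the partial
   interpenetration the contact-point alignment necessarily creates).
2. *Distinctness*: each survivor is summarised by a 9-component geometric
   descriptor - the concatenated geometric centers of analyte and placed
   probe plus the shared contact point, all in Angstrom - and accepted
   greedily only if its descriptor lies further than a threshold (default
   0.08) from every previously accepted descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .complexes import ComplexConfiguration

__all__ = [
    "FilterParams",
    "FilterReport",
    "has_overlap",
    "descriptor",
    "distinctness_filter",
    "run_filters",
]


@dataclass
class FilterParams:
    """Tunables of the two filters: overlap scale sigma and the
    distinctness threshold in Angstrom."""

    sigma: float = 0.5
    distinctness_threshold: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma <= 1.0):
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")
        if self.distinctness_threshold <= 0:
            raise ValueError(
                f"distinctness_threshold must be positive, got {self.distinctness_threshold}"
            )


@dataclass
class FilterReport:
    """Stream accounting: generated = overlap_rejected + duplicate_rejected + retained."""

    generated: int = 0
    overlap_rejected: int = 0
    duplicate_rejected: int = 0
    retained: int = 0

    def as_text(self) -> str:
        return (
            f"generated          {self.generated}\n"
            f"overlap_rejected   {self.overlap_rejected}\n"
            f"duplicate_rejected {self.duplicate_rejected}\n"
            f"retained           {self.retained}\n"
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "generated": self.generated,
            "overlap_rejected": self.overlap_rejected,
            "duplicate_rejected": self.duplicate_rejected,
            "retained": self.retained,
        }


def _coords_overlap(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
    sigma: float,
) -> bool:
    """True iff some cross pair has distance strictly below sigma*(r_i + r_j)."""
    d = cdist(coords_a, coords_b)
    limit = sigma * (radii_a[:, None] + radii_b[None, :])
    return bool(np.any(d < limit))


def has_overlap(config: ComplexConfiguration, sigma: float = 0.5) -> bool:
    """Steric clash check between the fixed analyte and the placed probe.

    A pair exactly at sigma*(r_i + r_j) does not count as overlapping.
    """
    return _coords_overlap(
        config.analyte.coords,
        config.analyte.radii,
        config.placed_probe_coords,
        config.probe.radii,
        sigma,
    )


def descriptor(config: ComplexConfiguration) -> np.ndarray:
    """9-vector [analyte center, placed-probe center, contact point] in Angstrom.

    Geometric centers are unweighted means of atomic coordinates.  The
    result is also cached on the configuration.
    """
    desc = np.concatenate(
        [
            config.analyte.coords.mean(axis=0),
            config.placed_probe_coords.mean(axis=0),
            config.contact_point,
        ]
    )
    config.descriptor = desc
    return desc


class _DescriptorBank:
    """Accepted descriptors with amortized O(1) growth and vectorized queries."""

    def __init__(self, dim: int = 9):
        self._buf = np.empty((64, dim))
        self._n = 0

    def __len__(self) -> int:
        return self._n

    def add(self, desc: np.ndarray) -> None:
        if self._n == len(self._buf):
            self._buf = np.vstack([self._buf, np.empty_like(self._buf)])
        self._buf[self._n] = desc
        self._n += 1

    def all_further_than(self, desc: np.ndarray, threshold: float) -> bool:
        if self._n == 0:
            return True
        d2 = np.sum((self._buf[: self._n] - desc) ** 2, axis=1)
        return bool(np.all(d2 > threshold * threshold))


def distinctness_filter(
    configs: Iterable[ComplexConfiguration], threshold: float = 0.08
) -> list[ComplexConfiguration]:
    """Greedy sequential duplicate collapse in stream order.

    The first configuration is accepted; each later one is accepted iff its
    descriptor's Euclidean distance to EVERY previously accepted descriptor
    strictly exceeds ``threshold``.  Hence all pairwise distances among
    retained descriptors exceed the threshold.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    retained: list[ComplexConfiguration] = []
    bank = _DescriptorBank()
    for cfg in configs:
        desc = cfg.descriptor if cfg.descriptor is not None else descriptor(cfg)
        if bank.all_further_than(desc, threshold):
            retained.append(cfg)
            bank.add(desc)
    return retained


def run_filters(
    configs: Iterable[ComplexConfiguration], params: FilterParams | None = None
) -> tuple[list[ComplexConfiguration], FilterReport]:
    """Overlap filter then distinctness filter, streaming, with accounting.

    Overlap-rejected configurations never reach the distinctness stage.
    """
    params = params or FilterParams()
    report = FilterReport()
    retained: list[ComplexConfiguration] = []
    bank = _DescriptorBank()
    for cfg in configs:
        report.generated += 1
        if has_overlap(cfg, params.sigma):
            report.overlap_rejected += 1
            continue
        desc = descriptor(cfg)
        if not bank.all_further_than(desc, params.distinctness_threshold):
            report.duplicate_rejected += 1
            continue
        retained.append(cfg)
        bank.add(desc)
    report.retained = len(retained)
    return retained, report
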