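# Methods

## Model and assumptions

Molecules are rigid bodies: fixed element symbols, Cartesian coordinates in
Å, and one van der Waals radius per atom. No conformational sampling, bond
perception, protonation assignment, or electronic structure is performed —
the pipeline produces *geometric candidates* for downstream quantum-chemical
refinement, and separately does the bookkeeping on energies computed
externally. The analyte is held fixed in its input frame; all motion lives
in the probe's rigid transform, so every configuration is reconstructible
from three integers (analyte representative, probe representative, rotation
grid index) plus the two input structures.

The van der Waals radius source is the Bondi (1964) set, shipped as a
plain-text resource and recorded in `VdwRadiusTable.provenance`. Any
two-column `symbol radius` file can replace it (`radius_table_path` in the
config); unknown elements are an error, never a silent default.

## Surface mapping

The molecular surface is the outermost boundary of the union of atom
spheres, optionally uniformly scaled (`radius_scale`, default 1.0). Per
atom, `points_per_atom` (default 256) points are generated with Deserno's
equal-area lattice: with per-point area `a = 4πr²/n` and `d = √a`, the
sphere is split into `M_θ = round(π/d)` latitude bands at
`θ_m = π(m+0.5)/M_θ`, each carrying `M_φ = round(2π sinθ / (a/d_θ))`
equally spaced azimuths. The construction is deterministic and returns a
count within a few percent of the request. A point strictly interior to any
other atom's scaled sphere — by more than the occlusion tolerance of
1e−6 Å — is discarded; points exactly on two spheres are kept.

Each surviving point is featurized per element species as
`v_s = Σ_i exp(−d_i²/3)` over atoms `i` of species `s`, `d_i` in Å. The
decay denominator 3.0 is a config constant (`ENV_DECAY_DENOMINATOR`); the
Gaussian-like decay makes the vector a soft count of nearby atoms per
species, so points over a carboxyl oxygen and points over a methyl group
land in different feature-space regions. The species order used for
featurization is the sorted union of elements over *both* molecules of a
run, so the two feature spaces are commensurate; species absent from a
molecule contribute zeros. Summation (rather than max or mean) within a
species preserves additivity — two nearby oxygens weigh twice one.

k-means (scikit-learn: Lloyd iterations, k-means++ seeding from the stage
seed, `n_init=10`, `max_iter=300`, `tol=1e−6`) groups the feature vectors
into `k_surface` clusters (default 8). The representative of each cluster
is the *medoid*: the actual member closest to the centroid in feature
space, ties broken by lowest point index. `k = n` short-circuits to the
identity selection. Representatives are always input points, never
synthetic centroids.

## Complex enumeration

The orientation grid is an Euler zyz lattice: `α, γ ∈ {2πi/n}` and
`β ∈ {π(j+0.5)/n}` with `n = rotation_n_per_axis` (default 6, giving 216
rotations). The half-step β offset avoids the gimbal-degenerate poles;
duplicate matrices (max-abs difference < 1e−8) are removed. At the default
resolution the grid's measured geodesic covering radius is ≈ 41°, below
π/3. For each (analyte representative, probe representative) pair and each
grid rotation, the probe is rotated about its own contact point and
translated so the two contact points coincide: `x′ = R(x − p_probe) +
p_analyte`. Rotating about the contact point (not the centroid) keeps the
contact constraint exact under every rotation. Enumeration is a generator
in lexicographic provenance order, constant-memory, with no randomness.

The coincidence convention deliberately creates surface interpenetration;
that is exactly what the σ filter polices. An alternative — offsetting
along surface normals — is isolated inside `place_probe` and could be
swapped without touching enumeration or filtering.

## Filtering

*Overlap*: reject iff some cross-molecule atom pair has distance strictly
less than `σ(r_i + r_j)`; σ defaults to 0.5, the value found optimal for
monomer–analyte screening. Strict inequality means a pair exactly at the
limit is not an overlap. Rejection counts are monotonically non-decreasing
in σ.

*Distinctness*: each surviving configuration is summarised by a 9-vector in
Å — analyte geometric center, placed-probe geometric center, shared
contact point (under the coincidence convention the two alignment points
collapse to one, making the three-point descriptor self-consistent).
Greedy sequential acceptance in enumeration order: accept iff the
Euclidean distance to *every* previously accepted descriptor strictly
exceeds the threshold (default 0.08, interpreted as Å since the quantity
is a distance between Å-valued vectors). Consequently, all pairwise
distances among retained descriptors exceed the threshold. Greedy order =
generation order keeps runs reproducible.

Filter accounting is conserved by construction and asserted in tests:
`generated = overlap_rejected + duplicate_rejected + retained`.

## Representative extraction

k-means on the retained pool's descriptors (same algorithmic contract as
the surface clustering), one medoid per cluster, `k_extract` default 24
per molecular pair. A screening campaign over a 20-amino-acid × 15-monomer
panel at ~8–24 per pair lands at the few-thousand-structure scale that DFT
refinement can absorb. If fewer configurations remain than `k_extract`,
all are returned; an empty retained pool yields an empty ensemble with a
logged warning rather than an error, so parameter sweeps (e.g. σ → 1)
stay comparable. The seeded t-SNE embedding (`embed_2d`, perplexity
`min(30, (n−1)/3)`) is an export for visual inspection only and carries no
downstream semantics.

## Energy bookkeeping

Total energies are exchanged in hartree and reported in kcal·mol⁻¹
(conversion constant 627.5094740631, pinned and unit-tested). The binding
energy is defined as

    ΔE = E_complex − (E_analyte + E_probe)

so ΔE < 0 iff the complex is more stable than its separated components;
per-(analyte, probe) minima over all records give the monomer-ranking
matrix, with missing pairs flagged NaN, never zero-filled. The
complex-minus-fragments orientation was chosen deliberately: the
fragments-minus-complex ordering would flip the sign and contradict the
"more negative = more favorable" convention used for reporting; this
package keeps definition and convention consistent and documents the
choice here. The input writer emits single-job B3LYP/TZVP inputs with
CPCM water and tight SCF/optimization criteria (ORCA dialect); the output
parser takes the *last* `FINAL SINGLE POINT ENERGY` in a file, matching
the final value of an optimization trace. No QM code is ever launched.

## Determinism and seeds

One global seed fans out to per-stage seeds (surface clustering per
molecule, extraction, embedding) via an affine map mod 2³¹, so stages can
be rerun in isolation. Everything else — Deserno lattice, rotation grid,
enumeration order, both filters — is deterministic by construction.
Identical inputs, config and seed reproduce the manifest and ensemble
byte-for-byte; molecule identifiers are content hashes, not process
counters, so reproducibility survives process boundaries.

## Synthetic fixtures: what they do and do not show

The packaged fixtures (`glycine_like`, an H-bond donor/acceptor amino
acid; `methacrylic_like`, a vinyl carboxylic acid monomer; plus degenerate
single-atom/diatomic/triatomic shapes and a seeded random cluster) are
rigid, chemically plausible geometries — not DFT-optimized structures.
They exercise every code path offline: union-surface occlusion,
multi-species featurization, clash-heavy enumeration, duplicate collapse,
and pool reduction (13 824 trials → 24 representatives at defaults).
They do not probe conformational flexibility, protonation states, or
charged species, and passing tests on them says nothing about the
quantitative binding ranking of real monomers — that requires the external
DFT step this package prepares inputs for.

## Problem sizes

Default test and acceptance runs use the fixture pair at full default
resolution (256 points/atom, 8 surface clusters per molecule, 216
rotations → 13 824 trials), which completes in seconds; oracle-based
checks use reduced budgets (16–96 points/atom, 200–1000 random cases)
chosen to keep brute-force reference computations exact and exhaustive.

## Known limitations

- Rigid bodies only; no induced fit, no torsional relaxation.
- The chemical-environment vector sees species counts only, not
  hybridization, charge, or aromaticity.
- The distinctness descriptor is translation-sensitive by design but blind
  to probe rotations about its own center when centers and contact
  coincide; such near-duplicates are left for the extraction clustering to
  absorb.
- PDB input is restricted to single-model, single-chain small molecules.
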