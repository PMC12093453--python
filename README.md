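# mbasm

Rigid-body surface screening of functional monomers against small analytes,
for molecularly imprinted polymer (MIP) design.

Choosing the functional monomer that binds a template molecule most strongly
is the central decision in MIP synthesis. Exhaustive quantum-chemical
evaluation of monomer–analyte binding poses is infeasible: even one pair
admits hundreds of thousands of mutual orientations. `mbasm` implements a
deterministic, chemically informed way to enumerate those poses and reduce
them to a small representative set that *is* feasible to refine with DFT:

1. **Surface mapping.** Each molecule's surface is the outermost boundary of
   the union of atom-centred van der Waals spheres. Quasi-uniform points are
   laid on each sphere with Deserno's equal-area lattice and points buried
   inside another atom's sphere are discarded. Each surviving point gets a
   chemical-environment vector: per element species *s*,
   `v_s = Σ_{i: species(i)=s} exp(−d_i²/3)` with `d_i` the point–atom distance
   in Å. k-means over these vectors groups the surface into chemically similar
   patches; the member closest to each centroid (the medoid) becomes a
   representative interaction point.
2. **Complex enumeration.** For every pair of representative points (analyte
   × probe), the probe is placed so the two points coincide, and rotated
   through a systematic Euler-grid of orientations about the contact point.
3. **Filtering.** A configuration is rejected if any cross-molecule atom pair
   sits closer than `σ·(r_i + r_j)` (default σ = 0.5), and collapsed as a
   near-duplicate if its 9-component geometric descriptor — concatenated
   geometric centers of both molecules plus the contact point — lies within
   0.08 of an already-accepted configuration (greedy, in enumeration order).
4. **Extraction.** k-means over the descriptors of the retained pool, one
   medoid per cluster: the ensemble handed to quantum-chemical refinement.
5. **Energy bookkeeping.** For externally computed total energies (hartree),
   the binding energy is `ΔE = 627.5094740631 · (E_complex − E_analyte −
   E_probe)` kcal·mol⁻¹ — more negative means more favorable — and per-pair
   minima form the monomer-ranking matrix. Single-job DFT inputs
   (B3LYP/TZVP, CPCM water, tight criteria) can be written for any structure
   or placed complex.

## Worked example

```sh
mbasm fixtures --kind glycine_like --out gly.xyz
mbasm fixtures --kind methacrylic_like --out maa.xyz
mbasm --seed 1 run gly.xyz maa.xyz --outdir out
```

prints

```
generated          13824
overlap_rejected   8339
duplicate_rejected 54
retained           5431
ensemble size: 24
```

13 824 trial complexes (8 × 8 representative-point pairs × 216 grid
rotations) were enumerated; 8 339 clashed sterically at σ = 0.5, 54 were
geometric near-duplicates, and the 5 431 survivors were reduced to a
24-member medoid ensemble — the structures one would submit to DFT geometry
optimization. `out/` contains the ensemble as multi-frame XYZ, a manifest
CSV (provenance indices and descriptors per member), the filter report, and
a `run.yaml` reproducibility record; the same seed reproduces all of them
byte-for-byte.

The same workflow is available as a library:

```python
from mbasm import PipelineConfig, make_fixture, run_pipeline
res = run_pipeline(make_fixture("glycine_like"), make_fixture("methacrylic_like"),
                   PipelineConfig(seed=1))
print(res.report.as_dict(), len(res.ensemble.members))
```

To rank monomers once DFT energies exist, put component energies in a CSV
(`complex_id,analyte,probe,E_complex,E_analyte,E_probe`, hartree) and run
`mbasm energy energies.csv --out matrix.csv`: the output matrix holds the
minimum ΔE per (analyte, monomer) pair.

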