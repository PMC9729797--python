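# osteolattice

Design, finite-element evaluation and strut-size optimization of titanium
lattice implants for large segmental bone defects, built around a
biomechanical (yield-strength) and mechanobiological (bone strain-window)
design loop:

1. **Fixtures** — a seeded, watertight synthetic mandible-segment surrogate
   (curved prism with defect region, stump cut planes, occlusal/condylar
   node sets and 2×8 muscle attachment sites), plus analytic solver
   benchmarks (cantilever, voxel patch test). No external data needed.
2. **Lattice generation** — an interior trabecular-like wireframe from
   space-filling rhombic-dodecahedron cells (5 mm pores, with a
   regular-dodecahedron option), an exterior quadrilateral grid shell traced
   on the region surface, linear gradient strut diameters (0.2–0.8 mm, thin
   at the alveolar side), retainer frames and 8 mm fixation screws (5–7 per
   side), and a Boolean graft region (voxels inside the region, outside the
   strut capsules).
3. **FE core** — 3D Timoshenko beams for struts, trilinear voxel hexahedra
   for bone/graft/disc/tooth, grounded springs + point forces for the eight
   masticatory muscle groups per side, an 800 N bite load, and rigid
   beam–continuum translation ties; von-Mises stress and equivalent strain
   recovery (microstrain).
4. **Healing-stage sweep** — three graft materials (granulation tissue
   E=0.2 MPa, immature bone 1,000 MPa, mature bone 5,000 MPa) with binned
   frequency statistics: eight stress intervals (<50 … >350 MPa) and four
   strain intervals (0–3,000 … >10,000 με).
5. **Optimizer** — deterministic fully-stressed-design resizing of hotspot
   struts until the implant maximum equivalent stress is ≤ 897 MPa (Ti6Al4V
   yield) at every stage and the fraction of graft nodes inside the
   0–3,000 με strain-adaptation window stops improving.

Units are mm–N–MPa throughout; strains are reported in microstrain.

## CLI

```sh
osteolattice all --out out/                 # full pipeline, default config
osteolattice fixture --out out/             # fixture STLs + node-set JSON
osteolattice generate --config cfg.yaml     # lattice JSON + implant STL
osteolattice analyze --out out/             # three-stage frequency reports
osteolattice optimize --out out/            # size-optimization loop + trace
osteolattice solve --stage G-T --out out/   # one stage, VTK result grid
```

Configuration is a flat YAML file (see `osteolattice.config.PipelineConfig`
for every key and default); missing keys take package defaults, and a
content hash of the full config is logged with every run. The pipeline is
deterministic: identical configs give byte-identical CSV outputs.

Note: the muscle *force magnitudes* and spring stiffnesses are published
values; the muscle *direction vectors* are fixture-defined placeholders
(the anatomical source data is not published alongside the magnitudes) and
can be overridden via `muscle_directions` in the config.

## Layout

```
src/osteolattice/
  geometry.py    triangle meshes: STL I/O, containment, slicing, distances
  fixtures.py    synthetic defect surrogate + analytic FE benchmarks
  lattice.py     unit cells, grid shell, gradient, fixation, Boolean graft
  materials.py   tissue/metal constants, muscle forces, load case
  fe.py          beam/voxel/spring assembly, sparse solve, stress recovery
  model.py       voxel classification + per-stage FE model building
  healing.py     stage sweep, frequency bins, criteria evaluation
  optimizer.py   hotspot detection, diameter update law, optimization loop
  config.py      PipelineConfig (YAML round-trip, hashing)
  pipeline.py    end-to-end artifact generation
  cli.py         click subcommands
```
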